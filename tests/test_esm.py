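"""Spreading-model dynamics, parameter fitting and epicenter search."""

import numpy as np
import pandas as pd
import pytest

import tauspread as ts
from conftest import tiny_random_system


def oracle_integrate(weights, seed_idx, beta, delta, t, x0, dt):
    """Independent fine-step reference integrator (naive loops)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    chat = np.zeros_like(w)
    for i in range(n):
        s = w[i].sum()
        if s > 0:
            chat[i] = w[i] / s
    x = np.zeros(n)
    for i in seed_idx:
        x[i] = x0
    for _ in range(int(round(t / dt))):
        influx = chat @ x
        x = x + dt * (beta * (1.0 - x) * influx - delta * x)
        x = np.minimum(1.0, np.maximum(0.0, x))
    return x


class TestForward:
    def test_closed_form_zero_connectivity(self):
        names = ["a", "b", "c"]
        zero = ts.Connectome(pd.DataFrame(np.zeros((3, 3)), index=names, columns=names))
        p = ts.ESMParameters(beta=0.0, delta=0.5, t_eff=2.0, x0=0.1)
        x = ts.esm_forward(zero, ["a"], p, dt=1e-4)
        assert abs(x[0] - 0.1 * np.exp(-1.0)) < 1e-6
        assert x[1] == 0 and x[2] == 0

    def test_frozen_dynamics(self):
        sys = tiny_random_system(5, 0)
        p = ts.ESMParameters(beta=0.0, delta=0.0, t_eff=10.0, x0=0.2)
        x = ts.esm_forward(sys, ["n0"], p)
        expect = np.zeros(5)
        expect[0] = 0.2
        assert np.allclose(x, expect)

    def test_complete_graph_saturates(self):
        n = 6
        w = np.ones((n, n)) - np.eye(n)
        names = [f"n{i}" for i in range(n)]
        c = ts.Connectome(pd.DataFrame(w, index=names, columns=names))
        p = ts.ESMParameters(beta=1.0, delta=0.0, t_eff=100.0, x0=0.1)
        x = ts.esm_forward(c, ["n0"], p)
        assert (x > 0.99).all()

    @pytest.mark.parametrize("n_nodes,seed", [(2, 1), (5, 2), (10, 3)])
    def test_matches_fine_step_oracle(self, n_nodes, seed):
        sys = tiny_random_system(n_nodes, seed)
        p = ts.ESMParameters(beta=1.0, delta=0.2, t_eff=10.0, x0=0.1)
        x = ts.esm_forward(sys, ["n0"], p, dt=0.01)
        ref = oracle_integrate(sys.weights.to_numpy(), [0], 1.0, 0.2, 10.0, 0.1, 1e-4)
        assert np.abs(x - ref).max() < 1e-3

    def test_trajectory_bounded(self):
        sys = tiny_random_system(8, 4)
        p = ts.ESMParameters(beta=2.5, delta=1.5, t_eff=30.0, x0=0.5)
        x, traj = ts.esm_forward(sys, ["n0", "n3"], p, return_trajectory=True)
        assert traj.min() >= 0 and traj.max() <= 1

    def test_unstable_step_raises(self):
        sys = tiny_random_system(4, 5)
        p = ts.ESMParameters(beta=3.0, delta=3.0, t_eff=10.0, x0=1.0)
        with pytest.raises(RuntimeError, match="unstable"):
            ts.esm_forward(sys, ["n0"], p, dt=1.0)

    def test_burden_monotone_in_rates(self):
        sys = tiny_random_system(8, 6)
        base = dict(t_eff=15.0, x0=0.1)
        burden = lambda b, d: ts.esm_forward(
            sys, ["n0"], ts.ESMParameters(beta=b, delta=d, **base)).sum()
        assert burden(1.0, 0.2) >= burden(0.5, 0.2)
        assert burden(0.5, 0.1) >= burden(0.5, 0.4)

    def test_balanced_rates_little_spread(self):
        # matched production and clearance with a small seed stays low
        sys = tiny_random_system(8, 7)
        p = ts.ESMParameters(beta=0.3, delta=0.3, t_eff=30.0, x0=0.05)
        x = ts.esm_forward(sys, ["n0"], p)
        assert x.sum() < 0.5

    def test_misaligned_epicenter(self):
        sys = tiny_random_system(3, 8)
        p = ts.ESMParameters(beta=1.0, delta=0.1, t_eff=5.0)
        with pytest.raises(KeyError):
            ts.esm_forward(sys, ["missing"], p)


class TestFitSubject:
    def test_grid_point_self_recovery(self):
        sys = tiny_random_system(8, 10)
        grid = ts.ParameterGrid(betas=(0.1, 0.5), deltas=(0.05, 0.2),
                                t_effs=(10, 20), dt=0.05)
        truth = ts.ESMParameters(beta=0.5, delta=0.2, t_eff=20.0, x0=0.1)
        obs = ts.esm_forward(sys, ["n0"], truth, dt=0.05)
        p, pred, r2, sse = ts.fit_subject(sys, ["n0"], obs, grid)
        assert (p.beta, p.delta, p.t_eff) == (0.5, 0.2, 20.0)
        assert sse < 1e-12
        assert r2 == pytest.approx(1.0)

    def test_all_zero_subject(self):
        sys = tiny_random_system(6, 11)
        grid = ts.ParameterGrid.coarse(n_rates=4, t_effs=(5, 20), dt=0.1)
        p, pred, r2, sse = ts.fit_subject(sys, ["n0"], np.zeros(6), grid)
        assert pred.sum() < 0.01
        assert r2 is None

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ts.ParameterGrid(betas=(), deltas=(0.1,), t_effs=(5,))

    def test_noise_robust_recovery(self):
        # chain topology gives a graded spatial pattern whose variance
        # dominates the observation noise
        n = 10
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        names = [f"n{i}" for i in range(n)]
        sys = ts.Connectome(pd.DataFrame(w, index=names, columns=names))
        rng = np.random.default_rng(0)
        truth = ts.ESMParameters(beta=0.4, delta=0.15, t_eff=15.0, x0=0.1)
        obs = ts.esm_forward(sys, ["n0"], truth, dt=0.01)
        obs = np.clip(obs + rng.normal(0, 0.05, obs.shape), 0, 1)
        grid = ts.ParameterGrid(
            betas=tuple(np.geomspace(0.01, 3, 12)),
            deltas=tuple(np.geomspace(0.01, 3, 12)),
            t_effs=tuple(range(5, 51, 5)), dt=0.05)
        p, pred, r2, sse = ts.fit_subject(sys, ["n0"], obs, grid)
        assert r2 > 0.8
        ratio = (p.beta / p.delta) / (truth.beta / truth.delta)
        assert 0.5 < ratio < 2.0


class TestFitCohort:
    def test_perfect_fit(self, connectome, coarse_grid):
        # observations generated exactly at grid points
        epi = ["L_entorhinal", "R_entorhinal"]
        rows = []
        for b, d, t in [(0.47, 0.18, 20.0), (0.18, 0.069, 30.0)]:
            rows.append(ts.esm_forward(
                connectome, epi, ts.ESMParameters(b, d, t), dt=coarse_grid.dt))
        obs = pd.DataFrame(rows, index=["s0", "s1"], columns=connectome.region_names)
        grid = ts.ParameterGrid(
            betas=(0.47, 0.18), deltas=(0.18, 0.069), t_effs=(20, 30), dt=coarse_grid.dt)
        fit = ts.fit_cohort(obs, connectome, epi, grid)
        assert fit.global_r2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.individual_r2, 1.0)

    def test_singleton_reduction(self, connectome, coarse_grid):
        epi = ["L_entorhinal", "R_entorhinal"]
        x = ts.esm_forward(connectome, epi,
                           ts.ESMParameters(0.4, 0.15, 20.0), dt=coarse_grid.dt)
        rng = np.random.default_rng(1)
        x = np.clip(x + rng.normal(0, 0.03, x.shape), 0, 1)
        obs = pd.DataFrame([x], index=["s0"], columns=connectome.region_names)
        fit = ts.fit_cohort(obs, connectome, epi, coarse_grid)
        assert fit.global_r2 == pytest.approx(fit.individual_r2[0])

    def test_probability_matrix_required(self, connectome, coarse_grid):
        obs = pd.DataFrame(np.full((2, 66), 1.5), columns=connectome.region_names)
        with pytest.raises(ValueError):
            ts.fit_cohort(obs, connectome, ["L_entorhinal"], coarse_grid)


class TestEpicenterSearch:
    def test_planted_pair_ranks_first(self, regions66, connectome):
        cohort = ts.simulate_cohort(regions66, connectome,
                                    ts.epicenter_ranking_spec("entorhinal"), seed=7)
        ranking = ts.epicenter_search(
            cohort.ground_truth.probabilities, connectome,
            regions=regions66, mode="homotopic_pairs",
            grid=ts.ParameterGrid.coarse())
        assert len(ranking) == 33
        assert ranking.iloc[0]["left"] == "L_entorhinal"

    def test_relabeling_equivariance(self, regions66):
        # permute region order; rankings must identify the same pairs
        conn = ts.simulate_connectome(regions66, seed=2)
        co = ts.simulate_cohort(regions66, conn, ts.recovery_benchmark_spec(n=10), seed=5)
        grid = ts.ParameterGrid.coarse(n_rates=4, t_effs=(10, 25), dt=0.1)
        rank0 = ts.epicenter_search(co.ground_truth.probabilities, conn,
                                    regions=regions66, mode="homotopic_pairs", grid=grid)
        perm = np.random.default_rng(0).permutation(len(regions66))
        names_p = [list(regions66["name"])[i] for i in perm]
        regions_p = regions66.set_index("name").loc[names_p].reset_index()
        conn_p = ts.Connectome(conn.weights.loc[names_p, names_p],
                               modality=conn.modality)
        obs_p = co.ground_truth.probabilities[names_p]
        rank1 = ts.epicenter_search(obs_p, conn_p, regions=regions_p,
                                    mode="homotopic_pairs", grid=grid)
        order0 = list(zip(rank0["left"], rank0["right"]))
        order1 = [tuple(sorted(p, key=lambda n: n[0] != "L")) for p in
                  zip(rank1["left"], rank1["right"])]
        assert order0 == order1

    def test_per_subject_grid_point_classification(self, regions66, connectome):
        # subjects simulated exactly at grid nodes from unilateral limbic seeds
        grid = ts.ParameterGrid.coarse(n_rates=5, t_effs=(10, 20), dt=0.05)
        seeds = [["L_hippocampus"], ["R_entorhinal"], ["L_entorhinal"]]
        rows = []
        for s in seeds:
            x = ts.esm_forward(connectome, s,
                               ts.ESMParameters(grid.betas[3], grid.deltas[2], 20.0),
                               dt=grid.dt)
            rows.append(x)
        obs = pd.DataFrame(rows, index=["s0", "s1", "s2"],
                           columns=connectome.region_names)
        per = ts.epicenter_search(obs, connectome, regions=regions66,
                                  mode="per_subject", grid=grid)
        assert list(per["epicenter_class"]) == ["left-limbic", "right-limbic", "left-limbic"]
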