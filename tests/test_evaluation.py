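"""Fit summaries, null significance, residual/asymmetry reports, staging,
matching."""

import numpy as np
import pandas as pd
import pytest

import tauspread as ts


class TestRSquared:
    @pytest.mark.parametrize(
        "x,y,expect",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], 1.0),  # squared anticorrelation
            ([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8], None),
        ],
    )
    def test_values(self, x, y, expect):
        r2 = ts.r_squared(x, y)
        if expect is not None:
            assert r2 == pytest.approx(expect)
        else:
            assert 0.9 < r2 < 1.0

    def test_zero_variance_undefined(self):
        assert ts.r_squared([1, 1, 1], [1, 2, 3]) is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ts.r_squared([1, 2], [1, 2, 3])


class TestNullSignificance:
    def _fit_and_stats(self, connectome, matrix, ensemble, grid):
        epi = ["L_entorhinal", "R_entorhinal"]
        obs = ts.fit_cohort(matrix, connectome, epi, grid).global_r2
        return ts.null_significance(obs, matrix, ensemble, epi, grid)

    def test_p_floor_when_observed_exceeds_all(self, regions66, connectome,
                                               benchmark_cohort):
        grid = ts.ParameterGrid.coarse(n_rates=5, t_effs=(10, 25, 40), dt=0.1)
        ensemble = ts.generate_nulls(connectome, n=25, seed=1)
        sig = self._fit_and_stats(connectome, benchmark_cohort.ground_truth.probabilities,
                                  ensemble, grid)
        assert sig.p_value >= 1.0 / 25
        # strong planted signal should beat the nulls
        assert sig.observed > sig.null_mean

    def test_counting_convention(self):
        # constructed null vector: observed at the median of 101 nulls
        nulls = np.linspace(0, 1, 101)
        observed = 0.5
        p = max(float((nulls >= observed).sum()) / len(nulls), 1 / len(nulls))
        assert p == pytest.approx(51 / 101)

    def test_p_bounds_contract(self):
        sig = ts.NullSignificance(observed=0.0, null_values=np.ones(100),
                                  null_mean=1.0, ci95=(1, 1), p_value=1.0, n_null=100)
        assert 1.0 / sig.n_null <= sig.p_value <= 1.0


class TestSummarizeFit:
    def test_perfect_fit_all_ones(self, connectome):
        rng = np.random.default_rng(0)
        obs = pd.DataFrame(rng.random((6, 66)), columns=connectome.region_names,
                           index=[f"s{i}" for i in range(6)])
        fit = ts.ESMFit(
            epicenter=["L_entorhinal"], subject_ids=list(obs.index),
            params=[None] * 6, predicted=obs.copy(),
            individual_r2=np.ones(6), sse=np.zeros(6), global_r2=1.0,
            observed_mean=obs.mean(axis=0).to_numpy(),
            predicted_mean=obs.mean(axis=0).to_numpy(),
        )
        ts.attach_observed(fit, obs)
        summary = ts.summarize_fit(fit, strata=["a"] * 3 + ["b"] * 3)
        assert summary.global_r2 == 1.0
        assert summary.mean_individual_r2 == 1.0
        assert np.allclose(summary.strata["global_r2"].to_numpy(), 1.0)

    def test_identical_strata_identical_summaries(self, connectome):
        rng = np.random.default_rng(1)
        half = rng.random((4, 66))
        obs = pd.DataFrame(np.vstack([half, half]), columns=connectome.region_names,
                           index=[f"s{i}" for i in range(8)])
        pred = obs * 0.9
        fit = ts.ESMFit(
            epicenter=["L_entorhinal"], subject_ids=list(obs.index),
            params=[None] * 8, predicted=pred,
            individual_r2=np.full(8, 0.81), sse=np.zeros(8), global_r2=0.9,
            observed_mean=obs.mean(axis=0).to_numpy(),
            predicted_mean=pred.mean(axis=0).to_numpy(),
        )
        ts.attach_observed(fit, obs)
        summary = ts.summarize_fit(fit, strata=["a"] * 4 + ["b"] * 4)
        g = summary.strata.set_index("stratum")["global_r2"]
        assert g["a"] == pytest.approx(g["b"])


class TestAmyloidResidual:
    def test_degenerate_zero_residuals(self, connectome):
        obs = pd.DataFrame(np.full((4, 66), 0.3), columns=connectome.region_names,
                           index=[f"s{i}" for i in range(4)])
        fit = ts.ESMFit(
            epicenter=[], subject_ids=list(obs.index), params=[None] * 4,
            predicted=obs.copy(), individual_r2=np.full(4, np.nan),
            sse=np.zeros(4), global_r2=0.0,
        )
        rep = ts.amyloid_residual_report(fit, obs, obs)
        assert rep.degenerate

    def test_planted_amyloid_signal_recovered(self, regions66, connectome):
        co = ts.simulate_cohort(regions66, connectome,
                                ts.recovery_benchmark_spec(n=60), seed=9)
        grid = ts.ParameterGrid.coarse(n_rates=8, t_effs=(5, 15, 25, 35, 45), dt=0.05)
        obs = co.tau_probability_truth
        fit = ts.fit_cohort(obs, connectome, ["L_entorhinal", "R_entorhinal"], grid)
        rep = ts.amyloid_residual_report(fit, obs, _amyloid_probabilities(co))
        assert rep.t_stat > 0 and rep.t_p < 0.05
        assert rep.corr_r > 0 and rep.corr_p < 0.05
        classified = set(rep.table["classification"])
        assert classified <= {"underestimated", "overestimated"}
        # exhaustive and exclusive classification
        assert rep.table["classification"].notna().all()


def _amyloid_probabilities(cohort, seed=0):
    """Amyloid-positive probability matrix mirroring the generator: high in
    the vulnerable set for amyloid-positive subjects, low noisy background
    elsewhere."""
    names = list(cohort.tau_probability_truth.columns)
    vuln = [n for n in names
            if n.split("_", 1)[1] in ts.synthetic_data.AMYLOID_VULNERABLE_BASES]
    pos = (cohort.subjects["amyloid_status"] == "pos").to_numpy()
    rng = np.random.default_rng(seed)
    amy = rng.beta(1.0, 12.0, size=(len(cohort.subjects), len(names)))
    amy[np.ix_(pos, [names.index(v) for v in vuln])] = rng.beta(
        8.0, 2.5, size=(int(pos.sum()), len(vuln)))
    return pd.DataFrame(amy, index=cohort.tau_probability_truth.index, columns=names)


class TestAsymmetry:
    def test_symmetric_subject_zero_laterality(self, regions66):
        names = list(regions66["name"])
        vals = pd.DataFrame(np.full((1, 66), 0.4), columns=names, index=["s0"])
        lat = ts.laterality_index(vals, regions66)
        assert lat.iloc[0] == pytest.approx(0.0)

    def test_left_seeded_cohort_recovered(self, regions66, connectome):
        spec = ts.lateralization_benchmark_spec(n=80)
        spec.lateralized = False
        spec.epicenter_bases = ("entorhinal",)
        # simulate all-left seeds by post-hoc class assignment from truth
        spec.lateralized = True
        co = ts.simulate_cohort(regions66, connectome, spec, seed=17)
        cls = ["left-limbic" if e[0].startswith("L") else "right-limbic"
               for e in co.ground_truth.epicenters]
        per = pd.DataFrame({"subject": co.subjects["subject_id"],
                            "epicenter_class": cls})
        rep = ts.asymmetry_report(per, co.ground_truth.probabilities,
                                  regions66, co.subjects)
        row = rep.covariate_glms[rep.covariate_glms["outcome"] == "laterality"].iloc[0]
        assert row["coef"] > 0
        assert row["p"] < 0.01

    def test_bh_fdr_textbook_example(self):
        # hand-computed BH q-values for 5 p-values
        p = np.array([0.01, 0.04, 0.03, 0.005, 0.5])
        q, rej = ts.bh_fdr(p, alpha=0.05)
        # sorted: .005 .01 .03 .04 .5 -> raw q: .025 .025 .05 .05 .5
        assert q[np.argsort(p)] == pytest.approx([0.025, 0.025, 0.05, 0.05, 0.5])
        assert rej[:4].all() and not rej[4]


class TestBraakStageSummary:
    def test_staged_progression_ordering(self, regions66, mixed_cohort):
        # entorhinal-seeded spread reproduces the staged ordering: stage-ROI
        # population means decrease with stage (medial temporal stages may
        # nearly tie once both saturate)
        from scipy.stats import spearmanr

        stage_means, _, order = ts.braak_stage_summary(
            mixed_cohort.ground_truth.probabilities, regions66)
        pop = stage_means.mean(axis=0).to_numpy()
        rho = spearmanr(pop, np.arange(1, 7)).statistic
        assert rho < -0.9
        # subjects are ordered from least to most total burden
        totals = mixed_cohort.ground_truth.probabilities.sum(axis=1)
        assert (totals.loc[order].diff().dropna() >= 0).all()

    def test_threshold_maps_nested(self, regions66, benchmark_cohort):
        _, maps, _ = ts.braak_stage_summary(
            benchmark_cohort.ground_truth.probabilities, regions66)
        cols = list(maps.columns)
        for hi, lo in zip(cols, cols[1:]):
            assert (maps[lo] | ~maps[hi]).all()  # hi-threshold set ⊆ lo set

    def test_single_hot_region_in_all_maps(self, regions66):
        names = list(regions66["name"])
        vals = np.zeros((3, 66))
        vals[:, 5] = 0.5
        frame = pd.DataFrame(vals, columns=names, index=["a", "b", "c"])
        _, maps, _ = ts.braak_stage_summary(frame, regions66)
        assert maps.loc[names[5]].all()
        assert maps.drop(index=names[5]).to_numpy().sum() == 0

    def test_thresholds_must_decrease(self, regions66, benchmark_cohort):
        with pytest.raises(ValueError):
            ts.braak_stage_summary(benchmark_cohort.ground_truth.probabilities,
                                   regions66, thresholds=(0.1, 0.2))


class TestMatchCohorts:
    def test_exact_copies_selected(self):
        rng = np.random.default_rng(0)
        ref = pd.DataFrame({"age": rng.normal(70, 5, 20),
                            "education": rng.normal(14, 3, 20)})
        pool = pd.concat([ref, ref + rng.normal(0, 5, ref.shape)],
                         ignore_index=True)
        chosen = ts.match_cohorts(ref, pool, ["age", "education"])
        assert chosen == list(range(20))

    def test_without_replacement_contract(self):
        rng = np.random.default_rng(1)
        ref = pd.DataFrame({"age": rng.normal(70, 5, 30)})
        pool = pd.DataFrame({"age": rng.normal(70, 5, 100)})
        chosen = ts.match_cohorts(ref, pool, ["age"])
        assert len(chosen) == 30
        assert len(set(chosen)) == 30

    def test_matches_brute_force_greedy(self):
        rng = np.random.default_rng(2)
        ref = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        pool = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        chosen = ts.match_cohorts(ref, pool, ["a", "b"])
        # oracle: explicit greedy walk over the full z-scored distance matrix
        comb = pd.concat([ref, pool], ignore_index=True)
        mu, sd = comb.mean(), comb.std(ddof=0)
        rz = ((ref - mu) / sd).to_numpy()
        pz = ((pool - mu) / sd).to_numpy()
        expect, used = [], set()
        for r in rz:
            d = np.sqrt(((pz - r) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")
            j = next(int(k) for k in order if int(k) not in used)
            used.add(j)
            expect.append(j)
        assert chosen == expect

    def test_pool_too_small(self):
        ref = pd.DataFrame({"a": [1.0, 2.0]})
        pool = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            ts.match_cohorts(ref, pool, ["a"])
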