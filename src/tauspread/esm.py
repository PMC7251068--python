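"""Epidemic spreading model (ESM) of pathology propagation on a connectome.

The model simulates the diffusion of a pathological signal (here, the
probability of abnormal tau) from an epicenter through a weighted region x
region connectivity system.  Regional state ``X_i(t)`` in [0, 1] evolves as

    dX_i/dt = beta * (1 - X_i) * sum_j Chat_ij X_j  -  delta * X_i

where ``Chat`` is the row-normalized connectome (rows sum to 1 where
nonzero), ``beta`` is a global production rate (1/year) scaling how strongly
connectivity-weighted neighbor burden seeds the remaining regional capacity
``(1 - X_i)``, and ``delta`` is a first-order clearance rate (1/year).  A
balance of production and clearance produces little to no spreading; an
imbalance accelerates spread.

Subject-level parameters (beta, delta, effective spreading duration t_eff)
are fit by exhaustive simulation over a parameter grid, selecting the
parameter set whose simulated terminal pattern most closely approximates the
observed regional probabilities (minimum sum of squared errors).  Model
accuracy is summarized as the squared Pearson correlation (r^2) between
predicted and observed regional values, within subject and globally on the
subject-mean patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectomics import Connectome
from .evaluation import r_squared

DEFAULT_DT = 0.01
DEFAULT_X0 = 0.1
#: maximum per-step state change allowed before the integrator aborts
STABILITY_LIMIT = 0.5


@dataclass(frozen=True)
class ESMParameters:
    """Subject-level ESM parameters.

    beta, delta in 1/year; t_eff in years (scan age minus onset age);
    x0 is the epicenter seed amplitude in probability units.
    """

    beta: float
    delta: float
    t_eff: float
    x0: float = DEFAULT_X0

    def __post_init__(self):
        if self.beta < 0 or self.delta < 0:
            raise ValueError("beta and delta must be nonnegative")
        if self.t_eff <= 0:
            raise ValueError("t_eff must be positive")
        if not (0 < self.x0 <= 1):
            raise ValueError("x0 must be in (0, 1]")


@dataclass(frozen=True)
class ParameterGrid:
    """Grid over which subject parameters are searched.

    Defaults: 20 log-spaced production/clearance values in [0.01, 3] plus 0,
    effective durations 5..50 years in steps of 5, seed amplitude 0.1 (not
    fit).  These are package defaults chosen to cover slow to aggressive
    spreading; they are configurable.
    """

    betas: tuple = tuple([0.0] + list(np.geomspace(0.01, 3.0, 20)))
    deltas: tuple = tuple([0.0] + list(np.geomspace(0.01, 3.0, 20)))
    t_effs: tuple = tuple(range(5, 51, 5))
    x0: float = DEFAULT_X0
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if not (self.betas and self.deltas and self.t_effs):
            raise ValueError("empty parameter grid")

    @classmethod
    def coarse(cls, n_rates: int = 10,
               t_effs=(5, 10, 15, 20, 25, 30, 35, 40, 45), dt: float = 0.05):
        """Reduced-resolution grid for large searches (e.g. epicenter scans).

        Ten log-spaced rates keep enough resolution to separate adjacent
        candidate epicenters; coarser grids blur near-equivalent seeds.
        """
        rates = tuple([0.0] + list(np.geomspace(0.01, 3.0, n_rates)))
        return cls(betas=rates, deltas=rates, t_effs=tuple(t_effs), dt=dt)


@dataclass
class ESMFit:
    """Result of fitting the ESM to a cohort."""

    epicenter: list
    subject_ids: list
    params: list  # per-subject ESMParameters
    predicted: pd.DataFrame  # subjects x regions
    individual_r2: np.ndarray  # nan where undefined
    sse: np.ndarray
    global_r2: float
    observed_mean: np.ndarray = field(default=None, repr=False)
    predicted_mean: np.ndarray = field(default=None, repr=False)

    @property
    def mean_individual_r2(self) -> float:
        vals = self.individual_r2[~np.isnan(self.individual_r2)]
        return float(vals.mean()) if vals.size else float("nan")


def row_normalize(weights: np.ndarray) -> np.ndarray:
    """Scale each row to sum to 1 (rows of all zeros stay zero)."""
    w = np.asarray(weights, dtype=float)
    sums = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, w / sums, 0.0)
    return out


def _epicenter_indices(connectome: Connectome, epicenter) -> np.ndarray:
    names = list(connectome.region_names)
    idx = []
    for e in epicenter:
        if isinstance(e, str):
            if e not in names:
                raise KeyError(f"epicenter region {e!r} not in connectome")
            idx.append(names.index(e))
        else:
            i = int(e)
            if not (0 <= i < len(names)):
                raise KeyError(f"epicenter index {i} out of range")
            idx.append(i)
    if not idx:
        raise ValueError("epicenter must be non-empty")
    return np.asarray(idx)


def esm_forward(
    connectome: Connectome,
    epicenter,
    params: ESMParameters,
    dt: float = DEFAULT_DT,
    return_trajectory: bool = False,
):
    """Integrate the ESM from an epicenter seed for ``params.t_eff`` years.

    Explicit Euler with post-step clamping to [0, 1].  Raises RuntimeError
    if any single step changes a regional state by more than 0.5 (unstable
    step size for the given rates).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    idx = _epicenter_indices(connectome, epicenter)
    chat = row_normalize(connectome.weights.to_numpy())
    n = chat.shape[0]
    x = np.zeros(n)
    x[idx] = params.x0
    n_steps = int(round(params.t_eff / dt))
    traj = [x.copy()] if return_trajectory else None
    for _ in range(n_steps):
        influx = chat @ x
        dx = dt * (params.beta * (1.0 - x) * influx - params.delta * x)
        if np.max(np.abs(dx)) > STABILITY_LIMIT:
            raise RuntimeError(
                "integration unstable: per-step change exceeds 0.5; reduce dt"
            )
        x = np.clip(x + dx, 0.0, 1.0)
        if return_trajectory:
            traj.append(x.copy())
    if return_trajectory:
        return x, np.asarray(traj)
    return x


def _grid_predictions(connectome: Connectome, epicenter, grid: ParameterGrid):
    """Simulate every (beta, delta) pair once, batched, recording the state
    at each requested t_eff.

    Predictions are subject-independent, so they are shared across the whole
    cohort.  Returns (param_list, predictions) where predictions has shape
    (n_candidates, n_regions) aligned with param_list.
    """
    idx = _epicenter_indices(connectome, epicenter)
    chat = row_normalize(connectome.weights.to_numpy())
    n = chat.shape[0]
    combos = [(b, d) for b in grid.betas for d in grid.deltas]
    betas = np.array([c[0] for c in combos])[:, None]
    deltas = np.array([c[1] for c in combos])[:, None]
    x = np.zeros((len(combos), n))
    x[:, idx] = grid.x0
    t_effs = sorted(grid.t_effs)
    checkpoints = {int(round(t / grid.dt)): t for t in t_effs}
    n_steps = max(checkpoints)
    params, preds = [], []
    chat_t = chat.T.copy()
    for step in range(1, n_steps + 1):
        influx = x @ chat_t
        dx = grid.dt * (betas * (1.0 - x) * influx - deltas * x)
        if np.max(np.abs(dx)) > STABILITY_LIMIT:
            raise RuntimeError(
                "integration unstable: per-step change exceeds 0.5; reduce dt"
            )
        x = np.clip(x + dx, 0.0, 1.0)
        if step in checkpoints:
            t = checkpoints[step]
            for (b, d), row in zip(combos, x):
                params.append(ESMParameters(b, d, float(t), grid.x0))
            preds.append(x.copy())
    return params, np.concatenate(preds, axis=0)


def fit_subject(
    connectome: Connectome,
    epicenter,
    observed: np.ndarray,
    grid: ParameterGrid = None,
    _precomputed=None,
):
    """Exhaustive grid search for one subject's best-fitting parameters.

    Returns (ESMParameters, predicted vector, r2 (nan if undefined), SSE).
    """
    grid = grid or ParameterGrid()
    observed = np.asarray(observed, dtype=float)
    if observed.min() < 0 or observed.max() > 1:
        raise ValueError("observed values must lie in [0, 1]")
    if _precomputed is None:
        _precomputed = _grid_predictions(connectome, epicenter, grid)
    params, preds = _precomputed
    sse = ((preds - observed[None, :]) ** 2).sum(axis=1)
    best = int(np.argmin(sse))
    pred = preds[best]
    r2 = r_squared(pred, observed)
    return params[best], pred, r2, float(sse[best])


def fit_cohort(
    matrix,
    connectome: Connectome,
    epicenter,
    grid: ParameterGrid = None,
    _precomputed=None,
) -> ESMFit:
    """Fit the ESM independently to every subject of a probability matrix.

    ``matrix`` is a RegionalMatrix (or plain DataFrame) of subjects x
    regions with values in [0, 1].  Global r^2 is the squared Pearson
    correlation between the subject-mean predicted and subject-mean observed
    regional vectors.
    """
    grid = grid or ParameterGrid()
    values = _matrix_frame(matrix)
    obs = values.to_numpy(dtype=float)
    if obs.min() < 0 or obs.max() > 1:
        raise ValueError("fit_cohort requires a probability matrix in [0, 1]")
    pre = _precomputed or _grid_predictions(connectome, epicenter, grid)
    fitted, preds, r2s, sses = [], [], [], []
    for row in obs:
        p, pred, r2, sse = fit_subject(connectome, epicenter, row, grid, _precomputed=pre)
        fitted.append(p)
        preds.append(pred)
        r2s.append(np.nan if r2 is None else r2)
        sses.append(sse)
    pred_arr = np.asarray(preds)
    obs_mean = obs.mean(axis=0)
    pred_mean = pred_arr.mean(axis=0)
    g = r_squared(pred_mean, obs_mean)
    return ESMFit(
        epicenter=list(epicenter),
        subject_ids=list(values.index),
        params=fitted,
        predicted=pd.DataFrame(pred_arr, index=values.index, columns=values.columns),
        individual_r2=np.asarray(r2s, dtype=float),
        sse=np.asarray(sses),
        global_r2=0.0 if g is None else g,
        observed_mean=obs_mean,
        predicted_mean=pred_mean,
    )


def _matrix_frame(matrix) -> pd.DataFrame:
    return matrix if isinstance(matrix, pd.DataFrame) else matrix.data


def epicenter_search(
    matrix,
    connectome: Connectome,
    regions: pd.DataFrame = None,
    mode: str = "homotopic_pairs",
    grid: ParameterGrid = None,
):
    """Search for the best-fitting epicenter.

    mode='homotopic_pairs': fit the cohort once per left-right pair and rank
    pairs by global r^2 (ties broken by mean individual r^2, then pair
    index).  Returns a DataFrame ranking.

    mode='per_subject': find each subject's best single-region epicenter (by
    SSE) and classify it as left-limbic / right-limbic / other using the
    region table's limbic and hemisphere flags.  Returns a DataFrame with
    one row per subject.
    """
    from .synthetic_data import homotopic_pairs  # late import to avoid cycle

    grid = grid or ParameterGrid.coarse()
    frame = _matrix_frame(matrix)
    if mode == "homotopic_pairs":
        if regions is None:
            raise ValueError("homotopic_pairs mode requires a region table")
        pairs = homotopic_pairs(regions, names=list(frame.columns))
        rows = []
        for i, (left, right) in enumerate(pairs):
            fit = fit_cohort(frame, connectome, [left, right], grid)
            rows.append(
                {
                    "pair_index": i,
                    "left": left,
                    "right": right,
                    "global_r2": fit.global_r2,
                    "mean_individual_r2": fit.mean_individual_r2,
                }
            )
        ranking = pd.DataFrame(rows).sort_values(
            ["global_r2", "mean_individual_r2", "pair_index"],
            ascending=[False, False, True],
        )
        ranking["rank"] = np.arange(1, len(ranking) + 1)
        return ranking.reset_index(drop=True)
    if mode == "per_subject":
        if regions is None:
            raise ValueError("per_subject mode requires a region table")
        obs = frame.to_numpy(dtype=float)
        names = list(frame.columns)
        n_sub = obs.shape[0]
        best_sse = np.full(n_sub, np.inf)
        best_region = np.empty(n_sub, dtype=object)
        best_r2 = np.full(n_sub, np.nan)
        for name in names:
            pre = _grid_predictions(connectome, [name], grid)
            _, preds = pre
            sse = ((preds[None, :, :] - obs[:, None, :]) ** 2).sum(axis=2)
            cand = sse.min(axis=1)
            improved = cand < best_sse
            if improved.any():
                arg = sse.argmin(axis=1)
                for s in np.where(improved)[0]:
                    best_sse[s] = cand[s]
                    best_region[s] = name
                    r2 = r_squared(preds[arg[s]], obs[s])
                    best_r2[s] = np.nan if r2 is None else r2
        info = regions.set_index("name")
        classes = []
        for name in best_region:
            row = info.loc[name]
            if bool(row["limbic"]):
                classes.append("left-limbic" if row["hemisphere"] == "L" else "right-limbic")
            else:
                classes.append("other")
        return pd.DataFrame(
            {
                "subject": list(frame.index),
                "epicenter": best_region,
                "epicenter_class": classes,
                "sse": best_sse,
                "r2": best_r2,
            }
        )
    raise ValueError(f"unknown mode {mode!r}")
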