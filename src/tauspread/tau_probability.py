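"""Conversion of regional SUVR matrices into spreading-model-ready values.

Tau-PET SUVR signal mixes target (pathological tau) and off-target binding.
Across a population, off-target signal in a region is roughly normally
distributed while genuine pathology produces a second, right-shifted mode.
Per region, one- and two-component Gaussian mixtures are fit across the
population and compared by AIC; where the two-component model wins, each
subject's SUVR is converted to the posterior probability of the upper
(abnormal) component, evaluated out-of-fold under repeated five-fold
cross-validation.  Alternatives: per-region min-max scaling, and a
reference-region bootstrap ECDF (probability that a value exceeds the
maximum of resampled reference values).  Confounds (age, sex, choroid-plexus
signal) can be regressed out beforehand, either across all subjects
(residualization) or against an amyloid-negative cognitively normal
reference group (W-scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

CONFOUND_COLUMNS = ("age", "sex", "choroid_plexus")


@dataclass
class RegionalMatrix:
    """Subjects x regions value matrix with provenance of how the values
    were produced (transformation, confound strategy, PVC flag, region set)."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("regional matrix must not contain missing values")

    @property
    def subjects(self):
        return list(self.data.index)

    @property
    def regions(self):
        return list(self.data.columns)

    def with_data(self, data: pd.DataFrame, **prov) -> "RegionalMatrix":
        newprov = dict(self.provenance)
        newprov.update(prov)
        return RegionalMatrix(data=data, provenance=newprov)


@dataclass
class MixtureFit:
    region: str
    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    aic_1: float
    aic_2: float
    bimodal: bool
    upper_component_index: int


def _as_frame(matrix) -> pd.DataFrame:
    return matrix if isinstance(matrix, pd.DataFrame) else matrix.data


def regress_confounds(suvr, covariates: pd.DataFrame, strategy: str = "residualize",
                      reference_group=None) -> RegionalMatrix:
    """Remove confound effects from each region separately.

    residualize: per-region OLS of SUVR on age, sex and choroid-plexus
    signal across all subjects; output is residual plus the regional grand
    mean (keeps values on the SUVR scale for mixture fitting).

    wscore: the same model fit on the reference group only (amyloid-negative
    cognitively normal); output is (observed - predicted) / SD of reference
    residuals.
    """
    frame = _as_frame(suvr)
    prov = suvr.provenance if isinstance(suvr, RegionalMatrix) else {}
    if strategy == "none":
        return RegionalMatrix(frame.copy(), {**prov, "confound_strategy": "none"})
    if strategy not in ("residualize", "wscore"):
        raise ValueError(f"unknown strategy {strategy!r}")
    cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
    cov = cov.loc[list(frame.index)]
    for c in CONFOUND_COLUMNS:
        if c not in cov.columns or cov[c].isna().any():
            raise ValueError(f"covariate {c!r} missing or incomplete")
    X = np.column_stack([
        np.ones(len(frame)),
        cov["age"].to_numpy(dtype=float),
        cov["sex"].to_numpy(dtype=float),
        cov["choroid_plexus"].to_numpy(dtype=float),
    ])
    y = frame.to_numpy(dtype=float)
    if strategy == "residualize":
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient covariates")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        out = resid + y.mean(axis=0, keepdims=True)
        return RegionalMatrix(
            pd.DataFrame(out, index=frame.index, columns=frame.columns),
            {**prov, "confound_strategy": "residualize"},
        )
    # wscore
    if reference_group is None:
        raise ValueError("wscore requires a reference_group mask")
    ref_mask = np.asarray(reference_group, dtype=bool)
    if ref_mask.sum() == 0:
        raise ValueError("empty reference group")
    Xr, yr = X[ref_mask], y[ref_mask]
    if np.linalg.matrix_rank(Xr) < Xr.shape[1]:
        raise ValueError("rank-deficient covariates in reference group")
    beta, *_ = np.linalg.lstsq(Xr, yr, rcond=None)
    ref_resid = yr - Xr @ beta
    sd = ref_resid.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan
    w = (y - X @ beta) / sd
    if np.isnan(w).any():
        raise ValueError("zero reference residual variance in some region")
    return RegionalMatrix(
        pd.DataFrame(w, index=frame.index, columns=frame.columns),
        {**prov, "confound_strategy": "wscore"},
    )


def _fit_gmm(x: np.ndarray, n_components: int, seed: int, n_restarts: int = 10):
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=n_restarts,
        init_params="k-means++",
        reg_covar=1e-6,
        random_state=seed,
        max_iter=500,
    )
    gm.fit(x)
    if not gm.converged_:
        raise RuntimeError(f"EM did not converge for {n_components}-component model")
    return gm


def fit_region_mixture(values, seed: int = 0, region: str = "", min_n: int = 50) -> MixtureFit:
    """Fit one- and two-component Gaussian mixtures to one region's values
    across the population; compare by AIC; components sorted by mean.

    AIC parameter counts follow the standard univariate bookkeeping: 2 for
    the one-component model, 5 for the two-component model.  Bimodality is
    declared by strict inequality AIC_2 < AIC_1.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    x = x[np.isfinite(x[:, 0])]
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} finite values, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: zero variance")
    g1 = _fit_gmm(x, 1, seed)
    g2 = _fit_gmm(x, 2, seed)
    aic_1, aic_2 = float(g1.aic(x)), float(g2.aic(x))
    means = g2.means_.ravel()
    sds = np.sqrt(g2.covariances_.ravel())
    weights = g2.weights_.ravel()
    order = np.argsort(means)
    return MixtureFit(
        region=region,
        n_components=2,
        means=means[order],
        sds=sds[order],
        weights=weights[order],
        aic_1=aic_1,
        aic_2=aic_2,
        bimodal=aic_2 < aic_1,
        upper_component_index=1,
    )


def posterior_upper(x, fit: MixtureFit) -> np.ndarray:
    """Posterior probability that each value belongs to the fit's upper
    (right-most) component."""
    from scipy.stats import norm

    x = np.asarray(x, dtype=float)
    lo = fit.weights[0] * norm.pdf(x, fit.means[0], fit.sds[0])
    hi = fit.weights[1] * norm.pdf(x, fit.means[1], fit.sds[1])
    total = lo + hi
    out = np.where(total > 0, hi / np.where(total > 0, total, 1.0), x > fit.means.mean())
    return np.clip(out.astype(float), 0.0, 1.0)


def _cv_posteriors(x: np.ndarray, folds: int, repeats: int, rng: np.random.Generator,
                   seed_pool) -> np.ndarray:
    """Mean held-out posterior over repeated k-fold splits."""
    n = len(x)
    acc = np.zeros(n)
    for rep in range(repeats):
        perm = rng.permutation(n)
        fold_ids = np.array_split(perm, folds)
        for f, test_idx in enumerate(fold_ids):
            train_idx = np.setdiff1d(perm, test_idx)
            sub_seed = int(next(seed_pool))
            g2 = _fit_gmm(x[train_idx].reshape(-1, 1), 2, sub_seed)
            means = g2.means_.ravel()
            order = np.argsort(means)
            fit = MixtureFit(
                region="", n_components=2, means=means[order],
                sds=np.sqrt(g2.covariances_.ravel())[order],
                weights=g2.weights_.ravel()[order],
                aic_1=np.nan, aic_2=np.nan, bimodal=True, upper_component_index=1,
            )
            acc[test_idx] += posterior_upper(x[test_idx], fit)
    return acc / repeats


def mixture_probability_transform(suvr, folds: int = 5, repeats: int = 10,
                                  seed: int = 0, min_n: int = 50):
    """Convert a SUVR matrix to tau-positive probabilities region by region.

    For each region and each repeat, two-component mixtures are fit on the
    training folds and the posterior probability of the upper component is
    evaluated on the held-out fold; a subject's value is the mean over
    repeats.  Bimodality (and the reported component parameters) come from
    the full-sample fit.  Unimodal regions are still transformed (forced
    two-component fit) and flagged; dropping them is a region-set decision.
    """
    frame = _as_frame(suvr)
    n = len(frame)
    if n < folds:
        raise ValueError("not enough subjects for the requested folds")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    seed_pool = iter(ss.generate_state(200_000) % (2**31 - 1))
    fits, cols = [], {}
    failures = {}
    for region in frame.columns:
        x = frame[region].to_numpy(dtype=float)
        try:
            fit = fit_region_mixture(x, seed=int(next(seed_pool)), region=region,
                                     min_n=min_n)
            probs = _cv_posteriors(x, folds, repeats, rng, seed_pool)
        except (ValueError, RuntimeError) as err:
            failures[region] = str(err)
            continue
        fits.append(fit)
        cols[region] = np.clip(probs, 0.0, 1.0)
    if failures:
        raise RuntimeError(f"mixture fits failed for regions: {failures}")
    prov = suvr.provenance if isinstance(suvr, RegionalMatrix) else {}
    out = RegionalMatrix(
        pd.DataFrame(cols, index=frame.index)[list(frame.columns)],
        {**prov, "transformation": "mixture_probability",
         "cv": {"folds": folds, "repeats": repeats, "seed": seed}},
    )
    return out, fits


def alternative_transform(suvr, mode: str, reference_values=None,
                          n_boot: int = 40000, boot_range=(0.05, 0.95),
                          seed: int = 0) -> RegionalMatrix:
    """Comparison transformations to a 0-1 scale.

    minmax: per-region (x - min) / (max - min).

    reference_ecdf: build a null distribution of the maxima of ``n_boot``
    bootstrap resamples of the 5-95% trimmed reference values, then apply
    its ECDF to every regional value (the probability a value exceeds
    reference signal).  Applied at region level.
    """
    frame = _as_frame(suvr)
    prov = suvr.provenance if isinstance(suvr, RegionalMatrix) else {}
    if mode == "minmax":
        lo = frame.min(axis=0)
        hi = frame.max(axis=0)
        spread = hi - lo
        if (spread <= 0).any():
            bad = list(spread[spread <= 0].index)
            raise ValueError(f"zero spread in regions {bad}")
        out = (frame - lo) / spread
        return RegionalMatrix(out, {**prov, "transformation": "minmax"})
    if mode == "reference_ecdf":
        if reference_values is None or len(np.atleast_1d(reference_values)) == 0:
            raise ValueError("reference_ecdf requires reference values")
        ref = np.sort(np.asarray(reference_values, dtype=float))
        lo_q, hi_q = np.quantile(ref, boot_range[0]), np.quantile(ref, boot_range[1])
        trimmed = ref[(ref >= lo_q) & (ref <= hi_q)]
        if trimmed.size == 0:
            trimmed = ref
        rng = np.random.default_rng(seed)
        samples = rng.choice(trimmed, size=(n_boot, trimmed.size), replace=True)
        maxima = np.sort(samples.max(axis=1))
        vals = frame.to_numpy(dtype=float)
        ecdf = np.searchsorted(maxima, vals.ravel(), side="right") / n_boot
        out = pd.DataFrame(ecdf.reshape(vals.shape), index=frame.index,
                           columns=frame.columns)
        return RegionalMatrix(out, {**prov, "transformation": "reference_ecdf",
                                    "n_boot": n_boot, "boot_range": tuple(boot_range)})
    raise ValueError(f"unknown mode {mode!r}")


def select_region_set(matrix, regions: pd.DataFrame, mode: str = "cortical66",
                      fits=None) -> RegionalMatrix:
    """Restrict a matrix's columns to a region set.

    full78: all atlas regions present; cortical66: the cortical set
    including bilateral hippocampus and amygdala; bimodal_only: regions
    whose full-sample mixture fit preferred two components.
    """
    from .synthetic_data import cortical66_names

    frame = _as_frame(matrix)
    prov = matrix.provenance if isinstance(matrix, RegionalMatrix) else {}
    if mode == "full78":
        keep = [c for c in frame.columns if c in set(regions["name"])]
    elif mode == "cortical66":
        allowed = set(cortical66_names(regions))
        keep = [c for c in frame.columns if c in allowed]
    elif mode == "bimodal_only":
        if fits is None:
            raise ValueError("bimodal_only requires mixture fits")
        bimodal = {f.region for f in fits if f.bimodal}
        keep = [c for c in frame.columns if c in bimodal]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep:
        raise ValueError("region-set selection produced an empty matrix")
    return RegionalMatrix(frame[keep].copy(), {**prov, "region_set": mode})
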