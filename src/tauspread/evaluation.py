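"""Downstream statistics for spreading-model fits.

Fit accuracy is the squared Pearson correlation between predicted and
observed regional probability vectors, within subject and globally on
subject-mean patterns, optionally stratified (amyloid status, diagnosis,
cohort).  Significance of a fit statistic against chance uses an ensemble of
degree/strength-preserving null connectomes: the model is refit per null and
the one-sided exceedance p-value is floored at 1/n_null.  Regional model
residuals (observed minus predicted group means) are related to regional
amyloid burden; per-subject best epicenters feed an asymmetry analysis with
regional GLMs corrected by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

def r_squared(x, y):
    """Squared Pearson correlation between two equal-length vectors.

    Returns None (undefined) when either vector has zero variance.  Note a
    perfect anticorrelation also yields 1.0 — this is the documented
    behavior of squared Pearson.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class FitSummary:
    global_r2: float
    mean_individual_r2: float
    sd_individual_r2: float
    n_undefined: int
    strata: pd.DataFrame  # stratum, n, global_r2, mean_individual_r2, flagged


def summarize_fit(fit, strata=None) -> FitSummary:
    """Summarize an ESMFit overall and within strata.

    Stratum-level global r^2 is recomputed from stratum-mean predicted and
    observed vectors (requires the observed matrix attached via
    ``attach_observed``).  Strata with fewer than 3 subjects are flagged and
    get no global r^2.  Undefined individual r^2 values (flat observed
    vectors) are excluded from means; the count is reported.
    """
    pred = fit.predicted.to_numpy(dtype=float)
    ind = np.asarray(fit.individual_r2, dtype=float)
    defined = ~np.isnan(ind)
    rows = []
    if strata is not None:
        obs = fit_observed(fit)
        strata = pd.Series(list(strata), index=fit.subject_ids)
        if len(strata) != len(fit.subject_ids):
            raise ValueError("strata must cover all subjects")
        for label, idx in strata.groupby(strata).groups.items():
            mask = strata.index.isin(idx)
            n = int(mask.sum())
            flagged = n < 3
            g = None
            if not flagged:
                g = r_squared(pred[mask].mean(axis=0), obs[mask].mean(axis=0))
            sub_ind = ind[mask]
            sub_def = sub_ind[~np.isnan(sub_ind)]
            rows.append(
                {
                    "stratum": label,
                    "n": n,
                    "global_r2": np.nan if g is None else g,
                    "mean_individual_r2": sub_def.mean() if sub_def.size else np.nan,
                    "flagged": flagged,
                }
            )
    return FitSummary(
        global_r2=fit.global_r2,
        mean_individual_r2=float(ind[defined].mean()) if defined.any() else float("nan"),
        sd_individual_r2=float(ind[defined].std()) if defined.any() else float("nan"),
        n_undefined=int((~defined).sum()),
        strata=pd.DataFrame(rows),
    )


def fit_observed(fit) -> np.ndarray:
    """Per-subject observed values carried on a fit (see attach_observed)."""
    obs = getattr(fit, "_observed", None)
    if obs is None:
        raise ValueError(
            "fit carries no per-subject observations; attach them with attach_observed")
    return obs


def attach_observed(fit, matrix):
    """Attach the observed subjects x regions values to an ESMFit so
    stratified summaries can be recomputed from raw data."""
    frame = matrix if isinstance(matrix, pd.DataFrame) else matrix.data
    fit._observed = frame.to_numpy(dtype=float)
    return fit


@dataclass
class NullSignificance:
    observed: float
    null_values: np.ndarray
    null_mean: float
    ci95: tuple
    p_value: float
    n_null: int
    n_failed: int = 0


def null_significance(observed_stat, matrix, nulls, epicenter, grid=None,
                      statistic: str = "global_r2") -> NullSignificance:
    """Refit the ESM once per null connectome and locate the observed
    statistic in the null distribution.

    p = count(null >= observed) / n_null, floored at 1/n_null (with 100
    nulls the lowest possible p is 0.01).  The 95% CI is the 2.5-97.5
    percentile range of the null values.
    """
    from .connectomics import Connectome
    from .esm import fit_cohort

    vals, failed = [], 0
    for frame in nulls.nulls:
        try:
            null_conn = Connectome(frame, modality="null")
            fit = fit_cohort(matrix, null_conn, epicenter, grid)
            v = fit.global_r2 if statistic == "global_r2" else fit.mean_individual_r2
            vals.append(v)
        except Exception:
            failed += 1
    vals = np.asarray(vals, dtype=float)
    if vals.size == 0:
        raise ValueError("all null refits failed")
    n_null = vals.size
    p = max(float((vals >= observed_stat).sum()) / n_null, 1.0 / n_null)
    return NullSignificance(
        observed=float(observed_stat),
        null_values=vals,
        null_mean=float(vals.mean()),
        ci95=(float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))),
        p_value=min(p, 1.0),
        n_null=n_null,
        n_failed=failed,
    )


@dataclass
class ResidualReport:
    table: pd.DataFrame  # region, residual, classification, amyloid_mean
    t_stat: float
    t_p: float
    corr_r: float
    corr_p: float
    partial: pd.DataFrame  # term, coef, se, t, p
    degenerate: bool = False
    t_flag: str = ""


def amyloid_residual_report(fit, observed, amyloid_prob, tau_means=None) -> ResidualReport:
    """Relate regional model residuals to regional amyloid burden.

    Residual = mean observed - mean predicted per region; positive residuals
    mark regions the connectivity model underestimates.  Group-mean amyloid
    probabilities are compared between under- and overestimated regions
    (Welch two-sided t-test), correlated with residuals (Pearson), and
    entered in an OLS of residual on amyloid + regional tau to assess the
    independent amyloid relationship.
    """
    import statsmodels.api as sm

    obs_frame = observed if isinstance(observed, pd.DataFrame) else observed.data
    amy_frame = amyloid_prob if isinstance(amyloid_prob, pd.DataFrame) else amyloid_prob.data
    regions = list(fit.predicted.columns)
    obs_mean = obs_frame[regions].mean(axis=0).to_numpy()
    pred_mean = fit.predicted.mean(axis=0).to_numpy()
    resid = obs_mean - pred_mean
    amy_mean = amy_frame[regions].mean(axis=0).to_numpy()
    tau_means = obs_mean if tau_means is None else np.asarray(tau_means, dtype=float)
    if np.allclose(resid, 0):
        table = pd.DataFrame({"region": regions, "residual": resid,
                              "classification": "none", "amyloid_mean": amy_mean})
        return ResidualReport(table, np.nan, np.nan, np.nan, np.nan,
                              pd.DataFrame(), degenerate=True)
    classes = np.where(resid > 0, "underestimated", "overestimated")
    under = amy_mean[classes == "underestimated"]
    over = amy_mean[classes == "overestimated"]
    if under.size == 0 or over.size == 0:
        t_stat, t_p, t_flag = np.nan, np.nan, "one class empty; t-test skipped"
    else:
        t_stat, t_p = stats.ttest_ind(under, over, equal_var=False)
        t_flag = ""
    corr_r, corr_p = stats.pearsonr(resid, amy_mean)
    X = sm.add_constant(pd.DataFrame({"amyloid": amy_mean, "tau": tau_means}))
    ols = sm.OLS(resid, X).fit()
    partial = pd.DataFrame(
        {
            "term": X.columns,
            "coef": ols.params.to_numpy(),
            "se": ols.bse.to_numpy(),
            "t": ols.tvalues.to_numpy(),
            "p": ols.pvalues.to_numpy(),
        }
    )
    table = pd.DataFrame({"region": regions, "residual": resid,
                          "classification": classes, "amyloid_mean": amy_mean})
    return ResidualReport(table, float(t_stat), float(t_p), float(corr_r),
                          float(corr_p), partial, t_flag=t_flag)


def laterality_index(matrix, regions: pd.DataFrame) -> pd.Series:
    """Mean left minus mean right cortical tau value per subject."""
    frame = matrix if isinstance(matrix, pd.DataFrame) else matrix.data
    info = regions.set_index("name")
    cols = [c for c in frame.columns if c in info.index]
    cortical = [c for c in cols if info.loc[c, "tissue_class"] == "cortical"
                or info.loc[c, "base_name"] in ("hippocampus", "amygdala")]
    left = [c for c in cortical if info.loc[c, "hemisphere"] == "L"]
    right = [c for c in cortical if info.loc[c, "hemisphere"] == "R"]
    return frame[left].mean(axis=1) - frame[right].mean(axis=1)


def _fast_ols_t(y: np.ndarray, X: np.ndarray, col: int):
    """OLS t-test for one coefficient via normal equations (used in the
    per-region GLM loop; equivalent to statsmodels OLS)."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        return np.nan, np.nan, np.nan
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[col, col])
    if se == 0:
        return float(beta[col]), np.nan, np.nan
    t = beta[col] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[col]), float(t), float(p)


@dataclass
class AsymmetryReport:
    classes: pd.Series
    proportions: pd.Series
    proportions_by_stage: pd.DataFrame
    laterality: pd.Series
    covariate_glms: pd.DataFrame  # outcome, coef, t, p, flagged
    regional_glm: pd.DataFrame  # region, estimate, se, t, p, q, significant


def asymmetry_report(per_subject_epicenters, matrix, regions, covariates,
                     alpha: float = 0.05) -> AsymmetryReport:
    """Hemispheric-asymmetry analysis of per-subject best epicenters.

    Classes are left-limbic / right-limbic / other.  Among limbic-epicenter
    subjects, a left-epicenter indicator is related to the laterality index
    and to demographic covariates (GLMs adjusting for disease status), and
    to tau in every region (GLMs adjusting for disease status, age, sex)
    with Benjamini-Hochberg FDR across regions at q < alpha.
    """
    import statsmodels.api as sm

    frame = matrix if isinstance(matrix, pd.DataFrame) else matrix.data
    epi = per_subject_epicenters.set_index("subject").loc[list(frame.index)]
    classes = epi["epicenter_class"]
    cov = covariates.set_index("subject_id").loc[list(frame.index)] \
        if "subject_id" in covariates.columns else covariates.loc[list(frame.index)]
    proportions = classes.value_counts(normalize=True)
    by_stage = (
        pd.crosstab(cov["diagnosis"], classes, normalize="index")
        if "diagnosis" in cov.columns
        else pd.DataFrame()
    )
    lat = laterality_index(frame, regions)

    limbic_mask = classes.isin(["left-limbic", "right-limbic"]).to_numpy()
    left_ind = (classes == "left-limbic").astype(float).to_numpy()
    disease = pd.get_dummies(cov["diagnosis"], drop_first=True, dtype=float) \
        if "diagnosis" in cov.columns else pd.DataFrame(index=cov.index)

    glm_rows = []
    n_limbic_each = min((classes == "left-limbic").sum(), (classes == "right-limbic").sum())
    underpowered = n_limbic_each < 5
    for outcome_name in ["laterality", "age"]:
        y = lat.to_numpy() if outcome_name == "laterality" else (
            cov["age"].to_numpy(dtype=float) if "age" in cov.columns else None)
        if y is None:
            continue
        Xdf = pd.DataFrame({"left_epicenter": left_ind}, index=cov.index)
        Xdf = pd.concat([Xdf, disease], axis=1)
        X = sm.add_constant(Xdf.loc[limbic_mask])
        res = sm.OLS(y[limbic_mask], X.astype(float)).fit()
        glm_rows.append(
            {
                "outcome": outcome_name,
                "coef": float(res.params["left_epicenter"]),
                "t": float(res.tvalues["left_epicenter"]),
                "p": float(res.pvalues["left_epicenter"]),
                "flagged": underpowered,
            }
        )
    covariate_glms = pd.DataFrame(glm_rows)

    # per-region GLM of tau on epicenter class adjusting for disease, age, sex
    Xcols = [left_ind[limbic_mask]]
    names_x = ["left_epicenter"]
    if not disease.empty:
        for c in disease.columns:
            Xcols.append(disease[c].to_numpy()[limbic_mask])
            names_x.append(str(c))
    for c in ("age", "sex"):
        if c in cov.columns:
            v = cov[c]
            if v.dtype == object:
                v = (v == v.unique()[0]).astype(float)
            Xcols.append(v.to_numpy(dtype=float)[limbic_mask])
            names_x.append(c)
    X = np.column_stack([np.ones(int(limbic_mask.sum()))] + Xcols)
    reg_rows = []
    for region in frame.columns:
        y = frame[region].to_numpy(dtype=float)[limbic_mask]
        est, t, p = _fast_ols_t(y, X, col=1)
        reg_rows.append({"region": region, "estimate": est, "t": t, "p": p})
    regional = pd.DataFrame(reg_rows)
    pvals = regional["p"].to_numpy()
    ok = ~np.isnan(pvals)
    q = np.full(len(pvals), np.nan)
    sig = np.zeros(len(pvals), dtype=bool)
    if ok.any():
        rej, qv, _, _ = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        sig[ok] = rej
    regional["q"] = q
    regional["significant"] = sig
    return AsymmetryReport(classes, proportions, by_stage, lat,
                           covariate_glms, regional)


def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg q-values and rejection decisions."""
    rej, q, _, _ = multipletests(np.asarray(pvalues, dtype=float),
                                 alpha=alpha, method="fdr_bh")
    return q, rej


def braak_stage_summary(matrix, regions: pd.DataFrame,
                        thresholds=(0.35, 0.25, 0.15, 0.05)):
    """Stage-ROI summaries of a probability matrix.

    Returns (stage_means, threshold_maps, subject_order): per-subject mean
    probability within each of the six stage ROIs; nested binarizations of
    the population-mean regional vector at the given strictly decreasing
    thresholds; subjects ordered from least to most total burden.
    """
    thresholds = tuple(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    frame = matrix if isinstance(matrix, pd.DataFrame) else matrix.data
    info = regions.set_index("name")
    cols = [c for c in frame.columns if c in info.index]
    stages = info.loc[cols, "braak_stage"]
    if stages.isna().any():
        raise ValueError("braak_stage must be defined for all included regions")
    stage_means = pd.DataFrame(index=frame.index)
    for stage in sorted(stages.dropna().unique()):
        members = [c for c in cols if stages[c] == stage]
        stage_means[f"stage_{int(stage)}"] = frame[members].mean(axis=1)
    total = frame[cols].sum(axis=1)
    subject_order = list(total.sort_values().index)
    pop_mean = frame[cols].mean(axis=0)
    maps = pd.DataFrame(
        {f"thr_{t}": (pop_mean >= t) for t in thresholds}, index=cols
    )
    return stage_means, maps, subject_order


def match_cohorts(reference: pd.DataFrame, pool: pd.DataFrame, features) -> list:
    """Greedy nearest-neighbor matching without replacement.

    Features are z-scored over the combined sample; matching walks the
    reference table in order, each time taking the closest unused pool
    subject under Euclidean (Minkowski p=2) distance.  Returns pool ids.
    """
    features = list(features)
    if len(pool) < len(reference):
        raise ValueError("pool smaller than reference")
    ref = reference[features].to_numpy(dtype=float)
    pl = pool[features].to_numpy(dtype=float)
    combined = np.vstack([ref, pl])
    mu, sd = combined.mean(axis=0), combined.std(axis=0)
    sd[sd == 0] = 1.0
    ref = (ref - mu) / sd
    pl = (pl - mu) / sd
    available = np.ones(len(pl), dtype=bool)
    chosen = []
    pool_index = list(pool.index)
    for r in ref:
        d = np.sqrt(((pl - r) ** 2).sum(axis=1))
        d[~available] = np.inf
        j = int(np.argmin(d))
        available[j] = False
        chosen.append(pool_index[j])
    return chosen
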