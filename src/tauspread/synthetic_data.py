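"""Synthetic atlas, connectomes, and cohorts with known spreading ground truth.

Real tau-PET studies of this kind rely on restricted imaging cohorts; this
module generates stand-in data with the same structure so every downstream
stage (mixture-model calibration, spreading-model fitting, epicenter search,
statistical evaluation) can be exercised and validated against known ground
truth.

The atlas fixture follows the Mindboggle-compliant DKT parcellation: 31
cortical labels per hemisphere plus bilateral hippocampus and amygdala (66
regions counted as the cortical set) plus six further subcortical structures
per hemisphere (78 in the full set).  Each cortical region carries a Braak
stage ROI assignment (stage 1 = entorhinal, 2 = hippocampus, remaining
cortex distributed over stages 3-6 following the conventional staging
scheme; the mapping is approximate and editable).

Synthetic cohorts are built generatively: per-subject production/clearance/
duration parameters drive the epidemic spreading model forward from an
entorhinal (optionally lateralized) epicenter to produce ground-truth
tau-positive probabilities; amyloid-positive subjects get an additive tau
boost in a fixed amyloid-vulnerable region list; SUVR observations are then
emitted from a two-component Gaussian measurement model with age, sex and
choroid-plexus confound effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectomics import Connectome

# ---------------------------------------------------------------------------
# atlas fixture

DKT_CORTICAL = (
    "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus", "entorhinal",
    "fusiform", "inferiorparietal", "inferiortemporal", "isthmuscingulate",
    "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "transversetemporal", "insula",
)
#: hippocampus and amygdala are counted with the cortical set (66 regions)
MEDIAL_TEMPORAL = ("hippocampus", "amygdala")
DKT_SUBCORTICAL = ("thalamus", "caudate", "putamen", "pallidum",
                   "accumbens", "ventraldc")

LIMBIC = ("entorhinal", "hippocampus", "amygdala", "parahippocampal")

#: approximate stage-ROI mapping: which Braak stage a region first shows
#: abnormal tau.  Editable fixture; entorhinal and hippocampus anchor
#: stages 1 and 2, primary sensory cortex lands in stage 6.
BRAAK_STAGE = {
    "entorhinal": 1,
    "hippocampus": 2,
    "parahippocampal": 3, "amygdala": 3, "fusiform": 3, "lingual": 3,
    "insula": 4, "posteriorcingulate": 4, "isthmuscingulate": 4,
    "caudalanteriorcingulate": 4, "rostralanteriorcingulate": 4,
    "inferiortemporal": 4, "middletemporal": 4,
    "superiortemporal": 5, "supramarginal": 5, "inferiorparietal": 5,
    "superiorparietal": 5, "precuneus": 5, "lateraloccipital": 5,
    "lateralorbitofrontal": 5, "medialorbitofrontal": 5,
    "parsopercularis": 5, "parsorbitalis": 5, "parstriangularis": 5,
    "rostralmiddlefrontal": 5, "caudalmiddlefrontal": 5, "superiorfrontal": 5,
    "precentral": 6, "postcentral": 6, "paracentral": 6, "cuneus": 6,
    "pericalcarine": 6, "transversetemporal": 6,
}

#: regions with classically high amyloid burden; amyloid-positive synthetic
#: subjects get a planted additive tau boost here
AMYLOID_VULNERABLE_BASES = (
    "precuneus", "posteriorcingulate", "isthmuscingulate",
    "inferiorparietal", "supramarginal", "medialorbitofrontal",
    "lateralorbitofrontal", "rostralmiddlefrontal", "superiorfrontal",
)


def build_region_table(atlas_mode: str = "cortical66", coordinate_seed: int = 0) -> pd.DataFrame:
    """Region table for the packaged DKT-derived label set.

    Columns: region_id, name, base_name, hemisphere, tissue_class, limbic,
    braak_stage, x, y, z.  Centroids are synthetic: two mirrored hemispheric
    point clouds (seeded); only relative distances matter downstream.
    """
    if atlas_mode not in ("cortical66", "full78"):
        raise ValueError(f"unknown atlas_mode {atlas_mode!r}")
    bases = list(DKT_CORTICAL) + list(MEDIAL_TEMPORAL)
    if atlas_mode == "full78":
        bases += list(DKT_SUBCORTICAL)
    rng = np.random.default_rng(coordinate_seed)
    # One seeded layout per base region, mirrored across hemispheres.  The
    # anterior-posterior coordinate follows the Braak-stage gradient (the
    # staging scheme is, anatomically, a spatial progression from medial
    # temporal to association to primary cortex), so the distance-dependent
    # connectome preferentially links regions of adjacent stages and
    # entorhinal-seeded spread recapitulates the staged ordering.
    all_bases = list(DKT_CORTICAL) + list(MEDIAL_TEMPORAL) + list(DKT_SUBCORTICAL)
    # The medial temporal (limbic) origin cluster is anchored tightly, as in
    # real anatomy, so the spreading cascade can escape the entorhinal seed
    # through hippocampus/amygdala/parahippocampal cortex.
    # entorhinal sits between hippocampus and the cortical ribbon (perforant
    # path): it is the gateway, while the hippocampus is comparatively
    # secluded — this keeps entorhinal- and hippocampus-seeded spread
    # patterns distinguishable
    # fusiform/lingual form the ventral bridge from the medial temporal
    # cluster into the cortical ribbon, as in real ventral temporal anatomy
    limbic_anchor = {
        "entorhinal": (18.0, -84.0, -14.0),
        "hippocampus": (12.0, -101.0, -24.0),
        "amygdala": (14.0, -74.0, -12.0),
        "parahippocampal": (24.0, -80.0, -10.0),
        "fusiform": (30.0, -62.0, -12.0),
        "lingual": (28.0, -56.0, -6.0),
    }
    coords = {}
    for b in all_bases:
        if b in limbic_anchor:
            lat, y, z = limbic_anchor[b]
            coords[b] = (lat + rng.uniform(-2, 2), y + rng.uniform(-2, 2),
                         z + rng.uniform(-2, 2))
            continue
        deep = b in MEDIAL_TEMPORAL or b in DKT_SUBCORTICAL
        lat = rng.uniform(8, 25) if deep else rng.uniform(25, 65)
        stage = BRAAK_STAGE.get(b)
        if stage is not None:
            y = -90.0 + 15.0 * (stage - 1) + rng.uniform(-10, 10)
            if stage == 6:  # primary cortex sits beyond association cortex
                y += 18.0
        else:
            y = rng.uniform(-60, -20)
        z = rng.uniform(-30, 40) if not deep else rng.uniform(-25, 15)
        coords[b] = (lat, y, z)
    rows = []
    rid = 0
    for hemi in ("L", "R"):
        for b in bases:
            lat, y, z = coords[b]
            rows.append(
                {
                    "region_id": rid,
                    "name": f"{hemi}_{b}",
                    "base_name": b,
                    "hemisphere": hemi,
                    "tissue_class": "subcortical" if (b in MEDIAL_TEMPORAL or b in DKT_SUBCORTICAL) else "cortical",
                    "limbic": b in LIMBIC,
                    "braak_stage": BRAAK_STAGE.get(b, np.nan),
                    "x": -lat if hemi == "L" else lat,
                    "y": y,
                    "z": z,
                }
            )
            rid += 1
    return pd.DataFrame(rows)


def cortical66_names(regions: pd.DataFrame) -> list:
    """Names of the 66-region cortical set (31 DKT cortical labels per
    hemisphere plus bilateral hippocampus and amygdala)."""
    mask = (regions["tissue_class"] == "cortical") | regions["base_name"].isin(MEDIAL_TEMPORAL)
    return list(regions.loc[mask, "name"])


def homotopic_pairs(regions: pd.DataFrame, names=None) -> list:
    """(left, right) name tuples for every homotopic pair, restricted to
    ``names`` when given."""
    pairs = []
    for b in regions["base_name"].unique():
        sub = regions[regions["base_name"] == b]
        left = sub.loc[sub["hemisphere"] == "L", "name"]
        right = sub.loc[sub["hemisphere"] == "R", "name"]
        if len(left) == 1 and len(right) == 1:
            l, r = left.iloc[0], right.iloc[0]
            if names is None or (l in names and r in names):
                pairs.append((l, r))
    return pairs


# ---------------------------------------------------------------------------
# synthetic connectome

def simulate_connectome(regions: pd.DataFrame, density: float = 0.10,
                        homotopic_strength: float = 0.05, seed: int = 0,
                        heterotopic_attenuation: float = 0.02) -> Connectome:
    """Distance-dependent random connectome with strengthened homotopic edges.

    Edge propensity decays exponentially with centroid distance (length
    constant 25 mm) with multiplicative lognormal noise.  Interhemispheric
    edges other than homotopic ones are strongly attenuated (callosal
    connectivity is predominantly homotopic); every homotopic pair is
    connected at weight ``homotopic_strength`` on the final [0, 1] scale so
    bilateral seeds stay coupled without erasing hemispheric asymmetry.  The
    off-diagonal nonzero fraction matches ``density`` (homotopic edges
    counted within the quota) and all weights lie in [0, 1].
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    xyz = regions[["x", "y", "z"]].to_numpy(dtype=float)
    n = len(regions)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    base = np.exp(-dist / 25.0)
    noise = rng.lognormal(mean=0.0, sigma=0.5, size=(n, n))
    noise = (noise + noise.T) / 2
    w = base * noise
    hemi = regions["hemisphere"].to_numpy()
    cross = hemi[:, None] != hemi[None, :]
    w[cross] *= heterotopic_attenuation
    names = list(regions["name"])
    name_to_i = {nm: i for i, nm in enumerate(names)}
    pairs = [(name_to_i[l], name_to_i[r]) for l, r in homotopic_pairs(regions)]
    for i, j in pairs:  # homotopic edges handled separately below
        w[i, j] = w[j, i] = 0.0
    np.fill_diagonal(w, 0.0)
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    quota = max(int(round(density * len(vals))) - len(pairs), 1)
    order = np.argsort(-vals, kind="stable")
    mask = np.zeros(len(vals), dtype=bool)
    mask[order[:quota]] = True
    out = np.zeros_like(w)
    out[iu[mask], ju[mask]] = vals[mask] / vals[mask].max()
    out = out + out.T
    # homotopic edges are always present, at a fixed weight on the final
    # [0, 1] scale; weak enough that unilateral seeds stay lateralized
    for i, j in pairs:
        out[i, j] = out[j, i] = homotopic_strength
    return Connectome(
        pd.DataFrame(out, index=names, columns=names),
        modality="synthetic",
        preprocessing={"density": density, "homotopic_strength": homotopic_strength,
                       "seed": seed},
    )


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortSpec:
    """Distributional parameters of a synthetic cohort.

    Demographic marginals default to a representative multi-cohort
    Alzheimer's-continuum tau-PET study population
    (n=312; 52/28.5/19.5% CN/MCI/AD; mean age 71.7 (7.1); 53.1% women;
    education 14.6 (3.8); APOE4 51.7%; amyloid positivity 42.6/64/100% by
    diagnosis).  Spreading parameters are lognormal: clearance delta around
    0.15/year, production/clearance ratio around 2 (rising with disease
    severity), effective duration uniform on 15-35 years.
    """

    n: int = 100
    diagnosis_mix: dict = field(default_factory=lambda: {"CN": 0.52, "MCI": 0.285, "AD": 0.195})
    amyloid_pos_rate: dict = field(default_factory=lambda: {"CN": 0.426, "MCI": 0.64, "AD": 1.0})
    age_mean: float = 71.7
    age_sd: float = 7.1
    pct_women: float = 0.531
    education_mean: float = 14.6
    education_sd: float = 3.8
    apoe4_rate: float = 0.517
    choroid_mean: float = 1.2
    choroid_sd: float = 0.15
    delta_log_mean: float = float(np.log(0.15))
    delta_log_sd: float = 0.3
    ratio_log_mean: dict = field(default_factory=lambda: {
        "CN": float(np.log(1.6)), "MCI": float(np.log(2.1)), "AD": float(np.log(2.6))})
    ratio_log_sd: float = 0.30
    t_eff_range: tuple = (15.0, 35.0)
    epicenter_bases: tuple = ("entorhinal",)
    lateralized: bool = False
    x0: float = 0.1
    dt: float = 0.01
    amyloid_boost: float = 0.2
    noise_sd: float = 0.0  # optional additive noise on true probabilities
    cohort_label: str = "synthetic"


def recovery_benchmark_spec(n: int = 50, noise_sd: float = 0.05,
                            epicenter_bases=("entorhinal",),
                            lateralized: bool = False) -> CohortSpec:
    """Cohort spec for parameter/epicenter-recovery benchmarks.

    Uses a uniformly tau-accumulating population (production/clearance
    ratio ~3.5 across diagnoses with modest spread, durations of 10-25
    years) so each subject's terminal pattern is a partial, graded wave:
    saturated patterns carry no epicenter information and empty patterns
    are pure noise, and neither regime can benchmark recovery.
    """
    log_r = float(np.log(3.5))
    return CohortSpec(
        n=n,
        noise_sd=noise_sd,
        epicenter_bases=tuple(epicenter_bases),
        lateralized=lateralized,
        ratio_log_mean={"CN": log_r, "MCI": log_r, "AD": log_r},
        ratio_log_sd=0.2,
        t_eff_range=(8.0, 18.0),
    )


def epicenter_ranking_spec(base: str = "entorhinal", n: int = 50,
                           noise_sd: float = 0.05) -> CohortSpec:
    """Cohort spec for planted-epicenter ranking benchmarks.

    Longer durations (10-25 years) than the within-subject fit benchmark:
    the population-mean pattern must reflect the seed's position in the
    connectome, which requires spread to have escaped the seed's immediate
    neighborhood in most subjects.
    """
    spec = recovery_benchmark_spec(n=n, noise_sd=noise_sd,
                                   epicenter_bases=(base,))
    spec.t_eff_range = (10.0, 25.0)
    return spec


def lateralization_benchmark_spec(n: int = 150, noise_sd: float = 0.05) -> CohortSpec:
    """Cohort spec for planted-lateralization benchmarks.

    Per-subject unilateral entorhinal seeds with a stage-homogeneous
    population (narrow duration and production/clearance spreads) so the
    hemispheric class effect on regional tau is not swamped by disease-stage
    heterogeneity.
    """
    spec = recovery_benchmark_spec(n=n, noise_sd=noise_sd, lateralized=True)
    spec.t_eff_range = (16.0, 22.0)
    spec.ratio_log_sd = 0.12
    spec.delta_log_sd = 0.15
    return spec


@dataclass
class GroundTruth:
    beta: np.ndarray
    delta: np.ndarray
    t_eff: np.ndarray
    epicenters: list  # per-subject list of region names
    probabilities: pd.DataFrame  # terminal true probabilities, subjects x regions

    def to_json_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "delta": self.delta.tolist(),
            "t_eff": self.t_eff.tolist(),
            "epicenters": self.epicenters,
        }


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame
    tau_suvr: "object"  # RegionalMatrix
    amyloid_suvr: "object"
    tau_probability_truth: pd.DataFrame
    ground_truth: GroundTruth
    seed: int


def _simulate_batch(connectome: Connectome, seed_indices, beta, delta, t_eff,
                    x0: float, dt: float) -> np.ndarray:
    """Forward-simulate all subjects simultaneously (batched Euler)."""
    from .esm import row_normalize, STABILITY_LIMIT

    chat_t = row_normalize(connectome.weights.to_numpy()).T.copy()
    n_sub = len(beta)
    n_reg = chat_t.shape[0]
    x = np.zeros((n_sub, n_reg))
    for s, idx in enumerate(seed_indices):
        x[s, idx] = x0
    steps = np.round(np.asarray(t_eff) / dt).astype(int)
    out = np.zeros_like(x)
    done = np.zeros(n_sub, dtype=bool)
    b = np.asarray(beta)[:, None]
    d = np.asarray(delta)[:, None]
    for step in range(1, int(steps.max()) + 1):
        influx = x @ chat_t
        dx = dt * (b * (1.0 - x) * influx - d * x)
        if np.max(np.abs(dx)) > STABILITY_LIMIT:
            raise RuntimeError("integration unstable; reduce dt")
        x = np.clip(x + dx, 0.0, 1.0)
        hit = (steps == step) & ~done
        out[hit] = x[hit]
        done |= hit
    out[~done] = x[~done]
    return out


def simulate_cohort(regions: pd.DataFrame, connectome: Connectome,
                    cohort_spec: CohortSpec = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort with known ground truth.

    Terminal tau-positive probabilities come from the spreading model run
    forward with each subject's drawn parameters; amyloid-positive subjects
    additionally receive an additive boost in the amyloid-vulnerable region
    list (the planted signal for the residual analysis).
    """
    spec = cohort_spec or CohortSpec()
    if list(connectome.region_names) != list(regions["name"]):
        raise ValueError("connectome regions misaligned with region table")
    for k, v in spec.diagnosis_mix.items():
        if v < 0:
            raise ValueError("invalid diagnosis mix")
    if abs(sum(spec.diagnosis_mix.values()) - 1.0) > 1e-6:
        raise ValueError("diagnosis mix must sum to 1")
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_demo, rng_par, rng_tau, rng_amy = (np.random.default_rng(s) for s in ss)

    n = spec.n
    diags = rng_demo.choice(list(spec.diagnosis_mix), p=list(spec.diagnosis_mix.values()), size=n)
    age = rng_demo.normal(spec.age_mean, spec.age_sd, size=n)
    sex = (rng_demo.random(n) < spec.pct_women).astype(int)  # 1 = female
    education = rng_demo.normal(spec.education_mean, spec.education_sd, size=n)
    apoe4 = (rng_demo.random(n) < spec.apoe4_rate).astype(int)
    amyloid_status = np.array(
        [rng_demo.random() < spec.amyloid_pos_rate[d] for d in diags], dtype=int
    )
    choroid = rng_demo.normal(spec.choroid_mean, spec.choroid_sd, size=n)

    delta = rng_par.lognormal(spec.delta_log_mean, spec.delta_log_sd, size=n)
    ratio = np.array(
        [rng_par.lognormal(spec.ratio_log_mean[d], spec.ratio_log_sd) for d in diags]
    )
    beta = ratio * delta
    t_eff = rng_par.uniform(*spec.t_eff_range, size=n)

    names = list(regions["name"])
    name_to_i = {nm: i for i, nm in enumerate(names)}
    epicenters, seed_indices = [], []
    for s in range(n):
        if spec.lateralized:
            hemi = "L" if rng_par.random() < 0.5 else "R"
            regs = [f"{hemi}_{b}" for b in spec.epicenter_bases]
        else:
            regs = [f"{h}_{b}" for b in spec.epicenter_bases for h in ("L", "R")]
        missing = [r for r in regs if r not in name_to_i]
        if missing:
            raise ValueError(f"epicenter regions not in atlas: {missing}")
        epicenters.append(regs)
        seed_indices.append([name_to_i[r] for r in regs])

    probs = _simulate_batch(connectome, seed_indices, beta, delta, t_eff,
                            spec.x0, spec.dt)
    if spec.noise_sd > 0:
        probs = np.clip(probs + rng_tau.normal(0, spec.noise_sd, probs.shape), 0, 1)

    vulnerable = [nm for nm in names
                  if nm.split("_", 1)[1] in AMYLOID_VULNERABLE_BASES]
    vuln_idx = [name_to_i[nm] for nm in vulnerable]
    boosted = probs.copy()
    boosted[np.ix_(amyloid_status == 1, vuln_idx)] = np.clip(
        boosted[np.ix_(amyloid_status == 1, vuln_idx)] + spec.amyloid_boost, 0, 1
    )

    # amyloid probabilities: high in vulnerable regions for positives,
    # low background elsewhere
    amy_prob = rng_amy.beta(1.0, 12.0, size=(n, len(names)))
    pos = amyloid_status == 1
    amy_prob[np.ix_(pos, vuln_idx)] = rng_amy.beta(
        8.0, 2.5, size=(int(pos.sum()), len(vuln_idx))
    )

    subject_ids = [f"sub-{s:04d}" for s in range(n)]
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            "education": education,
            "diagnosis": diags,
            "amyloid_status": np.where(amyloid_status == 1, "pos", "neg"),
            "apoe4": apoe4,
            "cohort": spec.cohort_label,
            "choroid_plexus": choroid,
        }
    )
    truth_frame = pd.DataFrame(boosted, index=subject_ids, columns=names)
    emission = EmissionSpec()
    tau_suvr = suvr_emission(
        pd.DataFrame(boosted, index=subject_ids, columns=names),
        emission, seed=int(ss[2].generate_state(1)[0] % (2**31)),
        covariates=subjects,
    )
    amyloid_suvr = suvr_emission(
        pd.DataFrame(amy_prob, index=subject_ids, columns=names),
        emission, seed=int(ss[3].generate_state(1)[0] % (2**31)),
        covariates=subjects,
    )
    gt = GroundTruth(beta=beta, delta=delta, t_eff=t_eff, epicenters=epicenters,
                     probabilities=pd.DataFrame(probs, index=subject_ids, columns=names))
    return SyntheticCohort(
        subjects=subjects,
        tau_suvr=tau_suvr,
        amyloid_suvr=amyloid_suvr,
        tau_probability_truth=truth_frame,
        ground_truth=gt,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SUVR emission (inverse of the mixture-model measurement step)

@dataclass
class EmissionSpec:
    """Two-component Gaussian measurement model per region.

    Lower (off-target background) component N(1.0, 0.10), upper (abnormal)
    component N(1.6, 0.20), with small seeded regional jitter on the means;
    chosen to give clear but overlapping modes.  Confound coefficients add
    age/sex/choroid-plexus effects on the SUVR scale.
    """

    lower_mean: float = 1.0
    lower_sd: float = 0.10
    upper_mean: float = 1.6
    upper_sd: float = 0.20
    regional_jitter_sd: float = 0.02
    age_coef: float = 0.002  # SUVR per year of age (centered at 70)
    sex_coef: float = 0.02
    choroid_coef: float = 0.05  # per unit choroid-plexus signal (centered)

    def __post_init__(self):
        if self.lower_sd <= 0 or self.upper_sd <= 0:
            raise ValueError("component SDs must be positive")


def suvr_emission(probabilities, emission_spec: EmissionSpec = None, seed: int = 0,
                  covariates: pd.DataFrame = None):
    """Emit SUVR observations from tau/amyloid-positive probabilities.

    Per subject/region, component membership is Bernoulli(p) and the SUVR is
    drawn from the corresponding Gaussian; confound effects (age, sex,
    choroid plexus) are added when covariates are supplied.  Output is
    clipped to be positive.
    """
    from .tau_probability import RegionalMatrix

    spec = emission_spec or EmissionSpec()
    frame = probabilities if isinstance(probabilities, pd.DataFrame) else probabilities.data
    p = frame.to_numpy(dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sub, n_reg = p.shape
    jitter = rng.normal(0.0, spec.regional_jitter_sd, size=n_reg)
    member = rng.random((n_sub, n_reg)) < p
    lower = rng.normal(spec.lower_mean + jitter, spec.lower_sd, size=(n_sub, n_reg))
    upper = rng.normal(spec.upper_mean + jitter, spec.upper_sd, size=(n_sub, n_reg))
    suvr = np.where(member, upper, lower)
    if covariates is not None:
        age = covariates["age"].to_numpy(dtype=float) - 70.0
        sex = covariates["sex"].to_numpy(dtype=float)
        cp = covariates["choroid_plexus"].to_numpy(dtype=float)
        cp = cp - cp.mean()
        shift = spec.age_coef * age + spec.sex_coef * sex + spec.choroid_coef * cp
        suvr = suvr + shift[:, None]
    suvr = np.maximum(suvr, 1e-6)
    return RegionalMatrix(
        data=pd.DataFrame(suvr, index=frame.index, columns=frame.columns),
        provenance={"transformation": "raw_suvr", "confound_strategy": "none",
                    "pvc": False, "region_set": "as-generated",
                    "emission": asdict(spec), "seed": seed,
                    # realized per-region component means (incl. jitter),
                    # the ground truth for mixture-recovery checks
                    "regional_lower_mean": dict(zip(frame.columns, spec.lower_mean + jitter)),
                    "regional_upper_mean": dict(zip(frame.columns, spec.upper_mean + jitter))},
    )
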