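"""Configuration, grid enumeration, orchestration and I/O.

The end-to-end analysis is parameterized by six methodological axes
(connectome template, region set, tau transformation, PVC provenance,
confound strategy, inclusion of amyloid-negative MCI subjects); the full
Cartesian product at the default option counts is the 432-configuration
grid.  ``run_pipeline`` executes one cell on synthetic (or file-based)
inputs: confound regression -> transformation -> region-set selection ->
spreading-model fit -> summaries, fully determined by a master seed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectomics import Connectome
from .tau_probability import (
    RegionalMatrix,
    alternative_transform,
    mixture_probability_transform,
    regress_confounds,
    select_region_set,
)

logger = logging.getLogger("tauspread")

TRANSFORMATIONS = ("mixture_probability", "minmax", "reference_ecdf")
REGION_SETS = ("full78", "cortical66", "bimodal_only")
CONFOUND_STRATEGIES = ("none", "residualize", "wscore")
PVC_OPTIONS = ("off", "on")
MCI_OPTIONS = ("include", "exclude")
CONNECTOME_TEMPLATES = (
    "structural_young", "structural_old", "functional_young", "functional_old",
)


@dataclass
class PipelineConfig:
    transformation: str = "mixture_probability"
    region_set: str = "cortical66"
    confound_strategy: str = "residualize"
    pvc: str = "off"
    mci_ab_negative: str = "exclude"
    connectome_template: str = "structural_young"
    use_distance_baseline: bool = False
    epicenter_bases: tuple = ("entorhinal",)
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        checks = [
            (self.transformation, TRANSFORMATIONS, "transformation"),
            (self.region_set, REGION_SETS, "region_set"),
            (self.confound_strategy, CONFOUND_STRATEGIES, "confound_strategy"),
            (self.pvc, PVC_OPTIONS, "pvc"),
            (self.mci_ab_negative, MCI_OPTIONS, "mci_ab_negative"),
            (self.connectome_template, CONNECTOME_TEMPLATES, "connectome_template"),
        ]
        for value, allowed, name in checks:
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")
        self.epicenter_bases = tuple(self.epicenter_bases)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epicenter_bases"] = list(self.epicenter_bases)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "epicenter_bases" in d:
            d["epicenter_bases"] = tuple(d["epicenter_bases"])
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        return cls.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def enumerate_grid(
    transformations=TRANSFORMATIONS,
    region_sets=REGION_SETS,
    confound_strategies=CONFOUND_STRATEGIES,
    pvc_options=PVC_OPTIONS,
    mci_options=MCI_OPTIONS,
    connectome_templates=CONNECTOME_TEMPLATES,
    seed: int = 0,
) -> list:
    """Full Cartesian product of the option sets, deterministic ordering.

    At the default option counts (3 x 3 x 3 x 2 x 2 x 4) this enumerates
    the 432-model grid.
    """
    axes = [connectome_templates, region_sets, transformations,
            pvc_options, confound_strategies, mci_options]
    if any(len(a) == 0 for a in axes):
        raise ValueError("empty option set")
    configs = []
    for ct, rs, tr, pvc, cs, mci in itertools.product(*axes):
        configs.append(
            PipelineConfig(
                transformation=tr, region_set=rs, confound_strategy=cs,
                pvc=pvc, mci_ab_negative=mci, connectome_template=ct,
                seed=seed,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# matrix I/O

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_matrix(path, kind: str = "regional", regions: pd.DataFrame = None):
    """Read a regional (subjects x regions) or connectome (regions x
    regions) matrix from CSV/TSV.

    Region columns are validated against (and reordered to) the region
    table when one is given; unknown regions and duplicate subjects are
    errors.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric cells: {err}") from err
    if frame.index.duplicated().any():
        dups = list(frame.index[frame.index.duplicated()])
        raise ValueError(f"{path}: duplicate subjects {dups}")
    if regions is not None:
        known = list(regions["name"])
        unknown = [c for c in frame.columns if c not in known]
        if unknown:
            raise ValueError(f"{path}: unknown region names {unknown}")
        ordered = [n for n in known if n in frame.columns]
        if list(frame.columns) != ordered:
            logger.info("%s: reordering regions to match region table", path)
            frame = frame[ordered]
    if kind == "regional":
        return RegionalMatrix(frame, provenance={"source": str(path)})
    if kind == "connectome":
        return Connectome(frame, modality="structural",
                          preprocessing={"source": str(path)})
    raise ValueError(f"unknown kind {kind!r}")


def write_matrix(obj, path):
    """Write a RegionalMatrix or Connectome as CSV/TSV (by extension)."""
    path = Path(path)
    frame = obj.data if isinstance(obj, RegionalMatrix) else obj.weights
    frame.to_csv(path, sep=_sep_for(path))
    return path


def write_region_table(regions: pd.DataFrame, path):
    cols = ["region_id", "name", "hemisphere", "tissue_class", "limbic",
            "braak_stage", "x", "y", "z"]
    regions[cols].to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class ResultsBundle:
    config: PipelineConfig
    version: str
    n_subjects: int
    global_r2: float
    mean_individual_r2: float
    sd_individual_r2: float
    epicenter: list
    fit: object = field(repr=False, default=None)
    probabilities: RegionalMatrix = field(repr=False, default=None)
    mixture_fits: list = field(repr=False, default=None)

    def summary_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.hash(),
            "version": self.version,
            "n_subjects": self.n_subjects,
            "global_r2": self.global_r2,
            "mean_individual_r2": self.mean_individual_r2,
            "sd_individual_r2": self.sd_individual_r2,
            "epicenter": list(self.epicenter),
        }


def _reference_values(frame: pd.DataFrame) -> np.ndarray:
    """Reference sample for the bootstrap-ECDF transform: pooled values of
    the region with the lowest population mean (a data-driven stand-in for
    a reference-region sample)."""
    region = frame.mean(axis=0).idxmin()
    return frame[region].to_numpy(dtype=float)


def run_pipeline(config: PipelineConfig, cohort, connectome: Connectome,
                 regions: pd.DataFrame, grid=None, outdir=None) -> ResultsBundle:
    """Execute one configuration end to end on a synthetic cohort.

    Steps: subject filtering -> confound regression -> transformation to
    [0, 1] -> region-set selection -> spreading-model cohort fit at the
    configured epicenter -> summary.  Fully determined by config.seed.
    """
    from .esm import ParameterGrid, fit_cohort

    subjects = cohort.subjects
    tau = cohort.tau_suvr
    mask = np.ones(len(subjects), dtype=bool)
    if config.mci_ab_negative == "exclude":
        mask &= ~((subjects["diagnosis"] == "MCI").to_numpy()
                  & (subjects["amyloid_status"] == "neg").to_numpy())
    kept = subjects.loc[mask].reset_index(drop=True)
    frame = tau.data.loc[mask]
    tau_kept = RegionalMatrix(frame, dict(tau.provenance))

    adjusted = regress_confounds(
        tau_kept, kept.assign(subject_id=frame.index),
        strategy=config.confound_strategy,
        reference_group=((kept["diagnosis"] == "CN")
                         & (kept["amyloid_status"] == "neg")).to_numpy(),
    )
    if config.transformation == "mixture_probability":
        probs, fits = mixture_probability_transform(
            adjusted, repeats=config.cv_repeats, seed=config.seed
        )
    elif config.transformation == "minmax":
        probs, fits = alternative_transform(adjusted, "minmax"), None
    else:
        ref = _reference_values(adjusted.data)
        probs = alternative_transform(adjusted, "reference_ecdf",
                                      reference_values=ref, seed=config.seed)
        fits = None
    selected = select_region_set(probs, regions, mode=config.region_set, fits=fits)

    epicenter = [f"{h}_{b}" for b in config.epicenter_bases for h in ("L", "R")]
    sub_conn = Connectome(
        connectome.weights.loc[selected.regions, selected.regions],
        modality=connectome.modality,
        preprocessing=dict(connectome.preprocessing),
    )
    grid = grid or ParameterGrid.coarse()
    fit = fit_cohort(selected, sub_conn, epicenter, grid)
    ind = fit.individual_r2[~np.isnan(fit.individual_r2)]
    bundle = ResultsBundle(
        config=config,
        version=__version__,
        n_subjects=len(kept),
        global_r2=fit.global_r2,
        mean_individual_r2=float(ind.mean()) if ind.size else float("nan"),
        sd_individual_r2=float(ind.std()) if ind.size else float("nan"),
        epicenter=epicenter,
        fit=fit,
        probabilities=selected,
        mixture_fits=fits,
    )
    if outdir is not None:
        outdir = Path(outdir) / bundle.config.hash()
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(bundle.summary_dict(), indent=2)
        )
        write_matrix(selected, outdir / "probabilities.csv")
        fit.predicted.to_csv(outdir / "predicted.csv")
        per_subject = pd.DataFrame(
            {
                "subject": fit.subject_ids,
                "beta": [p.beta for p in fit.params],
                "delta": [p.delta for p in fit.params],
                "t_eff": [p.t_eff for p in fit.params],
                "sse": fit.sse,
                "r2": fit.individual_r2,
            }
        )
        per_subject.to_csv(outdir / "subject_fits.tsv", sep="\t", index=False)
    return bundle


def run_grid(configs, cohort, connectome, regions, grid=None) -> pd.DataFrame:
    """Run several configurations and tabulate per-config fit summaries;
    the best configuration is the row with maximal global r^2."""
    rows = []
    for cfg in configs:
        bundle = run_pipeline(cfg, cohort, connectome, regions, grid=grid)
        row = bundle.summary_dict()
        cfg_d = row.pop("config")
        row.update({f"cfg_{k}": v for k, v in cfg_d.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    table["best"] = table["global_r2"] == table["global_r2"].max()
    return table
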