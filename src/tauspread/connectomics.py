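"""Connectivity systems the spreading model diffuses over.

Template connectomes are averages of per-subject region x region weight
matrices.  Functional templates are conventionally thresholded to keep only
the strongest 10% of connections and rescaled to [0, 1].  A Euclidean
distance similarity matrix (normalized, inverted) serves as the
extracellular-spread alternative hypothesis.  Significance of model fit
against "a matrix of similar properties" uses an ensemble of null
connectomes with exactly preserved binary degree sequence and approximately
preserved strength sequence (Maslov-Sneppen rewiring followed by iterative
strength correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class Connectome:
    """Symmetric nonnegative region x region weight matrix."""

    weights: pd.DataFrame
    modality: str = "synthetic"
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self):
        w = self.weights.to_numpy(dtype=float)
        if w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be square")
        if not np.allclose(w, w.T):
            raise ValueError("connectome must be symmetric")
        if (w < 0).any():
            raise ValueError("connectome weights must be nonnegative")
        if not np.allclose(np.diag(w), 0):
            raise ValueError("connectome diagonal must be zero")

    @property
    def region_names(self):
        return list(self.weights.columns)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class NullEnsemble:
    """Randomized connectomes preserving degree (exactly) and strength
    (approximately) of a source connectome."""

    nulls: list  # list of pd.DataFrame
    algorithm: str
    seed: int
    diagnostics: pd.DataFrame  # per-null degree_match (bool), strength_corr

    def __len__(self):
        return len(self.nulls)


def average_connectomes(matrices, region_names=None, modality="structural") -> Connectome:
    """Elementwise mean of same-shape weight matrices (template averaging)."""
    mats = [np.asarray(m.weights if isinstance(m, Connectome) else m, dtype=float) for m in mats_list(matrices)]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("all matrices must share the same shape")
    mean = np.mean(mats, axis=0)
    if region_names is None:
        first = matrices[0]
        if isinstance(first, Connectome):
            region_names = first.region_names
        elif isinstance(first, pd.DataFrame):
            region_names = list(first.columns)
        else:
            region_names = [f"r{i}" for i in range(shape[0])]
    frame = pd.DataFrame(mean, index=region_names, columns=region_names)
    return Connectome(frame, modality=modality, preprocessing={"averaged_n": len(mats)})


def mats_list(matrices):
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    return matrices


def threshold_and_scale(matrix, top_fraction: float = 0.10, modality=None) -> Connectome:
    """Keep the strongest ``top_fraction`` of off-diagonal connections and
    min-max scale the survivors to [0, 1].

    The quota is computed on the unique upper-triangle entries; ties are
    broken by stable index order so the retained count always matches the
    quota exactly.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if isinstance(matrix, Connectome):
        frame = matrix.weights
        modality = modality or matrix.modality
    else:
        frame = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
        modality = modality or "synthetic"
    w = frame.to_numpy(dtype=float).copy()
    if not np.allclose(w, w.T):
        raise ValueError("input must be symmetric")
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    quota = int(round(top_fraction * len(vals)))
    quota = max(quota, 1)
    # stable sort descending by value, ascending by index for ties
    order = np.lexsort((np.arange(len(vals)), -vals))
    keep = order[:quota]
    mask = np.zeros(len(vals), dtype=bool)
    mask[keep] = True
    kept_vals = vals[mask]
    lo, hi = kept_vals.min(), kept_vals.max()
    scaled = np.zeros(len(vals))
    if hi > lo:
        scaled[mask] = (vals[mask] - lo) / (hi - lo)
    else:
        scaled[mask] = 1.0
    out = np.zeros_like(w)
    out[iu, ju] = scaled
    out = out + out.T
    frame_out = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return Connectome(
        frame_out,
        modality=modality,
        preprocessing={"threshold_top_fraction": top_fraction, "scaled": True,
                       "retained_edges": int(quota), "candidate_edges": len(vals)},
    )


def distance_similarity(regions: pd.DataFrame) -> Connectome:
    """Inverted, normalized Euclidean distance matrix between region
    centroids: coincident centroids map to similarity 1, the most distant
    pair to 0.  The scale is anchored at distance zero and the maximum
    off-diagonal distance (so the self-distance does not set the maximum)."""
    for col in ("x", "y", "z"):
        if col not in regions.columns or regions[col].isna().any():
            raise ValueError("region table must provide complete centroids")
    xyz = regions[["x", "y", "z"]].to_numpy(dtype=float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    hi = dist[off].max()
    norm = dist / hi if hi > 0 else np.zeros_like(dist)
    sim = 1.0 - norm
    sim[~off] = 0.0
    sim = np.clip((sim + sim.T) / 2, 0, 1)
    names = list(regions["name"])
    return Connectome(
        pd.DataFrame(sim, index=names, columns=names),
        modality="distance",
        preprocessing={"normalized": "offdiag-minmax", "inverted": True},
    )


def _strength_corrected_weights(binary: np.ndarray, weights_sorted: np.ndarray,
                                target_strength: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Assign the source weight multiset to a rewired binary topology, then
    iteratively rescale edges toward the target strength sequence.

    Initial assignment is rank-matched: edges incident to high expected
    strength get large weights.  Correction multiplies each edge by the mean
    of its endpoint strength deficits.
    """
    n = binary.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    edge_mask = binary[iu, ju] > 0
    ei, ej = iu[edge_mask], ju[edge_mask]
    # rank edges by sum of endpoint target strengths, assign sorted weights
    score = target_strength[ei] + target_strength[ej]
    order = np.argsort(np.argsort(score))
    w_edges = np.sort(weights_sorted)[order]
    for _ in range(n_iter):
        w = np.zeros((n, n))
        w[ei, ej] = w_edges
        w = w + w.T
        s = w.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(s > 0, target_strength / s, 1.0)
        w_edges = w_edges * (ratio[ei] + ratio[ej]) / 2.0
    w = np.zeros((n, n))
    w[ei, ej] = w_edges
    return w + w.T


def generate_nulls(connectome: Connectome, n: int = 100, seed: int = 0,
                   swaps_per_edge: int = 10) -> NullEnsemble:
    """Degree- and strength-preserving null connectomes.

    Binary topology is randomized by Maslov-Sneppen double-edge swaps
    (degree sequence preserved exactly); the original weight multiset is
    then re-assigned with iterative strength correction so null strengths
    correlate highly with the source's.
    """
    w = connectome.weights.to_numpy(dtype=float)
    names = connectome.region_names
    binary = (w > 0).astype(int)
    g = nx.from_numpy_array(binary)
    if g.number_of_edges() < 2:
        raise ValueError("graph too sparse to rewire")
    degree_src = np.array([d for _, d in sorted(g.degree())])
    strength_src = w.sum(axis=1)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    weight_multiset = w[iu, ju][w[iu, ju] > 0]
    rng = np.random.default_rng(seed)
    nulls, diags = [], []
    n_swap = swaps_per_edge * g.number_of_edges()
    for k in range(n):
        gk = g.copy()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.double_edge_swap(gk, nswap=n_swap, max_tries=n_swap * 100,
                                seed=sub_seed)
        except nx.NetworkXAlgorithmError as err:
            raise ValueError(f"rewiring failed on null {k}: {err}") from err
        bk = nx.to_numpy_array(gk, nodelist=sorted(gk.nodes()))
        wk = _strength_corrected_weights(bk, weight_multiset.copy(), strength_src)
        degree_k = bk.sum(axis=1).astype(int)
        corr = float(np.corrcoef(wk.sum(axis=1), strength_src)[0, 1])
        nulls.append(pd.DataFrame(wk, index=names, columns=names))
        diags.append({"null": k, "degree_match": bool((degree_k == degree_src).all()),
                      "strength_corr": corr})
    return NullEnsemble(
        nulls=nulls,
        algorithm="maslov-sneppen+strength-correction",
        seed=seed,
        diagnostics=pd.DataFrame(diags),
    )
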