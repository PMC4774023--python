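"""Assessment statistics for reconstructed 3D structures.

A reconstruction from a contact map is identifiable only up to a similarity
transform (translation, rotation, reflection, uniform scale), so the two
headline accuracy measures are similarity-aware: the Pearson correlation
over all pairwise distances (scale-free by construction) and the Procrustes
superposition RMSD (minimized over the similarity group).  The remaining
statistics validate structures against the data itself (fitted-map
correlation) or against orthogonal assays (FISH distances, protein-mediated
loops) and compare local neighborhoods across structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, pearsonr, spearmanr

from .datamodel import ContactMap, ContactModel, FISHDataset, LoopSet, Structure3D, TrackCovariates
from .likelihood import build_pair_data, _eta, _pair_distances

__all__ = [
    "distance_pcc",
    "superposition_rmsd",
    "fitted_map_pcc",
    "FishScaleResult",
    "fish_scale_fit",
    "LoopTestResult",
    "loop_distance_test",
    "WindowCorrelationResult",
    "local_window_correlation",
]


def distance_pcc(a: Structure3D, b: Structure3D) -> float:
    """Pearson correlation between the condensed pairwise-distance vectors
    of two structures defined on the same loci.

    Invariant under any similarity transform of either argument."""
    if not np.array_equal(a.loci, b.loci):
        raise ValueError("structures must share the same loci")
    if a.n < 3:
        raise ValueError("distance correlation undefined for fewer than 3 loci")
    da, db = pdist(a.coords), pdist(b.coords)
    if np.ptp(da) == 0 or np.ptp(db) == 0:
        raise ValueError("constant distance vector; correlation undefined")
    return float(pearsonr(da, db).statistic)


def superposition_rmsd(
    a: Structure3D,
    b: Structure3D,
    allow_scale: bool = True,
    allow_reflection: bool = True,
) -> float:
    """Minimum root-mean-square coordinate deviation of ``b`` superposed
    onto ``a``.

    Minimizes over translation and rotation always, and optionally over
    reflection and uniform scale (closed form via the SVD of the
    cross-covariance).  Reflection and scaling are allowed by default
    because contact maps cannot resolve chirality or absolute scale.
    """
    if a.n != b.n:
        raise ValueError("structures must have the same number of loci")
    A = a.coords - a.coords.mean(axis=0)
    B = b.coords - b.coords.mean(axis=0)
    M = B.T @ A
    U, sig, Vt = np.linalg.svd(M)
    d = np.ones(3)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        d[-1] = -1.0
    R = U @ np.diag(d) @ Vt
    trace = float(sig @ d)
    if allow_scale:
        denom = float(np.sum(B * B))
        s = max(trace, 0.0) / denom if denom > 0 else 0.0
    else:
        s = 1.0
    resid = A - s * (B @ R)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def fitted_map_pcc(
    structure: Structure3D,
    model: ContactModel,
    cmap: ContactMap,
    covs: TrackCovariates | None = None,
) -> float:
    """Goodness of fit: Pearson correlation between the input map and the
    fitted map ``F_ij = exp(linear predictor)`` over all available pairs
    (power-law distance transform with the track's fitted coefficient,
    plus bias covariates for raw maps)."""
    (pd,) = build_pair_data([cmap], [covs], structure, model.log_covariates)
    d = _pair_distances(structure.coords, pd)
    fitted = np.exp(_eta(model, pd, d))
    if np.ptp(pd.y) == 0 or np.ptp(fitted) == 0:
        raise ValueError("constant input or fitted values; correlation undefined")
    return float(pearsonr(pd.y, fitted).statistic)


@dataclass
class FishScaleResult:
    """No-intercept regression of FISH distances on structure distances.

    ``betas`` and ``pccs`` are keyed by the global end-combination label
    ("AA", "AB", "BA", "BB": which candidate bin was used at each end);
    each beta is the per-structure scale factor vector."""

    betas: dict[str, np.ndarray]
    pccs: dict[str, float]
    membership: np.ndarray  # structure index of each record

    @property
    def pcc_range(self) -> tuple[float, float]:
        vals = list(self.pccs.values())
        return (min(vals), max(vals))


def fish_scale_fit(structures: list[Structure3D], fish: FISHDataset) -> FishScaleResult:
    """Scale ``p`` structures onto FISH physical distances.

    Each record's probed ends overlap two candidate bins; the four global
    end-combinations are enumerated.  For each combination, the FISH
    distances are regressed without intercept on the structure distances
    with per-structure membership indicators; the fitted scale factors and
    the Pearson correlation between FISH and scaled predictions are
    reported per combination.
    """
    p = len(structures)
    if p == 0:
        raise ValueError("need at least one structure")
    loci_sets = [set(int(b) for b in s.loci) for s in structures]
    positions = [s.index_of() for s in structures]
    membership = np.full(fish.n_records, -1)
    for r in range(fish.n_records):
        bins = set(fish.end1_bins[r]) | set(fish.end2_bins[r])
        hits = [k for k, ls in enumerate(loci_sets) if bins <= ls]
        if not hits:
            raise ValueError(f"FISH record {r} maps to no structure")
        membership[r] = hits[0]

    betas: dict[str, np.ndarray] = {}
    pccs: dict[str, float] = {}
    for c1, label1 in ((0, "A"), (1, "B")):
        for c2, label2 in ((0, "A"), (1, "B")):
            dist = np.empty(fish.n_records)
            for r in range(fish.n_records):
                k = membership[r]
                s = structures[k]
                i = positions[k][int(fish.end1_bins[r, c1])]
                j = positions[k][int(fish.end2_bins[r, c2])]
                dist[r] = np.linalg.norm(s.coords[i] - s.coords[j])
            if np.any(dist <= 0):
                raise ValueError("zero predicted distance between probed bins")
            X = np.zeros((fish.n_records, p))
            X[np.arange(fish.n_records), membership] = dist
            beta, *_ = np.linalg.lstsq(X, fish.distances, rcond=None)
            pred = X @ beta
            label = label1 + label2
            betas[label] = beta
            pccs[label] = (
                float(pearsonr(fish.distances, pred).statistic)
                if np.ptp(pred) > 0 else float("nan")
            )
    return FishScaleResult(betas=betas, pccs=pccs, membership=membership)


@dataclass
class LoopTestResult:
    loop_distances: np.ndarray      # scaled by the structure's max anchor distance
    nonloop_distances: np.ndarray
    p_value: float                  # one-sided rank test, loops closer


def loop_distance_test(structure: Structure3D, loops: LoopSet) -> LoopTestResult:
    """Are looped anchor pairs spatially closer than non-looped ones?

    All anchor-pair distances are scaled by their maximum (making
    structures from different methods comparable), then compared with a
    one-sided Mann-Whitney U test (alternative: loop < non-loop).
    """
    pos = structure.index_of()
    anchors = [int(a) for a in loops.anchors if int(a) in pos]
    if len(anchors) < 2:
        raise ValueError("need at least two anchors present in the structure")
    loop_d, nonloop_d = [], []
    for a, b in combinations(anchors, 2):
        d = float(np.linalg.norm(structure.coords[pos[a]] - structure.coords[pos[b]]))
        (loop_d if (a, b) in loops.loops else nonloop_d).append(d)
    if not loop_d or not nonloop_d:
        raise ValueError("both loop and non-loop groups must be non-empty")
    dmax = max(max(loop_d), max(nonloop_d))
    loop_d = np.asarray(loop_d) / dmax
    nonloop_d = np.asarray(nonloop_d) / dmax
    stat = mannwhitneyu(loop_d, nonloop_d, alternative="less")
    return LoopTestResult(loop_d, nonloop_d, float(stat.pvalue))


@dataclass
class WindowCorrelationResult:
    """Local-neighborhood structural conservation across structures."""

    min_pcc: np.ndarray        # per locus: min pairwise PCC (NaN if undefined)
    min_spearman: np.ndarray
    fraction_pcc: float        # fraction of defined loci with all PCC >= threshold
    fraction_spearman: float
    fraction_either: float
    n_undefined: int           # loci excluded for zero-variance windows
    truncated: np.ndarray      # loci whose window hit a chromosome end


def local_window_correlation(
    structures: list[Structure3D],
    window: int = 21,
    threshold: float = 0.7,
) -> WindowCorrelationResult:
    """Per-locus local-structure agreement between every pair of structures.

    For each locus, the pairwise-distance vectors of the ``window`` loci
    centered on it (truncated and flagged at the ends) are correlated
    (Pearson and Spearman) for every pair of structures.  The summary is
    the fraction of loci whose correlations all reach ``threshold``;
    zero-variance windows are excluded from both numerator and denominator
    and counted.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures to compare")
    loci = structures[0].loci
    for s in structures[1:]:
        if not np.array_equal(s.loci, loci):
            raise ValueError("structures must share the same loci")
    n = loci.size
    half = window // 2
    min_pcc = np.full(n, np.nan)
    min_sp = np.full(n, np.nan)
    truncated = np.zeros(n, dtype=bool)
    n_undefined = 0
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        truncated[i] = (hi - lo) < window
        dvecs = [pdist(s.coords[lo:hi]) for s in structures]
        if any(np.ptp(v) == 0 for v in dvecs):
            n_undefined += 1
            continue
        pcs, sps = [], []
        for va, vb in combinations(dvecs, 2):
            pcs.append(pearsonr(va, vb).statistic)
            sps.append(spearmanr(va, vb).statistic)
        min_pcc[i] = min(pcs)
        min_sp[i] = min(sps)
    defined = ~np.isnan(min_pcc)
    n_def = int(defined.sum())
    if n_def == 0:
        frac_p = frac_s = frac_e = float("nan")
    else:
        frac_p = float(np.sum(min_pcc[defined] >= threshold) / n_def)
        frac_s = float(np.sum(min_sp[defined] >= threshold) / n_def)
        frac_e = float(
            np.sum((min_pcc[defined] >= threshold) | (min_sp[defined] >= threshold))
            / n_def
        )
    return WindowCorrelationResult(
        min_pcc=min_pcc,
        min_spearman=min_sp,
        fraction_pcc=frac_p,
        fraction_spearman=frac_s,
        fraction_either=frac_e,
        n_undefined=n_undefined,
        truncated=truncated,
    )
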