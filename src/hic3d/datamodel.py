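"""Core domain types for Hi-C based 3D chromatin structure reconstruction.

A *track* is one contact map produced with one restriction enzyme. Because
enzymes cut at different recognition sites, each track has its own set of
*available* loci; a joint fit models the union of available loci across
tracks with a single shared 3D structure and track-specific regression
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ContactMap",
    "TrackCovariates",
    "Structure3D",
    "TrackGLM",
    "MarkovPrior",
    "ContactModel",
    "FISHDataset",
    "LoopSet",
    "COVARIATE_NAMES",
    "GAP_WEIGHT_MODES",
]

#: Bias covariates modeled for raw (count) contact maps, in column order.
COVARIATE_NAMES = ("frag_len", "gc", "mappability")

#: Supported weightings of the chain penalty by the genomic gap between
#: consecutive modeled loci.  ``linear_gap`` multiplies by the gap,
#: ``inverse_gap`` divides by it (polymer variance grows with gap), and
#: ``uniform`` ignores it.
GAP_WEIGHT_MODES = ("linear_gap", "inverse_gap", "uniform")


@dataclass
class ContactMap:
    """One track's binned intra-chromosomal interaction matrix.

    Entries are stored sparsely as an upper-triangular mapping
    ``(i, j) -> value`` with ``i < j``; zeros are implicit and the diagonal
    is never stored.  ``value`` is a paired-end read count for raw maps, or
    a non-negative normalized intensity.

    Parameters
    ----------
    track_id
        Label for the track (typically the restriction enzyme name).
    n_bins
        Number of binned loci along the region.
    entries
        Upper-triangular ``{(i, j): value}`` with ``0 <= i < j < n_bins``
        and ``value > 0``.
    resolution_bp
        Bin width in base pairs.
    is_normalized
        ``False`` for raw read counts (must be integral), ``True`` for
        normalized intensities (arbitrary non-negative reals).
    available
        Boolean mask over bins marking loci usable for this track.  When
        omitted, a locus is available iff it participates in at least one
        stored contact.
    """

    track_id: str
    n_bins: int
    entries: dict[tuple[int, int], float]
    resolution_bp: int = 1
    is_normalized: bool = False
    available: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("a contact map needs at least 2 bins")
        clean: dict[tuple[int, int], float] = {}
        for (i, j), v in self.entries.items():
            if i == j:
                raise ValueError(f"diagonal entry ({i},{i}) not allowed")
            if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
                raise ValueError(f"bin index out of range in entry ({i},{j})")
            if v < 0:
                raise ValueError(f"negative contact value at ({i},{j}): {v}")
            if not self.is_normalized and float(v) != int(v):
                raise ValueError(
                    f"raw contact map requires integer counts, got {v} at ({i},{j})"
                )
            if v == 0:
                continue
            key = (i, j) if i < j else (j, i)
            clean[key] = clean.get(key, 0.0) + float(v)
        self.entries = clean
        if self.available is None:
            mask = np.zeros(self.n_bins, dtype=bool)
            for i, j in clean:
                mask[i] = True
                mask[j] = True
            self.available = mask
        else:
            self.available = np.asarray(self.available, dtype=bool)
            if self.available.shape != (self.n_bins,):
                raise ValueError("availability mask length must equal n_bins")

    @property
    def available_loci(self) -> np.ndarray:
        """Sorted array of available bin indices."""
        return np.flatnonzero(self.available)

    def value(self, i: int, j: int) -> float:
        """Contact value between bins ``i`` and ``j`` (0 if unstored)."""
        if i == j:
            raise ValueError("diagonal has no contact value")
        key = (i, j) if i < j else (j, i)
        return self.entries.get(key, 0.0)

    def dense(self) -> np.ndarray:
        """Symmetric dense matrix view (zero diagonal)."""
        m = np.zeros((self.n_bins, self.n_bins))
        for (i, j), v in self.entries.items():
            m[i, j] = m[j, i] = v
        return m


@dataclass
class TrackCovariates:
    """Per-locus bias covariates for one track.

    Columns are strictly positive: pairwise covariates enter the model as
    logarithms of per-locus products, ``ln(x_ik * x_jk)``.
    """

    track_id: str
    values: np.ndarray  # (n_bins, k) strictly positive

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("covariates must be finite and strictly positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class Structure3D:
    """Ordered 3D coordinates of modeled loci.

    ``loci`` are the strictly increasing bin indices l_1 < ... < l_n (the
    union of available loci across tracks); ``coords`` is the matching
    (n, 3) coordinate matrix.  Fitted structures are anchored with the first
    locus at the origin; free-standing structures (e.g. simulated ground
    truths) need not be.
    """

    loci: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.loci.ndim != 1 or self.loci.size < 2:
            raise ValueError("need at least 2 loci")
        if np.any(np.diff(self.loci) <= 0):
            raise ValueError("loci must be strictly increasing")
        if self.coords.shape != (self.loci.size, 3):
            raise ValueError("coords must be (n_loci, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return self.loci.size

    def index_of(self) -> dict[int, int]:
        """Map bin index -> row in ``coords``."""
        return {int(b): r for r, b in enumerate(self.loci)}

    def pairwise_distances(self) -> np.ndarray:
        """Condensed vector of all n(n-1)/2 pairwise Euclidean distances."""
        from scipy.spatial.distance import pdist

        return pdist(self.coords)


@dataclass
class TrackGLM:
    """Poisson regression coefficients for one track.

    ln mu_ij = beta0 + beta1 * ln d_ij + sum_k beta_cov[k] * ln(x_ik x_jk).
    ``beta1`` is the power-law coefficient relating contact frequency to 3D
    distance; it is negative for any physically sensible fit.
    """

    beta0: float = 0.0
    beta1: float = -1.0
    beta_cov: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.beta_cov = np.asarray(self.beta_cov, dtype=float).ravel()


@dataclass
class MarkovPrior:
    """Gaussian chain prior on consecutive loci: S_i | S_{i-1} ~ N(A S_{i-1} + b, (1/lam) I).

    Acts on the log-likelihood as a quadratic distance penalty
    ``-lam * g(gap) * ||S_i - A S_{i-1} - b||^2`` summed over consecutive
    modeled loci, where ``g`` is set by ``gap_weight_mode``.  ``lam = 0``
    disables smoothing entirely.
    """

    A: np.ndarray = field(default_factory=lambda: np.eye(3))
    b: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lam: float = 0.0
    gap_weight_mode: str = "linear_gap"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.A.shape != (3, 3) or self.b.shape != (3,):
            raise ValueError("A must be 3x3 and b length 3")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.gap_weight_mode not in GAP_WEIGHT_MODES:
            raise ValueError(f"gap_weight_mode must be one of {GAP_WEIGHT_MODES}")

    def gap_weight(self, gap: np.ndarray | float) -> np.ndarray | float:
        if self.gap_weight_mode == "linear_gap":
            return gap
        if self.gap_weight_mode == "inverse_gap":
            return 1.0 / gap
        return np.ones_like(np.asarray(gap, dtype=float))


@dataclass
class ContactModel:
    """Full model state: per-track GLM coefficients plus the chain prior."""

    tracks: dict[str, TrackGLM]
    markov: MarkovPrior = field(default_factory=MarkovPrior)
    #: if False, pairwise covariates enter untransformed instead of as logs
    log_covariates: bool = True

    def track(self, track_id: str) -> TrackGLM:
        return self.tracks[track_id]


@dataclass
class FISHDataset:
    """FISH-measured mean physical distances between probed locus pairs.

    Each probed end overlaps two candidate Hi-C bins, so a record carries
    two candidate bin indices per end (repeat the index if unambiguous).
    """

    end1_bins: np.ndarray  # (M, 2)
    end2_bins: np.ndarray  # (M, 2)
    distances: np.ndarray  # (M,) physical distances, > 0

    def __post_init__(self) -> None:
        self.end1_bins = np.atleast_2d(np.asarray(self.end1_bins, dtype=int))
        self.end2_bins = np.atleast_2d(np.asarray(self.end2_bins, dtype=int))
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        m = self.distances.size
        if self.end1_bins.shape != (m, 2) or self.end2_bins.shape != (m, 2):
            raise ValueError("each end needs exactly 2 candidate bins per record")
        if np.any(self.distances <= 0):
            raise ValueError("FISH distances must be positive")

    @property
    def n_records(self) -> int:
        return self.distances.size


@dataclass
class LoopSet:
    """Protein-mediated interaction loops among a set of anchor bins."""

    anchors: np.ndarray
    loops: set[tuple[int, int]]

    def __post_init__(self) -> None:
        self.anchors = np.unique(np.asarray(self.anchors, dtype=int))
        anchor_set = set(int(a) for a in self.anchors)
        norm: set[tuple[int, int]] = set()
        for a, b in self.loops:
            if a == b:
                raise ValueError("a loop needs two distinct anchors")
            if a not in anchor_set or b not in anchor_set:
                raise ValueError(f"loop ({a},{b}) references a non-anchor bin")
            norm.add((min(a, b), max(a, b)))
        self.loops = norm
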