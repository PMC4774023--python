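"""Readers and writers for the plain-text table formats used by the package.

Formats
-------
* contact map, triplet: TSV rows ``i<TAB>j<TAB>value`` with 0-based bin
  indices; symmetric duplicates are merged, diagonal entries dropped.
* contact map, dense: whitespace-delimited square matrix (convenience).
* covariate table: BED-like TSV with header
  ``chrom start end available frag_len gc mappability``.
* structure: TSV with header
  ``bin_index genomic_start genomic_end x y z``; round-trips bit-exactly.
* FISH table: TSV ``end1_binA end1_binB end2_binA end2_binB distance``.
* loop table: TSV ``anchor_bin1 anchor_bin2 is_loop``.

Bin coordinates are 0-based, half-open ``[start, end)`` at the stated
resolution.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    COVARIATE_NAMES,
    ContactMap,
    FISHDataset,
    LoopSet,
    Structure3D,
    TrackCovariates,
)

__all__ = [
    "read_contact_map",
    "write_contact_map",
    "signal_coverage",
    "union_loci",
    "read_covariates",
    "write_covariates",
    "read_structure",
    "write_structure",
    "read_fish_table",
    "read_loop_table",
]


def read_contact_map(
    path: str | Path,
    format: str = "triplet",
    is_normalized: bool = False,
    track_id: str | None = None,
    n_bins: int | None = None,
    resolution_bp: int = 1,
) -> ContactMap:
    """Read a contact map from a triplet or dense text file.

    Symmetric duplicates ``(j, i)`` are merged with ``(i, j)`` (values must
    agree), the diagonal is dropped, and negative values are rejected.  For
    triplet input ``n_bins`` defaults to ``max index + 1``.
    """
    path = Path(path)
    if track_id is None:
        track_id = path.stem
    if format == "dense":
        m = np.loadtxt(path, ndmin=2)
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"dense contact map must be square, got {m.shape}")
        if n_bins is not None and n_bins != m.shape[0]:
            raise ValueError("n_bins does not match dense matrix size")
        entries: dict[tuple[int, int], float] = {}
        iu, ju = np.triu_indices(m.shape[0], k=1)
        for i, j in zip(iu, ju):
            a, b = m[i, j], m[j, i]
            if a != b:
                raise ValueError(f"asymmetric dense matrix at ({i},{j}): {a} != {b}")
            if a < 0:
                raise ValueError(f"negative contact value at ({i},{j}): {a}")
            if a != 0:
                entries[(int(i), int(j))] = float(a)
        return ContactMap(track_id, int(m.shape[0]), entries,
                          resolution_bp=resolution_bp, is_normalized=is_normalized)
    if format != "triplet":
        raise ValueError("format must be 'triplet' or 'dense'")

    entries = {}
    max_idx = -1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'i j value', got {line!r}")
            i, j = int(parts[0]), int(parts[1])
            v = float(parts[2])
            if v < 0:
                raise ValueError(f"{path}:{ln}: negative contact value {v}")
            if not is_normalized and v != int(v):
                raise ValueError(f"{path}:{ln}: raw map requires integer counts, got {v}")
            if i == j or v == 0:
                continue
            key = (min(i, j), max(i, j))
            if key in entries and entries[key] != v:
                raise ValueError(f"{path}:{ln}: conflicting duplicate for pair {key}")
            entries[key] = v
            max_idx = max(max_idx, i, j)
    nb = n_bins if n_bins is not None else max_idx + 1
    return ContactMap(track_id, nb, entries, resolution_bp=resolution_bp,
                      is_normalized=is_normalized)


def write_contact_map(cmap: ContactMap, path: str | Path) -> None:
    """Write the upper-triangular entries as a triplet TSV."""
    with open(path, "w") as fh:
        for (i, j), v in sorted(cmap.entries.items()):
            val = int(v) if not cmap.is_normalized else repr(v)
            fh.write(f"{i}\t{j}\t{val}\n")


def signal_coverage(cmap: ContactMap) -> float:
    """Fraction of non-zero off-diagonal upper-triangle entries in a map."""
    total = cmap.n_bins * (cmap.n_bins - 1) // 2
    return len(cmap.entries) / total


def union_loci(maps: list[ContactMap]) -> np.ndarray:
    """Sorted union of available bin indices across tracks (l_1 < ... < l_n)."""
    if not maps:
        raise ValueError("need at least one contact map")
    n_bins = maps[0].n_bins
    for m in maps[1:]:
        if m.n_bins != n_bins:
            raise ValueError(
                f"tracks disagree on n_bins: {m.n_bins} vs {n_bins}"
            )
    mask = np.zeros(n_bins, dtype=bool)
    for m in maps:
        mask |= m.available
    return np.flatnonzero(mask)


def read_covariates(path: str | Path, track_id: str | None = None
                    ) -> tuple[TrackCovariates, np.ndarray]:
    """Read a BED-like covariate table.

    Returns the covariates and the table's availability flags (used to
    override a map's contact-derived availability when supplied).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["chrom", "start", "end", "available", *COVARIATE_NAMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    covs = TrackCovariates(
        track_id or path.stem,
        df[list(COVARIATE_NAMES)].to_numpy(dtype=float),
    )
    avail = df["available"].to_numpy().astype(bool)
    return covs, avail


def write_covariates(
    covs: TrackCovariates,
    path: str | Path,
    available: np.ndarray | None = None,
    chrom: str = "chrSim",
    resolution_bp: int = 1,
) -> None:
    n = covs.n_bins
    df = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * resolution_bp,
        "end": (np.arange(n) + 1) * resolution_bp,
        "available": (np.ones(n, dtype=bool) if available is None
                      else np.asarray(available, dtype=bool)).astype(int),
    })
    for k, name in enumerate(COVARIATE_NAMES):
        df[name] = [repr(float(v)) for v in covs.values[:, k]]
    df.to_csv(path, sep="\t", index=False)


def write_structure(s: Structure3D, path: str | Path, resolution_bp: int = 1) -> None:
    """Write a structure as TSV; coordinates use full repr precision so the
    write→read round trip is bit-exact."""
    with open(path, "w") as fh:
        fh.write("bin_index\tgenomic_start\tgenomic_end\tx\ty\tz\n")
        for b, (x, y, z) in zip(s.loci, s.coords):
            fh.write(
                f"{int(b)}\t{int(b) * resolution_bp}\t{(int(b) + 1) * resolution_bp}"
                f"\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n"
            )


def read_structure(path: str | Path) -> Structure3D:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["bin_index", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"structure table missing columns: {missing}")
    return Structure3D(
        df["bin_index"].to_numpy(dtype=int),
        df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def read_fish_table(path: str | Path) -> FISHDataset:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["end1_binA", "end1_binB", "end2_binA", "end2_binB", "distance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"FISH table missing columns: {missing}")
    return FISHDataset(
        df[["end1_binA", "end1_binB"]].to_numpy(dtype=int),
        df[["end2_binA", "end2_binB"]].to_numpy(dtype=int),
        df["distance"].to_numpy(dtype=float),
    )


def read_loop_table(path: str | Path) -> LoopSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["anchor_bin1", "anchor_bin2", "is_loop"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"loop table missing columns: {missing}")
    a1 = df["anchor_bin1"].to_numpy(dtype=int)
    a2 = df["anchor_bin2"].to_numpy(dtype=int)
    flags = df["is_loop"].to_numpy().astype(bool)
    anchors = np.union1d(a1, a2)
    loops = {(min(i, j), max(i, j)) for i, j, f in zip(a1, a2, flags) if f}
    return LoopSet(anchors, loops)
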