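"""Poisson log-likelihood of contact maps given a 3D structure, with a
Gaussian-chain smoothing penalty, and its analytic coordinate gradient.

Model
-----
For each track ``c`` and each pair of available loci ``i < j``::

    n_ij ~ Poisson(mu_ij)
    ln mu_ij = beta_c0 + beta_c1 * ln d_ij + sum_k beta_ck * ln(x_ik x_jk)
    d_ij = ||S_i - S_j||

Raw maps use read counts and the bias covariates; normalized maps use the
normalized intensity as the response and drop the covariate sum (the same
score equations apply, in the quasi-Poisson sense).  The sum runs over ALL
available pairs — zero entries contribute ``-mu_ij``.

Consecutive modeled loci carry a Gaussian chain prior
``S_i | S_{i-1} ~ N(A S_{i-1} + b, (1/lambda) I3)`` whose log-density is,
up to a constant, the quadratic penalty
``-lambda * g(l_i - l_{i-1}) * ||S_i - A S_{i-1} - b||^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import ContactMap, ContactModel, Structure3D, TrackCovariates

__all__ = [
    "DegenerateGeometryError",
    "LogLikTerms",
    "EPS_GEOM",
    "TrackPairData",
    "build_pair_data",
    "linear_predictor",
    "glm_loglik",
    "markov_penalty",
    "loglik_terms",
    "loglik_gradient",
]

#: Floor on pair distances inside ``ln d`` to keep line searches finite.
EPS_GEOM = 1e-8


class DegenerateGeometryError(ValueError):
    """Raised when modeled loci coincide (zero pairwise distance)."""


@dataclass
class LogLikTerms:
    """Decomposed log-likelihood.

    ``total = glm_term + penalty_term + constant``; the constant
    ``-3(n-1)/2 ln(2pi)`` from the chain prior does not affect the argmax
    and is dropped during optimization but reported here.
    """

    glm_term: float
    penalty_term: float
    constant: float

    @property
    def total(self) -> float:
        return self.glm_term + self.penalty_term + self.constant


@dataclass
class TrackPairData:
    """Vectorized per-track pair arrays, in structure-row coordinates.

    Precomputed once per (maps, structure) combination so repeated
    likelihood/gradient evaluations inside the optimizer are cheap.
    """

    track_id: str
    rows_i: np.ndarray        # structure row of the first pair member
    rows_j: np.ndarray        # structure row of the second pair member
    y: np.ndarray             # counts / intensities, zeros included
    cov_logsum: np.ndarray | None   # (n_pairs, K) ln(x_ik x_jk), None if normalized


def _covs_for(covs, idx: int, track_id: str) -> TrackCovariates | None:
    if covs is None:
        return None
    if isinstance(covs, dict):
        return covs.get(track_id)
    return covs[idx]


def build_pair_data(
    maps: list[ContactMap],
    covs,
    structure: Structure3D,
    log_covariates: bool = True,
) -> list[TrackPairData]:
    """Assemble per-track pair arrays over each track's available loci.

    ``covs`` may be ``None``, a list parallel to ``maps``, or a dict keyed
    by track id.  Raw maps require covariates; normalized maps ignore them.
    """
    pos = structure.index_of()
    out = []
    for t, cmap in enumerate(maps):
        avail = cmap.available_loci
        missing = [int(b) for b in avail if int(b) not in pos]
        if missing:
            raise ValueError(
                f"track {cmap.track_id!r} has available loci outside the "
                f"structure: {missing[:5]}"
            )
        rows = np.array([pos[int(b)] for b in avail], dtype=int)
        a, b = np.triu_indices(avail.size, k=1)
        bins_i, bins_j = avail[a], avail[b]
        y = np.array([cmap.entries.get((int(i), int(j)), 0.0)
                      for i, j in zip(bins_i, bins_j)])
        cov_logsum = None
        tc = _covs_for(covs, t, cmap.track_id) if not cmap.is_normalized else None
        if tc is not None:
            if tc.n_bins != cmap.n_bins:
                raise ValueError("covariate table length must equal n_bins")
            x = tc.values[avail]          # (n_avail, K)
            if log_covariates:
                lx = np.log(x)
                cov_logsum = lx[a] + lx[b]
            else:
                cov_logsum = x[a] * x[b]
        out.append(TrackPairData(cmap.track_id, rows[a], rows[b], y, cov_logsum))
    return out


def _pair_distances(coords: np.ndarray, pd: TrackPairData) -> np.ndarray:
    diff = coords[pd.rows_i] - coords[pd.rows_j]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def _eta(model: ContactModel, pd: TrackPairData, d: np.ndarray) -> np.ndarray:
    g = model.track(pd.track_id)
    eta = g.beta0 + g.beta1 * np.log(np.maximum(d, EPS_GEOM))
    if pd.cov_logsum is not None and g.beta_cov.size:
        eta = eta + pd.cov_logsum @ g.beta_cov
    return eta


def linear_predictor(
    model: ContactModel,
    track_id: str,
    structure: Structure3D,
    covs: TrackCovariates | None,
    pair: tuple[int, int],
    is_normalized: bool = False,
) -> float:
    """``ln mu_ij`` for a single pair of bin indices on one track.

    For normalized maps (``is_normalized=True``) the covariate sum is
    omitted.  Coincident coordinates raise :class:`DegenerateGeometryError`.
    """
    i, j = pair
    if i == j:
        raise ValueError("linear predictor needs two distinct loci")
    pos = structure.index_of()
    d = float(np.linalg.norm(structure.coords[pos[i]] - structure.coords[pos[j]]))
    if d <= 0.0:
        raise DegenerateGeometryError(f"loci {i} and {j} coincide (d=0)")
    g = model.track(track_id)
    eta = g.beta0 + g.beta1 * np.log(d)
    if not is_normalized and covs is not None and g.beta_cov.size:
        xi, xj = covs.values[i], covs.values[j]
        pairwise = np.log(xi * xj) if model.log_covariates else xi * xj
        eta += float(pairwise @ g.beta_cov)
    return float(eta)


def _check_degenerate(d: np.ndarray) -> None:
    if np.any(d < EPS_GEOM):
        warnings.warn(
            "pair distance at the geometric floor; likelihood is degenerate there",
            RuntimeWarning,
            stacklevel=3,
        )


def glm_loglik(
    model: ContactModel,
    maps: list[ContactMap],
    covs,
    structure: Structure3D,
    pair_data: list[TrackPairData] | None = None,
) -> float:
    """Poisson GLM term: sum over tracks and all available pairs of
    ``-mu_ij + n_ij ln mu_ij``."""
    if pair_data is None:
        pair_data = build_pair_data(maps, covs, structure, model.log_covariates)
    total = 0.0
    for pd in pair_data:
        d = _pair_distances(structure.coords, pd)
        _check_degenerate(d)
        eta = _eta(model, pd, d)
        total += float(np.sum(-np.exp(eta) + pd.y * eta))
    return total


def markov_penalty(model: ContactModel, structure: Structure3D) -> float:
    """Chain-prior penalty ``-sum_i lam * g(gap_i) * ||S_i - A S_{i-1} - b||^2``.

    Returns 0 when ``lam = 0`` (no smoothing)."""
    mk = model.markov
    if mk.lam == 0.0:
        return 0.0
    gaps = np.diff(structure.loci).astype(float)
    resid = structure.coords[1:] - structure.coords[:-1] @ mk.A.T - mk.b
    sq = np.einsum("ij,ij->i", resid, resid)
    return float(-mk.lam * np.sum(mk.gap_weight(gaps) * sq))


def loglik_terms(
    model: ContactModel,
    maps: list[ContactMap],
    covs,
    structure: Structure3D,
    pair_data: list[TrackPairData] | None = None,
) -> LogLikTerms:
    """Full decomposed log-likelihood (GLM + penalty + prior constant)."""
    n = structure.n
    return LogLikTerms(
        glm_term=glm_loglik(model, maps, covs, structure, pair_data),
        penalty_term=markov_penalty(model, structure),
        constant=-1.5 * (n - 1) * np.log(2.0 * np.pi),
    )


def loglik_gradient(
    model: ContactModel,
    maps: list[ContactMap],
    covs,
    structure: Structure3D,
    pair_data: list[TrackPairData] | None = None,
) -> np.ndarray:
    """Gradient of (GLM term + penalty) with respect to coordinates, (n, 3).

    For a pair (i, j): d(lnL)/dS_i = (n_ij - mu_ij) * beta1 / d^2 * (S_i - S_j),
    and the opposite for S_j.  The chain penalty contributes
    ``-2 lam g (S_i - A S_{i-1} - b)`` to S_i and ``+2 lam g A^T (...)`` to
    S_{i-1}.
    """
    if pair_data is None:
        pair_data = build_pair_data(maps, covs, structure, model.log_covariates)
    coords = structure.coords
    n = coords.shape[0]
    grad = np.zeros((n, 3))
    for pd in pair_data:
        g = model.track(pd.track_id)
        diff = coords[pd.rows_i] - coords[pd.rows_j]
        d2 = np.einsum("ij,ij->i", diff, diff)
        d = np.sqrt(d2)
        _check_degenerate(d)
        d2 = np.maximum(d2, EPS_GEOM**2)
        eta = _eta(model, pd, d)
        w = (pd.y - np.exp(eta)) * g.beta1 / d2
        contrib = diff * w[:, None]
        for dim in range(3):
            grad[:, dim] += np.bincount(pd.rows_i, weights=contrib[:, dim], minlength=n)
            grad[:, dim] -= np.bincount(pd.rows_j, weights=contrib[:, dim], minlength=n)
    mk = model.markov
    if mk.lam > 0.0:
        gaps = np.diff(structure.loci).astype(float)
        gw = mk.lam * np.asarray(mk.gap_weight(gaps), dtype=float)
        resid = coords[1:] - coords[:-1] @ mk.A.T - mk.b
        grad[1:] += -2.0 * gw[:, None] * resid
        grad[:-1] += 2.0 * gw[:, None] * (resid @ mk.A)
    return grad
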