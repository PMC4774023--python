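"""Model fitting: two-stage initialization followed by simulated annealing
with Hamiltonian dynamics and alternating Poisson-GLM coefficient refits.

The fit maximizes the total log-likelihood (Poisson GLM term plus chain
penalty) jointly over the 3D coordinates of the union loci and the
per-track regression coefficients:

1. *Coefficient initialization* — per-track Poisson regression of counts on
   the log covariate products, without the distance term; the power-law
   coefficient starts at -1.
2. *Sequential structure initialization* — loci are placed one at a time,
   each maximizing the partial likelihood against its previous
   ``min(5, i-1)`` placed loci plus the chain penalty (smoothing weight
   ``ceil(sqrt(n))`` during this stage), with a small multistart.
3. *Annealed exploration* — at temperature ``T`` the sampler targets
   ``exp(loglik / T)``; each outer iteration makes one Hamiltonian
   (leapfrog) proposal on all coordinates, Metropolis-accepts it, refits
   all coefficients by IRLS with ``ln d`` as a regressor, and cools
   ``T <- T * cooling_rate``.  The best-ever state is tracked.
4. *Polish* — deterministic alternation of L-BFGS-B on coordinates and
   IRLS on coefficients until the likelihood stops improving.

Randomness is confined to one ``numpy`` Generator derived from the config
seed, so runs are reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .datamodel import (
    ContactMap,
    ContactModel,
    MarkovPrior,
    Structure3D,
    TrackGLM,
)
from .io import signal_coverage, union_loci
from .likelihood import (
    EPS_GEOM,
    TrackPairData,
    build_pair_data,
    loglik_gradient,
    loglik_terms,
    markov_penalty,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "IRLSError",
    "init_betas",
    "init_structure",
    "hmc_sa_fit",
    "fit_multitrack",
    "model_to_dict",
    "model_from_dict",
]


@dataclass
class HMCConfig:
    leapfrog_steps: int = 10
    step_size: float | None = None  # None -> auto-tuned during burn-in
    mass: float = 1.0


@dataclass
class AnnealConfig:
    T0: float = 10.0
    cooling_rate: float = 0.95
    T_min: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.cooling_rate < 1):
            raise ValueError("cooling_rate must lie in (0, 1)")
        if not (self.T0 >= self.T_min > 0):
            raise ValueError("need T0 >= T_min > 0")


@dataclass
class FitConfig:
    """Tuning knobs of the fit; defaults suit maps of ~100 loci."""

    seed: int = 0
    max_outer_iters: int = 400
    inner_hmc: HMCConfig = field(default_factory=HMCConfig)
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    #: "auto" applies smoothing (lambda=1) when any track's signal coverage
    #: is under 10%, none (lambda=0) otherwise; a number fixes lambda.
    lambda_policy: str | float = "auto"
    gap_weight_mode: str = "linear_gap"
    tol_rel_loglik: float = 1e-7
    beta1_sign_constraint: bool = True
    log_covariates: bool = True
    polish_rounds: int = 60


@dataclass
class FitResult:
    structure: Structure3D
    model: ContactModel
    loglik_trace: list[float]          # best-so-far total per outer iteration
    converged: bool
    per_track_alpha: dict[str, float]  # fitted power-law coefficients
    iteration_log: list[dict] = field(default_factory=list, repr=False)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


class IRLSError(RuntimeError):
    """Poisson IRLS failed to converge."""


def _irls_poisson(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    offset: np.ndarray | float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> np.ndarray:
    """Poisson maximum likelihood by iteratively reweighted least squares.

    Converges when the score norm drops below ``tol`` relative to the
    scale of ``X^T y``.  Works for non-integer responses too (quasi-Poisson
    score equations).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    scale = max(1.0, float(np.linalg.norm(X.T @ y)))

    def loglik(b: np.ndarray) -> float:
        eta = np.clip(X @ b + offset, -500, 500)
        return float(np.sum(y * eta - np.exp(eta)))

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -500, 500)
        mu = np.exp(eta)
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol * scale:
            return beta
        XtWX = (X * mu[:, None]).T @ X
        XtWX[np.diag_indices_from(XtWX)] += 1e-12
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:  # singular design
            raise IRLSError(f"singular weighted design: {exc}") from exc
        # step halving keeps the Newton iteration monotone
        t = 1.0
        for _ in range(60):
            cand = beta + t * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12 * abs(ll):
                break
            t *= 0.5
        beta = beta + t * step
        ll = loglik(beta)
    eta = np.clip(X @ beta + offset, -500, 500)
    score = X.T @ (y - np.exp(eta))
    if np.linalg.norm(score) < 1e-4 * scale:  # close enough to report
        return beta
    raise IRLSError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(|score|={np.linalg.norm(score):.3e}, scale={scale:.3e})"
    )


def init_betas(
    maps: list[ContactMap],
    covs,
    log_covariates: bool = True,
    gap_weight_mode: str = "linear_gap",
) -> ContactModel:
    """Initialize per-track coefficients by fitting the GLM *without* the
    distance power-law term; the power-law coefficient starts at -1."""
    if not maps:
        raise ValueError("need at least one contact map")
    model = ContactModel(
        tracks={},
        markov=MarkovPrior(gap_weight_mode=gap_weight_mode),
        log_covariates=log_covariates,
    )
    loci = union_loci(maps)
    structure = Structure3D(loci, _chain_placeholder(loci.size))
    pair_data = build_pair_data(maps, covs, structure, log_covariates)
    for pd in pair_data:
        if pd.cov_logsum is not None:
            X = np.column_stack([np.ones(pd.y.size), pd.cov_logsum])
        else:
            X = np.ones((pd.y.size, 1))
        start = np.zeros(X.shape[1])
        start[0] = math.log(max(pd.y.mean(), 1e-12))
        beta = _irls_poisson(X, pd.y, beta0=start)
        model.tracks[pd.track_id] = TrackGLM(
            beta0=float(beta[0]), beta1=-1.0, beta_cov=beta[1:]
        )
    return model


def _chain_placeholder(n: int) -> np.ndarray:
    # straight line; only used so build_pair_data has a valid structure
    return np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])


def _partial_neg_loglik_and_grad(
    s: np.ndarray,
    anchors: np.ndarray,       # (m, 3) fixed coordinates
    y: np.ndarray,             # (m_pairs,) counts, aligned with anchor_idx
    anchor_idx: np.ndarray,    # which anchor each observation refers to
    const: np.ndarray,         # beta0 + covariate part per observation
    beta1: np.ndarray,         # per-observation power-law coefficient
    lam_gap: float,            # chain weight toward the immediate predecessor
    prev: np.ndarray,          # predecessor coordinate
) -> tuple[float, np.ndarray]:
    diff = s[None, :] - anchors[anchor_idx]
    d2 = np.maximum(np.einsum("ij,ij->i", diff, diff), EPS_GEOM**2)
    d = np.sqrt(d2)
    eta = const + beta1 * np.log(d)
    mu = np.exp(np.clip(eta, -500, 500))
    ll = float(np.sum(-mu + y * eta))
    grad = np.sum(((y - mu) * beta1 / d2)[:, None] * diff, axis=0)
    if lam_gap > 0:
        r = s - prev
        ll -= lam_gap * float(r @ r)
        grad -= 2.0 * lam_gap * r
    return -ll, -grad


def init_structure(
    model: ContactModel,
    maps: list[ContactMap],
    covs,
    lambda_init: float | None = None,
    seed: int | np.random.Generator = 0,
    n_starts: int = 3,
) -> Structure3D:
    """Sequential structure initialization.

    The first locus sits at the origin; each subsequent locus maximizes the
    partial log-likelihood against its previous ``min(5, i-1)`` placed loci
    plus the chain penalty, by L-BFGS-B from ``n_starts`` jittered starts
    at the predecessor's position.  The default smoothing weight for this
    stage is ``ceil(sqrt(n))``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = union_loci(maps)
    n = loci.size
    lam = float(math.ceil(math.sqrt(n))) if lambda_init is None else float(lambda_init)
    pos = {int(b): r for r, b in enumerate(loci)}

    # per-track quick lookups: value and covariate part per bin pair
    lookups = []
    structure_stub = Structure3D(loci, _chain_placeholder(n))
    pair_data = build_pair_data(maps, covs, structure_stub, model.log_covariates)
    for cmap, pd in zip(maps, pair_data):
        g = model.track(cmap.track_id)
        const = np.full(pd.y.size, g.beta0)
        if pd.cov_logsum is not None and g.beta_cov.size:
            const = const + pd.cov_logsum @ g.beta_cov
        table: dict[tuple[int, int], tuple[float, float]] = {}
        for ri, rj, yv, cv in zip(pd.rows_i, pd.rows_j, pd.y, const):
            table[(int(ri), int(rj))] = (float(yv), float(cv))
        lookups.append((g.beta1, table))

    coords = np.zeros((n, 3))
    gap_w = model.markov.gap_weight
    flagged: list[int] = []
    jitter = 1.0
    for i in range(1, n):
        lo = max(0, i - 5)
        anchors = coords[lo:i]
        obs_y, obs_idx, obs_const, obs_b1 = [], [], [], []
        for t_beta1, table in lookups:
            for a in range(lo, i):
                key = (a, i)
                if key in table:
                    yv, cv = table[key]
                    obs_y.append(yv)
                    obs_idx.append(a - lo)
                    obs_const.append(cv)
                    obs_b1.append(t_beta1)
        gap = float(loci[i] - loci[i - 1])
        lam_gap = lam * float(gap_w(gap))
        prev = coords[i - 1]
        if not obs_y and lam_gap == 0.0:
            # no information at all: step one unit along the chain direction
            flagged.append(int(loci[i]))
            direction = coords[i - 1] - coords[i - 2] if i >= 2 else np.array([1.0, 0, 0])
            nrm = np.linalg.norm(direction)
            coords[i] = prev + (direction / nrm if nrm > 0 else np.array([1.0, 0, 0]))
            continue
        y = np.asarray(obs_y)
        idx = np.asarray(obs_idx, dtype=int)
        const = np.asarray(obs_const)
        b1 = np.asarray(obs_b1)
        best_val, best_s = np.inf, prev + np.array([jitter, 0, 0])
        for _ in range(n_starts):
            s0 = prev + rng.normal(scale=0.5 * jitter, size=3)
            res = minimize(
                _partial_neg_loglik_and_grad, s0, jac=True,
                args=(anchors, y, idx, const, b1, lam_gap, prev),
                method="L-BFGS-B",
            )
            if res.fun < best_val:
                best_val, best_s = res.fun, res.x
        coords[i] = best_s
        if i >= 2:
            placed = np.linalg.norm(np.diff(coords[: i + 1], axis=0), axis=1)
            jitter = max(float(np.median(placed)), 1e-3)
    s = Structure3D(loci, coords)
    s.flagged_loci = flagged  # loci placed without any data
    return s


def _resolve_lambda(maps: list[ContactMap], policy) -> float:
    if policy == "auto":
        return 1.0 if any(signal_coverage(m) < 0.10 for m in maps) else 0.0
    return float(policy)


def _refit_betas(
    model: ContactModel,
    pair_data: list[TrackPairData],
    coords: np.ndarray,
    sign_constraint: bool,
) -> None:
    """Conditional maximization over coefficients given the coordinates:
    per-track Poisson IRLS with ln d as a fixed regressor (in place)."""
    for pd in pair_data:
        g = model.track(pd.track_id)
        diff = coords[pd.rows_i] - coords[pd.rows_j]
        lnd = 0.5 * np.log(np.maximum(np.einsum("ij,ij->i", diff, diff), EPS_GEOM**2))
        cols = [np.ones(pd.y.size), lnd]
        if pd.cov_logsum is not None:
            cols.append(pd.cov_logsum)
        X = np.column_stack(cols)
        start = np.concatenate([[g.beta0, g.beta1], g.beta_cov])
        beta = _irls_poisson(X, pd.y, beta0=start, tol=1e-8)
        if sign_constraint and beta[1] >= 0.0:
            # pin the power-law coefficient slightly negative and refit the rest
            b1 = -1e-3
            Xr = np.delete(X, 1, axis=1)
            br = _irls_poisson(Xr, pd.y, offset=b1 * lnd, tol=1e-8)
            beta = np.concatenate([[br[0], b1], br[1:]])
        g.beta0, g.beta1, g.beta_cov = float(beta[0]), float(beta[1]), beta[2:]


def _potential(model, maps, covs, structure, pair_data) -> float:
    t = loglik_terms(model, maps, covs, structure, pair_data)
    return -(t.glm_term + t.penalty_term)


def _leapfrog(coords, p, eps, n_steps, grad_fn, inv_T, mass=1.0):
    """Leapfrog integration of H = U/T + |p|^2 / (2 mass)."""
    q = coords.copy()
    p = p.copy()
    g = grad_fn(q) * inv_T
    p -= 0.5 * eps * g
    for step in range(n_steps):
        q += eps * p / mass
        g = grad_fn(q) * inv_T
        if step != n_steps - 1:
            p -= eps * g
    p -= 0.5 * eps * g
    return q, -p  # momentum flip keeps the proposal symmetric


def hmc_sa_fit(
    maps: list[ContactMap],
    covs=None,
    config: FitConfig | None = None,
    init: Structure3D | None = None,
) -> FitResult:
    """Fit the model to one or more contact maps.

    Returns the best-ever (structure, coefficients) state, with the
    structure translated so its first locus sits at the origin.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    lam_iter = _resolve_lambda(maps, config.lambda_policy)

    model = init_betas(maps, covs, config.log_covariates, config.gap_weight_mode)
    if init is None:
        init = init_structure(model, maps, covs, seed=rng)
    structure = Structure3D(init.loci.copy(), init.coords.copy())
    n = structure.n
    model.markov.lam = lam_iter
    pair_data = build_pair_data(maps, covs, structure, config.log_covariates)

    _refit_betas(model, pair_data, structure.coords, config.beta1_sign_constraint)

    def neg_ll(coords_flat: np.ndarray) -> float:
        structure.coords = coords_flat.reshape(n, 3)
        return _potential(model, maps, covs, structure, pair_data)

    def grad_U(coords: np.ndarray) -> np.ndarray:
        structure.coords = coords
        return -loglik_gradient(model, maps, covs, structure, pair_data)

    mass = config.inner_hmc.mass
    L = config.inner_hmc.leapfrog_steps
    T = config.anneal.T0
    eps = config.inner_hmc.step_size

    coords = structure.coords.copy()
    U = neg_ll(coords.ravel())

    # --- burn-in step-size tuning toward 60-80% acceptance at T0 ---
    if eps is None:
        eps = 0.1
        for _ in range(25):
            p0 = rng.normal(scale=math.sqrt(mass), size=(n, 3))
            q, p1 = _leapfrog(coords, p0, eps, L, grad_U, 1.0 / T, mass)
            U_new = neg_ll(q.ravel())
            dH = (U_new - U) / T + 0.5 * (np.sum(p1**2) - np.sum(p0**2)) / mass
            if not np.isfinite(dH) or dH > 50:
                eps *= 0.5
                continue
            acc = math.exp(min(0.0, -dH))
            eps *= 1.15 if acc > 0.7 else 0.85

    best_coords = coords.copy()
    best_model = _copy_model(model)
    best_ll = -U + markov_constant(n)
    trace: list[float] = []
    iteration_log: list[dict] = []
    accepted = 0
    stall = 0
    converged = False

    for it in range(config.max_outer_iters):
        # (a) Hamiltonian proposal on all coordinates at temperature T
        ok = False
        for _ in range(10):
            p0 = rng.normal(scale=math.sqrt(mass), size=(n, 3))
            q, p1 = _leapfrog(coords, p0, eps, L, grad_U, 1.0 / T, mass)
            U_new = neg_ll(q.ravel())
            dH = (U_new - U) / T + 0.5 * (np.sum(p1**2) - np.sum(p0**2)) / mass
            if np.isfinite(dH) and dH < 1e3:
                ok = True
                break
            eps *= 0.5  # divergent trajectory: halve and retry
        if not ok:
            raise RuntimeError("leapfrog diverged repeatedly; step size collapsed")
        if math.log(max(rng.uniform(), 1e-300)) < -dH:
            coords, U = q, U_new
            accepted += 1
            eps *= 1.05
        else:
            eps *= 0.90

        # (b) conditional maximization of the coefficients
        structure.coords = coords
        _refit_betas(model, pair_data, coords, config.beta1_sign_constraint)
        U = neg_ll(coords.ravel())

        ll = -U + markov_constant(n)
        prev_best = best_ll
        if ll > best_ll:
            best_ll = ll
            best_coords = coords.copy()
            best_model = _copy_model(model)
        trace.append(best_ll)
        iteration_log.append(
            {"iter": it, "T": T, "eps": eps, "accept_rate": accepted / (it + 1),
             "loglik": ll, "best": best_ll}
        )

        # (c) cooling and stopping
        if best_ll - prev_best <= config.tol_rel_loglik * max(1.0, abs(best_ll)):
            stall += 1
        else:
            stall = 0
        T *= config.anneal.cooling_rate
        if T < config.anneal.T_min:
            converged = True
            break
        if stall >= 10:
            converged = True
            break

    # --- deterministic polish: alternate L-BFGS-B on coordinates / IRLS.
    # Annealing can end in a basin worse than the sequential start, so both
    # the best annealed state and the initial structure are polished and the
    # higher-likelihood result kept ("best-ever" across all visited states).
    def polish(coords0: np.ndarray, model0: ContactModel
               ) -> tuple[np.ndarray, ContactModel, float]:
        nonlocal model
        coords_p = coords0.copy()
        model = model0
        _refit_betas(model, pair_data, coords_p, config.beta1_sign_constraint)
        ll = -neg_ll(coords_p.ravel()) + markov_constant(n)
        for _ in range(config.polish_rounds):
            res = minimize(
                lambda v: neg_ll(v),
                coords_p.ravel(),
                jac=lambda v: grad_U(v.reshape(n, 3)).ravel(),
                method="L-BFGS-B",
                options={"maxiter": 200},
            )
            coords_p = res.x.reshape(n, 3)
            structure.coords = coords_p
            _refit_betas(model, pair_data, coords_p, config.beta1_sign_constraint)
            ll_new = -neg_ll(coords_p.ravel()) + markov_constant(n)
            if ll_new <= ll + 1e-9 * max(1.0, abs(ll)):
                ll = max(ll, ll_new)
                break
            ll = ll_new
        return coords_p, model, ll

    candidates = [(best_coords.copy(), _copy_model(best_model))]
    if config.polish_rounds > 0:
        candidates.append((init.coords.copy(), _copy_model(best_model)))
    for coords0, model0 in candidates:
        coords_p, model_p, ll = polish(coords0, model0)
        if ll > best_ll:
            best_ll = ll
            best_coords = coords_p
            best_model = model_p
            trace.append(best_ll)

    final_coords = best_coords - best_coords[0]  # anchor S_{l_1} at the origin
    result_structure = Structure3D(structure.loci, final_coords)
    alphas = {tid: g.beta1 for tid, g in best_model.tracks.items()}
    return FitResult(
        structure=result_structure,
        model=best_model,
        loglik_trace=trace,
        converged=converged,
        per_track_alpha=alphas,
        iteration_log=iteration_log,
    )


def markov_constant(n: int) -> float:
    """Chain-prior normalization constant, -3(n-1)/2 * ln(2 pi)."""
    return -1.5 * (n - 1) * math.log(2.0 * math.pi)


def fit_multitrack(
    maps: list[ContactMap],
    covs=None,
    config: FitConfig | None = None,
) -> FitResult:
    """Joint fit of two or more tracks sharing one structure on the union
    of their available loci; the likelihood is the sum over tracks."""
    if len(maps) < 2:
        raise ValueError("fit_multitrack needs at least two contact maps")
    resolutions = {m.resolution_bp for m in maps}
    if len(resolutions) > 1:
        raise ValueError(f"tracks disagree on resolution: {sorted(resolutions)}")
    return hmc_sa_fit(maps, covs, config)


def _copy_model(model: ContactModel) -> ContactModel:
    return ContactModel(
        tracks={
            tid: TrackGLM(g.beta0, g.beta1, g.beta_cov.copy())
            for tid, g in model.tracks.items()
        },
        markov=MarkovPrior(
            model.markov.A.copy(), model.markov.b.copy(),
            model.markov.lam, model.markov.gap_weight_mode,
        ),
        log_covariates=model.log_covariates,
    )


def model_to_dict(model: ContactModel) -> dict:
    """JSON-serializable snapshot of a fitted model (checkpointing)."""
    return {
        "tracks": {
            tid: {"beta0": g.beta0, "beta1": g.beta1, "beta_cov": g.beta_cov.tolist()}
            for tid, g in model.tracks.items()
        },
        "markov": {
            "A": model.markov.A.tolist(),
            "b": model.markov.b.tolist(),
            "lambda": model.markov.lam,
            "gap_weight_mode": model.markov.gap_weight_mode,
        },
        "log_covariates": model.log_covariates,
    }


def model_from_dict(d: dict) -> ContactModel:
    return ContactModel(
        tracks={
            tid: TrackGLM(t["beta0"], t["beta1"], np.asarray(t["beta_cov"]))
            for tid, t in d["tracks"].items()
        },
        markov=MarkovPrior(
            np.asarray(d["markov"]["A"]),
            np.asarray(d["markov"]["b"]),
            d["markov"]["lambda"],
            d["markov"]["gap_weight_mode"],
        ),
        log_covariates=d.get("log_covariates", True),
    )
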