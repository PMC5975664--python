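"""Collapsed variational inference for the branching GP mixture.

The observation model assigns each cell ``n`` to one of the three latent
functions through a one-hot indicator row ``Z_n`` over the expanded
representation of size M = 3N:

    p(Y | F, Z) = N(Y | Z F, sigma^2 I),      p(Z) = prod_nm Pi_nm^{Z_nm}.

A mean-field variational posterior q(Z) = prod_nm Phi_nm^{Z_nm} is used and
the latent functions F are integrated out analytically, giving the collapsed
evidence lower bound

    L2 = -N/2 log(2 pi s2) - Y'Y / (2 s2) - 1/2 log|K| - 1/2 log|A/s2 + K^-1|
         + 1/(2 s2^2) Yh' (A/s2 + K^-1)^-1 Yh - KL[q(Z) || p(Z)],

where A = E[Z'Z] = diag(w) with w the flattened Phi, and Yh = Phi' Y. All
linear algebra is routed through the well-conditioned matrix
B = I + (1/s2) A^{1/2} K A^{1/2} using the identities
log|K| + log|A/s2 + K^-1| = log|B| and
(A/s2 + K^-1)^-1 = K - (1/s2) K A^{1/2} B^-1 A^{1/2} K,
so no explicit inverse (or even Cholesky) of K is ever formed.

Optimisation alternates two monotone steps: a closed-form mean-field update
of Phi (derived from the uncollapsed structured bound, hence provably
non-decreasing in L2) and L-BFGS-B over the three log hyperparameters. The
sparse path replaces K by the Nystrom approximation built from inducing
points and subtracts the assignment-weighted trace correction, in the
collapsed inducing-point style; its cost is O(k^2 N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .kernel import (
    DEFAULT_JITTER,
    AugmentedInput,
    BranchingKernelSpec,
    branching_covariance,
    branching_covariance_dloglengthscale,
)

__all__ = [
    "NoiseModel",
    "AssignmentPrior",
    "VariationalState",
    "OptimiserConfig",
    "OptimiseResult",
    "build_assignment_prior",
    "kl_assignment",
    "collapsed_bound",
    "sparse_collapsed_bound",
    "update_assignments",
    "optimise",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation noise variance (expression units squared)."""

    noise_variance: float

    def __post_init__(self) -> None:
        if not (self.noise_variance > 0 and np.isfinite(self.noise_variance)):
            raise ValueError(f"noise_variance must be positive, got {self.noise_variance}")


@dataclass(frozen=True)
class AssignmentPrior:
    """Row-stochastic N x 3 prior Pi over (trunk, branch 1, branch 2)."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 2 or pi.shape[1] != 3:
            raise ValueError("pi must be an N x 3 matrix")
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("prior probabilities must lie in [0, 1]")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("prior rows must sum to 1")
        object.__setattr__(self, "pi", pi)


@dataclass(frozen=True)
class VariationalState:
    """Mean-field posterior assignment probabilities Phi (N x 3).

    The second-order expectation A = E[Z'Z] on the expanded representation
    is diagonal with the flattened Phi on its diagonal
    (``expanded_weights``); ``A_diag`` exposes the per-function totals
    (column sums of Phi), which add to N.
    """

    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim != 2 or phi.shape[1] != 3:
            raise ValueError("phi must be an N x 3 matrix")
        if np.any(phi < -1e-12):
            raise ValueError("phi entries must be non-negative")
        if not np.allclose(phi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("phi rows must sum to 1")
        object.__setattr__(self, "phi", np.clip(phi, 0.0, 1.0))

    @property
    def expanded_weights(self) -> np.ndarray:
        """Function-major flattened Phi: w[m * N + n] = Phi[n, m]."""
        return self.phi.T.ravel()

    @property
    def A_diag(self) -> np.ndarray:
        """Expected number of cells on each latent function (sums to N)."""
        return self.phi.sum(axis=0)


def build_assignment_prior(global_branching, candidate_tb: float, prior_confidence: float) -> AssignmentPrior:
    """Categorical prior over branch assignments for one candidate t_b.

    Cells before the candidate branching time can only lie on the trunk.
    Cells after both the candidate and the global branching time receive
    probability ``prior_confidence`` on their globally assigned branch.
    Cells after the candidate but before the global branching time carry no
    global label and get an uninformative (0.5, 0.5) split over branches.
    """
    if not (0.5 <= prior_confidence < 1.0):
        raise ValueError(f"prior_confidence must be in [0.5, 1), got {prior_confidence}")
    t = np.asarray(global_branching.pseudotime, dtype=float)
    lab = np.asarray(global_branching.label_codes, dtype=int)
    gtime = float(global_branching.global_branch_time)
    c = prior_confidence
    pi = np.zeros((t.shape[0], 3))
    pre = t < candidate_tb
    pi[pre, 0] = 1.0
    post = ~pre
    pi[post & (lab == 1), 1] = c
    pi[post & (lab == 1), 2] = 1.0 - c
    pi[post & (lab == 2), 1] = 1.0 - c
    pi[post & (lab == 2), 2] = c
    # No global label available: before the global branching time, or a
    # stray trunk label after it.
    unlabelled = post & ((t < gtime) | (lab == 0))
    pi[unlabelled, 1:] = 0.5
    pi[unlabelled, 0] = 0.0
    return AssignmentPrior(pi)


def trunk_only_prior(n: int) -> AssignmentPrior:
    """Prior for the non-branching model: every cell on the trunk."""
    pi = np.zeros((n, 3))
    pi[:, 0] = 1.0
    return AssignmentPrior(pi)


def kl_assignment(state: VariationalState, prior: AssignmentPrior) -> float:
    """KL[q(Z) || p(Z)] = sum_nm Phi_nm log(Phi_nm / Pi_nm), with 0 log 0 = 0."""
    phi, pi = state.phi, prior.pi
    active = phi > 0
    if np.any(active & (pi <= 0)):
        raise ValueError("infinite KL: phi places mass where the prior is zero")
    ratio = np.ones_like(phi)
    np.divide(phi, pi, out=ratio, where=active)
    kl = float(np.sum(phi[active] * np.log(ratio[active])))
    return max(kl, 0.0)


# ---------------------------------------------------------------------------
# Bound cores (everything except the KL term)
# ---------------------------------------------------------------------------


def _full_core(y, t, w, sv, ls, nv, tb, jitter, want_grad=False, want_estep=False):
    """Collapsed-bound core on the full 3N x 3N covariance.

    Returns ``(core, aux)`` where aux optionally holds the analytic
    gradient w.r.t. (log sv, log ls, log nv) and the E-step moments
    (posterior mean and variance of each latent function at each cell).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    beta = 1.0 / nv
    spec = BranchingKernelSpec(sv, ls, tb)
    x_aug = AugmentedInput.expand(t)
    kmat = branching_covariance(spec, x_aug, jitter=jitter)
    sqw = np.sqrt(w)
    bmat = np.eye(3 * n) + beta * (sqw[:, None] * kmat * sqw[None, :])
    lb = cholesky(bmat, lower=True, check_finite=False)
    logdet_b = 2.0 * float(np.sum(np.log(np.diag(lb))))
    # Since Phi rows sum to 1, sum_i w_i ytil_i^2 = Y'Y and the data terms
    # collapse to the cancellation-free weighted-GP form -1/2 e' B^-1 e
    # with e = sqrt(beta) Ah ytil.
    evec = np.sqrt(beta) * sqw * np.tile(y, 3)
    qvec = cho_solve((lb, True), evec, check_finite=False)
    core = -0.5 * n * (_LOG2PI - np.log(beta)) - 0.5 * logdet_b - 0.5 * (evec @ qvec)

    aux: dict = {}
    if want_grad or want_estep:
        aq = sqw * qvec  # sqrt(beta) times the dual weights v
    if want_grad:
        ksc = sqw[:, None] * kmat * sqw[None, :]
        tr1 = float(np.trace(cho_solve((lb, True), ksc, check_finite=False)))
        g_sv = -0.5 * beta * tr1 + 0.5 * beta * (aq @ (kmat @ aq))
        kdl = branching_covariance_dloglengthscale(spec, x_aug)
        ksl = sqw[:, None] * kdl * sqw[None, :]
        tr2 = float(np.trace(cho_solve((lb, True), ksl, check_finite=False)))
        g_ls = -0.5 * beta * tr2 + 0.5 * beta * (aq @ (kdl @ aq))
        g_nv = -0.5 * n + 0.5 * beta * tr1 + 0.5 * (evec @ qvec) - 0.5 * beta * (aq @ (kmat @ aq))
        aux["grad"] = np.array([g_sv, g_ls, g_nv])
    if want_estep:
        zmat = solve_triangular(lb, sqw[:, None] * kmat, lower=True, check_finite=False)
        sdiag = np.diag(kmat) - beta * np.einsum("ij,ij->j", zmat, zmat)
        aux["mu"] = np.sqrt(beta) * (kmat @ aq)
        aux["sdiag"] = np.maximum(sdiag, 0.0)
    return float(core), aux


def _inducing_times(t: np.ndarray, k: int) -> np.ndarray:
    """Quantile placement of k inducing pseudotimes (replicated per label)."""
    qs = (np.arange(k) + 0.5) / k
    return np.quantile(np.asarray(t, dtype=float), qs)


def _sparse_core(y, t, w, sv, ls, nv, tb, u_times, jitter, want_estep=False):
    """Collapsed-bound core under the Nystrom/inducing-point approximation.

    K is replaced by Q = K_xu K_uu^-1 K_ux inside the bound and the
    assignment-weighted trace correction (1/(2 s2)) sum_i w_i (K_ii - Q_ii)
    is subtracted. When the inducing set equals the data the bound equals
    the full one exactly (the jittered square covariance is reused for both
    K_uu and K_xu so the Nystrom identity holds to machine precision).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    u_times = np.asarray(u_times, dtype=float)
    n = y.shape[0]
    beta = 1.0 / nv
    spec = BranchingKernelSpec(sv, ls, tb)
    x_aug = AugmentedInput.expand(t)
    if u_times.shape == t.shape and np.array_equal(u_times, t):
        kuu = branching_covariance(spec, x_aug, jitter=jitter)
        kxu = kuu
    else:
        u_aug = AugmentedInput.expand(u_times)
        kuu = branching_covariance(spec, u_aug, jitter=jitter)
        kxu = branching_covariance(spec, x_aug, u_aug)
    try:
        luu = cholesky(kuu, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        kuu = kuu + 10.0 * jitter * sv * np.eye(kuu.shape[0])
        luu = cholesky(kuu, lower=True, check_finite=False)
    vmat = solve_triangular(luu, kxu.T, lower=True, check_finite=False)  # ku x 3N
    qdiag = np.einsum("ij,ij->j", vmat, vmat)
    kdiag = sv * (1.0 + jitter)
    tcorr = np.maximum(kdiag - qdiag, 0.0)
    sqw = np.sqrt(w)
    gmat = vmat * sqw[None, :]
    hmat = gmat @ gmat.T
    ku = hmat.shape[0]
    bs = np.eye(ku) + beta * hmat
    lbs = cholesky(bs, lower=True, check_finite=False)
    logdet_b = 2.0 * float(np.sum(np.log(np.diag(lbs))))
    yhat = w * np.tile(y, 3)
    p = vmat @ yhat
    # Woodbury form of -1/2 e' B_Q^-1 e with e = sqrt(beta) Ah ytil:
    # -beta/2 Y'Y + beta^2/2 p' Bs^-1 p (rows of Phi sum to 1).
    bp = cho_solve((lbs, True), p, check_finite=False)
    core = (
        -0.5 * n * (_LOG2PI - np.log(beta))
        - 0.5 * logdet_b
        - 0.5 * beta * (y @ y)
        + 0.5 * beta * beta * (p @ bp)
        - 0.5 * beta * (w @ tcorr)
    )
    aux: dict = {}
    if want_estep:
        zs = solve_triangular(lbs, vmat, lower=True, check_finite=False)
        aux["mu"] = beta * (vmat.T @ bp)
        aux["sdiag"] = tcorr + np.einsum("ij,ij->j", zs, zs)
    return float(core), aux


def collapsed_bound(
    y,
    t,
    state: VariationalState,
    spec: BranchingKernelSpec,
    noise: NoiseModel,
    prior: AssignmentPrior,
    jitter: float = DEFAULT_JITTER,
) -> float:
    """Collapsed evidence lower bound L2 on the full covariance."""
    core, _ = _full_core(
        y,
        t,
        state.expanded_weights,
        spec.signal_variance,
        spec.lengthscale,
        noise.noise_variance,
        spec.branch_point,
        jitter,
    )
    return core - kl_assignment(state, prior)


def sparse_collapsed_bound(
    y,
    t,
    state: VariationalState,
    spec: BranchingKernelSpec,
    noise: NoiseModel,
    prior: AssignmentPrior,
    inducing,
    jitter: float = DEFAULT_JITTER,
) -> float:
    """Inducing-point lower bound on L2; equals L2 when inducing == data.

    ``inducing`` is either an array of inducing pseudotimes (replicated
    across the three function labels) or an :class:`AugmentedInput` whose
    pseudotimes are function-major replicates.
    """
    if isinstance(inducing, AugmentedInput):
        u_times = inducing.pseudotime[: len(inducing) // 3]
    else:
        u_times = np.asarray(inducing, dtype=float)
    core, _ = _sparse_core(
        y,
        t,
        state.expanded_weights,
        spec.signal_variance,
        spec.lengthscale,
        noise.noise_variance,
        spec.branch_point,
        u_times,
        jitter,
    )
    return core - kl_assignment(state, prior)


# ---------------------------------------------------------------------------
# Mean-field update and optimiser
# ---------------------------------------------------------------------------


def update_assignments(y, prior: AssignmentPrior, mu, sdiag, noise_variance: float) -> np.ndarray:
    """Closed-form mean-field update of Phi given posterior GP moments.

    log Phi_nm propto log Pi_nm - ((y_n - mu_nm)^2 + s_nm) / (2 s2),
    restricted to the support of the prior row. Rows with a degenerate
    (one-hot) prior are returned unchanged by construction.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    mu_nm = np.asarray(mu).reshape(3, n).T
    s_nm = np.asarray(sdiag).reshape(3, n).T
    beta = 1.0 / noise_variance
    loglik = -0.5 * beta * ((y[:, None] - mu_nm) ** 2 + s_nm)
    with np.errstate(divide="ignore"):
        logw = np.where(prior.pi > 0, np.log(np.maximum(prior.pi, 1e-300)), -np.inf) + loglik
    logw -= logw.max(axis=1, keepdims=True)
    phi = np.exp(logw)
    phi /= phi.sum(axis=1, keepdims=True)
    return phi


@dataclass
class OptimiserConfig:
    """Knobs of the per-candidate alternating optimiser.

    ``n_inducing = 0`` selects the exact full-covariance path; otherwise a
    sparse path with ``n_inducing`` pseudotime quantiles per latent function
    is used (the full path is also chosen automatically when the data is no
    larger than the inducing set).
    """

    prior_confidence: float = 0.99
    n_inducing: int = 30
    jitter: float = DEFAULT_JITTER
    max_outer: int = 4
    lbfgs_maxiter_first: int = 20
    lbfgs_maxiter: int = 8
    n_estep: int = 2
    rel_tol: float = 1e-6
    noise_floor_rel: float = 1e-6
    init_theta: np.ndarray | None = None
    optimise_hyperparams: bool = True
    hyperprior_strength: float = 1.0


@dataclass
class OptimiseResult:
    state: VariationalState
    spec: BranchingKernelSpec
    noise: NoiseModel
    bound: float
    converged: bool
    theta: np.ndarray
    trace: list = field(default_factory=list)


def optimise(y, global_branching, candidate_tb: float, config: OptimiserConfig | None = None) -> OptimiseResult:
    """Maximise the collapsed bound for one candidate branching time.

    Alternates L-BFGS-B over (log signal variance, log lengthscale, log
    noise variance) with monotone mean-field sweeps over Phi. The prior is
    rebuilt from the global branching structure for the given candidate;
    the sentinel ``candidate_tb = inf`` fits the non-branching model
    (trunk-only support, no assignment updates).
    """
    cfg = config or OptimiserConfig()
    y = np.asarray(y, dtype=float)
    t = np.asarray(global_branching.pseudotime, dtype=float)
    n = y.shape[0]
    if y.shape != t.shape:
        raise ValueError("expression and pseudotime lengths differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("expression values must be finite")

    no_branch = np.isinf(candidate_tb)
    if no_branch:
        prior = trunk_only_prior(n)
    else:
        prior = build_assignment_prior(global_branching, candidate_tb, cfg.prior_confidence)
    phi = prior.pi.copy()
    has_free_rows = bool(np.any((prior.pi > 0).sum(axis=1) > 1))

    vy = max(float(np.var(y)), 1e-12)
    trange = float(np.ptp(t)) or 1.0
    if cfg.init_theta is not None:
        theta = np.asarray(cfg.init_theta, dtype=float).copy()
    else:
        theta = np.log([vy, 0.3 * trange, 0.25 * vy])
    lo = np.log([1e-6 * vy, 1e-2 * trange, cfg.noise_floor_rel * vy])
    hi = np.log([1e4 * vy, 1e1 * trange, 1e4 * vy])
    theta = np.clip(theta, lo, hi)
    bounds = list(zip(lo, hi))

    use_full = cfg.n_inducing <= 0 or cfg.n_inducing >= n
    u_times = None if use_full else _inducing_times(t, cfg.n_inducing)

    # Weak log-normal hyperprior, a regularised type-II MAP: it keeps the
    # M-step away from the signal-variance collapse that would otherwise
    # flatten the evidence profile at high noise, while being far too weak
    # to move an informative likelihood. Centres follow the initialisation.
    prior_mu = np.log([vy, 0.3 * trange, 0.25 * vy])
    prior_sd = np.array([1.5, 1.0, 2.5])

    def log_hyperprior(th):
        z = (th - prior_mu) / prior_sd
        return -0.5 * cfg.hyperprior_strength * float(z @ z)

    def dlog_hyperprior(th):
        return -cfg.hyperprior_strength * (th - prior_mu) / prior_sd**2

    def core_and_aux(th, w, want_grad=False, want_estep=False):
        sv, ls, nv = np.exp(th)
        if use_full:
            return _full_core(y, t, w, sv, ls, nv, candidate_tb, cfg.jitter, want_grad, want_estep)
        return _sparse_core(y, t, w, sv, ls, nv, candidate_tb, u_times, cfg.jitter, want_estep)

    from scipy.optimize import minimize

    trace: list[float] = []
    prev_obj = -np.inf
    bound = -np.inf
    converged = False
    kl = kl_assignment(VariationalState(phi), prior)
    for outer in range(cfg.max_outer):
        w = VariationalState(phi).expanded_weights
        if cfg.optimise_hyperparams:
            maxiter = cfg.lbfgs_maxiter_first if outer == 0 else cfg.lbfgs_maxiter
            if use_full:

                def neg(th):
                    core, aux = core_and_aux(th, w, want_grad=True)
                    return -(core + log_hyperprior(th)), -(aux["grad"] + dlog_hyperprior(th))

                res = minimize(neg, theta, jac=True, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter})
            else:

                def neg(th):
                    core, _ = core_and_aux(th, w)
                    return -(core + log_hyperprior(th))

                res = minimize(neg, theta, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter})
            if np.isfinite(res.fun):
                theta = res.x
                trace.append(-float(res.fun) - kl)
        if has_free_rows:
            for _ in range(cfg.n_estep):
                core, aux = core_and_aux(theta, VariationalState(phi).expanded_weights, want_estep=True)
                phi = update_assignments(y, prior, aux["mu"], aux["sdiag"], float(np.exp(theta[2])))
            kl = kl_assignment(VariationalState(phi), prior)
        core, _ = core_and_aux(theta, VariationalState(phi).expanded_weights)
        bound = core - kl
        obj = bound + log_hyperprior(theta)
        trace.append(obj)
        if abs(obj - prev_obj) <= cfg.rel_tol * (1.0 + abs(obj)):
            converged = True
            break
        prev_obj = obj
    sv, ls, nv = np.exp(theta)
    return OptimiseResult(
        state=VariationalState(phi),
        spec=BranchingKernelSpec(sv, ls, candidate_tb),
        noise=NoiseModel(nv),
        bound=float(bound),
        converged=converged,
        theta=theta,
        trace=trace,
    )
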