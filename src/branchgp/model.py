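"""Per-gene branching analysis.

For each gene the collapsed bound is maximised on a grid of candidate
branching times S_B; the bound values act as log marginal likelihoods.
The posterior over the branching time is their softmax,

    p(t_b = c | Y) = p(Y | t_b = c) / sum_{i in S_B} p(Y | t_b = i),

and the log Bayes factor of branching versus not branching is

    r_g = log[(1/N_b) sum_i p(Y | t_b = i)] - log p(Y | t_b -> inf),

with the non-branching evidence from a trunk-only (single GP) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp

from .inference import (
    NoiseModel,
    OptimiserConfig,
    VariationalState,
    optimise,
)
from .kernel import (
    DEFAULT_JITTER,
    NO_BRANCH,
    AugmentedInput,
    BranchingKernelSpec,
    branching_covariance,
)

__all__ = [
    "GeneProfile",
    "GlobalBranching",
    "CandidateGrid",
    "BranchingFit",
    "FitConfig",
    "branching_posterior",
    "bayes_factor",
    "credible_interval",
    "fit_gene",
    "fit_genes",
    "results_table",
    "predict_branches",
    "t_filter",
]

TRUNK_LABEL = "trunk"
_LABEL_TO_CODE = {"trunk": 0, "0": 0, "1": 1, "2": 2, 0: 0, 1: 1, 2: 2}


@dataclass(frozen=True)
class GeneProfile:
    """One gene's expression values over the cells (Gaussian-noise scale)."""

    gene_id: str
    y: np.ndarray
    cell_ids: tuple = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1:
            raise ValueError("expression must be a 1-D vector")
        if not np.all(np.isfinite(y)):
            raise ValueError(f"gene {self.gene_id}: non-finite expression values")
        object.__setattr__(self, "y", y)
        if self.cell_ids and len(self.cell_ids) != y.shape[0]:
            raise ValueError("cell_ids length does not match expression length")


@dataclass(frozen=True)
class GlobalBranching:
    """Pseudotime and global trunk/branch structure from an upstream method.

    ``global_label`` entries are 'trunk', 1 or 2 (strings or ints);
    ``label_codes`` maps them to 0/1/2. ``source`` records provenance
    (e.g. 'DPT', 'wishbone', 'monocle', 'truth').
    """

    pseudotime: np.ndarray
    global_label: np.ndarray
    global_branch_time: float
    source: str = "unknown"

    def __post_init__(self) -> None:
        t = np.asarray(self.pseudotime, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("pseudotime must be finite")
        lab = np.asarray(self.global_label)
        if lab.shape != t.shape:
            raise ValueError("pseudotime and labels must have equal length")
        try:
            codes = np.array([_LABEL_TO_CODE[x if not isinstance(x, str) else x.strip()] for x in lab.tolist()])
        except KeyError as exc:
            raise ValueError(f"unknown branch label {exc.args[0]!r}; expected trunk, 1 or 2") from None
        object.__setattr__(self, "pseudotime", t)
        object.__setattr__(self, "_codes", codes)

    @property
    def label_codes(self) -> np.ndarray:
        """Integer labels: 0 = trunk, 1 and 2 the two branches."""
        return self._codes

    def __len__(self) -> int:
        return self.pseudotime.shape[0]

    def rescaled(self) -> tuple["GlobalBranching", tuple[float, float]]:
        """Min-max map of pseudotime onto [0, 1]; returns (copy, (t0, span))."""
        t = self.pseudotime
        t0, t1 = float(t.min()), float(t.max())
        span = (t1 - t0) or 1.0
        scaled = GlobalBranching(
            (t - t0) / span,
            self.global_label,
            (self.global_branch_time - t0) / span,
            self.source,
        )
        return scaled, (t0, span)


@dataclass(frozen=True)
class CandidateGrid:
    """Strictly increasing candidate branching times S_B."""

    times: np.ndarray
    includes_no_branch: bool = True

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.shape[0] < 2:
            raise ValueError("candidate grid needs at least two times")
        if np.any(np.diff(times) <= 0):
            raise ValueError("candidate times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.shape[0]

    @classmethod
    def default(cls, t_min: float = 0.0, t_max: float = 1.0, n: int = 20, span: float = 0.9) -> "CandidateGrid":
        """n equally spaced candidates on the central ``span`` of the range."""
        pad = 0.5 * (1.0 - span) * (t_max - t_min)
        return cls(np.linspace(t_min + pad, t_max - pad, n))


@dataclass
class BranchingFit:
    """Per-gene evidence profile, branching-time posterior and Bayes factor."""

    gene_id: str
    times: np.ndarray
    log_evidence: np.ndarray
    log_evidence_no_branch: float
    posterior: np.ndarray
    map_time: float
    posterior_mean_time: float
    credible_interval: tuple[float, float]
    bayes_factor: float
    phi_map: np.ndarray
    map_spec: BranchingKernelSpec
    map_noise: NoiseModel
    n_candidates_failed: int = 0
    flagged: bool = False
    y_offset: float = 0.0
    t_transform: tuple[float, float] = (0.0, 1.0)
    credible_level: float = 0.98


@dataclass
class FitConfig:
    """Configuration of :func:`fit_gene`.

    ``n_inducing = 0`` forces full-covariance inference; otherwise the
    sparse path is used whenever it is actually smaller than the data.
    """

    n_candidates: int = 20
    grid_span: float = 0.9
    prior_confidence: float = 0.99
    n_inducing: int = 30
    credible_level: float = 0.98
    jitter: float = DEFAULT_JITTER
    max_outer: int = 4
    lbfgs_maxiter_first: int = 20
    lbfgs_maxiter: int = 8
    n_estep: int = 2
    rel_tol: float = 1e-6
    noise_floor_rel: float = 1e-6
    hyperprior_strength: float = 1.0
    shared_hyperparams: bool = True

    def optimiser_config(self, init_theta=None, optimise_hyperparams=True, max_outer=None) -> OptimiserConfig:
        return OptimiserConfig(
            prior_confidence=self.prior_confidence,
            n_inducing=self.n_inducing,
            jitter=self.jitter,
            max_outer=max_outer if max_outer is not None else self.max_outer,
            lbfgs_maxiter_first=self.lbfgs_maxiter_first,
            lbfgs_maxiter=self.lbfgs_maxiter,
            n_estep=self.n_estep,
            rel_tol=self.rel_tol,
            noise_floor_rel=self.noise_floor_rel,
            init_theta=init_theta,
            optimise_hyperparams=optimise_hyperparams,
            hyperprior_strength=self.hyperprior_strength,
        )


def branching_posterior(log_evidence) -> np.ndarray:
    """Softmax of per-candidate log evidence (max-subtracted)."""
    le = np.asarray(log_evidence, dtype=float)
    if np.all(np.isneginf(le)) or np.any(np.isnan(le)):
        raise ValueError("log evidence must contain at least one finite value")
    z = le - le[np.isfinite(le)].max()
    with np.errstate(under="ignore"):
        p = np.exp(z)
    p[~np.isfinite(z)] = 0.0
    return p / p.sum()


def bayes_factor(log_evidence, log_evidence_no_branch: float) -> float:
    """r_g = log mean evidence over the grid minus the no-branch evidence."""
    le = np.asarray(log_evidence, dtype=float)
    finite = le[np.isfinite(le)]
    if finite.size == 0 or not np.isfinite(log_evidence_no_branch):
        raise ValueError("finite log evidence required")
    return float(logsumexp(finite) - np.log(le.shape[0]) - log_evidence_no_branch)


def credible_interval(posterior, times, level: float) -> tuple[float, float]:
    """Smallest contiguous grid window holding >= level posterior mass.

    Ties between equally small windows are broken toward earlier times,
    matching the contiguous credible regions drawn by the model's plots.
    """
    p = np.asarray(posterior, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    nb = p.shape[0]
    csum = np.concatenate([[0.0], np.cumsum(p)])
    for width in range(1, nb + 1):
        mass = csum[width:] - csum[:-width]  # all windows of this width
        idx = np.flatnonzero(mass >= level - 1e-12)
        if idx.size:
            start = int(idx[0])
            return float(times[start]), float(times[start + width - 1])
    return float(times[0]), float(times[-1])


def fit_gene(
    profile: GeneProfile,
    global_branching: GlobalBranching,
    grid: CandidateGrid | None = None,
    config: FitConfig | None = None,
) -> BranchingFit:
    """Fit the branching model to one gene over the candidate grid.

    Pseudotime is min-max rescaled to [0, 1] internally and the expression
    is centred; all reported times are in the original pseudotime units.
    Hyperparameters are optimised per candidate (warm-started from the
    previous one); with ``shared_hyperparams`` (the default) a second pass
    then freezes them at the best candidate's optimum and re-evaluates the
    whole grid with assignments re-optimised, so the evidence profile is
    not distorted by candidate-to-candidate fitting differences.
    Candidates whose optimisation fails contribute zero evidence; the gene
    is flagged if more than half fail.
    """
    cfg = config or FitConfig()
    if isinstance(profile, GeneProfile):
        gene_id, y = profile.gene_id, profile.y
    else:
        gene_id, y = "gene", np.asarray(profile, dtype=float)
    if y.shape[0] != len(global_branching):
        raise ValueError("expression and global branching describe different numbers of cells")

    scaled, (t0, span) = global_branching.rescaled()
    if grid is None:
        grid = CandidateGrid.default(0.0, 1.0, cfg.n_candidates, cfg.grid_span)
        times_orig = grid.times * span + t0
        times_scaled = grid.times
    else:
        times_orig = grid.times
        times_scaled = (grid.times - t0) / span

    offset = float(y.mean())
    yc = y - offset

    log_ev = np.full(len(times_scaled), -np.inf)
    phis: list[np.ndarray | None] = [None] * len(times_scaled)
    specs: list = [None] * len(times_scaled)
    noises: list = [None] * len(times_scaled)
    n_failed = 0
    theta_warm = None
    for i, tb in enumerate(times_scaled):
        try:
            res = optimise(yc, scaled, float(tb), cfg.optimiser_config(init_theta=theta_warm))
            if not np.isfinite(res.bound):
                raise FloatingPointError("non-finite bound")
            log_ev[i] = res.bound
            phis[i], specs[i], noises[i] = res.state.phi, res.spec, res.noise
            theta_warm = res.theta
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            n_failed += 1
            warnings.warn(f"gene {gene_id}: candidate t_b={tb:.3g} failed ({exc})")
    flagged = n_failed > 0.5 * len(times_scaled)
    if np.all(np.isneginf(log_ev)):
        raise RuntimeError(f"gene {gene_id}: all candidate optimisations failed")

    if cfg.shared_hyperparams:
        # Profile pass: freeze the hyperparameters at the best candidate's
        # optimum and re-evaluate every candidate (assignments re-optimised)
        # so the evidence profile is not distorted by candidate-to-candidate
        # differences in hyperparameter fitting.
        best = int(np.argmax(log_ev))
        theta_star = np.log(
            [specs[best].signal_variance, specs[best].lengthscale, noises[best].noise_variance]
        )
        for i, tb in enumerate(times_scaled):
            try:
                res = optimise(
                    yc, scaled, float(tb),
                    cfg.optimiser_config(init_theta=theta_star, optimise_hyperparams=False, max_outer=6),
                )
                if np.isfinite(res.bound):
                    log_ev[i] = res.bound
                    phis[i], specs[i], noises[i] = res.state.phi, res.spec, res.noise
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):  # pragma: no cover
                pass

    res_nb = optimise(yc, scaled, NO_BRANCH, cfg.optimiser_config())
    log_ev_nb = res_nb.bound

    post = branching_posterior(log_ev)
    imap = int(np.argmax(post))
    ci = credible_interval(post, times_orig, cfg.credible_level)
    return BranchingFit(
        gene_id=gene_id,
        times=times_orig,
        log_evidence=log_ev,
        log_evidence_no_branch=float(log_ev_nb),
        posterior=post,
        map_time=float(times_orig[imap]),
        posterior_mean_time=float(np.sum(post * times_orig)),
        credible_interval=ci,
        bayes_factor=bayes_factor(log_ev, log_ev_nb),
        phi_map=phis[imap],
        map_spec=specs[imap],
        map_noise=noises[imap],
        n_candidates_failed=n_failed,
        flagged=flagged,
        y_offset=offset,
        t_transform=(t0, span),
        credible_level=cfg.credible_level,
    )


def fit_genes(
    expr: pd.DataFrame,
    global_branching: GlobalBranching,
    grid: CandidateGrid | None = None,
    config: FitConfig | None = None,
    progress: bool = False,
) -> list[BranchingFit]:
    """Fit every row (gene) of a genes x cells expression frame independently."""
    fits = []
    for gene_id, row in expr.iterrows():
        prof = GeneProfile(str(gene_id), row.to_numpy(dtype=float), tuple(expr.columns))
        fits.append(fit_gene(prof, global_branching, grid=grid, config=config))
        if progress:  # pragma: no cover - cosmetic
            print(f"fitted {gene_id}: t_b={fits[-1].map_time:.3f} r_g={fits[-1].bayes_factor:.1f}", flush=True)
    return fits


def results_table(fits) -> pd.DataFrame:
    """Summary frame: one row per gene with MAP time, CI and Bayes factor."""
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "map_time": [f.map_time for f in fits],
            "posterior_mean_time": [f.posterior_mean_time for f in fits],
            "ci_lo": [f.credible_interval[0] for f in fits],
            "ci_hi": [f.credible_interval[1] for f in fits],
            "bayes_factor": [f.bayes_factor for f in fits],
            "n_candidates_failed": [f.n_candidates_failed for f in fits],
        }
    ).set_index("gene_id")


def predict_branches(
    fit: BranchingFit,
    profile: GeneProfile,
    global_branching: GlobalBranching,
    t_query,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance of (trunk, branch 1, branch 2) curves.

    Uses the MAP-candidate model: the expected-assignment weights Phi act
    as per-point likelihood precisions. Returns arrays of shape (nq, 3).
    Far from the data the variance reverts to the prior signal variance; at
    the branching point all three means coincide by construction.
    """
    y = profile.y if isinstance(profile, GeneProfile) else np.asarray(profile, dtype=float)
    t0, span = fit.t_transform
    t = (np.asarray(global_branching.pseudotime, dtype=float) - t0) / span
    tq = (np.asarray(t_query, dtype=float) - t0) / span
    spec, nv = fit.map_spec, fit.map_noise.noise_variance
    beta = 1.0 / nv
    n, nq = t.shape[0], tq.shape[0]
    yc = y - fit.y_offset

    w = VariationalState(fit.phi_map).expanded_weights
    sqw = np.sqrt(w)
    x_aug = AugmentedInput.expand(t)
    q_aug = AugmentedInput.expand(tq)
    kmat = branching_covariance(spec, x_aug)
    bmat = np.eye(3 * n) + beta * (sqw[:, None] * kmat * sqw[None, :])
    lb = cholesky(bmat, lower=True, check_finite=False)
    yhat = w * np.tile(yc, 3)
    r = kmat @ yhat
    uvec = cho_solve((lb, True), sqw * r, check_finite=False)
    v = yhat - beta * sqw * uvec
    kqx = branching_covariance(spec, q_aug, x_aug)
    mean = beta * (kqx @ v)
    zq = solve_triangular(lb, sqw[:, None] * kqx.T, lower=True, check_finite=False)
    var = spec.signal_variance - beta * np.einsum("ij,ij->j", zq, zq)
    mean = mean.reshape(3, nq).T + fit.y_offset
    var = np.maximum(var.reshape(3, nq).T, 0.0)
    return mean, var


def t_filter(
    expr: pd.DataFrame,
    global_branching: GlobalBranching,
    tail_fraction: float = 0.25,
    threshold: float = 2.0,
) -> tuple[list, pd.DataFrame]:
    """Welch t-statistic prefilter on the end states of the two branches.

    For each gene, compares expression over the latest ``tail_fraction`` of
    pseudotime on branch 1 against branch 2 and keeps genes with
    |t| >= threshold. Returns (kept gene ids, full statistic table).
    """
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must be in (0, 1]")
    t = global_branching.pseudotime
    codes = global_branching.label_codes
    tails = []
    for b in (1, 2):
        on_branch = codes == b
        if not on_branch.any():
            raise ValueError(f"branch {b} has no cells")
        cutoff = np.quantile(t[on_branch], 1.0 - tail_fraction)
        sel = on_branch & (t >= cutoff)
        if sel.sum() < 3:
            raise ValueError(f"branch {b} tail has fewer than 3 cells")
        tails.append(sel)
    x1 = expr.to_numpy(dtype=float)[:, tails[0]]
    x2 = expr.to_numpy(dtype=float)[:, tails[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = stats.ttest_ind(x1, x2, axis=1, equal_var=False).statistic
    tstat = np.nan_to_num(tstat, nan=0.0)
    table = pd.DataFrame({"gene_id": expr.index, "t_stat": tstat, "abs_t": np.abs(tstat)}).set_index("gene_id")
    kept = table.index[table["abs_t"] >= threshold].tolist()
    return kept, table
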