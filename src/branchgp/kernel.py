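"""Constrained-intersection covariance for branching Gaussian processes.

A branching trajectory is modelled with three latent functions sharing one
base kernel: a trunk ``f`` and two branches ``g`` and ``h``, all constrained
to intersect at the branching point ``t_b``:

    f, g, h ~ GP(0, K),    f(t_b) = g(t_b) = h(t_b).

Conditioning the three independent GP priors on the intersection event gives
a joint covariance over the augmented input set of (pseudotime, label)
pairs: same-label blocks are the base kernel K(T, T'); different-label
blocks are the rank-one form K(T, t_b) K(t_b, T') / K(t_b, t_b).

When ``t_b`` is far beyond the data (or the no-branch sentinel ``inf``) the
cross blocks vanish and the three functions decouple into an overlapping
mixture of independent GPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TRUNK",
    "BRANCH_A",
    "BRANCH_B",
    "NO_BRANCH",
    "BranchingKernelSpec",
    "AugmentedInput",
    "base_kernel_eval",
    "branching_covariance",
    "branching_covariance_dloglengthscale",
]

#: Function labels on the augmented input.
TRUNK, BRANCH_A, BRANCH_B = 1, 2, 3

#: Sentinel branching point for the non-branching (t_b -> infinity) model.
NO_BRANCH = np.inf

#: Relative diagonal jitter (times signal variance) added before factorisation.
DEFAULT_JITTER = 1e-6


@dataclass(frozen=True)
class BranchingKernelSpec:
    """Hyperparameters of the branching kernel.

    Parameters
    ----------
    signal_variance
        Marginal variance of each latent function (expression units squared).
    lengthscale
        Smoothness scale of the base kernel, in pseudotime units.
    branch_point
        Pseudotime at which the three latent functions intersect, or the
        ``NO_BRANCH`` sentinel (``inf``) for the non-branching model.
    base_kernel
        Name of the base kernel. Only the squared exponential is built in;
        the field exists so alternative kernels can be added.
    """

    signal_variance: float
    lengthscale: float
    branch_point: float = NO_BRANCH
    base_kernel: str = "sqexp"

    def __post_init__(self) -> None:
        if not (self.signal_variance > 0 and np.isfinite(self.signal_variance)):
            raise ValueError(f"signal_variance must be positive, got {self.signal_variance}")
        if not (self.lengthscale > 0 and np.isfinite(self.lengthscale)):
            raise ValueError(f"lengthscale must be positive, got {self.lengthscale}")
        if np.isnan(self.branch_point):
            raise ValueError("branch_point must be a real number or inf (no-branch)")
        if self.base_kernel != "sqexp":
            raise ValueError(f"unsupported base kernel {self.base_kernel!r}")

    @property
    def branches(self) -> bool:
        """Whether this kernel has a finite branching point."""
        return np.isfinite(self.branch_point)


@dataclass(frozen=True)
class AugmentedInput:
    """Input locations for the joint (f, g, h) process.

    Each point is a (pseudotime, function label) pair with labels in
    {TRUNK, BRANCH_A, BRANCH_B}. The expanded representation evaluating all
    three functions at every cell has size M = 3N, stored function-major:
    index ``m * N + n`` is function ``m`` at cell ``n``.
    """

    pseudotime: np.ndarray
    function_label: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.pseudotime, dtype=float)
        lab = np.asarray(self.function_label, dtype=int)
        if t.ndim != 1 or lab.shape != t.shape:
            raise ValueError("pseudotime and function_label must be matching 1-D arrays")
        if not np.all(np.isfinite(t)):
            raise ValueError("pseudotime must be finite")
        if not np.isin(lab, (TRUNK, BRANCH_A, BRANCH_B)).all():
            raise ValueError("function labels must be in {1, 2, 3}")
        object.__setattr__(self, "pseudotime", t)
        object.__setattr__(self, "function_label", lab)

    def __len__(self) -> int:
        return self.pseudotime.shape[0]

    @classmethod
    def expand(cls, t: np.ndarray) -> "AugmentedInput":
        """All three functions evaluated at every pseudotime (function-major)."""
        t = np.asarray(t, dtype=float)
        n = t.shape[0]
        return cls(np.tile(t, 3), np.repeat([TRUNK, BRANCH_A, BRANCH_B], n))


def base_kernel_eval(spec: BranchingKernelSpec, t1, t2) -> np.ndarray:
    """Squared-exponential base kernel sv * exp(-(t - t')^2 / (2 ls^2))."""
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2, dtype=float))
    d2 = (t1[:, None] - t2[None, :]) ** 2
    return spec.signal_variance * np.exp(-0.5 * d2 / spec.lengthscale**2)


def _sqdist_matrix(spec: BranchingKernelSpec, x: AugmentedInput, y: AugmentedInput) -> np.ndarray:
    """Effective squared distance: |t-t'|^2 within a label, routed through
    the branching point across labels."""
    t1, t2 = x.pseudotime, y.pseudotime
    same = x.function_label[:, None] == y.function_label[None, :]
    d_same = (t1[:, None] - t2[None, :]) ** 2
    if not spec.branches:
        d_cross = np.full_like(d_same, np.inf)
    else:
        tp = spec.branch_point
        d_cross = (t1[:, None] - tp) ** 2 + (tp - t2[None, :]) ** 2
    return np.where(same, d_same, d_cross)


def branching_covariance(
    spec: BranchingKernelSpec,
    x: AugmentedInput,
    y: AugmentedInput | None = None,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Covariance of the constrained (f, g, h) process on augmented inputs.

    Same-label blocks are the base kernel; cross-label blocks are
    K(T, t_b) K(t_b, T') / K(t_b, t_b), which for the squared exponential is
    sv * exp(-((t - t_b)^2 + (t_b - t')^2) / (2 ls^2)).

    When ``y`` is omitted the matrix is square and ``jitter * signal_variance``
    is added to its diagonal so it is positive definite up to floating point.
    """
    square = y is None
    if square:
        y = x
    d2 = _sqdist_matrix(spec, x, y)
    with np.errstate(under="ignore"):
        k = spec.signal_variance * np.exp(-0.5 * d2 / spec.lengthscale**2)
    if square:
        k[np.diag_indices_from(k)] += jitter * spec.signal_variance
    return k


def branching_covariance_dloglengthscale(
    spec: BranchingKernelSpec,
    x: AugmentedInput,
    y: AugmentedInput | None = None,
) -> np.ndarray:
    """Derivative of ``branching_covariance`` w.r.t. log(lengthscale).

    Entrywise K_ij * d2_ij / ls^2 with the routed squared distance d2. The
    jitter term does not depend on the lengthscale and contributes nothing.
    """
    if y is None:
        y = x
    d2 = _sqdist_matrix(spec, x, y)
    ls2 = spec.lengthscale**2
    with np.errstate(under="ignore", invalid="ignore"):
        out = spec.signal_variance * np.exp(-0.5 * d2 / ls2) * (d2 / ls2)
    return np.where(np.isfinite(d2), out, 0.0)
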