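"""Synthetic branching-expression benchmark generator.

Datasets are drawn from the model itself: each branching gene is a joint
draw of (trunk, branch, branch) functions from the constrained-intersection
prior at its group's branching time, observed through iid Gaussian noise.
Draws whose two branch functions cross again after the branching point are
rejected and redrawn, so a branching gene separates cleanly once it
branches. Non-branching genes are single GP draws with the same base
kernel.

The default configuration is the benchmark design used throughout the
tests: N = 150 cells on a unit pseudotime interval, 10 genes branching at
t = 0.2, 20 at t = 0.8 and 10 not branching, with signal variance 2 and
lengthscale 1.2. Post-branch cells carry one shared fair-coin branch
membership per dataset (not per gene) so that a single global branching
structure describes every gene; the derived global assignment uses the true
memberships and the earliest true branching time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kernel import (
    AugmentedInput,
    BranchingKernelSpec,
    base_kernel_eval,
    branching_covariance,
)
from .model import GlobalBranching

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "DEFAULT_GROUPS",
    "EARLY_BIAS_GROUPS",
    "sample_branching_gene",
    "sample_nonbranching_gene",
    "make_benchmark",
    "corrupt_global_labels",
    "balanced_subsample",
]

#: Benchmark gene groups: (branching time or None, gene count).
DEFAULT_GROUPS: tuple = ((0.2, 10), (0.8, 20), (None, 10))
#: Bias-demonstration design: few very early, many late branching genes.
EARLY_BIAS_GROUPS: tuple = ((0.1, 3), (0.7, 27), (None, 10))

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_cells: int = 150
    gene_groups: tuple = DEFAULT_GROUPS
    signal_variance: float = 2.0
    lengthscale: float = 1.2
    noise_variance: float = 0.001
    global_prior_confidence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least two cells")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be positive")
        for tb, count in self.gene_groups:
            if count < 0:
                raise ValueError("gene counts must be non-negative")
            if tb is not None and not (0.0 < tb < 1.0):
                raise ValueError(f"branching times must lie in (0, 1), got {tb}")

    def scaled(self, scale: float) -> "SyntheticConfig":
        """Shrink gene counts proportionally (each group keeps >= 1 gene)."""
        if not (0.0 < scale <= 1.0):
            raise ValueError("scale must be in (0, 1]")
        groups = tuple((tb, max(1, round(cnt * scale))) for tb, cnt in self.gene_groups)
        return replace(self, gene_groups=groups)

    @property
    def n_genes(self) -> int:
        return sum(cnt for _, cnt in self.gene_groups)


@dataclass
class SyntheticDataset:
    """Generated expression with full ground truth."""

    expr: pd.DataFrame  # genes x cells
    pseudotime: np.ndarray
    true_branch_time: dict  # gene id -> branching time or None
    true_cell_branch: pd.DataFrame  # genes x cells, 0 = trunk / not branched
    global_branching: GlobalBranching
    config: SyntheticConfig

    @property
    def branching_genes(self) -> list:
        return [g for g, tb in self.true_branch_time.items() if tb is not None]


def _branching_chol(config: SyntheticConfig, branch_time: float, t: np.ndarray) -> np.ndarray:
    spec = BranchingKernelSpec(config.signal_variance, config.lengthscale, branch_time)
    kmat = branching_covariance(spec, AugmentedInput.expand(t))
    return np.linalg.cholesky(kmat)


def sample_branching_gene(
    config: SyntheticConfig,
    branch_time: float,
    rng: np.random.Generator,
    t: np.ndarray | None = None,
    membership: np.ndarray | None = None,
    chol: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one branching gene; returns (expression, per-cell branch).

    The latent (f, g, h) triple is drawn jointly from the constrained
    prior; draws where the two branch functions cross again after the
    branching point (a sign change of g - h on the post-branch cell grid)
    are rejected. Post-branch cells follow ``membership`` (1 or 2); if not
    given, a fair coin is tossed per cell. Pre-branch cells read the trunk.
    """
    if not (0.0 < branch_time < 1.0):
        raise ValueError("branch_time must lie in (0, 1)")
    if t is None:
        t = np.sort(rng.uniform(0.0, 1.0, config.n_cells))
    n = t.shape[0]
    if chol is None:
        chol = _branching_chol(config, branch_time, t)
    post = t > branch_time
    for _ in range(_MAX_REJECTIONS):
        latent = chol @ rng.standard_normal(3 * n)
        f, g, h = latent[:n], latent[n : 2 * n], latent[2 * n :]
        diff = (g - h)[post]
        if diff.size >= 2 and np.any(diff[:-1] * diff[1:] < 0):
            continue
        break
    else:
        raise RuntimeError(
            "rejection budget exhausted while avoiding post-branch crossings; "
            "a longer lengthscale makes crossings rarer"
        )
    if membership is None:
        membership = rng.integers(1, 3, size=n)
    cell_branch = np.where(post, membership, 0)
    expr = np.where(post, np.where(membership == 1, g, h), f)
    expr = expr + np.sqrt(config.noise_variance) * rng.standard_normal(n)
    return expr, cell_branch


def sample_nonbranching_gene(
    config: SyntheticConfig,
    rng: np.random.Generator,
    t: np.ndarray | None = None,
    chol: np.ndarray | None = None,
) -> np.ndarray:
    """Single-GP draw with the same base kernel plus observation noise."""
    if t is None:
        t = np.sort(rng.uniform(0.0, 1.0, config.n_cells))
    if chol is None:
        spec = BranchingKernelSpec(config.signal_variance, config.lengthscale)
        kmat = base_kernel_eval(spec, t, t)
        kmat[np.diag_indices_from(kmat)] += 1e-6 * config.signal_variance
        chol = np.linalg.cholesky(kmat)
    f = chol @ rng.standard_normal(t.shape[0])
    return f + np.sqrt(config.noise_variance) * rng.standard_normal(t.shape[0])


def make_benchmark(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full benchmark dataset, reproducible from its seed.

    Pseudotimes are sorted uniforms on [0, 1]. One fair-coin branch
    membership per cell is shared by all genes, and the derived global
    branching uses the true memberships with the earliest true branching
    time — an oracle global assignment (``corrupt_global_labels`` emulates
    imperfect upstream estimates).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    t = np.sort(rng.uniform(0.0, 1.0, n))
    membership = rng.integers(1, 3, size=n)

    branch_times = [tb for tb, _ in config.gene_groups if tb is not None]
    if not branch_times:
        raise ValueError("benchmark needs at least one branching group")
    global_time = min(branch_times)

    chols = {tb: _branching_chol(config, tb, t) for tb in set(branch_times)}
    spec0 = BranchingKernelSpec(config.signal_variance, config.lengthscale)
    k0 = base_kernel_eval(spec0, t, t)
    k0[np.diag_indices_from(k0)] += 1e-6 * config.signal_variance
    chol0 = np.linalg.cholesky(k0)

    rows, branches, gene_ids, truth = [], [], [], {}
    idx = 0
    for tb, count in config.gene_groups:
        for _ in range(count):
            gid = f"g{idx:03d}"
            if tb is None:
                expr = sample_nonbranching_gene(config, rng, t=t, chol=chol0)
                cb = np.zeros(n, dtype=int)
            else:
                expr, cb = sample_branching_gene(config, tb, rng, t=t, membership=membership, chol=chols[tb])
            rows.append(expr)
            branches.append(cb)
            gene_ids.append(gid)
            truth[gid] = tb
            idx += 1

    cell_ids = [f"c{i:03d}" for i in range(n)]
    labels = np.where(t < global_time, "trunk", membership.astype(str))
    global_branching = GlobalBranching(t, labels, global_time, source="truth")
    return SyntheticDataset(
        expr=pd.DataFrame(rows, index=gene_ids, columns=cell_ids),
        pseudotime=t,
        true_branch_time=truth,
        true_cell_branch=pd.DataFrame(branches, index=gene_ids, columns=cell_ids),
        global_branching=global_branching,
        config=config,
    )


def corrupt_global_labels(
    global_branching: GlobalBranching,
    flip_rate: float,
    rng: np.random.Generator,
) -> GlobalBranching:
    """Flip post-branch branch labels independently at ``flip_rate``.

    Emulates imperfect upstream global state estimation; trunk labels are
    untouched. ``flip_rate = 0.5`` destroys all label information.
    """
    if not (0.0 <= flip_rate <= 0.5):
        raise ValueError("flip_rate must be in [0, 0.5]")
    codes = global_branching.label_codes.copy()
    post = codes != 0
    flips = post & (rng.uniform(size=codes.shape[0]) < flip_rate)
    codes[flips] = 3 - codes[flips]  # swap 1 <-> 2
    labels = np.where(codes == 0, "trunk", codes.astype(str))
    return GlobalBranching(
        global_branching.pseudotime,
        labels,
        global_branching.global_branch_time,
        source=f"{global_branching.source}+flip{flip_rate}",
    )


def balanced_subsample(
    expr: pd.DataFrame,
    global_branching: GlobalBranching,
    n_target: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GlobalBranching, np.ndarray]:
    """Stratified cell subsample pushing trunk/branch counts toward equality.

    Each stratum (trunk, branch 1, branch 2) receives an equal quota; a
    stratum smaller than its quota is taken whole and the shortfall is
    redistributed over the remaining strata. Deterministic given the rng
    state. Returns (expression subset, branching subset, kept indices).
    """
    n = len(global_branching)
    if n_target > n:
        raise ValueError("n_target exceeds the number of cells")
    codes = global_branching.label_codes
    strata = {c: np.flatnonzero(codes == c) for c in (0, 1, 2) if np.any(codes == c)}
    quotas = {c: 0 for c in strata}
    remaining = n_target
    open_strata = dict(strata)
    while remaining > 0 and open_strata:
        share = remaining // len(open_strata)
        extra = remaining - share * len(open_strata)
        alloc = {}
        for i, c in enumerate(sorted(open_strata)):
            alloc[c] = share + (1 if i < extra else 0)
        progressed = False
        for c in sorted(open_strata):
            avail = strata[c].shape[0] - quotas[c]
            take = min(alloc[c], avail)
            quotas[c] += take
            remaining -= take
            progressed = progressed or take > 0
            if quotas[c] == strata[c].shape[0]:
                open_strata.pop(c)
        if not progressed:
            break
    keep = []
    for c, members in strata.items():
        chosen = rng.choice(members, size=quotas[c], replace=False)
        keep.append(chosen)
    keep = np.sort(np.concatenate(keep))
    sub_global = GlobalBranching(
        global_branching.pseudotime[keep],
        np.asarray(global_branching.global_label)[keep],
        global_branching.global_branch_time,
        source=global_branching.source,
    )
    return expr.iloc[:, keep], sub_global, keep
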