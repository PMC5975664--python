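"""Readers, writers, run configuration and provenance.

Expression matrices are genes x cells, either CSV (gene ids in the first
column, cell ids in the header) or MatrixMarket MTX with ``genes.tsv`` /
``barcodes.tsv`` sidecars. Pseudotime and global branch labels travel in a
TSV with columns ``cell_id``, ``pseudotime``, ``branch`` (trunk / 1 / 2)
and the global branching time in a ``# global_branch_time = ...`` header
comment. Every writer emits a provenance header (version, seed, config
hash) sufficient to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__ as _version
from .model import GlobalBranching, results_table

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_global_branching",
    "write_global_branching",
    "write_dataset",
    "write_results",
    "read_results_table",
]


@dataclass
class RunConfig:
    """Serialisable run-level settings, echoed into output provenance."""

    n_candidates: int = 20
    prior_confidence: float = 0.99
    n_inducing: int = 30
    credible_level: float = 0.98
    evidence_cutoff: float = 0.0
    posterior_samples: int = 5000
    network_confidence: float = 0.95
    seed: int = 0
    threads: int = 1
    noise_floor_rel: float = 1e-6
    max_outer: int = 4

    def __post_init__(self) -> None:
        if not (2 <= self.n_candidates):
            raise ValueError("n_candidates must be at least 2")
        if not (0.5 <= self.prior_confidence < 1.0):
            raise ValueError("prior_confidence must be in [0.5, 1)")
        if not (0.0 < self.credible_level < 1.0):
            raise ValueError("credible_level must be in (0, 1)")
        if not (0.5 < self.network_confidence <= 1.0):
            raise ValueError("network_confidence must be in (0.5, 1]")
        if self.posterior_samples < 1 or self.n_inducing < 0:
            raise ValueError("posterior_samples must be >= 1 and n_inducing >= 0")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def provenance_header(config: RunConfig | None = None, **extra) -> str:
    fields = {"branchgp": _version}
    if config is not None:
        fields.update(seed=config.seed, config_hash=config.config_hash)
    fields.update(extra)
    return "# " + " ".join(f"{k}={v}" for k, v in fields.items()) + "\n"


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def _check_unique(names, what: str) -> None:
    seen: dict = {}
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate {what} id: {name!r}")
        seen[name] = True


def read_expression(path) -> pd.DataFrame:
    """Genes x cells matrix from CSV or MatrixMarket (with sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx" or (path.is_dir() and (path / "matrix.mtx").exists()):
        mtx_path = path if path.suffix == ".mtx" else path / "matrix.mtx"
        base = mtx_path.parent
        mat = scipy.io.mmread(mtx_path)
        genes = pd.read_csv(base / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(base / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape[0] != len(genes):
            raise ValueError(f"matrix has {dense.shape[0]} rows but genes.tsv lists {len(genes)} genes")
        if dense.shape[1] != len(cells):
            raise ValueError(f"matrix has {dense.shape[1]} columns but barcodes.tsv lists {len(cells)} cells")
        df = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        df = pd.read_csv(path, index_col=0, comment="#")
        df.index = df.index.astype(str)
        try:
            df = df.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric expression entry in {path}: {exc}") from None
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "cell")
    if not np.all(np.isfinite(df.to_numpy())):
        bad = np.argwhere(~np.isfinite(df.to_numpy()))[0]
        raise ValueError(f"non-finite expression at gene {df.index[bad[0]]!r}, cell {df.columns[bad[1]]!r}")
    return df


def write_expression(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, kind="expression"))
        df.to_csv(fh)


# ---------------------------------------------------------------------------
# Global branching TSV
# ---------------------------------------------------------------------------


def read_global_branching(
    path,
    global_branch_time: float | None = None,
    expected_cells=None,
    source: str | None = None,
) -> GlobalBranching:
    """Pseudotime/label TSV -> :class:`GlobalBranching`.

    The global branching time may come from a ``# global_branch_time = x``
    header comment or the ``global_branch_time`` argument. Trunk labels at
    or after the global branching time trigger a warning (the prior treats
    them as unlabelled). ``expected_cells`` enables a completeness check
    against an expression matrix.
    """
    path = Path(path)
    header_time = None
    header_source = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "global_branch_time" in line:
                header_time = float(line.split("=")[-1])
            if "source" in line and "=" in line:
                header_source = line.split("=")[-1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"cell_id": str, "branch": str})
    required = {"cell_id", "pseudotime", "branch"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} must have columns {sorted(required)}, found {list(df.columns)}")
    _check_unique(df["cell_id"], "cell")
    if global_branch_time is None:
        global_branch_time = header_time
    if global_branch_time is None:
        raise ValueError("global branching time missing (no header comment and no argument)")
    if expected_cells is not None:
        missing = sorted(set(expected_cells) - set(df["cell_id"]))
        if missing:
            raise ValueError(f"cells present in expression but missing here: {missing[:10]}")
        df = df.set_index("cell_id").loc[list(expected_cells)].reset_index()
    gb = GlobalBranching(
        df["pseudotime"].to_numpy(dtype=float),
        df["branch"].to_numpy(),
        float(global_branch_time),
        source=source or header_source or str(path),
    )
    late_trunk = (gb.label_codes == 0) & (gb.pseudotime >= gb.global_branch_time)
    if late_trunk.any():
        warnings.warn(f"{int(late_trunk.sum())} trunk labels at/after the global branching time; treated as unlabelled")
    return gb


def write_global_branching(gb: GlobalBranching, path, cell_ids=None, config: RunConfig | None = None) -> None:
    path = Path(path)
    n = len(gb)
    cells = list(cell_ids) if cell_ids is not None else [f"c{i:03d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(provenance_header(config, kind="global_branching"))
        fh.write(f"# global_branch_time = {gb.global_branch_time!r}\n")
        fh.write(f"# source = {gb.source}\n")
        pd.DataFrame(
            {"cell_id": cells, "pseudotime": gb.pseudotime, "branch": np.asarray(gb.global_label)}
        ).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic dataset and per-gene results stores
# ---------------------------------------------------------------------------


def write_dataset(dataset, outdir, config: RunConfig | None = None) -> None:
    """Expression CSV + branching TSV + ground-truth JSON for a synthetic set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expr, outdir / "expression.csv", config)
    write_global_branching(
        dataset.global_branching, outdir / "branching.tsv", cell_ids=dataset.expr.columns, config=config
    )
    truth = {
        "true_branch_time": dataset.true_branch_time,
        "true_cell_branch": {g: dataset.true_cell_branch.loc[g].tolist() for g in dataset.true_cell_branch.index},
        "seed": dataset.config.seed,
        "config": asdict(dataset.config) | {"gene_groups": [list(g) for g in dataset.config.gene_groups]},
        "branchgp": _version,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def write_results(fits, outdir, config: RunConfig | None = None) -> None:
    """Directory-of-CSV results store: summary table + per-gene posteriors."""
    outdir = Path(outdir)
    (outdir / "posteriors").mkdir(parents=True, exist_ok=True)
    with open(outdir / "results.tsv", "w") as fh:
        fh.write(provenance_header(config, kind="results"))
        results_table(fits).to_csv(fh, sep="\t")
    for fit in fits:
        pd.DataFrame(
            {"candidate_tb": fit.times, "log_evidence": fit.log_evidence, "posterior": fit.posterior}
        ).to_csv(outdir / "posteriors" / f"{fit.gene_id}_posterior.csv", index=False)
        pd.DataFrame(fit.phi_map, columns=["trunk", "branch1", "branch2"]).to_csv(
            outdir / "posteriors" / f"{fit.gene_id}_phi.csv", index=False
        )
    meta = {
        "branchgp": _version,
        "genes": [f.gene_id for f in fits],
        "no_branch_log_evidence": {f.gene_id: f.log_evidence_no_branch for f in fits},
        "config": asdict(config) if config is not None else None,
    }
    (outdir / "provenance.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_results_table(outdir) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "results.tsv", sep="\t", comment="#", index_col=0)
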