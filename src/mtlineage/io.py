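"""Readers/writers for the pipeline's on-disk formats.

Conventions: tab-separated UTF-8 tables with a header row and no quoting;
sparse matrices as MatrixMarket with ``cells.tsv`` / ``variants.tsv``
sidecars; trees as Newick with cell barcodes as leaf labels; configuration
as YAML; run reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml
from skbio import TreeNode

from . import __version__
from .matrix import VariantCellMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_tree",
    "read_tree",
    "RunConfig",
    "write_run_report",
]

SCHEMA_VERSION = 1


def write_matrix(vcm: VariantCellMatrix, prefix) -> None:
    """Write counts as ``<prefix>.mtx`` with ``<prefix>.cells.tsv`` and
    ``<prefix>.variants.tsv`` sidecars (and ``<prefix>.coverage.mtx`` when
    per-position coverage is attached)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix) + ".mtx", vcm.C.tocoo())
    pd.DataFrame({"cell": vcm.cells}).to_csv(
        str(prefix) + ".cells.tsv", sep="\t", index=False)
    vcm.variants.to_csv(str(prefix) + ".variants.tsv", sep="\t", index=False)
    if vcm.coverage is not None:
        spio.mmwrite(str(prefix) + ".coverage.mtx",
                     sp.coo_matrix(vcm.coverage))


def read_matrix(prefix) -> VariantCellMatrix:
    """Read a matrix written by :func:`write_matrix`; round-trips are
    lossless for counts and id ordering."""
    prefix = str(prefix)
    C = sp.csr_matrix(spio.mmread(prefix + ".mtx"))
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t")["cell"].tolist()
    variants = pd.read_csv(prefix + ".variants.tsv", sep="\t")
    if C.shape != (len(cells), len(variants)):
        raise ValueError("matrix dimensions do not match the sidecar files")
    cov_path = Path(prefix + ".coverage.mtx")
    coverage = None
    if cov_path.exists():
        coverage = np.asarray(spio.mmread(str(cov_path)).todense(), dtype=np.int32)
    return VariantCellMatrix(C.astype(np.int64), cells, variants, coverage=coverage)


def load_priors(path) -> pd.Series:
    """Read a cross-donor mutation-rate table into per-variant priors.

    Expects a two-column TSV ``variant_id, avg_rate``; the returned prior
    is ``1 - avg_rate`` (mutations recurring across donors are likely
    homoplasic and get down-weighted).
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["variant_id", "avg_rate"]:
        raise ValueError("priors file needs columns: variant_id, avg_rate")
    rates = df.set_index("variant_id")["avg_rate"]
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("avg_rate must lie in [0, 1]")
    return (1.0 - rates).rename("prior")


def write_tree(tree: TreeNode, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    """Read a Newick tree; duplicate leaf labels are fatal."""
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in Newick file")
    return tree


@dataclass
class RunConfig:
    """Serializable configuration covering the pipeline stages.

    Unspecified sections fall back to each module's dataclass defaults.
    A single ``seed`` governs every stochastic stage through derived
    substreams.
    """

    seed: int = 0
    stringency_preset: str = "sensitive"
    simulate: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    matrix: dict = field(default_factory=dict)
    tree: dict = field(default_factory=dict)
    clones: dict = field(default_factory=dict)
    propagation: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def write_run_report(report: dict, path) -> None:
    """JSON run report echoing stage counts, resolved config and version."""
    payload = {"schema_version": SCHEMA_VERSION, "software_version": __version__}
    payload.update(report)
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
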