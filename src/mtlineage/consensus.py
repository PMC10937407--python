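"""Endogenous-UMI consensus variant calling.

Reads sharing the exact key (cell barcode, fragment start, fragment end)
derive from one original mtDNA molecule and are grouped into an eUMI group.
A single-molecule consensus is called per group: a non-reference base is
retained only when supported by at least ``consensus_threshold`` of the
group's reads (and, when required, seen on both paired-end mates), which
removes virtually all sequencing/PCR errors because independent errors
rarely recur at one site within a group.

Variant-level multistep filtering then removes known artefact-prone
positions (rCRS-style blacklist), near-homoplasmic variants present in
nearly all cells (germline/haplogroup), and variants seen in fewer than a
minimum number of cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .reference import BASES, reference_array
from .simulate import ReadTable

__all__ = [
    "FilterConfig",
    "EUMIGroup",
    "EUMIGroups",
    "ConsensusMolecules",
    "group_eumis",
    "call_consensus",
    "call_consensus_all",
    "call_variants",
    "position_coverage",
    "compute_coverage",
    "compute_burden",
    "mutation_signature",
]

# positions adjacent to the rCRS poly-C tracts that dominate alignment
# artefacts; excluded from calling by default
DEFAULT_BLACKLIST = tuple(range(300, 317)) + tuple(range(3106, 3111))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the multistep filter.

    ``stringency_preset`` switches between a sensitive default and a
    specific preset (groups of >= 3 reads, unanimous consensus).
    """

    min_group_size: int = 2
    consensus_threshold: float = 0.75
    require_strand_agreement: bool = True
    blacklist: tuple = DEFAULT_BLACKLIST
    germline_cell_frac: float = 0.9
    germline_het: float = 0.9
    min_cells_per_variant: int = 2
    min_molecules_per_cellvariant: int = 1
    stringency_preset: str = "sensitive"

    def __post_init__(self):
        if self.min_group_size < 1 or self.min_cells_per_variant < 1:
            raise ValueError("count thresholds must be >= 1")
        for name in ("consensus_threshold", "germline_cell_frac", "germline_het"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.stringency_preset not in ("sensitive", "specific"):
            raise ValueError("stringency_preset must be 'sensitive' or 'specific'")
        if self.stringency_preset == "specific":
            if self.min_group_size < 3 or self.consensus_threshold != 1.0:
                raise ValueError(
                    "the specific preset requires min_group_size >= 3 and "
                    "consensus_threshold == 1.0")

    @classmethod
    def preset(cls, name: str) -> "FilterConfig":
        if name == "sensitive":
            return cls()
        if name == "specific":
            return cls(min_group_size=3, consensus_threshold=1.0,
                       stringency_preset="specific")
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class EUMIGroup:
    """One eUMI group: all reads sharing (cell, start, end)."""

    key: tuple
    reads: pd.DataFrame
    mismatches: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class EUMIGroups:
    """Vectorised container of all eUMI groups of a read table.

    ``groups`` has one row per group (``group_id, cell, start, end, size``);
    ``reads`` carries the per-read ``group_id``.
    """

    groups: pd.DataFrame
    reads: pd.DataFrame
    mismatches: pd.DataFrame

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return self.groups["size"].to_numpy()

    def get(self, group_id: int) -> EUMIGroup:
        rows = self.reads[self.reads["group_id"] == group_id]
        mm = self.mismatches[self.mismatches["read_id"].isin(rows["read_id"])]
        g = self.groups.loc[self.groups["group_id"] == group_id].iloc[0]
        return EUMIGroup((g["cell"], int(g["start"]), int(g["end"])), rows, mm)

    def collision_rate(self) -> float:
        """Fraction of groups containing reads from more than one true
        molecule (requires simulator molecule labels)."""
        if "molecule" not in self.reads or (self.reads["molecule"] < 0).any():
            raise ValueError("collision rate needs truth molecule labels")
        nmol = self.reads.groupby("group_id")["molecule"].nunique()
        return float((nmol > 1).mean())


def group_eumis(read_table: ReadTable) -> EUMIGroups:
    """Partition reads by the exact eUMI key (cell, start, end).

    Malformed coordinates are flagged (dropped with a warning), not fatal.
    """
    reads = read_table.reads
    bad = (reads["start"] > reads["end"]) | (reads["start"] < 1) | (
        reads["end"] > read_table.genome_length)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} reads with malformed coordinates")
        reads = reads[~bad]
    reads = reads.copy()
    reads["group_id"] = reads.groupby(["cell", "start", "end"], sort=True, observed=True).ngroup()
    groups = (reads.groupby("group_id")
              .agg(cell=("cell", "first"), start=("start", "first"),
                   end=("end", "first"), size=("read_id", "size"))
              .reset_index())
    return EUMIGroups(groups, reads, read_table.mismatches)


def _consensus_calls(reads: pd.DataFrame, mismatches: pd.DataFrame,
                     sizes: pd.Series, config: FilterConfig) -> pd.DataFrame:
    """Vectorised per-(group, pos, alt) consensus scoring.

    A call is retained when its consensus score (supporting reads / group
    size) reaches the threshold and, when strand agreement is required and
    the group contains both mates, the alt is seen on both mates.
    """
    mm = mismatches.merge(reads[["read_id", "group_id", "mate"]], on="read_id")
    if mm.empty:
        return pd.DataFrame(columns=["group_id", "pos", "alt", "score"])
    mm["plus"] = (mm["mate"] == 0).astype(np.int32)
    mm["minus"] = (mm["mate"] == 1).astype(np.int32)
    sup = (mm.groupby(["group_id", "pos", "alt"], sort=False)
           .agg(n=("read_id", "size"), n_plus=("plus", "sum"),
                n_minus=("minus", "sum")).reset_index())
    sup["size"] = sup["group_id"].map(sizes)
    sup["score"] = sup["n"] / sup["size"]
    keep = sup["score"] >= config.consensus_threshold
    if config.require_strand_agreement:
        mates = reads.groupby("group_id")["mate"].nunique()
        both = sup["group_id"].map(mates) > 1
        keep &= ~both | ((sup["n_plus"] > 0) & (sup["n_minus"] > 0))
    out = sup.loc[keep, ["group_id", "pos", "alt", "score"]]
    # a threshold <= 0.5 could retain two alleles at one site; keep the majority
    out = (out.sort_values(["group_id", "pos", "score"])
           .drop_duplicates(["group_id", "pos"], keep="last"))
    return out.reset_index(drop=True)


def call_consensus(group: EUMIGroup, config: FilterConfig = FilterConfig()):
    """Call the consensus for a single eUMI group.

    Returns ``None`` (rejected) for undersized groups, else a DataFrame of
    retained non-reference calls (``pos, alt, score``); an empty frame means
    the molecule matches the reference everywhere.
    """
    if group.size == 0:
        raise ValueError("empty eUMI group")
    if group.size < config.min_group_size:
        return None
    calls = _consensus_calls(group.reads.assign(group_id=0), group.mismatches,
                             pd.Series({0: group.size}), config)
    return calls.drop(columns=["group_id"]).reset_index(drop=True)


@dataclass
class ConsensusMolecules:
    """Consensus-corrected single molecules.

    ``molecules``: one row per retained group (``group_id, cell, start,
    end, size``); ``calls``: retained non-reference consensus calls
    (``group_id, pos, alt, score``); ``report``: filter-stage counts,
    including the per-sample eUMI filtering rate.
    """

    molecules: pd.DataFrame
    calls: pd.DataFrame
    report: dict = field(default_factory=dict)


def call_consensus_all(read_table: ReadTable, config: FilterConfig = FilterConfig(),
                       sample: str = "sample1") -> ConsensusMolecules:
    """Group reads and consensus-call every eUMI group of a read table."""
    grouped = group_eumis(read_table)
    groups, reads = grouped.groups, grouped.reads
    sizes = groups.set_index("group_id")["size"]
    passing = groups["size"] >= config.min_group_size
    retained = groups[passing].copy()
    reads_kept = reads[reads["group_id"].isin(retained["group_id"])]
    calls = _consensus_calls(reads_kept, grouped.mismatches, sizes, config)
    rate = float(passing.mean()) if len(groups) else 0.0
    report = {
        "n_reads": int(len(reads)),
        "n_groups": int(len(groups)),
        "n_groups_retained": int(passing.sum()),
        "eumi_filter_rate": {sample: rate},
        "n_consensus_calls": int(len(calls)),
    }
    return ConsensusMolecules(retained.reset_index(drop=True), calls, report)


# ---------------------------------------------------------------------------
# variant calling


def variant_id(pos, ref, alt) -> str:
    """Canonical 1-based variant identifier ``{pos}_{ref}_{alt}``."""
    return f"{pos}_{ref}_{alt}"


def position_coverage(molecules: pd.DataFrame, positions, cells: list[str]) -> np.ndarray:
    """Molecule coverage per (cell, position): the number of retained
    molecules of the cell whose fragment spans the position."""
    positions = np.asarray(positions, dtype=np.int64)
    out = np.zeros((len(cells), len(positions)), dtype=np.int32)
    cell_index = {c: i for i, c in enumerate(cells)}
    for cell, grp in molecules.groupby("cell", sort=False, observed=True):
        i = cell_index[cell]
        starts = np.sort(grp["start"].to_numpy())
        ends = np.sort(grp["end"].to_numpy())
        out[i] = (np.searchsorted(starts, positions, side="right")
                  - np.searchsorted(ends, positions, side="left"))
    return out


def call_variants(consensus: ConsensusMolecules, reference: str,
                  config: FilterConfig = FilterConfig()):
    """Aggregate consensus molecules into a filtered variant-by-cell matrix.

    Returns ``(vcm, variant_table)`` where ``vcm`` is a
    :class:`mtlineage.matrix.VariantCellMatrix` (counts = consensus
    molecules supporting the variant per cell, with per-variant-position
    molecule coverage attached for heteroplasmy) and ``variant_table``
    describes the retained variants.  Filters: blacklist positions,
    germline/haplogroup variants (near-homoplasmic in nearly all covered
    cells), and variants seen in fewer than ``min_cells_per_variant``
    cells.
    """
    from .matrix import VariantCellMatrix

    ref_codes = reference_array(reference)
    molecules, calls = consensus.molecules, consensus.calls
    if len(calls) and int(calls["pos"].max()) > len(reference):
        raise ValueError("variant position exceeds reference length")

    cells = sorted(molecules["cell"].unique())
    calls = calls.merge(molecules[["group_id", "cell"]], on="group_id")
    calls = calls[~calls["pos"].isin(set(config.blacklist))]
    if calls.empty:
        empty = VariantCellMatrix(
            sp.csr_matrix((len(cells), 0), dtype=np.int64), cells,
            pd.DataFrame(columns=["variant", "pos", "ref", "alt"]),
            coverage=np.zeros((len(cells), 0), dtype=np.int32))
        return empty, empty.variants

    counts = (calls.groupby(["cell", "pos", "alt"], sort=True, observed=True)
              .size().rename("n").reset_index())
    ref_at = ref_codes[counts["pos"].to_numpy() - 1]
    if (ref_at == counts["alt"].to_numpy()).any():
        raise ValueError("consensus alt equals the reference base")

    var_index = (counts[["pos", "alt"]].drop_duplicates()
                 .sort_values(["pos", "alt"]).reset_index(drop=True))
    var_index["ref"] = [reference[p - 1] for p in var_index["pos"]]
    var_index["alt"] = [BASES[a] for a in var_index["alt"]]
    var_index["variant"] = [variant_id(p, r, a) for p, r, a in
                            zip(var_index["pos"], var_index["ref"], var_index["alt"])]
    vkey = {(p, a): j for j, (p, a) in
            enumerate(zip(var_index["pos"], var_index["alt"]))}
    ckey = {c: i for i, c in enumerate(cells)}

    rows = counts["cell"].map(ckey).to_numpy()
    cols = np.fromiter((vkey[(p, BASES[a])] for p, a in
                        zip(counts["pos"], counts["alt"])), dtype=np.int64,
                       count=len(counts))
    C = sp.csr_matrix((counts["n"].to_numpy(), (rows, cols)),
                      shape=(len(cells), len(var_index)), dtype=np.int64)

    # molecule coverage at each variant position, per cell
    upos, upos_inv = np.unique(var_index["pos"].to_numpy(), return_inverse=True)
    cov = position_coverage(consensus.molecules, upos, cells)[:, upos_inv]

    dense = C.toarray()
    support = dense >= config.min_molecules_per_cellvariant
    n_cells_per_variant = support.sum(axis=0)

    het = np.where(cov > 0, np.minimum(dense / np.maximum(cov, 1), 1.0), 0.0)
    covered = cov > 0
    n_covered = covered.sum(axis=0)
    high = (het >= config.germline_het) & covered
    frac_high = np.where(n_covered > 0, high.sum(axis=0) / np.maximum(n_covered, 1), 0.0)
    germline = frac_high >= config.germline_cell_frac

    keep = (~germline) & (n_cells_per_variant >= config.min_cells_per_variant)
    var_kept = var_index.loc[keep, ["variant", "pos", "ref", "alt"]].reset_index(drop=True)
    vcm = VariantCellMatrix(C[:, np.nonzero(keep)[0]].tocsr(), cells, var_kept,
                            coverage=cov[:, keep])
    report = dict(consensus.report)
    report.update({
        "n_candidate_variants": int(len(var_index)),
        "n_germline_removed": int(germline.sum()),
        "n_too_few_cells_removed": int(((~germline) & (
            n_cells_per_variant < config.min_cells_per_variant)).sum()),
        "n_variants_final": int(keep.sum()),
    })
    vcm.report = report
    return vcm, var_kept


def compute_coverage(molecules: pd.DataFrame, genome_length: int,
                     cells: list[str] | None = None) -> pd.Series:
    """Mean mtDNA copies per position per cell: total retained fragment
    length divided by the genome length.  Cells without molecules get 0."""
    span = molecules["end"] - molecules["start"] + 1
    cov = span.groupby(molecules["cell"], observed=True).sum() / genome_length
    if cells is not None:
        cov = cov.reindex(cells, fill_value=0.0)
        n_zero = int((cov == 0).sum())
        if n_zero:
            warnings.warn(f"{n_zero} cells have zero mtDNA coverage")
    return cov.rename("coverage")


def compute_burden(n_mutations: pd.Series, eumi_filter_rate: dict,
                   coverage: pd.Series, sample_of: pd.Series | str = "sample1"
                   ) -> pd.DataFrame:
    """Per-cell mutation burden.

    burden = n_mutations / (eUMI filtering rate of the cell's sample x
    mtDNA coverage of the cell), normalising detected mutation counts for
    technical detectability.  Cells with zero coverage are excluded with a
    warning; a zero filtering rate is fatal for that sample.
    """
    cells = n_mutations.index
    if isinstance(sample_of, str):
        sample_of = pd.Series(sample_of, index=cells)
    for s, r in eumi_filter_rate.items():
        if r == 0:
            raise ValueError(f"eUMI filter rate is 0 for sample {s!r}")
    df = pd.DataFrame({
        "cell": cells,
        "sample": sample_of.reindex(cells).to_numpy(),
        "n_mutations": n_mutations.to_numpy(),
        "coverage": coverage.reindex(cells).to_numpy(),
    })
    df["eumi_filter_rate"] = df["sample"].map(eumi_filter_rate)
    zero = df["coverage"] <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} cells with zero coverage "
                      "from burden computation")
        df = df[~zero]
    df["burden"] = df["n_mutations"] / (df["eumi_filter_rate"] * df["coverage"])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# mutational signature


def mutation_signature(variants: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Classify variants by strand, substitution and trinucleotide context.

    Following the standard signature convention, each substitution is
    reported on the strand whose reference base is a pyrimidine (C or T).
    The reference sense strand is taken to be the light (L) strand, so the
    strand label is L when the sense reference base is a pyrimidine and H
    otherwise.  The circular genome provides context at the ends.  Class
    counts sum to the number of input variants.
    """
    from .reference import complement

    L = len(reference)
    rows = []
    for pos, ref, alt in zip(variants["pos"], variants["ref"], variants["alt"]):
        alt_b = alt if isinstance(alt, str) else BASES[alt]
        if reference[pos - 1] != ref:
            raise ValueError(f"reference mismatch at {pos}: {ref} vs {reference[pos - 1]}")
        up = reference[(pos - 2) % L]
        down = reference[pos % L]
        if ref in "CT":
            strand, sub = "L", f"{ref}>{alt_b}"
            ctx = f"{up}[{sub}]{down}"
        else:
            strand = "H"
            sub = f"{complement(ref)}>{complement(alt_b)}"
            ctx = f"{complement(down)}[{sub}]{complement(up)}"
        rows.append((strand, sub, ctx))
    cls = pd.DataFrame(rows, columns=["strand", "substitution", "context"])
    return (cls.groupby(["strand", "substitution", "context"])
            .size().rename("count").reset_index())
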