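"""Generative model of a clonally structured population accruing mtDNA
mutations.

The population is simulated as a division tree.  A single ancestral cell
divides through a random (Yule) topology into ``n_clones`` clone founders
(``founder_divisions`` divisions root-to-founder), and each founder divides
through a further random topology into ``cells_per_clone`` sampled cells
(``divisions_per_cell`` divisions founder-to-leaf).  Every cell carries
``mt_copies`` mitochondrial genomes.  At each division all genomes replicate
once; each newly synthesised genome acquires ``Poisson(mu)`` substitutions at
uniform random positions, and the ``2 * mt_copies`` genomes are partitioned
binomially between the daughters, so heteroplasmy drifts neutrally.
Mutations are tracked as per-cell copy counts; co-occurrence of distinct
mutations on one genome is not tracked (they are assigned to molecules
independently at capture time), an approximation that is inconsequential for
every downstream statistic, which only uses per-variant molecule support.

Sequencing is emulated at molecule (fragment) level.  Library preparation
fragments every genome copy, so each copy contributes many independent
fragments; ``capture_rate`` is the fraction of each copy's sequence that is
recovered, making the expected per-position coverage (mtDNA copies seen per
position per cell) equal to ``mt_copies * capture_rate``.  Each captured
fragment is one molecule: it receives a random interval, forming an
endogenous UMI (cell barcode, fragment start, fragment end), and a
shifted-Poisson number of reads (minimum one).  Each read is corrupted
independently at ``seq_error_rate`` per covered base.  Fragments are
sampled on the linear coordinate system (no origin-spanning fragments);
eUMI collisions arise naturally when two molecules of a cell draw the same
fragment interval.

Cell states (cell type, lineage, stem/progeny flag, timepoint) are emitted
as labels only: per clone, lineage proportions are drawn once from a
symmetric Dirichlet and reused at every timepoint, so clone lineage biases
are persistent by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .reference import BASES, DEFAULT_GENOME_LENGTH, reference_array, synthetic_reference

__all__ = [
    "SimConfig",
    "CellGenome",
    "TruthSet",
    "ReadTable",
    "simulate_lineage",
    "simulate_reads",
    "simulate_states",
    "simulate_dataset",
    "simulate_yule_tree",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    Defaults describe a polyclonal human-haematopoiesis-like regime: 50
    clones of 40 cells, 300 mtDNA genomes per cell, and a mutation rate
    calibrated so that a cell carries a median of roughly nine detected
    (shared) mtDNA variants after consensus calling and filtering.
    """

    n_clones: int = 50
    cells_per_clone: int | tuple = 40
    divisions_per_cell: int = 15
    founder_divisions: int = 120
    mt_copies: int = 300
    mu: float = 0.022
    genome_length: int = DEFAULT_GENOME_LENGTH
    capture_rate: float = 0.04
    reads_per_eumi_mean: float = 4.8
    seq_error_rate: float = 1e-3
    fragment_len_mean: float = 500.0
    fragment_len_sd: float = 120.0
    bias_alpha: float = 0.8
    frac_hsc: float = 0.2
    n_timepoints: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be positive")
        sizes = self.clone_sizes()
        if len(sizes) != self.n_clones or any(s < 1 for s in sizes):
            raise ValueError("cells_per_clone must be positive (one value or "
                             "one per clone)")
        if self.divisions_per_cell < 1 or self.founder_divisions < 0:
            raise ValueError("division counts must be non-negative (per-cell >= 1)")
        if self.mt_copies < 1 or self.genome_length < 1:
            raise ValueError("mt_copies and genome_length must be positive")
        for name in ("mu", "seq_error_rate", "capture_rate", "frac_hsc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        for name in ("capture_rate", "seq_error_rate", "frac_hsc"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} is a probability and must be <= 1")
        if self.reads_per_eumi_mean < 1:
            raise ValueError("reads_per_eumi_mean must be >= 1")
        if self.fragment_len_mean <= 0 or self.fragment_len_sd < 0:
            raise ValueError("fragment length parameters must be positive")
        if self.bias_alpha <= 0:
            raise ValueError("bias_alpha must be positive")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")

    def clone_sizes(self) -> list[int]:
        """Sampled cells per clone: a shared value or one entry per clone."""
        if isinstance(self.cells_per_clone, (int, np.integer)):
            return [int(self.cells_per_clone)] * self.n_clones
        return [int(s) for s in self.cells_per_clone]

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CellGenome:
    """Mutation content of one cell: per-mutation copy counts.

    ``pos`` is 1-based; ``alt`` holds base codes (A,C,G,T -> 0..3);
    ``count`` is the number of the cell's ``n_copies`` genomes carrying the
    mutation.
    """

    n_copies: int
    pos: np.ndarray
    alt: np.ndarray
    count: np.ndarray

    def heteroplasmy(self) -> np.ndarray:
        return self.count / self.n_copies


@dataclass
class TruthSet:
    """Ground truth emitted by :func:`simulate_lineage`."""

    tree: TreeNode
    clone_label: pd.Series  # cell -> clone id
    genomes: dict[str, CellGenome]
    reference: str
    config: SimConfig

    @property
    def cells(self) -> list[str]:
        return list(self.clone_label.index)

    def true_variants(self) -> pd.DataFrame:
        """Long table of true per-cell variants with heteroplasmy in (0, 1]."""
        ref = self.reference
        rows = []
        for cell, g in self.genomes.items():
            for p, a, c in zip(g.pos, g.alt, g.count):
                rows.append((cell, int(p), ref[p - 1], BASES[a], c / g.n_copies))
        return pd.DataFrame(rows, columns=["cell", "pos", "ref", "alt", "het"])


# ---------------------------------------------------------------------------
# topology


class _Node:
    __slots__ = ("children", "name", "divisions")

    def __init__(self, divisions: int = 0, name: str | None = None):
        self.children: list[_Node] = []
        self.name = name
        self.divisions = divisions


def _yule_topology(n_leaves: int, rng: np.random.Generator) -> _Node:
    """Random bifurcating topology grown by uniform lineage splitting."""
    root = _Node(0)
    leaves = [root]
    while len(leaves) < n_leaves:
        i = int(rng.integers(len(leaves)))
        node = leaves[i]
        node.children = [_Node(1), _Node(1)]
        leaves[i] = node.children[0]
        leaves.append(node.children[1])
    return root


def _pad_to_depth(root: _Node, target: int) -> None:
    """Extend each terminal edge so every root-to-leaf path has ``target``
    divisions (paths already deeper than ``target`` are left as they are)."""
    stack = [(root, root.divisions)]
    while stack:
        node, depth = stack.pop()
        if not node.children:
            node.divisions += max(0, target - depth)
        else:
            for ch in node.children:
                stack.append((ch, depth + ch.divisions))


def _leaves(root: _Node) -> list[_Node]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        if node.children:
            stack.extend(reversed(node.children))
        else:
            out.append(node)
    return out


def _to_treenode(node: _Node) -> TreeNode:
    children = [_to_treenode(ch) for ch in node.children]
    return TreeNode(name=node.name, length=float(node.divisions), children=children or None)


def simulate_yule_tree(n_leaves: int, seed: int | np.random.Generator = 0) -> TreeNode:
    """Random neutral (Yule) cell tree with unit-division edges.

    Used as the null model when calibrating the coalescent expansion test.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = _yule_topology(n_leaves, rng)
    for i, leaf in enumerate(_leaves(root)):
        leaf.name = f"c{i:04d}"
    return _to_treenode(root)


# ---------------------------------------------------------------------------
# lineage + mutation accrual


def _divide(
    state: tuple[int, np.ndarray, np.ndarray, np.ndarray],
    mu: float,
    genome_length: int,
    ref_codes: np.ndarray,
    rng: np.random.Generator,
):
    """One cell division: replicate genomes, mutate new copies, partition.

    Returns the two daughter states; daughter totals sum to twice the parent
    copy number exactly.
    """
    n, pos, alt, cnt = state
    n2 = 2 * n
    cnt2 = 2 * cnt
    n_new = rng.poisson(mu * n)
    if n_new:
        new_pos = rng.integers(1, genome_length + 1, size=n_new)
        shift = rng.integers(1, 4, size=n_new)
        new_alt = ((ref_codes[new_pos - 1] + shift) % 4).astype(np.int8)
        pos = np.concatenate([pos, new_pos])
        alt = np.concatenate([alt, new_alt])
        cnt2 = np.concatenate([cnt2, np.ones(n_new, dtype=np.int64)])
    n_a = int(rng.binomial(n2, 0.5))
    if len(cnt2):
        c_a = rng.hypergeometric(cnt2, n2 - cnt2, n_a)
    else:
        c_a = cnt2
    c_b = cnt2 - c_a
    keep_a = c_a > 0
    keep_b = c_b > 0
    return (
        (n_a, pos[keep_a], alt[keep_a], c_a[keep_a]),
        (n2 - n_a, pos[keep_b], alt[keep_b], c_b[keep_b]),
    )


def _run_edge(state, k, mu, genome_length, ref_codes, rng):
    """Advance a lineage through ``k`` divisions, following one daughter
    (the sibling of each division is an unsampled lineage)."""
    for _ in range(k):
        state, _ = _divide(state, mu, genome_length, ref_codes, rng)
    return state


def _propagate_topology(root, init_state, mu, genome_length, ref_codes, rng, on_leaf):
    """Run the mutation/drift process over a division topology.

    Edge lengths are division counts; the first division of each child edge
    is the split at the parent, so sibling states at a split are the two
    complementary daughters of a single division.
    """
    state = _run_edge(init_state, root.divisions, mu, genome_length, ref_codes, rng)
    stack = [(root, state)]
    while stack:
        node, state = stack.pop()
        if node.children:
            a, b = node.children
            sa, sb = _divide(state, mu, genome_length, ref_codes, rng)
            stack.append((a, _run_edge(sa, a.divisions - 1, mu, genome_length, ref_codes, rng)))
            stack.append((b, _run_edge(sb, b.divisions - 1, mu, genome_length, ref_codes, rng)))
        else:
            on_leaf(node, state)


def simulate_lineage(config: SimConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Simulate the division tree and per-cell mtDNA mutation content.

    Clone founders sit at depth 0 of the within-clone trees; a common
    ancestral phase of ``founder_divisions`` divisions above the founders
    makes clones mutationally distinguishable while keeping the population
    polyclonal.  Deterministic given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51]))
    reference = synthetic_reference(config.genome_length)
    ref_codes = reference_array(reference)
    L = config.genome_length

    # ancestral phase: root -> clone founders
    founder_root = _yule_topology(config.n_clones, rng)
    _pad_to_depth(founder_root, config.founder_divisions)
    empty = (
        config.mt_copies,
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int8),
        np.empty(0, dtype=np.int64),
    )

    genomes: dict[str, CellGenome] = {}
    clone_of: dict[str, str] = {}

    founder_nodes: list[_Node] = []
    founder_states: list = []

    def _collect_founder(node, state):
        founder_nodes.append(node)
        founder_states.append(state)

    _propagate_topology(founder_root, empty, config.mu, L, ref_codes, rng,
                        _collect_founder)

    clone_sizes = config.clone_sizes()
    for ci, (fnode, fstate) in enumerate(zip(founder_nodes, founder_states)):
        clone = f"clone{ci:02d}"
        sub = _yule_topology(clone_sizes[ci], rng)
        _pad_to_depth(sub, config.divisions_per_cell)
        counter = [0]

        def _collect_cell(node, state, _ci=ci, _clone=clone, _counter=counter):
            cell = f"c{_ci:02d}_{_counter[0]:03d}"
            _counter[0] += 1
            node.name = cell
            n, pos, alt, cnt = state
            genomes[cell] = CellGenome(n, pos.copy(), alt.copy(), cnt.copy())
            clone_of[cell] = _clone

        if not sub.children:  # a clone sampled as a single cell
            sub.name = None
            state = _run_edge(fstate, sub.divisions, config.mu, L, ref_codes, rng)
            _collect_cell(fnode, state)
            fnode.divisions += sub.divisions
        else:
            # graft the within-clone topology under the founder's position
            fnode.children = sub.children
            _propagate_topology(sub, fstate, config.mu, L, ref_codes, rng,
                                _collect_cell)

    tree = _to_treenode(founder_root)
    clone_label = pd.Series(clone_of, name="clone")
    # order by tree tip order for reproducible downstream iteration
    tip_order = [t.name for t in tree.tips()]
    clone_label = clone_label.loc[tip_order]
    return TruthSet(tree=tree, clone_label=clone_label, genomes=genomes,
                    reference=reference, config=config)


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadTable:
    """Aligned mtDNA read records plus their reference mismatches.

    ``reads`` has one row per read: ``read_id, cell, start, end, mate,
    molecule`` (``molecule`` is the truth molecule index, -1 if unknown).
    ``mismatches`` is long-form: ``read_id, pos, alt`` with ``alt`` a base
    code.  Coordinates are 1-based inclusive and ``start <= end``.
    """

    reads: pd.DataFrame
    mismatches: pd.DataFrame
    genome_length: int = DEFAULT_GENOME_LENGTH
    #: optional molecule-level truth (molecule, pos, alt) for benchmarking
    molecule_truth: pd.DataFrame | None = None

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def to_tsv(self, path) -> None:
        """Write as TSV with mismatches encoded ``pos:base`` semicolon-joined."""
        mm = self.mismatches
        if len(mm):
            enc = mm.assign(tok=mm["pos"].astype(str) + ":" + mm["alt"].map(lambda a: BASES[a]))
            tokens = enc.groupby("read_id")["tok"].agg(";".join)
        else:
            tokens = pd.Series(dtype=str)
        out = self.reads.copy()
        out["mismatches"] = out["read_id"].map(tokens).fillna("")
        out["mate"] = out["mate"].map({0: "plus", 1: "minus"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome_length: int = DEFAULT_GENOME_LENGTH) -> "ReadTable":
        df = pd.read_csv(path, sep="\t", dtype={"mismatches": str}, keep_default_na=False)
        df["mate"] = df["mate"].map({"plus": 0, "minus": 1}).astype(np.int8)
        if "molecule" not in df:
            df["molecule"] = -1
        rows = []
        for rid, blob in zip(df["read_id"], df["mismatches"]):
            if blob:
                for tok in blob.split(";"):
                    p, b = tok.split(":")
                    rows.append((rid, int(p), BASES.index(b)))
        mm = pd.DataFrame(rows, columns=["read_id", "pos", "alt"])
        if len(mm):
            mm["alt"] = mm["alt"].astype(np.int8)
        bad = (df["start"] > df["end"]) | (df["start"] < 1) | (df["end"] > genome_length)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} reads have malformed coordinates")
        return cls(df.drop(columns=["mismatches"]), mm, genome_length)


def simulate_reads(truth: TruthSet, config: SimConfig | None = None,
                   rng: np.random.Generator | None = None) -> ReadTable:
    """Emit eUMI-structured reads for every cell of ``truth``.

    The number of captured fragments per cell is
    ``Poisson(mt_copies * capture_rate * genome_length /
    fragment_len_mean)``, each fragment drawn from a random genome copy of
    the cell, so the expected per-position coverage is ``mt_copies *
    capture_rate``.  Each fragment (molecule) yields one eUMI group of
    ``1 + Poisson(reads_per_eumi_mean - 1)`` reads; reads alternate between
    the plus and minus mate and span the whole fragment.  Per-base
    substitution errors are applied independently per read at
    ``seq_error_rate``.  Deterministic given the config seed.
    """
    config = config or truth.config
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x52]))
    L = config.genome_length
    ref_codes = reference_array(truth.reference)
    min_len = min(30, L)
    lam = config.capture_rate * L / config.fragment_len_mean  # fragments/copy

    cells_r, starts_r, ends_r, mates_r, mols_r = [], [], [], [], []
    mm_mol_rows, mm_pos, mm_alt = [], [], []
    mol_counter = 0

    for cell in truth.cells:
        g = truth.genomes[cell]
        m = int(rng.poisson(g.n_copies * lam))
        if m == 0:
            continue
        lens = np.clip(
            np.rint(rng.normal(config.fragment_len_mean, config.fragment_len_sd,
                               size=m)), min_len, L).astype(np.int64)
        starts = rng.integers(1, L - lens + 2)
        ends = starts + lens - 1
        sizes = 1 + rng.poisson(max(config.reads_per_eumi_mean - 1.0, 0.0), size=m)
        # each fragment originates from one genome copy; carrier copies of
        # mutation j are a random cyclic block of size count_j
        if len(g.pos):
            copy_of = rng.integers(0, g.n_copies, size=m)
            offsets = rng.integers(0, g.n_copies, size=len(g.pos))
            carrier = ((copy_of[None, :] + offsets[:, None]) % g.n_copies
                       < g.count[:, None])
            covered = (starts[None, :] <= g.pos[:, None]) & \
                      (g.pos[:, None] <= ends[None, :])
            jj, mi = np.nonzero(carrier & covered)
            if len(jj):
                mm_mol_rows.append(mol_counter + mi.astype(np.int64))
                mm_pos.append(g.pos[jj])
                mm_alt.append(g.alt[jj])
        n_reads = int(sizes.sum())
        cells_r.append(np.repeat(cell, n_reads))
        starts_r.append(np.repeat(starts, sizes).astype(np.int32))
        ends_r.append(np.repeat(ends, sizes).astype(np.int32))
        mols_r.append(np.repeat(np.arange(mol_counter, mol_counter + m), sizes))
        # alternate mates within each group
        offs = np.arange(n_reads) - np.repeat(np.cumsum(sizes) - sizes, sizes)
        mates_r.append((offs % 2).astype(np.int8))
        mol_counter += m

    if mol_counter == 0:
        reads = pd.DataFrame(columns=["read_id", "cell", "start", "end", "mate", "molecule"])
        return ReadTable(reads, pd.DataFrame(columns=["read_id", "pos", "alt"]), L,
                         pd.DataFrame(columns=["molecule", "pos", "alt"]))

    reads = pd.DataFrame({
        "cell": pd.Categorical(np.concatenate(cells_r)),
        "start": np.concatenate(starts_r),
        "end": np.concatenate(ends_r),
        "mate": np.concatenate(mates_r),
        "molecule": np.concatenate(mols_r),
    })
    reads.insert(0, "read_id", np.arange(len(reads), dtype=np.int64))

    # molecule mutations -> per-read mismatches
    mol_mm = pd.DataFrame({
        "molecule": (np.concatenate(mm_mol_rows) if mm_mol_rows
                     else np.empty(0, dtype=np.int64)),
        "pos": (np.concatenate(mm_pos) if mm_pos
                else np.empty(0, dtype=np.int64)).astype(np.int64),
        "alt": (np.concatenate(mm_alt) if mm_alt
                else np.empty(0, dtype=np.int8)).astype(np.int8),
    })
    read_mm = mol_mm.merge(reads[["read_id", "molecule"]], on="molecule")[
        ["read_id", "pos", "alt"]]

    # sequencing errors
    frag_len = (reads["end"] - reads["start"] + 1).to_numpy()
    n_err = rng.binomial(frag_len, config.seq_error_rate)
    err_reads = np.repeat(reads["read_id"].to_numpy(), n_err)
    err_off = rng.random(err_reads.size)
    err_start = np.repeat(reads["start"].to_numpy(), n_err)
    err_len = np.repeat(frag_len, n_err)
    err_pos = err_start + np.floor(err_off * err_len).astype(np.int64)
    err = pd.DataFrame({"read_id": err_reads, "pos": err_pos})
    err["shift"] = rng.integers(1, 4, size=len(err))
    err = err.drop_duplicates(["read_id", "pos"])

    merged = read_mm.merge(err, on=["read_id", "pos"], how="outer", indicator=True)
    ref_at = ref_codes[(merged["pos"].to_numpy(dtype=np.int64)) - 1]
    current = np.where(merged["_merge"] == "left_only", merged["alt"].fillna(0), ref_at)
    current = np.where(merged["_merge"] == "both", merged["alt"].fillna(0), current)
    shift = merged["shift"].fillna(0).to_numpy(dtype=np.int64)
    newbase = np.where(merged["_merge"] == "left_only",
                       merged["alt"].fillna(0).to_numpy(dtype=np.int64),
                       (current.astype(np.int64) + shift) % 4)
    keep = newbase != ref_at
    mismatches = pd.DataFrame({
        "read_id": merged.loc[keep, "read_id"].to_numpy(dtype=np.int64),
        "pos": merged.loc[keep, "pos"].to_numpy(dtype=np.int64),
        "alt": newbase[keep].astype(np.int8),
    }).sort_values(["read_id", "pos"], ignore_index=True)
    return ReadTable(reads, mismatches, L, mol_mm)


# ---------------------------------------------------------------------------
# cell states


def simulate_states(truth: TruthSet, config: SimConfig | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign cell-state labels: clone-biased lineages over timepoints.

    Per clone, lineage proportions are drawn once from a symmetric
    ``Dirichlet(bias_alpha)`` over the four haematopoietic lineages and
    reused at every timepoint; progeny cell types are drawn multinomially,
    stem cells are flagged with probability ``frac_hsc``.
    """
    from .clonal import LINEAGES, LINEAGE_TYPES

    config = config or truth.config
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x53]))
    clones = truth.clone_label.unique()
    props = {c: rng.dirichlet([config.bias_alpha] * len(LINEAGES)) for c in clones}

    rows = []
    for cell, clone in truth.clone_label.items():
        tp = int(rng.integers(1, config.n_timepoints + 1))
        if rng.random() < config.frac_hsc:
            rows.append((cell, clone, "HSC", "Stem", True, tp))
        else:
            lin = LINEAGES[int(rng.choice(len(LINEAGES), p=props[clone]))]
            ct = LINEAGE_TYPES[lin][int(rng.integers(len(LINEAGE_TYPES[lin])))]
            rows.append((cell, clone, ct, lin, False, tp))
    df = pd.DataFrame(rows, columns=["cell", "clone", "cell_type", "lineage",
                                     "is_hsc", "timepoint"]).set_index("cell")
    df.attrs["clone_lineage_props"] = {c: p.tolist() for c, p in props.items()}
    return df


def simulate_dataset(config: SimConfig) -> tuple[TruthSet, ReadTable, pd.DataFrame]:
    """Run the full generator: lineage, reads and states, seeded from
    ``config.seed`` via independent substreams."""
    truth = simulate_lineage(config)
    reads = simulate_reads(truth, config)
    states = simulate_states(truth, config)
    return truth, reads, states
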