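"""Phylogeny of an LTR subfamily: alignment, distances, NJ tree and clades.

The discovery step of the pipeline places every catalogued LTR on an
unrooted neighbor-joining tree built from Jukes-Cantor distances and cuts
the tree into a small number of clades whose mean divergence from the family
consensus summarises their age: recently amplified subfamilies sit close to
the consensus, older ones far from it.

Pairwise alignments use a Geneious-style parameterisation (65%-similarity
cost matrix realised as match +5 / mismatch -4, gap open 12, gap extend 3,
free end gaps).  The multiple alignment is a consensus-anchored star
alignment: every element is aligned pairwise to the consensus and the
pairwise alignments are merged on consensus coordinates.  This is a
deterministic stand-in for a progressive MSA and is adequate for
intra-family LTR alignment where indels are rare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .repeats import revcomp  # noqa: F401  (re-exported convenience)

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "PhyloTree",
    "CladePartition",
    "make_aligner",
    "pairwise_identity",
    "star_align_to_consensus",
    "p_distance",
    "p_to_consensus",
    "jukes_cantor",
    "neighbor_joining",
    "bootstrap_support",
    "partition_clades",
    "clade_divergence",
]


class SaturationError(ValueError):
    """p-distance at or beyond 0.75: Jukes-Cantor distance is undefined."""


class PartitionError(ValueError):
    """The requested number of clades cannot be cut from the tree."""


# ---------------------------------------------------------------------------
# pairwise alignment

def make_aligner(match: float = 5.0, mismatch: float = -4.0,
                 gap_open: float = 12.0, gap_extend: float = 3.0) -> Align.PairwiseAligner:
    """Global affine-gap aligner with free end gaps (Geneious-style scores)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _gapped_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _identity_from_rows(row_a: str, row_b: str) -> float:
    """Matches / aligned columns, excluding terminal-gap columns of either row."""
    n = len(row_a)
    # terminal gaps are the leading/trailing gap runs of either row
    lead_a = len(row_a) - len(row_a.lstrip("-"))
    lead_b = len(row_b) - len(row_b.lstrip("-"))
    tail_a = len(row_a) - len(row_a.rstrip("-"))
    tail_b = len(row_b) - len(row_b.rstrip("-"))
    first = max(lead_a, lead_b)
    last = n - max(tail_a, tail_b)
    if last <= first:
        return 0.0
    cols = 0
    matches = 0
    for c in range(first, last):
        cols += 1
        if row_a[c] == row_b[c] and row_a[c] != "-":
            matches += 1
    return matches / cols


def pairwise_identity(seq_a: str, seq_b: str,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction identical over the length of shared (aligned) sequence.

    Global affine-gap alignment; identity counts matches over all aligned
    columns except those inside a terminal gap of either sequence, so a
    shorter sequence fully contained in a longer one can still score 1.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = aligner or make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return _identity_from_rows(*_gapped_rows(aln))


# ---------------------------------------------------------------------------
# star alignment

@dataclass
class Alignment:
    """Gapped equal-length rows over {A,C,G,T,N,-} with an optional consensus row."""

    names: list[str]
    rows: list[str]
    consensus_row: str | None = None
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate names")
        lengths = {len(r) for r in self.rows}
        if self.consensus_row is not None:
            lengths.add(len(self.consensus_row))
        if len(lengths) > 1:
            raise ValueError("rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else (
            len(self.consensus_row) if self.consensus_row else 0)


def _align_to_consensus(consensus: str, seq: str, aligner) -> tuple[list[str], dict[int, str]]:
    """Return (per-consensus-position chars, insertions keyed by consensus index)."""
    aln = aligner.align(consensus, seq)[0]
    row_c, row_s = _gapped_rows(aln)
    chars: list[str] = []
    insertions: dict[int, str] = {}
    pos = 0  # next consensus position
    pending = ""
    for c_char, s_char in zip(row_c, row_s):
        if c_char == "-":
            if s_char != "-":
                pending += s_char
        else:
            if pending:
                insertions[pos] = pending
                pending = ""
            chars.append(s_char)
            pos += 1
    if pending:
        insertions[pos] = pending
    return chars, insertions


def star_align_to_consensus(
    elements: Mapping[str, str] | Sequence[tuple[str, str]],
    consensus: str,
    drop_threshold: float = 0.50,
    aligner: Align.PairwiseAligner | None = None,
) -> Alignment:
    """Consensus-anchored star alignment of elements.

    Each element is aligned pairwise to the consensus; columns are merged on
    consensus positions, with insertion columns (relative to the consensus)
    padded with gaps in all other rows.

    Elements that fail to align are excluded and listed in
    ``Alignment.dropped``.  The criterion is the alignment score normalised
    by the perfect-match score over the shorter sequence, below
    ``drop_threshold``: gapped *identity* cannot separate unalignable
    sequences here, because with affine gaps even uniform random DNA reaches
    ~0.53 identity against any consensus, while its normalised score stays
    near 0.1 (a family member at 13% divergence scores ~0.77).
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    items = list(elements.items()) if isinstance(elements, Mapping) else list(elements)
    aligner = aligner or make_aligner()
    consensus = consensus.upper()
    per_el: list[tuple[str, list[str], dict[int, str]]] = []
    dropped: list[str] = []
    for name, seq in items:
        aln = aligner.align(consensus, seq.upper())[0]
        norm = aln.score / (aligner.match_score * min(len(consensus), len(seq)))
        if norm < drop_threshold:
            dropped.append(name)
            continue
        chars, ins = _align_to_consensus(consensus, seq.upper(), aligner)
        per_el.append((name, chars, ins))
    L = len(consensus)
    ins_len = [0] * (L + 1)
    for _, _, ins in per_el:
        for k, s in ins.items():
            ins_len[k] = max(ins_len[k], len(s))
    names, rows = [], []
    for name, chars, ins in per_el:
        parts = []
        for j in range(L + 1):
            if ins_len[j]:
                s = ins.get(j, "")
                parts.append(s.ljust(ins_len[j], "-"))
            if j < L:
                parts.append(chars[j])
        names.append(name)
        rows.append("".join(parts))
    cparts = []
    for j in range(L + 1):
        if ins_len[j]:
            cparts.append("-" * ins_len[j])
        if j < L:
            cparts.append(consensus[j])
    return Alignment(names, rows, consensus_row="".join(cparts), dropped=dropped)


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    names: list[str]
    p: np.ndarray
    d: np.ndarray | None = None


def _pair_p(row_a: str, row_b: str) -> float:
    compared = 0
    mismatch = 0
    for a, b in zip(row_a, row_b):
        if a in "-N" or b in "-N":
            continue
        compared += 1
        if a != b:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable columns between rows")
    return mismatch / compared


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Observed proportion of differing sites; gap/N columns are skipped per pair."""
    n = len(alignment.rows)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = _pair_p(alignment.rows[i], alignment.rows[j])
    return DistanceMatrix(list(alignment.names), p)


def p_to_consensus(alignment: Alignment) -> dict[str, float]:
    """Per-element p-distance to the consensus row."""
    if alignment.consensus_row is None:
        raise ValueError("alignment has no consensus row")
    return {
        name: _pair_p(row, alignment.consensus_row)
        for name, row in zip(alignment.names, alignment.rows)
    }


def jukes_cantor(p, cap: float | None = None):
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p).

    Accepts a scalar or array.  ``p >= 0.75`` is saturated: raises
    :class:`SaturationError` unless ``cap`` is given, in which case saturated
    entries are set to ``cap``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("p must be >= 0")
    saturated = arr >= 0.75
    if saturated.any() and cap is None:
        raise SaturationError("p >= 0.75 has no finite Jukes-Cantor distance")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.75 * np.log1p(-4.0 * arr / 3.0)
    if cap is not None:
        d = np.where(saturated, cap, d)
    return float(d) if np.isscalar(p) else d


# ---------------------------------------------------------------------------
# trees

@dataclass
class PhyloTree:
    """Unrooted tree: integer nodes, adjacency with branch lengths.

    Leaves carry names in ``names``; ``supports`` maps leaf-set bipartitions
    (canonical frozenset, see :meth:`bipartitions`) to bootstrap fractions.
    """

    adj: dict[int, dict[int, float]]
    names: dict[int, str]
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def leaves(self) -> list[int]:
        return sorted(n for n in self.adj if n in self.names)

    @property
    def leaf_names(self) -> set[str]:
        return set(self.names.values())

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nbrs in self.adj.items():
            for v, w in nbrs.items():
                if u < v:
                    out.append((u, v, w))
        return out

    # -- metrics -----------------------------------------------------------
    def distance_matrix(self, order: Sequence[str] | None = None) -> DistanceMatrix:
        """Path-length matrix between leaves (additivity check oracle)."""
        order = list(order) if order is not None else sorted(self.leaf_names)
        by_name = {v: k for k, v in self.names.items()}
        n = len(order)
        D = np.zeros((n, n))
        for i, a in enumerate(order):
            # BFS accumulating path lengths
            dist = {by_name[a]: 0.0}
            stack = [by_name[a]]
            while stack:
                u = stack.pop()
                for v, w in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, b in enumerate(order):
                D[i, j] = dist[by_name[b]]
        return DistanceMatrix(order, D, D)

    def _side(self, u: int, v: int) -> set[str]:
        """Leaf names on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            x = stack.pop()
            if x in self.names:
                out.add(self.names[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out

    def bipartitions(self, collapse_tol: float = 1e-12) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions from internal edges.

        Internal edges with length <= ``collapse_tol`` are treated as
        collapsed (unresolved) and yield no bipartition.  Each bipartition is
        canonicalised as the side *not* containing the lexicographically
        smallest leaf name, so each split maps to one frozenset.
        """
        ref = min(self.leaf_names)
        parts = set()
        for u, v, w in self.edges():
            if u in self.names or v in self.names:
                continue
            if w <= collapse_tol:
                continue
            side = self._side(u, v)
            if ref in side:
                side = self.leaf_names - side
            if 1 < len(side) < len(self.leaf_names) - 1 or (
                    len(side) > 1 and len(self.leaf_names) - len(side) > 1):
                parts.add(frozenset(side))
        return parts

    # -- newick ------------------------------------------------------------
    def to_newick(self, include_supports: bool = True) -> str:
        internal = [n for n in self.adj if n not in self.names]
        root = internal[0] if internal else min(self.adj)
        ref = min(self.leaf_names) if self.leaf_names else ""

        def fmt(node: int, parent: int | None, blen: float | None) -> str:
            children = [v for v in self.adj[node] if v != parent]
            if node in self.names and not children:
                label = self.names[node]
            else:
                inner = ",".join(fmt(c, node, self.adj[node][c]) for c in sorted(children))
                label = f"({inner})"
                if include_supports and parent is not None and self.supports:
                    side = self._side(parent, node)
                    if ref in side:
                        side = self.leaf_names - side
                    sup = self.supports.get(frozenset(side))
                    if sup is not None:
                        label += f"{sup:g}"
            if blen is not None:
                label += f":{blen:.10g}"
            return label

        return fmt(root, None, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        text = text.strip().rstrip(";")
        adj: dict[int, dict[int, float]] = {}
        names: dict[int, str] = {}
        supports_raw: list[tuple[int, float]] = []
        counter = [0]

        def new_node() -> int:
            counter[0] += 1
            adj[counter[0]] = {}
            return counter[0]

        pos = [0]

        def parse() -> tuple[int, float | None]:
            node = None
            if text[pos[0]] == "(":
                pos[0] += 1
                node = new_node()
                while True:
                    child, blen = parse()
                    adj[node][child] = blen if blen is not None else 0.0
                    adj[child][node] = adj[node][child]
                    if text[pos[0]] == ",":
                        pos[0] += 1
                        continue
                    break
                assert text[pos[0]] == ")"
                pos[0] += 1
                # optional internal label = support
                label = _read_token(text, pos)
                if label:
                    try:
                        supports_raw.append((node, float(label)))
                    except ValueError:
                        pass
            else:
                node = new_node()
                names[node] = _read_token(text, pos)
            blen = None
            if pos[0] < len(text) and text[pos[0]] == ":":
                pos[0] += 1
                blen = float(_read_token(text, pos))
            return node, blen

        root, _ = parse()
        # suppress a degree-2 root introduced by rooting the newick string
        if len(adj[root]) == 2 and root not in names:
            (a, wa), (b, wb) = adj[root].items()
            del adj[a][root]
            del adj[b][root]
            del adj[root]
            adj[a][b] = wa + wb
            adj[b][a] = wa + wb
        tree = cls(adj, names)
        for node, sup in supports_raw:
            if node in tree.adj:
                nbrs = tree.adj[node]
                # reconstruct the bipartition this internal node subtends
                for parent in nbrs:
                    side = tree._side(parent, node)
                    if len(side) > 1 and len(tree.leaf_names - side) > 1:
                        ref = min(tree.leaf_names)
                        key = frozenset(tree.leaf_names - side if ref in side else side)
                        tree.supports.setdefault(key, sup)
        return tree


def _read_token(text: str, pos: list[int]) -> str:
    start = pos[0]
    while pos[0] < len(text) and text[pos[0]] not in ",():;":
        pos[0] += 1
    return text[start: pos[0]]


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on a distance matrix.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties are broken by the lexicographically smallest active index
    pair.  Negative branch lengths are clamped to zero.  The result is
    unrooted (final three lineages join at one internal node).
    """
    names = list(dm.names)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = np.array(dm.d if dm.d is not None else dm.p, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distances must be finite")
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_names = {i: names[i] for i in range(n)}
    active = list(range(n))
    node_of = {i: i for i in range(n)}  # active row index -> tree node
    next_node = n
    cur = D.copy()

    def connect(a: int, b: int, w: float) -> None:
        w = max(0.0, w)
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    while len(active) > 3:
        m = len(active)
        sub = cur[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, 1)
        qvals = Q[iu]
        k = int(np.argmin(qvals))  # first minimum in row-major upper triangle
        ai, aj = iu[0][k], iu[1][k]
        i, j = active[ai], active[aj]
        dij = cur[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        u = next_node
        next_node += 1
        connect(node_of[i], u, li)
        connect(node_of[j], u, lj)
        # distances from u to remaining
        newrow = 0.5 * (cur[i, :] + cur[j, :] - dij)
        cur = np.vstack([cur, newrow])
        cur = np.hstack([cur, np.append(newrow, 0.0)[:, None]])
        unew = cur.shape[0] - 1
        node_of[unew] = u
        active = [a for a in active if a not in (i, j)] + [unew]

    if len(active) == 2:
        i, j = active
        connect(node_of[i], node_of[j], cur[i, j])
    else:
        i, j, k = active
        u = next_node
        adj[u] = {}
        connect(node_of[i], u, 0.5 * (cur[i, j] + cur[i, k] - cur[j, k]))
        connect(node_of[j], u, 0.5 * (cur[i, j] + cur[j, k] - cur[i, k]))
        connect(node_of[k], u, 0.5 * (cur[i, k] + cur[j, k] - cur[i, j]))

    return PhyloTree(adj, leaf_names)


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    cap: float | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``replicates`` times; each
    replicate alignment is run through p-distance -> Jukes-Cantor -> NJ, and
    support of each internal bipartition of the full-data tree is the
    fraction of replicate trees containing it.  Zero-length internal edges
    are collapsed before counting, so an alignment of identical sequences
    yields no supported bipartitions.
    """
    rng = np.random.default_rng(seed)
    dm = p_distance(alignment)
    dm.d = jukes_cantor(dm.p, cap=cap)
    tree = neighbor_joining(dm)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    ncol = alignment.n_columns
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    mat = np.vstack(rows)
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        res = mat[:, cols]
        rep_aln = Alignment(list(alignment.names),
                            [b.tobytes().decode() for b in res])
        try:
            rdm = p_distance(rep_aln)
            rdm.d = jukes_cantor(rdm.p, cap=cap if cap is not None else 5.0)
            rtree = neighbor_joining(rdm)
        except (ValueError, SaturationError):
            continue
        for bp in rtree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    tree.supports = {bp: c / replicates for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# clades

@dataclass
class CladePartition:
    assignments: dict[str, str]  # element id -> clade label
    sizes: dict[str, int]
    mean_divergence: dict[str, float] | None = None  # percent, if provided


def partition_clades(
    tree: PhyloTree,
    k: int = 3,
    min_clade_size: int = 5,
    divergence: Mapping[str, float] | None = None,
) -> CladePartition:
    """Cut the tree into k clades at its longest internal edges.

    Greedily removes the longest internal edge whose removal leaves every
    resulting component with at least ``min_clade_size`` leaves, k-1 times.
    Components are labelled clade1..cladek by descending mean divergence
    (per-leaf values in ``divergence``, e.g. p-distance to consensus), so the
    most conserved clade receives the highest label; without divergences,
    labels are assigned by ascending component size.
    """
    leaves = tree.leaf_names
    if k < 1:
        raise ValueError("k must be >= 1")
    removed: set[frozenset[int]] = set()

    def components() -> list[set[str]]:
        seen: set[int] = set()
        comps = []
        for start in tree.adj:
            if start in seen:
                continue
            comp_nodes = [start]
            seen.add(start)
            stack = [start]
            names = set()
            while stack:
                u = stack.pop()
                if u in tree.names:
                    names.add(tree.names[u])
                for v in tree.adj[u]:
                    if v in seen or frozenset((u, v)) in removed:
                        continue
                    seen.add(v)
                    stack.append(v)
                    comp_nodes.append(v)
            comps.append(names)
        return comps

    internal = sorted(
        ((w, u, v) for u, v, w in tree.edges()
         if u not in tree.names and v not in tree.names),
        key=lambda t: -t[0],
    )
    cuts = 0
    while cuts < k - 1:
        progressed = False
        for w, u, v in internal:
            e = frozenset((u, v))
            if e in removed:
                continue
            removed.add(e)
            comps = [c for c in components() if c]
            if all(len(c) >= min_clade_size for c in comps):
                cuts += 1
                progressed = True
                break
            removed.discard(e)
        if not progressed:
            raise PartitionError(
                f"cannot cut {k} clades with min size {min_clade_size}")
    comps = [c for c in components() if c]
    if len(comps) != k:
        raise PartitionError(f"expected {k} components, got {len(comps)}")
    if divergence is not None:
        comps.sort(key=lambda c: -float(np.mean([divergence[x] for x in c])))
    else:
        comps.sort(key=len)
    assignments = {}
    sizes = {}
    meandiv = {} if divergence is not None else None
    for idx, comp in enumerate(comps, start=1):
        label = f"clade{idx}"
        sizes[label] = len(comp)
        for name in comp:
            assignments[name] = label
        if meandiv is not None:
            meandiv[label] = float(np.mean([divergence[x] for x in comp]))
    assert set(assignments) == leaves
    return CladePartition(assignments, sizes, meandiv)


def clade_divergence(alignment: Alignment, partition: CladePartition) -> dict[str, float]:
    """Mean p-distance (%) of each clade's members to the consensus row."""
    pcons = p_to_consensus(alignment)
    out: dict[str, list[float]] = {}
    for name, label in partition.assignments.items():
        out.setdefault(label, []).append(pcons[name])
    return {label: 100.0 * float(np.mean(v)) for label, v in sorted(out.items())}
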