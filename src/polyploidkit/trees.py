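"""Alignment and distance-tree machinery for anchor-gene phylogenies.

Protein alignments are delegated to MAFFT (the standard multiple aligner);
trimming uses an explicit maximum-gap-fraction rule; protein alignments are
back-translated to codon alignments; trees are neighbor-joining on
Jukes-Cantor distances with optional nonparametric bootstrap, plus an
exhaustive quartet-score species-tree search (a small-n stand-in for
coalescence summary methods) for up to eight taxa.

Neighbor joining is consistent on additive distances, so on simulated
(clock-like, indel-free) data it recovers the generating topology exactly;
the module boundary lets a likelihood engine drop in for real data.
"""
from __future__ import annotations

import itertools
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _seq

__all__ = [
    "MultipleAlignment",
    "align_progressive",
    "trim_columns",
    "backtranslate",
    "jc_distance_matrix",
    "nj_tree",
    "root_on_outgroup",
    "bootstrap_support",
    "concat_alignment",
    "quartet_species_tree",
    "tree_splits",
]

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXU*")
_NUC_ALPHABET = set("ACGTUN")


@dataclass
class MultipleAlignment:
    """Ordered taxa with equal-length aligned rows."""

    taxa: list
    rows: list
    alphabet: str = "protein"  # "protein" | "dna" | "codon"

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.alphabet == "codon" and self.n_columns % 3:
            raise ValueError("codon alignment length not divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def align_progressive(seqs, alphabet: str = "protein") -> MultipleAlignment:
    """Multiple alignment of protein (or nucleotide) sequences via MAFFT.

    ``seqs`` is a list of (name, sequence) pairs or a dict.  All residues are
    preserved (MAFFT inserts gaps only).  Sequences with characters outside
    the alphabet raise a ValueError naming the offending id.
    """
    if isinstance(seqs, dict):
        seqs = list(seqs.items())
    if len(seqs) < 2:
        raise ValueError("need at least two sequences to align")
    allowed = _PROTEIN_ALPHABET if alphabet == "protein" else _NUC_ALPHABET
    for name, s in seqs:
        bad = set(s.upper()) - allowed
        if bad:
            raise ValueError(f"illegal characters {sorted(bad)} in sequence {name}")
    if shutil.which("mafft") is None:  # pragma: no cover - environment guard
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fa"
        with open(infile, "w") as fh:
            for i, (name, s) in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--auto", "--anysymbol", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows = {}
    current = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            rows[current] = []
        elif current is not None:
            rows[current].append(line.strip())
    aligned = ["".join(rows[f"s{i}"]).upper() for i in range(len(seqs))]
    return MultipleAlignment([name for name, _ in seqs], aligned, alphabet)


def trim_columns(aln: MultipleAlignment, max_gap_fraction: float = 0.2) -> MultipleAlignment:
    """Keep exactly the columns whose gap fraction is <= ``max_gap_fraction``.

    Codon alignments are trimmed in whole-codon units.  Raises if no column
    survives (the threshold should then be relaxed).
    """
    unit = 3 if aln.alphabet == "codon" else 1
    n = len(aln.rows)
    keep = []
    for c in range(0, aln.n_columns, unit):
        gaps = sum(1 for r in aln.rows if "-" in r[c : c + unit])
        if gaps / n <= max_gap_fraction:
            keep.append(c)
    if not keep:
        raise ValueError(
            "all columns removed by trimming; raise max_gap_fraction"
        )
    rows = ["".join(r[c : c + unit] for c in keep) for r in aln.rows]
    return MultipleAlignment(list(aln.taxa), rows, aln.alphabet)


def backtranslate(protein_aln: MultipleAlignment, cds_map: dict) -> MultipleAlignment:
    """Convert a protein alignment to a codon alignment using source CDSs.

    Each CDS must translate exactly to its ungapped protein row; a mismatch
    raises with the offending residue position.  Protein gaps become ``---``.
    """
    rows = []
    for taxon, prow in zip(protein_aln.taxa, protein_aln.rows):
        cds = cds_map[taxon]
        prot = _seq.translate(cds)
        ungapped = prow.replace("-", "")
        if prot != ungapped:
            for i, (x, y) in enumerate(zip(prot, ungapped)):
                if x != y:
                    raise ValueError(
                        f"CDS for {taxon} translates to {x!r} at residue {i}, "
                        f"alignment row has {y!r}"
                    )
            raise ValueError(
                f"CDS length mismatch for {taxon}: {len(prot)} vs {len(ungapped)} residues"
            )
        out = []
        pos = 0
        for ch in prow:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * pos : 3 * pos + 3])
                pos += 1
        rows.append("".join(out))
    return MultipleAlignment(list(protein_aln.taxa), rows, "codon")


def jc_distance_matrix(aln: MultipleAlignment, cap: float = 5.0):
    """Pairwise Jukes-Cantor distances over shared ungapped nucleotide sites.

    Returns ``(taxa, matrix)``.  Saturated pairs (p >= 0.75) get distance
    ``cap`` with a warning.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least two rows")
    if aln.alphabet == "protein":
        raise ValueError("JC distances require nucleotide or codon alignments")
    n = len(aln.rows)
    codes = [(_seq.encode(r)) for r in aln.rows]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] <= 3) & (codes[j] <= 3)
            m = int(ok.sum())
            p = float((codes[i][ok] != codes[j][ok]).sum()) / m if m else 0.0
            if p >= 0.75:
                warnings.warn(
                    f"saturated pair ({aln.taxa[i]}, {aln.taxa[j]}): p={p:.3f}; "
                    f"distance capped at {cap}"
                )
                d = cap
            else:
                d = _seq.jc_correct(p, cap=cap)
            D[i, j] = D[j, i] = d
    return list(aln.taxa), D


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def nj_tree(taxa, dist) -> str:
    """Neighbor-joining tree (unrooted newick with branch lengths).

    Deterministic: Q-criterion ties join the lowest-index pair first.
    Negative branch-length estimates are clamped to zero.
    """
    D = np.array(dist, dtype=float)
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least three taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes = [f"{t}" for t in taxa]
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        newick = f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})"
        # new node reuses slot i
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k not in (i, j):
                new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D[i, :] = new_row
        D[:, i] = new_row
        nodes[i] = newick
        active.remove(j)
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    return f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f},{nodes[k]}:{lk:.6f});"


def _parse_newick(s: str):
    """Minimal newick parser -> nested (children tuples / leaf labels)."""
    s = s.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse()]
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            if s[pos] != ")":
                raise ValueError(f"bad newick near position {pos}")
            pos += 1
            label = _read_label()
            return tuple(children)
        label = _read_label()
        return label[0]

    def _read_label():
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        name = s[start:pos]
        if pos < len(s) and s[pos] == ":":  # skip the branch length
            pos += 1
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
        return (name,)

    return parse()


def newick_topology(s: str):
    """Parse a newick string into a nested tuple of leaf labels (no lengths)."""
    return _parse_newick(s)


def _leaves(node):
    if not isinstance(node, tuple):
        return [node]
    out = []
    for c in node:
        out.extend(_leaves(c))
    return out


def tree_splits(newick: str, taxa=None) -> set:
    """Nontrivial unrooted splits of a tree, as canonical frozensets.

    Each split is the side not containing the alphabetically first taxon.
    """
    tree = newick_topology(newick)
    all_taxa = sorted(_leaves(tree)) if taxa is None else sorted(taxa)
    ref = all_taxa[0]
    full = set(all_taxa)
    splits = set()

    def recurse(node):
        if not isinstance(node, tuple):
            return {node}
        leafset = set()
        for c in node:
            leafset |= recurse(c)
        if 2 <= len(leafset) <= len(full) - 2:
            side = leafset if ref not in leafset else full - leafset
            splits.add(frozenset(side))
        return leafset

    recurse(tree)
    return splits


def root_on_outgroup(newick: str, outgroup: str):
    """Root an unrooted tree on the edge leading to the outgroup tip.

    Returns a nested tuple ``(outgroup, ingroup_subtree)`` (topology only):
    the tree is re-hung from the internal node to which the outgroup
    attaches, so deep placements re-orient correctly.
    """
    tree = newick_topology(newick)
    if outgroup not in _leaves(tree):
        raise ValueError(f"outgroup {outgroup!r} not among tips")
    adj = {}
    counter = itertools.count()

    def build(node):
        if not isinstance(node, tuple):
            adj.setdefault(node, [])
            return node
        nid = next(counter)
        adj.setdefault(nid, [])
        for c in node:
            cid = build(c)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    build(tree)

    def grow(node, parent):
        if isinstance(node, str):
            return node
        kids = [grow(x, node) for x in adj[node] if x != parent]
        if len(kids) == 1:
            return kids[0]
        return tuple(kids)

    anchor = adj[outgroup][0]
    return (outgroup, grow(anchor, outgroup))


def bootstrap_support(aln: MultipleAlignment, n_replicates: int, seed: int, cap: float = 5.0):
    """NJ tree with split supports from column-resampling bootstrap.

    Columns (codons, for codon alignments) are resampled with replacement;
    support of each split of the full-data tree is the percentage of
    replicates whose tree contains that split.  Returns ``(newick,
    supports)`` where supports maps canonical splits to percentages in
    [0, 100]; with ``n_replicates=0`` supports is None.
    """
    if aln.n_columns < 1:
        raise ValueError("empty alignment")
    taxa, D = jc_distance_matrix(aln, cap=cap)
    base = nj_tree(taxa, D)
    if n_replicates == 0:
        return base, None
    base_splits = tree_splits(base, taxa)
    unit = 3 if aln.alphabet == "codon" else 1
    n_units = aln.n_columns // unit
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    counts = {s: 0 for s in base_splits}
    for _ in range(n_replicates):
        pick = rng.integers(0, n_units, n_units)
        rows = [
            "".join(r[unit * p : unit * p + unit] for p in pick) for r in aln.rows
        ]
        rep = MultipleAlignment(list(aln.taxa), rows, aln.alphabet)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t2, D2 = jc_distance_matrix(rep, cap=cap)
        rep_splits = tree_splits(nj_tree(t2, D2), taxa)
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return base, supports


def concat_alignment(alns: dict) -> tuple:
    """Concatenate alignments sharing one taxon set; returns (aln, partitions).

    ``alns`` maps partition name -> MultipleAlignment.  Raises listing the
    missing taxa if the sets differ.  Partitions are (name, start, end)
    0-based half-open column ranges.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    names = sorted(alns)
    first = alns[names[0]]
    taxa = sorted(first.taxa)
    for name in names:
        missing = set(taxa) ^ set(alns[name].taxa)
        if missing:
            raise ValueError(
                f"taxon set mismatch in partition {name}: {sorted(missing)}"
            )
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for name in names:
        a = alns[name]
        for t in taxa:
            rows[t].append(a.row(t))
        partitions.append((name, pos, pos + a.n_columns))
        pos += a.n_columns
    out = MultipleAlignment(taxa, ["".join(rows[t]) for t in taxa], first.alphabet)
    return out, partitions


# ----------------------------------------------------------------------
# exhaustive quartet-score species tree
# ----------------------------------------------------------------------

def _rooted_topologies(leaves):
    if len(leaves) == 1:
        yield leaves[0]
        return
    for t in _rooted_topologies(leaves[:-1]):
        yield from _insert_leaf(t, leaves[-1])


def _insert_leaf(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        a, b = t
        for na in _insert_leaf(a, x):
            yield (na, b)
        for nb in _insert_leaf(b, x):
            yield (a, nb)


def _subtree_masks(node, index, out):
    if not isinstance(node, tuple):
        return 1 << index[node]
    mask = 0
    for c in node:
        mask |= _subtree_masks(c, index, out)
    out.append(mask)
    return mask


def _quartet_resolution(splits, q):
    """0 if q[0] pairs with q[1], 1 with q[2], 2 with q[3]; None unresolved."""
    qa, qb, qc, qd = q
    qmask = (1 << qa) | (1 << qb) | (1 << qc) | (1 << qd)
    for m in splits:
        inter = m & qmask
        n = bin(inter).count("1")
        if n == 2:
            side = inter if (inter >> qa) & 1 else qmask & ~inter
            if (side >> qb) & 1:
                return 0
            if (side >> qc) & 1:
                return 1
            return 2
    return None


def _canonical_newick(node, index_to_name=None):
    if not isinstance(node, tuple):
        return str(node) if index_to_name is None else index_to_name[node]
    parts = sorted(_canonical_newick(c, index_to_name) for c in node)
    return "(" + ",".join(parts) + ")"


def quartet_species_tree(gene_trees, taxa=None, max_taxa: int = 8):
    """Species topology maximizing shared quartets with the gene trees.

    Performs an exhaustive search over all unrooted binary topologies (hence
    the ``max_taxa`` bound) and returns ``(newick, score, max_score)`` where
    ``max_score`` is ``n_trees * C(n, 4)``.  Gene trees are newick strings
    over the same taxon set.  Ties break to the lexicographically smallest
    canonical newick.
    """
    if not gene_trees:
        raise ValueError("no gene trees")
    if taxa is None:
        taxa = sorted(_leaves(newick_topology(gene_trees[0])))
    taxa = sorted(taxa)
    n = len(taxa)
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds the exhaustive-search bound ({max_taxa}); subsample"
        )
    index = {t: i for i, t in enumerate(taxa)}
    quartets = list(itertools.combinations(range(n), 4))
    counts = {q: [0, 0, 0] for q in quartets}
    for nwk in gene_trees:
        tree = newick_topology(nwk)
        if sorted(_leaves(tree)) != taxa:
            raise ValueError("gene tree taxa do not match the taxon set")
        masks = []
        _subtree_masks(tree, index, masks)
        for q in quartets:
            r = _quartet_resolution(masks, q)
            if r is not None:
                counts[q][r] += 1
    best = None
    self_index = {i: i for i in range(n)}
    for t in _rooted_topologies(list(range(1, n))):
        full = (0, t)
        masks = []
        _subtree_masks(full, self_index, masks)
        score = 0
        for q in quartets:
            r = _quartet_resolution(masks, q)
            if r is not None:
                score += counts[q][r]
        key = _canonical_newick(full, {i: t_ for t_, i in index.items()})
        if best is None or score > best[0] or (score == best[0] and key < best[1]):
            best = (score, key)
    max_score = len(gene_trees) * len(quartets)
    return best[1] + ";", best[0], max_score
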