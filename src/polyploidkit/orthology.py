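"""Orthogroup inference, collinear-block chaining and anchor-group extraction.

Orthogroups come from reciprocal-best-hit protein similarity (BLOSUM62 affine
local alignment with a shared-peptide prefilter) followed by single-linkage
clustering across genomes.  Collinear blocks are maximal-scoring chains of
homologous gene pairs under a dynamic-programming recurrence over gene-order
ranks (both orientations).  Anchor groups are syntenically connected gene sets
present at an exact per-genome copy ratio (1:2:4 for a
diploid : tetraploid : octoploid trio), the unit on which gene-tree topology
censuses are built.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from . import _seq

__all__ = [
    "GeneModel",
    "CollinearBlock",
    "AnchorGroup",
    "gene_models_from_simulation",
    "build_orthogroups",
    "homolog_pairs",
    "chain_collinear_blocks",
    "extract_anchor_groups",
    "find_single_copy_genes",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genome, position and gene-order rank on its chromosome."""

    id: str
    genome: str
    chrom: str
    rank: int      # 0-based gene-order index along the chromosome
    start: int     # 0-based half-open genomic coordinates
    end: int
    cds: str

    @property
    def protein(self) -> str:
        return _seq.translate(self.cds)


@dataclass
class CollinearBlock:
    genomes: tuple          # (genome_a, genome_b)
    chroms: tuple           # (chrom_a, chrom_b)
    pairs: list             # [(gene_id_a, gene_id_b)] in chain order
    score: float
    orientation: str        # "same" | "inverted"

    def __len__(self):
        return len(self.pairs)


@dataclass
class AnchorGroup:
    """Syntenically connected genes at an exact per-genome copy ratio."""

    genes: dict             # genome -> sorted list of gene ids
    chroms: dict            # genome -> sorted tuple of chromosomes
    blocks: list = field(default_factory=list)  # indices of supporting blocks

    def all_ids(self) -> list:
        return [g for ids in self.genes.values() for g in ids]

    @property
    def chrom_key(self) -> tuple:
        return tuple(
            (genome, self.chroms[genome]) for genome in sorted(self.chroms)
        )


def gene_models_from_simulation(result) -> list:
    """GeneModels (with ranks) from a :class:`~polyploidkit.simulate.SimulationResult`."""
    by_chrom = {}
    for a in result.annotations:
        by_chrom.setdefault((a.genome, a.chrom), []).append(a)
    out = []
    for (genome, chrom), anns in sorted(by_chrom.items()):
        anns.sort(key=lambda a: a.start)
        for rank, a in enumerate(anns):
            out.append(
                GeneModel(a.gene_id, genome, chrom, rank, a.start, a.end, result.cds(a))
            )
    return out


# ----------------------------------------------------------------------
# orthogroups
# ----------------------------------------------------------------------

def _peptide_index(proteins: dict, word: int = 5):
    """Inverted index of peptide words -> gene ids (the prefilter)."""
    index = {}
    for gid, prot in proteins.items():
        for i in range(len(prot) - word + 1):
            index.setdefault(prot[i : i + word], set()).add(gid)
    return index


def _candidate_pairs(proteins, genome_of, word=5, min_shared=2):
    """Cross-genome gene pairs sharing at least ``min_shared`` peptide words."""
    index = _peptide_index(proteins, word)
    shared = {}
    for gids in index.values():
        gids = sorted(gids)
        for i, a in enumerate(gids):
            for b in gids[i + 1 :]:
                if genome_of[a] != genome_of[b]:
                    key = (a, b)
                    shared[key] = shared.get(key, 0) + 1
    return [pair for pair, n in shared.items() if n >= min_shared]


def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


def build_orthogroups(
    genes: Iterable,
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
) -> list:
    """Partition genes into orthogroups via reciprocal protein similarity.

    Two genes end up in the same group iff they are connected in the
    reciprocal-hit graph: an edge joins a cross-genome pair whose local
    BLOSUM62 alignment passes both identity and coverage thresholds (the
    score is symmetric, so a passing hit is reciprocal by construction);
    groups are the connected components (single linkage).  A best-hit-only
    rule would orphan the extra paralogs of a polyploid, which is exactly
    what the 1:2:4 anchor ratio needs preserved.  Genes whose CDS cannot be
    translated are skipped with a warning.  Returns a sorted list of sets of
    gene ids (singletons included).
    """
    genes = list(genes)
    genomes = {g.genome for g in genes}
    if len(genomes) < 2 and genes:
        raise ValueError("need genes from at least two genomes")
    proteins, genome_of = {}, {}
    for g in genes:
        try:
            proteins[g.id] = g.protein
        except ValueError as exc:
            warnings.warn(f"skipping untranslatable CDS for {g.id}: {exc}")
            continue
        genome_of[g.id] = g.genome
    aligner = _make_aligner()
    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    for a, b in _candidate_pairs(proteins, genome_of):
        try:
            aln = aligner.align(proteins[a], proteins[b])[0]
        except (IndexError, ValueError):
            continue
        counts = aln.counts()
        ident, mism = counts.identities, counts.mismatches
        cols = ident + mism
        if cols == 0:
            continue
        identity = ident / cols
        coverage = cols / min(len(proteins[a]), len(proteins[b]))
        if identity >= min_identity and coverage >= min_coverage:
            graph.add_edge(a, b)
    groups = [set(c) for c in nx.connected_components(graph)]
    return sorted(groups, key=lambda s: sorted(s)[0])


def find_single_copy_genes(orthogroups, genes, genome_set=None) -> list:
    """Orthogroups with exactly one member in every named genome.

    Returns a list of dicts mapping genome -> gene id.
    """
    genome_of = {g.id: g.genome for g in genes}
    if genome_set is None:
        genome_set = sorted(set(genome_of.values()))
    genome_set = set(genome_set)
    out = []
    for group in orthogroups:
        counts = {}
        for gid in group:
            counts.setdefault(genome_of[gid], []).append(gid)
        if set(counts) == genome_set and all(len(v) == 1 for v in counts.values()):
            out.append({genome: ids[0] for genome, ids in counts.items()})
    return out


# ----------------------------------------------------------------------
# collinear blocks
# ----------------------------------------------------------------------

def homolog_pairs(orthogroups, genes, genome_a: str, genome_b: str, collapse_tandems: bool = True):
    """All cross pairs (GeneModel, GeneModel) between two genomes per orthogroup.

    Runs of same-orthogroup neighbors (rank distance <= 2) on one chromosome
    are collapsed to their first representative before pairing, so tandem
    duplicates do not inflate copy ratios.
    """
    by_id = {g.id: g for g in genes}
    group_of = {}
    for gi, group in enumerate(orthogroups):
        for gid in group:
            group_of[gid] = gi
    kept = set(by_id)
    if collapse_tandems:
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault((g.genome, g.chrom), []).append(g)
        for members in by_chrom.values():
            members.sort(key=lambda g: g.rank)
            for prev, cur in zip(members, members[1:]):
                if (
                    group_of.get(prev.id) is not None
                    and group_of.get(prev.id) == group_of.get(cur.id)
                    and cur.rank - prev.rank <= 2
                    and prev.id in kept
                ):
                    kept.discard(cur.id)
    pairs = []
    for group in orthogroups:
        left = sorted(g for g in group if g in kept and by_id[g].genome == genome_a)
        right = sorted(g for g in group if g in kept and by_id[g].genome == genome_b)
        for a in left:
            for b in right:
                pairs.append((by_id[a], by_id[b]))
    return pairs


def chain_collinear_blocks(
    pairs,
    match_score: float = 50.0,
    gap_penalty: float = 1.0,
    max_gap_genes: int = 25,
    min_block_genes: int = 5,
) -> list:
    """Chain homologous gene pairs into collinear blocks by dynamic programming.

    Within each chromosome pair, ``score(i) = match + max_j(score(j) -
    gap_penalty * rank gaps)`` over admissible predecessors j (ranks strictly
    monotone on both sides, per-side rank gap <= ``max_gap_genes``).  Both
    orientations are searched; blocks are extracted best-first without reusing
    pairs, and chains shorter than ``min_block_genes`` are discarded.  Ties
    break toward the lexicographically smallest block for determinism.
    """
    by_cc = {}
    for a, b in pairs:
        by_cc.setdefault(((a.genome, b.genome), (a.chrom, b.chrom)), []).append((a, b))
    blocks = []
    for (genomes, chroms), items in sorted(by_cc.items()):
        items = sorted(items, key=lambda ab: (ab[0].rank, ab[1].rank, ab[0].id, ab[1].id))
        used = [False] * len(items)
        while True:
            cand = []
            for orientation in ("same", "inverted"):
                chain = _best_chain(
                    items, used, orientation, match_score, gap_penalty, max_gap_genes
                )
                if chain is not None:
                    cand.append((chain[0], orientation, chain[1]))
            cand = [c for c in cand if len(c[2]) >= min_block_genes]
            if not cand:
                break
            cand.sort(
                key=lambda c: (-c[0], c[1] != "same", [items[i][0].id for i in c[2]])
            )
            score, orientation, idxs = cand[0]
            for i in idxs:
                used[i] = True
            blocks.append(
                CollinearBlock(
                    genomes=genomes,
                    chroms=chroms,
                    pairs=[(items[i][0].id, items[i][1].id) for i in idxs],
                    score=score,
                    orientation=orientation,
                )
            )
    blocks.sort(key=lambda b: (b.genomes, b.chroms, b.pairs[0]))
    return blocks


def _best_chain(items, used, orientation, match_score, gap_penalty, max_gap):
    """Best-scoring monotone chain over unused pairs; None if no pair is free."""
    idx = [i for i in range(len(items)) if not used[i]]
    if not idx:
        return None
    sign = 1 if orientation == "same" else -1
    ra = [items[i][0].rank for i in idx]
    rb = [sign * items[i][1].rank for i in idx]
    order = sorted(range(len(idx)), key=lambda j: (ra[j], rb[j]))
    score = [match_score] * len(idx)
    back = [-1] * len(idx)
    for oi, j in enumerate(order):
        for pk in order[:oi]:
            if ra[pk] >= ra[j] or rb[pk] >= rb[j]:
                continue
            ga = ra[j] - ra[pk] - 1
            gb = rb[j] - rb[pk] - 1
            if ga > max_gap or gb > max_gap:
                continue
            s = score[pk] + match_score - gap_penalty * (ga + gb)
            if s > score[j] + 1e-12:
                score[j] = s
                back[j] = pk
    bestj = max(range(len(idx)), key=lambda j: (score[j], -ra[j]))
    chain = []
    j = bestj
    while j != -1:
        chain.append(idx[j])
        j = back[j]
    chain.reverse()
    return score[bestj], chain


# ----------------------------------------------------------------------
# anchor groups
# ----------------------------------------------------------------------

def extract_anchor_groups(blocks, genes, ratio: dict) -> list:
    """Groups of syntenically connected genes at an exact per-genome ratio.

    ``ratio`` maps genome name to required copy count, e.g. ``{"outgroup": 1,
    "tetraploid": 2, "octoploid": 4}``.  Genes are connected by membership in
    collinear-block gene pairs; each connected component that matches the
    ratio exactly becomes an :class:`AnchorGroup`.  Components with missing or
    surplus copies are excluded, and no gene appears in two groups.
    """
    by_id = {g.id: g for g in genes}
    unknown = set(ratio) - {g.genome for g in genes}
    if unknown:
        raise ValueError(f"ratio names unknown genomes: {sorted(unknown)}")
    graph = nx.Graph()
    block_of_edge = {}
    for bi, block in enumerate(blocks):
        for a, b in block.pairs:
            graph.add_edge(a, b)
            block_of_edge.setdefault((a, b), bi)
    groups = []
    for comp in nx.connected_components(graph):
        counts = {}
        for gid in comp:
            counts.setdefault(by_id[gid].genome, []).append(gid)
        if {g: len(v) for g, v in counts.items()} != dict(ratio):
            continue
        chroms = {
            genome: tuple(sorted({by_id[g].chrom for g in ids}))
            for genome, ids in counts.items()
        }
        bidx = sorted(
            {
                bi
                for (a, b), bi in block_of_edge.items()
                if a in comp and b in comp
            }
        )
        groups.append(
            AnchorGroup(
                genes={g: sorted(v) for g, v in counts.items()},
                chroms=chroms,
                blocks=bidx,
            )
        )
    groups.sort(key=lambda g: min(g.all_ids()))
    return groups
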