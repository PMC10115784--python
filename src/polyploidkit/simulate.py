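"""Synthetic reticulate-polyploid genome simulator with full ground truth.

The simulator emulates the study system behind subgenome-phasing analyses: a
diploid outgroup, four diverged diploid progenitor lineages (A, B, C, D), two
allotetraploidization events (A x C -> AC, B x D -> BD) and one
allooctoploidization (AC x BD), with per-subgenome bursts of repeats and LTR
retrotransposons during each progenitor's divergence-hybridization window,
optional homoeologous exchanges, and gene families planted at an exact 1:2:4
copy ratio across outgroup : tetraploid : octoploid.

Sequences evolve under Jukes-Cantor with a uniform clock (substitutions per
site per million years), so divergence between any two copies is a monotone,
closed-form function of their true split time.  Everything is deterministic
given the scenario seed.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive; all features are on the "+" strand.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _seq

__all__ = [
    "Hybridization",
    "Exchange",
    "RepeatProfile",
    "LtrProfile",
    "ScenarioSpec",
    "ScenarioError",
    "SimulationResult",
    "TruthTable",
    "GeneAnnotation",
    "SimRead",
    "reticulate_scenario",
    "autopolyploid_scenario",
    "simulate_scenario",
    "simulate_reads",
    "write_fasta",
    "write_gff3",
    "write_fastq",
    "write_truth_tables",
]


class ScenarioError(ValueError):
    """A scenario failed validation; the message names the offending item."""


class Hybridization(NamedTuple):
    parent1: str
    parent2: str
    child: str
    time: float  # MY before present


class Exchange(NamedTuple):
    donor: str       # donor subgenome label
    recipient: str   # recipient subgenome label
    chrom_index: int  # homologous chromosome group (0-based)
    start: int       # backbone coordinates, 0-based half-open
    end: int
    time: float      # MY before present
    genome: str = "octoploid"


@dataclass(frozen=True)
class RepeatProfile:
    """Per-subgenome repeat library: one motif, burst-inserted in the window."""

    motif_length: int = 400
    burst_rate: float = 25.0  # insertions / chromosome / MY inside the window


@dataclass(frozen=True)
class LtrProfile:
    """LTR retrotransposon insertions: LTR + internal + identical LTR at birth."""

    rate: float = 10.0  # insertions / chromosome / MY inside the window
    ltr_length: int = 300
    internal_length: int = 600


#: default lineage tree: (((A,B),C) ; (D,outgroup)) with ages in MY
_DEFAULT_LINEAGE = (7.3, (6.0, (5.0, "A", "B"), "C"), (6.5, "D", "outgroup"))

_DEFAULT_HYBRIDIZATIONS = (
    Hybridization("A", "C", "AC", 0.5),
    Hybridization("B", "D", "BD", 0.91),
    Hybridization("AC", "BD", "ACBD", 0.44),
)

_DEFAULT_SAMPLED = {"outgroup": "outgroup", "tetraploid": "AC", "octoploid": "ACBD"}

#: default LTR/repeat activity windows (young, old) in MY, per subgenome
_DEFAULT_WINDOWS = {"A": (0.5, 5.0), "C": (0.5, 5.0), "B": (0.7, 7.3), "D": (0.7, 7.3)}


@dataclass
class ScenarioSpec:
    """Full parameterization of a reticulate polyploidization simulation."""

    lineage_tree: tuple = _DEFAULT_LINEAGE
    hybridizations: tuple = _DEFAULT_HYBRIDIZATIONS
    sampled_genomes: dict = field(default_factory=lambda: dict(_DEFAULT_SAMPLED))
    subst_rate: float = 0.005  # substitutions / site / MY
    n_chromosomes_per_subgenome: int = 3
    chrom_length: int = 300_000
    n_gene_families: int = 120
    n_single_copy_families: int = 0
    gene_length: int = 300  # bp, multiple of 3
    repeat: RepeatProfile = RepeatProfile()
    ltr: LtrProfile = LtrProfile()
    activity_windows: dict = field(default_factory=lambda: dict(_DEFAULT_WINDOWS))
    repeat_contamination: float = 0.0  # fraction of repeat copies drawn from a foreign library
    exchanges: tuple = ()
    copy_losses: tuple = ()  # (family_id, genome, subgenome) annotations to drop
    copy_tree: tuple | None = None  # explicit copy genealogy; derived if None
    seed: int = 0

    # -- convenience -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        if "repeat" in d and isinstance(d["repeat"], dict):
            d["repeat"] = RepeatProfile(**d["repeat"])
        if "ltr" in d and isinstance(d["ltr"], dict):
            d["ltr"] = LtrProfile(**d["ltr"])
        if "hybridizations" in d:
            d["hybridizations"] = tuple(Hybridization(*h) for h in d["hybridizations"])
        if "exchanges" in d:
            d["exchanges"] = tuple(Exchange(*e) for e in d["exchanges"])
        for key in ("lineage_tree", "copy_tree", "copy_losses"):
            if d.get(key) is not None:
                d[key] = _to_tuple(d[key])
        if "activity_windows" in d:
            d["activity_windows"] = {k: tuple(v) for k, v in d["activity_windows"].items()}
        return cls(**d)


def _to_tuple(x):
    if isinstance(x, (list, tuple)):
        return tuple(_to_tuple(i) for i in x)
    return x


def reticulate_scenario(**overrides) -> ScenarioSpec:
    """Default reticulate-allopolyploidization scenario (AC, BD, AC x BD)."""
    return ScenarioSpec(**overrides)


def autopolyploid_scenario(**overrides) -> ScenarioSpec:
    """Nested whole-genome-duplication scenario (the competing model).

    One WGD in the common ancestor of the tetraploid and octoploid lineages,
    speciation, then a second lineage-specific WGD in the octoploid.  The
    octoploid's subgenome pairs (A,B) and (C,D) are recent sister duplicates;
    there is no divergence-hybridization period, so no subgenome-specific
    repeat bursts are planted.
    """
    copy_tree = (
        7.7,
        (
            7.2,
            (4.5, ("tetraploid", "A"), (4.0, ("octoploid", "A"), ("octoploid", "B"))),
            (4.5, ("tetraploid", "C"), (4.0, ("octoploid", "C"), ("octoploid", "D"))),
        ),
        ("outgroup", "outgroup"),
    )
    defaults = dict(
        lineage_tree=(7.7, (7.2, (4.0, "A", "B"), (4.0, "C", "D")), "outgroup"),
        hybridizations=(),
        sampled_genomes=dict(_DEFAULT_SAMPLED),
        copy_tree=copy_tree,
        activity_windows={},
        repeat=RepeatProfile(burst_rate=0.0),
        ltr=LtrProfile(rate=0.0),
    )
    defaults.update(overrides)
    return ScenarioSpec(**defaults)


# ----------------------------------------------------------------------
# lineage / copy-tree machinery
# ----------------------------------------------------------------------

def _tree_leaves(node) -> list:
    if not isinstance(node, tuple):
        return [node]
    out = []
    for child in node[1:]:
        out.extend(_tree_leaves(child))
    return out


def _node_age(node) -> float:
    return 0.0 if not isinstance(node, tuple) else float(node[0])


def _lineage_divergences(tree) -> dict:
    """Pairwise divergence ages between diploid lineages from the nested tree."""
    ages = {}

    def recurse(node):
        if not isinstance(node, tuple):
            return [node]
        age = float(node[0])
        child_sets = [recurse(c) for c in node[1:]]
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for a in child_sets[i]:
                    for b in child_sets[j]:
                        ages[frozenset((a, b))] = age
        return [x for s in child_sets for x in s]

    recurse(tree)
    return ages


def _composition(lineage: str, hybridizations) -> list:
    """Ordered subgenome composition of a (possibly polyploid) lineage."""
    children = {h.child: h for h in hybridizations}
    if lineage not in children:
        return [lineage]
    h = children[lineage]
    return _composition(h.parent1, hybridizations) + _composition(
        h.parent2, hybridizations
    )


def _event_path(sub: str, target: str, hybridizations):
    """Hybridization events (child, time) along sub's route into ``target``."""
    if sub == target:
        return []
    for h in hybridizations:
        if sub in (h.parent1, h.parent2):
            rest = _event_path(h.child, target, hybridizations)
            if rest is not None:
                return [(h.child, h.time)] + rest
    return None


def _copy_split_age(c1, c2, spec, lineage_div) -> float:
    (g1, s1), (g2, s2) = c1, c2
    if s1 != s2:
        return lineage_div[frozenset((s1, s2))]
    if g1 == g2:
        raise ScenarioError(f"duplicate copy {c1}")
    p1 = _event_path(s1, spec.sampled_genomes[g1], spec.hybridizations)
    p2 = _event_path(s2, spec.sampled_genomes[g2], spec.hybridizations)
    if p1 is None or p2 is None:
        raise ScenarioError(f"no hybridization route for subgenome {s1}")
    i = 0
    while i < len(p1) and i < len(p2) and p1[i] == p2[i]:
        i += 1
    times = [p[i][1] for p in (p1, p2) if i < len(p)]
    if not times:
        raise ScenarioError(f"copies {c1} and {c2} never separate")
    return max(times)


def derive_copy_tree(spec: ScenarioSpec) -> tuple:
    """Build the genealogy of all sampled present-day subgenome copies.

    Nodes are ``(age, child, child, ...)``; leaves are ``(genome, subgenome)``
    pairs.  The tree is reconstructed from the ultrametric pairwise split ages
    implied by the lineage tree plus the hybridization events.
    """
    if spec.copy_tree is not None:
        return spec.copy_tree
    lineage_div = _lineage_divergences(spec.lineage_tree)
    copies = []
    for genome, lineage in spec.sampled_genomes.items():
        for sub in _composition(lineage, spec.hybridizations):
            copies.append((genome, sub))
    split = {}
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            split[frozenset((copies[i], copies[j]))] = _copy_split_age(
                copies[i], copies[j], spec, lineage_div
            )

    def build(group):
        if len(group) == 1:
            return group[0]
        top = max(split[frozenset((a, b))] for a in group for b in group if a != b)
        # cluster copies that diverged more recently than the top age
        parent = {c: c for c in group}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in group:
            for b in group:
                if a < b and split[frozenset((a, b))] < top - 1e-9:
                    parent[find(a)] = find(b)
        clusters = {}
        for c in group:
            clusters.setdefault(find(c), []).append(c)
        children = [build(sorted(v)) for v in clusters.values()]
        children.sort(key=_subtree_key)
        return (top, *children)

    return build(sorted(copies))


def _subtree_key(node):
    if not isinstance(node, tuple) or (len(node) == 2 and isinstance(node[0], str)):
        return node if isinstance(node, tuple) else (str(node),)
    return min(_subtree_key(c) for c in node[1:])


def _is_copy_leaf(node) -> bool:
    return (
        isinstance(node, tuple) and len(node) == 2 and isinstance(node[0], str)
    )


def _copy_leaves(node) -> list:
    if _is_copy_leaf(node):
        return [node]
    out = []
    for child in node[1:]:
        out.extend(_copy_leaves(child))
    return out


def _split_ages_from_tree(tree) -> dict:
    ages = {}

    def recurse(node):
        if _is_copy_leaf(node):
            return [node]
        age = float(node[0])
        sets = [recurse(c) for c in node[1:]]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                for a in sets[i]:
                    for b in sets[j]:
                        ages[frozenset((a, b))] = age
        return [x for s in sets for x in s]

    recurse(tree)
    return ages


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate_spec(spec: ScenarioSpec) -> None:
    if spec.gene_length % 3:
        raise ScenarioError("gene_length must be a multiple of 3")
    if spec.subst_rate < 0:
        raise ScenarioError("subst_rate must be non-negative")
    lineage_div = _lineage_divergences(spec.lineage_tree)
    formation = {h.child: h.time for h in spec.hybridizations}
    for h in spec.hybridizations:
        for parent in (h.parent1, h.parent2):
            if parent in formation and h.time >= formation[parent]:
                raise ScenarioError(
                    f"hybridization {h.child} at {h.time} MY is not younger than "
                    f"the formation of its parent {parent} at {formation[parent]} MY"
                )
        key = frozenset((h.parent1, h.parent2))
        if h.parent1 != h.parent2 and key in lineage_div:
            if h.time >= lineage_div[key]:
                raise ScenarioError(
                    f"hybridization {h.child} at {h.time} MY predates the "
                    f"divergence of its parents ({lineage_div[key]} MY)"
                )
    tree = derive_copy_tree(spec)
    root_age = _node_age(tree)
    for sub, (young, old) in spec.activity_windows.items():
        if not (0 <= young < old):
            raise ScenarioError(f"activity window for {sub} must satisfy 0 <= young < old")
        if old > root_age + 1e-9:
            raise ScenarioError(f"activity window for {sub} is older than the root")
    # gene capacity
    n_groups = spec.n_chromosomes_per_subgenome
    per_group = -(-(spec.n_gene_families + spec.n_single_copy_families) // n_groups)
    pad = 100
    if per_group * (spec.gene_length + pad) + pad >= spec.chrom_length:
        raise ScenarioError("chromosomes too short for the requested gene families")
    # exchanges
    by_recipient = {}
    for e in spec.exchanges:
        if e.donor == e.recipient:
            raise ScenarioError(f"exchange {e}: donor equals recipient")
        if not (0 <= e.start < e.end <= spec.chrom_length):
            raise ScenarioError(f"exchange {e}: coordinates outside chromosome bounds")
        if not (0 <= e.chrom_index < n_groups):
            raise ScenarioError(f"exchange {e}: bad chromosome index")
        host_time = _cohabitation_time(e.donor, e.recipient, spec)
        if e.time >= host_time:
            raise ScenarioError(
                f"exchange {e}: time {e.time} MY is not younger than the "
                f"hybridization creating its host nucleus ({host_time} MY)"
            )
        by_recipient.setdefault((e.genome, e.recipient, e.chrom_index), []).append(e)
    for events in by_recipient.values():
        events = sorted(events, key=lambda e: e.start)
        for a, b in zip(events, events[1:]):
            if a.end > b.start:
                raise ScenarioError(f"exchanges {a} and {b} overlap")


def _cohabitation_time(sub1, sub2, spec) -> float:
    """Formation time of the most recent nucleus containing both subgenomes."""
    times = [
        h.time
        for h in spec.hybridizations
        if sub1 in _composition(h.child, spec.hybridizations)
        and sub2 in _composition(h.child, spec.hybridizations)
    ]
    if not times:
        raise ScenarioError(f"subgenomes {sub1} and {sub2} never share a nucleus")
    return max(times)


# ----------------------------------------------------------------------
# outputs
# ----------------------------------------------------------------------

class GeneAnnotation(NamedTuple):
    genome: str
    chrom: str
    gene_id: str
    start: int  # 0-based half-open
    end: int
    family: int
    kind: str  # "anchor" | "single"


class SimRead(NamedTuple):
    read_id: str
    seq: str
    chrom: str
    pos: int
    strand: str
    label: str  # truth subgenome of origin


@dataclass
class TruthTable:
    """Ground truth for every emitted feature of a simulated scenario."""

    chromosomes: list  # dicts: genome, chrom, subgenome, group, length
    genes: list        # dicts: genome, chrom, gene_id, family, kind, subgenome, start, end, exchanged
    exchanges: list    # dicts: genome, chrom, start, end, donor, recipient, time
    ltrs: list         # dicts: genome, chrom, start, end, ltr_length, subgenome, age, exchanged
    repeats: list      # dicts: genome, chrom, start, end, subgenome, time, exchanged
    split_ages: dict   # frozenset({(genome, sub), (genome, sub)}) -> MY
    activity_windows: dict
    repeat_motifs: dict = field(default_factory=dict)   # subgenome -> motif str
    ltr_templates: dict = field(default_factory=dict)   # subgenome -> element str

    def chrom_subgenome(self, genome: str) -> dict:
        return {
            c["chrom"]: c["subgenome"] for c in self.chromosomes if c["genome"] == genome
        }

    def true_divergence(self, copy1, copy2) -> float:
        return self.split_ages[frozenset((tuple(copy1), tuple(copy2)))]


@dataclass
class SimulationResult:
    spec: ScenarioSpec
    genomes: dict      # genome -> {chrom: sequence str}
    annotations: list  # GeneAnnotation, ordered
    truth: TruthTable

    def cds(self, ann: GeneAnnotation) -> str:
        return self.genomes[ann.genome][ann.chrom][ann.start : ann.end]


# ----------------------------------------------------------------------
# the simulator
# ----------------------------------------------------------------------

def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(tags)))


class _Intergenic:
    """Uniform sampler over intergenic backbone positions of one group."""

    def __init__(self, gene_intervals, length, margin=20):
        gaps = []
        prev = 0
        for s, e in sorted(gene_intervals):
            lo, hi = prev, max(prev, s - margin)
            if hi > lo:
                gaps.append((lo, hi))
            prev = e + margin
        if length > prev:
            gaps.append((prev, length))
        self.starts = np.array([g[0] for g in gaps])
        self.lens = np.array([g[1] - g[0] for g in gaps])
        self.cum = np.concatenate([[0], np.cumsum(self.lens)])
        self.total = int(self.cum[-1])

    def sample(self, rng) -> int:
        u = int(rng.integers(0, self.total))
        i = int(np.searchsorted(self.cum, u, side="right")) - 1
        return int(self.starts[i] + (u - self.cum[i]))


def simulate_scenario(spec: ScenarioSpec) -> SimulationResult:
    """Generate genomes, gene annotations and a complete truth table."""
    validate_spec(spec)
    rate = spec.subst_rate
    copy_tree = derive_copy_tree(spec)
    split_ages = _split_ages_from_tree(copy_tree)
    copies = _copy_leaves(copy_tree)
    n_groups = spec.n_chromosomes_per_subgenome
    L = spec.chrom_length

    genome_order = [g for g in ("outgroup", "tetraploid", "octoploid") if g in spec.sampled_genomes]
    genome_order += [g for g in spec.sampled_genomes if g not in genome_order]
    comp = {}
    for genome in genome_order:
        subs = [c[1] for c in copies if c[0] == genome]
        comp[genome] = sorted(set(subs), key=subs.index)

    windowed_subs = sorted(spec.activity_windows)
    motifs = {
        s: _seq.random_seq(spec.repeat.motif_length, _rng(spec.seed, 1, i))
        for i, s in enumerate(windowed_subs)
    }
    # each subgenome carries one LTR-RT family: a template whose two terminal
    # repeats are identical, so every inserted copy is born with identical
    # LTRs and stays recognizable by the family's (subgenome-specific) k-mers
    ltr_templates = {}
    for i, s in enumerate(windowed_subs):
        rng_t = _rng(spec.seed, 8, i)
        ltr = _seq.random_seq(spec.ltr.ltr_length, rng_t)
        internal = _seq.random_seq(spec.ltr.internal_length, rng_t)
        ltr_templates[s] = np.concatenate([ltr, internal, ltr])

    total_families = spec.n_gene_families + spec.n_single_copy_families
    fam_kind = ["anchor"] * spec.n_gene_families + ["single"] * spec.n_single_copy_families
    fams_by_group = {g: [] for g in range(n_groups)}
    for f in range(total_families):
        fams_by_group[f % n_groups].append(f)

    losses = set(spec.copy_losses)

    # per (copy, group) assembled chromosome records
    records = {}
    for g in range(n_groups):
        rng_bb = _rng(spec.seed, 2, g)
        backbone = _seq.random_seq(L, rng_bb)
        fams = fams_by_group[g]
        n = len(fams)
        pad = 100
        span = L - n * (spec.gene_length + pad) - pad
        offs = np.sort(rng_bb.random(n)) * span
        gene_intervals = []
        for i, f in enumerate(fams):
            s = int(offs[i]) + pad // 2 + i * (spec.gene_length + pad)
            gene_intervals.append((s, s + spec.gene_length, f))
            backbone[s : s + spec.gene_length] = _seq.random_cds(
                spec.gene_length // 3, rng_bb
            )

        # evolve the backbone down the copy tree
        leaves_seq = {}
        rng_ev = _rng(spec.seed, 4, g)

        def evolve(node, seq):
            if _is_copy_leaf(node):
                leaves_seq[node] = seq
                return
            age = float(node[0])
            for child in node[1:]:
                d = rate * (age - _node_age(child) if not _is_copy_leaf(child) else age)
                evolve(child, _seq.jc_evolve(seq, max(d, 0.0), rng_ev))

        evolve(copy_tree, backbone)

        # insertion events (repeats + LTRs) per windowed subgenome
        sampler = _Intergenic([(s, e) for s, e, _ in gene_intervals], L)
        events_by_copy = {c: [] for c in copies}
        for si, s in enumerate(windowed_subs):
            rng_ins = _rng(spec.seed, 5, g, si)
            young, old = spec.activity_windows[s]
            carriers = sorted(c for c in copies if c[1] == s)
            if not carriers:
                continue
            n_rep = rng_ins.poisson(spec.repeat.burst_rate * (old - young))
            n_ltr = rng_ins.poisson(spec.ltr.rate * (old - young))
            for kind, count in (("repeat", n_rep), ("ltr", n_ltr)):
                for _ in range(count):
                    t = float(rng_ins.uniform(young, old))
                    pos = sampler.sample(rng_ins)
                    owner = s
                    if kind == "repeat" and spec.repeat_contamination > 0:
                        if rng_ins.random() < spec.repeat_contamination:
                            others = [x for x in windowed_subs if x != s]
                            owner = others[int(rng_ins.integers(0, len(others)))]
                    if kind == "repeat":
                        birth = motifs[owner]
                        meta = {"kind": "repeat", "owner": owner, "time": t}
                    else:
                        birth = ltr_templates[owner]
                        meta = {
                            "kind": "ltr",
                            "owner": owner,
                            "time": t,
                            "ltr_length": spec.ltr.ltr_length,
                        }
                    inheritors = _inheritors(carriers, t, split_ages, rng_ins)
                    for c in carriers:
                        if c in inheritors:
                            seq_c = _seq.jc_evolve(birth, rate * t, rng_ins)
                            events_by_copy[c].append((pos, meta, seq_c))

        for c in copies:
            records[(c, g)] = _assemble(
                leaves_seq[c], events_by_copy[c], gene_intervals, c
            )

    # homoeologous exchanges (segments extracted from the pre-exchange donor
    # state first, so a chromosome may be both donor and recipient)
    truth_exchanges = []
    ex_by_rec = {}
    for ei, e in enumerate(spec.exchanges):
        ex_by_rec.setdefault(((e.genome, e.recipient), e.chrom_index), []).append((ei, e))
    seg_plan = {}
    for ((genome, recipient), g), evs in sorted(ex_by_rec.items()):
        segs = []
        for ei, e in sorted(evs, key=lambda x: x[1].start):
            don = records[((genome, e.donor), g)]
            rng_x = _rng(spec.seed, 6, ei)
            segs.append((e, _extract_segment(don, e.start, e.end, rate, e.time, rng_x)))
        seg_plan[((genome, recipient), g)] = segs
    for ((genome, recipient), g), segs in sorted(seg_plan.items()):
        rec = records[((genome, recipient), g)]
        new_rec, intervals = _apply_exchanges(rec, segs)
        records[((genome, recipient), g)] = new_rec
        truth_exchanges.extend(intervals)

    # emit genomes / annotations / truth
    single_carriers = _single_copy_carriers(comp)
    genomes = {}
    annotations = []
    chrom_rows, gene_rows, ltr_rows, repeat_rows = [], [], [], []
    ex_rows = []
    for genome in genome_order:
        seqs = {}
        counter = 0
        for sub in comp[genome]:
            for g in range(n_groups):
                counter += 1
                chrom = f"chr{counter}"
                rec = records[((genome, sub), g)]
                seqs[chrom] = _seq.decode(rec["seq"])
                chrom_rows.append(
                    dict(
                        genome=genome,
                        chrom=chrom,
                        subgenome=sub,
                        group=g,
                        length=len(rec["seq"]),
                    )
                )
                gi = 0
                for gene in rec["genes"]:
                    fam = gene["family"]
                    kind = fam_kind[fam]
                    if kind == "single" and (genome, gene["subgenome"]) not in single_carriers:
                        continue
                    if (fam, genome, gene["subgenome"]) in losses:
                        continue
                    gi += 1
                    gid = f"{genome[:3]}_{chrom}_g{gi:04d}"
                    annotations.append(
                        GeneAnnotation(genome, chrom, gid, gene["start"], gene["end"], fam, kind)
                    )
                    gene_rows.append(
                        dict(
                            genome=genome,
                            chrom=chrom,
                            gene_id=gid,
                            family=fam,
                            kind=kind,
                            subgenome=gene["subgenome"],
                            start=gene["start"],
                            end=gene["end"],
                            exchanged=gene["exchanged"],
                        )
                    )
                for r in rec["repeats"]:
                    repeat_rows.append(
                        dict(genome=genome, chrom=chrom, start=r["start"], end=r["end"],
                             subgenome=r["owner"], time=r["time"], exchanged=r["exchanged"])
                    )
                for l in rec["ltrs"]:
                    ltr_rows.append(
                        dict(genome=genome, chrom=chrom, start=l["start"], end=l["end"],
                             ltr_length=l["ltr_length"], subgenome=l["owner"],
                             age=l["time"], exchanged=l["exchanged"])
                    )
                for iv in truth_exchanges:
                    if iv["copy"] == (genome, sub) and iv["group"] == g:
                        ex_rows.append(
                            dict(genome=genome, chrom=chrom, start=iv["start"], end=iv["end"],
                                 donor=iv["donor"], recipient=iv["recipient"], time=iv["time"])
                        )
        genomes[genome] = seqs

    truth = TruthTable(
        chromosomes=chrom_rows,
        genes=gene_rows,
        exchanges=ex_rows,
        ltrs=ltr_rows,
        repeats=repeat_rows,
        split_ages=split_ages,
        activity_windows=dict(spec.activity_windows),
        repeat_motifs={s: _seq.decode(m) for s, m in motifs.items()},
        ltr_templates={s: _seq.decode(t) for s, t in ltr_templates.items()},
    )
    return SimulationResult(spec=spec, genomes=genomes, annotations=annotations, truth=truth)


def _single_copy_carriers(comp) -> set:
    """Single-copy families are annotated in the first subgenome of each genome."""
    return {(genome, subs[0]) for genome, subs in comp.items()}


def _inheritors(carriers, t, split_ages, rng) -> set:
    """Copies of one subgenome that inherit an insertion of age ``t``.

    At time t the carriers form clusters of lineages that had not yet
    separated (pairwise split age > t means still one lineage at t); the
    insertion occurred in exactly one lineage alive at t.
    """
    if len(carriers) == 1:
        return {carriers[0]}
    parent = {c: c for c in carriers}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(carriers):
        for b in carriers[i + 1 :]:
            if split_ages[frozenset((a, b))] < t:
                parent[find(a)] = find(b)
    clusters = {}
    for c in carriers:
        clusters.setdefault(find(c), []).append(c)
    keys = sorted(clusters)
    pick = keys[int(rng.integers(0, len(keys)))]
    return set(clusters[pick])


def _assemble(backbone, events, gene_intervals, copy_id):
    """Splice insertion events into a backbone; compute final coordinates."""
    events = sorted(enumerate(events), key=lambda x: (x[1][0], x[0]))
    pieces = []
    repeats, ltrs = [], []
    prev = 0
    offset = 0
    ins_positions, ins_offsets = [0], [0]
    for _, (pos, meta, seq) in events:
        pieces.append(backbone[prev:pos])
        start = pos + offset
        pieces.append(seq)
        rec = dict(b_pos=pos, start=start, end=start + len(seq), owner=meta["owner"],
                   time=meta["time"], exchanged=False)
        if meta["kind"] == "repeat":
            repeats.append(rec)
        else:
            rec["ltr_length"] = meta["ltr_length"]
            ltrs.append(rec)
        offset += len(seq)
        prev = pos
        ins_positions.append(pos)
        ins_offsets.append(offset)
    pieces.append(backbone[prev:])
    seq = np.concatenate(pieces) if pieces else backbone.copy()
    ins_positions = np.array(ins_positions)
    ins_offsets = np.array(ins_offsets)

    def bmap(b):  # backbone -> final coordinate (insertions at p < b shift b)
        i = int(np.searchsorted(ins_positions, b, side="right")) - 1
        return int(b + ins_offsets[i])

    genes = []
    for s, e, fam in gene_intervals:
        genes.append(
            dict(b_start=s, b_end=e, start=bmap(s), end=bmap(s) + (e - s),
                 family=fam, subgenome=copy_id[1], exchanged=False)
        )
    return dict(seq=seq, genes=genes, repeats=repeats, ltrs=ltrs, bmap=bmap, copy=copy_id)


def _extract_segment(donor_rec, b_start, b_end, rate, t, rng):
    """Donor-side content of an exchange: sequence plus carried annotations."""
    f = donor_rec["bmap"]
    s, e = f(b_start), f(b_end)
    seg = _seq.jc_evolve(donor_rec["seq"][s:e], rate * t, rng)
    genes = [
        dict(g, exchanged=True)
        for g in donor_rec["genes"]
        if b_start <= (g["b_start"] + g["b_end"]) // 2 < b_end
    ]
    repeats = [dict(r, exchanged=True) for r in donor_rec["repeats"] if b_start <= r["b_pos"] < b_end]
    ltrs = [dict(l, exchanged=True) for l in donor_rec["ltrs"] if b_start <= l["b_pos"] < b_end]
    return dict(seq=seg, f_start=s, genes=genes, repeats=repeats, ltrs=ltrs,
                b_start=b_start, b_end=b_end)


def _apply_exchanges(rec, segs):
    """Replace recipient intervals by donor segments; rebuild annotations."""
    f = rec["bmap"]
    seq = rec["seq"]
    pieces = []
    new_genes, new_repeats, new_ltrs = [], [], []
    intervals = []
    prev_f = 0
    delta = 0
    cut = []  # (b_start, b_end, length change of this splice)
    for e, seg in segs:
        fs, fe = f(e.start), f(e.end)
        pieces.append(seq[prev_f:fs])
        new_start = fs + delta
        pieces.append(seg["seq"])
        intervals.append(
            dict(copy=(e.genome, e.recipient), group=e.chrom_index,
                 start=new_start, end=new_start + len(seg["seq"]),
                 donor=e.donor, recipient=e.recipient, time=e.time)
        )
        shift = new_start - seg["f_start"]
        for g in seg["genes"]:
            new_genes.append(dict(g, start=g["start"] + shift, end=g["end"] + shift))
        for r in seg["repeats"]:
            new_repeats.append(dict(r, start=r["start"] + shift, end=r["end"] + shift))
        for l in seg["ltrs"]:
            new_ltrs.append(dict(l, start=l["start"] + shift, end=l["end"] + shift))
        cut.append((e.start, e.end, len(seg["seq"]) - (fe - fs)))
        delta += len(seg["seq"]) - (fe - fs)
        prev_f = fe
    pieces.append(seq[prev_f:])
    new_seq = np.concatenate(pieces)

    def keep_shift(b_pos):
        """Coordinate shift for a surviving feature, or None if replaced."""
        d = 0
        for bs, be, dlen in cut:
            if bs <= b_pos < be:
                return None
            if b_pos >= be:
                d += dlen
        return d

    for g in rec["genes"]:
        d = keep_shift((g["b_start"] + g["b_end"]) // 2)
        if d is not None:
            new_genes.append(dict(g, start=g["start"] + d, end=g["end"] + d))
    for r in rec["repeats"]:
        d = keep_shift(r["b_pos"])
        if d is not None:
            new_repeats.append(dict(r, start=r["start"] + d, end=r["end"] + d))
    for l in rec["ltrs"]:
        d = keep_shift(l["b_pos"])
        if d is not None:
            new_ltrs.append(dict(l, start=l["start"] + d, end=l["end"] + d))

    new_genes.sort(key=lambda g: g["start"])
    new_repeats.sort(key=lambda r: r["start"])
    new_ltrs.sort(key=lambda l: l["start"])
    out = dict(rec)
    out.update(seq=new_seq, genes=new_genes, repeats=new_repeats, ltrs=new_ltrs)
    return out, intervals


# ----------------------------------------------------------------------
# reads
# ----------------------------------------------------------------------

def simulate_reads(
    sequences: dict,
    read_length: int,
    coverage: float,
    seed: int,
    labels: dict | None = None,
) -> list:
    """Uniform error-free reads from a genome, truth-labeled by source.

    ``sequences`` maps chromosome name to sequence; ``labels`` (optional) maps
    chromosome name to its subgenome of origin.  Read count is Poisson with
    mean coverage * genome_length / read_length; positions are uniform.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    chroms = sorted(sequences)
    lens = np.array([len(sequences[c]) for c in chroms])
    if read_length > lens.min():
        short = chroms[int(np.argmin(lens))]
        raise ValueError(f"read_length {read_length} exceeds chromosome {short}")
    rng = _rng(seed, 7)
    n_valid = lens - read_length + 1
    total = int(rng.poisson(coverage * lens.sum() / read_length))
    picks = rng.choice(len(chroms), size=total, p=n_valid / n_valid.sum())
    reads = []
    for i in range(total):
        ci = int(picks[i])
        chrom = chroms[ci]
        pos = int(rng.integers(0, n_valid[ci]))
        seq = sequences[chrom][pos : pos + read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = _seq.revcomp(seq)
        label = labels.get(chrom, "?") if labels else "?"
        reads.append(SimRead(f"read{i:07d}", seq, chrom, pos, strand, label))
    return reads


# ----------------------------------------------------------------------
# writers (plain-text formats)
# ----------------------------------------------------------------------

def write_fasta(path, sequences: dict, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            s = sequences[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gff3(path, annotations, genome: str | None = None) -> None:
    """Gene/mRNA/CDS features, 1-based inclusive, '+' strand."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            if genome is not None and a.genome != genome:
                continue
            s1, e1 = a.start + 1, a.end
            base = f"{a.chrom}\tpolyploidkit\t"
            fh.write(f"{base}gene\t{s1}\t{e1}\t.\t+\t.\tID={a.gene_id}\n")
            fh.write(f"{base}mRNA\t{s1}\t{e1}\t.\t+\t.\tID={a.gene_id}.t1;Parent={a.gene_id}\n")
            fh.write(f"{base}CDS\t{s1}\t{e1}\t.\t+\t0\tID={a.gene_id}.cds;Parent={a.gene_id}.t1\n")


def write_fastq(path, reads) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} {r.chrom}:{r.pos}:{r.strand}:{r.label}\n")
            fh.write(r.seq + "\n+\n" + "I" * len(r.seq) + "\n")


def write_truth_tables(outdir, truth: TruthTable) -> None:
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.chromosomes).to_csv(outdir / "truth_chromosomes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.genes).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.exchanges).to_csv(outdir / "truth_exchanges.tsv", sep="\t", index=False)
    pd.DataFrame(truth.ltrs).to_csv(outdir / "truth_ltrs.tsv", sep="\t", index=False)
    pd.DataFrame(truth.repeats).to_csv(outdir / "truth_repeats.tsv", sep="\t", index=False)
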