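"""Rooted gene-tree topology census for polyploidy-model discrimination.

An anchor gene tree relates one outgroup copy (role O), two tetraploid
subgenome copies (T1, T2) and four octoploid subgenome copies (P1..P4).
Under a nested whole-genome-duplication origin the four octoploid copies form
two recent sister pairs, each pair sister to one tetraploid copy:

    (O, ((T1,(Pi,Pj)), (T2,(Pk,Pl))))

Under a reticulate allopolyploidization origin each tetraploid copy is sister
to the octoploid copy that shares its diploid progenitor, one further
octoploid copy attaches to the first such clade, and the last is the earliest
ingroup branch:

    (O, (Pw, (((T1,Px),Py), (T2,Pz))))

Counting canonicalized rooted topologies over many anchor trees and tagging
each class by the model(s) that predict it turns a gene-tree forest into a
test between the two origins: the plurality class carries the verdict.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .trees import newick_topology

__all__ = [
    "ROLES",
    "canonicalize",
    "model_predicted_classes",
    "classify",
    "census",
    "TopologyCensus",
    "macro_synteny_groups",
]

#: canonical role labels: outgroup, tetraploid subgenomes, octoploid subgenomes
ROLES = ("O", "T1", "T2", "P1", "P2", "P3", "P4")


def canonicalize(tree, roles: dict | None = None) -> str:
    """Canonical string of a rooted leaf-labeled topology.

    ``tree`` is a nested tuple (leaves = tip labels) or a newick string;
    ``roles`` optionally maps tip labels to role labels first.  Children are
    ordered by the lexicographically smallest role label they contain, so the
    string is invariant under sibling order.  Unmapped tips raise KeyError.
    """
    if isinstance(tree, str):
        tree = newick_topology(tree)

    def recurse(node):
        if not isinstance(node, tuple):
            label = roles[node] if roles is not None else node
            return label, label
        parts = sorted(recurse(c) for c in node)
        key = parts[0][0]
        return key, "(" + ",".join(p[1] for p in parts) + ")"

    return recurse(tree)[1]


def _wgd_topologies():
    out = set()
    ps = ("P1", "P2", "P3", "P4")
    for pair in itertools.combinations(ps, 2):
        rest = tuple(p for p in ps if p not in pair)
        tree = ("O", (("T1", pair), ("T2", rest)))
        out.add(canonicalize(tree))
    return out


def _reticulate_topologies():
    out = set()
    ps = ("P1", "P2", "P3", "P4")
    for ta, tb in (("T1", "T2"), ("T2", "T1")):
        for px, py, pz, pw in itertools.permutations(ps):
            tree = ("O", (pw, (((ta, px), py), (tb, pz))))
            out.add(canonicalize(tree))
    return out


_MODEL_SETS = {}


def model_predicted_classes(model: str) -> frozenset:
    """Canonical topology strings predicted by a polyploidy model.

    ``model`` is ``"WGD"`` (nested autopolyploid duplications: the octoploid
    copies form two recent cherries, one per tetraploid copy) or
    ``"reticulate"`` (shared-progenitor tetraploid/octoploid ortholog pairs).
    The two sets are disjoint.
    """
    if not _MODEL_SETS:
        _MODEL_SETS["WGD"] = frozenset(_wgd_topologies())
        _MODEL_SETS["reticulate"] = frozenset(_reticulate_topologies())
    try:
        return _MODEL_SETS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected 'WGD' or 'reticulate'")


def classify(canonical: str) -> str:
    """Model tag for a canonical topology: WGD-model, reticulate-model or other."""
    if canonical in model_predicted_classes("WGD"):
        return "WGD-model"
    if canonical in model_predicted_classes("reticulate"):
        return "reticulate-model"
    return "other"


@dataclass
class TopologyCensus:
    """Counts of canonical rooted topologies over a gene-tree forest."""

    counts: dict               # canonical string -> count
    total: int
    ranked: list = field(default_factory=list)  # (canonical, count, fraction, tag)

    @property
    def fractions(self) -> dict:
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def plurality(self):
        """(canonical, count, fraction, tag) of the most frequent class."""
        return self.ranked[0] if self.ranked else None

    def model_support(self) -> dict:
        """Fraction of trees whose class is predicted by each model."""
        out = {"WGD-model": 0.0, "reticulate-model": 0.0, "other": 0.0}
        for canonical, count, frac, tag in self.ranked:
            out[tag] += frac
        return out


def census(trees, roles: dict | None = None) -> TopologyCensus:
    """Census of rooted tree topologies.

    ``trees`` is an iterable of rooted trees (nested tuples or newick
    strings, all rooted on the outgroup); ``roles`` maps tip labels to role
    labels and may be omitted when tips already carry role labels.  Classes
    are ranked by descending count (ties broken lexicographically).
    """
    counts = {}
    for t in trees:
        s = canonicalize(t, roles)
        counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = [(k, v, v / total, classify(k)) for k, v in ranked]
    return TopologyCensus(counts=counts, total=total, ranked=ranked)


def macro_synteny_groups(anchors, min_genes: int = 1) -> dict:
    """Group anchor groups by their full homoeologous chromosome set.

    Anchors whose member genes lie on the identical per-genome chromosome
    tuple belong to one macro-synteny group (the unit whose concatenated
    alignment yields a macro-synteny tree).  Groups with fewer than
    ``min_genes`` anchors are dropped.  Returns ``{chrom_key: [anchor, ...]}``.
    """
    groups = {}
    for anchor in anchors:
        groups.setdefault(anchor.chrom_key, []).append(anchor)
    return {k: v for k, v in sorted(groups.items()) if len(v) >= min_genes}
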