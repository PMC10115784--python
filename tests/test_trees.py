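"""Alignment/trimming/backtranslation and distance-tree correctness."""
import numpy as np
import pytest

from polyploidkit import _seq, trees
from polyploidkit.trees import (
    MultipleAlignment,
    align_progressive,
    backtranslate,
    bootstrap_support,
    concat_alignment,
    jc_distance_matrix,
    nj_tree,
    quartet_species_tree,
    root_on_outgroup,
    tree_splits,
    trim_columns,
)


def test_alignment_of_identical_sequences_has_no_gaps():
    aln = align_progressive([("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR"), ("c", "MKTAYIAKQR")])
    assert aln.rows == ["MKTAYIAKQR"] * 3


def test_internal_insertion_becomes_one_gap_block():
    aln = align_progressive([("a", "MKTAYIAKQR"), ("b", "MKTAYWWWIAKQR")])
    row = aln.row("a")
    assert row.replace("-", "") == "MKTAYIAKQR"
    gap_cols = [i for i, ch in enumerate(row) if ch == "-"]
    assert len(gap_cols) == 3
    assert gap_cols == list(range(gap_cols[0], gap_cols[0] + 3))


def test_illegal_characters_are_rejected_by_name():
    with pytest.raises(ValueError, match="bad_seq"):
        align_progressive([("ok", "MKTA"), ("bad_seq", "MK7A")])
    with pytest.raises(ValueError, match="two sequences"):
        align_progressive([("one", "MKTA")])


def test_trimming_rule_is_exactly_the_gap_fraction_threshold():
    aln = MultipleAlignment(
        ["a", "b", "c", "d"],
        ["AAAAA-AAA-", "AA-AAAAAA-", "AAAAAAAAA-", "AAAAAAAAAA"],
        "dna",
    )
    # per-column gap fractions: col2=1/4, col5=1/4, col9=3/4
    assert trim_columns(aln, 0.5).n_columns == 9
    assert trim_columns(aln, 0.25).n_columns == 9
    assert trim_columns(aln, 0.2).n_columns == 7
    gap_free = MultipleAlignment(["a", "b"], ["ACGT", "ACGT"], "dna")
    assert trim_columns(gap_free, 0.0).rows == gap_free.rows
    with pytest.raises(ValueError, match="max_gap_fraction"):
        trim_columns(MultipleAlignment(["a", "b"], ["A-", "-A"], "dna"), 0.0)


def test_backtranslate_and_roundtrip():
    prot = align_progressive([("a", "MKR"), ("b", "MR")])
    cds = {"a": "ATGAAACGT", "b": "ATGCGG"}
    codon = backtranslate(prot, cds)
    assert codon.alphabet == "codon"
    assert codon.row("a") == "ATGAAACGT"
    b_row = codon.row("b")
    assert b_row.replace("---", "", 1) == "ATGCGG" and "---" in b_row
    # round trip: translating ungapped codon rows gives the protein rows
    for taxon in prot.taxa:
        assert _seq.translate(codon.row(taxon).replace("---", "")) == prot.row(taxon).replace("-", "")
    with pytest.raises(ValueError, match="translates"):
        backtranslate(prot, {"a": "ATGAAACGT", "b": "ATGGGG"})


def test_jc_distance_closed_form_and_properties():
    n = 1000
    k = 300  # p = 0.3
    a = "A" * n
    b = "C" * k + "A" * (n - k)
    aln = MultipleAlignment(["a", "b"], [a, b], "dna")
    _, D = jc_distance_matrix(aln)
    expected = -0.75 * np.log(1 - 4 * 0.3 / 3)
    assert D[0, 1] == pytest.approx(expected, rel=1e-9)
    assert D[0, 0] == 0
    rng = np.random.default_rng(0)
    rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
    _, D2 = jc_distance_matrix(MultipleAlignment(list("abcd"), rows, "dna"))
    assert np.allclose(D2, D2.T) and (D2 >= 0).all()


def test_jc_saturation_is_capped_with_warning():
    aln = MultipleAlignment(["a", "b"], ["A" * 100, "C" * 100], "dna")
    with pytest.warns(UserWarning, match="saturated"):
        _, D = jc_distance_matrix(aln, cap=5.0)
    assert D[0, 1] == 5.0


def _random_additive_tree(taxa, rng):
    """Random binary topology with positive lengths; returns (D, splits)."""

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        k = int(rng.integers(1, len(leaves)))
        return (build(leaves[:k]), build(leaves[k:]))

    shuffled = list(taxa)
    rng.shuffle(shuffled)
    topo = build(shuffled)
    lengths = {}

    def assign(node):
        for child in node if isinstance(node, tuple) else ():
            lengths[id(child) if isinstance(child, tuple) else child] = float(
                rng.uniform(0.05, 1.0)
            )
            if isinstance(child, tuple):
                assign(child)

    assign(topo)

    def leafset(node):
        return [node] if not isinstance(node, tuple) else [x for c in node for x in leafset(c)]

    def depth_map(node, acc):
        out = {}
        if not isinstance(node, tuple):
            return {node: acc}
        for child in node:
            key = id(child) if isinstance(child, tuple) else child
            out.update(depth_map(child, acc + lengths[key]))
        return out

    n = len(taxa)
    M = np.zeros((n, n))
    idx = {t: i for i, t in enumerate(taxa)}

    def fill(node):
        if not isinstance(node, tuple):
            return
        kids = list(node)
        maps = []
        for child in kids:
            key = id(child) if isinstance(child, tuple) else child
            maps.append(depth_map(child, lengths[key]))
            fill(child)
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for a, da in maps[i].items():
                    for b, db in maps[j].items():
                        M[idx[a], idx[b]] = M[idx[b], idx[a]] = da + db

    fill(topo)
    # true unrooted splits
    ref = sorted(taxa)[0]
    full = set(taxa)
    splits = set()

    def collect(node):
        if not isinstance(node, tuple):
            return {node}
        ls = set()
        for c in node:
            ls |= collect(c)
        if 2 <= len(ls) <= n - 2:
            splits.add(frozenset(ls if ref not in ls else full - ls))
        return ls

    collect(topo)
    return M, splits


def test_nj_recovers_additive_topologies():
    """NJ is consistent: it recovers the generating topology of every
    additive distance matrix (50 random 6-taxon trees)."""
    taxa = list("ABCDEF")
    rng = np.random.default_rng(7)
    for rep in range(50):
        M, true_splits = _random_additive_tree(taxa, rng)
        nwk = nj_tree(taxa, M)
        assert tree_splits(nwk, taxa) == true_splits, f"rep {rep}"


def test_nj_matches_scikit_bio_on_random_matrix():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    taxa = list("ABCDEF")
    rng = np.random.default_rng(1)
    M, _ = _random_additive_tree(taxa, rng)
    ours = tree_splits(nj_tree(taxa, M), taxa)
    sk = skbio_nj(DistanceMatrix(M, taxa))
    theirs = set()
    ref = sorted(taxa)[0]
    full = set(taxa)
    for node in sk.non_tips():
        side = {t.name for t in node.tips()}
        if 2 <= len(side) <= len(taxa) - 2:
            theirs.add(frozenset(side if ref not in side else full - side))
    assert ours == theirs


def test_nj_small_and_tie_determinism():
    with pytest.raises(ValueError):
        nj_tree(["a", "b"], np.zeros((2, 2)))
    D3 = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
    assert nj_tree(list("abc"), D3).count(",") == 2
    D4 = np.ones((4, 4)) - np.eye(4)
    t1 = nj_tree(list("abcd"), D4)
    t2 = nj_tree(list("abcd"), D4)
    assert t1 == t2  # documented tie rule: lowest-index pair joins first


def test_root_on_outgroup_reorients_deep_placements():
    nwk = "((O:1,A:1):1,B:1,(C:1,D:1):1);"
    rooted = root_on_outgroup(nwk, "O")
    assert rooted[0] == "O"
    from polyploidkit.census import canonicalize

    assert canonicalize(rooted) == canonicalize(("O", ("A", ("B", ("C", "D")))))


def test_bootstrap_supports():
    rng = np.random.default_rng(5)
    base = rng.choice(list("ACGT"), 200)
    rows = []
    for muts in (0, 0, 25, 25):  # two clean pairs -> one strong split
        row = base.copy()
        pos = rng.choice(200, muts, replace=False)
        row[pos] = [chr(c) for c in rng.choice([65, 67, 71, 84], muts)]
        rows.append("".join(row))
    aln = MultipleAlignment(list("abcd"), rows, "dna")
    nwk, supports = bootstrap_support(aln, 50, seed=3)
    assert supports and all(0 <= v <= 100 for v in supports.values())
    nwk2, supports2 = bootstrap_support(aln, 50, seed=3)
    assert supports == supports2 and nwk == nwk2
    _, none_supports = bootstrap_support(aln, 0, seed=3)
    assert none_supports is None
    # a zero-conflict alignment gives 100% support everywhere
    clean = MultipleAlignment(
        list("abcd"),
        ["AAAA" * 20, "AAAA" * 20, "CCCC" * 20, "CCCC" * 20],
        "dna",
    )
    _, s_clean = bootstrap_support(clean, 30, seed=1)
    assert all(v == 100.0 for v in s_clean.values())


def test_concat_alignment_identity_and_additivity():
    a1 = MultipleAlignment(["x", "y"], ["AAA", "CCC"], "dna")
    a2 = MultipleAlignment(["y", "x"], ["GGGG", "TTTT"], "dna")
    cat, parts = concat_alignment({"p1": a1, "p2": a2})
    assert cat.n_columns == 7
    assert cat.row("x") == "AAATTTT"
    assert parts == [("p1", 0, 3), ("p2", 3, 7)]
    (one, _) = concat_alignment({"only": a1})
    assert one.rows == [a1.row(t) for t in sorted(a1.taxa)]
    with pytest.raises(ValueError, match="z"):
        concat_alignment({"p1": a1, "p3": MultipleAlignment(["x", "z"], ["A", "C"], "dna")})


def test_quartet_species_tree_majority_and_optimum():
    gts = ["((A,B),(C,D));"] * 3 + ["((A,C),(B,D));"]
    nwk, score, max_score = quartet_species_tree(gts)
    assert tree_splits(nwk) == tree_splits("((A,B),(C,D));")
    assert score == 3 and max_score == 4
    same = ["(((A,B),C),(D,E));"] * 5
    nwk2, score2, max2 = quartet_species_tree(same)
    assert tree_splits(nwk2) == tree_splits(same[0])
    assert score2 == max2 == 5 * 5  # C(5,4)=5 quartets, all matched
    with pytest.raises(ValueError, match="bound"):
        quartet_species_tree(["((A,B),(C,D));"], taxa=list("ABCDEFGHI"))


def test_quartet_score_is_exhaustive_optimum():
    rng = np.random.default_rng(11)
    taxa = list("ABCDEF")
    gts = []
    for _ in range(7):
        M, _ = _random_additive_tree(taxa, rng)
        gts.append(nj_tree(taxa, M))
    nwk, score, _ = quartet_species_tree(gts, taxa)
    # independent rescoring of the winner and a few alternatives
    import itertools

    def rescore(candidate):
        total = 0
        for quartet in itertools.combinations(taxa, 4):
            cand_side = _induced(candidate, quartet)
            for g in gts:
                if cand_side is not None and _induced(g, quartet) == cand_side:
                    total += 1
        return total

    def _induced(nwk_str, quartet):
        for s in tree_splits(nwk_str, taxa):
            inter = frozenset(quartet) & s
            if len(inter) == 2:
                return frozenset([inter, frozenset(quartet) - inter])
        return None

    assert rescore(nwk) == score
    for alt in ["((A,B),((C,D),(E,F)));", "((A,F),((B,E),(C,D)));"]:
        assert rescore(alt) <= score
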