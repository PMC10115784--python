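"""K-mer counting (vs naive recount), phasing, enrichment (vs exact
hypergeometric tails), exchange calling and read classification."""
import math

import numpy as np
import pandas as pd
import pytest

from polyploidkit import _seq, phasing, simulate
from polyphase_helpers import best_assignment_accuracy  # noqa: F401  (helper module)
from polyploidkit.phasing import (
    ExchangeSegment,
    assign_interval,
    call_exchanges,
    cluster_chromosomes,
    count_kmers,
    kmer_codes,
    read_composition,
    select_differential_kmers,
    specific_kmer_sets,
    window_calls,
    window_enrichment,
)


def naive_canonical_counts(seq: str, k: int) -> dict:
    """Dictionary-based recount oracle with string reverse complements."""
    out = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k].upper()
        if set(w) - set("ACGT"):
            continue
        canon = min(w, _seq.revcomp(w))
        out[canon] = out.get(canon, 0) + 1
    return out


def test_kmer_window_arithmetic_and_canonical_strands():
    assert kmer_codes("ACGTACGT", 3).shape[0] == 6
    a = kmer_codes("ACGTT", 5)
    b = kmer_codes(_seq.revcomp("ACGTT"), 5)
    assert a.tolist() == b.tolist()
    with pytest.raises(ValueError, match="odd"):
        kmer_codes("ACGTACGTACGT", 4)


def test_counts_equal_naive_recount_on_random_sequence():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), 10_000))
    seq = seq[:5000] + "N" + seq[5000:]  # ambiguity breaks windows
    k = 15
    matrix = count_kmers({"chr1": seq}, k)
    oracle = naive_canonical_counts(seq, k)
    got = {
        phasing.decode_kmer(int(c), k): int(n)
        for c, n in zip(matrix.kmers, matrix.counts[0])
    }
    assert got == oracle
    assert matrix.counts.sum() == sum(oracle.values())


def test_differential_selection_keeps_private_and_drops_uniform_kmers():
    motif = "ACGTGGTCAGTTACG"  # one 15-mer
    uniform = "TTGACCAGTGGCATA"
    chroms = {
        "c1": (motif + "N") * 30 + (uniform + "N") * 10,
        "c2": (uniform + "N") * 10,
        "c3": (uniform + "N") * 10,
    }
    m = count_kmers(chroms, 15)
    diff = select_differential_kmers(m, min_fold=2.0, min_count=10)
    kept = {phasing.decode_kmer(int(c), 15) for c in diff.kmers}
    canon = lambda s: min(s, _seq.revcomp(s))
    assert canon(motif) in kept
    assert canon(uniform) not in kept


def test_planted_repeat_kmers_are_selected(small_result):
    truth = small_result.truth
    seqs = small_result.genomes["octoploid"]
    k = 15
    matrix = count_kmers(seqs, k, min_total=10)
    diff = select_differential_kmers(matrix, min_fold=2.0, min_count=10)
    kept = set(diff.kmers.tolist())
    planted = set()
    for motif in truth.repeat_motifs.values():
        planted |= set(kmer_codes(motif, k).tolist())
    present = {
        c for c, tot in zip(matrix.kmers.tolist(), matrix.counts.sum(axis=0).tolist())
        if c in planted and tot >= 10
    }
    assert present, "no planted k-mers present at depth"
    assert len(present & kept) / len(present) >= 0.99
    # background: retained set should be dominated by planted repeat/LTR k-mers
    ltr_kmers = set()
    for t in truth.ltr_templates.values():
        ltr_kmers |= set(kmer_codes(t, k).tolist())
    foreign = kept - planted - ltr_kmers
    assert len(foreign) / max(len(kept), 1) <= 0.10


def test_clean_planted_clusters_are_recovered_exactly(small_result, phased_octoploid):
    truth_map = small_result.truth.chrom_subgenome("octoploid")
    acc = best_assignment_accuracy(phased_octoploid.assignment, truth_map)
    assert acc == 1.0


def test_clustering_invariant_to_kmer_column_permutation(small_result):
    seqs = small_result.genomes["octoploid"]
    m = count_kmers(seqs, 15, min_total=10)
    diff = select_differential_kmers(m)
    a1 = cluster_chromosomes(diff, 4, seed=0)
    rng = np.random.default_rng(0)
    perm = rng.permutation(diff.kmers.shape[0])
    shuffled = phasing.KmerMatrix(
        diff.chroms, diff.lengths, diff.kmers[perm], diff.counts[:, perm], diff.k
    )
    a2 = cluster_chromosomes(shuffled, 4, seed=0)
    assert a1 == a2


def test_degenerate_all_zero_chromosome_is_an_error():
    m = phasing.KmerMatrix(
        ["c1", "c2"], np.array([100, 100]), np.array([1], dtype=np.uint64),
        np.array([[5], [0]]), 15,
    )
    with pytest.raises(ValueError, match="c2"):
        cluster_chromosomes(m, 2)


def _toy_enrichment():
    """Two specific 15-mers; windows built from spaced planted copies."""
    kA = "ACGTGGTCAGTTACG"
    kB = "TTGACCAGTGGCATA"
    win = 2000

    def window(content):
        s = "".join(content)
        return s + "N" * (win - len(s))

    chrom = (
        window([kA + "NN"] * 10)          # A-heavy window
        + window([kB + "NN"] * 10)        # B-heavy window
        + window([kA + "NN"] * 5 + [kB + "NN"] * 5)  # mixed
        + window([])                       # empty
    )
    sets = {
        "A": np.sort(kmer_codes(kA, 15)),
        "B": np.sort(kmer_codes(kB, 15)),
    }
    return {"chr1": chrom}, sets, win


def exact_hypergeom_sf(k, N, K, n) -> float:
    """Exact upper tail P(X >= k) by direct enumeration with math.comb."""
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)


def test_enrichment_pvalues_match_exact_tail_enumeration():
    seqs, sets, win = _toy_enrichment()
    df = window_enrichment(seqs, sets, 15, window_size=win)
    occ = {lab: int(df[df["label"] == lab]["count"].sum()) for lab in sets}
    N = sum(occ.values())
    for row in df.itertuples():
        expected = exact_hypergeom_sf(row.count, N, occ[row.label], row.total)
        assert row.p == pytest.approx(expected, rel=1e-9), (row.chrom, row.start, row.label)
    calls = window_calls(df)
    assert calls.iloc[0]["call"] == "A"
    assert calls.iloc[1]["call"] == "B"
    assert calls.iloc[3]["call"] is None  # no specific k-mers -> no label


def test_window_tiling_covers_chromosomes_without_gaps(phased_octoploid, small_result):
    seqs = small_result.genomes["octoploid"]
    calls = phased_octoploid.calls
    for chrom, grp in calls.groupby("chrom"):
        grp = grp.sort_values("start")
        assert grp["start"].iloc[0] == 0
        assert (grp["start"].iloc[1:].to_numpy() == grp["end"].iloc[:-1].to_numpy()).all()
        assert grp["end"].iloc[-1] == len(seqs[chrom])
    with pytest.raises(ValueError, match="window_size"):
        window_enrichment(seqs, phased_octoploid.specific_sets, 15, window_size=7)


def _calls_frame(labels, win=10_000):
    rows = [("chr1", i * win, (i + 1) * win, lab) for i, lab in enumerate(labels)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "call"])


def test_exchange_run_rules():
    host = {"chr1": "A"}
    win = 10_000
    # single discordant window below the length threshold: no call
    calls = _calls_frame(["A", "B", "A", "A", "A", "A"])
    assert call_exchanges(host, calls, 5 * win) == []
    # an 8-window discordant run: one segment with the right donor
    calls = _calls_frame(["A"] + ["B"] * 8 + ["A", "A"])
    segs = call_exchanges(host, calls, 5 * win)
    assert len(segs) == 1
    seg = segs[0]
    assert (seg.start, seg.end, seg.donor, seg.host) == (win, 9 * win, "B", "A")
    # two runs separated by more than max_bridge_windows none-calls
    calls = _calls_frame(["B"] * 5 + [None, None] + ["B"] * 5 + ["A"])
    segs = call_exchanges(host, calls, 5 * win, max_bridge_windows=1)
    assert len(segs) == 2
    # ... but a single none-call inside a run bridges it
    calls = _calls_frame(["B"] * 5 + [None] + ["B"] * 5 + ["A"])
    segs = call_exchanges(host, calls, 5 * win, max_bridge_windows=1)
    assert len(segs) == 1 and segs[0].n_windows == 10


def test_assign_interval_midpoint_rule():
    assignment = {"chr1": "A"}
    segs = [ExchangeSegment("chr1", 100, 200, "A", "B", 5, 100)]
    assert assign_interval(assignment, segs, "chr1", 120, 180) == "B"
    assert assign_interval(assignment, segs, "chr1", 300, 400) == "A"
    assert assign_interval(assignment, segs, "chr1", 180, 260) == "A"  # midpoint 220
    assert assign_interval(assignment, segs, "chr1", 60, 260) == "B"   # midpoint 160
    with pytest.raises(ValueError, match="outside"):
        assign_interval(assignment, segs, "chr1", -5, 10)
    with pytest.raises(ValueError, match="unknown"):
        assign_interval(assignment, segs, "chrX", 0, 10)


def test_reads_from_one_subgenome_classify_to_it(small_result, phased_octoploid):
    truth_map = small_result.truth.chrom_subgenome("octoploid")
    seqs = small_result.genomes["octoploid"]
    a_chroms = {c: s for c, s in seqs.items() if truth_map[c] == "A"}
    reads = simulate.simulate_reads(a_chroms, 100, 1.0, seed=8, labels={c: "A" for c in a_chroms})
    df, totals = read_composition(
        reads, phased_octoploid.specific_sets, phased_octoploid.assignment, seqs, 15, 20_000
    )
    # which sg label is subgenome A?
    lab_votes = {}
    for c, lab in phased_octoploid.assignment.items():
        lab_votes[lab] = truth_map[c]
    assigned = {k: v for k, v in totals.items() if k != "unassigned"}
    n_assigned = sum(assigned.values())
    a_lab = [lab for lab, sub in lab_votes.items() if sub == "A"][0]
    assert n_assigned > 100
    assert assigned[a_lab] / n_assigned >= 0.95
    # reads without specific k-mers and too-short reads stay unassigned
    class R:
        seq = "ACG"
    _, t2 = read_composition([R()], phased_octoploid.specific_sets,
                             phased_octoploid.assignment, seqs, 15, 20_000)
    assert t2["unassigned"] == 1


def test_equal_subgenome_mixture_splits_by_repeat_content(small_result, phased_octoploid):
    """Reads from an equal-coverage A+C mixture classify to the two clusters
    in proportion to the planted classifiable (repeat/LTR) content, within 3
    binomial standard errors — and never to the B/D clusters."""
    truth_map = small_result.truth.chrom_subgenome("octoploid")
    seqs = small_result.genomes["octoploid"]
    mix = {c: s for c, s in seqs.items() if truth_map[c] in ("A", "C")}
    reads = simulate.simulate_reads(mix, 100, 0.5, seed=9, labels=truth_map)
    _, totals = read_composition(
        reads, phased_octoploid.specific_sets, phased_octoploid.assignment, seqs, 15, 20_000
    )
    lab_of = {truth_map[c]: phased_octoploid.assignment[c] for c in mix}
    nA, nC = totals[lab_of["A"]], totals[lab_of["C"]]
    n = nA + nC
    assert n > 500
    # multinomial expectation: a read classifies when it covers planted
    # repeat/LTR content, so the A share follows the planted content share
    bp = {"A": 0, "C": 0}
    for r in small_result.truth.repeats + small_result.truth.ltrs:
        if r["genome"] == "octoploid" and r["subgenome"] in bp:
            bp[r["subgenome"]] += r["end"] - r["start"]
    p_a = bp["A"] / (bp["A"] + bp["C"])
    assert abs(nA / n - p_a) < 3 * np.sqrt(p_a * (1 - p_a) / n)
    # no leakage into the subgenomes absent from the mixture
    others = [v for k, v in totals.items() if k not in (lab_of["A"], lab_of["C"], "unassigned")]
    assert sum(others) <= 0.01 * n
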