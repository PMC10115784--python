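"""Simulator contracts: determinism, copy ratios, clock calibration, truth."""
import numpy as np
import pytest

from polyploidkit import _seq, simulate
from polyploidkit.simulate import (
    Exchange,
    Hybridization,
    ScenarioError,
    reticulate_scenario,
    simulate_reads,
    simulate_scenario,
)

from conftest import anchor_copies, gene_seq


def tiny_spec(**kw):
    defaults = dict(
        n_chromosomes_per_subgenome=2,
        chrom_length=60_000,
        n_gene_families=12,
        seed=1,
        repeat=simulate.RepeatProfile(burst_rate=3.0),
        ltr=simulate.LtrProfile(rate=2.0),
    )
    defaults.update(kw)
    return reticulate_scenario(**defaults)


def test_identical_seed_gives_byte_identical_output():
    r1 = simulate_scenario(tiny_spec())
    r2 = simulate_scenario(tiny_spec())
    assert r1.genomes == r2.genomes
    assert r1.annotations == r2.annotations
    assert r1.truth.ltrs == r2.truth.ltrs
    r3 = simulate_scenario(tiny_spec(seed=2))
    assert r3.genomes != r1.genomes


def test_zero_rate_limit_gives_identical_homologs():
    res = simulate_scenario(tiny_spec(subst_rate=0.0))
    by = anchor_copies(res)
    for fam, copies in by.items():
        seqs = {gene_seq(res, t) for t in copies.values()}
        assert len(seqs) == 1, f"family {fam} copies differ at rate 0"


def test_copy_ratio_is_exactly_1_2_4(small_result):
    by = anchor_copies(small_result)
    assert len(by) == small_result.spec.n_gene_families
    for fam, copies in by.items():
        genomes = sorted(c[0] for c in copies)
        assert genomes == ["octoploid"] * 4 + ["outgroup"] + ["tetraploid"] * 2


def test_single_copy_families_one_per_genome(small_result):
    singles = {}
    for t in small_result.truth.genes:
        if t["kind"] == "single":
            singles.setdefault(t["family"], []).append(t["genome"])
    assert len(singles) == small_result.spec.n_single_copy_families
    for genomes in singles.values():
        assert sorted(genomes) == ["octoploid", "outgroup", "tetraploid"]


def test_pairwise_divergence_matches_jc_clock(small_result):
    """Mean p-distance between subgenome copies matches 2*t*rate after JC
    inversion, within 3 binomial standard errors (pooled over sites)."""
    res = small_result
    rate = res.spec.subst_rate
    by = anchor_copies(res)
    for c1, c2 in [
        (("octoploid", "A"), ("octoploid", "B")),      # t = 5.0
        (("tetraploid", "A"), ("octoploid", "A")),     # t = 0.44
        (("octoploid", "D"), ("outgroup", "outgroup")),  # t = 6.5
    ]:
        t = res.truth.true_divergence(c1, c2)
        p_exp = _seq.jc_expected_p(2 * t * rate)
        diffs = sites = 0
        for copies in by.values():
            a, b = gene_seq(res, copies[c1]), gene_seq(res, copies[c2])
            ca, cb = _seq.encode(a), _seq.encode(b)
            diffs += int((ca != cb).sum())
            sites += len(a)
        p_obs = diffs / sites
        se = np.sqrt(p_exp * (1 - p_exp) / sites)
        assert abs(p_obs - p_exp) < 3 * se, (c1, c2, p_obs, p_exp)


def test_divergence_is_monotone_in_time(small_result):
    res = small_result
    by = anchor_copies(res)
    pairs = sorted(
        {
            (res.truth.true_divergence(c1, c2), c1, c2)
            for copies in by.values()
            for c1 in copies
            for c2 in copies
            if c1 < c2
        }
    )

    def mean_p(c1, c2):
        vals = [
            _seq.p_distance(gene_seq(res, c[c1]), gene_seq(res, c[c2]))
            for c in by.values()
        ]
        return float(np.mean(vals))

    by_time = {}
    for t, c1, c2 in pairs:
        by_time.setdefault(t, []).append(mean_p(c1, c2))
    times = sorted(by_time)
    means = [float(np.mean(by_time[t])) for t in times]
    assert means == sorted(means)


def test_time_ordering_violations_are_rejected():
    with pytest.raises(ScenarioError, match="AC"):
        spec = tiny_spec(
            hybridizations=(
                Hybridization("A", "C", "AC", 6.5),  # older than A-C divergence (6.0)
                Hybridization("B", "D", "BD", 0.91),
                Hybridization("AC", "BD", "ACBD", 0.44),
            )
        )
        simulate_scenario(spec)
    with pytest.raises(ScenarioError, match="coordinates"):
        simulate_scenario(tiny_spec(exchanges=(Exchange("B", "C", 0, 0, 99_000_000, 0.1),)))
    with pytest.raises(ScenarioError, match="host nucleus"):
        simulate_scenario(tiny_spec(exchanges=(Exchange("B", "C", 0, 1000, 5000, 2.0),)))


def test_repeat_and_ltr_timestamps_inside_activity_windows(small_result):
    windows = small_result.truth.activity_windows
    for r in small_result.truth.repeats:
        # contaminated copies keep their library owner's label but were
        # inserted in the host's window; the default scenario is clean
        young, old = windows[r["subgenome"]]
        assert young <= r["time"] <= old
    for l in small_result.truth.ltrs:
        young, old = windows[l["subgenome"]]
        assert young <= l["age"] <= old


def test_ltr_terminal_repeats_diverge_with_age(small_result):
    res = small_result
    rate = res.spec.subst_rate
    young = [l for l in res.truth.ltrs if l["age"] < 2.0]
    old = [l for l in res.truth.ltrs if l["age"] > 5.0]

    def mean_ltr_p(elements):
        vals = []
        for l in elements:
            seq = res.genomes[l["genome"]][l["chrom"]]
            n = l["ltr_length"]
            vals.append(_seq.p_distance(seq[l["start"] : l["start"] + n], seq[l["end"] - n : l["end"]]))
        return float(np.mean(vals))

    assert mean_ltr_p(young) < mean_ltr_p(old)
    ages = np.array([l["age"] for l in res.truth.ltrs])
    exp = _seq.jc_expected_p(2 * rate * ages).mean()
    obs = mean_ltr_p(res.truth.ltrs)
    assert abs(obs - exp) < 0.1 * exp + 0.002


def test_exchange_transfers_donor_sequence():
    W = 20_000
    spec = tiny_spec(
        chrom_length=200_000,
        exchanges=(Exchange("B", "C", 0, 60_000, 140_000, 0.2),),
    )
    res = simulate_scenario(spec)
    assert len(res.truth.exchanges) == 1
    ex = res.truth.exchanges[0]
    assert ex["donor"] == "B" and ex["recipient"] == "C"
    # recipient interval sequence is the donor's segment plus ~2*t*rate drift
    chrom_sub = res.truth.chrom_subgenome("octoploid")
    rec_seq = res.genomes["octoploid"][ex["chrom"]][ex["start"] : ex["end"]]
    donors = [c for c, s in chrom_sub.items() if s == "B"]
    # homologous donor chromosome: same group as the recipient chromosome
    groups = {c["chrom"]: c["group"] for c in res.truth.chromosomes if c["genome"] == "octoploid"}
    donor_chrom = [c for c in donors if groups[c] == groups[ex["chrom"]]][0]
    donor_seq = res.genomes["octoploid"][donor_chrom]
    # the exchanged block should align near-perfectly somewhere on the donor
    probe = rec_seq[1000:3000]
    best = _best_window_identity(donor_seq, probe)
    assert best > 0.98
    # and poorly against the recipient's own (pre-exchange) homolog elsewhere
    res0 = simulate_scenario(tiny_spec(chrom_length=200_000))
    orig = res0.genomes["octoploid"][ex["chrom"]]
    assert _best_window_identity(orig, probe) < 0.95


def _best_window_identity(haystack: str, probe: str) -> float:
    ca = _seq.encode(haystack)
    cb = _seq.encode(probe)
    best = 0.0
    for off in range(0, len(ca) - len(cb), 200):
        ident = float((ca[off : off + len(cb)] == cb).mean())
        best = max(best, ident)
    return best


def test_read_simulation_counts_and_labels(small_result):
    seqs = small_result.genomes["octoploid"]
    labels = small_result.truth.chrom_subgenome("octoploid")
    reads = simulate_reads(seqs, read_length=100, coverage=2.0, seed=5, labels=labels)
    total_len = sum(len(s) for s in seqs.values())
    expected = 2.0 * total_len / 100
    assert abs(len(reads) - expected) < 5 * np.sqrt(expected)
    reads2 = simulate_reads(seqs, read_length=100, coverage=2.0, seed=5, labels=labels)
    assert reads == reads2
    # label counts proportional to subgenome lengths (multinomial expectation)
    sub_len = {}
    for c, s in seqs.items():
        sub_len[labels[c]] = sub_len.get(labels[c], 0) + len(s)
    from collections import Counter

    obs = Counter(r.label for r in reads)
    for sub, L in sub_len.items():
        p = L / total_len
        exp = p * len(reads)
        se = np.sqrt(len(reads) * p * (1 - p))
        assert abs(obs[sub] - exp) < 5 * se


def test_read_length_longer_than_chromosome_errors(small_result):
    with pytest.raises(ValueError, match="read_length"):
        simulate_reads(small_result.genomes["outgroup"], 10**9, 1.0, seed=0)


def test_writers_roundtrip(tmp_path, small_result):
    simulate.write_fasta(tmp_path / "g.fa", small_result.genomes["outgroup"])
    text = (tmp_path / "g.fa").read_text().splitlines()
    assert text[0].startswith(">")
    assert all(len(l) <= 80 for l in text)
    simulate.write_gff3(tmp_path / "g.gff3", small_result.annotations, genome="outgroup")
    lines = [l for l in (tmp_path / "g.gff3").read_text().splitlines() if not l.startswith("#")]
    ann = [a for a in small_result.annotations if a.genome == "outgroup"]
    assert len(lines) == 3 * len(ann)  # gene + mRNA + CDS
    first = lines[0].split("\t")
    assert int(first[3]) == ann[0].start + 1 and int(first[4]) == ann[0].end
    reads = simulate_reads(small_result.genomes["outgroup"], 50, 0.1, seed=1)
    simulate.write_fastq(tmp_path / "r.fq", reads)
    fq = (tmp_path / "r.fq").read_text().splitlines()
    assert len(fq) == 4 * len(reads)
    assert set(fq[3]) == {"I"}
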