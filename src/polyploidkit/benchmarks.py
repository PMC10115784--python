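"""Parameter-recovery benchmarks on simulated scenarios with known truth.

Each function simulates scenarios at the package's standard desk-scale study
conditions, runs the corresponding analysis end to end, and scores the result
against the simulator's truth tables.  They back both the validation test
suite and the reproduction script.
"""
from __future__ import annotations

from itertools import permutations

from . import dating, phasing, simulate, trees
from .census import census as run_census

__all__ = [
    "ROLE_OF_COPY",
    "best_assignment_accuracy",
    "anchor_gene_trees",
    "census_discrimination",
    "phasing_accuracy",
    "exchange_benchmark",
    "ltr_window_ordering",
    "dating_recovery",
    "calibration_identity",
]

ROLE_OF_COPY = {
    ("outgroup", "outgroup"): "O",
    ("tetraploid", "A"): "T1",
    ("tetraploid", "C"): "T2",
    ("octoploid", "A"): "P1",
    ("octoploid", "B"): "P2",
    ("octoploid", "C"): "P3",
    ("octoploid", "D"): "P4",
}


def best_assignment_accuracy(assignment: dict, truth: dict) -> float:
    """Chromosome-assignment accuracy under the best cluster-label matching."""
    labels = sorted(set(assignment.values()))
    subs = sorted(set(truth.values()))
    chroms = sorted(assignment)
    best = 0.0
    for perm in permutations(subs, len(labels)):
        mapping = dict(zip(labels, perm))
        acc = sum(mapping[assignment[c]] == truth[c] for c in chroms) / len(chroms)
        best = max(best, acc)
    return best


def _anchor_copies(result):
    by = {}
    for t in result.truth.genes:
        if t["kind"] == "anchor":
            by.setdefault(t["family"], {})[(t["genome"], t["subgenome"])] = t
    return by


def _gene_seq(result, row):
    return result.genomes[row["genome"]][row["chrom"]][row["start"] : row["end"]]


def anchor_gene_trees(result):
    """NJ gene trees (rooted on the outgroup) for every complete anchor family."""
    rooted = []
    for copies in _anchor_copies(result).values():
        if len(copies) != 7:
            continue
        names = [ROLE_OF_COPY[c] for c in copies]
        rows = [_gene_seq(result, t) for t in copies.values()]
        aln = trees.MultipleAlignment(names, rows, "dna")
        taxa, D = trees.jc_distance_matrix(aln)
        rooted.append(trees.root_on_outgroup(trees.nj_tree(taxa, D), "O"))
    return rooted


def census_discrimination(seeds, n_families: int = 200):
    """Per-seed plurality tags for the reticulate and nested-WGD scenarios.

    Returns ``(n_reticulate_correct, n_wgd_correct, n_seeds)``: the number of
    seeds whose plurality census class carries the generating model's tag.
    """
    ret_ok = wgd_ok = 0
    for seed in seeds:
        spec = simulate.reticulate_scenario(
            n_chromosomes_per_subgenome=1,
            chrom_length=80_000 + 400 * n_families,
            n_gene_families=n_families,
            repeat=simulate.RepeatProfile(burst_rate=0.0),
            ltr=simulate.LtrProfile(rate=0.0),
            seed=seed,
        )
        cen = run_census(anchor_gene_trees(simulate.simulate_scenario(spec)))
        ret_ok += cen.plurality[3] == "reticulate-model"
        spec2 = simulate.autopolyploid_scenario(
            n_chromosomes_per_subgenome=1,
            chrom_length=80_000 + 400 * n_families,
            n_gene_families=n_families,
            seed=seed,
        )
        cen2 = run_census(anchor_gene_trees(simulate.simulate_scenario(spec2)))
        wgd_ok += cen2.plurality[3] == "WGD-model"
    return ret_ok, wgd_ok, len(list(seeds))


def phasing_accuracy(seeds, contamination: float = 0.0):
    """Chromosome->subgenome clustering accuracy per seed.

    Counts differential k-mers and clusters chromosomes (the assignment step
    of phasing); ``contamination`` is the fraction of repeat insertions drawn
    from a foreign subgenome's library.
    """
    accs = []
    for seed in seeds:
        spec = simulate.reticulate_scenario(
            n_chromosomes_per_subgenome=3,
            chrom_length=150_000,
            n_gene_families=30,
            repeat_contamination=contamination,
            seed=seed,
        )
        res = simulate.simulate_scenario(spec)
        seqs = res.genomes["octoploid"]
        matrix = phasing.count_kmers(seqs, 15, min_total=10)
        diff = phasing.select_differential_kmers(matrix)
        assignment = phasing.cluster_chromosomes(diff, 4, seed=0)
        accs.append(
            best_assignment_accuracy(assignment, res.truth.chrom_subgenome("octoploid"))
        )
    return accs


def _label_to_subgenome(assignment, truth_map):
    votes = {}
    for c, lab in assignment.items():
        votes.setdefault(lab, {}).setdefault(truth_map[c], 0)
        votes[lab][truth_map[c]] += 1
    return {lab: max(v, key=v.get) for lab, v in votes.items()}


def exchange_benchmark(seeds, clean_seeds=()):
    """Recall/precision of exchange calling on planted exchanges.

    Each seeded scenario plants two homoeologous exchanges well above the
    minimum length; a call matches a planted exchange when chromosome and
    donor agree and both boundaries lie within one window.  ``clean_seeds``
    run scenarios without exchanges and count any call as a false positive.
    Returns a dict with recall, precision, boundary hit rate and the false
    call count on clean scenarios.
    """
    W = 20_000
    matched_truth = total_truth = 0
    matched_calls = total_calls = 0
    boundary_ok = 0
    min_len = 5 * W
    for seed in seeds:
        exchanges = (
            simulate.Exchange("B", "C", 0, 60_000, 130_000, 0.2),
            simulate.Exchange("A", "D", 1, 80_000, 170_000, 0.3),
        )
        spec = simulate.reticulate_scenario(
            n_chromosomes_per_subgenome=2,
            chrom_length=250_000,
            n_gene_families=30,
            exchanges=exchanges,
            seed=seed,
        )
        res = simulate.simulate_scenario(spec)
        part = phasing.phase_genome(
            res.genomes["octoploid"], 4, k=15, min_total=10, seed=0,
            window_size=W, min_exchange_length=5 * W,
        )
        truth_map = res.truth.chrom_subgenome("octoploid")
        lab2sub = _label_to_subgenome(part.assignment, truth_map)
        # only exchanges at or above the minimum call length are recoverable
        truth_segments = [
            ex for ex in res.truth.exchanges if ex["end"] - ex["start"] >= min_len
        ]
        total_truth += len(truth_segments)
        total_calls += len(part.exchanges)
        for ex in truth_segments:
            for seg in part.exchanges:
                if (
                    seg.chrom == ex["chrom"]
                    and lab2sub.get(seg.donor) == ex["donor"]
                    and seg.start < ex["end"]
                    and ex["start"] < seg.end
                ):
                    matched_truth += 1
                    if abs(seg.start - ex["start"]) <= W and abs(seg.end - ex["end"]) <= W:
                        boundary_ok += 1
                    break
        for seg in part.exchanges:
            if any(
                seg.chrom == ex["chrom"]
                and lab2sub.get(seg.donor) == ex["donor"]
                and seg.start < ex["end"]
                and ex["start"] < seg.end
                for ex in res.truth.exchanges
            ):
                matched_calls += 1
    false_calls = 0
    for seed in clean_seeds:
        spec = simulate.reticulate_scenario(
            n_chromosomes_per_subgenome=2, chrom_length=250_000,
            n_gene_families=30, seed=seed,
        )
        res = simulate.simulate_scenario(spec)
        part = phasing.phase_genome(
            res.genomes["octoploid"], 4, k=15, min_total=10, seed=0,
            window_size=W, min_exchange_length=5 * W,
        )
        false_calls += len(part.exchanges)
    return dict(
        recall=matched_truth / total_truth if total_truth else float("nan"),
        precision=matched_calls / total_calls if total_calls else float("nan"),
        boundary_rate=boundary_ok / matched_truth if matched_truth else float("nan"),
        n_truth=total_truth,
        n_calls=total_calls,
        false_calls_on_clean=false_calls,
    )


def ltr_window_ordering(seeds):
    """Seeds whose LTR 95% CI ordering matches the planted windows.

    The planted activity windows make subgenomes B and D older than A and C;
    a seed counts as correct when upper(B) > upper(A) and upper(D) >
    upper(C) in the measured insertion-age CIs.
    """
    ok = 0
    for seed in seeds:
        spec = simulate.reticulate_scenario(
            n_chromosomes_per_subgenome=2, chrom_length=120_000,
            n_gene_families=20, seed=seed,
        )
        res = simulate.simulate_scenario(spec)
        mu = spec.subst_rate / 1e6
        elements = [l for l in res.truth.ltrs if l["genome"] == "octoploid"]
        ages = dating.ltr_ages(res.genomes["octoploid"], elements, mu)
        cis = dating.divergence_hybridization_window(ages, min_elements=20)
        ok += cis["B"].upper > cis["A"].upper and cis["D"].upper > cis["C"].upper
    return ok, len(list(seeds))


def dating_recovery(seed: int, n_families: int = 200):
    """Ks-ratio recovery of the planted deep divergence times.

    The calibration pair is outgroup vs tetraploid subgenome A (the root
    split); the queries are the four progenitor divergences.  Returns a list
    of dicts with true and estimated times and relative errors.
    """
    spec = simulate.reticulate_scenario(
        n_chromosomes_per_subgenome=2,
        chrom_length=40_000 + 220 * n_families,
        n_gene_families=n_families,
        repeat=simulate.RepeatProfile(burst_rate=0.0),
        ltr=simulate.LtrProfile(rate=0.0),
        seed=seed,
    )
    res = simulate.simulate_scenario(spec)
    by = _anchor_copies(res)

    def med(c1, c2):
        pairs = [
            (_gene_seq(res, copies[c1]), _gene_seq(res, copies[c2]))
            for copies in by.values()
            if c1 in copies and c2 in copies
        ]
        return dating.median_ks(pairs)

    O = ("outgroup", "outgroup")
    TA, TC = ("tetraploid", "A"), ("tetraploid", "C")
    PA, PB, PD = ("octoploid", "A"), ("octoploid", "B"), ("octoploid", "D")
    cal_pair = (O, TA)
    t_cal = res.truth.true_divergence(*cal_pair)
    ks_cal = med(*cal_pair)
    out = []
    for c1, c2 in [(O, PA), (TA, TC), (PA, PB), (PD, O)]:
        t_true = res.truth.true_divergence(c1, c2)
        est = dating.ks_ratio_dating(med(c1, c2), ks_cal, t_cal)
        out.append(
            dict(
                pair=f"{c1[0]}:{c1[1]}-{c2[0]}:{c2[1]}",
                true_my=t_true,
                estimated_my=est,
                rel_error=abs(est - t_true) / t_true,
            )
        )
    return out


def calibration_identity(seed: int = 0) -> float:
    """Formula check: a query with the calibration's own median Ks must date
    to exactly the calibration age (7.7 MY by default)."""
    spec = simulate.reticulate_scenario(
        n_chromosomes_per_subgenome=1, chrom_length=40_000, n_gene_families=30,
        repeat=simulate.RepeatProfile(burst_rate=0.0),
        ltr=simulate.LtrProfile(rate=0.0), seed=seed,
    )
    res = simulate.simulate_scenario(spec)
    by = _anchor_copies(res)
    pairs = [
        (_gene_seq(res, c[("outgroup", "outgroup")]), _gene_seq(res, c[("tetraploid", "A")]))
        for c in by.values()
    ]
    m = dating.median_ks(pairs)
    return dating.ks_ratio_dating(m, m)
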