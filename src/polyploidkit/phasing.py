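"""Subgenome phasing by differential k-mers, and homoeologous-exchange calling.

The phasing logic follows the differential-k-mer paradigm for neoallopolyploid
genomes: repetitive k-mers that expanded during one progenitor's independent
evolution (the divergence-hybridization period) mark that progenitor's
chromosomes.  Chromosomes are clustered on per-bp-normalized differential
k-mer counts with k-means; subgenome-specific k-mer sets are then fixed, and
sliding windows are tested for enrichment of each set with an exact
hypergeometric upper tail plus Benjamini-Hochberg FDR control.  Windows whose
enrichment contradicts their chromosome's assignment flag candidate
homoeologous exchanges; runs of such windows above a minimum length (5x the
window size by default, mirroring a 5 Mb cut-off at 1 Mb windows) become
exchange segments.  Reads are classified to subgenomes by their
specific-k-mer content to profile the genomic composition of a relative.

All k-mers are counted canonically (lexicographic minimum of a window and its
reverse complement), which requires odd k; ambiguous bases break windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import _seq

__all__ = [
    "KmerMatrix",
    "kmer_codes",
    "decode_kmer",
    "count_kmers",
    "select_differential_kmers",
    "cluster_chromosomes",
    "specific_kmer_sets",
    "window_enrichment",
    "window_calls",
    "ExchangeSegment",
    "call_exchanges",
    "assign_interval",
    "read_composition",
    "SubgenomePartition",
    "phase_genome",
]


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical strand-min k-mers are ambiguous for even k)")
    if not 1 <= k <= 31:
        raise ValueError("k must be between 1 and 31")


def kmer_codes(seq: str, k: int, with_positions: bool = False):
    """Canonical k-mer codes (uint64) for every valid window of a sequence.

    A window is valid when it contains no ambiguous base.  With
    ``with_positions`` also returns the 0-based window start positions.
    """
    _check_k(k)
    codes = _seq.encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return (empty, np.empty(0, dtype=np.int64)) if with_positions else empty
    bad = (codes > 3).astype(np.int32)
    c = np.where(codes > 3, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        fwd |= c[i : i + n] << np.uint64(2 * (k - 1 - i))
        rev |= (np.uint64(3) - c[i : i + n]) << np.uint64(2 * i)
    cs = np.concatenate([[0], np.cumsum(bad)])
    ok = (cs[k:] - cs[:-k]) == 0
    canon = np.minimum(fwd, rev)[ok]
    if with_positions:
        return canon, np.nonzero(ok)[0].astype(np.int64)
    return canon


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append("ACGT"[(int(code) >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


@dataclass
class KmerMatrix:
    """Per-chromosome counts of (a subset of) canonical k-mers."""

    chroms: list
    lengths: np.ndarray          # bp per chromosome
    kmers: np.ndarray            # sorted uint64 codes
    counts: np.ndarray           # (n_chroms, n_kmers) int64
    k: int

    def normalized(self) -> np.ndarray:
        """Counts per bp, row-wise."""
        return self.counts / self.lengths[:, None]

    def subset(self, mask) -> "KmerMatrix":
        return KmerMatrix(
            list(self.chroms), self.lengths.copy(), self.kmers[mask], self.counts[:, mask], self.k
        )


def count_kmers(sequences: dict, k: int, min_total: int = 1) -> KmerMatrix:
    """Count canonical k-mers per chromosome.

    ``min_total`` drops k-mers whose genome-wide count is below the
    threshold; raising it to, say, 10-20 restricts the matrix to repetitive
    k-mers and keeps memory proportional to repeat content rather than genome
    size.
    """
    _check_k(k)
    chroms = sorted(sequences)
    per_chrom = []
    for c in chroms:
        vals = kmer_codes(sequences[c], k)
        u, n = np.unique(vals, return_counts=True)
        per_chrom.append((u, n))
    if per_chrom:
        union = np.unique(np.concatenate([u for u, _ in per_chrom]))
    else:
        union = np.empty(0, dtype=np.uint64)
    totals = np.zeros(union.shape[0], dtype=np.int64)
    for u, n in per_chrom:
        totals[np.searchsorted(union, u)] += n
    keep = totals >= min_total
    union = union[keep]
    counts = np.zeros((len(chroms), union.shape[0]), dtype=np.int64)
    for i, (u, n) in enumerate(per_chrom):
        idx = np.searchsorted(union, u)
        ok = (idx < union.shape[0]) & (union[np.minimum(idx, union.shape[0] - 1)] == u)
        counts[i, idx[ok]] = n[ok]
    lengths = np.array([len(sequences[c]) for c in chroms], dtype=np.int64)
    return KmerMatrix(chroms, lengths, union, counts, k)


def select_differential_kmers(
    matrix: KmerMatrix, min_fold: float = 2.0, min_count: int = 10
) -> KmerMatrix:
    """Retain k-mers concentrated on a subset of chromosomes.

    A k-mer is differential when its largest per-bp chromosome count is at
    least ``min_fold`` times its mean per-bp count over all chromosomes, and
    its genome-wide raw count is at least ``min_count``.  Uniformly
    distributed k-mers fail the fold criterion; k-mers private to one
    chromosome group pass it.
    """
    if matrix.kmers.size == 0:
        return matrix
    norm = matrix.normalized()
    top = norm.max(axis=0)
    mean = norm.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean > 0, top / np.where(mean > 0, mean, 1), np.inf)
    keep = (fold >= min_fold) & (matrix.counts.sum(axis=0) >= min_count)
    return matrix.subset(keep)


def cluster_chromosomes(
    matrix: KmerMatrix,
    n_subgenomes: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> dict:
    """Assign chromosomes to subgenomes by k-means on differential k-mers.

    Rows are per-bp normalized and columns standardized before clustering;
    the best of ``n_restarts`` runs by inertia wins.  Cluster labels are
    renamed canonically (largest cluster first, ties by first chromosome
    index) to ``sg1..sgN`` for determinism.
    """
    from sklearn.cluster import KMeans

    n_chroms = len(matrix.chroms)
    if n_subgenomes > n_chroms:
        raise ValueError("more subgenomes than chromosomes")
    X = matrix.normalized()
    zero = (X.sum(axis=1) == 0)
    if zero.any():
        bad = [matrix.chroms[i] for i in np.nonzero(zero)[0]]
        raise ValueError(
            f"chromosomes with no differential k-mers: {bad}; "
            "lower min_count/min_fold or change k"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(
        n_clusters=n_subgenomes,
        n_init=n_restarts,
        random_state=int(seed) % (2**32),
    ).fit(Z)
    labels = km.labels_
    order = sorted(
        range(n_subgenomes),
        key=lambda c: (-(labels == c).sum(), int(np.nonzero(labels == c)[0][0])),
    )
    rename = {c: f"sg{i + 1}" for i, c in enumerate(order)}
    return {chrom: rename[labels[i]] for i, chrom in enumerate(matrix.chroms)}


def specific_kmer_sets(
    matrix: KmerMatrix,
    assignment: dict,
    min_fold: float = 2.0,
    min_count: int = 10,
) -> dict:
    """Subgenome-specific k-mer sets given a chromosome assignment.

    A k-mer is specific to a subgenome when that subgenome's per-bp count is
    at least ``min_fold`` times every other subgenome's, and its raw total is
    at least ``min_count``.  Returns label -> sorted uint64 code array.
    """
    labels = sorted(set(assignment.values()))
    rows = {lab: [i for i, c in enumerate(matrix.chroms) if assignment[c] == lab] for lab in labels}
    group_norm = np.zeros((len(labels), matrix.kmers.shape[0]))
    for gi, lab in enumerate(labels):
        idx = rows[lab]
        group_norm[gi] = matrix.counts[idx].sum(axis=0) / matrix.lengths[idx].sum()
    totals = matrix.counts.sum(axis=0)
    out = {}
    for gi, lab in enumerate(labels):
        others = np.delete(group_norm, gi, axis=0)
        other_max = others.max(axis=0) if others.size else np.zeros(matrix.kmers.shape[0])
        own = group_norm[gi]
        keep = (totals >= min_count) & (own > 0) & (own >= min_fold * np.maximum(other_max, 1e-300)) & (
            (other_max == 0) | (own / np.maximum(other_max, 1e-300) >= min_fold)
        )
        out[lab] = np.sort(matrix.kmers[keep])
    return out


def window_enrichment(
    sequences: dict,
    specific_sets: dict,
    k: int,
    window_size: int = 1_000_000,
    step: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window enrichment of each subgenome-specific k-mer set.

    For each window and set, an exact hypergeometric upper-tail p-value asks
    whether the window's share of that set's occurrences exceeds the
    genome-wide expectation given the window's total specific-k-mer content;
    Benjamini-Hochberg FDR is applied across all window x set tests.  Returns
    a tidy frame (chrom, start, end, label, count, total, p, q, enriched)
    where ``enriched`` marks the winning label per window (smallest q below
    ``alpha``).
    """
    if window_size < k:
        raise ValueError("window_size must be at least k")
    if step is None:
        step = window_size
    labels = sorted(specific_sets)
    rows = []
    occ = {lab: 0 for lab in labels}
    window_counts = []  # (chrom, start, end, {label: count})
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        vals, pos = kmer_codes(seq, k, with_positions=True)
        member_pos = {}
        for lab in labels:
            hit = pos[np.isin(vals, specific_sets[lab])]
            member_pos[lab] = hit
            occ[lab] += hit.shape[0]
        L = len(seq)
        starts = list(range(0, max(L - window_size, 0) + 1, step))
        if not starts:
            starts = [0]
        if starts[-1] + window_size < L:
            starts.append(starts[-1] + step)
        for s in starts:
            e = min(s + window_size, L)
            cts = {
                lab: int(
                    np.searchsorted(member_pos[lab], e, side="left")
                    - np.searchsorted(member_pos[lab], s, side="left")
                )
                for lab in labels
            }
            window_counts.append((chrom, s, e, cts))
    N = sum(occ.values())
    recs = []
    for chrom, s, e, cts in window_counts:
        n_window = sum(cts.values())
        for lab in labels:
            kk = cts[lab]
            if N == 0 or n_window == 0:
                p = 1.0
            else:
                p = float(hypergeom.sf(kk - 1, N, occ[lab], n_window))
            recs.append((chrom, s, e, lab, kk, n_window, p))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "label", "count", "total", "p"])
    df["q"] = _bh_fdr(df["p"].to_numpy())
    df["enriched"] = False
    for (chrom, s), grp in df.groupby(["chrom", "start"], sort=False):
        ok = grp[(grp["q"] < alpha) & (grp["count"] > 0)]
        if len(ok):
            best = ok.sort_values(["q", "p", "label"]).index[0]
            df.loc[best, "enriched"] = True
    return df


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def window_calls(enrichment: pd.DataFrame) -> pd.DataFrame:
    """One row per window with its enriched label (or None)."""
    rows = []
    for (chrom, s, e), grp in enrichment.groupby(["chrom", "start", "end"], sort=True):
        hit = grp[grp["enriched"]]
        label = hit["label"].iloc[0] if len(hit) else None
        rows.append((chrom, s, e, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "call"])


@dataclass
class ExchangeSegment:
    chrom: str
    start: int
    end: int
    host: str
    donor: str
    n_windows: int
    length: int
    borderline: bool = False


def call_exchanges(
    assignment: dict,
    calls: pd.DataFrame,
    min_exchange_length: int,
    max_bridge_windows: int = 1,
) -> list:
    """Exchange segments from runs of windows discordant with their chromosome.

    A run is a maximal series of windows enriched for a non-host subgenome,
    allowing up to ``max_bridge_windows`` interior windows with no call; a
    host-enriched window terminates the run.  Runs shorter than
    ``min_exchange_length`` (bp) are discarded; the donor is the modal
    discordant label (lexicographic tie-break).  Runs within one window of
    the length threshold are flagged borderline for manual review.
    """
    out = []
    for chrom, grp in calls.groupby("chrom", sort=True):
        host = assignment[chrom]
        grp = grp.sort_values("start")
        run = []  # discordant window rows
        bridge = 0
        win_len = int(grp["end"].iloc[0] - grp["start"].iloc[0]) if len(grp) else 0

        def flush():
            if not run:
                return
            start = int(run[0]["start"])
            end = int(run[-1]["end"])
            length = end - start
            if length >= min_exchange_length:
                donors = sorted(r["call"] for r in run)
                modal = max(set(donors), key=lambda d: (donors.count(d), d))
                out.append(
                    ExchangeSegment(
                        chrom=chrom,
                        start=start,
                        end=end,
                        host=host,
                        donor=modal,
                        n_windows=len(run),
                        length=length,
                        borderline=length < min_exchange_length + win_len,
                    )
                )

        for _, row in grp.iterrows():
            call = row["call"]
            if call is not None and call != host:
                run.append(row)
                bridge = 0
            elif call is None and run:
                bridge += 1
                if bridge > max_bridge_windows:
                    flush()
                    run, bridge = [], 0
            else:  # host-enriched window (or leading none)
                flush()
                run, bridge = [], 0
        flush()
    out.sort(key=lambda e: (e.chrom, e.start))
    return out


def assign_interval(
    assignment: dict, exchanges: list, chrom: str, start: int, end: int,
    chrom_length: int | None = None,
) -> str:
    """Subgenome of an interval: exchange donor at its midpoint, else host.

    An interval straddling an exchange boundary is classified by the segment
    containing its midpoint (documented midpoint rule).
    """
    if chrom not in assignment:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if start < 0 or end <= start or (chrom_length is not None and end > chrom_length):
        raise ValueError(f"interval [{start}, {end}) outside chromosome {chrom}")
    mid = (start + end) // 2
    for seg in exchanges:
        if seg.chrom == chrom and seg.start <= mid < seg.end:
            return seg.donor
    return assignment[chrom]


def read_composition(
    reads,
    specific_sets: dict,
    assignment: dict,
    sequences: dict,
    k: int,
    window_size: int = 1_000_000,
):
    """Classify reads to subgenomes by specific-k-mer content; profile depth.

    Each read is assigned to the subgenome whose specific k-mers it matches
    most (ties and zero matches leave it unassigned; reads shorter than k are
    unassigned).  Assigned reads are placed on the host genome at their first
    matching specific k-mer's position and tabulated per window.  Returns
    ``(per_window DataFrame, totals dict)``.
    """
    labels = sorted(specific_sets)
    index = {}
    for chrom in sorted(sequences):
        vals, pos = kmer_codes(sequences[chrom], k, with_positions=True)
        for lab in labels:
            hit = np.isin(vals, specific_sets[lab])
            for v, p in zip(vals[hit], pos[hit]):
                index.setdefault(int(v), (chrom, int(p)))
    totals = {lab: 0 for lab in labels}
    totals["unassigned"] = 0
    depth = {}
    for read in reads:
        seq = read.seq if hasattr(read, "seq") else read
        if len(seq) < k:
            totals["unassigned"] += 1
            continue
        vals = kmer_codes(seq, k)
        counts = [int(np.isin(vals, specific_sets[lab]).sum()) for lab in labels]
        best = max(counts)
        if best == 0 or counts.count(best) > 1:
            totals["unassigned"] += 1
            continue
        lab = labels[counts.index(best)]
        totals[lab] += 1
        placed = None
        members = specific_sets[lab]
        for v in vals:
            iv = int(v)
            if iv in index and np.searchsorted(members, v) < members.shape[0] and members[
                np.searchsorted(members, v)
            ] == v:
                placed = index[iv]
                break
        if placed is not None:
            chrom, p = placed
            key = (chrom, p // window_size * window_size, lab)
            depth[key] = depth.get(key, 0) + 1
    rows = [
        (chrom, s, min(s + window_size, len(sequences[chrom])), lab, n)
        for (chrom, s, lab), n in sorted(depth.items())
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "reads"])
    return df, totals


@dataclass
class SubgenomePartition:
    """Chromosome assignments, window calls and exchange segments."""

    assignment: dict
    specific_sets: dict
    enrichment: pd.DataFrame
    calls: pd.DataFrame
    exchanges: list = field(default_factory=list)
    k: int = 15
    window_size: int = 1_000_000


def phase_genome(
    sequences: dict,
    n_subgenomes: int,
    k: int = 15,
    min_total: int = 10,
    min_fold: float = 2.0,
    min_count: int = 10,
    n_restarts: int = 10,
    seed: int = 0,
    window_size: int = 1_000_000,
    alpha: float = 0.05,
    min_exchange_length: int | None = None,
    max_bridge_windows: int = 1,
    exclude_exchanges: bool = True,
) -> SubgenomePartition:
    """End-to-end phasing: count, select, cluster, enrich, call exchanges.

    With ``exclude_exchanges`` the subgenome-specific k-mer sets are
    recomputed once after masking called exchange segments (so exchanged
    repeats do not blur the sets), and windows/exchanges are re-called with
    the refined sets.
    """
    if min_exchange_length is None:
        min_exchange_length = 5 * window_size
    matrix = count_kmers(sequences, k, min_total=min_total)
    diff = select_differential_kmers(matrix, min_fold=min_fold, min_count=min_count)
    assignment = cluster_chromosomes(diff, n_subgenomes, n_restarts=n_restarts, seed=seed)
    sets = specific_kmer_sets(diff, assignment, min_fold=min_fold, min_count=min_count)
    enr = window_enrichment(sequences, sets, k, window_size, alpha=alpha)
    calls = window_calls(enr)
    exchanges = call_exchanges(assignment, calls, min_exchange_length, max_bridge_windows)
    if exclude_exchanges and exchanges:
        masked = dict(sequences)
        for seg in exchanges:
            s = masked[seg.chrom]
            masked[seg.chrom] = s[: seg.start] + "N" * (seg.end - seg.start) + s[seg.end :]
        matrix2 = count_kmers(masked, k, min_total=min_total)
        diff2 = select_differential_kmers(matrix2, min_fold=min_fold, min_count=min_count)
        sets = specific_kmer_sets(diff2, assignment, min_fold=min_fold, min_count=min_count)
        enr = window_enrichment(sequences, sets, k, window_size, alpha=alpha)
        calls = window_calls(enr)
        exchanges = call_exchanges(assignment, calls, min_exchange_length, max_bridge_windows)
    return SubgenomePartition(
        assignment=assignment,
        specific_sets=sets,
        enrichment=enr,
        calls=calls,
        exchanges=exchanges,
        k=k,
        window_size=window_size,
    )
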