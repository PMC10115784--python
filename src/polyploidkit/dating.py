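"""Molecular dating of subgenome divergence and hybridization.

Two complementary clocks:

* **LTR retrotransposon insertion ages.**  The two terminal repeats of an
  LTR-RT are identical at insertion and diverge afterwards, so their
  Jukes-Cantor distance K dates the insertion as T = K / (2 mu), with mu in
  substitutions/site/year.  Subgenome-specific elements burst during the
  divergence-hybridization period, so the symmetric 95% percentile interval
  of their ages brackets that period per subgenome.  Elements inside called
  exchange segments are excluded (their k-mer identity is misleading).

* **Ks-ratio dating.**  Under rate constancy, the synonymous distance Ks
  between two lineages is proportional to their divergence time, so
  T = Ks_query / Ks_calibration * T_calibration for any calibration pair of
  known age.  Ks is computed per syntenic gene pair with the Nei-Gojobori
  (1986) method and summarized per lineage pair by the median.

The mutation rate mu for LTR dating has no universal value and must be
supplied explicitly.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from . import _seq

__all__ = [
    "LtrAge",
    "ltr_insertion_age",
    "ltr_ages",
    "InsertionTimeCI",
    "divergence_hybridization_window",
    "KsRecord",
    "ng86_ka_ks",
    "median_ks",
    "ks_ratio_dating",
    "ks_distribution_peaks",
]


@dataclass
class LtrAge:
    p: float       # raw mismatch fraction between the two LTRs
    K: float       # JC-corrected divergence
    T: float       # insertion age, MY


def ltr_insertion_age(ltr5: str, ltr3: str, mu: float) -> LtrAge | None:
    """Insertion age of an LTR element from its two terminal repeats.

    ``mu`` is in substitutions/site/year; the returned age is in MY.
    Returns None (with a warning) for saturated pairs (p >= 0.75).
    """
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if len(ltr5) == len(ltr3):
        p = _seq.p_distance(ltr5, ltr3)
    else:
        p = _aligned_p(ltr5, ltr3)
    if p >= 0.75:
        warnings.warn(f"saturated LTR pair (p={p:.3f}); age undefined, element excluded")
        return None
    K = _seq.jc_correct(p)
    T = K / (2.0 * mu) / 1e6
    return LtrAge(p=p, K=K, T=T)


def _aligned_p(a: str, b: str) -> float:
    """Mismatch fraction over a global DNA alignment (for unequal lengths)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches
    return counts.mismatches / cols if cols else 0.0


def ltr_ages(
    sequences: dict,
    elements,
    mu: float,
    exclude_exchanged: bool = True,
) -> dict:
    """Ages of annotated LTR elements, grouped by subgenome.

    ``elements`` is an iterable of mappings with keys chrom, start, end,
    ltr_length, subgenome and (optionally) exchanged; LTR detection itself is
    delegated to annotation.  Returns subgenome -> list of ages (MY).
    """
    out = {}
    for el in elements:
        if exclude_exchanged and el.get("exchanged", False):
            continue
        seq = sequences[el["chrom"]]
        s, e, ltr_len = int(el["start"]), int(el["end"]), int(el["ltr_length"])
        age = ltr_insertion_age(seq[s : s + ltr_len], seq[e - ltr_len : e], mu)
        if age is not None:
            out.setdefault(el["subgenome"], []).append(age.T)
    return out


@dataclass
class InsertionTimeCI:
    subgenome: str
    n: int
    lower: float   # MY
    upper: float   # MY
    percentile: float = 95.0


def divergence_hybridization_window(
    ages_by_subgenome: dict,
    percentile: float = 95.0,
    min_elements: int = 20,
) -> dict:
    """Symmetric percentile bounds of LTR insertion ages per subgenome.

    The (100-percentile)/2 and (100+percentile)/2 percentiles of the
    subgenome-specific insertion ages estimate the hybridization (lower) and
    divergence (upper) boundaries of that subgenome's independent period.
    """
    out = {}
    for sub in sorted(ages_by_subgenome):
        ages = np.asarray(ages_by_subgenome[sub], dtype=float)
        if ages.shape[0] < min_elements:
            raise ValueError(
                f"subgenome {sub}: only {ages.shape[0]} datable elements "
                f"(minimum {min_elements})"
            )
        lo, hi = np.percentile(ages, [(100 - percentile) / 2, (100 + percentile) / 2])
        out[sub] = InsertionTimeCI(sub, int(ages.shape[0]), float(lo), float(hi), percentile)
    return out


# ----------------------------------------------------------------------
# NG86 Ka/Ks
# ----------------------------------------------------------------------

_BASES = "TCAG"


def _syn_fraction(codon: str, table: dict) -> float:
    """Synonymous site count of one codon (0..3): per position, the fraction
    of single-base changes that preserve the amino acid.  Changes to stop
    codons count as nonsynonymous."""
    aa = table[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if table[alt] != "*" and table[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _path_differences(c1: str, c2: str, table: dict):
    """Average synonymous/nonsynonymous difference counts between two codons.

    All substitution orders between the differing positions are enumerated;
    paths through stop codons are excluded (all paths are used if every path
    hits a stop).  Returns (syn, nonsyn)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[nxt] == "*" and nxt != c2:
                blocked = True
            if table[cur] != "*" and table[nxt] != "*" and table[cur] == table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((blocked, sd, nd))
    open_paths = [(s, n) for b, s, n in results if not b]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in results]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


@dataclass
class KsRecord:
    n_codons: int
    S: float       # synonymous sites (averaged over the two sequences)
    N: float       # nonsynonymous sites
    Sd: float      # synonymous differences (path-averaged)
    Nd: float      # nonsynonymous differences
    ps: float
    pn: float
    Ks: float
    Ka: float


def ng86_ka_ks(cds1: str, cds2: str) -> KsRecord:
    """Nei-Gojobori (1986) Ka/Ks for an aligned codon sequence pair.

    Gapped codons (any gap character in either sequence) are skipped; an
    internal stop codon raises with its codon index.  ps and pn are
    JC-corrected to Ks and Ka.
    """
    if len(cds1) != len(cds2):
        raise ValueError("aligned CDS lengths differ")
    if len(cds1) % 3:
        raise ValueError("aligned CDS length not divisible by 3")
    table = _seq.codon_table()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    n_total = len(cds1) // 3
    for ci in range(n_total):
        a = cds1[3 * ci : 3 * ci + 3].upper()
        b = cds2[3 * ci : 3 * ci + 3].upper()
        if "-" in a or "-" in b:
            continue
        if a not in table or b not in table:
            continue  # ambiguous bases
        for name, codon in (("first", a), ("second", b)):
            if table[codon] == "*" and ci < n_total - 1:
                raise ValueError(f"internal stop codon in {name} sequence at codon {ci}")
        if table[a] == "*" or table[b] == "*":
            continue  # terminal stop: not informative
        n_codons += 1
        S += (_syn_fraction(a, table) + _syn_fraction(b, table)) / 2.0
        sd, nd = _path_differences(a, b, table)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    N = 3.0 * n_codons - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        warnings.warn("saturated NG86 estimate; JC correction capped")
    Ks = max(0.0, float(_seq.jc_correct(min(ps, 0.749999))))
    Ka = max(0.0, float(_seq.jc_correct(min(pn, 0.749999))))
    return KsRecord(n_codons, S, N, Sd, Nd, ps, pn, Ks, Ka)


def mask_internal_stops(a: str, b: str) -> tuple:
    """Replace codons that are stops in either sequence by gap codons.

    Dropping whole pairs over an in-frame stop would preferentially discard
    the most diverged pairs and bias Ks down; masking just the offending
    codon keeps the pair comparable.
    """
    table = _seq.codon_table()
    out_a, out_b = [], []
    for i in range(0, len(a) - len(a) % 3, 3):
        ca, cb = a[i : i + 3].upper(), b[i : i + 3].upper()
        if table.get(ca) == "*" or table.get(cb) == "*":
            out_a.append("---")
            out_b.append("---")
        else:
            out_a.append(ca)
            out_b.append(cb)
    return "".join(out_a), "".join(out_b)


def median_ks(cds_pairs, mask_stops: bool = True) -> float:
    """Median NG86 Ks over aligned CDS pairs.

    With ``mask_stops`` (default), codons carrying an in-frame stop in either
    sequence are gap-masked before the NG86 computation; pairs that still
    fail are skipped.
    """
    values = []
    for a, b in cds_pairs:
        if mask_stops:
            a, b = mask_internal_stops(a, b)
        try:
            values.append(ng86_ka_ks(a, b).Ks)
        except ValueError:
            continue
    if not values:
        raise ValueError("no Ks values could be computed")
    return float(np.median(values))


def ks_ratio_dating(
    median_ks_query: float,
    median_ks_calibration: float,
    t_calibration: float = 7.7,
) -> float:
    """Divergence time from a Ks ratio against a calibration pair.

    T = Ks_query / Ks_calibration * T_calibration (MY), assuming an equal
    substitution rate per year across lineages.  The default calibration age
    of 7.7 MY is the tetraploid-outgroup split used by the source analyses;
    pass your own for other systems.
    """
    if median_ks_calibration <= 0:
        raise ValueError("calibration median Ks must be positive")
    if median_ks_query < 0:
        raise ValueError("query median Ks must be non-negative")
    return median_ks_query / median_ks_calibration * t_calibration


def ks_distribution_peaks(
    ks_values,
    bin_width: float = 0.01,
    cap: float | None = None,
    min_prominence_frac: float = 0.1,
):
    """Histogram of a Ks distribution with modal peak detection.

    Peaks are local maxima of the binned counts with prominence at least
    ``min_prominence_frac`` of the tallest bin.  Returns ``(edges, counts,
    peak_positions)``; an empty peak list means no detectable mode (e.g. no
    recent WGD signal in a paralog Ks distribution).
    """
    from scipy.signal import find_peaks

    values = np.asarray(list(ks_values), dtype=float)
    if values.shape[0] == 0:
        return np.array([0.0, bin_width]), np.array([0]), []
    if values.shape[0] < 50:
        warnings.warn("fewer than 50 Ks values; peak detection is unreliable")
    if cap is None:
        cap = float(values.max()) + bin_width
    values = values[values <= cap]
    edges = np.arange(0.0, cap + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    if counts.size == 0:
        return edges, counts, []
    prom = max(min_prominence_frac * counts.max(), 1.0)
    idx, _ = find_peaks(np.concatenate([[0], counts, [0]]), prominence=prom)
    idx = idx - 1
    centers = (edges[:-1] + edges[1:]) / 2
    return edges, counts, [float(centers[i]) for i in idx]
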