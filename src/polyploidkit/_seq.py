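"""Low-level nucleotide utilities shared by the simulator and the analysis modules.

Sequences are handled internally as ``numpy.uint8`` arrays with the encoding
A=0, C=1, G=2, T=3; anything else encodes to 255 ("ambiguous").  The
Jukes-Cantor helpers work on expected substitutions per site (d = rate * time).
"""
from __future__ import annotations

import numpy as np

BASES = b"ACGT"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lower case
_DEC = np.frombuffer(BASES, dtype=np.uint8)

#: the 61 sense codons of the standard genetic code, as strings
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
STOP_CODONS = ("TAA", "TAG", "TGA")

_CODON_TABLE = {}


def codon_table() -> dict:
    """Standard genetic code, codon -> one-letter amino acid ('*' for stops)."""
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (ambiguous bases -> 255)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _ENC[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        out = np.full(codes.shape, ord("N"), dtype=np.uint8)
        ok = codes <= 3
        out[ok] = _DEC[codes[ok]]
        return out.tobytes().decode()
    return _DEC[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (A<->T, C<->G is ``3 - x``)."""
    out = (3 - codes[::-1].astype(np.int16)).astype(np.uint8)
    out[out > 3] = 255
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def jc_expected_p(d: float) -> float:
    """Expected proportion of differing sites after d substitutions/site (JC69)."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def jc_correct(p: float, cap: float = 5.0):
    """Invert the JC69 formula: substitutions/site from an observed p-distance.

    For p >= 0.75 the formula diverges; the returned distance saturates at
    ``cap``.  Works on scalars and arrays.
    """
    p = np.asarray(p, dtype=float)
    arg = 1.0 - 4.0 * p / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.inf)
    d = np.minimum(d, cap)
    if d.ndim == 0:
        return float(d)
    return d


def jc_evolve(codes: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Mutate a sequence under JC69 for d expected substitutions per site.

    Each site differs from its ancestor with probability 3/4(1 - e^{-4d/3}),
    and a differing site takes one of the three other bases uniformly.
    """
    if d < 0:
        raise ValueError("negative branch length")
    if d == 0:
        return codes.copy()
    p = jc_expected_p(d)
    out = codes.copy()
    hit = rng.random(codes.shape[0]) < p
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return out


def random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, length, dtype=np.uint8)


def random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Random stop-free coding sequence of ``n_codons`` codons."""
    idx = rng.integers(0, len(SENSE_CODONS), n_codons)
    return encode("".join(SENSE_CODONS[i] for i in idx))


def translate(cds: str) -> str:
    """Translate a CDS; internal stop codons become 'X' (unknown residue).

    The simulator evolves coding sequence under an unconstrained nucleotide
    model, so rare in-frame stops can arise; mapping them to 'X' keeps the
    protein alphabet alignable.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    table = codon_table()
    out = []
    for i in range(0, len(cds), 3):
        aa = table.get(cds[i : i + 3].upper(), "X")
        out.append("X" if aa == "*" else aa)
    return "".join(out)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over positions ungapped in both rows."""
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    ca, cb = encode(a), encode(b)
    ok = (ca <= 3) & (cb <= 3)
    n = int(ok.sum())
    if n == 0:
        return 0.0
    return float((ca[ok] != cb[ok]).sum()) / n
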