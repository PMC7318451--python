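"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's code paths: exact Fraction
arithmetic, explicit enumeration, and naive loops.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import permutations

import numpy as np

GENETIC_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_AAS):
    GENETIC_CODE[_BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]] = _a


def codon_sites_oracle(codon: str) -> tuple[Fraction, Fraction]:
    """Exact (synonymous, nonsynonymous) site count of one codon."""
    aa = GENETIC_CODE[codon]
    syn = Fraction(0)
    for pos in range(3):
        hits = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[alt] != "*" and GENETIC_CODE[alt] == aa:
                hits += 1
        syn += Fraction(hits, 3)
    return syn, 3 - syn


def codon_diff_oracle(c1: str, c2: str) -> tuple[Fraction, Fraction]:
    """Exact pathway-averaged (syn, nonsyn) differences between two codons."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return Fraction(0), Fraction(0)

    def classify_path(order):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [classify_path(order) for order in permutations(positions)]
    valid = [r for r in results if r is not None]
    if not valid:
        valid = []
        for order in permutations(positions):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if GENETIC_CODE[nxt] != "*" and GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((sd, nd))
    k = len(valid)
    return (
        Fraction(sum(v[0] for v in valid), k),
        Fraction(sum(v[1] for v in valid), k),
    )


def nei_gojobori_oracle(seq1: str, seq2: str) -> tuple[float, float]:
    """Brute-force Nei-Gojobori (Ka, Ks) with Jukes-Cantor correction."""
    import math

    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Fraction(0)
    Sd = Nd = Fraction(0)
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1, n1 = codon_sites_oracle(c1)
        s2, n2 = codon_sites_oracle(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = codon_diff_oracle(c1, c2)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N

    def jc(p: Fraction) -> float:
        return -0.75 * math.log(1 - float(4 * p) / 3)

    return jc(pn), jc(ps)


def weighted_accuracy_oracle(called: np.ndarray, truth: np.ndarray):
    """Per-locus loop implementation of R_w = sum_t P_t R_t."""
    credits = {"DUP": [], "DEL": [], "CN1": []}
    for c, t in zip(np.ravel(called), np.ravel(truth)):
        if t >= 2:
            if c <= 1:
                credits["DUP"].append(0.0)
            elif c == t:
                credits["DUP"].append(1.0)
            else:
                credits["DUP"].append(min(c, t) / max(c, t))
        elif t == 0:
            credits["DEL"].append(1.0 if c == t else 0.0)
        else:
            credits["CN1"].append(1.0 if c == t else 0.0)
    n = sum(len(v) for v in credits.values())
    rw = 0.0
    for v in credits.values():
        if v:
            rw += (len(v) / n) * (sum(v) / len(v))
    return rw


def bh_adjust_oracle(pvals):
    """Step-up Benjamini-Hochberg adjusted p-values, naive implementation."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        value = min(prev, p[idx] * m / rank)
        adj[idx] = value
        prev = value
    return adj


def window_means_oracle(per_base, bin_size):
    """Direct per-base window averaging."""
    out = []
    for start in range(0, len(per_base), bin_size):
        chunk = per_base[start : start + bin_size]
        out.append(sum(chunk) / len(chunk))
    return out
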