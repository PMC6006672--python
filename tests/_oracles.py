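"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code with the package:
codon translation goes through Bio.Seq, pathway counting is a recursion
over remaining edit positions, Tajima's D is spelled out directly from
its defining formula, and window overlaps are counted per base.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> tuple[float, float]:
    """Per-codon (synonymous, nonsynonymous) site counts by enumeration."""
    s = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            nonstop += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


def oracle_pathways(ca: str, cb: str) -> tuple[float, float] | None:
    """Average (syn, nonsyn) step counts over stop-free pathways."""

    def walk(cur: str, remaining: list[int]) -> list[tuple[float, float]]:
        if not remaining:
            return [(0.0, 0.0)]
        results = []
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                continue
            step = (1.0, 0.0) if _aa(cur) == _aa(nxt) else (0.0, 1.0)
            for s, n in walk(nxt, remaining[:i] + remaining[i + 1 :]):
                results.append((step[0] + s, step[1] + n))
        return results

    diff = [i for i in range(3) if ca[i] != cb[i]]
    paths = walk(ca, diff)
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_ng86_counts(seq_a: str, seq_b: str) -> dict:
    """Total S, N, Sd, Nd over usable codon pairs, by enumeration."""
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(ca + cb) - set("ACGT") or ca in STOPS or cb in STOPS:
            continue
        path = oracle_pathways(ca, cb)
        if path is None:
            continue
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += path[0]
        Nd += path[1]
        used += 1
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "codons_used": used}


def oracle_tajima_d(sequences: list[str]) -> dict:
    """Tajima's D from first principles on clean {ACGT} columns."""
    n = len(sequences)
    cols = [
        [s[j] for s in sequences]
        for j in range(len(sequences[0]))
        if all(s[j] in "ACGT" for s in sequences)
    ]
    S = sum(1 for c in cols if len(set(c)) > 1)
    pi = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi += sum(1 for c in cols if c[i] != c[j])
    pi /= n * (n - 1) / 2
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    if S == 0:
        d = math.nan
    else:
        d = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return {"n": n, "S": S, "pi": pi, "theta_w": S / a1, "D": d}


def oracle_window_te_bases(
    mask_intervals: list[tuple[int, int]], length: int, w0: int, w1: int
) -> int:
    """Per-base recount of masked bases inside [w0, w1)."""
    covered = np.zeros(length, dtype=bool)
    for s, e in mask_intervals:
        covered[s:e] = True
    return int(covered[w0:w1].sum())
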