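"""Codon-aware sequence statistics.

Implements the Nei–Gojobori (1986) counting estimator of synonymous and
nonsynonymous divergence (dS, dN) with Jukes–Cantor correction, Wright's
effective number of codons (ENC), major-allele consensus building from a
set of aligned copies, and gap-aware pairwise identity.

dS from NG86 counting is used throughout the package as the neutral
divergence measure that makes transposable-element sequences comparable
with host genes. A maximum-likelihood estimator (codeml-style) can be
plugged in downstream wherever a ``ds_fn`` hook is accepted; the counting
estimator is the fully specified, deterministic default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodonAlignment",
    "DSEstimate",
    "EncEstimate",
    "CopyAlignment",
    "syn_nonsyn_sites",
    "ng86",
    "effective_number_of_codons",
    "build_consensus",
    "pairwise_identity",
]

_BASES = "ACGT"

#: codon -> amino acid for the 61 sense codons of the standard code
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

# amino-acid redundancy classes of the standard code (stop codons excluded)
_DEGENERACY: dict[str, int] = {}
for _codon, _aa in GENETIC_CODE.items():
    _DEGENERACY[_aa] = _DEGENERACY.get(_aa, 0) + 1


@dataclass(frozen=True)
class CodonAlignment:
    """Two equal-length, in-frame nucleotide sequences.

    The frame starts at position 0 and the length must be a multiple of 3.
    Codons containing gaps, ambiguity characters or stop codons are flagged
    for pairwise exclusion by :func:`ng86`, not rejected at construction.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(
                f"sequences differ in length ({len(a)} vs {len(b)})"
            )
        if len(a) % 3 != 0:
            raise ValueError(f"alignment length {len(a)} is not a multiple of 3")

    def codon_pairs(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class DSEstimate:
    """NG86 divergence estimate between two coding sequences."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when saturated/undefined
    dN: float
    codons_used: int
    codons_excluded: int = 0
    saturated_s: bool = False
    saturated_n: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.dS)


@dataclass
class EncEstimate:
    """Wright's effective number of codons for one coding sequence."""

    Nc: float  # NaN when undefined
    F_bar: dict[int, float] = field(default_factory=dict)
    codons_counted: int = 0
    reason: str | None = None  # set when Nc is undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.Nc)


@dataclass(frozen=True)
class CopyAlignment:
    """Aligned copies of one TE family within one species.

    Alphabet {A, C, G, T, N, -}; all rows equal length.
    """

    sequences: tuple[str, ...]

    def __post_init__(self):
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if not seqs:
            raise ValueError("CopyAlignment requires at least one sequence")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("copies are not aligned (unequal lengths)")
        bad = set("".join(seqs)) - set("ACGTN-")
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")

    @property
    def n_copies(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(s[j] for s in self.sequences)


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts of one sense codon.

    At each of the three positions the synonymous fraction is the number of
    single-nucleotide changes that preserve the amino acid divided by the
    number of changes that do not create a stop codon; mutational paths to
    stop codons are excluded from the denominator, so s + n = 3 exactly.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in GENETIC_CODE:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(ca: str, cb: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are discarded and the counts averaged over the
    remaining pathways. Returns None when every pathway is blocked.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = ca
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return sd_total / n_paths, nd_total / n_paths


def _usable(codon: str) -> bool:
    return codon in GENETIC_CODE  # excludes stops, gaps, N, partial codons


def ng86(alignment: CodonAlignment) -> DSEstimate:
    """Nei–Gojobori (1986) dS/dN between two aligned coding sequences.

    Codon pairs containing gaps, ambiguity characters or stop codons are
    excluded pairwise, as are pairs whose every mutational pathway crosses
    a stop codon. pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
    d = -(3/4)·ln(1 - (4/3)·p); p ≥ 3/4 flags saturation (d = NaN) rather
    than raising.
    """
    S = N = Sd = Nd = 0.0
    used = excluded = 0
    for ca, cb in alignment.codon_pairs():
        if not (_usable(ca) and _usable(cb)):
            excluded += 1
            continue
        diffs = _pair_differences(ca, cb)
        if diffs is None:
            excluded += 1
            continue
        sa, na = syn_nonsyn_sites(ca)
        sb, nb = syn_nonsyn_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        used += 1
    if used == 0:
        raise ValueError("no usable codon pairs in alignment")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    def _jc(p: float) -> tuple[float, bool]:
        if p >= 0.75:
            return math.nan, True
        return -0.75 * math.log1p(-4.0 * p / 3.0), False

    dS, sat_s = _jc(pS)
    dN, sat_n = _jc(pN)
    return DSEstimate(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
        codons_used=used, codons_excluded=excluded,
        saturated_s=sat_s, saturated_n=sat_n,
    )


# redundancy class -> (number of amino acids in class, Wright weight)
_ENC_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


def effective_number_of_codons(cds: str) -> EncEstimate:
    """Wright's ENC (Nc) of a coding sequence.

    Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with the class means F̄ taken over
    amino acids observed at least twice, using the unbiased homozygosity
    F̂ = (n·Σp² − 1)/(n − 1). Stop codons and codons containing non-ACGT
    characters are skipped. Nc is capped to [20, 61]. If any redundancy
    class has no usable amino acid (or zero mean homozygosity) the estimate
    is reported undefined with a reason, not imputed.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    counts: dict[str, dict[str, int]] = {}
    total = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in GENETIC_CODE:
            continue
        aa = GENETIC_CODE[codon]
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no usable codons in CDS")

    f_by_class: dict[int, list[float]] = {c: [] for c in _ENC_CLASSES}
    for aa, codon_counts in counts.items():
        k = _DEGENERACY[GENETIC_CODE[next(iter(codon_counts))]]
        if k == 1:
            continue  # Met, Trp carry no usage information
        n = sum(codon_counts.values())
        if n < 2:
            continue
        p2 = sum((c / n) ** 2 for c in codon_counts.values())
        f_by_class[k].append((n * p2 - 1.0) / (n - 1.0))

    f_bar: dict[int, float] = {}
    for k, weight in _ENC_CLASSES.items():
        if not f_by_class[k]:
            return EncEstimate(
                Nc=math.nan, F_bar=f_bar, codons_counted=total,
                reason=f"no amino acid of {k}-fold class observed >= 2 times",
            )
        f_bar[k] = sum(f_by_class[k]) / len(f_by_class[k])
        if f_bar[k] <= 0.0:
            return EncEstimate(
                Nc=math.nan, F_bar=f_bar, codons_counted=total,
                reason=f"zero mean homozygosity in {k}-fold class",
            )

    nc = 2.0 + sum(w / f_bar[k] for k, w in _ENC_CLASSES.items())
    nc = min(61.0, max(20.0, nc))
    return EncEstimate(Nc=nc, F_bar=f_bar, codons_counted=total)


def build_consensus(copies: CopyAlignment, ties: str = "lexicographic") -> str:
    """Major-allele consensus of aligned copies.

    Per column the most frequent base among {A, C, G, T} wins; N and gaps do
    not vote. Columns where gaps hold a strict majority of copies, and
    columns with no votes at all, are dropped. Base-count ties go to the
    lexicographically smallest base (the only supported rule; deterministic
    and seed-free).
    """
    if ties != "lexicographic":
        raise ValueError(f"unknown tie rule {ties!r}")
    if all(set(s) <= {"-"} for s in copies.sequences):
        raise ValueError("all-gap alignment has no consensus")
    out = []
    n = copies.n_copies
    for j in range(copies.n_columns):
        col = copies.column(j)
        if 2 * col.count("-") > n:
            continue
        votes = {b: col.count(b) for b in _BASES if col.count(b) > 0}
        if not votes:
            continue
        best = max(votes.values())
        out.append(min(b for b, c in votes.items() if c == best))
    if not out:
        raise ValueError("no consensus columns survive gap filtering")
    return "".join(out)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching bases over comparable aligned columns.

    Columns with a gap or N in either sequence are excluded. Raises if no
    column is comparable.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    matches = compared = 0
    for x, y in zip(a, b):
        if x in "N-" or y in "N-":
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        raise ValueError("no comparable columns (all gap/N)")
    return matches / compared
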