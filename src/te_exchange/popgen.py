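"""Within-family polymorphism statistics.

Tajima's D with the TE copy number as the sample size, an ms-style
neutral coalescent null for its significance, shared polymorphism
between species, copy-number variability and rank correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._coalescent import drop_mutations, sample_genealogy
from .codonstats import CopyAlignment

__all__ = [
    "PolymorphismSummary",
    "NullDistribution",
    "SharedPolymorphism",
    "tajima_constants",
    "tajimas_d",
    "tajimas_d_from_counts",
    "coalescent_null",
    "tajima_p",
    "shared_polymorphism",
    "copy_number_cv",
    "rank_correlation",
]

_BASES = "ACGT"


@dataclass
class PolymorphismSummary:
    n: int
    S: int
    pi: float
    theta_w: float
    tajima_d: float  # NaN when undefined
    p_value: float | None = None
    sites_used: int | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.tajima_d)


@dataclass
class NullDistribution:
    """Tajima's D replicates under the neutral coalescent.

    Replicates with no segregating sites have undefined D and are stored
    as NaN; quantile/p-value consumers use only the defined ones.
    """

    d_values: np.ndarray
    n: int
    theta: float
    n_reps: int

    @property
    def defined(self) -> np.ndarray:
        return self.d_values[~np.isnan(self.d_values)]

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.d_values).sum())


@dataclass
class SharedPolymorphism:
    species_pair: tuple[str, str]
    family_id: str
    shared_sites: int
    union_sites: int
    proportion: float  # NaN when no polymorphism in either species

    @property
    def defined(self) -> bool:
        return not math.isnan(self.proportion)


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
        "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


def _d_from_pi_s(n: int, S: int, pi: float) -> float:
    if S == 0 or n < 4:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi - S / c["a1"]) / math.sqrt(var)


def tajimas_d(copies: CopyAlignment) -> PolymorphismSummary:
    """Tajima's D from an alignment of TE copies.

    Columns containing a gap or N in any copy are excluded listwise. The
    number of copies is the sample size n — the route used when copy
    number is taken as sample size. D is undefined (NaN) when S = 0 or
    n < 4.
    """
    n = copies.n_copies
    if n < 2:
        raise ValueError(f"need at least 2 copies, got {n}")
    S = 0
    pi_sum = 0.0
    sites_used = 0
    npairs = n * (n - 1) / 2.0
    for j in range(copies.n_columns):
        col = copies.column(j)
        if any(b not in _BASES for b in col):
            continue
        sites_used += 1
        counts = [col.count(b) for b in _BASES if b in col]
        if len(counts) > 1:
            S += 1
            same = sum(c * (c - 1) / 2.0 for c in counts)
            pi_sum += (npairs - same) / npairs
    a1 = tajima_constants(n)["a1"] if n >= 2 else math.nan
    theta_w = S / a1
    d = _d_from_pi_s(n, S, pi_sum)
    return PolymorphismSummary(
        n=n, S=S, pi=pi_sum, theta_w=theta_w, tajima_d=d, sites_used=sites_used
    )


def tajimas_d_from_counts(n: int, derived_counts: list[int]) -> PolymorphismSummary:
    """Tajima's D from per-site derived-allele counts (coalescent output)."""
    S = len(derived_counts)
    pi = sum(2.0 * i * (n - i) for i in derived_counts) / (n * (n - 1))
    a1 = tajima_constants(n)["a1"]
    return PolymorphismSummary(
        n=n, S=S, pi=pi, theta_w=S / a1, tajima_d=_d_from_pi_s(n, S, pi)
    )


def coalescent_null(
    n: int, theta: float, n_reps: int = 1000, seed: int | None = None
) -> NullDistribution:
    """Neutral (Hudson/ms-style) null distribution of Tajima's D.

    Each replicate draws a Kingman genealogy for n samples and drops
    Poisson mutations at locus rate theta/2 per unit branch length
    (E[S] = theta * a1(n)). Replicates with S = 0 are recorded as NaN.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 for a defined D, got {n}")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    d = np.empty(n_reps)
    for r in range(n_reps):
        counts = drop_mutations(sample_genealogy(n, rng), theta, rng)
        d[r] = tajimas_d_from_counts(n, counts).tajima_d
    return NullDistribution(d_values=d, n=n, theta=theta, n_reps=n_reps)


def tajima_p(observed: float, null: NullDistribution) -> float:
    """One-sided lower-tail empirical p-value with add-one correction.

    p = (1 + #{replicates <= observed}) / (1 + R) over the R defined
    replicates — the probability, under neutrality, of a D at least as
    negative as observed.
    """
    defined = null.defined
    if defined.size < 100:
        raise ValueError(
            f"only {defined.size} defined replicates; need >= 100"
        )
    return (1.0 + float((defined <= observed).sum())) / (1.0 + defined.size)


def _polymorphic_sites(copies: CopyAlignment) -> dict[int, frozenset[str]]:
    """Column index -> segregating allele set, over clean {ACGT} columns."""
    out: dict[int, frozenset[str]] = {}
    for j in range(copies.n_columns):
        col = [b for b in copies.column(j) if b in _BASES]
        alleles = frozenset(col)
        if len(alleles) > 1:
            out[j] = alleles
    return out


def shared_polymorphism(
    copies_a: CopyAlignment,
    copies_b: CopyAlignment,
    species_pair: tuple[str, str] = ("a", "b"),
    family_id: str = "",
    denominator: str = "union",
) -> SharedPolymorphism:
    """Shared polymorphism between two species' copy sets of one family.

    Both alignments must be on the same family-consensus coordinate frame
    (equal column counts). A site is shared iff it is polymorphic in both
    species and the two segregating allele sets intersect in at least two
    alleles. The denominator is the union of polymorphic sites by default;
    ``denominator="sum"`` uses S_a + S_b instead.
    """
    if copies_a.n_columns != copies_b.n_columns:
        raise ValueError(
            "alignments are on different coordinate frames "
            f"({copies_a.n_columns} vs {copies_b.n_columns} columns)"
        )
    if denominator not in ("union", "sum"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    pa = _polymorphic_sites(copies_a)
    pb = _polymorphic_sites(copies_b)
    shared = sum(
        1 for j in set(pa) & set(pb) if len(pa[j] & pb[j]) >= 2
    )
    union = len(set(pa) | set(pb))
    denom = union if denominator == "union" else len(pa) + len(pb)
    prop = shared / denom if denom > 0 else math.nan
    return SharedPolymorphism(
        species_pair=species_pair, family_id=family_id,
        shared_sites=shared, union_sites=union, proportion=prop,
    )


def copy_number_cv(values) -> float:
    """Coefficient of variation (sample SD / mean) of per-species copy numbers."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 species values, got {v.size}")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean copy number must be positive")
    return float(v.std(ddof=1) / mean)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p). rho is NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError(f"need at least 4 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
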