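"""Candidate TE classification, family clustering, filters, copy number
and density windows.

Mirrors a de novo TE annotation workflow: BLAST hits against a repeat
database drive a decision tree (known family / novel within superfamily /
novel within order / gene-like discard / unknown retained); families are
clustered at >90% identity with the longest member as representative;
repeat-hit-count and relative-coverage filters prune weakly supported
families; copy number is estimated as median TE depth over the median
depth of a single-copy reference chromosome; and TE density is computed
in 1-Mb sliding windows (100-kb step) with assembly-gap (N) correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codonstats import pairwise_identity

__all__ = [
    "HitRecord",
    "CandidateClass",
    "CoverageProfile",
    "WindowDensity",
    "classify_candidate",
    "cluster_families",
    "hit_count_filter",
    "estimate_copy_number",
    "coverage_filter",
    "insertion_frequency_filter",
    "window_density",
    "insertion_density",
]

DEFAULT_EVALUE = 1e-8


@dataclass(frozen=True)
class HitRecord:
    """One BLAST hit of a candidate query against the repeat/nr database."""

    query_id: str
    subject_family: str
    subject_superfamily: str
    subject_order: str
    e_value: float
    pct_identity: float
    is_te_subject: bool = True
    nr_subject_kind: str | None = None  # "gene" | "other" for nr subjects

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("percent identity must be in [0, 100]")


@dataclass(frozen=True)
class CandidateClass:
    """Decision-tree outcome for one candidate query."""

    label: str  # known_family | novel_in_superfamily | novel_in_order
    #         | discarded_gene_like | unknown_retained
    detail: str | None = None  # family / superfamily / order name

    LABELS = (
        "known_family",
        "novel_in_superfamily",
        "novel_in_order",
        "discarded_gene_like",
        "unknown_retained",
    )

    def __post_init__(self):
        if self.label not in self.LABELS:
            raise ValueError(f"unknown class label {self.label!r}")


def _primary_hit(hits: list[HitRecord]) -> HitRecord:
    # lowest e-value, ties by highest identity then lexicographic subject id
    return min(hits, key=lambda h: (h.e_value, -h.pct_identity, h.subject_family))


def classify_candidate(
    hits: list[HitRecord], evalue_max: float = DEFAULT_EVALUE
) -> CandidateClass:
    """Classify one candidate from its hit rows.

    Rules, applied to TE-database hits at e-value <= evalue_max:
    a single hit identifies a known family; multiple hits all within one
    superfamily mark a putative novel family of that superfamily; hits in
    one order but several superfamilies mark a novel element of that
    order. With no TE hits, a primary nr hit annotated as a gene discards
    the candidate; anything else (including an empty hit set) is retained
    as unknown. The outcome is independent of row order.
    """
    kept = [h for h in hits if h.e_value <= evalue_max]
    te_hits = [h for h in kept if h.is_te_subject]
    if te_hits:
        if len(te_hits) == 1:
            return CandidateClass("known_family", te_hits[0].subject_family)
        superfams = {h.subject_superfamily for h in te_hits}
        if len(superfams) == 1:
            return CandidateClass("novel_in_superfamily", superfams.pop())
        orders = {h.subject_order for h in te_hits}
        if len(orders) == 1:
            return CandidateClass("novel_in_order", orders.pop())
        return CandidateClass("unknown_retained")
    nr_hits = [h for h in kept if not h.is_te_subject]
    if nr_hits and _primary_hit(nr_hits).nr_subject_kind == "gene":
        return CandidateClass("discarded_gene_like")
    return CandidateClass("unknown_retained")


def _ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in "-N")


def cluster_families(
    sequences: dict[str, str], identity_threshold: float = 0.90
) -> list[dict]:
    """Single-linkage clustering of aligned sequences at > threshold identity.

    ``sequences`` maps id -> aligned sequence (equal lengths). Two
    sequences join a cluster when their gap-excluded identity is strictly
    greater than the threshold; clusters are the transitive closure. The
    representative is the longest (ungapped) member, ties broken by
    lexicographic id. Returns a list of {"representative", "members"}.
    """
    ids = sorted(sequences)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            try:
                ident = pairwise_identity(sequences[a], sequences[b])
            except ValueError:
                continue  # no comparable columns: cannot link
            if ident > identity_threshold:
                parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda m: (-_ungapped_length(sequences[m]), m))
        clusters.append({"representative": rep, "members": sorted(members)})
    clusters.sort(key=lambda c: c["representative"])
    return clusters


def hit_count_filter(per_species_hit_counts, min_hits: int = 25) -> bool:
    """Keep a family iff it has >= min_hits repeat-mask hits in >= 1 species."""
    counts = list(per_species_hit_counts)
    if any(c < 0 for c in counts):
        raise ValueError("hit counts must be non-negative")
    return bool(counts) and max(counts) >= min_hits


@dataclass
class CoverageProfile:
    """Per-base read depth over a TE consensus plus the single-copy baseline.

    ``baseline_median`` is the median depth over a reference chromosome
    known to be single-copy (chromosome 3 in the original design), used
    as the denominator for relative coverage and copy number.
    """

    te_id: str
    depths: np.ndarray
    baseline_median: float
    true_copy_number: float | None = None  # ground truth, simulator only

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        if (d < 0).any():
            raise ValueError("depths must be non-negative")
        self.depths = d


def estimate_copy_number(
    profile: CoverageProfile, segments: list[tuple[int, int]] | None = None
) -> float:
    """Copy number = median TE depth / baseline median depth.

    With ``segments`` (0-based half-open, e.g. solo-LTR terminus vs
    element body), the ratio is estimated per segment and the unweighted
    mean over segments returned — the rule used for LTR elements whose
    termini are inflated by solo-LTRs.
    """
    if profile.baseline_median <= 0:
        raise ValueError("baseline median depth must be positive")
    if segments is None:
        return float(np.median(profile.depths) / profile.baseline_median)
    ests = []
    for start, end in segments:
        seg = profile.depths[start:end]
        if seg.size == 0:
            raise ValueError(f"empty segment ({start}, {end})")
        ests.append(np.median(seg) / profile.baseline_median)
    return float(np.mean(ests))


def coverage_filter(
    profile: CoverageProfile, fold: float = 2.0, min_frac: float = 0.8
) -> bool:
    """Keep iff >= min_frac of positions have depth >= fold x baseline.

    Both boundaries are inclusive. This implements the relative-coverage
    support filter: families whose consensus is mostly covered below
    fold x the single-copy chromosome's depth are discarded as weakly
    supported.
    """
    if profile.baseline_median <= 0:
        raise ValueError("baseline median depth must be positive")
    if profile.depths.size == 0:
        raise ValueError("empty coverage profile")
    frac = float((profile.depths >= fold * profile.baseline_median).mean())
    return frac >= min_frac


def insertion_frequency_filter(calls: list[dict], min_freq: float = 0.5) -> list[dict]:
    """Retain insertion records whose estimated frequency is >= min_freq.

    Each record is a mapping with a ``frequency`` key in [0, 1].
    """
    for c in calls:
        f = c["frequency"]
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency {f} outside [0, 1]")
    return [c for c in calls if c["frequency"] >= min_freq]


@dataclass
class WindowDensity:
    """Sliding-window TE density over one or more chromosomes."""

    chrom: list[str] = field(default_factory=list)
    start: list[int] = field(default_factory=list)
    end: list[int] = field(default_factory=list)
    te_bases: list[int] = field(default_factory=list)
    n_bases: list[int] = field(default_factory=list)
    density: list[float] = field(default_factory=list)  # NaN when span == Ns

    def __len__(self):
        return len(self.chrom)


def _merged(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    srt = sorted(intervals)
    out = [list(srt[0])]
    for s, e in srt[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _overlap_bases(merged: list[tuple[int, int]], w0: int, w1: int) -> int:
    return sum(max(0, min(e, w1) - max(s, w0)) for s, e in merged)


def _check_bounds(intervals, lengths, what):
    for chrom, ivs in intervals.items():
        if chrom not in lengths:
            raise ValueError(f"{what} interval on unknown chromosome {chrom!r}")
        for s, e in ivs:
            if s < 0 or e > lengths[chrom] or s >= e:
                raise ValueError(
                    f"{what} interval {chrom}:{s}-{e} out of bounds "
                    f"(chromosome length {lengths[chrom]})"
                )


def _windows(length: int, window: int, step: int):
    start = 0
    while start < length:
        yield start, min(start + window, length)
        start += step


def window_density(
    mask_intervals: dict[str, list[tuple[int, int]]],
    chrom_lengths: dict[str, int],
    n_intervals: dict[str, list[tuple[int, int]]] | None = None,
    window: int = 1_000_000,
    step: int = 100_000,
) -> WindowDensity:
    """TE base density per sliding window, corrected for assembly gaps.

    All intervals are 0-based half-open. Per window, te_bases is the
    number of masked bases overlapping the window (overlapping mask
    records are unioned), and density = te_bases / (span - N bases in the
    window). Terminal windows keep their actual (shorter) span. Windows
    consisting entirely of Ns get NaN density.
    """
    n_intervals = n_intervals or {}
    _check_bounds(mask_intervals, chrom_lengths, "mask")
    _check_bounds(n_intervals, chrom_lengths, "N")
    out = WindowDensity()
    for chrom in sorted(chrom_lengths):
        masks = _merged(mask_intervals.get(chrom, []))
        ns = _merged(n_intervals.get(chrom, []))
        for w0, w1 in _windows(chrom_lengths[chrom], window, step):
            te = _overlap_bases(masks, w0, w1)
            nn = _overlap_bases(ns, w0, w1)
            span = w1 - w0
            dens = te / (span - nn) if span > nn else math.nan
            out.chrom.append(chrom)
            out.start.append(w0)
            out.end.append(w1)
            out.te_bases.append(te)
            out.n_bases.append(nn)
            out.density.append(dens)
    return out


def insertion_density(
    insertion_positions: dict[str, list[int]],
    chrom_lengths: dict[str, int],
    n_intervals: dict[str, list[tuple[int, int]]] | None = None,
    window: int = 1_000_000,
    step: int = 100_000,
) -> WindowDensity:
    """Insertions per Mb per sliding window, N-corrected.

    Insertions are assigned to windows by their (midpoint) position;
    density = count / (span - Ns) scaled to events per megabase. The
    ``te_bases`` field carries the raw insertion count.
    """
    n_intervals = n_intervals or {}
    _check_bounds(n_intervals, chrom_lengths, "N")
    for chrom, positions in insertion_positions.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"insertion on unknown chromosome {chrom!r}")
        for p in positions:
            if not 0 <= p < chrom_lengths[chrom]:
                raise ValueError(f"insertion position {chrom}:{p} out of bounds")
    out = WindowDensity()
    for chrom in sorted(chrom_lengths):
        positions = sorted(insertion_positions.get(chrom, []))
        ns = _merged(n_intervals.get(chrom, []))
        for w0, w1 in _windows(chrom_lengths[chrom], window, step):
            count = sum(1 for p in positions if w0 <= p < w1)
            nn = _overlap_bases(ns, w0, w1)
            span = w1 - w0
            dens = count / (span - nn) * 1e6 if span > nn else math.nan
            out.chrom.append(chrom)
            out.start.append(w0)
            out.end.append(w1)
            out.te_bases.append(count)
            out.n_bases.append(nn)
            out.density.append(dens)
    return out
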