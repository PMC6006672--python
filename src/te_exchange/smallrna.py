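"""Small-RNA signatures of TE silencing.

piRNAs produced by germline ping-pong amplification come in sense /
antisense pairs whose 5' ends overlap by exactly 10 nt, with a uridine
bias at position 1 of the initiator and — by complementarity — an
adenine bias at position 10 of the responder. This module classifies
reads by length (21–23 nt siRNA, 24–29 nt piRNA), computes the 5'-end
overlap spectrum between sense and antisense piRNAs with a z-score for
the 10-nt offset, and the per-position base composition split by strand.

Reads are assumed to be pre-filtered against miRNA/snoRNA/viral
databases upstream; ingest does not re-check this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SmallRNARead",
    "OverlapSpectrum",
    "classify_length",
    "overlap_spectrum",
    "positional_composition",
]

SIRNA_RANGE = (21, 23)
PIRNA_RANGE = (24, 29)
MIN_LENGTH, MAX_LENGTH = 16, 35


@dataclass(frozen=True)
class SmallRNARead:
    """A small RNA mapped to a TE consensus.

    ``start`` is the 0-based leftmost mapped base on the consensus;
    ``sequence`` is in read orientation (5'→3'), with U written as T.
    """

    te_id: str
    start: int
    length: int
    strand: str
    sequence: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not MIN_LENGTH <= self.length <= MAX_LENGTH:
            raise ValueError(
                f"read length {self.length} outside ingest bounds "
                f"[{MIN_LENGTH}, {MAX_LENGTH}]"
            )
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match read length")

    @property
    def five_prime(self) -> int:
        """Consensus coordinate of the read's 5' base."""
        return self.start if self.strand == "+" else self.start + self.length - 1


def classify_length(read: SmallRNARead | int) -> str:
    """siRNA (21–23 nt), piRNA (24–29 nt) or other; boundaries inclusive."""
    length = read.length if isinstance(read, SmallRNARead) else read
    if SIRNA_RANGE[0] <= length <= SIRNA_RANGE[1]:
        return "siRNA"
    if PIRNA_RANGE[0] <= length <= PIRNA_RANGE[1]:
        return "piRNA"
    return "other"


@dataclass
class OverlapSpectrum:
    counts: np.ndarray  # counts[d-1] = pairs with 5' overlap d, d = 1..max
    z10: float  # NaN when undefined
    n_pairs_total: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(1, self.counts.size + 1)

    @property
    def modal_offset(self) -> int:
        return int(np.argmax(self.counts)) + 1


def overlap_spectrum(
    reads: list[SmallRNARead],
    max_offset: int = 25,
    focal_offset: int = 10,
    read_cap: int | None = None,
) -> OverlapSpectrum:
    """Sense/antisense 5'-overlap spectrum over one TE.

    For every (+, −) read pair the overlap is (5' of the − read) −
    (5' of the + read) + 1; values in 1..max_offset increment that
    offset's count. All pairs are enumerated (via position-histogram
    correlation, so cost is linear in TE length, not quadratic in read
    count). z10 compares the focal offset's count against the mean/SD of
    the remaining offsets; it is NaN when that SD is zero or no pair
    exists. ``read_cap`` optionally subsamples each strand
    deterministically (first reads kept) for very deep libraries.
    """
    plus = [r.five_prime for r in reads if r.strand == "+"]
    minus = [r.five_prime for r in reads if r.strand == "-"]
    if read_cap is not None:
        plus, minus = plus[:read_cap], minus[:read_cap]
    counts = np.zeros(max_offset, dtype=np.int64)
    if plus and minus:
        pmin = min(min(plus), min(minus))
        pmax = max(max(plus), max(minus))
        span = pmax - pmin + 1
        hp = np.bincount(np.asarray(plus) - pmin, minlength=span)
        hm = np.bincount(np.asarray(minus) - pmin, minlength=span)
        # counts[d-1] = sum_x hp[x] * hm[x + d - 1]
        full = np.correlate(hm, hp, mode="full")  # lag k at index k + span - 1
        for d in range(1, max_offset + 1):
            idx = (d - 1) + span - 1
            if 0 <= idx < full.size:
                counts[d - 1] = full[idx]
    background = np.delete(counts, focal_offset - 1)
    sd = background.std(ddof=1)
    if counts.sum() == 0 or sd == 0:
        z10 = math.nan
    else:
        z10 = float((counts[focal_offset - 1] - background.mean()) / sd)
    return OverlapSpectrum(
        counts=counts, z10=z10, n_pairs_total=len(plus) * len(minus)
    )


def positional_composition(
    reads: list[SmallRNARead], n_positions: int = 24
) -> dict[str, dict]:
    """Per-position base frequencies of sense and antisense reads.

    Positions are 1-based in read orientation (position 1 = 5' base).
    Returns, per strand class ("sense", "antisense"), a frequency matrix
    ``freq[base][pos-1]`` over A/C/G/T (renormalised over reads covering
    that position) plus the argmax position of T (sense; the uridine bias)
    and of A (antisense; the emergent position-10 adenine bias).
    """
    if not reads:
        raise ValueError("empty read set")
    out: dict[str, dict] = {}
    for label, strand in (("sense", "+"), ("antisense", "-")):
        seqs = [r.sequence for r in reads if r.strand == strand and r.sequence]
        counts = {b: np.zeros(n_positions) for b in "ACGT"}
        for s in seqs:
            for i, b in enumerate(s[:n_positions]):
                if b in counts:
                    counts[b][i] += 1
        totals = sum(counts.values())
        freq = {
            b: np.divide(
                counts[b], totals, out=np.full(n_positions, np.nan),
                where=totals > 0,
            )
            for b in "ACGT"
        }
        bias_base = "T" if label == "sense" else "A"
        with np.errstate(invalid="ignore"):
            bias_freq = freq[bias_base]
        argmax = (
            int(np.nanargmax(bias_freq)) + 1
            if seqs and not np.all(np.isnan(bias_freq))
            else None
        )
        out[label] = {
            "freq": freq,
            "n_reads": len(seqs),
            f"{bias_base}_argmax": argmax,
        }
    return out
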