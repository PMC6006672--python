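"""Kingman coalescent genealogies shared by the copy simulator and the
neutral Tajima's D null.

A genealogy is represented as a flat list of branches; each branch knows
its duration (in coalescent units, pairwise coalescence rate 1) and the
set of sampled copies it subtends, which is all a neutral
infinite/finite-sites mutation process needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Branch:
    duration: float
    leaves: frozenset[int]

    @property
    def n_descendants(self) -> int:
        return len(self.leaves)


def sample_genealogy(
    n: int, rng: np.random.Generator, external_scale: float = 1.0
) -> list[Branch]:
    """Draw one n-sample Kingman genealogy.

    While k lineages remain, the waiting time to the next coalescence is
    exponential with rate k(k-1)/2; the merging pair is uniform. External
    (leaf) branch durations are multiplied by ``external_scale``; values
    > 1 caricature a copy-number expansion by inflating the share of
    mutations that end up as singletons.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if external_scale <= 0:
        raise ValueError("external_scale must be positive")
    # active lineage -> (leaf set, accumulated duration)
    active: dict[int, list] = {i: [frozenset([i]), 0.0] for i in range(n)}
    next_id = n
    branches: list[Branch] = []
    k = n
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        for lin in active.values():
            lin[1] += t
        ids = list(active)
        i, j = rng.choice(len(ids), size=2, replace=False)
        a, b = active.pop(ids[i]), active.pop(ids[j])
        for leaves, dur in (a, b):
            scale = external_scale if len(leaves) == 1 else 1.0
            branches.append(Branch(duration=dur * scale, leaves=leaves))
        active[next_id] = [a[0] | b[0], 0.0]
        next_id += 1
        k -= 1
    return branches


def drop_mutations(
    branches: list[Branch], theta_total: float, rng: np.random.Generator
) -> list[int]:
    """Poisson mutations on a genealogy; returns the derived-allele count
    (number of subtended samples) of each mutation.

    Mutation rate is theta_total/2 per unit branch length, so the expected
    number of segregating sites is theta_total * a1(n) for an unscaled
    neutral genealogy.
    """
    counts: list[int] = []
    for br in branches:
        m = rng.poisson(0.5 * theta_total * br.duration)
        counts.extend([br.n_descendants] * m)
    return counts
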