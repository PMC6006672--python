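"""Horizontal-transfer classification of TE families.

A TE family's synonymous divergence between a species pair is compared
against the distribution of dS over host nuclear genes for the same
pair: dS strictly below the genic 2.5% quantile is strong evidence of
exchange, between the 2.5% and 50% quantiles is a potential transfer,
above the median is no evidence. Strong calls can be confirmed by an
ENC-conditioned rule (TE dS more than two genic SDs below the genic
mean within a sliding 5-unit ENC window), and corroborated by
gene-tree/species-tree discordance of a neighbor-joining tree built
from the family's pairwise dS matrix.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "GenicDsDistribution",
    "HTTCall",
    "DistanceMatrix",
    "EncConfirmation",
    "empirical_quantile",
    "classify_htt",
    "enc_conditioned_test",
    "nj_tree",
    "rf_discordance",
    "summarize_transfers",
]

CATEGORIES = ("strong", "potential", "none", "undefined")

#: genic sets smaller than this make the 2.5% quantile unstable
MIN_GENIC_VALUES = 40


def empirical_quantile(values, q: float) -> float:
    """Linear-interpolation (type-7) empirical quantile."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take a quantile of an empty vector")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile {q} outside [0, 1]")
    return float(np.quantile(v, q, method="linear"))


@dataclass
class GenicDsDistribution:
    """Per-pair distribution of genic dS with its decision quantiles.

    Undefined (NaN / saturated) values are dropped at construction with a
    count retained in ``n_dropped``.
    """

    species_pair: tuple[str, str]
    ds_values: np.ndarray
    q_strong: float = 0.025
    q_none: float = 0.50
    n_dropped: int = 0
    q_lower: float = field(init=False)
    q_median: float = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.ds_values, dtype=float)
        keep = ~np.isnan(v)
        self.n_dropped += int((~keep).sum())
        v = v[keep]
        if v.size == 0:
            raise ValueError(
                f"no defined genic dS values for pair {self.species_pair}"
            )
        if (v < 0).any():
            raise ValueError("genic dS values must be non-negative")
        self.ds_values = v
        self.q_lower = empirical_quantile(v, self.q_strong)
        self.q_median = empirical_quantile(v, self.q_none)


@dataclass
class HTTCall:
    family_id: str
    species_pair: tuple[str, str]
    te_ds: float
    category: str
    enc_confirmed: bool | None = None
    discordant: bool | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_htt(
    te_ds: float,
    genic: GenicDsDistribution,
    family_id: str = "",
) -> HTTCall:
    """Classify one family x pair by the genic-quantile rule.

    strong: te_ds strictly below the genic 2.5% quantile; potential:
    within [2.5%, 50%] inclusive; none: above the median; undefined when
    te_ds is NaN (saturated or unavailable). Boundary values resolve
    toward the weaker category.
    """
    if genic.ds_values.size < MIN_GENIC_VALUES:
        warnings.warn(
            f"only {genic.ds_values.size} genic dS values for "
            f"{genic.species_pair}; the {genic.q_strong:.1%} quantile is "
            "unstable below 40",
            stacklevel=2,
        )
    if te_ds is None or math.isnan(te_ds):
        category = "undefined"
    elif te_ds < genic.q_lower:
        category = "strong"
    elif te_ds <= genic.q_median:
        category = "potential"
    else:
        category = "none"
    return HTTCall(
        family_id=family_id, species_pair=genic.species_pair,
        te_ds=te_ds, category=category,
    )


@dataclass
class EncConfirmation:
    confirmed: bool | None  # None when no verdict is possible
    reason: str | None = None
    window_mean: float = math.nan
    window_sd: float = math.nan
    n_window: int = 0


def enc_conditioned_test(
    te: tuple[float, float],
    genic: list[tuple[float, float]],
    window_width: float = 5.0,
    k: float = 2.0,
    min_window_points: int = 5,
) -> EncConfirmation:
    """Confirm a low TE dS conditioning on codon-usage bias (ENC).

    ``te`` and each genic entry are (dS, Nc) pairs. Genic points whose Nc
    lies within window_width/2 of the TE's Nc form the window; the call is
    confirmed iff te_ds < mean(window dS) - k * sd(window dS). Fewer than
    ``min_window_points`` genic points in the window yields no verdict
    (reason "insufficient window"); an undefined TE Nc yields reason
    "no ENC".
    """
    te_ds, te_nc = te
    if te_nc is None or math.isnan(te_nc):
        return EncConfirmation(confirmed=None, reason="no ENC")
    window = [
        ds for ds, nc in genic
        if not math.isnan(nc) and not math.isnan(ds)
        and abs(nc - te_nc) <= window_width / 2.0
    ]
    if len(window) < min_window_points:
        return EncConfirmation(
            confirmed=None, reason="insufficient window", n_window=len(window)
        )
    mean = float(np.mean(window))
    sd = float(np.std(window, ddof=1))
    return EncConfirmation(
        confirmed=bool(te_ds < mean - k * sd),
        window_mean=mean, window_sd=sd, n_window=len(window),
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dS (or raw divergence) matrix over species."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a pairwise distance matrix.

    Negative branch lengths produced by the NJ agglomeration are clamped
    to zero. Returns an unrooted scikit-bio TreeNode.
    """
    if len(d.labels) < 3:
        raise ValueError(f"need at least 3 taxa, got {len(d.labels)}")
    sk_dm = _SkbioDM(d.values, ids=list(d.labels))
    return _skbio_nj(sk_dm, neg_as_zero=True)


def rf_discordance(family_tree: TreeNode, species_tree: TreeNode) -> tuple[int, bool]:
    """Robinson–Foulds distance between unrooted topologies.

    Returns (rf, discordant) with discordant = rf > 0. Raises when the tip
    sets differ, naming the difference.
    """
    tips_a = {t.name for t in family_tree.tips()}
    tips_b = {t.name for t in species_tree.tips()}
    if tips_a != tips_b:
        raise ValueError(
            "tip sets differ: "
            f"only in family tree {sorted(tips_a - tips_b)}, "
            f"only in species tree {sorted(tips_b - tips_a)}"
        )
    a, b = family_tree.copy(), species_tree.copy()
    a.unroot()
    b.unroot()
    rf = int(a.compare_rfd(b))
    return rf, rf > 0


def parse_newick(newick: str) -> TreeNode:
    """Parse a newick string into a scikit-bio TreeNode."""
    return TreeNode.read(io.StringIO(newick))


def summarize_transfers(calls: list[HTTCall]) -> dict[str, pd.DataFrame | list[str]]:
    """Per-pair category counts plus all-pairs family lists.

    Returns a dict with ``per_pair`` (DataFrame of strong/potential/none/
    undefined counts per species pair), ``per_family`` (long DataFrame of
    calls), ``strong_all_pairs`` (families strong in every pair they were
    scored in, scored in >= 1 pair) and ``none_all_pairs``.
    """
    if not calls:
        return {
            "per_pair": pd.DataFrame(
                columns=["pair", *CATEGORIES]
            ).set_index("pair"),
            "per_family": pd.DataFrame(
                columns=["family_id", "pair", "te_ds", "category"]
            ),
            "strong_all_pairs": [],
            "none_all_pairs": [],
        }
    rows = [
        {
            "family_id": c.family_id,
            "pair": "-".join(c.species_pair),
            "te_ds": c.te_ds,
            "category": c.category,
        }
        for c in calls
    ]
    long = pd.DataFrame(rows)
    per_pair = (
        long.pivot_table(
            index="pair", columns="category", values="family_id",
            aggfunc="count", fill_value=0,
        )
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .rename_axis(columns=None)
    )
    by_family = long.groupby("family_id")["category"]
    strong_all = sorted(by_family.agg(lambda s: (s == "strong").all()).pipe(
        lambda s: s[s].index
    ))
    none_all = sorted(by_family.agg(lambda s: (s == "none").all()).pipe(
        lambda s: s[s].index
    ))
    return {
        "per_pair": per_pair,
        "per_family": long,
        "strong_all_pairs": strong_all,
        "none_all_pairs": none_all,
    }
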