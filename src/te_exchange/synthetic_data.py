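"""Synthetic inputs with known ground truth for every pipeline stage.

The simulator emulates (a) TE family coding sequences evolving on a
five-species tree with optional injected horizontal transfers, (b)
within-species TE copy sets with coalescent-structured polymorphism,
(c) per-base coverage profiles with known true copy number, (d)
ping-pong-structured small-RNA read sets, (e) BLAST-style hit tables
for the candidate decision tree, and (f) genome mosaics with N gaps for
the density windows and insertion filters.

The default species tree mirrors the *D. pseudoobscura* group —
((((pseudoobscura, persimilis), miranda), lowei), affinis) — with the
pseudoobscura–persimilis path anchored at 0.018 substitutions per
synonymous site (their average genic synonymous divergence) and deeper
nodes at 3x, 6x and 12x that depth. Only the relative depths matter for
the classifier tests; absolute divergence times of the group are not
published, so the deeper depths are round placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from ._coalescent import sample_genealogy
from .annotation import CoverageProfile, HitRecord
from .codonstats import GENETIC_CODE, CopyAlignment
from .htt import parse_newick
from .smallrna import SmallRNARead

__all__ = [
    "SpeciesTree",
    "HTEvent",
    "SimulationConfig",
    "GenomeMosaic",
    "default_species_tree",
    "random_orf",
    "evolve_family_on_tree",
    "simulate_te_copies",
    "simulate_coverage_profile",
    "simulate_pingpong_reads",
    "simulate_hit_table",
    "simulate_genome_mosaic",
]

_BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_TREE_NEWICK = (
    "((((pseudoobscura:0.009,persimilis:0.009):0.018,miranda:0.027):0.027,"
    "lowei:0.054):0.054,affinis:0.108);"
)

SENSE_CODONS = sorted(GENETIC_CODE)


@dataclass
class SpeciesTree:
    """Rooted binary species tree with branch lengths in expected
    substitutions per site."""

    newick: str = DEFAULT_TREE_NEWICK
    tree: TreeNode = field(init=False, repr=False)

    def __post_init__(self):
        self.tree = parse_newick(self.newick)
        tips = [t.name for t in self.tree.tips()]
        if len(tips) < 2:
            raise ValueError("species tree needs at least 2 tips")
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")
        for node in self.tree.traverse():
            if node.length is not None and node.length < 0:
                raise ValueError("branch lengths must be non-negative")

    @property
    def species(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def depth(self, species: str) -> float:
        """Root-to-tip path length for one species."""
        tip = self._tip(species)
        return sum(
            n.length or 0.0 for n in tip.ancestors() if not n.is_root()
        ) + (tip.length or 0.0)

    def path_length(self, a: str, b: str) -> float:
        """Patristic distance between two tips."""
        return float(self._tip(a).distance(self._tip(b)))

    def _tip(self, species: str) -> TreeNode:
        for t in self.tree.tips():
            if t.name == species:
                return t
        raise ValueError(f"unknown species label {species!r}")


def default_species_tree() -> SpeciesTree:
    return SpeciesTree()


@dataclass(frozen=True)
class HTEvent:
    """A horizontal transfer: the recipient's TE lineage is re-grafted
    onto the donor lineage at ``time_fraction`` of the recipient's
    root-to-tip depth (0 = now, 1 = root)."""

    family_id: str
    donor: str
    recipient: str
    time_fraction: float

    def __post_init__(self):
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if not 0.0 <= self.time_fraction < 1.0:
            raise ValueError("time_fraction must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    Defaults describe a typical mid-size TE family in the group: a 300
    codon ORF, per-site within-family diversity theta = 0.01, 20 copies
    per species, 30x single-copy sequencing depth with 10% depth noise.
    The same seed always reproduces byte-identical outputs.
    """

    seed: int = 0
    substitution_model: str = "JC69"  # or "K2P"
    kappa: float = 2.0
    sequence_length_codons: int = 300
    theta_per_site: float = 0.01
    copy_number: int = 20
    coverage_depth_baseline: float = 30.0
    noise_cv: float = 0.1

    def __post_init__(self):
        if self.substitution_model not in ("JC69", "K2P"):
            raise ValueError(
                f"unknown substitution model {self.substitution_model!r}"
            )
        for name in ("kappa", "theta_per_site", "coverage_depth_baseline",
                     "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sequence_length_codons < 1:
            raise ValueError("sequence_length_codons must be >= 1")


def random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """Random open reading frame: uniform draws from the 61 sense codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _transition_matrix(model: str, kappa: float, t: float) -> np.ndarray:
    """K80 transition probabilities at branch length t (expected
    substitutions per site); JC69 is the kappa = 1 special case.
    Base order A, C, G, T; transitions are A<->G and C<->T."""
    if model == "JC69":
        kappa = 1.0
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * e1  # each of two transversions
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv
    P = np.empty((4, 4))
    transition_partner = {0: 2, 2: 0, 1: 3, 3: 1}
    for i in range(4):
        for j in range(4):
            if i == j:
                P[i, j] = p_same
            elif j == transition_partner[i]:
                P[i, j] = p_ts
            else:
                P[i, j] = p_tv
    return P


def _evolve_ints(
    seq: np.ndarray, t: float, model: str, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if t == 0:
        return seq.copy()
    P = _transition_matrix(model, kappa, t)
    cum = P.cumsum(axis=1)
    u = rng.random(seq.size)
    return (u[:, None] > cum[seq]).sum(axis=1).astype(seq.dtype)


def _seq_to_ints(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_TO_INT[b] for b in seq), dtype=np.int8, count=len(seq))


def _ints_to_seq(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def evolve_family_on_tree(
    tree: SpeciesTree,
    config: SimulationConfig,
    ht: HTEvent | None = None,
    root_sequence: str | None = None,
    rate_scale: float = 1.0,
) -> dict[str, str]:
    """Evolve one TE family's ORF down the species tree.

    Returns one consensus sequence per tip. Without a transfer, expected
    pairwise divergence equals the tree path length (times
    ``rate_scale``, a per-locus rate multiplier that models among-locus
    rate variation). With an ``HTEvent``, the recipient's sequence is
    re-derived from the donor lineage's state at age time_fraction x the
    recipient's depth, so the expected donor–recipient divergence is
    2 x time_fraction x depth x rate_scale.
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be non-negative")
    rng = np.random.default_rng(config.seed)
    root = (
        _seq_to_ints(root_sequence)
        if root_sequence is not None
        else _seq_to_ints(random_orf(config.sequence_length_codons, rng))
    )
    model, kappa = config.substitution_model, config.kappa

    split_branch = None  # (node id of branch's child on donor path, offset from top)
    transfer_age = 0.0
    if ht is not None:
        species = set(tree.species)
        for label in (ht.donor, ht.recipient):
            if label not in species:
                raise ValueError(f"HTEvent references unknown species {label!r}")
        donor_depth = tree.depth(ht.donor)
        transfer_age = ht.time_fraction * tree.depth(ht.recipient)
        # locate the point at distance (donor_depth - transfer_age) from the
        # root along the donor's root-to-tip path
        target = donor_depth - transfer_age
        tip = tree._tip(ht.donor)
        path = list(reversed([n for n in tip.ancestors() if not n.is_root()])) + [tip]
        dist = 0.0
        for node in path:
            bl = node.length or 0.0
            if dist + bl >= target - 1e-12:
                split_branch = (id(node), max(0.0, target - dist))
                break
            dist += bl
        if split_branch is None:  # numerical edge: transfer at donor tip
            split_branch = (id(path[-1]), path[-1].length or 0.0)

    donor_state_at_transfer: np.ndarray | None = None
    sequences: dict[str, str] = {}
    stack = [(tree.tree, root)]
    # iterative pre-order walk so child seeds depend only on rng call order,
    # which is fixed by the tree's traversal order
    while stack:
        node, state = stack.pop(0)
        for child in node.children:
            bl = child.length or 0.0
            if split_branch is not None and id(child) == split_branch[0]:
                l1 = min(split_branch[1], bl)
                mid = _evolve_ints(state, l1 * rate_scale, model, kappa, rng)
                donor_state_at_transfer = mid
                child_state = _evolve_ints(
                    mid, (bl - l1) * rate_scale, model, kappa, rng
                )
            else:
                child_state = _evolve_ints(
                    state, bl * rate_scale, model, kappa, rng
                )
            if child.is_tip():
                sequences[child.name] = _ints_to_seq(child_state)
            else:
                stack.append((child, child_state))

    if ht is not None:
        assert donor_state_at_transfer is not None
        recipient_state = _evolve_ints(
            donor_state_at_transfer, transfer_age * rate_scale, model, kappa, rng
        )
        sequences[ht.recipient] = _ints_to_seq(recipient_state)
    return sequences


def simulate_te_copies(
    consensus: str,
    n_copies: int,
    theta_per_site: float,
    seed: int | None = None,
    expansion: bool = False,
    expansion_factor: float = 10.0,
) -> CopyAlignment:
    """Within-species TE copies under a Kingman coalescent.

    Mutations are Poisson on branches at locus rate theta_total/2 per
    coalescent unit (theta_total = theta_per_site x length), each placed
    at a uniform site and applied to the branch's descendant copies
    (finite sites; repeated hits at a site resample it, so infinite
    sites holds only approximately at low theta). The expected number of
    segregating sites is theta_total x a1(n). With ``expansion`` the
    external branch lengths are multiplied by ``expansion_factor``,
    loading the frequency spectrum with singletons as after a recent
    copy-number expansion, which drives Tajima's D negative.
    """
    if n_copies < 2:
        raise ValueError(f"need at least 2 copies, got {n_copies}")
    rng = np.random.default_rng(seed)
    L = len(consensus)
    theta_total = theta_per_site * L
    scale = expansion_factor if expansion else 1.0
    branches = sample_genealogy(n_copies, rng, external_scale=scale)

    copies = np.tile(_seq_to_ints(consensus), (n_copies, 1))
    # older branches first so a nested younger mutation can overwrite
    for br in sorted(branches, key=lambda b: -b.n_descendants):
        m = rng.poisson(0.5 * theta_total * br.duration)
        if m == 0:
            continue
        sites = rng.integers(0, L, size=m)
        rows = list(br.leaves)
        for site in sites:
            old = copies[rows[0], site]
            new = (old + rng.integers(1, 4)) % 4
            copies[rows, site] = new
    return CopyAlignment(tuple(_ints_to_seq(row) for row in copies))


def simulate_coverage_profile(
    te_length: int,
    true_copy_number: float,
    baseline_depth: float,
    noise_cv: float = 0.1,
    seed: int | None = None,
    te_id: str = "te",
) -> CoverageProfile:
    """Per-base depth over a TE consensus with known true copy number.

    Mean depth is true_copy_number x baseline_depth with multiplicative
    lognormal noise of the given coefficient of variation; the
    single-copy reference chromosome's median depth is recorded as the
    baseline. noise_cv = 0 gives exact constant depth.
    """
    if te_length < 1:
        raise ValueError("te_length must be >= 1")
    if true_copy_number < 0:
        raise ValueError("true_copy_number must be >= 0")
    rng = np.random.default_rng(seed)
    mean = true_copy_number * baseline_depth
    if mean == 0:
        depths = np.zeros(te_length)
    elif noise_cv == 0:
        depths = np.full(te_length, mean)
    else:
        sigma2 = np.log1p(noise_cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        depths = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=te_length)
    return CoverageProfile(
        te_id=te_id, depths=depths, baseline_median=baseline_depth,
        true_copy_number=true_copy_number,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_pingpong_reads(
    consensus: str,
    n_pairs: int,
    offset: int = 10,
    u1_freq: float = 0.75,
    background_frac: float = 0.2,
    length_range: tuple[int, int] = (24, 29),
    seed: int | None = None,
    te_id: str = "te",
) -> list[SmallRNARead]:
    """Ping-pong-structured piRNA reads over one TE consensus.

    Each structured pair is a sense initiator whose 5' base is a T with
    probability ``u1_freq`` (start sites are chosen among consensus
    positions carrying / not carrying a T, so reads stay exact consensus
    substrings) and an antisense responder whose 5' end is placed so the
    5'/5' overlap equals ``offset``; the responder sequence is the exact
    reverse complement of the covered consensus span, so any adenine
    bias at responder position ``offset`` is emergent from
    complementarity, never written in. A ``background_frac`` fraction of
    all reads is uniform-position, uniform-strand noise.
    """
    lmin, lmax = length_range
    if not 1 <= offset <= lmin:
        raise ValueError(f"offset {offset} outside [1, min length {lmin}]")
    if not 0.0 <= background_frac <= 1.0:
        raise ValueError("background_frac must be in [0, 1]")
    if not 0.0 <= u1_freq <= 1.0:
        raise ValueError("u1_freq must be in [0, 1]")
    L = len(consensus)
    if L < 3 * lmax:
        raise ValueError("consensus too short for the read length range")
    rng = np.random.default_rng(seed)
    consensus = consensus.upper()

    if background_frac >= 1.0:
        n_struct_pairs, n_background = 0, 2 * n_pairs
    else:
        n_struct_pairs = n_pairs
        n_background = round(
            2 * n_pairs * background_frac / (1.0 - background_frac)
        )

    # valid initiator 5' positions keep both mates inside the consensus
    lo, hi = lmax, L - lmax  # inclusive lower, exclusive upper
    valid = np.arange(lo, hi)
    is_t = np.array([consensus[p] == "T" for p in valid])
    t_pos, non_t_pos = valid[is_t], valid[~is_t]

    reads: list[SmallRNARead] = []
    for _ in range(n_struct_pairs):
        want_t = rng.random() < u1_freq
        pool = t_pos if (want_t and t_pos.size) else non_t_pos
        if pool.size == 0:
            pool = valid
        p5 = int(pool[rng.integers(pool.size)])
        lp = int(rng.integers(lmin, lmax + 1))
        reads.append(SmallRNARead(
            te_id=te_id, start=p5, length=lp, strand="+",
            sequence=consensus[p5 : p5 + lp],
        ))
        q5 = p5 + offset - 1
        lr = int(rng.integers(lmin, lmax + 1))
        start = q5 - lr + 1
        reads.append(SmallRNARead(
            te_id=te_id, start=start, length=lr, strand="-",
            sequence=_revcomp(consensus[start : q5 + 1]),
        ))
    for _ in range(n_background):
        lr = int(rng.integers(lmin, lmax + 1))
        start = int(rng.integers(0, L - lr + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        segment = consensus[start : start + lr]
        reads.append(SmallRNARead(
            te_id=te_id, start=start, length=lr, strand=strand,
            sequence=segment if strand == "+" else _revcomp(segment),
        ))
    return reads


_HIT_SCENARIOS = ("known_single", "multi_one_superfamily", "multi_one_order",
                  "gene_like", "orphan")


def simulate_hit_table(scenario: str, seed: int | None = None) -> list[HitRecord]:
    """BLAST-style hit rows for one candidate under a named scenario.

    Scenarios map one-to-one onto the decision-tree outcomes:
    ``known_single`` (one TE subject), ``multi_one_superfamily``,
    ``multi_one_order`` (several superfamilies of one order),
    ``gene_like`` (nr gene as primary hit, no TE subjects) and
    ``orphan`` (no hits at all).
    """
    if scenario not in _HIT_SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {_HIT_SCENARIOS}"
        )
    rng = np.random.default_rng(seed)

    def ev():
        return float(10.0 ** rng.uniform(-40, -9))

    def ident():
        return float(rng.uniform(85.0, 99.9))

    q = "cand1"
    if scenario == "known_single":
        return [HitRecord(q, "Gypsy10_Dpse", "Gypsy", "LTR", ev(), ident())]
    if scenario == "multi_one_superfamily":
        fams = ["Gypsy3_Dpse", "Gypsy7_Dpse", "Gypsy12_Dper"]
        return [HitRecord(q, f, "Gypsy", "LTR", ev(), ident()) for f in fams]
    if scenario == "multi_one_order":
        rows = [
            HitRecord(q, "Gypsy3_Dpse", "Gypsy", "LTR", ev(), ident()),
            HitRecord(q, "Copia1_Dpse", "Copia", "LTR", ev(), ident()),
            HitRecord(q, "BEL2_Dpse", "BEL-Pao", "LTR", ev(), ident()),
        ]
        return rows
    if scenario == "gene_like":
        return [
            HitRecord(q, "XP_001354321", "", "", ev(), ident(),
                      is_te_subject=False, nr_subject_kind="gene"),
            HitRecord(q, "hypothetical_prot", "", "", ev(), ident(),
                      is_te_subject=False, nr_subject_kind="other"),
        ]
    return []  # orphan


@dataclass
class GenomeMosaic:
    """A synthetic genome with TE insertions and N gaps, plus truth."""

    sequence: str
    te_intervals: list[tuple[int, int, str]]  # (start, end, family_id), disjoint
    n_intervals: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.sequence)


def simulate_genome_mosaic(
    families: dict[str, str],
    genome_length: int,
    n_insertions: int,
    n_gap_frac: float = 0.0,
    seed: int | None = None,
) -> GenomeMosaic:
    """Random genome with disjoint TE insertions and N runs.

    TE insertions are copies of the given family sequences placed at
    disjoint 0-based half-open intervals that also avoid the N runs; the
    N runs cover approximately ``n_gap_frac`` of the genome. Raises when
    the requested content cannot fit.
    """
    if not 0.0 <= n_gap_frac < 1.0:
        raise ValueError("n_gap_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fam_ids = sorted(families)
    if n_insertions > 0 and not fam_ids:
        raise ValueError("n_insertions > 0 but no family sequences given")
    need = sum(
        len(families[fam_ids[i % len(fam_ids)]]) for i in range(n_insertions)
    ) if n_insertions else 0
    n_total = int(round(n_gap_frac * genome_length))
    if need + n_total > genome_length:
        raise ValueError(
            f"requested content ({need} TE + {n_total} N bases) exceeds "
            f"genome length {genome_length}"
        )

    occupied: list[tuple[int, int]] = []

    def place(length: int) -> tuple[int, int]:
        for _ in range(10_000):
            s = int(rng.integers(0, genome_length - length + 1))
            e = s + length
            if all(e <= s0 or s >= e0 for s0, e0 in occupied):
                occupied.append((s, e))
                return s, e
        raise ValueError("could not place interval; genome too full")

    n_intervals: list[tuple[int, int]] = []
    remaining = n_total
    while remaining > 0:
        run = int(min(remaining, rng.integers(200, 2000)))
        s, e = place(run)
        n_intervals.append((s, e))
        remaining -= run

    te_intervals: list[tuple[int, int, str]] = []
    for i in range(n_insertions):
        fam = fam_ids[i % len(fam_ids)]
        s, e = place(len(families[fam]))
        te_intervals.append((s, e, fam))

    genome = rng.integers(0, 4, size=genome_length)
    seq = list(_ints_to_seq(genome.astype(np.int8)))
    for s, e in n_intervals:
        seq[s:e] = "N" * (e - s)
    for s, e, fam in te_intervals:
        seq[s:e] = families[fam]
    te_intervals.sort()
    n_intervals.sort()
    return GenomeMosaic(
        sequence="".join(seq), te_intervals=te_intervals, n_intervals=n_intervals
    )
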