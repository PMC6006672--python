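"""End-to-end orchestration on a simulated family bundle.

``run_pipeline`` generates genes and TE families on the species tree
(with injected horizontal transfers as ground truth), computes genic and
TE dS, classifies every family x species pair with the quantile rule,
applies the ENC confirmation and NJ/RF discordance check, runs the
polymorphism and ping-pong stages, and writes one TSV artifact per stage
plus a machine-readable summary. Identical config + seed reproduces
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codonstats, htt, popgen, smallrna, synthetic_data
from .io import write_tsv

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "divergence", "classify", "popgen", "smallrna")


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the study's rules."""

    seed: int = 0
    out_dir: str = "te_exchange_run"
    stages: tuple = STAGES
    # decision thresholds
    q_strong: float = 0.025
    q_none: float = 0.50
    identity_threshold: float = 0.90
    min_hits: int = 25
    fold: float = 2.0
    min_frac: float = 0.8
    window: int = 1_000_000
    step: int = 100_000
    min_freq: float = 0.5
    enc_window_width: float = 5.0
    enc_k: float = 2.0
    # simulated study conditions
    n_genes: int = 120
    n_vertical_families: int = 20
    n_ht_families: int = 5
    sequence_length_codons: int = 300
    rate_sd: float = 0.3  # lognormal sd of per-locus substitution rate
    ht_time_fraction: float = 0.05
    copies_per_species: int = 10
    theta_per_site: float = 0.005
    n_popgen_families: int = 5
    pingpong_pairs: int = 2000

    def __post_init__(self):
        for name in ("q_strong", "q_none", "identity_threshold", "min_frac",
                     "min_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.q_strong > self.q_none:
            raise ValueError("q_strong must not exceed q_none")
        for name in ("min_hits", "window", "step", "n_genes",
                     "n_vertical_families", "sequence_length_codons",
                     "copies_per_species", "pingpong_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fold", "rate_sd", "theta_per_site"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ht_time_fraction < 1.0:
            raise ValueError("ht_time_fraction must be in [0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _raw_divergence(a: str, b: str) -> float:
    diffs = sum(x != y for x, y in zip(a, b))
    return diffs / len(a)


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the machine-readable summary.

    Artifacts (TSV with config-hash/seed header comments) are written to
    ``config.out_dir``. Any stage failure raises with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": config.config_hash(), "seed": config.seed}
    tree = synthetic_data.default_species_tree()
    species = tree.species
    pairs = [
        _pair_key(a, b) for a, b in itertools.combinations(species, 2)
    ]
    rng = np.random.default_rng(config.seed)
    n_fam = config.n_vertical_families + config.n_ht_families
    seeds = _child_seeds(config.seed, config.n_genes + n_fam + 4)
    gene_seeds = seeds[: config.n_genes]
    fam_seeds = seeds[config.n_genes : config.n_genes + n_fam]
    aux_seeds = seeds[config.n_genes + n_fam :]
    written: dict[str, str] = {}

    def _emit(name: str, df: pd.DataFrame):
        path = out_dir / name
        write_tsv(path, df, header_comments=header)
        written[name] = hashlib.sha1(path.read_bytes()).hexdigest()

    def _check_artifacts(stage: str):
        for name, digest in written.items():
            now = hashlib.sha1((out_dir / name).read_bytes()).hexdigest()
            if now != digest:
                raise RuntimeError(
                    f"stage {stage!r} mutated earlier artifact {name}"
                )

    report: dict = {"config_hash": header["config_hash"], "seed": config.seed}

    # --- simulate + divergence: genes -----------------------------------
    try:
        rate = lambda: float(rng.lognormal(-config.rate_sd**2 / 2.0,  # noqa: E731
                                           config.rate_sd))
        genic_ds: dict[tuple[str, str], list[float]] = {p: [] for p in pairs}
        genic_enc: dict[tuple[str, str], list[tuple[float, float]]] = {
            p: [] for p in pairs
        }
        gene_rows = []
        for g, gseed in enumerate(gene_seeds):
            cfg = synthetic_data.SimulationConfig(
                seed=gseed,
                sequence_length_codons=config.sequence_length_codons,
            )
            seqs = synthetic_data.evolve_family_on_tree(
                tree, cfg, rate_scale=rate()
            )
            for a, b in pairs:
                est = codonstats.ng86(
                    codonstats.CodonAlignment(seqs[a], seqs[b])
                )
                enc = codonstats.effective_number_of_codons(seqs[a])
                genic_ds[(a, b)].append(est.dS)
                genic_enc[(a, b)].append((est.dS, enc.Nc))
                gene_rows.append({
                    "gene_id": f"gene{g}", "pair": f"{a}-{b}", "ds": est.dS,
                    "enc": enc.Nc,
                })
        _emit("genic_ds.tsv", pd.DataFrame(gene_rows))
        genic_dists = {
            p: htt.GenicDsDistribution(
                species_pair=p, ds_values=np.array(genic_ds[p]),
                q_strong=config.q_strong, q_none=config.q_none,
            )
            for p in pairs
        }
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' (genes) failed: {e}") from e

    # --- simulate + divergence + classify: TE families ------------------
    try:
        # transfers are injected between sympatric non-sister species: the
        # allopatric outgroup does not exchange TEs, and exchange between
        # the sister pair is observationally confounded with hybridisation
        sympatric = [s for s in species if s != "affinis"]
        sister_cutoff = 2.5 * min(
            tree.path_length(a, b)
            for a, b in itertools.combinations(sympatric, 2)
        )
        donor_pairs = [
            (a, b)
            for a, b in itertools.permutations(sympatric, 2)
            if tree.path_length(a, b) >= sister_cutoff
        ]
        injected: dict[str, dict] = {}
        fam_consensus: dict[str, dict[str, str]] = {}
        calls: list[htt.HTTCall] = []
        te_rows = []
        n_discordant = 0
        for i, fseed in enumerate(fam_seeds):
            fam_id = f"fam{i}"
            is_ht = i >= config.n_vertical_families
            ht_event = None
            if is_ht:
                donor, recipient = donor_pairs[
                    int(rng.integers(len(donor_pairs)))
                ]
                ht_event = synthetic_data.HTEvent(
                    family_id=fam_id, donor=donor, recipient=recipient,
                    time_fraction=config.ht_time_fraction,
                )
                injected[fam_id] = {"donor": donor, "recipient": recipient}
            cfg = synthetic_data.SimulationConfig(
                seed=fseed,
                sequence_length_codons=config.sequence_length_codons,
            )
            seqs = synthetic_data.evolve_family_on_tree(
                tree, cfg, ht=ht_event, rate_scale=rate()
            )
            fam_consensus[fam_id] = seqs

            dm = np.zeros((len(species), len(species)))
            for (ia, a), (ib, b) in itertools.combinations(
                enumerate(species), 2
            ):
                key = _pair_key(a, b)
                est = codonstats.ng86(
                    codonstats.CodonAlignment(seqs[a], seqs[b])
                )
                enc = codonstats.effective_number_of_codons(seqs[a])
                call = htt.classify_htt(est.dS, genic_dists[key], fam_id)
                conf = htt.enc_conditioned_test(
                    (est.dS, enc.Nc), genic_enc[key],
                    window_width=config.enc_window_width, k=config.enc_k,
                )
                call.enc_confirmed = conf.confirmed
                calls.append(call)
                raw = _raw_divergence(seqs[a], seqs[b])
                dm[ia, ib] = dm[ib, ia] = raw
                te_rows.append({
                    "family_id": fam_id, "pair": f"{key[0]}-{key[1]}",
                    "ds": est.dS, "enc": enc.Nc, "category": call.category,
                    "enc_confirmed": conf.confirmed,
                })
            fam_tree = htt.nj_tree(
                htt.DistanceMatrix(tuple(species), dm)
            )
            rf, disc = htt.rf_discordance(fam_tree, tree.tree)
            n_discordant += disc
            for c in calls:
                if c.family_id == fam_id:
                    c.discordant = disc
        _emit("te_calls.tsv", pd.DataFrame(te_rows))
        summary = htt.summarize_transfers(calls)
        _emit("calls_per_pair.tsv", summary["per_pair"].reset_index())
        strong_families = sorted({
            c.family_id for c in calls if c.category == "strong"
        })
        report.update({
            "n_families": n_fam,
            "n_genes": config.n_genes,
            "calls_per_category": {
                cat: sum(c.category == cat for c in calls)
                for cat in htt.CATEGORIES
            },
            "strong_families": strong_families,
            "strong_all_pairs": summary["strong_all_pairs"],
            "n_discordant_families": int(n_discordant),
            "injected_ht": injected,
        })
        _check_artifacts("classify")
    except RuntimeError:
        raise
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    # --- popgen ----------------------------------------------------------
    if "popgen" in config.stages:
        try:
            rows = []
            null = popgen.coalescent_null(
                n=config.copies_per_species,
                theta=config.theta_per_site
                * config.sequence_length_codons * 3,
                n_reps=1000, seed=aux_seeds[0],
            )
            pg_rng = np.random.default_rng(aux_seeds[1])
            for fam_id in list(fam_consensus)[: config.n_popgen_families]:
                copies = {}
                for sp in ("pseudoobscura", "persimilis"):
                    copies[sp] = synthetic_data.simulate_te_copies(
                        fam_consensus[fam_id][sp],
                        n_copies=config.copies_per_species,
                        theta_per_site=config.theta_per_site,
                        seed=int(pg_rng.integers(2**31)),
                    )
                for sp, aln in copies.items():
                    s = popgen.tajimas_d(aln)
                    p = (
                        popgen.tajima_p(s.tajima_d, null)
                        if s.defined else math.nan
                    )
                    rows.append({
                        "family_id": fam_id, "species": sp, "n": s.n,
                        "S": s.S, "pi": s.pi, "theta_w": s.theta_w,
                        "tajima_d": s.tajima_d, "p_value": p,
                    })
                shared = popgen.shared_polymorphism(
                    copies["pseudoobscura"], copies["persimilis"],
                    species_pair=("pseudoobscura", "persimilis"),
                    family_id=fam_id,
                )
                rows.append({
                    "family_id": fam_id, "species": "shared",
                    "n": shared.shared_sites, "S": shared.union_sites,
                    "pi": shared.proportion, "theta_w": math.nan,
                    "tajima_d": math.nan, "p_value": math.nan,
                })
            _emit("popgen.tsv", pd.DataFrame(rows))
            _check_artifacts("popgen")
        except RuntimeError:
            raise
        except Exception as e:
            raise RuntimeError(f"stage 'popgen' failed: {e}") from e

    # --- smallrna --------------------------------------------------------
    if "smallrna" in config.stages:
        try:
            consensus = fam_consensus["fam0"]["pseudoobscura"]
            reads = synthetic_data.simulate_pingpong_reads(
                consensus, n_pairs=config.pingpong_pairs, seed=aux_seeds[2]
            )
            pirnas = [r for r in reads
                      if smallrna.classify_length(r) == "piRNA"]
            spec = smallrna.overlap_spectrum(pirnas)
            _emit("smallrna_spectrum.tsv", pd.DataFrame({
                "offset": spec.offsets, "count": spec.counts,
            }))
            report["pingpong"] = {
                "modal_offset": spec.modal_offset,
                "z10": spec.z10,
            }
            _check_artifacts("smallrna")
        except RuntimeError:
            raise
        except Exception as e:
            raise RuntimeError(f"stage 'smallrna' failed: {e}") from e

    summary_df = pd.DataFrame([{
        "key": k,
        "value": json.dumps(v, sort_keys=True) if isinstance(
            v, (dict, list)) else v,
    } for k, v in report.items()])
    _emit("summary.tsv", summary_df)
    return report
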