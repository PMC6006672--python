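"""Simulator calibration and determinism."""

import math

import numpy as np
import pytest

from te_exchange.codonstats import GENETIC_CODE, STOP_CODONS
from te_exchange.popgen import tajima_constants
from te_exchange.synthetic_data import (
    HTEvent,
    SimulationConfig,
    SpeciesTree,
    default_species_tree,
    evolve_family_on_tree,
    random_orf,
    simulate_coverage_profile,
    simulate_genome_mosaic,
    simulate_hit_table,
    simulate_pingpong_reads,
    simulate_te_copies,
)


def _raw_div(a, b):
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestSpeciesTree:
    def test_default_is_anchored_at_sister_pair_ds(self, species_tree):
        assert species_tree.path_length(
            "pseudoobscura", "persimilis"
        ) == pytest.approx(0.018)

    def test_default_is_ultrametric(self, species_tree):
        depths = {sp: species_tree.depth(sp) for sp in species_tree.species}
        assert all(d == pytest.approx(0.108) for d in depths.values())

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SpeciesTree("((a:1,a:1):1,b:2);")

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SpeciesTree("((a:1,b:-1):1,c:2);")


class TestEvolveFamily:
    def test_zero_length_branches_identical_tips(self):
        tree = SpeciesTree("(a:0,b:0);")
        cfg = SimulationConfig(seed=1, sequence_length_codons=50)
        seqs = evolve_family_on_tree(tree, cfg)
        assert seqs["a"] == seqs["b"]

    def test_root_is_valid_orf(self, rng):
        orf = random_orf(100, rng)
        codons = {orf[i:i + 3] for i in range(0, len(orf), 3)}
        assert codons <= set(GENETIC_CODE)
        assert not codons & STOP_CODONS

    def test_sister_pair_divergence_calibration(self, species_tree):
        """pse-per raw divergence matches the JC expectation for the
        0.018 path within 3 binomial SE at 3000 codons."""
        cfg = SimulationConfig(seed=8, sequence_length_codons=3000)
        seqs = evolve_family_on_tree(species_tree, cfg)
        L = 9000
        p_exp = 0.75 * (1 - math.exp(-4 * 0.018 / 3))
        se = math.sqrt(p_exp * (1 - p_exp) / L)
        obs = _raw_div(seqs["pseudoobscura"], seqs["persimilis"])
        assert abs(obs - p_exp) < 3 * se

    def test_k2p_model_supported(self, species_tree):
        cfg = SimulationConfig(
            seed=2, substitution_model="K2P", kappa=4.0,
            sequence_length_codons=500,
        )
        seqs = evolve_family_on_tree(species_tree, cfg)
        assert len(seqs) == 5

    def test_ht_shrinks_divergence(self, species_tree):
        cfg = SimulationConfig(seed=3, sequence_length_codons=1000)
        ht = HTEvent("f", "pseudoobscura", "lowei", 0.05)
        seqs = evolve_family_on_tree(species_tree, cfg, ht=ht)
        vertical = evolve_family_on_tree(species_tree, cfg)
        d_ht = _raw_div(seqs["pseudoobscura"], seqs["lowei"])
        d_vert = _raw_div(vertical["pseudoobscura"], vertical["lowei"])
        assert d_ht < d_vert / 3

    def test_ht_divergence_matches_expectation(self, species_tree):
        # expected donor-recipient divergence = 2 * tf * depth
        tf = 0.1
        expected_t = 2 * tf * 0.108
        p_exp = 0.75 * (1 - math.exp(-4 * expected_t / 3))
        L = 3000 * 3
        divs = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, sequence_length_codons=3000)
            ht = HTEvent("f", "miranda", "persimilis", tf)
            seqs = evolve_family_on_tree(species_tree, cfg, ht=ht)
            divs.append(_raw_div(seqs["miranda"], seqs["persimilis"]))
        se = math.sqrt(p_exp * (1 - p_exp) / (L * 5))
        assert abs(np.mean(divs) - p_exp) < 4 * se

    def test_unknown_species_in_ht_named(self, species_tree):
        cfg = SimulationConfig(seed=1)
        ht = HTEvent("f", "pseudoobscura", "melanogaster", 0.1)
        with pytest.raises(ValueError, match="melanogaster"):
            evolve_family_on_tree(species_tree, cfg, ht=ht)

    def test_donor_equals_recipient_rejected(self):
        with pytest.raises(ValueError):
            HTEvent("f", "a", "a", 0.1)

    def test_determinism(self, species_tree):
        cfg = SimulationConfig(seed=77, sequence_length_codons=100)
        assert evolve_family_on_tree(species_tree, cfg) == \
            evolve_family_on_tree(species_tree, cfg)


class TestTeCopies:
    def test_zero_theta_identical_copies(self):
        aln = simulate_te_copies("ACGTAG", 5, 0.0, seed=1)
        assert set(aln.sequences) == {"ACGTAG"}

    def test_mean_segregating_sites_calibration(self):
        """Mean S over 2000 replicates within 3 SE of theta * a1(10).

        theta_total = 5 is spread over 1000 sites so that the
        finite-sites simulator is in its infinite-sites regime and the
        closed-form coalescent expectation applies.
        """
        consensus = "ACGT" * 250  # L=1000, theta_total = 5
        a1 = tajima_constants(10)["a1"]
        s_vals = []
        for seed in range(2000):
            aln = simulate_te_copies(consensus, 10, 0.005, seed=seed)
            mat = np.array([list(s) for s in aln.sequences])
            s_vals.append(int((~(mat == mat[0]).all(axis=0)).sum()))
        mean = np.mean(s_vals)
        se = np.std(s_vals, ddof=1) / math.sqrt(len(s_vals))
        assert abs(mean - 5 * a1) < 3 * se

    def test_too_few_copies_rejected(self):
        with pytest.raises(ValueError):
            simulate_te_copies("ACGT", 1, 0.01)

    def test_determinism(self):
        a = simulate_te_copies("ACGT" * 50, 8, 0.01, seed=12)
        b = simulate_te_copies("ACGT" * 50, 8, 0.01, seed=12)
        assert a.sequences == b.sequences


class TestCoverage:
    def test_noise_free_exact(self):
        prof = simulate_coverage_profile(100, 5, 10.0, noise_cv=0.0, seed=1)
        np.testing.assert_allclose(prof.depths, 50.0)

    def test_zero_copies_zero_depth(self):
        prof = simulate_coverage_profile(100, 0, 10.0, seed=1)
        assert prof.depths.sum() == 0

    def test_mean_and_cv(self):
        prof = simulate_coverage_profile(
            50_000, 7, 30.0, noise_cv=0.1, seed=2
        )
        assert prof.depths.mean() == pytest.approx(210.0, rel=0.01)
        cv = prof.depths.std() / prof.depths.mean()
        assert cv == pytest.approx(0.1, rel=0.1)

    def test_recovery_through_estimator(self):
        from te_exchange.annotation import estimate_copy_number
        prof = simulate_coverage_profile(
            5000, 7, 30.0, noise_cv=0.1, seed=3
        )
        assert estimate_copy_number(prof) == pytest.approx(7.0, rel=0.1)


class TestHitTables:
    def test_scenarios_shape(self):
        known = simulate_hit_table("known_single", seed=1)
        assert len(known) == 1 and known[0].is_te_subject

        multi = simulate_hit_table("multi_one_superfamily", seed=1)
        assert len(multi) >= 2
        assert len({h.subject_superfamily for h in multi}) == 1

        order = simulate_hit_table("multi_one_order", seed=1)
        assert len({h.subject_superfamily for h in order}) > 1
        assert len({h.subject_order for h in order}) == 1

        gene = simulate_hit_table("gene_like", seed=1)
        assert not any(h.is_te_subject for h in gene)

        assert simulate_hit_table("orphan", seed=1) == []

    def test_scenarios_round_trip_through_classifier(self):
        from te_exchange.annotation import classify_candidate
        expected = {
            "known_single": "known_family",
            "multi_one_superfamily": "novel_in_superfamily",
            "multi_one_order": "novel_in_order",
            "gene_like": "discarded_gene_like",
            "orphan": "unknown_retained",
        }
        for scenario, label in expected.items():
            hits = simulate_hit_table(scenario, seed=3)
            assert classify_candidate(hits).label == label, scenario

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            simulate_hit_table("nonsense")


class TestGenomeMosaic:
    def test_no_insertions_empty_truth(self):
        mosaic = simulate_genome_mosaic({}, 10_000, 0, seed=1)
        assert mosaic.te_intervals == []

    def test_truth_intervals_disjoint_and_match_sequence(self):
        fams = {"f1": "ACGTA" * 40, "f2": "GGCCA" * 30}
        mosaic = simulate_genome_mosaic(fams, 50_000, 20, 0.05, seed=2)
        ivs = [(s, e) for s, e, _ in mosaic.te_intervals]
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        for s, e, fam in mosaic.te_intervals:
            assert mosaic.sequence[s:e] == fams[fam]

    def test_n_fraction(self):
        mosaic = simulate_genome_mosaic({}, 100_000, 0, 0.10, seed=3)
        n_frac = mosaic.sequence.count("N") / len(mosaic.sequence)
        assert n_frac == pytest.approx(0.10, abs=0.01)

    def test_overfull_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_genome_mosaic({"f": "A" * 600}, 1000, 2, seed=1)

    def test_determinism(self):
        a = simulate_genome_mosaic({"f": "ACGT" * 10}, 5000, 5, 0.02, seed=4)
        b = simulate_genome_mosaic({"f": "ACGT" * 10}, 5000, 5, 0.02, seed=4)
        assert a.sequence == b.sequence
        assert a.te_intervals == b.te_intervals


class TestPingPongReads:
    def test_determinism(self):
        consensus = random_orf(250, np.random.default_rng(1))
        a = simulate_pingpong_reads(consensus, 100, seed=6)
        b = simulate_pingpong_reads(consensus, 100, seed=6)
        assert a == b

    def test_responder_is_exact_complement(self):
        consensus = random_orf(250, np.random.default_rng(2))
        reads = simulate_pingpong_reads(
            consensus, 50, background_frac=0.0, seed=7
        )
        comp = str.maketrans("ACGT", "TGCA")
        for r in reads:
            if r.strand == "-":
                span = consensus[r.start:r.start + r.length]
                assert r.sequence == span.translate(comp)[::-1]

    def test_invalid_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            simulate_pingpong_reads("ACGT" * 100, 10, offset=30)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="model"):
            SimulationConfig(substitution_model="GTR")
        with pytest.raises(ValueError):
            SimulationConfig(theta_per_site=-1)
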