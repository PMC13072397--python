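"""Synthetic-data generators: determinism, composition targets, planted
structure, and configuration validation."""

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.errors import ConfigError
from mitocomp.selection import f3x4_frequencies
from mitocomp.simulate import _codon_freqs, simulate_study


class TestDeterminism:
    def test_same_seed_identical_genome(self):
        cfg = mc.SimulationConfig(seed=99)
        a = mc.simulate_mitogenome(cfg)
        b = mc.simulate_mitogenome(cfg)
        assert a.sequence == b.sequence and a.features == b.features

    def test_same_seed_identical_alignment_and_truth(self):
        cfg = mc.SimulationConfig(seed=99, n_codons=60)
        a1, t1, c1 = mc.simulate_codon_alignment(cfg)
        a2, t2, c2 = mc.simulate_codon_alignment(cfg)
        assert (a1.codons == a2.codons).all()
        assert (c1 == c2).all()
        assert t1.to_newick() == t2.to_newick()

    def test_different_seed_differs(self):
        a = mc.simulate_mitogenome(mc.SimulationConfig(seed=1))
        b = mc.simulate_mitogenome(mc.SimulationConfig(seed=2))
        assert a.sequence != b.sequence


class TestMitogenome:
    def test_gene_census_always_complete(self):
        for seed in range(4):
            g = mc.simulate_mitogenome(mc.SimulationConfig(seed=seed))
            assert g.gene_census() == {"PCG": 13, "tRNA": 22, "rRNA": 2}

    def test_at_target_within_two_points(self):
        for seed in range(4):
            cfg = mc.SimulationConfig(seed=seed, at_target=0.78)
            g = mc.simulate_mitogenome(cfg)
            at = (g.sequence.count("A") + g.sequence.count("T")) / g.length
            assert 0.76 <= at <= 0.80

    def test_cr_between_rrns_and_genome_end(self):
        g = mc.simulate_mitogenome(mc.SimulationConfig(seed=0))
        names = [f.name for f in g.features]
        assert names.index("CR") == names.index("rrnS") + 1
        assert names[0] == "trnI"  # circularly adjacent to the CR

    def test_planted_repeat_recovered(self):
        cfg = mc.SimulationConfig(seed=13, cr=mc.simulate.CRSpec("TATTA", 8, 0.0))
        g = mc.simulate_mitogenome(cfg)
        cr = mc.extract_gene(g, "CR")
        reports = mc.find_tandem_repeats(cr, min_score=20, max_period=60)
        hit = [r for r in reports if r.period == 5]
        assert hit and hit[0].copy_number == pytest.approx(8.0)

    def test_pcgs_translate_cleanly(self):
        g = mc.simulate_mitogenome(mc.SimulationConfig(seed=3))
        for gene in mc.io.PCG_NAMES:
            peptide = mc.translate(mc.extract_gene(g, gene))
            assert len(peptide) > 0

    def test_infeasible_at_target_raises(self):
        with pytest.raises(ConfigError):
            mc.SimulationConfig(seed=0, at_target=0.99)


class TestCodonAlignment:
    def test_no_stop_codons_in_output(self, small_alignment):
        aln, _, _ = small_alignment
        for seq in aln.to_seqs().values():
            mc.translate(seq)  # raises on internal stops

    def test_degenerate_mixture_reduces_to_null(self):
        cfg = mc.SimulationConfig(seed=4, n_codons=50, omega2=1.0)
        aln, tree, classes = mc.simulate_codon_alignment(cfg)
        assert aln.n_sites == 50 and len(classes) == 50

    def test_unmarked_foreground_with_selected_classes_raises(self):
        cfg = mc.SimulationConfig(seed=4, n_codons=30,
                                  tree="((t1:0.1,t2:0.1):0.1,t3:0.1);", n_taxa=3)
        with pytest.raises(ConfigError):
            mc.simulate_codon_alignment(cfg)

    def test_empirical_frequencies_approach_f3x4_target(self):
        cfg = mc.SimulationConfig(seed=8, n_codons=4000, n_taxa=4)
        aln, _, _ = mc.simulate_codon_alignment(cfg)
        target = _codon_freqs(cfg.position_at(), aln.code)
        empirical = f3x4_frequencies(aln)
        assert np.abs(empirical - target).sum() < 0.15  # L1 over 62 states

    def test_truth_labels_match_mixture_proportions(self):
        cfg = mc.SimulationConfig(seed=9, n_codons=5000)
        _, _, classes = mc.simulate_codon_alignment(cfg)
        frac = np.bincount(classes, minlength=4) / classes.size
        assert np.abs(frac - [cfg.p0, cfg.p1, cfg.p2a, cfg.p2b]).max() < 0.03


class TestPopulation:
    def test_zero_mutation_probability(self):
        cfg = mc.SimulationConfig(
            seed=0, population=mc.simulate.PopulationSpec(4, 0.0, 500)
        )
        haps, s = mc.simulate_population(cfg)
        assert s == 0
        assert mc.nucleotide_diversity(list(haps.values())) == 0.0
        hd, _ = mc.haplotype_diversity(list(haps.values()))
        assert hd == 0.0

    def test_returned_s_matches_realised_alignment(self):
        cfg = mc.SimulationConfig(
            seed=5, population=mc.simulate.PopulationSpec(6, 0.01, 800)
        )
        haps, s = mc.simulate_population(cfg)
        assert mc.segregating_sites(list(haps.values())) == s

    def test_pi_matches_expectation_over_replicates(self):
        """E[pairwise difference] per site = 2p(1-p) + (2/3)p^2 for two
        independently mutated copies of one reference."""
        p, length = 0.01, 2000
        pis = []
        for seed in range(30):
            cfg = mc.SimulationConfig(
                seed=seed, population=mc.simulate.PopulationSpec(4, p, length)
            )
            haps, _ = mc.simulate_population(cfg)
            pis.append(mc.nucleotide_diversity(list(haps.values())))
        expected = 2 * p * (1 - p) + (2 / 3) * p * p
        se = expected / np.sqrt(len(pis) * length / 50)  # generous band
        assert np.mean(pis) == pytest.approx(expected, abs=5 * se + 5e-4)


class TestStudySimulation:
    def test_shared_coordinates_and_clean_cds(self):
        genomes = simulate_study(mc.SimulationConfig(seed=6, n_taxa=4))
        assert len({g.length for g in genomes}) == 1
        for g in genomes:
            for gene in mc.io.PCG_NAMES:
                mc.translate(mc.extract_gene(g, gene))

    def test_divergence_orders_identity(self):
        genomes = simulate_study(mc.SimulationConfig(seed=6, n_taxa=4))
        ident = mc.pairwise_identity([g.sequence for g in genomes])
        assert 90.0 < ident < 100.0


@pytest.mark.parametrize(
    "kwargs",
    [
        {"p0": 0.5, "p1": 0.1, "p2a": 0.1, "p2b": 0.1},  # proportions != 1
        {"omega0": 1.5},
        {"omega2": 0.5},
        {"at_target": 0.01},
        {"n_taxa": 1},
    ],
)
def test_invalid_configs_raise(kwargs):
    with pytest.raises(ConfigError):
        mc.SimulationConfig(seed=0, **kwargs)
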