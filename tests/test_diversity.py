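"""Pi, sliding windows, Hd, identity, and Nei-Gojobori Ka/Ks."""

import itertools
import math

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.diversity import _codon_site_counts, _pathway_diffs, jukes_cantor
from mitocomp.errors import (
    InsufficientDataError,
    MitocompError,
    SaturationError,
)


class TestNucleotideDiversity:
    def test_single_difference_fraction(self):
        a = "A" * 100
        b = "A" * 99 + "T"
        assert mc.nucleotide_diversity([a, b]) == pytest.approx(0.01)

    def test_identical_is_zero(self):
        assert mc.nucleotide_diversity(["ACGT", "ACGT", "ACGT"]) == 0.0

    def test_matches_all_pairs_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT-N"), size=80)) for _ in range(6)]
        total, pairs = 0.0, 0
        for a, b in itertools.combinations(seqs, 2):
            ok = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
            pairs += 1
            if ok:
                total += sum(x != y for x, y in ok) / len(ok)
        assert mc.nucleotide_diversity(seqs) == pytest.approx(total / pairs)

    def test_order_invariance(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(5)]
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        assert mc.nucleotide_diversity(seqs) == pytest.approx(
            mc.nucleotide_diversity(shuffled)
        )

    def test_requires_two_sequences(self):
        with pytest.raises(InsufficientDataError):
            mc.nucleotide_diversity(["ACGT"])


class TestSlidingWindow:
    def test_constant_alignment_all_zero(self):
        aln = ["A" * 200] * 3
        windows = mc.sliding_window_pi(aln)
        assert all(pi == 0.0 for _, pi in windows)

    @pytest.mark.parametrize(
        "length,window,step,expected",
        [(200, 100, 25, 5), (100, 100, 25, 1), (199, 100, 25, 4), (1000, 100, 25, 37)],
    )
    def test_window_count_formula(self, length, window, step, expected):
        aln = ["A" * length] * 2
        windows = mc.sliding_window_pi(aln, window=window, step=step)
        assert len(windows) == (length - window) // step + 1 == expected

    def test_non_overlapping_windows_average_to_global(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(4)]
        windows = mc.sliding_window_pi(seqs, window=100, step=100)
        assert np.mean([pi for _, pi in windows]) == pytest.approx(
            mc.nucleotide_diversity(seqs)
        )

    def test_window_longer_than_alignment_raises(self):
        with pytest.raises(MitocompError):
            mc.sliding_window_pi(["AAAA", "AAAT"], window=100)


class TestHaplotypeDiversity:
    def test_all_distinct(self):
        hd, counts = mc.haplotype_diversity(["AAAA", "AAAT", "AATT", "ATTT"])
        assert hd == pytest.approx(1.0)
        assert len(counts) == 4

    def test_two_plus_two_split(self):
        hd, _ = mc.haplotype_diversity(["AAAA", "AAAA", "TTTT", "TTTT"])
        assert hd == pytest.approx((4 / 3) * 0.5)

    def test_all_identical_zero(self):
        hd, counts = mc.haplotype_diversity(["ACGT"] * 5)
        assert hd == 0.0 and len(counts) == 1

    def test_excluded_position_differences_collapse(self):
        hd, counts = mc.haplotype_diversity(["ACGT", "ACGN", "ACGT"])
        assert len(counts) == 1 and hd == 0.0


class TestPairwiseIdentity:
    def test_identical_pair(self):
        assert mc.pairwise_identity(["ACGT", "ACGT"]) == 100.0

    def test_single_mismatch_in_thousand(self):
        a = "A" * 1000
        b = "A" * 999 + "C"
        assert mc.pairwise_identity([a, b]) == pytest.approx(99.9)

    def test_amino_acid_level(self):
        a = "TTTATAAAA"  # F M K
        b = "TTCATAAAA"  # F M K (synonymous change)
        assert mc.pairwise_identity([a, b], level="amino_acid") == 100.0
        assert mc.pairwise_identity([a, b]) == pytest.approx(100 * 8 / 9)


class TestKaKs:
    def test_identical_sequences(self):
        est = mc.ka_ks("TTTATAAAA", "TTTATAAAA")
        assert est.ka == 0.0 and est.ks == 0.0 and math.isnan(est.ratio)

    def test_single_synonymous_change(self):
        est = mc.ka_ks("TTT" * 20, "TTC" + "TTT" * 19)
        assert est.ka == 0.0 and est.ks > 0.0

    def test_single_nonsynonymous_change(self):
        est = mc.ka_ks("TTT" * 20, "GTT" + "TTT" * 19)
        assert est.ks == 0.0 and est.ka > 0.0

    def test_site_counts_total_three_per_codon(self, code5, rng):
        sense = list(code5.sense_codons)
        for _ in range(25):
            c = sense[int(rng.integers(len(sense)))]
            s, n = _codon_site_counts(c, code5)
            assert s + n == pytest.approx(3.0)

    def test_symmetry_exact(self, code5, rng):
        sense = list(code5.sense_codons)
        for _ in range(10):
            a_codons = list(rng.choice(sense, size=40))
            b_codons = list(a_codons)
            for i in rng.choice(40, size=6, replace=False):  # moderate divergence
                b_codons[i] = str(rng.choice(sense))
            a, b = "".join(a_codons), "".join(b_codons)
            e1 = mc.ka_ks(a, b, code5)
            e2 = mc.ka_ks(b, a, code5)
            assert e1.ka == e2.ka and e1.ks == e2.ks
            assert e1.s_sites == e2.s_sites and e1.n_sites == e2.n_sites

    def test_pathway_average_oracle_sampled(self, code5, rng):
        """Spot-check pathway averaging against explicit order enumeration
        (the full pairwise sweep lives in the acceptance suite)."""
        sense = list(code5.sense_codons)
        checked = 0
        while checked < 30:
            a, b = rng.choice(sense, size=2)
            ndiff = sum(x != y for x, y in zip(a, b))
            if ndiff < 2:
                continue
            syn, non = _pathway_diffs(a, b, code5)
            o_syn, o_non, n_used = _oracle_pathways(a, b, code5)
            assert syn == pytest.approx(o_syn) and non == pytest.approx(o_non)
            checked += 1

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.8)

    def test_length_mismatch(self):
        with pytest.raises(MitocompError):
            mc.ka_ks("TTT", "TTTTTT")

    def test_purifying_simulation_gives_ratio_below_one(self):
        """Alignments evolved entirely under omega0 < 1 show Ka/Ks < 1 for
        every sequence pair."""
        cfg = mc.SimulationConfig(
            seed=3, n_codons=400, p0=1.0, p1=0.0, p2a=0.0, p2b=0.0, omega0=0.1
        )
        aln, tree, _ = mc.simulate_codon_alignment(cfg)
        seqs = aln.to_seqs()
        mean_ratio, pairs = mc.diversity.clade_ka_ks(seqs)
        assert mean_ratio < 1.0
        for _, _, est in pairs:
            assert math.isnan(est.ratio) or est.ratio < 1.0


def _oracle_pathways(a, b, code):
    """Independent enumeration over orderings of differing positions."""
    positions = [i for i in range(3) if a[i] != b[i]]
    usable, all_paths = [], []
    for order in itertools.permutations(positions):
        steps, cur, blocked = [], a, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            blocked = blocked or code.is_stop(nxt)
            steps.append((cur, nxt))
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            usable.append(steps)
    chosen = usable if usable else all_paths
    syn = non = 0.0
    for steps in chosen:
        for x, y in steps:
            if code.is_stop(x) or code.is_stop(y):
                non += 1
            elif code.aa(x) == code.aa(y):
                syn += 1
            else:
                non += 1
    return syn / len(chosen), non / len(chosen), len(chosen)
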