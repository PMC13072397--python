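"""RSCU, ENC (Wright's estimator and the null curve), CBI."""

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.codon_usage import (
    cbi,
    count_codons,
    default_optimal_codons,
    enc,
    enc_expected,
    gc3,
    rscu,
)
from mitocomp.errors import UndefinedStatisticError


def _uniform_counts(code, per_codon=50):
    return {c: per_codon for c in code.sense_codons}


class TestRSCU:
    def test_uniform_usage_all_one(self, code5):
        values = rscu(_uniform_counts(code5), code5)
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_exclusive_codon_in_fourfold_family(self, code5):
        fam = code5.families["V"]  # GTN, 4-fold
        counts = dict.fromkeys(code5.sense_codons, 0)
        counts[fam[0]] = 40
        values = rscu(counts, code5)
        assert values[fam[0]] == pytest.approx(4.0)
        assert all(values[c] == 0.0 for c in fam[1:])

    def test_family_sums_equal_family_sizes(self, code5, rng):
        counts = {c: int(rng.integers(0, 50)) for c in code5.sense_codons}
        values = rscu(counts, code5)
        for aa, codons in code5.families.items():
            total = sum(counts[c] for c in codons)
            fam_sum = sum(values[c] for c in codons)
            if total == 0:
                assert all(np.isnan(values[c]) for c in codons)
            else:
                assert fam_sum == pytest.approx(len(codons))

    def test_zero_family_reported_missing_not_zero(self, code5):
        counts = dict.fromkeys(code5.sense_codons, 5)
        for c in code5.families["K"]:
            counts[c] = 0
        values = rscu(counts, code5)
        assert all(np.isnan(values[c]) for c in code5.families["K"])


class TestENC:
    @pytest.mark.parametrize("table", [1, 5])
    def test_uniform_usage_gives_sense_codon_count(self, table):
        code = mc.get_code(table)
        assert enc(_uniform_counts(code), code) == pytest.approx(code.n_sense)

    @pytest.mark.parametrize("table", [1, 5])
    def test_one_codon_per_amino_acid_gives_aa_count(self, table):
        code = mc.get_code(table)
        counts = dict.fromkeys(code.sense_codons, 0)
        for aa, codons in code.families.items():
            counts[codons[0]] = 30
        assert enc(counts, code) == pytest.approx(len(code.families))

    def test_matches_direct_formula_oracle(self, code5, rng):
        """Independent re-derivation of Wright's estimator from raw counts."""
        for _ in range(10):
            counts = {c: int(rng.integers(1, 60)) for c in code5.sense_codons}
            by_size: dict[int, list[float]] = {}
            n_single = 0
            sizes: dict[int, int] = {}
            for aa, codons in code5.families.items():
                k = len(codons)
                if k == 1:
                    n_single += 1
                    continue
                sizes[k] = sizes.get(k, 0) + 1
                n = sum(counts[c] for c in codons)
                p2 = sum((counts[c] / n) ** 2 for c in codons)
                f = (n * p2 - 1) / (n - 1)
                if f > 0:
                    by_size.setdefault(k, []).append(f)
            expected = n_single + sum(
                sizes[k] / float(np.mean(v)) for k, v in by_size.items()
            )
            expected = min(expected, code5.n_sense)
            assert enc(counts, code5) == pytest.approx(expected, abs=1e-9)

    def test_monotone_decrease_under_concentration(self, code5):
        """Shifting each family's usage onto one codon lowers ENC."""
        previous = np.inf
        for lam in np.linspace(0.0, 0.9, 7):
            counts = {}
            for aa, codons in code5.families.items():
                total = 60
                k = len(codons)
                base = total * (1 - lam) / k
                for i, c in enumerate(codons):
                    counts[c] = int(round(base + (total * lam if i == 0 else 0)))
            value = enc(counts, code5)
            assert value <= previous + 1e-6
            previous = value

    def test_all_uninformative_raises(self, code5):
        counts = dict.fromkeys(code5.sense_codons, 0)
        counts[code5.families["M"][0]] = 1  # n < 2 in every family
        with pytest.raises(UndefinedStatisticError):
            enc(counts, code5)


class TestENCExpected:
    def test_closed_form_at_half(self):
        assert enc_expected(0.5) == 60.5

    def test_nonlinear_term_symmetric_about_half(self, rng):
        """The curvature term 29/(s^2+(1-s)^2) is symmetric in s; the full
        curve adds the linear +s offset on top of it."""
        for s in rng.uniform(0.01, 0.99, 10):
            assert enc_expected(s) - s == pytest.approx(enc_expected(1 - s) - (1 - s))

    def test_maximum_at_half(self):
        grid = np.linspace(0.01, 0.99, 99)
        values = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5, abs=0.02)

    def test_biased_fixture_falls_below_curve(self, sim_genome, code5):
        """A genome with composition-driven codon bias plots below the
        null expectation."""
        counts = count_codons(
            [mc.extract_gene(sim_genome, g) for g in mc.io.PCG_NAMES], code5
        )
        observed = enc(counts, code5)
        assert observed < enc_expected(gc3(counts))


class TestCBI:
    def test_only_optimal_codons_is_one(self, code5):
        counts = dict.fromkeys(code5.sense_codons, 0)
        optimal = set()
        for aa, codons in code5.degenerate_families().items():
            counts[codons[0]] = 25
            optimal.add(codons[0])
        assert cbi(counts, code5, optimal) == pytest.approx(1.0)

    def test_uniform_usage_is_zero(self, code5):
        counts = _uniform_counts(code5)
        optimal = default_optimal_codons(counts, code5)
        assert cbi(counts, code5, optimal) == pytest.approx(0.0)

    def test_against_expected_count_oracle(self, code5, rng):
        for _ in range(10):
            counts = {c: int(rng.integers(0, 40)) for c in code5.sense_codons}
            optimal = default_optimal_codons(counts, code5)
            n_tot = n_opt = n_ran = 0.0
            for aa, codons in code5.degenerate_families().items():
                fam_total = sum(counts[c] for c in codons)
                n_tot += fam_total
                n_opt += sum(counts[c] for c in codons if c in optimal)
                n_ran += fam_total * sum(c in optimal for c in codons) / len(codons)
            expected = (n_opt - n_ran) / (n_tot - n_ran)
            assert cbi(counts, code5, optimal) == pytest.approx(expected, abs=1e-12)


def test_at_ending_rscu_exceeds_one_on_biased_fixture(sim_genome, code5):
    """AT3-driven composition shows as preference for A/T-terminating
    codons in every larger family."""
    counts = count_codons(
        [mc.extract_gene(sim_genome, g) for g in mc.io.PCG_NAMES], code5
    )
    values = rscu(counts, code5)
    for aa, codons in code5.degenerate_families().items():
        if len(codons) < 4:
            continue
        at_mean = np.nanmean([values[c] for c in codons if c[2] in "AT"])
        gc_mean = np.nanmean([values[c] for c in codons if c[2] in "GC"])
        assert at_mean > gc_mean


def test_enc_cbi_gc_correlation_signs(code5, rng):
    """Composition-driven fixtures reproduce the expected signs: ENC rises
    with GC3 toward the unbiased ceiling while CBI falls."""
    enc_vals, cbi_vals, gc3_vals = [], [], []
    for at3 in np.linspace(0.55, 0.92, 8):
        cfg = mc.SimulationConfig(seed=int(at3 * 1000), at_target=0.70,
                                  at_third_position=at3)
        genome = mc.simulate_mitogenome(cfg)
        counts = count_codons(
            [mc.extract_gene(genome, g) for g in mc.io.PCG_NAMES], code5
        )
        enc_vals.append(enc(counts, code5))
        cbi_vals.append(cbi(counts, code5))
        gc3_vals.append(gc3(counts))
    assert mc.correlate(gc3_vals, enc_vals).r > 0
    assert mc.correlate(gc3_vals, cbi_vals).r < 0
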