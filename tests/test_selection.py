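"""GY94 engine, branch-site fits, LRT, BEB, RELL tests."""

import numpy as np
import pytest
from scipy import stats

import mitocomp as mc
from mitocomp.errors import MitocompError
from mitocomp.selection import (
    BranchSiteModel,
    M0Model,
    PruningEngine,
    _eigen,
    _transition_matrix,
    f3x4_frequencies,
    gy94_matrix,
    mixture_scale,
    rate_coefficients,
    substitution_rate,
)
from mitocomp.trees import PhyloTree


@pytest.fixture(scope="module")
def freqs62(code5=mc.get_code(5)):
    rng = np.random.default_rng(42)
    return rng.dirichlet(np.ones(code5.n_sense))


class TestGY94:
    def test_rows_sum_to_zero(self, code5, freqs62):
        Q = gy94_matrix(2.5, 0.3, freqs62, code5)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_detailed_balance(self, code5, freqs62):
        Q = gy94_matrix(2.5, 0.3, freqs62, code5)
        flux = freqs62[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-14

    def test_unit_mean_rate_when_scaled(self, code5, freqs62):
        Q = gy94_matrix(2.5, 0.3, freqs62, code5, scale=True)
        assert -float(freqs62 @ np.diag(Q)) == pytest.approx(1.0)

    def test_transition_matrix_matches_series_expansion(self, code5, freqs62):
        Q = gy94_matrix(2.0, 0.5, freqs62, code5)
        eig = _eigen(Q, freqs62)
        t = 1e-4
        P = _transition_matrix(eig, t)
        series = np.eye(code5.n_sense) + Q * t + Q @ Q * t * t / 2
        assert np.abs(P - series).max() < 1e-9

    def test_rate_coefficients_match_generator(self, code5, freqs62):
        coeffs = rate_coefficients(freqs62, code5)
        for kappa, omega in [(1.0, 1.0), (3.0, 0.2), (2.0, 5.0)]:
            Q = gy94_matrix(kappa, omega, freqs62, code5, scale=False)
            direct = -float(freqs62 @ np.diag(Q))
            assert substitution_rate(kappa, omega, coeffs) == pytest.approx(direct)


class TestF3x4:
    def test_uniform_alignment_gives_equal_frequencies(self, code5):
        codons = np.arange(code5.n_sense)
        # every sense codon once -> position frequencies of the code itself
        aln = mc.CodonAlignment(["a"], codons[None, :], code5)
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)

    def test_at_rich_fixture_overweights_at_ending_codons(self, small_alignment):
        aln, _, _ = small_alignment
        pi = f3x4_frequencies(aln)
        code = aln.code
        at_mass = sum(p for p, c in zip(pi, code.sense_codons) if c[2] in "AT")
        assert at_mass > 0.6


class TestSiteLogLikelihoods:
    def test_single_taxon_tree_is_log_frequencies(self, code5):
        tree = PhyloTree.from_newick("A;")
        states = np.array([[0, 5, 10]])
        aln = mc.CodonAlignment(["A"], states, code5)
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(code5.n_sense))
        ll = mc.site_log_likelihoods(aln, tree, M0Model(2.0, 0.5, pi))
        assert np.allclose(ll, np.log(pi[states[0]]))

    def test_mixture_total_equals_per_site_sum(self, small_alignment):
        aln, tree, _ = small_alignment
        pi = f3x4_frequencies(aln)
        model = BranchSiteModel(2.0, 0.1, 3.0, 0.8, 0.1, pi)
        ll = mc.site_log_likelihoods(aln, tree, model)
        assert ll.shape == (aln.n_sites,)
        assert np.isfinite(ll).all()

    def test_taxon_mismatch_lists_offenders(self, small_alignment, code5):
        aln, tree, _ = small_alignment
        bad = mc.CodonAlignment(["zz"] + aln.taxa[1:], aln.codons, code5)
        with pytest.raises(MitocompError, match="zz"):
            PruningEngine(bad, tree)


@pytest.fixture(scope="module")
def fitted():
    cfg = mc.SimulationConfig(seed=5, n_codons=300, omega2=8.0)
    aln, tree, classes = mc.simulate_codon_alignment(cfg)
    fit = mc.branch_site_test(aln, tree, run_beb=True)
    return fit, classes


class TestBranchSiteFit:
    def test_nested_model_dominance(self, fitted):
        fit, _ = fitted
        assert fit.lnl_alt >= fit.lnl_null - 1e-6

    def test_proportion_constraint(self, fitted):
        fit, _ = fitted
        p = fit.proportions
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()
        # Model A constraint p2a/p2b derived from (p0, p1)
        rest = 1 - p[0] - p[1]
        assert p[2] == pytest.approx(rest * p[0] / (p[0] + p[1]))

    def test_selection_detected_under_strong_regime(self, fitted):
        fit, _ = fitted
        assert fit.two_dl > stats.chi2.ppf(0.95, 1)
        assert fit.omega2 > 1.5

    def test_beb_posteriors_valid_and_ranked(self, fitted):
        fit, classes = fitted
        post = fit.beb.posterior.values
        assert ((post >= 0) & (post <= 1)).all()
        planted = np.isin(classes, [2, 3])
        assert post[planted].mean() > post[~planted].mean()

    def test_beb_star_convention(self, fitted):
        fit, _ = fitted
        for _, row in fit.beb.iterrows():
            if row.posterior > 0.99:
                assert row.stars == "**"
            elif row.posterior > 0.95:
                assert row.stars == "*"
            else:
                assert row.stars == ""

    def test_report_shape(self, fitted):
        fit, _ = fitted
        rep = fit.report()
        assert list(rep.model) == ["null", "alternative"]
        assert rep.twoDeltaL.iloc[0] == pytest.approx(fit.two_dl)

    def test_unmarked_tree_raises(self, small_alignment):
        aln, tree, _ = small_alignment
        bare = PhyloTree.from_newick(tree.to_newick().replace(" #1", ""))
        with pytest.raises(MitocompError, match="foreground"):
            mc.fit_branch_site(aln, bare)


class TestLRT:
    def test_zero_gives_one(self):
        assert mc.lrt_pvalue(0.0) == 1.0

    def test_critical_value(self):
        assert mc.lrt_pvalue(3.841) == pytest.approx(0.05, abs=1e-3)

    def test_significant_likelihood_difference(self):
        # twice the log-likelihood gap of a clearly selected gene
        assert mc.lrt_pvalue(8.25) < 0.05

    def test_mixture_halves_tail(self):
        assert mc.lrt_pvalue(2.0, mixture=True) == pytest.approx(
            0.5 * stats.chi2.sf(2.0, 1)
        )


class TestMixtureScale:
    def test_neutral_mixture_equals_single_rate(self, code5, freqs62):
        coeffs = rate_coefficients(freqs62, code5)
        f = mixture_scale(2.0, np.array([1.0]), np.array([1.0]), coeffs)
        assert f == pytest.approx(substitution_rate(2.0, 1.0, coeffs))


class TestRELL:
    def test_identical_trees_tie(self, rng):
        row = rng.normal(-10, 1, 200)
        out = mc.rell_tests(np.vstack([row, row, row]), rng=1)
        assert (out.kh_p == 1.0).all()
        assert (out.sh_p == 1.0).all()
        assert np.allclose(out.elw, 1 / 3)

    def test_clearly_better_tree_rejects_competitor(self, rng):
        better = rng.normal(-10, 0.5, 100)
        worse = better - 2.0  # 2 lnL per site worse
        out = mc.rell_tests(np.vstack([better, worse]), rng=1)
        assert out.loc[1, "kh_p"] < 0.05
        assert out.loc[1, "sh_p"] < 0.05
        assert out.loc[0, "elw"] > 0.99

    def test_elw_sums_to_one(self, rng):
        M = rng.normal(-8, 1, size=(4, 150))
        out = mc.rell_tests(M, rng=7)
        assert out.elw.sum() == pytest.approx(1.0)

    def test_single_tree_trivial(self):
        out = mc.rell_tests(np.full((1, 50), -3.0))
        assert out.kh_p.iloc[0] == 1.0 and out.elw.iloc[0] == 1.0

    def test_seeded_reproducibility(self, rng):
        M = rng.normal(-8, 1, size=(3, 120))
        a = mc.rell_tests(M, rng=11)
        b = mc.rell_tests(M, rng=11)
        assert (a == b).all().all()


def test_rell_on_simulated_topologies(small_alignment):
    """End-to-end: per-site likelihoods under the generating topology and a
    deliberately wrong topology; the true tree is never rejected in favour
    of the scrambled one."""
    aln, tree, _ = small_alignment
    pi = f3x4_frequencies(aln)
    m0 = mc.fit_m0(aln, tree, pi)
    ll_true = mc.site_log_likelihoods(aln, m0.tree, M0Model(m0.kappa, m0.omega, pi))
    taxa = list(tree.taxa)
    swapped = tree.to_newick().replace(" #1", "")
    swapped = (
        swapped.replace(taxa[0], "@@").replace(taxa[-1], taxa[0]).replace("@@", taxa[-1])
    )
    wrong_tree = PhyloTree.from_newick(swapped)
    m0w = mc.fit_m0(aln, wrong_tree, pi)
    ll_wrong = mc.site_log_likelihoods(
        aln, m0w.tree, M0Model(m0w.kappa, m0w.omega, pi)
    )
    out = mc.rell_tests(np.vstack([ll_true, ll_wrong]), rng=5)
    assert out.lnL.iloc[0] >= out.lnL.iloc[1]
    assert out.kh_p.iloc[0] > 0.05
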