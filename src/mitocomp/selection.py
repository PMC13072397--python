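"""Codon-substitution likelihood engine: GY94 rate matrices, Felsenstein
pruning, branch-site Model A fitting (null and alternative), the
likelihood-ratio test, Bayes empirical Bayes (BEB) site identification,
and RELL-based topology tests (KH / SH / ELW).

Model A structure.  Sites fall into four classes: class 0 (purifying,
omega0 < 1 on all branches), class 1 (neutral, omega = 1 everywhere),
and classes 2a/2b which behave like 0/1 on background branches but evolve
with omega2 >= 1 on the designated foreground branch(es).  The class
proportions are (p0, p1, p2a, p2b) with p2a = (1-p0-p1) p0/(p0+p1) and
p2b = (1-p0-p1) p1/(p0+p1).  The null model fixes omega2 = 1; twice the
log-likelihood difference is referred to chi-square with df = 1 (a 50:50
mixture of 0 and chi2_1 is available as an option).

Branch lengths are taken from a preliminary one-ratio (M0) fit that
rescales the input tree, then held fixed for both Model A fits, mirroring
the usual codeml workflow at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

from .errors import FitError, MitocompError
from .genetic_code import GeneticCode, get_code, is_transition
from .trees import PhyloTree

OMEGA2_CAP = 999.0  # upper bound for the foreground omega
OMEGA0_FLOOR = 1e-4

# ---------------------------------------------------------------------------
# codon alignment container
# ---------------------------------------------------------------------------


class CodonAlignment:
    """In-frame aligned coding sequences mapped to sense-codon states.

    Codons containing gaps, N, or other ambiguity are treated as fully
    missing data (state -1); stop codons in ungapped positions are
    rejected.
    """

    def __init__(self, taxa: list[str], codons: np.ndarray, code: GeneticCode):
        self.taxa = list(taxa)
        self.codons = np.asarray(codons, dtype=np.int64)
        self.code = code
        if self.codons.shape[0] != len(self.taxa):
            raise MitocompError("taxa/codon-matrix shape mismatch")

    @classmethod
    def from_seqs(cls, seqs: dict[str, str], code: GeneticCode | int = 5) -> "CodonAlignment":
        if isinstance(code, int):
            code = get_code(code)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise MitocompError("aligned sequences have unequal lengths")
        (length,) = lengths
        if length % 3:
            raise MitocompError(f"alignment length {length} not divisible by 3")
        taxa = list(seqs)
        mat = np.full((len(taxa), length // 3), -1, dtype=np.int64)
        for r, t in enumerate(taxa):
            s = seqs[t].upper()
            for i in range(length // 3):
                codon = s[3 * i : 3 * i + 3]
                if set(codon) - set("ACGT"):
                    continue  # missing
                if code.is_stop(codon):
                    raise MitocompError(
                        f"{t}: stop codon {codon} at aligned codon {i + 1}"
                    )
                mat[r, i] = code.codon_index[codon]
        return cls(taxa, mat, code)

    @classmethod
    def from_fasta(cls, path, code: GeneticCode | int = 5) -> "CodonAlignment":
        from .io import read_fasta

        return cls.from_seqs(read_fasta(path), code)

    def to_seqs(self) -> dict[str, str]:
        out = {}
        for r, t in enumerate(self.taxa):
            codons = [
                self.code.sense_codons[s] if s >= 0 else "---" for s in self.codons[r]
            ]
            out[t] = "".join(codons)
        return out

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def __repr__(self) -> str:  # pragma: no cover
        return f"CodonAlignment(n_taxa={len(self.taxa)}, n_sites={self.n_sites})"


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 equilibrium codon frequencies: products of position-specific
    nucleotide frequencies over sense codons, renormalised after stop
    removal.  Zero position frequencies are floored with a warning."""
    code = aln.code
    counts = np.zeros((3, 4))
    base_index = {b: i for i, b in enumerate("ACGT")}
    flat = aln.codons[aln.codons >= 0]
    if flat.size == 0:
        raise MitocompError("empty alignment: no resolved codons")
    for state in np.unique(flat):
        n = int((flat == state).sum())
        codon = code.sense_codons[state]
        for pos in range(3):
            counts[pos, base_index[codon[pos]]] += n
    freqs = counts / counts.sum(axis=1, keepdims=True)
    if (freqs == 0).any():
        warnings.warn("F3x4: zero nucleotide frequency floored at 1e-6")
        freqs = np.maximum(freqs, 1e-6)
        freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.empty(code.n_sense)
    for i, codon in enumerate(code.sense_codons):
        pi[i] = np.prod([freqs[p, base_index[codon[p]]] for p in range(3)])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# GY94 rate matrix
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _single_step_structure(table_id: int):
    """For each ordered sense-codon pair differing at one position:
    (i, j, is_transition, is_synonymous) index arrays."""
    code = get_code(table_id)
    ii, jj, ts, syn = [], [], [], []
    for i, a in enumerate(code.sense_codons):
        for j, b in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if a[p] != b[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(a[p], b[p]))
            syn.append(code.is_synonymous(a, b))
    return (np.array(ii), np.array(jj), np.array(ts, bool), np.array(syn, bool))


def gy94_matrix(
    kappa: float,
    omega: float,
    freqs: np.ndarray,
    code: GeneticCode | int = 5,
    scale: bool = True,
) -> np.ndarray:
    """Goldman-Yang codon rate generator over sense codons.

    Off-diagonal rate for a single-nucleotide change i->j is
    pi_j * {1, kappa, omega, omega*kappa} according to transversion /
    transition x synonymous / nonsynonymous; multi-nucleotide changes have
    rate 0; the diagonal makes rows sum to zero.  With ``scale=True`` the
    generator is rescaled to one expected substitution per codon per unit
    time at equilibrium.
    """
    if isinstance(code, int):
        code = get_code(code)
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    ii, jj, ts, syn = _single_step_structure(code.table_id)
    n = code.n_sense
    rate = np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    Q = np.zeros((n, n))
    Q[ii, jj] = rate * freqs[jj]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -float(freqs @ np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


def rate_coefficients(freqs: np.ndarray, code: GeneticCode | int = 5) -> np.ndarray:
    """Coefficients (A, B, C, D) such that the equilibrium substitution
    rate of the *unscaled* GY94 generator is A + kappa*B + omega*(C +
    kappa*D): synonymous/nonsynonymous x transversion/transition mass."""
    if isinstance(code, int):
        code = get_code(code)
    ii, jj, ts, syn = _single_step_structure(code.table_id)
    mass = freqs[ii] * freqs[jj]
    return np.array(
        [
            mass[syn & ~ts].sum(),
            mass[syn & ts].sum(),
            mass[~syn & ~ts].sum(),
            mass[~syn & ts].sum(),
        ]
    )


def substitution_rate(kappa: float, omega: float, coeffs: np.ndarray) -> float:
    """Expected substitutions per codon per unit time, unscaled generator."""
    a, b, c, d = coeffs
    return float(a + kappa * b + omega * (c + kappa * d))


def mixture_scale(
    kappa: float,
    proportions: np.ndarray,
    bg_omegas: np.ndarray,
    coeffs: np.ndarray,
) -> float:
    """Common rate normalisation for a site-class mixture: the
    proportion-weighted equilibrium rate over the background omegas.

    Dividing every class's unscaled generator by this factor expresses
    branch lengths as expected substitutions per codon under the
    background mixture; a foreground branch with omega2 > 1 then runs
    faster than its nominal length — the rate component of the
    positive-selection signal."""
    return float(
        sum(p * substitution_rate(kappa, w, coeffs)
            for p, w in zip(proportions, bg_omegas))
    )


def _eigen(Q: np.ndarray, freqs: np.ndarray):
    """Symmetrised eigendecomposition of a reversible generator."""
    sq = np.sqrt(freqs)
    B = (Q * sq[:, None]) / sq[None, :]
    w, U = np.linalg.eigh((B + B.T) / 2)
    return w, U, sq


def _transition_matrix(eig, t: float) -> np.ndarray:
    w, U, sq = eig
    P = (U * np.exp(w * t)) @ U.T
    P = P / sq[:, None] * sq[None, :]
    return np.maximum(P, 0.0)


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------


class PruningEngine:
    """Felsenstein pruning over a fixed alignment/tree pair, batched over
    an arbitrary set of (background-omega, foreground-omega) site classes."""

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        missing_in_aln = set(tree.taxa) - set(aln.taxa)
        missing_in_tree = set(aln.taxa) - set(tree.taxa)
        if missing_in_aln or missing_in_tree:
            raise MitocompError(
                "taxon mismatch between alignment and tree: "
                f"tree-only={sorted(missing_in_aln)}, "
                f"alignment-only={sorted(missing_in_tree)}"
            )
        self.aln = aln
        self.tree = tree
        self.code = aln.code
        row = {t: i for i, t in enumerate(aln.taxa)}
        ordered = np.vstack([aln.codons[row[n.taxon]] for n in tree.tips])
        # site-pattern compression: identical codon columns are computed
        # once and expanded on return
        patterns, self.pattern_index = np.unique(ordered, axis=1,
                                                 return_inverse=True)
        self.pattern_index = self.pattern_index.ravel()
        self.tip_states = {
            n.index: patterns[k] for k, n in enumerate(tree.tips)
        }
        self.n_patterns = patterns.shape[1]

    def class_site_loglik(
        self,
        kappa: float,
        freqs: np.ndarray,
        class_omegas: np.ndarray,
        scale: float = 1.0,
        normalize: bool = True,
    ) -> np.ndarray:
        """Per-site log-likelihood for each class.

        ``class_omegas``: array (C, 2) of (background, foreground) omega
        per class.  ``scale`` multiplies all branch lengths.  With
        ``normalize=True`` each class generator is rescaled to unit mean
        rate (single-class / M0 use); mixture models pass
        ``normalize=False`` and fold their common mixture-scale factor
        into ``scale``.  Returns an array (C, n_sites).

        Classes whose omega assignments agree over a node's whole subtree
        share that node's partial likelihood, so the four Model A classes
        cost only two pruning passes below the foreground branch (and the
        large BEB batch collapses to its distinct background omegas).
        """
        class_omegas = np.atleast_2d(np.asarray(class_omegas, float))
        C = class_omegas.shape[0]
        S = self.n_patterns
        n = self.code.n_sense
        eigs = {
            om: _eigen(gy94_matrix(kappa, om, freqs, self.code, scale=normalize), freqs)
            for om in np.unique(class_omegas)
        }
        pcache: dict[tuple[float, float], np.ndarray] = {}

        def pmat(om: float, t: float) -> np.ndarray:
            key = (om, t)
            if key not in pcache:
                pcache[key] = _transition_matrix(eigs[om], t)
            return pcache[key]

        tree = self.tree
        # per node: (reps, partial (U, n, S), logscale (U, S)); reps maps
        # class -> row in the partial array
        store: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for node in tree.nodes:
            if node.is_tip:
                store[node.index] = (np.zeros(C, int), None, None)
                continue
            # group classes by their subtree signature
            sig_of_class = []
            for c in range(C):
                sig = []
                for ci in node.children:
                    child = tree.nodes[ci]
                    om = class_omegas[c, 1 if child.foreground else 0]
                    sig.append((store[ci][0][c], om))
                sig_of_class.append(tuple(sig))
            uniq: dict[tuple, int] = {}
            reps = np.empty(C, int)
            for c, sig in enumerate(sig_of_class):
                reps[c] = uniq.setdefault(sig, len(uniq))
            U = len(uniq)
            acc = np.ones((U, n, S))
            lsc = np.zeros((U, S))
            class_for_rep = [sig_of_class.index(sig) for sig in uniq]
            for ci in node.children:
                child = tree.nodes[ci]
                t = child.length * scale
                col = 1 if child.foreground else 0
                c_reps, c_part, c_lsc = store[child.index]
                if child.is_tip:
                    states = self.tip_states[child.index]
                    obs = states >= 0
                    for u, c in enumerate(class_for_rep):
                        P = pmat(class_omegas[c, col], t)
                        contrib = np.ones((n, S))
                        contrib[:, obs] = P[:, states[obs]]
                        acc[u] *= contrib
                else:
                    for u, c in enumerate(class_for_rep):
                        P = pmat(class_omegas[c, col], t)
                        acc[u] *= P @ c_part[c_reps[c]]
                        lsc[u] += c_lsc[c_reps[c]]
            m = np.maximum(acc.max(axis=1, keepdims=True), 1e-300)
            acc /= m
            lsc += np.log(m[:, 0, :])
            store[node.index] = (reps, acc, lsc)
            for ci in node.children:
                store[ci] = (store[ci][0], None, None)  # free child partials
        reps, part, lsc = store[tree.root]
        if part is None:  # single-taxon tree: root is a tip
            states = self.tip_states[tree.root]
            obs = states >= 0
            site_ll = np.where(obs, np.log(freqs[np.maximum(states, 0)]), 0.0)
            return np.broadcast_to(site_ll[self.pattern_index],
                                   (C, self.aln.n_sites)).copy()
        site_l = np.einsum("j,ujs->us", freqs, part)
        with np.errstate(divide="ignore"):
            ll = np.log(np.maximum(site_l, 1e-300)) + lsc
        return ll[reps][:, self.pattern_index]


# ---------------------------------------------------------------------------
# model containers and public likelihood entry point
# ---------------------------------------------------------------------------


@dataclass
class M0Model:
    """One-ratio GY94 model (same omega on every branch)."""

    kappa: float
    omega: float
    freqs: np.ndarray


@dataclass
class BranchSiteModel:
    """Model A parameterisation (see module docstring)."""

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    freqs: np.ndarray

    @property
    def proportions(self) -> np.ndarray:
        rest = 1.0 - self.p0 - self.p1
        denom = self.p0 + self.p1
        p2a = rest * self.p0 / denom
        p2b = rest * self.p1 / denom
        return np.array([self.p0, self.p1, p2a, p2b])

    @property
    def class_omegas(self) -> np.ndarray:
        return np.array(
            [
                [self.omega0, self.omega0],
                [1.0, 1.0],
                [self.omega0, self.omega2],
                [1.0, self.omega2],
            ]
        )


def site_log_likelihoods(
    aln: CodonAlignment, tree: PhyloTree, model: M0Model | BranchSiteModel
) -> np.ndarray:
    """Per-site log-likelihood vector under an M0 or branch-site model."""
    engine = PruningEngine(aln, tree)
    if isinstance(model, M0Model):
        return engine.class_site_loglik(
            model.kappa, model.freqs, [[model.omega, model.omega]]
        )[0]
    coeffs = rate_coefficients(model.freqs, aln.code)
    f = mixture_scale(model.kappa, model.proportions,
                      model.class_omegas[:, 0], coeffs)
    class_ll = engine.class_site_loglik(
        model.kappa, model.freqs, model.class_omegas, scale=1.0 / f,
        normalize=False,
    )
    logw = np.log(np.maximum(model.proportions, 1e-300))
    return logsumexp(class_ll + logw[:, None], axis=0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class M0Fit:
    kappa: float
    omega: float
    scale: float
    lnl: float
    tree: PhyloTree  # input tree rescaled by the fitted factor


def fit_m0(aln: CodonAlignment, tree: PhyloTree, freqs: np.ndarray | None = None) -> M0Fit:
    """One-ratio fit used to set branch lengths: optimises kappa, omega,
    and a single scale factor applied to the input tree's branch lengths."""
    if freqs is None:
        freqs = f3x4_frequencies(aln)
    engine = PruningEngine(aln, tree)
    if tree.total_length <= 0:
        raise MitocompError("M0 refit needs an input tree with branch lengths")

    def nll(x):
        kappa, omega, scale = np.exp(x)
        ll = engine.class_site_loglik(kappa, freqs, [[omega, omega]], scale=scale)
        return -float(ll.sum())

    res = optimize.minimize(
        nll, np.log([2.0, 0.2, 1.0]), method="L-BFGS-B",
        bounds=[(-3, 4), (-9, 3), (-4, 4)],
        options={"maxiter": 200, "eps": 1e-5, "ftol": 1e-9, "gtol": 1e-3},
    )
    kappa, omega, scale = np.exp(res.x)
    return M0Fit(float(kappa), float(omega), float(scale), -float(res.fun),
                 tree.scaled(float(scale)))


@dataclass
class ModelAFit:
    """One fitted Model A (null or alternative)."""

    null: bool
    lnl: float
    model: BranchSiteModel
    n_evaluations: int = 0


def _pack_null(kappa, omega0, p0, p1):
    a = np.log([p0, p1]) - np.log(max(1 - p0 - p1, 1e-6))
    return np.array([np.log(kappa), logit((omega0 - OMEGA0_FLOOR) / (1 - OMEGA0_FLOOR)),
                     a[0], a[1]])


def _unpack(x, null: bool, freqs) -> BranchSiteModel:
    kappa = float(np.exp(x[0]))
    omega0 = OMEGA0_FLOOR + (1 - OMEGA0_FLOOR) * float(expit(x[1]))
    e = np.exp([x[2], x[3], 0.0])
    p0, p1 = e[0] / e.sum(), e[1] / e.sum()
    omega2 = 1.0 if null else 1.0 + (OMEGA2_CAP - 1.0) * float(expit(x[4]))
    return BranchSiteModel(kappa, omega0, omega2, float(p0), float(p1), freqs)


def fit_branch_site(
    aln: CodonAlignment,
    tree: PhyloTree,
    null: bool = False,
    freqs: np.ndarray | None = None,
    starts: list[BranchSiteModel] | None = None,
    engine: PruningEngine | None = None,
) -> ModelAFit:
    """Fit branch-site Model A (null: foreground omega2 fixed at 1).

    Branch lengths of ``tree`` are held fixed; run :func:`fit_m0` first to
    set them.  ``starts`` overrides the default start list (for the
    alternative model, two warm starts at omega2 = 1.5 and 5 around the
    supplied or default parameter values).
    """
    if tree.n_foreground < 1:
        raise MitocompError("no foreground branch marked on the tree")
    if freqs is None:
        freqs = f3x4_frequencies(aln)
    if engine is None:
        engine = PruningEngine(aln, tree)
    if starts is None:
        base = BranchSiteModel(2.0, 0.1, 2.0, 0.8, 0.1, freqs)
        starts = [base] if null else [
            BranchSiteModel(base.kappa, base.omega0, w2, base.p0, base.p1, freqs)
            for w2 in (1.5, 5.0)
        ]

    n_eval = 0
    coeffs = rate_coefficients(freqs, aln.code)

    def nll(x):
        nonlocal n_eval
        n_eval += 1
        m = _unpack(x, null, freqs)
        f = mixture_scale(m.kappa, m.proportions, m.class_omegas[:, 0], coeffs)
        class_ll = engine.class_site_loglik(
            m.kappa, freqs, m.class_omegas, scale=1.0 / f, normalize=False
        )
        logw = np.log(np.maximum(m.proportions, 1e-300))
        return -float(logsumexp(class_ll + logw[:, None], axis=0).sum())

    best = None
    for s in starts:
        x0 = _pack_null(s.kappa, s.omega0, s.p0, s.p1)
        if not null:
            w2 = min(max(s.omega2, 1.0 + 1e-6), OMEGA2_CAP - 1e-6)
            x0 = np.append(x0, logit((w2 - 1.0) / (OMEGA2_CAP - 1.0)))
        # finite-difference step large enough that delta-lnL dominates the
        # float rounding of a sum over sites (|lnL| can be in the thousands)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-9, "gtol": 1e-3, "eps": 1e-5},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("branch-site optimisation failed for every start")
    model = _unpack(best.x, null, freqs)
    return ModelAFit(null=null, lnl=-float(best.fun), model=model, n_evaluations=n_eval)


@dataclass
class BranchSiteFit:
    """Null + alternative Model A fits with the LRT and BEB results."""

    lnl_null: float
    lnl_alt: float
    null_model: BranchSiteModel
    alt_model: BranchSiteModel
    tree: PhyloTree
    m0: M0Fit
    two_dl: float = field(init=False)
    p_value: float = field(init=False)
    beb: pd.DataFrame | None = None

    def __post_init__(self):
        self.two_dl = max(0.0, 2.0 * (self.lnl_alt - self.lnl_null))
        self.p_value = lrt_pvalue(self.two_dl)

    @property
    def kappa(self) -> float:
        return self.alt_model.kappa

    @property
    def omega0(self) -> float:
        return self.alt_model.omega0

    @property
    def omega2(self) -> float:
        return self.alt_model.omega2

    @property
    def proportions(self) -> np.ndarray:
        return self.alt_model.proportions

    def report(self) -> pd.DataFrame:
        rows = []
        for label, lnl, m in (
            ("null", self.lnl_null, self.null_model),
            ("alternative", self.lnl_alt, self.alt_model),
        ):
            p = m.proportions
            rows.append(
                {"model": label, "lnL": lnl, "kappa": m.kappa,
                 "p0": p[0], "p1": p[1], "p2a": p[2], "p2b": p[3],
                 "omega0": m.omega0, "omega2_foreground": m.omega2,
                 "twoDeltaL": self.two_dl, "p_value": self.p_value}
            )
        return pd.DataFrame(rows)


def lrt_pvalue(two_dl: float, mixture: bool = False) -> float:
    """Upper-tail p for the branch-site LRT.

    Default reference is chi-square with df = 1; ``mixture=True`` uses the
    50:50 mixture of a point mass at 0 and chi2_1 (conservative default is
    the plain chi2_1, matching reported plain p-values)."""
    if two_dl < 0:
        two_dl = 0.0
    p = float(stats.chi2.sf(two_dl, df=1))
    if mixture:
        p = 0.5 * p if two_dl > 0 else 1.0
    return p


def lrt(fit: "BranchSiteFit | float", mixture: bool = False) -> float:
    """LRT p-value from a completed test object or a 2-delta-lnL value."""
    two_dl = fit.two_dl if isinstance(fit, BranchSiteFit) else float(fit)
    return lrt_pvalue(two_dl, mixture=mixture)


def branch_site_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    run_beb: bool = True,
    beb_grid: int = 10,
    alt_omega2_starts: tuple[float, ...] = (1.5, 5.0),
) -> BranchSiteFit:
    """Full branch-site positive-selection test on one gene.

    Workflow: M0 rescales branch lengths; the Model A null and alternative
    are fitted with those lengths fixed (the alternative warm-started from
    the null optimum at each omega2 start); the LRT refers 2(lnL_alt -
    lnL_null) to chi2_1; BEB posteriors identify selected sites.
    """
    freqs = f3x4_frequencies(aln)
    m0 = fit_m0(aln, tree, freqs)
    stree = m0.tree
    engine = PruningEngine(aln, stree)
    null_fit = fit_branch_site(aln, stree, null=True, freqs=freqs, engine=engine)
    nm = null_fit.model
    starts = [
        BranchSiteModel(nm.kappa, nm.omega0, w2, nm.p0, nm.p1, freqs)
        for w2 in alt_omega2_starts
    ]
    alt_fit = fit_branch_site(
        aln, stree, null=False, freqs=freqs, starts=starts, engine=engine
    )
    fit = BranchSiteFit(
        lnl_null=null_fit.lnl,
        lnl_alt=alt_fit.lnl,
        null_model=null_fit.model,
        alt_model=alt_fit.model,
        tree=stree,
        m0=m0,
    )
    if run_beb:
        fit.beb = beb(fit, aln, stree, grid=beb_grid, engine=engine)
    return fit


# ---------------------------------------------------------------------------
# Bayes empirical Bayes
# ---------------------------------------------------------------------------


def _beb_stars(pp: float) -> str:
    if pp > 0.99:
        return "**"
    if pp > 0.95:
        return "*"
    return ""


def beb(
    fit: BranchSiteFit,
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    grid: int = 10,
    engine: PruningEngine | None = None,
) -> pd.DataFrame:
    """Grid-based Bayes empirical Bayes posterior of positive selection.

    A uniform prior is placed on a grid of ``grid`` midpoints per dimension
    over (p0+p1, p0/(p0+p1), omega0 in (0,1), omega2 in (1,11)); kappa,
    branch lengths, and the mixture rate normalisation are fixed at their
    MLEs.  Each grid point is weighted by its whole-alignment likelihood;
    the reported per-site posterior is for membership in the positively
    selected classes 2a+2b.

    Returns a DataFrame (site, ref_aa, posterior, stars) with sites 1-based
    and ``ref_aa`` the amino acid of the first ungapped sequence; stars
    follow the * PP>0.95 / ** PP>0.99 convention.
    """
    if engine is None:
        engine = PruningEngine(aln, tree if tree is not None else fit.tree)
    freqs = fit.alt_model.freqs
    kappa = fit.alt_model.kappa
    mid = (np.arange(grid) + 0.5) / grid
    omega0_grid = mid
    omega2_grid = 1.0 + 10.0 * mid
    # batched per-site class likelihoods for every needed omega combination
    classes = [[w0, w0] for w0 in omega0_grid]            # class 0
    classes.append([1.0, 1.0])                            # class 1
    classes += [[w0, w2] for w0 in omega0_grid for w2 in omega2_grid]  # 2a
    classes += [[1.0, w2] for w2 in omega2_grid]          # 2b
    coeffs = rate_coefficients(freqs, aln.code)
    alt = fit.alt_model
    f = mixture_scale(kappa, alt.proportions, alt.class_omegas[:, 0], coeffs)
    ll = engine.class_site_loglik(
        kappa, freqs, np.array(classes), scale=1.0 / f, normalize=False
    )
    K = grid
    S = aln.n_sites
    l0 = ll[:K]                                # (K, S)
    l1 = ll[K]                                 # (S,)
    l2a = ll[K + 1 : K + 1 + K * K].reshape(K, K, S)
    l2b = ll[K + 1 + K * K :]                  # (K, S)
    post_num = np.zeros(S)
    log_evidence = []
    posts = []
    for u in mid:          # u = p0 + p1
        for v in mid:      # v = p0 / (p0 + p1)
            p0, p1 = u * v, u * (1 - v)
            rest = 1.0 - u
            w = np.array([p0, p1, rest * v, rest * (1 - v)])
            logw = np.log(np.maximum(w, 1e-300))
            comp = np.stack(
                [
                    np.broadcast_to(l0[:, None, :], (K, K, S)) + logw[0],
                    np.broadcast_to(l1[None, None, :], (K, K, S)) + logw[1],
                    l2a + logw[2],
                    np.broadcast_to(l2b[None, :, :], (K, K, S)) + logw[3],
                ]
            )  # (4, K, K, S)
            f = logsumexp(comp, axis=0)  # (K, K, S)
            log_evidence.append(f.sum(axis=2).ravel())
            post = np.exp(logsumexp(comp[2:], axis=0) - f)  # P(2a or 2b | site)
            posts.append(post.reshape(K * K, S))
    log_evidence = np.concatenate(log_evidence)
    posts = np.concatenate(posts, axis=0)
    wgrid = np.exp(log_evidence - logsumexp(log_evidence))
    post_num = wgrid @ posts
    ref_aa = _reference_aas(aln)
    return pd.DataFrame(
        {
            "site": np.arange(1, S + 1),
            "ref_aa": ref_aa,
            "posterior": post_num,
            "stars": [_beb_stars(pp) for pp in post_num],
        }
    )


def _reference_aas(aln: CodonAlignment) -> list[str]:
    out = []
    for s in range(aln.n_sites):
        col = aln.codons[:, s]
        resolved = col[col >= 0]
        if resolved.size == 0:
            out.append("-")
        else:
            codon = aln.code.sense_codons[int(resolved[0])]
            out.append(aln.code.aa(codon))
    return out


# ---------------------------------------------------------------------------
# RELL topology tests
# ---------------------------------------------------------------------------


def rell_tests(
    site_lnl: np.ndarray,
    n_resamples: int = 1000,
    rng: np.random.Generator | int | None = None,
    tree_names: list[str] | None = None,
) -> pd.DataFrame:
    """KH, SH and ELW topology tests by RELL bootstrap.

    ``site_lnl``: array (n_trees, n_sites) of per-site log-likelihoods
    (from :func:`site_log_likelihoods` under each candidate topology).
    Site log-likelihood sums are bootstrap-resampled ``n_resamples`` times
    (resampling estimated log-likelihoods — no re-optimisation).

    Returns one row per tree: total lnL, delta lnL to the best tree,
    one-sided KH p (vs the best tree, centred bootstrap), SH p
    (simultaneous comparison against the best resampled tree), and the
    expected likelihood weight (ELW; weights sum to 1).
    """
    M = np.atleast_2d(np.asarray(site_lnl, float))
    T, S = M.shape
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    totals = M.sum(axis=1)
    best = int(np.argmax(totals))
    if T == 1:
        return pd.DataFrame(
            {"tree": tree_names or ["tree_1"], "lnL": totals, "delta_lnL": [0.0],
             "kh_p": [1.0], "sh_p": [1.0], "elw": [1.0]}
        )
    counts = rng.multinomial(S, np.full(S, 1.0 / S), size=n_resamples)  # (B, S)
    R = M @ counts.T  # (T, B) resampled totals
    Rc = R - R.mean(axis=1, keepdims=True)  # centred per tree
    kh = np.empty(T)
    sh = np.empty(T)
    for t in range(T):
        d_obs = totals[best] - totals[t]
        d_star = Rc[best] - Rc[t]
        kh[t] = float(np.mean(d_star >= d_obs)) if t != best else 1.0
        s_star = Rc.max(axis=0) - Rc[t]
        sh[t] = float(np.mean(s_star >= d_obs))
    w = np.exp(R - logsumexp(R, axis=0, keepdims=True))
    elw = w.mean(axis=1)
    return pd.DataFrame(
        {
            "tree": tree_names or [f"tree_{i + 1}" for i in range(T)],
            "lnL": totals,
            "delta_lnL": totals - totals[best],
            "kh_p": kh,
            "sh_p": sh,
            "elw": elw,
        }
    )
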