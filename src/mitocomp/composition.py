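"""Nucleotide composition, strand skews, per-codon-position profiles, and
the habitat/lineage group comparisons used in comparative mitogenomics.

Skews are directional measures of strand asymmetry computed on the major
(J) strand as given: AT-skew = (A - T)/(A + T), GC-skew = (G - C)/(G + C).
N bases (and alignment gaps) are excluded from both numerators and
denominators of every composition statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError


@dataclass
class CompositionProfile:
    """Base counts and derived composition statistics for one scope."""

    scope: str
    A: int
    C: int
    G: int
    T: int

    @property
    def total(self) -> int:
        return self.A + self.C + self.G + self.T

    @property
    def fractions(self) -> dict[str, float]:
        n = self.total
        return {b: getattr(self, b) / n for b in "ACGT"}

    @property
    def at_percent(self) -> float:
        return 100.0 * (self.A + self.T) / self.total

    @property
    def gc_percent(self) -> float:
        return 100.0 * (self.G + self.C) / self.total

    @property
    def at_skew(self) -> float:
        if self.A + self.T == 0:
            raise UndefinedStatisticError(f"{self.scope}: no A/T bases for AT-skew")
        return (self.A - self.T) / (self.A + self.T)

    @property
    def gc_skew(self) -> float:
        if self.G + self.C == 0:
            raise UndefinedStatisticError(f"{self.scope}: no G/C bases for GC-skew")
        return (self.G - self.C) / (self.G + self.C)

    def as_row(self) -> dict:
        return {
            "scope": self.scope,
            "A": self.A, "C": self.C, "G": self.G, "T": self.T,
            "AT_percent": self.at_percent,
            "GC_percent": self.gc_percent,
            "AT_skew": self.at_skew if self.A + self.T else np.nan,
            "GC_skew": self.gc_skew if self.G + self.C else np.nan,
        }


def base_composition(seq: str, scope: str = "sequence") -> CompositionProfile:
    """Count bases and derive AT%/GC% and skews; N and '-' are ignored."""
    seq = seq.upper()
    profile = CompositionProfile(
        scope, seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T")
    )
    if profile.total == 0:
        raise UndefinedStatisticError(f"{scope}: no countable bases")
    return profile


def per_position_composition(
    cds_set: list[str] | str,
) -> tuple[CompositionProfile, CompositionProfile, CompositionProfile]:
    """Composition at codon positions 1/2/3 pooled across in-frame CDSs."""
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    pooled = ["", "", ""]
    for cds in cds_set:
        cds = cds.upper().replace("-", "")
        if len(cds) % 3:
            # a trailing incomplete stop codon (1-2 nt) is trimmed
            if len(cds) % 3 in (1, 2):
                cds = cds[: 3 * (len(cds) // 3)]
        for p in range(3):
            pooled[p] += cds[p::3]
    return tuple(
        base_composition(pooled[p], scope=f"codon_position_{p + 1}") for p in range(3)
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_compare(
    values_by_group: dict[str, list[float]],
    test: str = "welch",
    adjust: str | None = None,
) -> pd.DataFrame:
    """All pairwise two-sample contrasts between groups.

    Uses Welch's t-test (unequal variances) by default; ``test='student'``
    selects the pooled-variance form.  Each group needs at least two
    observations.  Raw p-values are reported by default (matching how such
    panels are usually starred); ``adjust='bh'`` adds a
    Benjamini-Hochberg-corrected column and stars on the corrected values.

    Returns a DataFrame with one row per unordered group pair: group means,
    the t statistic, two-sided p, and significance stars (* p<0.05,
    ** p<0.01, *** p<0.001, ns otherwise).
    """
    for name, vals in values_by_group.items():
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {name!r} has {len(vals)} value(s); at least 2 required"
            )
    equal_var = {"welch": False, "student": True}[test]
    rows = []
    for (g1, v1), (g2, v2) in itertools.combinations(values_by_group.items(), 2):
        t, p = stats.ttest_ind(v1, v2, equal_var=equal_var)
        rows.append(
            {
                "group1": g1, "group2": g2,
                "n1": len(v1), "n2": len(v2),
                "mean1": float(np.mean(v1)), "mean2": float(np.mean(v2)),
                "t": float(t), "p": float(p), "stars": significance_stars(p),
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adjusted"] = stats.false_discovery_control(out["p"], method="bh")
        out["stars"] = [significance_stars(p) for p in out["p_adjusted"]]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    slope: float
    intercept: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with the least-squares line, as used for the
    ENC/CBI-vs-GC and Ka/Ks-vs-GC relationships."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in x or y")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def composition_report(mitos, per_gene: bool = True) -> pd.DataFrame:
    """Per-taxon composition table: whole genome, CR, and optionally each
    annotated gene (one row per (id, scope))."""
    from .io import extract_gene

    rows = []
    for m in mitos:
        prof = base_composition(m.sequence, scope="genome")
        rows.append({"id": m.id, "taxon": m.taxon, **prof.as_row()})
        if per_gene:
            for f in m.features:
                seq = extract_gene(m, f.name)
                prof = base_composition(seq, scope=f.name)
                rows.append({"id": m.id, "taxon": m.taxon, **prof.as_row()})
    return pd.DataFrame(rows)
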