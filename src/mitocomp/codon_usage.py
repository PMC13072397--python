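"""Codon-usage bias statistics: RSCU, Wright's effective number of codons
(ENC), the ENC null curve, and the codon bias index (CBI).

All statistics are driven by the synonymous-family structure of the active
:class:`~mitocomp.genetic_code.GeneticCode`, so they are correct for any
code table (the mitochondrial tables have no 3-fold Ile family, for
example).  Stop codons are never counted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .genetic_code import GeneticCode, get_code


def count_codons(seqs: str | list[str], code: GeneticCode | int = 5) -> dict[str, int]:
    """Count sense codons over one or more in-frame CDSs.

    Gaps are stripped; codons containing N (or any non-ACGT character) and
    stop codons are skipped.  A trailing incomplete codon is ignored.
    """
    if isinstance(code, int):
        code = get_code(code)
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = dict.fromkeys(code.sense_codons, 0)
    for seq in seqs:
        seq = seq.upper().replace("-", "")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    return counts


def rscu(counts: dict[str, int], code: GeneticCode | int = 5) -> dict[str, float]:
    """Relative synonymous codon usage: observed count / family mean.

    Families with zero total usage give NaN (undefined, not 0) for each
    member codon.  Within every used family the RSCU values sum to the
    family size.
    """
    if isinstance(code, int):
        code = get_code(code)
    out: dict[str, float] = {}
    for aa, codons in code.families.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                out[c] = float("nan")
        else:
            mean = total / len(codons)
            for c in codons:
                out[c] = counts.get(c, 0) / mean
    return out


def _family_homozygosity(n: int, counts: np.ndarray) -> float:
    """Wright's codon homozygosity estimator F-hat for one family."""
    p = counts / n
    return (n * float(p @ p) - 1.0) / (n - 1.0)


def enc(counts: dict[str, int], code: GeneticCode | int = 5) -> float:
    """Wright's effective number of codons, generalised to the family-size
    classes of the active code.

    For each synonymous family with n >= 2 observations the homozygosity
    F-hat = (n * sum(p^2) - 1)/(n - 1) is computed; families are grouped by
    size k and ENC = n_singleton_families + sum_k a_k / Fbar_k, where a_k is
    the number of size-k families in the code.  A size class with no
    informative family (or only F-hat <= 0) is imputed by linear
    interpolation between the nearest informative classes, with a warning.
    The estimate is capped at the number of sense codons.
    """
    if isinstance(code, int):
        code = get_code(code)
    class_f: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    for aa, codons in code.families.items():
        k = len(codons)
        if k == 1:
            continue
        class_sizes[k] = class_sizes.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in codons)
        if n >= 2:
            f = _family_homozygosity(n, np.array([counts.get(c, 0) for c in codons], float))
            if f > 0:
                class_f.setdefault(k, []).append(f)
    if not class_f:
        raise UndefinedStatisticError("ENC undefined: no informative synonymous family")
    fbar = {k: float(np.mean(v)) for k, v in class_f.items()}
    missing = [k for k in class_sizes if k not in fbar]
    if missing:
        ks = np.array(sorted(fbar))
        for k in missing:
            lower = ks[ks < k]
            upper = ks[ks > k]
            if lower.size and upper.size:
                k0, k1 = lower.max(), upper.min()
                w = (k - k0) / (k1 - k0)
                fbar[k] = (1 - w) * fbar[k0] + w * fbar[k1]
            else:
                fbar[k] = fbar[lower.max() if lower.size else upper.min()]
        warnings.warn(f"ENC: imputed mean homozygosity for family-size classes {missing}")
    n_single = sum(1 for cs in code.families.values() if len(cs) == 1)
    value = n_single + sum(a / fbar[k] for k, a in class_sizes.items())
    return min(value, float(code.n_sense))


def enc_expected(gc3: float) -> float:
    """Expected ENC under pure compositional (mutation) bias at a given GC3.

    ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2), computed literally for any
    s in [0, 1]; the curve is symmetric about s = 0.5.
    """
    s = float(gc3)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def gc3(counts: dict[str, int]) -> float:
    """G+C fraction at third codon positions of counted sense codons."""
    total = sum(counts.values())
    if total == 0:
        raise UndefinedStatisticError("GC3 undefined: no codons counted")
    gc = sum(n for c, n in counts.items() if c[2] in "GC")
    return gc / total


def gc_content(counts: dict[str, int]) -> float:
    """G+C fraction over all positions of counted sense codons."""
    total = 3 * sum(counts.values())
    if total == 0:
        raise UndefinedStatisticError("GC undefined: no codons counted")
    gc = sum(n * sum(b in "GC" for b in c) for c, n in counts.items())
    return gc / total


def default_optimal_codons(
    counts: dict[str, int], code: GeneticCode | int = 5
) -> frozenset[str]:
    """One optimal codon per degenerate family: the most frequent synonym
    (alphabetically first on ties)."""
    if isinstance(code, int):
        code = get_code(code)
    chosen = []
    for aa, codons in code.degenerate_families().items():
        chosen.append(max(codons, key=lambda c: (counts.get(c, 0), c), default=None))
    return frozenset(c for c in chosen if c is not None)


def cbi(
    counts: dict[str, int],
    code: GeneticCode | int = 5,
    optimal_set: frozenset[str] | set[str] | None = None,
) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran).

    N_tot is the total usage in degenerate families, N_opt the usage of
    optimal codons, and N_ran the optimal usage expected under uniform
    synonymous choice.  1 = only optimal codons; 0 = uniform usage.  The
    default optimal set is the most frequent synonym per family, computed
    from ``counts`` itself (override for a dataset-wide set).
    """
    if isinstance(code, int):
        code = get_code(code)
    if optimal_set is None:
        optimal_set = default_optimal_codons(counts, code)
    optimal_set = set(optimal_set)
    n_tot = n_opt = n_ran = 0.0
    for aa, codons in code.degenerate_families().items():
        fam_opt = optimal_set & set(codons)
        if not fam_opt:
            raise UndefinedStatisticError(
                f"CBI: optimal set has no codon for family {aa}"
            )
        fam_n = sum(counts.get(c, 0) for c in codons)
        n_tot += fam_n
        n_opt += sum(counts.get(c, 0) for c in fam_opt)
        n_ran += fam_n * len(fam_opt) / len(codons)
    if n_tot == n_ran:
        raise UndefinedStatisticError("CBI undefined: N_tot equals N_ran")
    return (n_opt - n_ran) / (n_tot - n_ran)


def codon_usage_table(
    seqs_by_taxon: dict[str, list[str] | str],
    code: GeneticCode | int = 5,
    optimal_set: frozenset[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon codon-usage summary.

    Returns ``(summary, rscu_long)``: one row per taxon with ENC, CBI, GC%,
    GC3% and total codons; and a long-format RSCU table (taxon, codon,
    amino_acid, count, rscu).
    """
    if isinstance(code, int):
        code = get_code(code)
    if optimal_set is None:
        pooled: dict[str, int] = dict.fromkeys(code.sense_codons, 0)
        for seqs in seqs_by_taxon.values():
            for c, n in count_codons(seqs, code).items():
                pooled[c] += n
        optimal_set = default_optimal_codons(pooled, code)
    summary, rscu_rows = [], []
    for taxon, seqs in seqs_by_taxon.items():
        counts = count_codons(seqs, code)
        r = rscu(counts, code)
        for c in code.sense_codons:
            rscu_rows.append(
                {"taxon": taxon, "codon": c, "amino_acid": code.aa(c),
                 "count": counts[c], "rscu": r[c]}
            )
        summary.append(
            {"taxon": taxon,
             "n_codons": sum(counts.values()),
             "ENC": enc(counts, code),
             "CBI": cbi(counts, code, optimal_set),
             "GC_percent": 100 * gc_content(counts),
             "GC3_percent": 100 * gc3(counts)}
        )
    return pd.DataFrame(summary), pd.DataFrame(rscu_rows)
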