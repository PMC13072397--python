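"""Population- and clade-level sequence diversity.

Implements segregating sites, nucleotide diversity (Pi, mean pairwise
proportion of differing sites) with the 100 bp / 25 bp sliding-window
profile, haplotype diversity (Hd), mean pairwise identity, and the
Nei-Gojobori (1986) counting estimator of Ka and Ks with Jukes-Cantor
correction.

Gap handling: the default is pairwise deletion (a column is dropped only
for pairs in which either member carries a gap or N); complete deletion
(drop the column for everyone) is available via ``deletion="complete"``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, MitocompError, SaturationError
from .genetic_code import GeneticCode, get_code
from .io import translate

_EXCLUDED = set("N-?")


def _as_rows(aln: dict[str, str] | list[str]) -> list[str]:
    rows = list(aln.values()) if isinstance(aln, dict) else list(aln)
    if len({len(r) for r in rows}) > 1:
        raise MitocompError("alignment rows have unequal lengths")
    return [r.upper() for r in rows]


def _included_mask(rows: list[str]) -> np.ndarray:
    arr = np.array([list(r) for r in rows])
    return ~np.isin(arr, list(_EXCLUDED)).any(axis=0)


def segregating_sites(aln: dict[str, str] | list[str]) -> int:
    """Number of columns with more than one distinct base, ignoring columns
    containing gaps or N (complete deletion, the convention under which a
    'variable site' is unambiguous)."""
    rows = _as_rows(aln)
    if len(rows) < 2:
        raise InsufficientDataError("segregating sites require >= 2 sequences")
    arr = np.array([list(r) for r in rows])
    keep = _included_mask(rows)
    sub = arr[:, keep]
    return int(((sub != sub[0]).any(axis=0)).sum())


def nucleotide_diversity(
    aln: dict[str, str] | list[str], deletion: str = "pairwise"
) -> float:
    """Pi: mean over unordered pairs of the proportion of differing sites.

    With pairwise deletion, columns holding a gap/N in either member of a
    pair are excluded for that pair only.
    """
    rows = _as_rows(aln)
    if len(rows) < 2:
        raise InsufficientDataError("nucleotide diversity requires >= 2 sequences")
    arr = np.array([list(r) for r in rows])
    valid = ~np.isin(arr, list(_EXCLUDED))
    if deletion == "complete":
        keep = valid.all(axis=0)
        arr, valid = arr[:, keep], valid[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    total, n_pairs = 0.0, 0
    for i, j in itertools.combinations(range(len(rows)), 2):
        both = valid[i] & valid[j]
        n_sites = int(both.sum())
        n_pairs += 1
        if n_sites:
            total += float((arr[i, both] != arr[j, both]).sum()) / n_sites
    return total / n_pairs


def sliding_window_pi(
    aln: dict[str, str] | list[str],
    window: int = 100,
    step: int = 25,
    deletion: str = "pairwise",
) -> list[tuple[float, float]]:
    """Sliding-window Pi profile in alignment coordinates.

    Windows of ``window`` columns advance by ``step``; the trailing partial
    window is dropped.  Returns (midpoint, Pi) tuples, midpoints 1-based.
    The number of windows is floor((L - window)/step) + 1.
    """
    rows = _as_rows(aln)
    length = len(rows[0])
    if window > length:
        raise MitocompError(f"window ({window}) exceeds alignment length ({length})")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    out = []
    for start in range(0, length - window + 1, step):
        sub = [r[start : start + window] for r in rows]
        try:
            pi = nucleotide_diversity(sub, deletion=deletion)
        except ZeroDivisionError:  # pragma: no cover - defensive
            pi = math.nan
        out.append((start + (window + 1) / 2, pi))
    return out


def haplotype_diversity(
    seqs: dict[str, str] | list[str],
) -> tuple[float, dict[str, int]]:
    """Hd = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies.

    Haplotypes are grouped on the columns that are gap/N-free in every
    sequence, so sequences differing only at excluded positions collapse
    into one haplotype.  Returns (Hd, haplotype -> count) with haplotypes
    keyed by their included-column string.
    """
    rows = _as_rows(seqs)
    n = len(rows)
    if n < 2:
        raise InsufficientDataError("haplotype diversity requires >= 2 sequences")
    keep = _included_mask(rows)
    keys = ["".join(np.array(list(r))[keep]) for r in rows]
    counts: dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    hd = n / (n - 1) * (1.0 - sum_p2)
    return hd, counts


def pairwise_identity(
    aln: dict[str, str] | list[str],
    level: str = "nucleotide",
    code: GeneticCode | int = 5,
) -> float:
    """Mean pairwise percent identity over included columns.

    ``level='amino_acid'`` translates each row first (rows must be in-frame
    CDSs).  Pairs with no included columns are skipped with a warning.
    """
    rows = _as_rows(aln)
    if len(rows) < 2:
        raise InsufficientDataError("pairwise identity requires >= 2 sequences")
    if level in ("amino_acid", "aa"):
        rows = [translate(r.replace("-", ""), code) for r in rows]
        if len({len(r) for r in rows}) > 1:
            raise MitocompError("translated rows have unequal lengths")
    elif level not in ("nucleotide", "nt"):
        raise ValueError(f"unknown identity level {level!r}")
    arr = np.array([list(r) for r in rows])
    valid = ~np.isin(arr, list(_EXCLUDED) + ["X"])
    idents = []
    for i, j in itertools.combinations(range(len(rows)), 2):
        both = valid[i] & valid[j]
        n_sites = int(both.sum())
        if n_sites == 0:
            import warnings

            warnings.warn(f"pair ({i},{j}): no included columns; pair skipped")
            continue
        idents.append(100.0 * float((arr[i, both] == arr[j, both]).sum()) / n_sites)
    if not idents:
        raise InsufficientDataError("no pair had included columns")
    return float(np.mean(idents))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsEstimate:
    """Nei-Gojobori counting estimate between two in-frame CDSs."""

    ka: float
    ks: float
    n_sites: float  # nonsynonymous site count (fractional)
    s_sites: float  # synonymous site count (fractional)
    n_diffs: float
    s_diffs: float

    @property
    def ratio(self) -> float:
        """Ka/Ks; NaN when Ks = 0 (undefined, reported as missing)."""
        return self.ka / self.ks if self.ks > 0 else math.nan


def _codon_site_counts(codon: str, code: GeneticCode) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    At each position the synonymous fraction is taken over the mutational
    neighbours that are not stop codons.
    """
    syn = 0.0
    non = 0.0
    for pos in range(3):
        n_syn = n_non = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(alt):
                continue
            if code.is_synonymous(codon, alt):
                n_syn += 1
            else:
                n_non += 1
        if n_syn + n_non:
            syn += n_syn / (n_syn + n_non)
            non += n_non / (n_syn + n_non)
    # positions whose every neighbour is a stop contribute no sites; scale
    # so the codon always carries 3 sites in total
    total = syn + non
    if total == 0:
        return 0.0, 3.0
    return 3 * syn / total, 3 * non / total


def _pathway_diffs(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal mutational pathways; pathways through stop codons are
    excluded (unless every pathway is blocked, in which case all are used).
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
            steps.append((current, nxt))
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = non = 0.0
    for steps in usable:
        for a, b in steps:
            if code.is_stop(a) or code.is_stop(b):
                # a stop intermediate on a blocked-only pathway counts as
                # nonsynonymous
                non += 1
            elif code.is_synonymous(a, b):
                syn += 1
            else:
                non += 1
    k = len(usable)
    return syn / k, non / k


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); undefined at p >= 3/4."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ka_ks(cds1: str, cds2: str, code: GeneticCode | int = 5) -> KaKsEstimate:
    """Nei-Gojobori Ka and Ks between two equal-length, in-frame, stop-free
    CDSs, with Jukes-Cantor multiple-hit correction.

    Codons containing gaps or N in either sequence are skipped.
    """
    if isinstance(code, int):
        code = get_code(code)
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2):
        raise MitocompError("CDS length mismatch")
    n_codons = len(cds1) // 3
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for i in range(n_codons):
        a = cds1[3 * i : 3 * i + 3]
        b = cds2[3 * i : 3 * i + 3]
        if set(a + b) - set("ACGT"):
            continue
        if code.is_stop(a) or code.is_stop(b):
            raise MitocompError(f"stop codon in compared sequence at codon {i + 1}")
        sa, na = _codon_site_counts(a, code)
        sb, nb = _codon_site_counts(b, code)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        sd, nd = _pathway_diffs(a, b, code)
        s_diffs += sd
        n_diffs += nd
    if s_sites == 0 or n_sites == 0:
        raise InsufficientDataError("no comparable codons")
    ps = s_diffs / s_sites
    pn = n_diffs / n_sites
    return KaKsEstimate(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=n_diffs,
        s_diffs=s_diffs,
    )


def clade_ka_ks(
    cds_by_taxon: dict[str, str], code: GeneticCode | int = 5
) -> tuple[float, list[tuple[str, str, KaKsEstimate]]]:
    """Mean Ka/Ks over all within-clade pairs, plus the per-pair estimates
    so any other aggregation can be recomputed."""
    pairs = []
    ratios = []
    for (t1, s1), (t2, s2) in itertools.combinations(cds_by_taxon.items(), 2):
        est = ka_ks(s1, s2, code)
        pairs.append((t1, t2, est))
        if not math.isnan(est.ratio):
            ratios.append(est.ratio)
    if not pairs:
        raise InsufficientDataError("clade Ka/Ks requires >= 2 sequences")
    mean = float(np.mean(ratios)) if ratios else math.nan
    return mean, pairs
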