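"""Genetic-code tables and synonymous-family structure.

Everything downstream that touches codons (translation, RSCU/ENC/CBI,
Nei–Gojobori site counting, the GY94 engine) works through a
:class:`GeneticCode` so that non-default tables can be substituted.  The
package default is the invertebrate mitochondrial code (NCBI table 5:
ATA = Met, TGA = Trp, AGA/AGG = Ser), which is the appropriate table for
insect mitochondrial protein-coding genes.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (a in PURINES) == (b in PURINES) and a != b


class GeneticCode:
    """A codon translation table plus its synonymous-family partition.

    Parameters
    ----------
    table_id
        NCBI genetic-code table number (default 5, invertebrate
        mitochondrial).
    """

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.name = table.names[0]
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        self.stop_codons = frozenset(table.stop_codons)
        self.start_codons = frozenset(table.start_codons)
        # fixed, sorted sense-codon ordering shared by all numeric code
        self.sense_codons: tuple[str, ...] = tuple(sorted(self.codon_to_aa))
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        fams: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fams.setdefault(aa, []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())
        }
        self._family_of = {c: aa for aa, cs in self.families.items() for c in cs}
        if len(self.sense_codons) + len(self.stop_codons) != 64:
            raise ValueError(f"table {table_id}: sense + stop codons != 64")

    # -- basic queries ----------------------------------------------------

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.families)

    def aa(self, codon: str) -> str | None:
        """Amino acid for a codon, or None for a stop codon."""
        codon = codon.upper()
        if codon in self.stop_codons:
            return None
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def is_synonymous(self, c1: str, c2: str) -> bool:
        """True if two sense codons encode the same amino acid."""
        return self.codon_to_aa[c1.upper()] == self.codon_to_aa[c2.upper()]

    def family_of(self, codon: str) -> str:
        return self._family_of[codon.upper()]

    def degenerate_families(self) -> dict[str, tuple[str, ...]]:
        """Families with two or more synonymous codons."""
        return {aa: cs for aa, cs in self.families.items() if len(cs) > 1}

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticCode(table_id={self.table_id}, n_sense={self.n_sense})"


@lru_cache(maxsize=None)
def get_code(table_id: int = 5) -> GeneticCode:
    """Cached accessor; the default is the invertebrate mitochondrial code."""
    return GeneticCode(table_id)


INVERTEBRATE_MITO_TABLE = 5
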