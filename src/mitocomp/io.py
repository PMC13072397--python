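"""Annotated-mitogenome I/O: GenBank/FASTA parsing, gene extraction,
supermatrix concatenation, and mitochondrial translation.

Coordinate convention: internal coordinates are 0-based half-open on the
forward (J) strand; GenBank 1-based inclusive coordinates are converted on
read and restored on write, including features that wrap the origin of the
circular molecule.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    FeatureNotFoundError,
    FrameError,
    GenBankParseError,
    MitocompError,
)
from .genetic_code import GeneticCode, get_code, reverse_complement

# ---------------------------------------------------------------------------
# canonical gene inventory
# ---------------------------------------------------------------------------

PCG_NAMES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
#: fixed order used for supermatrix concatenation (alphabetical, deterministic)
PCG_CONCAT_ORDER = PCG_NAMES

TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
RRNA_NAMES = ("rrnS", "rrnL")

#: ancestral insect (Drosophila-like) gene order on the circular molecule,
#: as (name, strand) starting from trnI; the control region sits between
#: rrnS and trnI, i.e. at the end of this listing.
ANCESTRAL_GENE_ORDER = (
    ("trnI", "+"), ("trnQ", "-"), ("trnM", "+"), ("nad2", "+"),
    ("trnW", "+"), ("trnC", "-"), ("trnY", "-"), ("cox1", "+"),
    ("trnL2", "+"), ("cox2", "+"), ("trnK", "+"), ("trnD", "+"),
    ("atp8", "+"), ("atp6", "+"), ("cox3", "+"), ("trnG", "+"),
    ("nad3", "+"), ("trnA", "+"), ("trnR", "+"), ("trnN", "+"),
    ("trnS1", "+"), ("trnE", "+"), ("trnF", "-"), ("nad5", "-"),
    ("trnH", "-"), ("nad4", "-"), ("nad4L", "-"), ("trnT", "+"),
    ("trnP", "-"), ("nad6", "+"), ("cob", "+"), ("trnS2", "+"),
    ("nad1", "-"), ("trnL1", "-"), ("rrnL", "-"), ("trnV", "-"),
    ("rrnS", "-"), ("CR", "+"),
)


class FeatureKind(str, enum.Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL_REGION = "control_region"
    INTERGENIC = "intergenic"


class Habitat(str, enum.Enum):
    AQUATIC = "aquatic"
    SEMI_AQUATIC = "semi_aquatic"
    TERRESTRIAL = "terrestrial"
    UNKNOWN = "unknown"


def kind_of(name: str) -> FeatureKind:
    if name in PCG_NAMES:
        return FeatureKind.PCG
    if name in TRNA_NAMES:
        return FeatureKind.TRNA
    if name in RRNA_NAMES:
        return FeatureKind.RRNA
    if name == "CR":
        return FeatureKind.CONTROL_REGION
    return FeatureKind.INTERGENIC


@dataclass
class GeneFeature:
    """One annotated feature on the forward strand, 0-based half-open."""

    name: str
    kind: FeatureKind
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for origin-spanning feature")
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class Mitogenome:
    """A circular annotated mitogenome with habitat/taxonomy metadata."""

    id: str
    taxon: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    family: str = ""
    subfamily: str = ""
    habitat: Habitat = Habitat.UNKNOWN

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise MitocompError(
                f"{self.id}: ambiguity codes other than N are not supported: "
                f"{sorted(bad)}"
            )
        for f in self.features:
            if f.wraps_origin:
                ok = 0 <= f.end <= f.start <= self.length
            else:
                ok = 0 <= f.start < f.end <= self.length
            if not ok:
                raise MitocompError(
                    f"{self.id}: feature {f.name} span [{f.start},{f.end}) "
                    f"invalid for length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_census(self) -> dict[str, int]:
        counts = {"PCG": 0, "tRNA": 0, "rRNA": 0}
        for f in self.features:
            if f.kind.value in counts:
                counts[f.kind.value] += 1
        return counts

    def is_complete(self) -> bool:
        """True when the canonical 37-gene set (13 PCG / 22 tRNA / 2 rRNA)
        is annotated."""
        c = self.gene_census()
        return c == {"PCG": 13, "tRNA": 22, "rRNA": 2}

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise FeatureNotFoundError(f"{self.id}: no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)


# ---------------------------------------------------------------------------
# gene-name canonicalisation
# ---------------------------------------------------------------------------

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

# anticodon (DNA, as annotated) -> isoacceptor number for Leu and Ser
_LEU_SER_BY_ANTICODON = {
    ("L", "TAG"): "trnL1",   # CUN codons
    ("L", "TAA"): "trnL2",   # UUR codons
    ("S", "GCT"): "trnS1",   # AGN codons
    ("S", "TCT"): "trnS1",
    ("S", "TGA"): "trnS2",   # UCN codons
}


def _normalise(name: str) -> str:
    return re.sub(r"[\s\-_()]+", "", name.strip().lower())


def _load_synonyms() -> dict[str, str]:
    table = {}
    text = (resources.files("mitocomp") / "data" / "gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[alias] = canonical
    return table


_SYNONYMS = _load_synonyms()


def canonical_gene_name(raw: str, extra_synonyms: dict[str, str] | None = None) -> str | None:
    """Map a raw gene/product string to a canonical symbol, or None.

    tRNA names of the form ``tRNA-Leu`` / ``trnL`` map to ``trnX``; Leu and
    Ser isoacceptors are left ambiguous (``trnL``/``trnS``) here and
    disambiguated by the GenBank reader from anticodon annotation or
    occurrence order.
    """
    key = _normalise(raw)
    if extra_synonyms:
        extra = {_normalise(k): v for k, v in extra_synonyms.items()}
        if key in extra:
            return extra[key]
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    direct = {_normalise(n): n for n in TRNA_NAMES + PCG_NAMES + RRNA_NAMES + ("CR",)}
    if key in direct:
        return direct[key]
    m = re.match(r"^trna?([a-z]{3})\d?$", key)
    if m and m.group(1) in _AA3_TO_1:
        return "trn" + _AA3_TO_1[m.group(1)]
    m = re.match(r"^trn([a-z])(\d)?$", key)
    if m:
        aa = m.group(1).upper()
        num = m.group(2) or ""
        cand = f"trn{aa}{num}"
        if cand in TRNA_NAMES or cand in ("trnL", "trnS"):
            return cand
    return None


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

_GB_KIND = {"CDS": FeatureKind.PCG, "tRNA": FeatureKind.TRNA, "rRNA": FeatureKind.RRNA}


def _feature_name(f: SeqFeature) -> str:
    for q in ("gene", "product", "note"):
        if q in f.qualifiers:
            return str(f.qualifiers[q][0])
    return ""


def _feature_span(f: SeqFeature, length: int) -> tuple[int, int, bool]:
    """Return (start, end, wraps_origin) in 0-based half-open coordinates."""
    loc = f.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # an origin-spanning join(x..L, 1..y) has a part ending at L and a
        # part starting at 0
        if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
            return int(parts[1].start), int(parts[0].end), True
        return int(parts[0].start), int(parts[-1].end), False
    return int(loc.start), int(loc.end), False


def _disambiguate_leu_ser(f: SeqFeature, name: str) -> str | None:
    aa = name[-1]  # 'L' or 'S'
    anticodon = None
    if "anticodon" in f.qualifiers:
        m = re.search(r"seq:([acgtu]{3})", f.qualifiers["anticodon"][0], re.I)
        if m:
            anticodon = m.group(1).upper().replace("U", "T")
    if anticodon is None and "note" in f.qualifiers:
        m = re.search(r"\(([acgtu]{3})\)", f.qualifiers["note"][0], re.I)
        if m:
            anticodon = m.group(1).upper().replace("U", "T")
    if anticodon:
        return _LEU_SER_BY_ANTICODON.get((aa, anticodon))
    return None


def record_to_mitogenome(record: SeqRecord) -> Mitogenome:
    """Convert a parsed GenBank record into a :class:`Mitogenome`."""
    seq = str(record.seq).upper()
    if not seq or "?" in seq:
        raise GenBankParseError(f"locus {record.name}: missing or malformed sequence")
    taxon = record.annotations.get("organism", "") or ""
    family = subfamily = ""
    habitat = Habitat.UNKNOWN
    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for f in record.features:
        if f.type == "source" and "note" in f.qualifiers:
            for item in f.qualifiers["note"][0].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    k, v = k.strip(), v.strip()
                    if k == "habitat":
                        try:
                            habitat = Habitat(v)
                        except ValueError:
                            pass
                    elif k == "family":
                        family = v
                    elif k == "subfamily":
                        subfamily = v
            continue
        if f.type in _GB_KIND or f.type in ("D-loop", "misc_feature"):
            raw = _feature_name(f)
            name = canonical_gene_name(raw) if raw else None
            if f.type in ("D-loop", "misc_feature"):
                if name != "CR":
                    continue  # unrelated misc features are skipped
                kind = FeatureKind.CONTROL_REGION
            else:
                kind = _GB_KIND[f.type]
            if name in ("trnL", "trnS"):
                resolved = _disambiguate_leu_ser(f, name)
                if resolved is None:
                    # fall back to genomic occurrence order of the ancestral
                    # arrangement: L2 precedes L1, S1 precedes S2
                    n = seen.get(name, 0)
                    resolved = {"trnL": ("trnL2", "trnL1"),
                                "trnS": ("trnS1", "trnS2")}[name][min(n, 1)]
                    warnings.warn(
                        f"{record.name}: no anticodon for {raw!r}; assigned "
                        f"{resolved} by occurrence order"
                    )
                seen[name] = seen.get(name, 0) + 1
                name = resolved
            if name is None:
                warnings.warn(
                    f"{record.name}: unmappable gene name {raw!r}; kept as intergenic"
                )
                name = raw or "unknown"
                kind = FeatureKind.INTERGENIC
            try:
                start, end, wraps = _feature_span(f, len(seq))
            except (TypeError, ValueError) as exc:
                raise GenBankParseError(
                    f"locus {record.name}: bad location for {raw!r}: {exc}"
                ) from exc
            strand = "-" if f.location.strand == -1 else "+"
            features.append(GeneFeature(name, kind, start, end, strand, wraps))
    return Mitogenome(
        id=record.id or record.name,
        taxon=taxon,
        sequence=seq,
        features=features,
        family=family,
        subfamily=subfamily,
        habitat=habitat,
    )


def read_genbank(path: str | Path) -> list[Mitogenome]:
    """Read one or more annotated mitogenomes from a GenBank flat file."""
    out = []
    for record in SeqIO.parse(str(path), "genbank"):
        out.append(record_to_mitogenome(record))
    if not out:
        raise GenBankParseError(f"{path}: no GenBank records found")
    return out


# ---------------------------------------------------------------------------
# GenBank writing
# ---------------------------------------------------------------------------

_KIND_GB = {
    FeatureKind.PCG: "CDS",
    FeatureKind.TRNA: "tRNA",
    FeatureKind.RRNA: "rRNA",
    FeatureKind.CONTROL_REGION: "D-loop",
    FeatureKind.INTERGENIC: "misc_feature",
}


def mitogenome_to_record(mito: Mitogenome) -> SeqRecord:
    record = SeqRecord(
        Seq(mito.sequence),
        id=mito.id,
        name=re.sub(r"[^A-Za-z0-9_.]", "_", mito.id)[:16],
        description=f"{mito.taxon} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": mito.taxon,
        },
    )
    note = f"habitat={mito.habitat.value};family={mito.family};subfamily={mito.subfamily}"
    record.features.append(
        SeqFeature(
            SimpleLocation(0, mito.length, 1),
            type="source",
            qualifiers={"organism": [mito.taxon], "note": [note]},
        )
    )
    strand_map = {"+": 1, "-": -1}
    for f in mito.features:
        s = strand_map[f.strand]
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start, mito.length, s), SimpleLocation(0, f.end, s)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, s)
        quals = {"gene": [f.name]}
        record.features.append(SeqFeature(loc, type=_KIND_GB[f.kind], qualifiers=quals))
    return record


def write_genbank(mitos: list[Mitogenome] | Mitogenome, path: str | Path) -> None:
    if isinstance(mitos, Mitogenome):
        mitos = [mitos]
    SeqIO.write([mitogenome_to_record(m) for m in mitos], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA and metadata
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (plain or aligned) FASTA file into an ordered id->sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the id/taxon/family/subfamily/habitat TSV; habitat defaults to
    'unknown' when the column is absent or empty."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise MitocompError(f"{path}: metadata must have an 'id' column")
    if "habitat" not in df.columns:
        df["habitat"] = Habitat.UNKNOWN.value
    df.loc[df["habitat"] == "", "habitat"] = Habitat.UNKNOWN.value
    return df


def apply_metadata(mitos: list[Mitogenome], meta: pd.DataFrame) -> list[Mitogenome]:
    by_id = meta.set_index("id")
    out = []
    for m in mitos:
        if m.id in by_id.index:
            row = by_id.loc[m.id]
            out.append(
                replace(
                    m,
                    taxon=row.get("taxon", m.taxon) or m.taxon,
                    family=row.get("family", m.family) or m.family,
                    subfamily=row.get("subfamily", m.subfamily) or m.subfamily,
                    habitat=Habitat(row.get("habitat", m.habitat.value)),
                )
            )
        else:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# gene extraction / concatenation / translation
# ---------------------------------------------------------------------------

def extract_gene(mito: Mitogenome, name: str) -> str:
    """Oriented nucleotide sequence of a named feature.

    Minus-strand features are reverse-complemented; origin-spanning features
    are concatenated across the origin before orientation.
    """
    f = mito.feature(name)
    if f.wraps_origin:
        raw = mito.sequence[f.start :] + mito.sequence[: f.end]
    else:
        raw = mito.sequence[f.start : f.end]
    return reverse_complement(raw) if f.strand == "-" else raw


def concatenate_pcgs(
    aligned_blocks: dict[str, dict[str, str]],
    gene_order: tuple[str, ...] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate per-gene aligned blocks into a supermatrix.

    Parameters
    ----------
    aligned_blocks
        gene -> (taxon -> aligned sequence).  All blocks must share the same
        taxon set; rows within a block must have equal lengths.
    gene_order
        Concatenation order; defaults to the canonical alphabetical PCG
        order, restricted to the genes present (extra blocks such as rRNAs
        are appended after the PCGs in sorted order).

    Returns
    -------
    (supermatrix, partitions)
        supermatrix: taxon -> concatenated sequence;
        partitions: DataFrame with 1-based inclusive start/end per gene.
    """
    if not aligned_blocks:
        raise MitocompError("no aligned blocks supplied")
    if gene_order is None:
        pcgs = [g for g in PCG_CONCAT_ORDER if g in aligned_blocks]
        extras = sorted(g for g in aligned_blocks if g not in PCG_CONCAT_ORDER)
        gene_order = tuple(pcgs + extras)
    taxa = None
    for gene in gene_order:
        block = aligned_blocks[gene]
        lengths = {len(s) for s in block.values()}
        if len(lengths) != 1:
            raise MitocompError(f"block {gene}: unequal aligned lengths {lengths}")
        if taxa is None:
            taxa = set(block)
        elif set(block) != taxa:
            missing = sorted(taxa ^ set(block))
            raise MitocompError(
                f"block {gene}: taxon set mismatch; differing taxa: {missing}"
            )
    order_taxa = list(aligned_blocks[gene_order[0]])
    supermatrix = {t: "" for t in order_taxa}
    rows = []
    pos = 0
    for gene in gene_order:
        block = aligned_blocks[gene]
        width = len(next(iter(block.values())))
        rows.append({"gene": gene, "start": pos + 1, "end": pos + width, "width": width})
        pos += width
        for t in order_taxa:
            supermatrix[t] += block[t]
    return supermatrix, pd.DataFrame(rows)


def write_partitions(partitions: pd.DataFrame, path: str | Path, style: str = "tsv") -> None:
    """Write a partition table as plain TSV or NEXUS-style charset lines."""
    if style == "tsv":
        partitions.to_csv(path, sep="\t", index=False)
    elif style == "nexus":
        with open(path, "w") as fh:
            fh.write("#nexus\nbegin sets;\n")
            for _, r in partitions.iterrows():
                fh.write(f"  charset {r.gene} = {r.start}-{r.end};\n")
            fh.write("end;\n")
    else:
        raise ValueError(f"unknown partition style {style!r}")


def translate(cds: str, code: GeneticCode | int = 5) -> str:
    """Translate an in-frame CDS under the given genetic code.

    A trailing incomplete codon of length 1-2 is treated as a stop completed
    by polyadenylation and excluded from the peptide, as is a complete
    terminal stop codon.  An internal stop raises :class:`FrameError` naming
    the codon position.
    """
    if isinstance(code, int):
        code = get_code(code)
    cds = cds.upper().replace("-", "")
    n_full = len(cds) // 3
    peptide = []
    for i in range(n_full):
        codon = cds[3 * i : 3 * i + 3]
        if code.is_stop(codon):
            if i == n_full - 1:
                break  # terminal stop, excluded
            raise FrameError(f"internal stop codon {codon} at codon {i + 1}")
        if "N" in codon:
            peptide.append("X")
        else:
            peptide.append(code.aa(codon))
    return "".join(peptide)
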