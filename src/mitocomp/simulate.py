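"""Synthetic mitogenome, codon-alignment, and population generators.

The generators emulate the statistical structure of insect (hydrophiloid)
mitochondrial data: 37-gene genomes in the ancestral gene order with
AT-biased composition and a repeat-bearing control region between rrnS and
trnI; codon alignments evolved on a tree under the branch-site Model A
site-class mixture (GY94 generator shared with the selection module); and
low-diversity population haplotype samples.

Determinism contract: one integer seed drives a single root
``numpy.random.Generator``; identical configuration + seed reproduces
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .genetic_code import GeneticCode, get_code, reverse_complement
from .io import (
    ANCESTRAL_GENE_ORDER,
    FeatureKind,
    GeneFeature,
    Habitat,
    Mitogenome,
    kind_of,
)
from .selection import (
    CodonAlignment,
    _eigen,
    _transition_matrix,
    gy94_matrix,
    mixture_scale,
    rate_coefficients,
)
from .trees import PhyloTree

# typical hydrophiloid PCG lengths in bp, stop codon included
PCG_LENGTHS = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "nad1": 939, "nad2": 1023,
    "nad3": 354, "nad4": 1341, "nad4L": 288, "nad5": 1719, "nad6": 522,
    "atp6": 678, "atp8": 162, "cob": 1137,
}
RRNA_LENGTHS = {"rrnS": 780, "rrnL": 1290}


@dataclass
class CRSpec:
    """Control-region recipe: a planted tandem array plus poly-A/T runs."""

    motif: str = "TATTA"
    copies: int = 8
    mutation_rate: float = 0.02  # per-base substitution probability per copy

    def __post_init__(self):
        if not self.motif or set(self.motif.upper()) - set("ACGT"):
            raise ConfigError(f"invalid CR motif {self.motif!r}")
        if self.copies < 1:
            raise ConfigError("CR copy number must be >= 1")
        if not 0 <= self.mutation_rate < 1:
            raise ConfigError("CR mutation rate must be in [0, 1)")


@dataclass
class PopulationSpec:
    """Haplotype sample: n copies of a reference mutated site-wise."""

    n_haplotypes: int = 8
    mutation_prob: float = 2e-4  # per-site, per-haplotype
    length: int = 1000

    def __post_init__(self):
        if self.n_haplotypes < 2:
            raise ConfigError("population needs >= 2 haplotypes")
        if not 0 <= self.mutation_prob < 1:
            raise ConfigError("mutation probability must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Study conditions for all synthetic fixtures.

    The site-class mixture defaults place 10% of sites in the
    foreground-selected classes (2a+2b split in the Model A proportions),
    with strong purifying selection elsewhere (omega0 = 0.05) and a
    foreground omega2 = 5 — a regime in which branch-site tests have
    appreciable but not trivial power.  Composition defaults target the
    strong AT bias of hydrophiloid mitogenomes (78% AT genome-wide,
    highest at third codon positions).
    """

    seed: int = 0
    n_taxa: int = 8
    tree: str | None = None  # newick; generated from the seed when None
    at_target: float = 0.78  # whole-genome AT fraction
    at_third_position: float | None = None  # default: at_target + 0.10
    p0: float = 0.85
    p1: float = 0.05
    p2a: float = 0.85 / 0.90 * 0.10
    p2b: float = 0.05 / 0.90 * 0.10
    omega0: float = 0.05
    omega2: float = 5.0
    kappa: float = 4.0
    n_codons: int = 500
    genetic_code: int = 5
    cr: CRSpec = field(default_factory=CRSpec)
    population: PopulationSpec = field(default_factory=PopulationSpec)

    def __post_init__(self):
        props = np.array([self.p0, self.p1, self.p2a, self.p2b])
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-6:
            raise ConfigError("site-class proportions must be >= 0 and sum to 1")
        if not 0 < self.omega0 < 1:
            raise ConfigError("omega0 must lie in (0, 1)")
        if self.omega2 < 1:
            raise ConfigError("omega2 must be >= 1")
        if not 0.05 < self.at_target < 0.97:
            raise ConfigError("AT target composition is infeasible")
        if self.n_taxa < 2:
            raise ConfigError("need at least 2 taxa")

    # -- derived composition targets -------------------------------------

    def position_at(self) -> tuple[float, float, float]:
        """Per-codon-position AT targets whose mean equals at_target."""
        t3 = self.at_third_position
        if t3 is None:
            t3 = min(self.at_target + 0.10, 0.96)
        t12 = (3 * self.at_target - t3) / 2
        if not 0.02 < t12 < 0.98:
            raise ConfigError("AT target composition is infeasible at codon positions")
        return (t12, t12, t3)


def _nuc_probs(at: float) -> np.ndarray:
    """P(A), P(C), P(G), P(T) with the A/T and C/G halves symmetric."""
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


def _codon_freqs(position_at, code: GeneticCode) -> np.ndarray:
    """F3x4-style sense-codon frequencies from per-position AT targets."""
    base_index = {b: i for i, b in enumerate("ACGT")}
    pos = [_nuc_probs(a) for a in position_at]
    pi = np.array(
        [
            pos[0][base_index[c[0]]] * pos[1][base_index[c[1]]] * pos[2][base_index[c[2]]]
            for c in code.sense_codons
        ]
    )
    return pi / pi.sum()


def _random_seq(rng: np.random.Generator, length: int, at: float) -> str:
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.choice(4, size=length, p=_nuc_probs(at))])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def random_tree(
    rng: np.random.Generator,
    n_taxa: int,
    length_range: tuple[float, float] = (0.05, 0.2),
    mark_foreground: bool = True,
) -> PhyloTree:
    """Random coalescent-style topology with uniform branch lengths.

    When ``mark_foreground`` is set, one internal branch (never the root or
    a child of the root, where reversibility would confound the mark) is
    designated foreground; with few taxa a terminal branch is used.
    """
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    lo, hi = length_range

    def bl() -> str:
        return f"{rng.uniform(lo, hi):.6f}"

    nodes = [f"{lab}:{bl()}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl()}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    tree = PhyloTree.from_newick(newick)
    if mark_foreground:
        root_children = set(tree.nodes[tree.root].children)
        candidates = [
            n for n in tree.nodes
            if not n.is_tip and n.parent != -1 and n.index not in root_children
        ]
        if not candidates:
            candidates = [n for n in tree.tips]
        pick = candidates[int(rng.integers(len(candidates)))]
        pick.foreground = True
    return tree


# ---------------------------------------------------------------------------
# codon alignments under the branch-site mixture
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    cfg: SimulationConfig,
    foreground_branch=None,
    rng: np.random.Generator | None = None,
) -> tuple[CodonAlignment, PhyloTree, np.ndarray]:
    """Evolve a codon alignment on a tree under the Model A mixture.

    Site classes are drawn from (p0, p1, p2a, p2b); background branches use
    omega0 / 1 and the foreground branch uses omega2 for classes 2a/2b.
    Returns (alignment, tree, true class label per site).  Simulated
    sequences can contain no stop codons by construction (the state space
    is the sense-codon set).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    code = get_code(cfg.genetic_code)
    if cfg.tree is not None:
        tree = PhyloTree.from_newick(cfg.tree)
    else:
        tree = random_tree(rng, cfg.n_taxa)
    if foreground_branch is not None:
        tree.mark_foreground(foreground_branch)
    if tree.n_foreground == 0 and (cfg.p2a + cfg.p2b) > 0:
        raise ConfigError(
            "site classes 2a/2b require a marked foreground branch"
        )
    pi = _codon_freqs(cfg.position_at(), code)
    props = np.array([cfg.p0, cfg.p1, cfg.p2a, cfg.p2b])
    classes = rng.choice(4, size=cfg.n_codons, p=props)
    class_omegas = np.array(
        [
            [cfg.omega0, cfg.omega0],
            [1.0, 1.0],
            [cfg.omega0, cfg.omega2],
            [1.0, cfg.omega2],
        ]
    )
    # same rate convention as the selection module: branch lengths are
    # expected substitutions per codon under the background mixture
    f = mixture_scale(cfg.kappa, props, class_omegas[:, 0],
                      rate_coefficients(pi, code))
    eigs = {
        om: _eigen(gy94_matrix(cfg.kappa, om, pi, code, scale=False), pi)
        for om in np.unique(class_omegas)
    }
    n = code.n_sense
    states = {tree.root: rng.choice(n, size=cfg.n_codons, p=pi)}
    for node in reversed(tree.nodes):  # preorder
        if node.parent == -1:
            continue
        parent_states = states[node.parent]
        col = 1 if node.foreground else 0
        child = np.empty(cfg.n_codons, dtype=np.int64)
        for c in range(4):
            sites = np.flatnonzero(classes == c)
            if sites.size == 0:
                continue
            P = _transition_matrix(eigs[class_omegas[c, col]], node.length / f)
            P = P / P.sum(axis=1, keepdims=True)
            for s in np.unique(parent_states[sites]):
                idx = sites[parent_states[sites] == s]
                child[idx] = rng.choice(n, size=idx.size, p=P[s])
        states[node.index] = child
    mat = np.vstack([states[t.index] for t in tree.tips])
    aln = CodonAlignment(list(tree.taxa), mat, code)
    return aln, tree, classes


# ---------------------------------------------------------------------------
# whole mitogenomes
# ---------------------------------------------------------------------------

def _simulate_cds(rng, length: int, position_at, code: GeneticCode) -> str:
    """Random stop-free CDS: start codon, body codons from the F3x4 target,
    terminal TAA stop.  ``length`` includes start and stop and must be a
    multiple of 3."""
    if length % 3:
        raise ConfigError("CDS length must be a multiple of 3")
    pi = _codon_freqs(position_at, code)
    n_body = length // 3 - 2
    body = rng.choice(code.n_sense, size=n_body, p=pi)
    start = "ATA" if rng.random() < 0.7 else "ATG"
    return start + "".join(code.sense_codons[s] for s in body) + "TAA"


def _mutate_copy(rng, motif: str, rate: float) -> str:
    out = []
    for ch in motif:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def _other_base(avoid: str) -> str:
    return "C" if avoid != "C" else "G"


def _guard_flanks(head: str, array: str, tail: str, period: int) -> tuple[str, str]:
    """Edit up to one period of flank on each side so the planted array's
    periodicity terminates exactly at its boundaries."""
    h, t = list(head), list(tail)
    for k in range(1, min(period, len(h)) + 1):
        if h[-k] == array[period - k]:
            h[-k] = _other_base(array[period - k])
    for k in range(min(period, len(t))):
        if t[k] == array[len(array) - period + k]:
            t[k] = _other_base(array[len(array) - period + k])
    return "".join(h), "".join(t)


def _simulate_cr(rng, cr: CRSpec, at: float) -> tuple[str, int, int]:
    """Control region: AT-rich spacer, poly-T, the tandem array, poly-A,
    AT-rich tail.  Returns (sequence, array_start, array_end)."""
    motif = cr.motif.upper()
    array = "".join(_mutate_copy(rng, motif, cr.mutation_rate) for _ in range(cr.copies))
    head = _random_seq(rng, 40, min(at + 0.02, 0.97)) + "T" * 10
    tail = "A" * 10 + _random_seq(rng, 120, min(at + 0.02, 0.97))
    head, tail = _guard_flanks(head, array, tail, len(motif))
    start = len(head)
    return head + array + tail, start, start + len(array)


def simulate_mitogenome(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "SIM000001",
    taxon: str = "Simulatus mitogenomicus",
    habitat: Habitat = Habitat.UNKNOWN,
) -> Mitogenome:
    """A complete 37-gene mitogenome in the ancestral insect gene order.

    Protein-coding genes are stop-free random CDSs under the per-position
    AT targets; tRNAs/rRNAs and spacers are AT-biased random sequence; the
    control region sits between rrnS and trnI and carries the configured
    tandem array with poly-A/T stretches; a conserved-style 17-42 bp
    intergenic spacer separates trnS2 and nad1.  Whole-genome AT lands
    within about two points of the configured target.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    code = get_code(cfg.genetic_code)
    pos_at = cfg.position_at()
    at = cfg.at_target
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, strand in ANCESTRAL_GENE_ORDER:
        kind = kind_of(name)
        if kind is FeatureKind.PCG:
            gene_seq = _simulate_cds(rng, PCG_LENGTHS[name], pos_at, code)
        elif kind is FeatureKind.TRNA:
            gene_seq = _random_seq(rng, int(rng.integers(64, 72)), at)
        elif kind is FeatureKind.RRNA:
            gene_seq = _random_seq(rng, RRNA_LENGTHS[name], min(at + 0.05, 0.96))
        else:  # control region
            gene_seq, _, _ = _simulate_cr(rng, cfg.cr, at)
        placed = reverse_complement(gene_seq) if strand == "-" else gene_seq
        features.append(
            GeneFeature(name, kind, pos, pos + len(placed), strand=strand)
        )
        parts.append(placed)
        pos += len(placed)
        if name == "trnS2":
            spacer = _random_seq(rng, int(rng.integers(17, 43)), at)
            parts.append(spacer)
            pos += len(spacer)
    return Mitogenome(
        id=sample_id,
        taxon=taxon,
        sequence="".join(parts),
        features=features,
        habitat=habitat,
    )


def _mutate_cds_codons(rng, cds: str, rate: float, code: GeneticCode) -> str:
    """Point-mutate a CDS while keeping it stop-free: each non-terminal
    codon mutates with probability 3*rate to a random single-nucleotide
    neighbour that is not a stop codon."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for k in range(1, len(codons) - 1):
        if rng.random() >= 3 * rate:
            continue
        codon = codons[k]
        neighbours = []
        for pos in range(3):
            for b in "ACGT":
                if b != codon[pos]:
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if not code.is_stop(alt):
                        neighbours.append(alt)
        codons[k] = neighbours[int(rng.integers(len(neighbours)))]
    return "".join(codons)


def simulate_study(
    cfg: SimulationConfig,
    n_genomes: int | None = None,
    divergence: tuple[float, float] = (0.01, 0.06),
    habitats: list[Habitat] | None = None,
) -> list[Mitogenome]:
    """A small comparative study: one ancestral mitogenome plus relatives
    derived from it by point mutation.

    Per genome a divergence level is drawn uniformly from ``divergence``;
    protein-coding genes are mutated at codon level so they stay stop-free,
    non-coding regions site-wise.  Gene coordinates are shared (mutation is
    substitution-only), so extracted genes are alignment-ready.
    """
    rng = np.random.default_rng(cfg.seed)
    code = get_code(cfg.genetic_code)
    if n_genomes is None:
        n_genomes = cfg.n_taxa
    ancestor = simulate_mitogenome(cfg, rng=rng, sample_id="SIM000001",
                                   taxon="Simulatus mitogenomicus 1")
    if habitats is None:
        cycle = [Habitat.AQUATIC, Habitat.SEMI_AQUATIC, Habitat.TERRESTRIAL]
        habitats = [cycle[i % 3] for i in range(n_genomes)]
    genomes = []
    pcg_spans = [(f.start, f.end, f.strand) for f in ancestor.features
                 if f.kind is FeatureKind.PCG]
    for g in range(n_genomes):
        if g == 0:
            seq = ancestor.sequence
        else:
            d = rng.uniform(*divergence)
            chars = np.array(list(ancestor.sequence))
            coding = np.zeros(chars.size, bool)
            for a, b, _ in pcg_spans:
                coding[a:b] = True
            bases = np.array(list("ACGT"))
            hit = np.flatnonzero((rng.random(chars.size) < d) & ~coding)
            for i in hit:
                chars[i] = bases[bases != chars[i]][int(rng.integers(3))]
            seq = "".join(chars)
            for a, b, strand in pcg_spans:
                cds = seq[a:b]
                if strand == "-":
                    cds = reverse_complement(cds)
                cds = _mutate_cds_codons(rng, cds, d / 3, code)
                if strand == "-":
                    cds = reverse_complement(cds)
                seq = seq[:a] + cds + seq[b:]
        genomes.append(
            Mitogenome(
                id=f"SIM{g + 1:06d}",
                taxon=f"Simulatus mitogenomicus {g + 1}",
                sequence=seq,
                features=[GeneFeature(f.name, f.kind, f.start, f.end, f.strand,
                                      f.wraps_origin)
                          for f in ancestor.features],
                habitat=habitats[g],
                family="Simulatidae",
                subfamily="Simulatinae" if g % 2 else "Alterinae",
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# population samples
# ---------------------------------------------------------------------------

def simulate_population(
    cfg: SimulationConfig,
    reference: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], int]:
    """Haplotypes mutated independently from a common reference.

    Each site of each haplotype mutates with probability
    ``cfg.population.mutation_prob`` to a uniformly chosen different base.
    Returns (haplotype map, S) where S is the realised number of
    segregating sites.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spec = cfg.population
    if reference is None:
        reference = _random_seq(rng, spec.length, cfg.at_target)
    ref = np.array(list(reference))
    bases = np.array(list("ACGT"))
    haps = {}
    matrix = []
    for h in range(spec.n_haplotypes):
        hit = rng.random(ref.size) < spec.mutation_prob
        seq = ref.copy()
        for i in np.flatnonzero(hit):
            choices = bases[bases != ref[i]]
            seq[i] = choices[int(rng.integers(3))]
        matrix.append(seq)
        haps[f"hap{h + 1}"] = "".join(seq)
    arr = np.vstack(matrix)
    s = int(((arr != arr[0]).any(axis=0)).sum())
    return haps, s
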