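"""End-to-end orchestration of the comparative mitogenomic analysis.

Stages: simulate -> compose -> codon -> diversity -> select -> cr.  Each
stage reads its inputs from the run directory (so stages are re-runnable
from cached intermediates), writes deterministic TSV reports, and
contributes to a machine-readable ``summary.json``.  A ``MANIFEST.tsv``
records per-stage status; a stage failure halts downstream stages but
retains completed outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import composition_report, group_compare, per_position_composition
from .codon_usage import codon_usage_table
from .control_region import annotate_cr, conserved_blocks
from .diversity import (
    clade_ka_ks,
    haplotype_diversity,
    nucleotide_diversity,
    segregating_sites,
    sliding_window_pi,
)
from .errors import ConfigError, MitocompError
from .io import (
    PCG_NAMES,
    Habitat,
    extract_gene,
    read_genbank,
    read_metadata,
    apply_metadata,
    write_fasta,
    write_genbank,
)
from .selection import CodonAlignment, branch_site_test
from .simulate import SimulationConfig, simulate_study
from .trees import PhyloTree
from .simulate import random_tree

log = logging.getLogger("mitocomp")

ALL_STAGES = ("simulate", "compose", "codon", "diversity", "select", "cr")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    genomes: str | None = None      # GenBank path; default: <out_dir>/genomes.gb
    metadata: str | None = None     # TSV path
    tree: str | None = None         # Newick path (used by select)
    foreground: tuple[str, ...] | None = None
    selection_genes: tuple[str, ...] = ("cox3", "nad5")
    window: int = 100
    step: int = 25
    lrt_mixture: bool = False
    beb_grid: int = 10
    repeat_min_score: float = 50.0
    n_taxa: int = 6
    genetic_code: int = 5

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("stages", "foreground", "selection_genes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def genomes_path(self) -> Path:
        return Path(self.genomes) if self.genomes else Path(self.out_dir) / "genomes.gb"


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Cross-check genomes / tree / metadata; returns diagnostics (empty
    when clean).  Checks: taxa concordance, duplicate ids, missing habitat
    labels, CDS frame violations, and internal stop codons."""
    from .io import translate
    from .errors import FrameError

    diagnostics: list[str] = []
    gpath = cfg.genomes_path()
    if not gpath.exists():
        diagnostics.append(f"genomes file missing: {gpath}")
        return diagnostics
    mitos = read_genbank(gpath)
    ids = [m.id for m in mitos]
    for dup in {i for i in ids if ids.count(i) > 1}:
        diagnostics.append(f"duplicate genome id: {dup}")
    for m in mitos:
        if m.habitat is Habitat.UNKNOWN:
            diagnostics.append(f"{m.id}: habitat unknown")
        for f in m.features:
            if f.kind.value != "PCG":
                continue
            cds = extract_gene(m, f.name)
            if len(cds) % 3:
                diagnostics.append(
                    f"{m.id} {f.name}: length {len(cds)} not divisible by 3 "
                    "(incomplete terminal codon)"
                )
            try:
                translate(cds, cfg.genetic_code)
            except FrameError as exc:
                diagnostics.append(f"{m.id} {f.name}: {exc}")
    if cfg.tree:
        tree = PhyloTree.from_newick(Path(cfg.tree).read_text())
        missing = set(tree.taxa) - set(ids)
        for t in sorted(missing):
            diagnostics.append(f"tree taxon absent from genomes: {t}")
    if cfg.metadata:
        meta = read_metadata(cfg.metadata)
        for mid in set(meta["id"]) - set(ids):
            diagnostics.append(f"metadata id absent from genomes: {mid}")
    return diagnostics


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, summary: dict) -> None:
    sim = SimulationConfig(seed=cfg.seed, n_taxa=cfg.n_taxa,
                           genetic_code=cfg.genetic_code)
    genomes = simulate_study(sim, n_genomes=cfg.n_taxa)
    write_genbank(genomes, out / "genomes.gb")
    meta = pd.DataFrame(
        [{"id": m.id, "taxon": m.taxon, "family": m.family,
          "subfamily": m.subfamily, "habitat": m.habitat.value} for m in genomes]
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    for gene in PCG_NAMES:
        write_fasta({m.id: extract_gene(m, gene) for m in genomes},
                    out / f"gene_{gene}.fasta")
    # a codon alignment evolved under the branch-site mixture, with truth
    # tables for selection-recovery exercises
    from .simulate import simulate_codon_alignment

    aln, tree, classes = simulate_codon_alignment(sim)
    write_fasta(aln.to_seqs(), out / "codon_alignment.fasta")
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    pd.DataFrame(
        {"site": np.arange(1, classes.size + 1), "true_class": classes}
    ).to_csv(out / "truth_site_classes.tsv", sep="\t", index=False)
    summary["simulate"] = {"n_genomes": len(genomes),
                           "genome_length": genomes[0].length}


def _load_genomes(cfg: RunConfig):
    mitos = read_genbank(cfg.genomes_path())
    if cfg.metadata:
        mitos = apply_metadata(mitos, read_metadata(cfg.metadata))
    return mitos


def _stage_compose(cfg: RunConfig, out: Path, summary: dict) -> None:
    mitos = _load_genomes(cfg)
    report = composition_report(mitos, per_gene=True)
    report.to_csv(out / "composition.tsv", sep="\t", index=False)
    genome_at = report[report.scope == "genome"].set_index("id")["AT_percent"]
    by_habitat: dict[str, list[float]] = {}
    for m in mitos:
        by_habitat.setdefault(m.habitat.value, []).append(float(genome_at[m.id]))
    usable = {k: v for k, v in by_habitat.items() if len(v) >= 2}
    if len(usable) >= 2:
        group_compare(usable).to_csv(out / "group_compare.tsv", sep="\t", index=False)
    pcgs = [extract_gene(m, g) for m in mitos for g in PCG_NAMES]
    p1, p2, p3 = per_position_composition(pcgs)
    summary["compose"] = {
        "mean_genome_AT_percent": float(genome_at.mean()),
        "pos1_AT_percent": p1.at_percent,
        "pos2_AT_percent": p2.at_percent,
        "pos3_AT_percent": p3.at_percent,
    }


def _stage_codon(cfg: RunConfig, out: Path, summary: dict) -> None:
    mitos = _load_genomes(cfg)
    seqs = {m.id: [extract_gene(m, g) for g in PCG_NAMES] for m in mitos}
    table, rscu_long = codon_usage_table(seqs, cfg.genetic_code)
    table.to_csv(out / "codon_summary.tsv", sep="\t", index=False)
    rscu_long.to_csv(out / "rscu.tsv", sep="\t", index=False)
    summary["codon"] = {"mean_ENC": float(table["ENC"].mean()),
                        "mean_CBI": float(table["CBI"].mean())}


def _stage_diversity(cfg: RunConfig, out: Path, summary: dict) -> None:
    mitos = _load_genomes(cfg)
    rows, win_rows, kaks_rows = [], [], []
    for gene in PCG_NAMES:
        aln = {m.id: extract_gene(m, gene) for m in mitos}
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            log.warning("gene %s: unequal lengths, skipped", gene)
            continue
        pi = nucleotide_diversity(aln)
        hd, _ = haplotype_diversity(aln)
        s = segregating_sites(aln)
        rows.append({"gene": gene, "n": len(aln), "S": s, "Pi": pi, "Hd": hd})
        if min(lengths) >= cfg.window:
            for mid, wpi in sliding_window_pi(aln, cfg.window, cfg.step):
                win_rows.append({"gene": gene, "midpoint": mid, "Pi": wpi})
        cds = {k: v[: 3 * (len(v) // 3) - 3] for k, v in aln.items()}  # drop stop
        mean_ratio, pairs = clade_ka_ks(cds, cfg.genetic_code)
        for t1, t2, est in pairs:
            kaks_rows.append({"gene": gene, "seq1": t1, "seq2": t2,
                              "Ka": est.ka, "Ks": est.ks, "KaKs": est.ratio})
        rows[-1]["mean_KaKs"] = mean_ratio
    pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
    pd.DataFrame(win_rows).to_csv(out / "windows.tsv", sep="\t", index=False)
    pd.DataFrame(kaks_rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
    df = pd.DataFrame(rows)
    summary["diversity"] = {"mean_Pi": float(df["Pi"].mean()),
                            "mean_KaKs": float(df["mean_KaKs"].mean())}


def _stage_select(cfg: RunConfig, out: Path, summary: dict) -> None:
    mitos = _load_genomes(cfg)
    if cfg.tree:
        tree = PhyloTree.from_newick(Path(cfg.tree).read_text())
    else:
        rng = np.random.default_rng([cfg.seed, 4])
        tree = random_tree(rng, len(mitos), mark_foreground=False)
        relabel = dict(zip(sorted(tree.taxa), [m.id for m in mitos]))
        for tip in tree.tips:
            tip.taxon = relabel[tip.taxon]
        tree = PhyloTree(tree.nodes)
    if cfg.foreground:
        tree.mark_foreground(list(cfg.foreground) if len(cfg.foreground) > 1
                             else cfg.foreground[0])
    elif tree.n_foreground == 0:
        tree.mark_foreground(mitos[-1].id)
    fit_rows, beb_frames = [], []
    for gene in cfg.selection_genes:
        aln_seqs = {m.id: extract_gene(m, gene) for m in mitos}
        aln_seqs = {k: v[: len(v) - len(v) % 3 - 3] for k, v in aln_seqs.items()}
        aln = CodonAlignment.from_seqs(aln_seqs, cfg.genetic_code)
        fit = branch_site_test(aln, tree, beb_grid=cfg.beb_grid)
        rep = fit.report()
        rep.insert(0, "gene", gene)
        fit_rows.append(rep)
        beb = fit.beb.copy()
        beb.insert(0, "gene", gene)
        beb_frames.append(beb)
        summary.setdefault("select", {})[gene] = {
            "twoDeltaL": fit.two_dl, "p_value": fit.p_value,
            "omega2": fit.omega2,
            "n_sites_pp95": int((fit.beb.posterior > 0.95).sum()),
        }
    pd.concat(fit_rows).to_csv(out / "selection.tsv", sep="\t", index=False)
    pd.concat(beb_frames).to_csv(out / "beb.tsv", sep="\t", index=False)


def _stage_cr(cfg: RunConfig, out: Path, summary: dict) -> None:
    mitos = _load_genomes(cfg)
    frames = []
    for m in mitos:
        df = annotate_cr(m, min_score=cfg.repeat_min_score)
        df.insert(0, "id", m.id)
        frames.append(df)
    pd.concat(frames).to_csv(out / "cr_features.tsv", sep="\t", index=False)
    crs = {m.id: extract_gene(m, "CR") for m in mitos}
    n_blocks = None
    if len({len(s) for s in crs.values()}) == 1 and len(crs) >= 2:
        blocks = conserved_blocks(crs)
        pd.DataFrame(
            [{"block": b.block_id, "start": b.start, "end": b.end,
              "length": b.length} for b in blocks]
        ).to_csv(out / "cr_blocks.tsv", sep="\t", index=False)
        n_blocks = len(blocks)
    n_repeats = int(sum((f.feature == "tandem_repeat").sum() for f in frames))
    summary["cr"] = {"n_tandem_repeat_reports": n_repeats,
                     "n_conserved_blocks": n_blocks}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "compose": _stage_compose,
    "codon": _stage_codon,
    "diversity": _stage_diversity,
    "select": _stage_select,
    "cr": _stage_cr,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dictionary
    (also written to ``summary.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items() if k != "out_dir"},
    }
    manifest = []
    failed = False
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        if failed:
            manifest.append({"stage": stage, "status": "skipped"})
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FN[stage](cfg, out, summary)
            manifest.append({"stage": stage, "status": "ok"})
        except MitocompError as exc:
            log.error("stage %s failed: %s", stage, exc)
            manifest.append({"stage": stage, "status": f"failed: {exc}"})
            failed = True
    pd.DataFrame(manifest).to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
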