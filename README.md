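# mitocomp

Comparative mitogenomics of insect mitochondrial genomes, as a tested,
reusable Python library and CLI.  The package covers the quantitative
core of a typical mitogenome comparison across a beetle superfamily:

- **Composition & skews** — AT%/GC%, AT-skew (A−T)/(A+T) and GC-skew
  (G−C)/(G+C) for whole genomes, genes, and codon positions; Welch
  t-test group contrasts (habitat, family, subfamily) with significance
  stars; Pearson correlations with fitted lines.
- **Codon-usage bias** — RSCU, Wright's effective number of codons (ENC)
  generalised to any genetic code's family structure, the null curve
  ENC(s) = 2 + s + 29/(s²+(1−s)²), and the codon bias index (CBI).
- **Diversity** — segregating sites, nucleotide diversity Pi with a
  100 bp / 25 bp sliding-window profile, haplotype diversity Hd,
  pairwise identity (nucleotide and amino-acid), and Nei–Gojobori Ka/Ks
  with Jukes–Cantor correction and exact pathway averaging.
- **Positive selection** — a GY94 codon-likelihood engine (Felsenstein
  pruning, F3x4 frequencies) driving branch-site Model A: null
  (foreground ω₂ = 1) and alternative fits with branch lengths fixed
  from a one-ratio refit, the 2ΔL likelihood-ratio test against χ²₁, and
  grid-based Bayes empirical Bayes posteriors for selected sites
  (* PP>0.95, ** PP>0.99).  ω is the nonsynonymous/synonymous rate
  ratio dN/dS: <1 purifying, >1 positive selection.
- **Topology tests** — KH, SH and ELW from RELL bootstrap of per-site
  log-likelihoods.
- **Control region** — tandem-repeat detection (period, copy number,
  consensus, percent identity) by k-mer seeding plus wraparound
  consensus alignment, conserved-block segmentation of aligned CRs, and
  poly-A/T / (TA)n / AT-richness annotation.
- **Synthetic data** — seeded generators for 37-gene AT-biased
  mitogenomes with repeat-bearing control regions, codon alignments
  evolved under the branch-site mixture (with ground-truth site
  classes), and low-diversity population samples; these are first-class,
  tested code and make the whole pipeline runnable with no downloads.

Annotated GenBank mitogenomes (e.g. a superfamily's deposited records
plus relatives) go through the same path: `read_genbank` →
composition/codon/diversity/selection/CR stages → TSV + JSON reports.

## Worked example

Simulate a codon alignment with 10% of sites under positive selection
(ω₂ = 5) on a marked foreground branch, run the branch-site test, and
inspect the control region of a simulated genome:

```python
import mitocomp as mc

cfg = mc.SimulationConfig(seed=3)
aln, tree, true_classes = mc.simulate_codon_alignment(cfg)
fit = mc.branch_site_test(aln, tree)
print(f"2dL = {fit.two_dl:.2f}, p = {fit.p_value:.4f}")
print(f"foreground omega2 = {fit.omega2:.2f} (simulated: {cfg.omega2})")
hits = fit.beb[fit.beb.stars != ""]
print(f"sites with PP > 0.95: {len(hits)}")

genome = mc.simulate_mitogenome(cfg)
prof = mc.base_composition(genome.sequence)
print(f"genome: {genome.length} bp, AT = {prof.at_percent:.2f}%")
r = max(mc.find_tandem_repeats(mc.extract_gene(genome, "CR"),
                               min_score=20, max_period=100),
        key=lambda r: r.score)
print(f"CR repeat: period {r.period}, {r.copy_number:.1f} copies")
```

prints

```
2dL = 12.33, p = 0.0004
foreground omega2 = 4.19 (simulated: 5.0)
sites with PP > 0.95: 9
genome: 14982 bp, AT = 78.06%
CR repeat: period 5, 8.0 copies
```

The test recovers the planted selection: 2ΔL = 12.33 exceeds the χ²₁
5% critical value 3.84, the foreground ω₂ estimate 4.19 sits near the
simulated 5, and the flagged sites are drawn from the planted selected
classes.  The genome lands on its 78% AT composition target and the
planted TATTA×8 repeat array is recovered with its exact period.

## Command line

```bash
mitocomp run --out runs/demo --seed 1          # simulate + all stages
mitocomp select --out runs/demo --tree my.nwk  # one stage, cached inputs
mitocomp validate --out runs/demo --strict     # input concordance checks
```

Stage reports are deterministic TSVs plus `summary.json`; a Newick tree
marks foreground branches codeml-style (`clade #1`).

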