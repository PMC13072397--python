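# Methods

`mitocomp` implements the quantitative core of a comparative mitogenomic
analysis of insect mitochondrial genomes: composition and strand-skew
profiling, codon-usage bias, population diversity, pairwise Ka/Ks,
branch-site tests of positive selection with Bayes empirical Bayes (BEB)
site identification, RELL-based topology tests, and control-region (CR)
tandem-repeat architecture.  This note records the models, the defaults
and their rationale, the numerical choices, and the limits of what the
synthetic-data tests demonstrate.

## Coordinates, genetic code, and I/O

Internal coordinates are 0-based half-open on the forward (J) strand;
GenBank's 1-based inclusive convention is converted losslessly on read and
restored on write, including features that wrap the origin of the circular
molecule (stored as `join` locations).  The default translation table is
the invertebrate mitochondrial code (NCBI table 5: ATA=Met, TGA=Trp,
AGA/AGG=Ser), the appropriate table for beetle mitogenomes; every
codon-aware function accepts another `GeneticCode` instead.  Gene names
are canonicalised through a shipped synonym table (e.g. COI→cox1,
ND5→nad5, 16S→rrnL); tRNA-Leu/Ser isoacceptors are resolved from
anticodon annotation when present, otherwise by genomic occurrence order
with a warning.  Ambiguity codes other than N are rejected at parse time;
N is accepted but excluded from all composition denominators.

## Composition and group comparisons

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) are computed on the major
strand as given; reverse-complementing a sequence negates both skews, a
property the tests exercise.  Codon-position profiles pool positions 1/2/3
across in-frame CDSs.  Group contrasts (habitat, family, subfamily) use
Welch's unequal-variance t-test rather than the pooled form: the source
workflows say only "independent samples t-test", and Welch is the safer
default under unequal group sizes and variances; the pooled form is
available via `test="student"`.  Raw p-values are starred at
0.05/0.01/0.001 with no multiple-testing correction by default (matching
how such panels are usually reported); `adjust="bh"` adds a
Benjamini–Hochberg column and stars the corrected values instead.  Correlations (ENC/CBI vs GC
and GC3, Ka/Ks vs GC) are Pearson r with the least-squares line and the
two-sided p for r.

## Codon-usage bias

RSCU is the observed codon count divided by its synonymous-family mean;
families with zero usage report NaN rather than 0.  ENC generalises
Wright's estimator to the family structure of the active code (the
invertebrate mitochondrial code has an 8-fold serine family and no
singleton families): per family with n ≥ 2 codons observed, homozygosity
F̂ = (nΣp̂²−1)/(n−1); families are grouped by size k and
ENC = n₁ + Σₖ aₖ/F̄ₖ with aₖ the number of size-k families in the code and
n₁ the count of non-degenerate families.  A size class with no usable
family (or only F̂ ≤ 0, which the estimator can produce at small n) is
imputed by linear interpolation between neighbouring classes — the
generalisation of the classical F̄₃ ≈ (F̄₂+F̄₄)/2 recommendation — and
flagged with a warning.  The estimate is capped at the number of sense
codons, which also makes the uniform-usage closed form exact at finite n.
The null ENC curve is 2 + s + 29/(s²+(1−s)²) with s = GC3, evaluated
literally at any s; note the curve is *not* symmetric about s = 0.5 (the
linear +s term breaks the symmetry of the curvature term), and its
maximum sits at s ≈ 0.5.  CBI = (N_opt − N_ran)/(N_tot − N_ran) over
degenerate families; the default optimal set is the most frequent synonym
per family over the analysed data (alphabetical tie-break), overridable
with a dataset-wide or literature set.  Stop codons are never counted;
terminal stops are excluded before counting.

## Diversity and Ka/Ks

Pi is the mean pairwise proportion of differing sites over all unordered
pairs.  Gap/N handling is pairwise-deletion by default (a column is
dropped only for pairs in which either member is unresolved);
complete-deletion is available because some established tools default to
it for some statistics, and segregating-site counts always use
complete-deletion so that "variable column" is unambiguous.  Sliding
windows (default 100 bp window, 25 bp step) are taken in alignment
coordinates and the trailing partial window is dropped; the window count
is floor((L−w)/s)+1.  Hd = n/(n−1)(1−Σp̂ᵢ²) with haplotypes grouped on the
columns resolved in every sequence, so sequences differing only at
excluded positions collapse.

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon fractional
synonymous/nonsynonymous site counts (stop-codon neighbours excluded from
the fractions, with each codon always carrying 3 sites) averaged between
the two sequences; differences averaged over all minimal mutational
pathways, excluding pathways through stop codons unless every ordering is
blocked; Jukes–Cantor correction d = −(3/4)ln(1−4p/3), with a saturation
error at p ≥ 3/4.  The estimate is exactly symmetric in its two
arguments.  Clade-level values are means over within-clade pairs, and the
per-pair table is always returned so any other aggregation can be
recomputed.  Maximum-likelihood pairwise dN/dS is deliberately out of
scope; the counting method is what the upstream comparative workflow
uses.

## Branch-site selection machinery

The engine is a GY94 codon model over the sense codons of the active
code: single-nucleotide changes have rate πⱼ·{1, κ, ω, ωκ} by
transversion/transition × synonymous/nonsynonymous, zero otherwise.
Equilibrium frequencies are F3x4 (position-specific nucleotide frequency
products renormalised over sense codons, zero frequencies floored at 1e-6
with a warning).  Likelihoods come from Felsenstein pruning with
per-site rescaling; gapped/ambiguous codons are missing data at the tip
(partial likelihood 1), not column deletions, so site indices stay
aligned with BEB output.  Two engine-level optimisations are behaviour
neutral: identical codon columns are collapsed to patterns, and site
classes whose ω assignments agree over a node's whole subtree share that
node's partial likelihood (the four Model A classes cost two pruning
passes below the foreground branch; the BEB grid collapses to its
distinct background ω values).  The pruning engine is verified against
exhaustive enumeration over internal-node states on small instances to
1e-8.

Model A has classes 0 (ω0 < 1 everywhere), 1 (neutral), and 2a/2b (ω2 on
the foreground branch only), with proportions p0, p1,
p2a = (1−p0−p1)p0/(p0+p1), p2b = (1−p0−p1)p1/(p0+p1).  Rate
normalisation holds the *background mixture* at one expected substitution
per codon: every class generator is divided by the proportion-weighted
equilibrium rate over the background ωs, so a foreground branch with
ω2 > 1 runs faster than its nominal length.  That rate elevation is part
of the selection signal; normalising each class separately would erase it
and cripple the test.  The simulator shares this convention (and the same
generator code path), so branch lengths mean the same thing on both
sides.

Fitting workflow: a one-ratio (M0) fit first estimates κ, ω, and a single
scale factor applied to the input tree's relative branch lengths; those
lengths are then fixed for the null (ω2 = 1) and alternative Model A
fits.  Estimating only a tree scale rather than every branch length is a
deliberate desk-scale simplification: input trees carry estimated
lengths, and the full per-branch optimisation would dominate runtime
without changing the LRT materially at these divergences.  Parameters are
optimised on transformed scales (log κ; ω0 sigmoid-bounded in (1e-4, 1);
proportions by additive log-ratio; ω2 = 1+(999−1)·sigmoid, the 999 cap
being the conventional reporting bound) with L-BFGS-B.  The
finite-difference step is set to 1e-5 — large enough that the likelihood
difference dominates float rounding of a sum over hundreds of sites; with
the library default step the gradient is noise and the optimiser stalls
at its start point.  The alternative fit is warm-started from the null
optimum at ω2 ∈ {1.5, 5} (configurable); because the null is the
alternative's ω2→1 boundary, warm starting enforces lnL_alt ≥ lnL_null up
to optimiser tolerance, and 2ΔL is clamped at 0.  The LRT refers 2ΔL to
χ²₁ (conservative for a boundary test; the 50:50 mixture of 0 and χ²₁ is
available via a flag).

BEB places a uniform prior on a grid of 10 midpoints per dimension over
(p0+p1, p0/(p0+p1), ω0 ∈ (0,1), ω2 ∈ (1,11)), weights each grid point by
its whole-alignment likelihood with κ, branch lengths, *and the mixture
rate normalisation* fixed at the alternative-model MLEs (holding the
normalisation at the MLE keeps the per-site class likelihoods
precomputable across the grid; the grid then varies only the prior
weights), and reports the per-site posterior of classes 2a+2b with the
conventional star notation (* PP>0.95, ** PP>0.99) and the first
sequence's amino acid as the site label.

RELL topology tests resample per-site log-likelihood sums (multinomial
weights, no re-optimisation): KH is the one-sided centred-bootstrap
comparison against the best tree, SH the simultaneous comparison against
the per-replicate best after row centring, and ELW the mean normalised
likelihood weight (weights sum to 1).  1000 resamples by default,
seed-controlled.  The AU test (multiscale bootstrap) is out of scope.

## Control-region architecture

The tandem-repeat detector is a compact reimplementation of the
tandem-repeat-finder idea, not a port: candidate periods are seeded by
exact 4-mer recurrence distances; for each period, runs of lag-p
agreement are extracted under +2/−7 match/mismatch scoring; the consensus
is the column majority; boundaries are then extended against the tiled
consensus (where one substitution costs one mismatch rather than the two
it costs in the lag profile, letting the span cross isolated mutations);
and the array is scored by wraparound dynamic programming against the
cyclic consensus under (match 2, mismatch 7, indel 7) weights.
Overlapping reports are resolved in favour of the smallest period that
explains most of the larger span comparably well (within 3 points of
percent identity), which removes lag-2p/3p harmonics without letting a
short internal micro-repeat absorb a long primitive array.  Perfect
arrays with ≥ 3 copies and periods up to the 2000 bp default are
recovered with exact period, span and integer copy number; the detector's
full probabilistic treatment of highly indel-divergent arrays is out of
proportion to its use here.  Conserved blocks across aligned CRs are
maximal runs of gap-free, 100%-identical columns of length ≥ 3 (the
threshold is exposed because the upstream criterion is stated only as
"> 2 bp").  The CR report combines repeats with poly-A/poly-T runs,
(TA)n microsatellites, windowed AT%, and the spacers between them.

## Synthetic data: what it emulates and what it does not

The generator produces 37-gene mitogenomes in the ancestral insect gene
order (no rearrangement), with the CR between rrnS and trnI carrying a
planted tandem array (default TATTA × 8 with 2% per-copy substitution)
plus poly-A/T runs, and a 17–42 bp spacer between trnS2 and nad1.
Composition targets default to 78% AT genome-wide with the third codon
position at +10 points and positions 1/2 compensating, so the whole
genome lands within about two points of target and the third position
carries the excess — the regime in which AT-ending codon preference and
below-curve ENC emerge from composition alone.  Codon alignments evolve
by the selection module's own GY94 generator under the Model A mixture
(defaults: p0=0.85, p1=0.05, 10% foreground-selected sites, ω0=0.05,
ω2=5, κ=4, 8 taxa × 500 codons, random coalescent-style topologies with
branch lengths uniform in 0.05–0.2 and an internal non-root-adjacent
foreground branch) — conditions chosen to give the branch-site test real
but not saturating power.  Population samples mutate a common reference
site-wise (default 2×10⁻⁴ per site), emulating near-clonal high-altitude
samples.  One integer seed drives a single root generator; identical
configuration and seed give byte-identical outputs.

Passing tests on these fixtures demonstrate internal correctness and
statistical calibration of the methods, not robustness to what real
mitogenomes add: alignment error and indels, among-site rate
heterogeneity beyond the mixture, strand-asymmetric mutation processes,
saturated third positions at deep divergences, and annotation noise.
Real-data behaviour should be validated on annotated GenBank records via
the same `read_genbank → pipeline` path.

## Numerical choices and degenerate inputs

Reversible-generator exponentials use the symmetrised eigendecomposition
(clipped at 0); per-site scaling guards underflow; mixture logs use
log-sum-exp with proportions floored at 1e-300.  Undefined statistics
raise typed errors rather than returning sentinels: empty composition
scopes, zero-variance correlations, <2 sequences, Ks = 0 ratios (NaN),
JC saturation, ENC with no informative family.  The LRT p-value at the
printed critical value 3.841 reproduces 0.05 to 1e-3.  Optimiser
tolerances (ftol 1e-9, projected-gradient 1e-3) keep 2ΔL stable to well
below the 3.84 decision threshold while holding a full null/alternative
fit pair to a couple of seconds at 8 taxa × 300 codons.

## Problem sizes used by the checks

The statistical checks run at desk scale: engine-vs-enumeration at 3 taxa
× 2 codons (20 replicates); null calibration at 200 replicates of 8 taxa
× 300 codons; power/recovery at 50 replicates of 8 taxa × 500 codons;
repeat recovery at 100 planted arrays (periods 2–50, 3–20 copies); the
acceptance script's study at 6 genomes with a 20-replicate null
calibration.  These sizes were chosen so the whole battery completes in a
coffee break on one core while leaving the binomial error bands tight
enough to be meaningful.

## Known limitations

- Branch lengths are refit only through a common scale factor under M0.
- BEB fixes κ and the rate normalisation at the MLE (standard practice
  fixes κ; the normalisation is this implementation's additional
  approximation, see above).
- The repeat detector handles substitution-divergent arrays well but does
  not model indel-heavy arrays; copy numbers there are approximate.
- `pairwise_identity` at the amino-acid level requires in-frame rows of
  equal translated length (it does not re-align).
- The pipeline's `select` stage expects equal-length extracted CDSs
  (true for the synthetic study; real data should be aligned upstream).
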