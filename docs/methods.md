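# Methods

## Scope and data model

The package operates downstream of read processing: its inputs are a gene
catalog (subgenome, chromosome, position, exonic length, optional TF
family), a homeolog-group map, a counts matrix over a
tissue/timepoint/replicate design, and a genotype panel (biallelic
SNP/InDel dosages) with a germination-rate phenotype. All tables travel
as TSV; genotypes additionally as a minimal GT-only VCF v4.2 written
directly and read back through cyvcf2.

## Synthetic-data generator

The generator is the package's validation instrument: it emulates the
structure of an allohexaploid salt-stress study so that every analysis
stage can be scored against planted truth.

**Design.** Three tissues (Seed, Leaf, Root) × timepoints 0/6/12/24/48 h
× 3 replicates (45 samples); 0 h is the control. The association panel
defaults to 225 accessions and 500 markers.

**Counts.** Negative binomial with a single shared dispersion
(`var = μ + φμ²`, default φ = 0.1, a mid-range bulk RNA-seq value). The
per-gene/sample mean on the log₂ scale is

```
log₂ μ = baseline + log₂(length_kb) + log₂(3 f_X) [triads]
         + s·Δ·1[salt timepoint, responsive tissue]
         + snr·z_m[sample] [module members] + group effect
```

with baseline 6 (≈64 counts per kb), DE magnitude Δ = 2 log₂ units and
random sign s, planted triad fractions (f_A, f_C, f_D), and a latent
standard-normal module profile z_m scaled by `module_snr` (default 2).
`φ = 0` is a degenerate noise-free mode (counts = rounded means) used by
exact-recovery tests. Three choices keep planted parameters identifiable
and are deliberate simplifications of real data:

- DE status, sign and responsive tissues are shared within a homeolog
  group, and the per-group baseline effect is shared too; otherwise
  independent per-copy effects would scramble the planted subgenome
  fractions. Real homeologs are only partially co-regulated.
- Each planted module has one responsive tissue and one shared sign, so
  modules form coherent signed co-expression blocks (and are genuinely
  tissue-enriched, which the enrichment stage must detect).
- DE applies only at timepoints > 0 h, making the 0-h contrast an exact
  null.

Consequently, passing recovery tests demonstrates that the estimators
are correct under the stated model, not that they are robust to
homeolog-specific regulation, batch effects, library-composition bias or
isoform-level variation, none of which are simulated.

**Dominance fractions.** Triad labels are drawn from `dominance_mix`
(default 0.3/0.4/0.2/0.1 for A/C/D-dominant/balanced, echoing the
C-subgenome excess reported for oat). Dominant triads put a fraction
drawn U(0.6, 0.85) on the dominant copy and split the rest evenly;
balanced triads are drawn uniformly in a disc of radius 0.08 around the
centroid, safely inside the 0.2 balanced radius so that low-noise
classification is unambiguous.

**Population.** Genotypes are Hardy–Weinberg draws at uniform MAF in
(0.05, 0.5]. The causal record is a 3-bp promoter deletion
(REF `TCACTC` = Hap1, ALT `TCC` = Hap2) at a fixed position on
chromosome 4D, MAF 0.30; twenty markers cluster within ±500 kb of it so
LD heatmaps have a region to show. Phenotype =
40 + 10·(Hap1 copies) + N(0, 8²) percentage points; the planted causal
gene — a WRKY-family D-subgenome copy of a dyad, always salt-upregulated
— sits 701 bp from the InDel. Missing genotypes are masked at rate 0.02
after the phenotype is drawn.

## Analysis choices

**DEG calling.** The fold-change filter uses a pseudocount ε = 0.01 FPKM
(small enough to preserve large fold changes for on/off genes); the
FPKM > 0.5 floor applies to the larger of the two group means, which
retains genes switching fully on or off. Threshold-only calling is the
default surface; an optional test mode adds a Welch t-test on
log₂(FPKM+1) with Benjamini–Hochberg adjustment per contrast at
α = 0.05. Its null false-positive rate is calibrated on a 0-h
split-replicate design simulated with 6 replicates (a 3/3 split; a 3-
replicate design cannot be split into two groups that both carry a
variance estimate).

**Ternary bias.** The balanced region is a Euclidean ball of radius 0.2
around (⅓, ⅓, ⅓) — a conventional central region; the radius is a
config knob. The bias context defaults to salt samples only
(timepoints > 0) per tissue; an all-samples mode is available. Triads
with summed mean FPKM < 0.5 are labelled unexpressed. Argmax ties break
in fixed A < C < D order and are logged.

**Network.** Signed adjacency ((1+r)/2)^β with Pearson correlation
throughout. The scale-free fit index discretizes connectivity into 10
equal-width bins and regresses log₁₀(frequency) on log₁₀(mean bin k),
sign-flipping R² negative when the slope is positive; the chosen β is
the smallest reaching R² ≥ 0.85, falling back to the argmax with a
warning. Module detection replaces the dynamic hybrid tree cut with a
static cut at the 0.99 quantile of merge heights followed by the
minimum-size (30) filter — simpler, configurable, and sufficient for the
block-structured inputs in scope (≤ ~5,000 genes, one block). Eigengenes
are first PCs of gene-standardized module expression, sign-oriented
toward the module mean profile; merging iteratively joins the closest
pair with eigengene dissimilarity 1 − cor below 0.25.

**Association.** The kinship mixed model is replaced by fixed-effect
genotype PCs (default k = 3) in an OLS scan with a Wald test — adequate
for the simulated panels, which carry no explicit family structure;
results on strongly structured real panels would be anti-conservative.
Missing dosages are mean-imputed per marker for the PCA and the scan; LD
r² uses pairwise-complete correlations. The haplotype comparison uses
homozygotes only (heterozygotes excluded; the insertion-carrying allele
defines Hap1) with a pooled-variance Student's t by default and a Welch
flag. Two genome-wide thresholds circulate for this design (1e-4 and
2.76e-7); the default config uses 1e-4 and either may be set.

**Candidate triage.** Genes within 50 kb (config) of any marker below
the threshold, annotated stepwise: expressed (FPKM above the 0.5 floor
in ≥ 1 sample) → DEG → homeolog category and module → divergent
salt-responsive TF (a TF-family DEG whose group is non-triad or
dominance-biased in some tissue).

## Numerical notes

- FPKM conservation (Σ_g fpkm·length_kb·libsize/10⁶ = column sum) holds
  to machine precision and is tested.
- TOM is computed via one matrix product with a zeroed diagonal, which
  drops the u = i, j terms exactly; agreement with a brute-force triple
  loop is ≤ 1e-12 on random instances.
- All randomness flows through `numpy.random.default_rng` seeded per
  generator stage from the config seed; repeated runs are byte-identical
  (fixed float formatting, sorted serialisation, no timestamps).
- Degenerate inputs raise informative errors: zero library sizes name
  the sample, zero-variance genes are dropped (network input) or named
  (adjacency), monomorphic markers yield NaN r² and are skipped by the
  scan.

## Problem sizes

Default validation runs use desk-scale data chosen to exercise every
code path with comfortable statistical margins: 1,500 genes / 45 samples
for the end-to-end pipeline, 2,000 triads for dominance recovery, five
planted modules of 40–60 genes for network recovery, and a
225 × 500 panel for the association experiments (ten seeds for the
causal-recovery rate). Genome-scale counts (≥ 10⁵ genes) are out of
scope for the bundled experiments, though the algorithms have no
hard-coded size limits beyond memory for the gene × gene matrices.

## Known limitations

- The negative binomial shares one dispersion across genes; no
  gene-wise dispersion estimation or shrinkage is provided (count-model
  inference beyond the threshold/t-test surface is out of scope).
- The static quantile tree cut is not the dynamic hybrid algorithm;
  numeric parity with the reference WGCNA implementation is explicitly
  a non-goal.
- The association scan is not a REML mixed model; population structure
  is handled only through PCs.
- Suppressed-type homeolog categories (single-copy-low) are not
  modelled; the vocabulary is dominant/balanced/unexpressed.
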