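# Methods

This note documents the statistical model behind `strainexpr`, the choices
made where the published description left the design open, what the
synthetic-data generator does and does not emulate, and the package's
numerical conventions and limitations.

## Setting and model

The data are candidate-gene expression signals measured across a panel of
fully inbred mouse strains (the motivating design: 8 strains — parental
healer/nonhealer lines plus recombinant-inbred (RI) derivatives — with 3–4
mice each), read by a multiplex branched-DNA hybridization assay directly
from tissue lysates. Each *well* is one hybridization of one lysate, read
for all probes at once; technical replicates are separate wells of the same
lysate; background wells contain no lysate.

Per-gene expression is modelled as

    Y_ij = μ + Sex_i + Strain_j + e_ij

with sex a fixed effect (droppable; off by default because the original
analysis found no sex differences) and strain a random effect. Because the
strains are fully inbred, each strain replicates one genotype and the
between-strain variance component is genetic in toto, so

    H² = σ²_st / (σ²_st + σ²_r)

is a broad-sense heritability.

## Estimators

**Variance components** are method-of-moments from the one-way ANOVA mean
squares, with the unbalanced coefficient n₀ = (M − Σnᵢ²/M)/(N−1):
Vw = MS_within, Vb = (MS_between − MS_within)/n₀. Method-of-moments rather
than REML is deliberate: the published tables print negative Vb and H²
values, which REML cannot produce. Negative point estimates are *retained*
— they say the estimate is compatible with zero — but the estimate is
truncated at zero inside the confidence computation.

**Interval** (intraclass-correlation form, t′ = max(H², 0)):

    SE(t′) = (1 − t′)(1 + (k−1)t′) √(2 / (k (k−1) (N−1)))
    upper  = t′ + z₀.₉₅ · SE,  z₀.₉₅ = 1.645 (one-tailed)

`k` defaults to M/N; k = 3.25 (26 mice over 8 strains) reproduces the
published CI column exactly, including SE(0) = 0.19766 and 1.645·SE = 0.325
for every negative-H² row. Note the bound is *not* monotone in H² all the
way to 1: above t ≈ 0.96 (at k = 3.25, N = 8) the shrinking SE overtakes the
growing centre. The property test therefore asserts monotonicity on
[0, 0.95] only.

The same estimator, with the *individual* as the grouping factor and wells
as replicates, gives assay **repeatability** t_rep = Vb/(Vb+Vw). Negative
values are reported, never clamped.

The ratio Vb/(Vb+Vw) is biased slightly downward at small N (Jensen): at 8
strains × 3–4 mice the measured bias is −0.02 to −0.05 over H² ∈
[0.2, 0.8], largest mid-range. Calibration tests measure the mean over
thousands of replicate genes because a 500-replicate mean has Monte-Carlo
error of the same order as the distance between this bias and the ±0.05
acceptance band.

**Tukey HSD** uses the studentized range on the pooled MS_within with the
Tukey–Kramer standard error √(MSw/2·(1/nᵢ+1/nⱼ)) for unbalanced pairs.

**Normalization.** Each target gene's signal is regressed (OLS, intercept)
on the reference-gene signals across all measurement rows jointly; the
residuals are the normalized expression, averaged per individual afterwards.
The default regression row is the well (before replicate averaging); a
per-individual option exists — the two differ only in weighting and the
original description does not distinguish them. Ratio normalization
(target / geometric mean of references) exists only as a diagnostic
(`ratio_compare`): ratios amplify measurement error and induce artifactual
correlation with the denominator, which is exactly what the residual scheme
avoids. Background subtraction and replicate averaging commute, so their
order is cosmetic; subtraction happens first here. Negative
background-subtracted signals are kept (the residual regression is
translation-tolerant; flooring would bias low expressors).

**Association** is Pearson correlation at strain level (phenotypes are
scored per strain), p from t = r√(n−2)/√(1−r²). One-tailed is the default
reporting convention: the published correlation p-values are not exactly
reproducible under either convention for any single n, so the tail is
recorded in every record and both are implemented. No multiple-testing
correction is applied on the default path, matching the source analysis; an
FDR column can be requested.

**Clustering** input is the strain × gene least-square-mean matrix with
per-gene unit-variance scaling. Ward minimum-variance agglomeration is
implemented directly (not via scipy) so that merge heights are the ΔSSE
objective increments,

    d(A,B) = |A||B|/(|A|+|B|) · ‖c_A − c_B‖²,

and ties break deterministically on the lexicographically smallest
strain-name pair, making results independent of input order. scipy's ward
linkage is used in the test suite as an independent cross-check
(scipy heights² / 2 = ΔSSE). Bootstrap support resamples *genes* (columns)
with replacement — the standard unit when the tree is over samples — after a
canonical column sort so support is invariant to column order; a node's
support is the fraction of bootstrap trees containing its leaf bipartition
(unordered). Fold-change tiers bin the per-gene z-scaled difference against
the reference strain at symmetric edges ±0.5, ±1.5, ±2.5 (seven tiers,
4 = no change); a value exactly on an edge takes the lower tier. The edges
are a stated default, not inferred from the source figures.

**SNP annotation** is 1-based inclusive throughout (VCF convention).
Region classes: 5′/3′ UTR, coding exon, intron, and 2500-bp flanks measured
from the UTR-side transcript boundaries, all strand-aware (the physical
right flank of a minus-strand gene is its upstream). UTR positions inside
exons are labelled UTR, not exonic, so per-gene totals partition cleanly.
Coding calls splice the CDS across exons, reverse-complement on the minus
strand, and translate the affected codon for both alleles with the standard
code; conservation ≥ 0.90 (inclusive) flags a site as highly conserved, and
conserved nonsynonymous SNPs form the candidate hand-off list. External
effect predictors (PolyPhen-2/SIFT/LRT) are pass-through annotation only.
A SNP may count toward several genes independently; there is no
nearest-gene arbitration.

**RI genotypes** come from the nearest informative markers at or left of the
gene start and at or right of the gene end: agreement → that genotype
(heterozygous LS/LS flanks yield LS); disagreement → unassigned (`?`);
a marker inside the gene decides directly; a single flank at a chromosome
end is used with a note. Distance is physical (bp); "closest flanking
markers" is read as the two nearest informative flanks. No
recombination-probability imputation: abstention is the contract.

## Synthetic data

The generator emulates the study's design, not its biology. Latent
(log-scale) expression for gene g, strain s, mouse i, well w is

    L = μ_g + A_s + B_i + ε_w,   Var A = h², Var B = 1 − h² − σ²_ε,
    Var ε = σ²_ε  (residual_sd², latent scale)

so Var A / (Var A + Var B + Var ε) = h² exactly. The raw well signal is
`background_mean + load_w · exp(L)` with a log-normal per-well loading
factor (SD `well_load_sd` = 0.2) multiplying every probe in the well —
including the reference genes, which is why the residual regression removes
it. References are modelled as abundant, tight housekeeping transcripts:
per-individual SD 0.05 and per-well noise at a quarter of the target level
(zero when targets are noise-free). Defaults: 8 strains, 3 or 4 mice each
with equal probability, 3 technical replicates, background 50 ± 2 signal
units, h² = 0.5. All effects are normal draws — matching the assumptions of
the ANOVA machinery under test is the point. Everything drawn is recorded
in a `SyntheticTruth` object that round-trips through TSV serialization;
recovery tests read only this truth.

Phenotypes are simulated at strain level: a phenotype coupled to a gene at
target correlation r is r·z + √(1−r²)·noise with z the z-scored strain
effects, then mapped to the phenotype's scale (ear healing 1 + 0.4·value mm,
clipped to [0, 2] with clipping logged; cartilage score 2 + 0.8·value).

Not emulated: probe cross-hybridization, bead-count QC, plate-position
effects beyond the scalar load factor, tissue composition, and any real
genome. A green test therefore establishes that the *estimators and
bookkeeping* behave as claimed under the stated model — not that the model
describes a particular assay.

The annotation generator builds a single synthetic chromosome of
three-exon genes on alternating strands (CDS length 702 nt), places SNPs in
every region class with labels known by construction, and installs two
constructed coding variants per gene: a third-position synonymous change at
codon 10 and a second-position Gly→Ala at codon 26 — the shape of conserved
coding variant the source study highlighted. The genetic-map generator
produces blocky LL/SS genotypes with ~5% residual heterozygosity and forces
one discordant first interval so the unassigned path is always exercised.

## Numerical conventions

- A fixed seed yields byte-identical serialized output; reading tables back
  uses round-trip float parsing.
- One sample correlation at n = 200 has sampling SD ≈ 0.03 even under
  perfect decorrelation, so the load-removal check is stated on the panel
  mean |r| (< 0.05) with a 0.1 per-gene cap.
- Sub-detection p-values printed as "<0.001" in the shipped fixture parse to
  5e-4; only the 0.05 threshold is ever applied to them.
- The fixture's CI column for the four consecutive rows Mmp1a/Mmp3/Mmp13/
  Mmp9 is cyclically shifted in print relative to the formula; both printed
  and formula-consistent values are stored and flagged, and the audit
  (`verify_fixture`) reports them rather than silently correcting.
- The miRNA fixture also stores the unrounded heritability percentages
  quoted in the source's results prose; the printed CI column reproduces
  from those, not from the 2-decimal table values.
- Zero-variance genes, all-singleton strain designs, and missing wells
  produce flagged records or logged missing values, never silent drops; a
  pipeline stage failure aborts with the stage name in the error.

## Limitations

- H² here is broad-sense and panel-relative: it measures variance among
  *these* strains, not additive heritability in a segregating population.
- With 8 strains the correlation and selection steps have little power and
  no multiplicity control by default; the dual-phenotype gene list is a
  screen, not an inference.
- The published per-gene strain counts are unpublished, so k = 3.25 is a
  reconstruction (it reproduces the printed CI column) rather than a known
  quantity; per-gene k can be supplied.
- Bootstrap support resamples genes under an exchangeability assumption that
  co-regulated gene sets violate; support values are descriptive.
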