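# Methods

## The screening model

The screen targets loci with the metastable-epiallele signature: wide methylation
differences between genetically identical individuals, consistency across cell types
within an individual, and stochastic (re-)establishment each generation. In pooled
bisulfite tracks this signature appears as "ragged" per-replicate mean methylation at
the distal CpGs of an ERV's LTR, because each pooled replicate averages a different
draw of individual methylation levels.

Per element end, the pipeline (i) takes the 8 CpGs of the LTR closest to the
element-external boundary (the promoter-proximal, best-mapped part of the LTR; the
repetitive interior is unreliable under short-read alignment), (ii) averages the 16
strand-level values per replicate, and (iii) scores interindividual variation as
100·(second-highest − second-lowest) across the 16 replicate means. Using the second
order statistics instead of max − min keeps the score robust to one aberrant replicate
at each extreme while still responding to genuine spread. Cell-type and sex DMRs
mimic high scores without being metastable (their variation is group-structured, not
individual-structured), so an element whose 8 highest and/or 8 lowest means are
group-pure under strict separation is excluded. The 5′ and 3′ ends are scored
separately — homologous LTRs of one element acquire their methylation states
independently — and element candidacy is the union over ends, with per-end results
retained.

## Synthetic study design

The generator reproduces the statistical structure the analysis assumes, not raw
reads (no FASTQ simulation, no bisulfite-conversion error, no mappability artifacts).

- **Replicates.** 16 pooled replicates: {B, T} cell type × {F, M} sex × {WGBS, oxBS}
  assay × 2 pools, with pool sizes alternating 4 and 5 individuals. By default every
  replicate pools its own individuals; a shared mode reuses the same individuals for
  the B and T pools of matching sex/assay, which makes the cross-cell-type consistency
  of individual levels explicit.
- **Latent classes.** Hypermethylated elements draw per-individual levels from
  N(0.90, 0.03) clipped to [0, 1] (the genomic default for these repeats);
  hypomethylated from N(0.05, 0.02). Variably methylated elements draw each
  individual's level from Uniform(0.05, 0.95) — validated variable loci span nearly
  the full methylation range with an approximately flat interindividual spread — with
  a Beta alternative behind a config switch. The draw is made **per LTR end**, since
  the two LTRs of one element vary independently, and is constant across an
  individual's cell types. Cell-type DMRs use group means 0.9 (B) / 0.1 (T); sex DMRs
  0.85 (F) / 0.15 (M).
- **Observation model.** Each CpG contributes two strand records per replicate. The
  observed fraction is Binomial(d, p_pool)/d with d ~ Poisson(coverage) per strand
  (default mean depth 30) and p_pool the mean latent level of the replicate's pooled
  individuals. oxBS reads 5mC only, so oxBS tracks carry p_pool·(1 − h) with
  h = 0.015, the hydroxymethylated share of the modified signal; WGBS and oxBS tracks
  are treated as biological replicates downstream. (Stated as a 5mC:5hmC ratio of
  1:0.015 the share would be 0.0148; the simpler multiplicative reading is used, and
  the difference is far below all tolerances here.)
- **Annotation.** Elements are laid out non-overlapping with 12–30 kb spacing on a
  2 × 20 Mb synthetic genome. Full-length elements emit LTR–internal–LTR fragment
  triplets with 5–60 bp intra-element gaps (below the assembler's default 250 bp merge
  gap); truncated forms drop one LTR (strand-aware: on the minus strand the 5′ LTR is
  genomically rightmost); solo LTRs emit a single LTR fragment; internal-only elements
  emit a split internal fragment pair. LTR sequences are generated with an exact
  planted CpG count hitting the family's target density (IAP highest at 4 %/bp,
  matching the rank order of CpG densities across ERV families); accidental CG
  dinucleotides in the background sequence are broken so track CpG positions equal the
  planted ones. Only LTR sequence is generated — nothing downstream needs interior
  sequence.
- **Default composition.** 50 variable, 500 hypermethylated and 20 cell-type-DMR IAP
  elements, mixing full-length, solo-LTR and truncated structures. These are the study
  conditions under which the recovery benchmarks are quoted.
- **Context and pedigrees.** ChIP-like peaks are planted 0–1.5 kb from the borders of
  variable elements over a uniform background (the flanking-enrichment observation the
  profile and peak-distance stages must reproduce); transcripts are planted in chosen
  (cell type, sex) replicate triplets initiating inside elements; DE gene lists contain
  the nearest genes of flagged elements. Pedigrees simulate the inheritance model
  exactly: offspring logit-methylation is a linear combination of parental
  logit-levels and sex plus pair, litter and residual Gaussian noise (defaults 0.3,
  0.2, 0.5 on the logit scale — moderate litter/pair clustering), with parental levels
  drawn from the variable range.

A design-time power analysis of the pooled design shaped two defaults: pooling 4–5
individuals attenuates the observable spread (the standard deviation of a pool mean is
the individual spread divided by √(12k) for uniform levels), so the generator uses the
wide Uniform(0.05, 0.95) individual range and draws ends independently; with those
conditions the 25 pp threshold recovers ≥ 90 % of planted variable elements at the
element level while hypermethylated elements essentially never reach 25 pp.

## Numerical and statistical choices

- **Distal-CpG extraction** orders CpGs outer→inner from the element-external LTR
  boundary (right edge of the 5′ LTR on the minus strand). Strand records at p and
  p+1 are collapsed to the C-strand coordinate p. Replicate means flag missing when
  fewer than 8 of the 16 values are covered; elements missing any replicate are
  excluded from scoring by default (overridable to score ≥ 4 available means).
- **Score threshold** is inclusive (≥ 25 pp). `calibrate_threshold` scans observed
  scores ascending and returns the smallest threshold whose validation precision
  (fraction of validated pairs with experimental range > 10 pp) reaches the target
  (default 0.75).
- **DMR rule ties.** Strict separation is required at the k-th boundary; a flat
  profile is never a DMR. This is conservative and avoids sort-order artifacts.
- **Profiles** use base-weighted means over piecewise-constant bedGraph signal with
  float bin edges (50 fixed-width flank bins per side over 5 kb, 20 body bins; the
  figure-axis bin sizes are not derivable, so these are package defaults). Bins
  without signal coverage contribute 0 and are tracked in a coverage mask. Two exact
  identities are enforced in tests: a constant field profiles flat, and reflecting the
  genome flips the profile left-right.
- **Nearest-gene ties** go to the lower start coordinate (logged); the biased DE
  screen uses a 10 kb "within or near" window by default (no distance is derivable
  from the source analysis).
- **Co-variation** tests pairwise Pearson r with exact-t two-tailed p values; the
  Bonferroni divisor is the number of loci (6 → α = 0.008), not the number of pairs —
  matching the published adjusted α — and is configurable. Pearson r is invariant to
  the per-locus range normalisation used for display, so the matrix is computed on raw
  levels. Note that with 15 pairs tested at 0.05/6 the family-wise error over pairs is
  ≈ 0.12; the null simulation accordingly checks the per-pair rate against the
  adjusted level.
- **Mixed model.** The two-variance-component REML criterion is optimised directly
  (profiled over the residual variance, L-BFGS-B on the variance ratios from three
  starts; dense Cholesky algebra — pedigrees here are a few hundred rows).
  Satterthwaite denominator df are computed as 2f²/(gᵀAg), with f the sampling
  variance of a fixed effect as a function of the variance components, g its central
  finite-difference gradient, and A the inverse observed REML information (central
  finite-difference Hessian). Variance components estimated at the zero boundary are
  held fixed in g and A (flagged as boundary fits), which reduces df to the residual
  n − p in the all-zero limit, matching both the OLS limit and the reference R
  implementation's singular-fit behaviour. The fit reproduces lmerTest estimates, SEs,
  dfs and p values to ≈ 1e-6 relative on a frozen synthetic pedigree, and statsmodels
  MixedLM variance components at a second dataset.
- **Logit clamping** uses eps = 0.005 (boundary methylation values occur in real
  pyrosequencing data; the source analysis is silent on the handling). BH q values
  delegate to statsmodels (`fdr_bh`) and are adjusted across all fixed-effect p values
  of all loci in one invocation by default (per-locus family by flag); the intercept
  is not part of the family. The maternal×paternal interaction is excluded by default.
  The litter-mean validation test is Welch by default (pooled variance by flag) — the
  source analysis does not state the variance assumption.

## Benchmark sizes

The recovery benchmarks (also what `scripts/acceptance.py` reports) use 20 simulated
studies of 570 elements for the screen, 1000 six-locus null panels for co-variation,
100 pedigrees of 30 pairs × 2 litters × 6 pups for maternal-effect recovery, and 200
null pedigrees of 20 pairs × 2 × 5 for type-I error — sizes chosen so the whole suite
runs in a few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins.

## Limitations

- The generator plants no mappability or alignment artifacts, no bisulfite-conversion
  error, and no nested/overlapping elements; passing recovery tests demonstrates the
  statistical machinery, not robustness to repeat-alignment pathologies, which
  dominate false positives on real data.
- Assembly merges purely by adjacency (same chromosome, strand, family, gap ≤ 250 bp);
  elements nested inside other elements are not modelled. An element consisting of
  LTR sequence only is reported in the 5′ slot — an isolated LTR carries no internal
  anchor to orient it.
- The inheritance model is Gaussian on the logit scale with independent random
  intercepts; no additive-genetic (animal) model, no variance-component tests.
- Thresholds calibrated on synthetic validation data reflect the synthetic score
  distribution (a gap between hypermethylated and variable scores), not the
  continuous spectrum seen in real validation experiments.
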