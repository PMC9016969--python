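# Methods

## The screen

`emqtlkit` implements an expression–methylation QTL (emQTL) screen around
transcription-factor binding sites (TFBSs). The premise: if a TF's binding
is mechanistically coupled to local DNA (de-)methylation, then across bulk
tumour samples its expression — used as a surrogate for binding activity —
should correlate with methylation beta values at CpGs near its own binding
sites, and do so *specifically* there rather than genome-wide.

Per cohort, for TF *t* and CpG *j* with beta vector **b**ⱼ and expression
vector **x**ₜ over the shared samples:

1. **Universe construction.** CpGs are restricted to probes within 200 bp
   (gap distance; 0 inside a site) of at least one TF's binding sites, then
   filtered to those with beta IQR > 0.1 across samples (type-7,
   linear-interpolation quantiles; strictly greater). CpGs missing in more
   than 20% of samples are dropped; remaining missing values are handled
   with pairwise-complete observations.
2. **Correlation.** Spearman ρ(t, j) by Pearson correlation of average
   ranks (tie-corrected by construction), two-sided p from the
   t-approximation on n−2 degrees of freedom. Zero-variance vectors yield an
   undefined ρ which can never be significant.
3. **Significance.** Bonferroni at α = 0.01 over the full per-cohort
   TF × CpG grid (the most conservative family; a per-TF family is available
   via `family="per_tf"`).
4. **Per-TF statistics.** For each TF: the *proximal fraction* — significant
   proximal CpGs / all proximal CpGs — and a one-sided Mann–Whitney U test
   that |ρ| of the TF's proximal CpGs exceeds |ρ| of the non-proximal
   complement of the considered universe (exact null enumeration when
   min(n₁, n₂) ≤ 8 without ties, otherwise the normal approximation with tie
   and continuity corrections).
5. **Gates.** A TF-cohort pair is a candidate when (i) its total
   significant CpG count is ≥ `min_sig` (default 5000), (ii) its proximal
   fraction is ≥ the `percentile`-th type-7 quantile (default 95) of the
   pooled fraction distribution over all TF-cohort pairs, with a ≥
   comparison so full ties pass, and (iii) its MWU p, Bonferroni-corrected
   across all tested pairs, is < 0.01.
6. **emTF call.** A TF is an emTF when it is a candidate in at least
   `min_cohorts` (default 2) cohorts. Its emCpGs in a cohort are the
   significant proximal CpGs there, partitioned by the sign of ρ; the
   reported sign proportions are relative to *all* proximal CpGs of the TF.

The MWU comparison group is the non-proximal complement rather than the
whole universe: a two-sample rank test of a set against a superset
containing it is ill-formed. The ranked variable is |ρ|.

## Downstream characterisation

**Binding signatures.** For each (emTF, cohort): ±200 bp windows around the
emCpGs form the foreground; windows around the non-correlated considered
CpGs (the universe minus the emCpGs) form the comparison set. For every TFBS
set, a region counts as supported when it shares ≥ 1 bp with a site; the
one-sided Fisher p is the hypergeometric tail on the 2×2 table over the
combined universe, BH-adjusted across TFBS sets, with Haldane-corrected odds
ratios at zero cells. The test is run in both directions. %GC uses the
bedtools-nuc convention (ambiguous bases count only in the denominator).
Genomic context is HOMER-like: promoter (strand-aware TSS −1000..+100) >
exon > intron > intergenic. TF-list overlaps (e.g. emTFs vs literature
pioneer-TF lists) use the hypergeometric tail with an *explicit* universe
size — there is no defensible default, so the argument is required.

**Target linking.** emCpGs inside a regulatory-element→gene map element link
to the element's target genes; the remainder link to the gene with the
nearest TSS (equidistant ties broken to the lexicographically smallest
gene id, logged). Links are retained when the Spearman correlation between
CpG methylation and gene expression is negative with Bonferroni-corrected
p < 0.01, the family being the links tested in that call (per emTF-cohort).
Spearman is the default for consistency with the screen; Pearson is a
config option. Over-representation of linked genes uses the hypergeometric
tail per gene set, BH across sets, reporting ≤ 10 sets below adjusted 0.05.

**Cellular context.** TFs are classified by the Pearson correlation of
expression with tumour purity: `cancer_cell` (r > 0, p < 0.05),
`microenvironment` (r < 0, p < 0.05), otherwise `ambiguous`; the p
threshold is a package choice, configurable. Accessibility coupling:
each emCpG's ±200 bp window is intersected with ATAC peaks and every
(CpG, overlapping peak) pair yields one Spearman ρ between beta and
normalised counts over matched samples (pairs are not averaged per CpG);
cohorts with < 20 matched samples are skipped.

## The synthetic-cohort generator

Real inputs at the scale this screen targets (hundreds of samples, ~377k
TFBS-proximal array probes, curated TFBS collections) are external
resources; the generator produces studies with the statistical structure
the method assumes, plus ground truth.

Layout: one synthetic chromosome partitioned into 2 kb slots, one binding
locus per slot, so different TFs' ±200 bp proximity neighbourhoods are
disjoint and recovery is well defined. Sites are 10–20 bp; planted emTFs
receive homotypic clusters (factor 3 at 30% of loci). CpG roles:

* **planted emCpGs** (750 per planted TF) within ±200 bp of their own TF's
  sites, with `beta = logistic(a_j − s·b·z + ε)`, where z is the TF's
  standardised log-expression, a_j ~ U(−1, 1) varies baselines,
  ε ~ N(0, 0.5), s = +1 for the demethylating direction. The logistic link
  keeps betas in (0, 1) without clipping artifacts. The default slope
  b = 0.3 targets a median |Spearman ρ| of ~0.5 at n = 150 via
  ρ_S = (6/π)·asin(r/2) with r = b/√(b² + σ²) — a closed-form calibration,
  verified empirically by the suite (observed median 0.499).
* **protected CpGs** (1000) near the sites of three designated protector
  TFs, i.i.d. Beta(2, 8) per sample: hypomethylated (mean 0.2) but with
  IQR ≈ 0.15, so they remain inside the considered universe and appear in
  the non-correlated foreground — this is what lets the signature stage
  recover the protector signal. A Beta(1, 20) profile (IQR ≈ 0.05) would be
  removed by the IQR filter; it remains available through
  `protected_cpg_beta_params` and is covered by a unit test.
* **null CpGs** (the remainder): half placed near random TFs' sites, half
  far from all sites; half of them variable (Beta(2, 2), kept by the IQR
  filter) and half near-constant (dropped), so the filter is exercised.

TF expression is log-normal; purity (U(0.2, 0.95)) is added to selected
TFs' log-expression with signed loadings (±0.8) to emulate tumour-content
confounding. Target genes (60 per planted TF, one per linked emCpG) have
log-expression `1 − 0.8·z(beta) + N(0, 1)`, giving link |ρ| ≈ 0.6 at
n = 150; 150 further genes are pure noise and act as decoys for the
anti-correlation filter. ATAC counts over 1000 emCpG peaks are
`exp(1 − z(beta) + N(0, 0.3))` over the first 60 samples.

What the generator does *not* emulate: array probe-type chemistry, batch
effects, copy-number contamination, genuine genomic CpG density, linkage
between neighbouring probes, or realistic TFBS co-occurrence structure.
Passing recovery tests therefore demonstrates the correctness and
calibration of the inference machinery under the assumed generative
structure, not performance on real tumour cohorts.

## Scaled thresholds for synthetic designs

Two of the gates encode the scale of the real screen and are rescaled for
synthetic universes (`PipelineConfig.for_synthetic` applies both):

* `min_sig`: the ≥ 5000-significant-CpGs rule presumes a ~377k-probe
  TFBS-proximal universe; synthetic runs use
  `round(5000 · n_cpgs / 376,997)` (≈ 398 at 30k CpGs), floored at 20.
* `percentile`: the pooled 95th-percentile fraction cutoff presumes that
  signal pairs are rare (< 5% of all TF-cohort pairs, as in a
  231 TF × 19 cohort screen). The standard synthetic design plants 10
  signal pairs out of 80 (12.5%), so a 95th-percentile cutoff would sit
  *inside* the planted-fraction mode and reject true pairs by construction,
  regardless of effect size. The scaled rule reserves 1.5× the planted pair
  share (at least 5%) above the cutoff: percentile 81.25 under the standard
  design, 95 under a null design.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open throughout; 1-based manifests are
  converted on read (flagged); chromosome dialects normalised to `chr`.
* Quantiles are type-7 everywhere (IQR filter, percentile gate).
* Undefined statistics (constant vectors, < 3 complete pairs, empty MWU
  groups) propagate as NaN and fail the corresponding gate; they never
  raise mid-screen.
* ρ = 0 cannot be Bonferroni-significant, so the sign partition guards that
  branch with an assertion rather than a silent third class.
* TSV outputs use a fixed `%.6g` float format, logs carry no timestamps,
  and every output embeds the config hash, making same-seed runs
  byte-identical (checked by the suite and the reproduction script).

## Problem sizes used by the test suite

The suite runs the standard recovery design (2 cohorts × 150 samples,
40 TFs, 30,000 CpGs, 5 planted demethylating emTFs) for seeds 1–10, twenty
null-design runs, a 500-test MWU gate calibration, and reduced-scale
configurations (8 TFs, 1500 CpGs, 60 samples) for unit and CLI tests.
These sizes keep a full run deterministic and fast while leaving every gate
(min_sig, percentile, MWU, recurrence) with real work to do.

## Known limitations

* The screen treats expression as a surrogate for binding activity; the
  generator builds that assumption in, so it cannot probe its validity.
* The Bonferroni grid family is conservative; with correlated CpGs the
  effective test count is smaller, and sensitivity on real data will
  depend on that correlation structure.
* Nearest-TSS fallback linking is distance-only; on real genomes many such
  links are wrong, which is precisely why the anti-correlation filter
  exists, but the generator's decoys are easier than real confounded genes
  (they are independent noise).
* The ATAC stage consumes externally normalised counts and does not model
  peak-level library effects.
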