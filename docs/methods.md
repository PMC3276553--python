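# Methods

`epinstab` analyses DNA methylation dynamics at stem-cell loci on
Infinium-27k-style β-value arrays and scores per-tumour epigenetic
instability. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data generator does and
does not emulate.

## Data model

A **β value** estimates the methylated fraction of DNA molecules at a
CpG from the two allele intensities of an Infinium probe:

    β = max(M, 0) / (max(M, 0) + max(U, 0) + 100)

The +100 offset regularises low-intensity probes; β lies in [0, 1).
Matrices are probes × samples with per-sample annotations (stage group,
age, chip, bisulfite-control intensity, survival time/event).

Two locus classes organise the analysis:

* **MESC** — CpGs heavily methylated in human embryonic stem cells.
  Derived from strand-resolved whole-genome bisulfite read counts: a
  site qualifies when the C+T reads summed over both strands reach the
  coverage minimum (default 5; a strict per-strand mode is available
  behind `per_strand_coverage=True`) and the overall mean methylation
  level — the average of the two strand-level C/(C+T) fractions, or the
  covered strand's level when only one strand has reads — is strictly
  greater than 0.8.
* **PCGT** — Polycomb group target loci (PRC2 occupancy / H3K27me3 in
  hESC), consumed as an annotation table keyed by probe id.

PMD (partially methylated domain) membership is consumed as BED
intervals with half-open [start, end) semantics against 1-based probe
coordinates.

## Quality control

Samples with bisulfite-control intensity strictly below 4000 are
excluded; exactly 4000 is retained (verbatim reading of the "<4000"
rule). Total-intensity outliers (per-sample median U+M outside
median ± 3·IQR) are flagged but only dropped on request, because no
numeric rule for them is canonical; β-histogram shape is summarised by
a bimodality coefficient for diagnostics and never auto-excludes.
Probes are kept when detected (detection p < 0.05) in ≥ 95% of samples
— conventional Infinium practice, configurable. QC never alters
retained values; missing β propagates as missing.

## Differential methylation

Per CpG, ordinary least squares of β on a binary disease status plus
covariates (age, bisulfite-control intensity, and chip as a dummy-coded
categorical — the covariate alternative to empirical-Bayes batch
correction). The status coefficient is the adjusted β difference
(cases − controls); its t statistic and two-sided p form the result.
Probes with complete data share one design factorisation (vectorised
closed form, verified against statsmodels); probes with missing values
are refit on their complete samples. A globally rank-deficient design
(e.g. status identical to chip) raises immediately; a per-probe
deficient design yields an NA row with a logged reason. Raw p-value
thresholds define hyper/hypo call lists (no multiplicity correction, by
design — thresholds are per-analysis choices such as 0.1 for the
pre-dysplasia comparison and 0.001 for invasive cancer); the
hyper-vs-hypo imbalance is tested with the exact two-sided binomial
test against 0.5.

## Enrichment

Two-tailed Fisher exact tests of locus-class membership among selected
CpGs against a reference universe (default: all QC-passing probes).
The odds ratio is the sample cross-product ratio; the 95% CI is the
Woolf log-OR normal approximation, with the Haldane–Anscombe 0.5
correction applied (and flagged) on zero cells. Tables with an empty
margin are flagged degenerate and carry no p-value. Two baseline-aware
variants control for normal-tissue methylation level:

* *baseline-matched*: the universe is restricted to probes starting
  unmethylated (normal mean β < 0.2, hypermethylation direction) or
  methylated (> 0.4, hypomethylation direction); selection is a strict
  move of the case mean in the stated direction, optionally intersected
  with a significance list.
* *control-matched*: the comparison set is non-target probes whose
  normal mean β lies in the same band as the target probes, so
  enrichment cannot be a baseline artifact.

A caution discovered during validation: with unequal group sizes the
raw sign-of-mean-change selection is not symmetric under case/control
label permutation (small-sample means of skewed mixtures sit above
large-sample means more often than not), so permutation nulls must be
run through the variance-normalised significance-gated route. The test
suite encodes this.

## Epigenetic instability indices

β is discretized into three states: unmethylated (0) for β < 0.25,
hemimethylated (1) for 0.25 ≤ β ≤ 0.7 (boundaries inclusive), and
methylated (2) for β > 0.7. A CpG is **stable** when its state is
identical in all normal reference samples; stability is assessed on a
probe's non-missing normals and requires at least two observations (an
agreement claim on one observation is vacuous). For each tumour, four
indices give the fraction of stable CpGs undergoing each transition:
0→1/2, 1→2, 1→0, and 2→0/1 — the last is the **demethylation
instability index (DeMI)**. A transition is called only when the
tumour state differs from the stable state *and* |tumour β − normal
mean β| ≥ 0.10; the buffer stops trivially small shifts across a
threshold from counting. The buffer's reference point is the mean β
over the normal samples (the quantity stability is defined on).

Denominators are per-sample: stable probes of the relevant baseline
state with a non-missing tumour β. Zero-denominator indices are
reported as missing, never 0, so they cannot bias downstream survival
models. Restricting the stable set to locus classes yields the three
stem-cell indices PCGT (0→1/2), MESC (1→0) and MESC (2→0/1); the
**combined DeMI** pools the two demethylation transitions at MESC loci
— qualifying 1→0 plus 2→0/1 transitions over the pooled count of
stable MESC probes in states {1, 2} (a micro-average, keeping the
statistic a fraction of CpGs rather than a mean of two fractions).
Per-probe hypomethylation frequency is the fraction of tumours in
which a stable fully-methylated MESC probe undergoes a qualifying
demethylation transition, ranked descending with ties broken by probe
id.

## Outcome analysis

* **Tertiles**: empirical thirds of the index with stable-order tie
  breaking; the middle tertile is retained in labels but excluded from
  the two-group Kaplan–Meier comparison (log-rank test, lifelines).
* **Cox**: proportional-hazards fit (lifelines); the HR is reported per
  SD of the index by default so indices are comparable; a helper
  screens candidate covariates at a univariate p < 0.05 (logged) for
  the multivariate model. Tertile-contrast fits are available by
  passing the tertile indicator as the index.
* **Metastasis shift**: one-tailed Wilcoxon rank-sum (exact null
  distribution up to 25 per group, normal approximation with
  continuity correction above; all-tied inputs return p = 1, flagged).
* **ROC/AUC**: rank-based (Mann–Whitney) AUC with a DeLong-variance
  95% CI by default (stratified bootstrap optional), clipped to [0, 1].
* **TET anti-correlation**: per-probe Spearman correlation (Pearson
  behind a flag) of β with TET expression across tumours; "significantly
  anti-correlated" means ρ < 0 and p < 0.05 (configurable); MESC
  enrichment among the significant set against the remaining
  hypomethylated probes, plus a rank-ordered table for heatmaps.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not raw array chemistry:

* Manifest of `n_probes` (default 2000) with disjoint PCGT (15%) and
  MESC (25%) classes and an independent 20% PMD overlay. Baseline
  normal-tissue means: PCGT uniform 0.04–0.12, MESC 0.80–0.92, others
  a low/mid/high mixture.
* Normal β values are Beta-distributed around each probe's baseline
  with concentration 100 (sd ≈ 0.035 at β = 0.85) — tight enough that
  most probes are stable across normals, loose enough that the
  stability filter does real work.
* Stage design mirrors a cervical-carcinogenesis layout: 77 + 75
  pre-dysplasia, 30 + 18 dysplasia, 15 + 48 invasive cancer, 15 + 17
  metastasis (normals + cases). Each case draws a personal alteration
  probability from a Beta centred on the stage rate (concentration 50),
  then flips each susceptible probe independently; MESC flips land at
  β ≈ 0.03–0.14 (a full demethylation, always crossing the 0.25
  threshold by more than the buffer), PCGT flips at 0.45–0.85. Stage
  MESC-loss rates default to 0.05/0.10/0.20/0.35 (monotone, enforced);
  PCGT gain 0.08 then ≈ 0.12, reflecting early hypermethylation that
  plateaus.
* Per-probe susceptibility weights (2×Beta(0.6, 0.6), renormalised to
  mean exactly 1 within each locus class) concentrate alterations in
  "hot" loci, reproducing the frequently-hypomethylated-ranking
  structure of real tumours while leaving the average per-sample
  alteration rate exactly at the nominal stage probability — this
  renormalisation is what makes the planted-rate recovery property
  exact rather than approximate.
* Chip batch effects: samples fill chips of 12; each chip applies a
  N(0, 0.05) shift on the logit-β scale (a confounded assignment mode
  exists for adjustment tests). Effects on the logit scale keep values
  inside (0, 1) and preserve Beta-like marginals.
* Survival: exponential with log-hazard linear in the standardized
  DeMI (default HR per SD 1.8), independent exponential censoring at
  half the baseline hazard (≈ 1/3 censored).
* TET expression: slope × per-sample demethylation burden + N(0, 1)
  noise. The anti-correlation is identifiable only when tumours differ
  in burden; analyses of it use a dispersed-burden configuration
  (per-sample concentration 5), since with near-identical burdens the
  per-probe correlations are zero by construction.
* A truth table (sample, probe, transition) is a first-class output, so
  recovery tests compare against recorded ground truth rather than
  re-inferring it. All outputs are deterministic functions of the
  config seed.

What the generator does **not** emulate: raw intensities/idat, probe
cross-reactivity, stromal or immune admixture, HPV genotype, spatial
or chromosomal autocorrelation of methylation, and detection-p
structure beyond an optional matrix. Passing tests therefore
demonstrate correctness of the statistics under the stated generative
assumptions, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Exact tests use scipy (`fisher_exact`, `binomtest`, exact
`mannwhitneyu`); the suite pins them against independent brute-force
oracles (hypergeometric enumeration, Fraction tail sums, full
permutation enumeration). State-boundary conventions: 0.25 and 0.70
belong to the hemimethylated state; the MESC level rule is strictly
greater than 0.8; the BS QC rule is strictly less than 4000. p-values
from the vectorised OLS are floored at the smallest positive float so
they remain in (0, 1]. Degenerate inputs raise structured errors
(no events, constant index, empty stable set, both-strand zero
coverage) or return flagged results (degenerate enrichment tables,
all-tied rank-sum) rather than silent zeros.

## Problem sizes

Default analyses and the reproduction script run at 2000 probes,
cohorts of tens to ~100 tumours, and 100 survival replicates — sizes
chosen so the full test suite and the end-to-end script complete in
well under a minute each while keeping Monte-Carlo error far below the
asserted tolerances (e.g. planted-rate recovery to ±0.02).

## Known limitations

The empirical-Bayes batch adjuster is not implemented; chip enters as
a covariate (the sanctioned alternative). Region-level (DMR) calling,
GSEA, stromal-composition deconvolution, and 450k/EPIC-specific
manifest handling are out of scope. The DeLong CI can exceed a
clipped boundary only at AUC near 0 or 1, where the normal
approximation is poor; the bootstrap option is preferable there.
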