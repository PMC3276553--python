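# epinstab

Epigenetic instability analysis of DNA methylation arrays: stem-cell
locus sets, differential methylation, enrichment, and the prognostic
demethylation instability index (DeMI).

## The problem

During carcinogenesis, DNA methylation changes concentrate at two sets
of stem-cell loci with opposite dynamics: promoters of Polycomb group
target genes (**PCGTs**, unmethylated in normal tissue) gain
methylation very early, while CpGs heavily methylated in embryonic
stem cells (**MESCs**, methylated in normal tissue) progressively lose
methylation as tumours invade and metastasise. `epinstab` implements
the full analysis pipeline for quantifying these dynamics on
Infinium-27k-style β-value matrices and for scoring per-tumour
epigenetic instability, aimed at computational epigenomics
researchers.

The core statistic discretizes β into three methylation states
(unmethylated β < 0.25, hemimethylated 0.25 ≤ β ≤ 0.7, methylated
β > 0.7), selects CpGs whose state is *stable* across all normal
reference samples, and scores each tumour by the fraction of stable
CpGs undergoing each state transition (0→1/2, 1→2, 1→0, 2→0/1),
requiring additionally a ≥ 10% β change so that trivial shifts across
a threshold do not count. The 2→0/1 fraction is the **DeMI**; at MESC
loci it is prognostic, and the pooled MESC (1→0) + (2→0/1) fraction is
the **combined DeMI** used to discriminate metastases from primaries.

The package covers the surrounding pipeline end to end: β computation
from allele intensities (β = max(M,0)/(max(M,0)+max(U,0)+100)) and QC,
MESC derivation from strand-resolved bisulfite read counts, per-CpG
covariate-adjusted differential methylation with binomial skew tests,
two-tailed Fisher enrichment with baseline matching, tertile
Kaplan–Meier / Cox survival analysis, ROC analysis, and TET-expression
anti-correlation — plus a synthetic data generator that emulates the
whole study design with planted ground truth.

## Worked example

```bash
epinstab demo --seed 7 --out-dir demo_run
```

simulates a four-stage study (2000 probes) and chains MESC derivation,
QC, differential methylation, enrichment, instability scoring,
survival and TET analysis. It prints:

```json
{
  "seed": 7,
  "n_probes": 2000,
  "wgbs_mesc_sites": 209,
  "n_hyper_p001": 0,
  "n_hypo_p001": 15,
  "skew_p_hyper_vs_hypo": 6.103515625e-05,
  "pcgt_hyper_or": 13.130022321428571,
  "mesc_hypo_or": 13.174402250351617,
  "cox_hr_per_sd": 1.800447253771583,
  "cox_p": 0.0017136250325181666,
  "met_shift_p": 5.562585809887822e-08,
  "met_auc": 0.9362745098039216,
  "tet_mesc_or": 2.4077922077922076
}
```

Reading the numbers: 209 simulated bisulfite-sequencing sites pass the
MESC rule (≥ 5 reads, mean level > 80%); in the invasive-cancer arm the
p < 0.001 call list is skewed toward hypomethylation (15 hypo vs 0
hyper, binomial p ≈ 6×10⁻⁵); PCGTs are ~13-fold enriched among CpGs
gaining methylation from an unmethylated baseline and MESCs ~13-fold
among CpGs losing it from a methylated baseline; the Cox hazard ratio
per SD of the MESC DeMI is 1.80 (the generator's planted value is
1.8); the combined DeMI separates metastases from primaries with
AUC 0.94; and MESCs are enriched (OR 2.4) among CpGs anti-correlated
with TET expression. Running the same command twice produces
byte-identical output.

The same stages are available as library functions
(`epinstab.find_stable`, `epinstab.epi_indices`, `epinstab.cox_fit`,
…) and as file-based subcommands (`simulate`, `derive-loci`, `qc`,
`diff`, `enrich`, `instability`, `survival`, `tet`).

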