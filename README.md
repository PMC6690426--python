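# exactlogrank

Conditional multi-group log-rank testing with **exact permutation
p-values**, for survival analyses where the familiar chi-square p-value
cannot be trusted.

The log-rank test is the standard way to compare survival between patient
groups — treatment arms, biomarker strata, or the clusters produced by a
subtype-discovery algorithm. Its p-value is almost always computed from
the chi-square approximation (the **AP**). That approximation is accurate
for large balanced groups with many events, but in the regimes where
modern cancer analyses operate — several small clusters, heavy censoring,
unequal follow-up between groups — it can overstate significance several
fold. This package provides, for K >= 2 groups:

* the conditional (hypergeometric-variance) log-rank statistic

  T = z' V⁻¹ z, with z_j = O_j − E_j, E_j = Σ_i d_i n_ij / n_i and
  V_jl = Σ_i [d_i (n_i − d_i)/(n_i − 1)] (n_ij/n_i)(δ_jl − n_il/n_i),

  with its chi-square AP (df = K − 1);
* the **exact permutation p-value (EP)**, EP = (b+1)/(B+1), with
  Clopper–Pearson confidence intervals, a full-enumeration oracle for
  small samples, and a follow-up-conditioned resampling scheme (after
  Heinze et al.) that remains valid when censoring differs between
  groups;
* Kaplan–Meier / reverse-KM estimation and risk tables;
* a synthetic survival generator and calibration harnesses that measure
  the real false-positive rate of any of these p-values under a chosen
  null scenario;
* diagnostics for clustering evaluation: AP-vs-EP comparison with
  discordance flags, the AP distribution under label permutation, and
  the false-positive-rate curve for random small-cluster solutions.

## Worked example

A small two-arm study, 6 + 6 patients, all events
(`examples/exact_vs_asymptotic.py`):

```python
from exactlogrank import (validate_dataset, logrank_statistic,
                          permutation_pvalue, enumerate_pvalue)

data = validate_dataset(time, event, arm)       # per-patient records
ap   = logrank_statistic(data)                  # T and chi-square AP
mc   = permutation_pvalue(data, 99_999, seed=1) # Monte Carlo EP + CI
ex   = enumerate_pvalue(data)                   # all C(12,6)=924 assignments
```

prints

```
T = 4.1135, AP (chi-square) = 0.0425
EP (Monte Carlo, B=99999) = 0.0645 [95% CI 0.0630, 0.0660]
EP (full enumeration)              = 0.0628

AP/EP fold gap = 1.48; AP inside the EP CI: False
```

The chi-square approximation calls this difference significant at the 5%
level (AP = 0.043); the exact permutation distribution says it is not
(EP = 0.063). The enumeration value is exact for this dataset, the Monte
Carlo EP converges to it, and the interval shows the remaining sampling
noise.

The other example scripts demonstrate the calibration machinery:
`small_cluster_fpr.py` shows the false-positive rate of "AP <= 0.05"
climbing above 10% for random k-cluster solutions on a 600-patient null
cohort as k grows, while the conditional EP stays at the nominal level;
`unequal_followup.py` shows AP over-rejecting (~8–9%) on a null two-group
design with a tiny early-truncated arm while the conditional EP holds 5%.

## Command line

```bash
exactlogrank logrank  --input cohort.tsv                      # T, df, AP
exactlogrank permtest --input cohort.tsv --B 100000 --seed 17 # EP + CI
exactlogrank permtest --input cohort.tsv --scheme conditional --imputations 10
exactlogrank km       --input cohort.tsv                      # KM curves
exactlogrank simulate --group-sizes 200,200 --censoring exponential:0.5
exactlogrank ap-null  --input cohort.tsv --n-perm 100000
exactlogrank fpr-curve --input cohort.tsv --k-min 2 --k-max 20
exactlogrank compare  --input cohort.tsv --id-col pid --solutions s1.tsv
```

Input is delimited text (TSV/CSV auto-detected) with `time`, `event`
(0/1) and `group` columns, overridable via flags. Every stochastic
command is bit-reproducible given `--seed`, and the seed is recorded in
every result file.

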