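# Methods

## The test

Comparing survival between K groups of right-censored patients is done with
the log-rank test. For each distinct time t_i carrying d_i events, with n_i
patients at risk (observed time >= t_i) of whom n_ij belong to group j and
d_ij experience the event, the conditional (hypergeometric) version of the
test treats the group split of the d_i events as hypergeometric given the
at-risk configuration. The statistic aggregates

    z_j   = O_j - E_j,
    O_j   = sum_i d_ij,
    E_j   = sum_i d_i * n_ij / n_i,
    V_jl  = sum_i [d_i (n_i - d_i) / (n_i - 1)] * (n_ij / n_i) * (delta_jl - n_il / n_i),

with a summand of zero whenever n_i = 1, and

    T = z' V^{-1} z

restricted to the first K-1 groups. Under the null hypothesis of equal
survival functions T is asymptotically chi-square with K-1 degrees of
freedom; the upper-tail probability is the **asymptotic p-value (AP)**.

Tie convention: events precede censorings, so a patient censored exactly at
an event time is in the at-risk set at that time. Time zero is a legal
observation time. These conventions match the mainstream implementations
(lifelines, R `survival`), which the test suite uses as an independent
cross-check (agreement to 1e-8 on T; observed agreement is ~1e-14).

**Degenerate covariance.** V is singular when some group's at-risk period
never overlaps an event (common in permutation loops over pathological
labelings). We then use the eigendecomposition pseudo-inverse with
eigenvalue cutoff 1e-10 relative to max|V|, report df = rank(V), and log a
warning. In the fully degenerate rank-0 case (e.g. every patient an event
at one tied time) T = 0 and we report df = max(rank, 1) so the chi-square
tail is defined; the p-value is 1 regardless. Mainstream tools keep
df = K-1 even on singular V, so p-values (never T) may differ from
lifelines in these corner cases; this behaviour is deliberate and
documented rather than hidden.

## The exact permutation p-value (EP)

The permutation distribution of T over group-label assignments is the
exact reference. The Monte Carlo estimator is the add-one form

    EP = (b + 1) / (B + 1),   b = #{ T_perm >= T_obs },

which is a valid p-value (never zero; ties between T_perm and T_obs count
as extreme, compared with a 1e-9 relative slop so that reproductions of
the observed assignment always tie). Monte Carlo uncertainty is
quantified by the Clopper–Pearson interval on the exceedance probability:
low = BetaQuantile(alpha/2; b, B-b+1), high = BetaQuantile(1-alpha/2; b+1,
B-b), with the natural 0 / 1 endpoints at b = 0 / b = B.

On small samples `enumerate_pvalue` enumerates every distinct arrangement
of the label multiset (multinomial(n; n_1..n_K) of them, capped at 1e6 by
default) and returns the exact exceedance proportion. It is the oracle
the sampled EP is validated against: on 50 random datasets with n <= 8
and B = 20,000, the sampled EP falls within 4 Monte Carlo standard errors
of the enumeration value (plus the 1/(B+1) estimator offset) in >= 95% of
cases.

### Label scheme

Plain permutation of the group labels over patient slots. Exact when
censoring is independent of group membership.

### Conditional (follow-up-preserving) scheme

When follow-up differs between groups (e.g. administrative cutoffs at
different dates), label permutation destroys the follow-up structure and
the test can be invalid. The conditional scheme, following Heinze, Gnant &
Schemper's construction for two groups extended to K:

1. estimate the pooled event-time distribution S by Kaplan–Meier and the
   pooled follow-up (censoring) distribution G by reverse KM (event flags
   complemented);
2. for each censored patient impute a latent event time from S conditional
   on strictly exceeding the observed time; for each event patient impute
   a latent follow-up time from G conditional on >= the observed time;
3. keep each patient slot's group label and latent follow-up fixed;
   permute the latent event times across slots;
4. re-censor: observed time = min(event, follow-up), event flag =
   (event <= follow-up).

Each group's follow-up multiset is therefore held fixed within an
imputation — that is the conditioning. The procedure uses M independent
imputations (default 10); the EP is the average of the per-imputation
estimates, i.e. the reported b is mean_m b_m (possibly fractional) and
EP = (b+1)/(B+1) still holds. The Clopper–Pearson CI uses the fractional
b at n = B — conservative, since it does not credit the variance reduction
from averaging imputations.

Numerical conventions for the imputation distributions:

* KM tail: mass remaining after the last support point (largest
  observation censored for S, largest an event for G) is placed at the
  largest observed time — the simplest proper distribution; the sampler is
  isolated so an exponential-tail option could be added.
* A conditional draw whose threshold is at or beyond the entire support
  has no mass to draw from and returns +inf: that slot can never produce
  an event (for S) or is followed indefinitely (for G). If a permuted
  +inf event time lands on a +inf follow-up slot (rare), the record is
  stored as censored at the dataset's largest observed time.
* A resample with zero events gets T = 0: it counts as a non-exceedance
  unless T_obs = 0.
* With no censored patients there is nothing to impute and the scheme
  reduces exactly to label permutation; the implementation takes that
  fast path explicitly.

## Synthetic data

The generator draws latent event times Exponential(hazard_j) per group and
latent censoring from a per-group model: none, exponential(rate),
uniform(0, tau), or administrative(tau). Exponential event times keep the
checks closed-form: mean 1/lambda, and censored fraction
lambda_c/(lambda_e + lambda_c) under exponential censoring — both asserted
within 3 standard errors in the tests. Equal hazards define the null.
Weibull shapes, covariates, dependent censoring and non-proportional
alternatives are deliberately out of scope: the generator exists to probe
calibration of the testing machinery, not to mimic any particular cohort,
so conclusions from passing tests are about test validity, not about fit
to real cancer registries (real data add correlation structure, cure
fractions and inspection-time ties that this generator does not emulate).

Scenarios with very heavy censoring can produce zero-event samples; the
calibration harness redraws (up to 100 attempts) so that every replicate
carries a defined statistic, i.e. results are conditional on testable
samples — the same conditioning any analyst applies implicitly.

## Calibration experiments and the sizes used

All rejection fractions are reported with their binomial Monte Carlo
standard error and tolerances are expressed in SE multiples, so the
checks are scale-invariant in the replicate count. Sizes chosen for the
shipped experiments:

* **Valid regime**: two balanced groups of 200 with exponential censoring
  at rate 0.5 (~2/3 events), 2000 null replicates: AP rejection at
  alpha = 0.05 lands within 3 SE of 0.05 (observed ~0.046–0.050).
* **Small-cluster inflation**: one 600-patient null cohort (~80% events);
  for each k in 2..20, random partitions into k-1 clusters of 10 plus a
  remainder cluster, 300 replicates per k. The fraction of solutions with
  AP <= 0.05 rises from ~0.05–0.07 at k <= 4 to ~0.10–0.13 at k >= 14.
  On the same cohort the conditional-scheme EP (150 replicates at k = 20,
  B = 99, M = 3) stays at the nominal level (~0.02–0.06).
* **Unequal follow-up**: null two-group design, groups (3, 300), unit
  hazards, administrative cutoffs 2.0 vs 4.0, 1000 replicates: AP type-I
  error ~0.08–0.09, conditional EP ~0.045–0.055. The tiny arm is the
  operative ingredient: in our experiments two *moderately sized* groups
  under unequal administrative follow-up make the chi-square AP
  *conservative* rather than liberal; material over-rejection in two-group
  designs appears when one group is very small (the same mechanism as the
  small-cluster inflation above). The shipped scenario reflects that
  finding.
* **Ten tiny groups**: 10 groups of 10, administrative cutoff 3.0:
  AP rejects ~11% at the 5% level. Inflation strengthens with *more*
  events per tiny group (at cutoff 0.4, i.e. ~1/3 events, it is only
  ~6%): heavy administrative censoring is itself partly conservative.

Replicate counts were fixed once to keep the full suite a few minutes on
one core; every threshold is stated in SE multiples of the chosen count.

## Determinism

Every stochastic routine takes an explicit integer seed (or a numpy
Generator) and is bit-reproducible: identical seeds give identical
results, and the CLI writes byte-identical result files (JSON floats in
shortest round-trip notation, key order fixed by dataclass field order).
Seeds are recorded inside every result object; run metadata (version,
config hash, wall clock) goes to stderr only.

## Known limitations

* Exact enumeration is limited by the multinomial assignment count
  (default cap 1e6); beyond it only Monte Carlo EP is available.
* The conditional scheme's imputation uses the *pooled* S and G; under
  strong group-specific censoring this is an approximation to per-group
  conditioning, mitigated by holding each slot's follow-up fixed.
* p-values in singular-covariance corner cases use df = rank(V) and so
  deliberately differ from tools that keep df = K-1.
* No support for left truncation, interval censoring, competing risks,
  weighted (Fleming–Harrington / Wilcoxon) statistics, trend or
  stratified tests.
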