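"""Kaplan-Meier estimation and the conditional log-rank test on a tiny cohort.

Builds an 8-patient, two-arm dataset, prints the risk table, the pooled
KM curve and the log-rank result.  The statistic T sums observed-minus-
expected event counts over event times; its chi-square upper tail with
K-1 degrees of freedom is the asymptotic p-value (AP).
"""
import numpy as np

from exactlogrank import kaplan_meier, logrank_statistic, risk_table, validate_dataset

data = validate_dataset(
    time=[2, 4, 5, 5, 1, 3, 6, 8],
    event=[1, 1, 0, 1, 1, 1, 0, 1],
    group=["treated"] * 4 + ["control"] * 4,
)

rt = risk_table(data)
print("risk table (time, at-risk, events, at-risk treated):")
for i, t in enumerate(rt.event_times):
    print(f"  t={t:4.1f}  n={rt.n_at_risk[i]}  d={rt.n_events[i]}  "
          f"n_treated={rt.n_at_risk_group[i, 0]}")

km = kaplan_meier(data.time, data.event)
print("\npooled Kaplan-Meier: S(t) =",
      np.round(km.survival, 3).tolist(), "at times", km.times.tolist())

res = logrank_statistic(data)
print(f"\nlog-rank: T = {res.statistic:.4f}, df = {res.df}, AP = {res.p_value:.4f}")
print("observed events per arm:", dict(zip(res.group_labels, res.observed)))
print("expected under equal survival:",
      dict(zip(res.group_labels, np.round(res.expected, 3))))
# With so few patients the chi-square AP is only a rough guide; see
# exact_vs_asymptotic.py for the permutation p-value on the same data.
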