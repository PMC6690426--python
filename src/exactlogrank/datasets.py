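"""Core survival data structures.

A :class:`SurvivalDataset` holds one row per patient: a non-negative
follow-up time, an event indicator (``True`` = event observed, ``False`` =
right-censored) and a group label.  From it the other modules derive the
risk table — the per-event-time at-risk and event counts that are the
sufficient statistic of the conditional log-rank test — and Kaplan–Meier
product-limit curves.

Tie convention (standard): at tied times events are ranked before
censorings, so a patient censored exactly at an event time is still in the
at-risk set at that time.  Time zero is allowed; an event at t=0 enters the
first risk set.
"""
from __future__ import annotations

import dataclasses
from typing import Any, Sequence

import numpy as np

__all__ = [
    "SurvivalDataset",
    "RiskTable",
    "KMCurve",
    "validate_dataset",
    "risk_table",
    "kaplan_meier",
]

#: event codes accepted by default (anything else must be mapped explicitly)
DEFAULT_TRUE_CODES = (1, True, "1", "true", "True", "TRUE")
DEFAULT_FALSE_CODES = (0, False, "0", "false", "False", "FALSE")


@dataclasses.dataclass(frozen=True)
class SurvivalDataset:
    """Validated per-patient survival data.

    Groups are stored as integer codes ``0..K-1`` in first-appearance order;
    ``group_labels`` maps codes back to the original labels.  All outputs
    that face the user report original labels.
    """

    time: np.ndarray          # float64, shape (n,), all >= 0
    event: np.ndarray         # bool, shape (n,)
    group: np.ndarray         # int64 codes 0..K-1, shape (n,)
    group_labels: tuple       # original labels, first-appearance order

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group, minlength=self.n_groups)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def with_labels(self, labels: Sequence[Any]) -> "SurvivalDataset":
        """Same patients, different grouping (used by the diagnostics)."""
        return validate_dataset(self.time, self.event, labels)


@dataclasses.dataclass(frozen=True)
class RiskTable:
    """Per-event-time counts: the conditioning quantities of the test.

    One row per distinct time with >= 1 event.  ``n_at_risk[i]`` counts
    patients with time >= ``event_times[i]`` (so censored-at-event-time
    patients are included); per-group columns follow first-appearance
    group order.
    """

    event_times: np.ndarray   # (m,) strictly increasing
    n_events: np.ndarray      # (m,) d_i, total events at t_i
    n_at_risk: np.ndarray     # (m,) n_i
    n_events_group: np.ndarray  # (m, K) d_ij
    n_at_risk_group: np.ndarray  # (m, K) n_ij
    group_labels: tuple


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier product-limit estimate evaluated at the event times."""

    times: np.ndarray       # (m,) event times
    survival: np.ndarray    # (m,) S(t_i) = prod_{l<=i} (1 - d_l/n_l)
    at_risk: np.ndarray     # (m,) n_i
    events: np.ndarray      # (m,) d_i

    def survival_at(self, t: np.ndarray) -> np.ndarray:
        """Step-function value S(t) (right-continuous; 1 before first event)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]


def _parse_event(event: Sequence[Any],
                 true_codes: Sequence[Any] = DEFAULT_TRUE_CODES,
                 false_codes: Sequence[Any] = DEFAULT_FALSE_CODES) -> np.ndarray:
    arr = np.asarray(event, dtype=object).ravel()
    if arr.dtype == bool:
        return arr.astype(bool)
    out = np.empty(arr.size, dtype=bool)
    true_set = set(true_codes)
    false_set = set(false_codes)
    for i, v in enumerate(arr):
        if isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
        elif v in true_set:
            out[i] = True
        elif v in false_set:
            out[i] = False
        else:
            raise ValueError(
                f"unrecognised event code {v!r} at row {i}: accepted codes are "
                f"{sorted(map(str, true_set))} / {sorted(map(str, false_set))}; "
                "pass explicit true_codes/false_codes for other encodings"
            )
    return out


def validate_dataset(time: Sequence[float],
                     event: Sequence[Any],
                     group: Sequence[Any],
                     *,
                     true_codes: Sequence[Any] = DEFAULT_TRUE_CODES,
                     false_codes: Sequence[Any] = DEFAULT_FALSE_CODES,
                     ) -> SurvivalDataset:
    """Validate raw per-patient records and build a :class:`SurvivalDataset`.

    Raises ``ValueError`` on: negative or non-finite times; fewer than two
    groups; zero events in the pooled data; unmappable event codes; length
    mismatches.  Group codes are assigned in first-appearance order.
    """
    t = np.asarray(time, dtype=float).ravel()
    e = _parse_event(event, true_codes, false_codes)
    g_raw = np.asarray(group, dtype=object).ravel()
    if not (t.size == e.size == g_raw.size):
        raise ValueError(
            f"length mismatch: {t.size} times, {e.size} events, {g_raw.size} groups"
        )
    if t.size < 2:
        raise ValueError(f"need at least 2 patients, got {t.size}")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite follow-up times")
    if np.any(t < 0):
        bad = int(np.argmax(t < 0))
        raise ValueError(f"negative follow-up time {t[bad]} at row {bad}")
    if not e.any():
        raise ValueError("no events in the pooled data: log-rank statistic undefined")

    labels: list = []
    index: dict = {}
    codes = np.empty(t.size, dtype=np.int64)
    for i, lab in enumerate(g_raw):
        if lab not in index:
            index[lab] = len(labels)
            labels.append(lab)
        codes[i] = index[lab]
    if len(labels) < 2:
        raise ValueError(f"K < 2: need at least two distinct groups, got {len(labels)}")
    # every group has >= 1 member by construction (codes are first-appearance)
    t.setflags(write=False)
    e.setflags(write=False)
    codes.setflags(write=False)
    return SurvivalDataset(time=t, event=e, group=codes, group_labels=tuple(labels))


def risk_table(data: SurvivalDataset) -> RiskTable:
    """Build the risk table: one row per distinct event time.

    Counts follow the events-before-censoring tie convention: the at-risk
    set at t_i is every patient with observed time >= t_i.
    """
    t, e, g = data.time, data.event, data.group
    K = data.n_groups
    event_times = np.unique(t[e])
    m = event_times.size
    t_sorted = np.sort(t)
    n_at_risk = t.size - np.searchsorted(t_sorted, event_times, side="left")

    rows_ev = np.searchsorted(event_times, t[e])
    d = np.bincount(rows_ev, minlength=m)
    d_group = np.zeros((m, K), dtype=np.int64)
    np.add.at(d_group, (rows_ev, g[e]), 1)

    n_group = np.zeros((m, K), dtype=np.int64)
    for j in range(K):
        tj_sorted = np.sort(t[g == j])
        n_group[:, j] = tj_sorted.size - np.searchsorted(tj_sorted, event_times, side="left")

    return RiskTable(event_times=event_times, n_events=d, n_at_risk=n_at_risk,
                     n_events_group=d_group, n_at_risk_group=n_group,
                     group_labels=data.group_labels)


def kaplan_meier(time: Sequence[float], event: Sequence[Any]) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the event-time distribution.

    Pass the complemented event flags to estimate the follow-up (censoring)
    distribution instead — the reverse-KM estimate used by the
    follow-up-conditioned permutation scheme.
    """
    t = np.asarray(time, dtype=float).ravel()
    e = np.asarray(event, dtype=bool).ravel()
    if not e.any():
        raise ValueError("no events: Kaplan-Meier estimate undefined")
    event_times = np.unique(t[e])
    t_sorted = np.sort(t)
    n_at_risk = t.size - np.searchsorted(t_sorted, event_times, side="left")
    d = np.bincount(np.searchsorted(event_times, t[e]), minlength=event_times.size)
    survival = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(times=event_times, survival=survival, at_risk=n_at_risk, events=d)
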