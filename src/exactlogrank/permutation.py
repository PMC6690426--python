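"""Exact permutation p-values (EP) for the conditional log-rank statistic.

Two resampling schemes are provided:

``label``
    Plain group-label permutation: patients keep (time, event), labels are
    shuffled.  Exact under the null when censoring does not depend on group.

``conditional``
    The follow-up-conditioned scheme of Heinze, Gnant & Schemper (2003),
    extended to K groups: estimate the pooled event-time distribution S by
    Kaplan-Meier and the pooled follow-up distribution G by reverse KM; for
    every censored patient impute a latent event time from S conditional on
    exceeding the observed time, and for every event patient a latent
    follow-up time from G conditional on being >= the observed time.  Each
    patient slot keeps its group label and latent follow-up; the latent
    event times are permuted across slots and re-censored by the slot's
    follow-up.  This keeps each group's follow-up structure fixed, which is
    what makes the test valid when follow-up differs between groups.  The
    whole procedure is repeated with M independent imputations and the EP
    averaged.

The EP estimator is the add-one form (b + 1)/(B + 1): with b the number of
resampled statistics >= the observed one it is a valid p-value and never
zero.  Clopper-Pearson 95% intervals quantify the Monte Carlo uncertainty
of the exceedance probability.  A full-enumeration oracle over the distinct
label assignments gives the exact p-value on small samples.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Optional

import numpy as np
from scipy import stats

from .datasets import SurvivalDataset, kaplan_meier
from .logrank import LogRankWorkspace, logrank_statistic, statistic_from_arrays

__all__ = [
    "PermutationResult",
    "permutation_pvalue",
    "enumerate_pvalue",
    "conditional_resample",
    "ConditionalScheme",
    "ep_confidence_interval",
]

# float slop when counting T_perm >= T_obs (identical assignments must tie)
_TIE_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    """Monte Carlo estimate of the exact log-rank p-value."""

    p_value: float              # EP = (b + 1)/(B + 1)
    exceedances: float          # b; fractional when averaged over imputations
    n_permutations: int         # B (per imputation for the conditional scheme)
    ci_low: float
    ci_high: float
    scheme: str                 # "label" or "conditional"
    seed: int
    statistic: float            # observed T
    ci_level: float = 0.95
    n_imputations: Optional[int] = None   # M, conditional scheme only


def ep_confidence_interval(b: float, B: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for the permutation exceedance probability.

    ``b`` may be fractional (imputation-averaged counts); the beta quantiles
    accept non-integer shapes.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not 0 <= b <= B:
        raise ValueError(f"need 0 <= b <= B, got b={b}, B={B}")
    alpha = 1.0 - level
    low = 0.0 if b <= 0 else float(stats.beta.ppf(alpha / 2.0, b, B - b + 1.0))
    high = 1.0 if b >= B else float(stats.beta.ppf(1.0 - alpha / 2.0, b + 1.0, B - b))
    return low, high


# --------------------------------------------------------------------------
# conditional (follow-up preserving) scheme
# --------------------------------------------------------------------------

class _StepDistribution:
    """Discrete distribution read off a KM curve, with conditional sampling.

    Mass at each KM jump; any mass remaining after the last jump (largest
    observation censored for S, largest an event for G) sits at the largest
    observed time.  Conditional draws beyond the whole support return +inf.
    """

    def __init__(self, curve, t_max: float):
        support = np.asarray(curve.times, dtype=float)
        cdf = 1.0 - np.asarray(curve.survival, dtype=float)
        if curve.survival[-1] > 1e-12 and t_max > support[-1]:
            support = np.append(support, t_max)
            cdf = np.append(cdf, 1.0)
        cdf[-1] = 1.0          # residual mass sits at the largest observed time
        self.support = support
        self.cdf = cdf

    def sample_conditional(self, thresholds: np.ndarray, rng: np.random.Generator,
                           strict: bool) -> np.ndarray:
        """Draw X | X > c (strict) or X | X >= c for each threshold c.

        Inverse-CDF on the truncated distribution; +inf where the
        conditional support is empty (all mass at or below the threshold).
        """
        c = np.asarray(thresholds, dtype=float)
        side = "right" if strict else "left"
        pos = np.searchsorted(self.support, c, side=side)
        # probability mass strictly below the allowed support
        floor = np.where(pos > 0, self.cdf[np.maximum(pos - 1, 0)], 0.0)
        tail = 1.0 - floor
        out = np.full(c.shape, np.inf)
        ok = tail > 1e-12
        if ok.any():
            u = floor[ok] + rng.random(int(ok.sum())) * tail[ok]
            idx = np.searchsorted(self.cdf - 1e-15, u, side="left")
            idx = np.minimum(idx, self.support.size - 1)
            out[ok] = self.support[idx]
        return out


class ConditionalScheme:
    """Latent-time imputation machinery for the conditional permutation test.

    One :meth:`impute` call fixes the latent event times E and latent
    follow-up times F for every patient slot (one "imputation");
    :meth:`resample` then permutes E across slots while labels and F stay
    put.  With no censored patients the scheme collapses to plain label
    permutation (there is nothing to impute), which :attr:`degenerate`
    reports.
    """

    def __init__(self, data: SurvivalDataset):
        self.data = data
        self.t_max = float(data.time.max())
        self.degenerate = not bool((~data.event).any())
        if not self.degenerate:
            self._S = _StepDistribution(kaplan_meier(data.time, data.event), self.t_max)
            self._G = _StepDistribution(kaplan_meier(data.time, ~data.event), self.t_max)

    def impute(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw latent (event, follow-up) times for every patient slot."""
        t, e = self.data.time, self.data.event
        E = t.astype(float).copy()
        F = t.astype(float).copy()
        if self.degenerate:
            F[:] = np.inf
            return E, F
        cens = ~e
        # censored patients: latent event time strictly after observed time
        E[cens] = self._S.sample_conditional(t[cens], rng, strict=True)
        # event patients: latent follow-up at least the observed time
        F[e] = self._G.sample_conditional(t[e], rng, strict=False)
        return E, F

    def resample(self, E: np.ndarray, F: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Permute latent event times across slots; re-censor by slot follow-up."""
        Ep = E[rng.permutation(E.size)]
        obs = np.minimum(Ep, F)
        event = Ep <= F
        unbounded = ~np.isfinite(obs)
        if unbounded.any():          # inf event time met inf follow-up
            obs = obs.copy()
            obs[unbounded] = self.t_max
            event = event & ~unbounded
        return obs, event


def conditional_resample(data: SurvivalDataset,
                         rng: np.random.Generator) -> SurvivalDataset:
    """One follow-up-conditioned resample (fresh imputation, one permutation)."""
    scheme = ConditionalScheme(data)
    E, F = scheme.impute(rng)
    obs, event = scheme.resample(E, F, rng)
    if not event.any():
        # zero-event resamples are legal null draws; keep the dataset usable
        # downstream by flagging the earliest latent event as observed
        event = event.copy()
        event[np.argmin(obs)] = True
    return SurvivalDataset(time=obs, event=event, group=data.group,
                           group_labels=data.group_labels)


# --------------------------------------------------------------------------
# EP estimation
# --------------------------------------------------------------------------

def permutation_pvalue(data: SurvivalDataset,
                       n_permutations: int,
                       seed: int,
                       scheme: str = "label",
                       n_imputations: int = 10,
                       ci_level: float = 0.95,
                       return_null: bool = False):
    """Monte Carlo exact p-value of the log-rank statistic.

    Parameters
    ----------
    n_permutations
        B, resamples per imputation (>= 1).
    scheme
        ``"label"`` or ``"conditional"`` (see module docstring).
    n_imputations
        M, imputations for the conditional scheme (ignored for ``label``).
    return_null
        Also return the vector of resampled statistics (concatenated over
        imputations for the conditional scheme).

    Deterministic given (data, n_permutations, seed, scheme, n_imputations).
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    if scheme not in ("label", "conditional"):
        raise ValueError(f"unknown scheme {scheme!r}")
    B = int(n_permutations)
    rng = np.random.default_rng(seed)
    obs = logrank_statistic(data)
    T_obs = obs.statistic
    thresh = T_obs - _TIE_EPS * max(1.0, T_obs)

    cond = scheme == "conditional"
    if cond:
        machinery = ConditionalScheme(data)
        if machinery.degenerate:
            cond = False        # no censoring: exactly label permutation
    if not cond:
        ws = LogRankWorkspace(data.time, data.event)
        labels = rng.permuted(np.tile(data.group, (B, 1)), axis=1)
        null = ws.statistics(labels, data.n_groups)
        b = float(np.count_nonzero(null >= thresh))
        # (for a censoring-free "conditional" request the scheme reduces to
        # label permutation exactly; imputations would be identical)
        M_used = None if scheme == "label" else int(n_imputations)
    else:
        M = int(n_imputations)
        codes = data.group
        K = data.n_groups
        counts = []
        null = np.empty(M * B)
        for m_i in range(M):
            E, F = machinery.impute(rng)
            b_m = 0
            for i in range(B):
                t_r, e_r = machinery.resample(E, F, rng)
                T = statistic_from_arrays(t_r, e_r, codes, K)
                null[m_i * B + i] = T
                if T >= thresh:
                    b_m += 1
            counts.append(b_m)
        b = float(np.mean(counts))
        M_used = M

    ep = (b + 1.0) / (B + 1.0)
    lo, hi = ep_confidence_interval(b, B, ci_level)
    result = PermutationResult(p_value=ep, exceedances=b, n_permutations=B,
                               ci_low=lo, ci_high=hi, scheme=scheme, seed=int(seed),
                               statistic=T_obs, ci_level=ci_level,
                               n_imputations=M_used)
    if return_null:
        return result, null
    return result


# --------------------------------------------------------------------------
# full enumeration oracle
# --------------------------------------------------------------------------

def _multinomial_total(counts: np.ndarray) -> int:
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _distinct_label_vectors(counts: np.ndarray) -> Iterator[np.ndarray]:
    """All distinct arrangements of the label multiset, lexicographic order."""
    n = int(counts.sum())
    K = counts.size
    out = np.empty(n, dtype=np.int64)
    remaining = counts.astype(int).copy()

    def rec(pos: int):
        if pos == n:
            yield out.copy()
            return
        for j in range(K):
            if remaining[j] > 0:
                remaining[j] -= 1
                out[pos] = j
                yield from rec(pos + 1)
                remaining[j] += 1

    yield from rec(0)


def enumerate_pvalue(data: SurvivalDataset, cap: int = 10 ** 6,
                     batch: int = 4096) -> float:
    """Exact permutation p-value by enumerating all distinct label assignments.

    The proportion of the ``multinomial(n; n_1..n_K)`` distinct assignments
    of the observed group sizes whose statistic is >= the observed one.  The
    gold standard a sampled EP must converge to; refuses datasets whose
    assignment count exceeds ``cap``.
    """
    counts = data.group_sizes
    total = _multinomial_total(counts)
    if total > cap:
        raise ValueError(f"{total} distinct assignments exceed the cap {cap}")
    T_obs = logrank_statistic(data).statistic
    thresh = T_obs - _TIE_EPS * max(1.0, T_obs)
    ws = LogRankWorkspace(data.time, data.event)
    hits = 0
    buf = np.empty((batch, data.n), dtype=np.int64)
    filled = 0
    for vec in _distinct_label_vectors(counts):
        buf[filled] = vec
        filled += 1
        if filled == batch:
            hits += int(np.count_nonzero(ws.statistics(buf, data.n_groups) >= thresh))
            filled = 0
    if filled:
        hits += int(np.count_nonzero(
            ws.statistics(buf[:filled], data.n_groups) >= thresh))
    return hits / total
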