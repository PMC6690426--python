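"""The K-group conditional log-rank statistic and its chi-square p-value.

At each distinct event time t_i the test conditions on the at-risk
configuration: given n_i patients at risk, n_ij of them in group j, and d_i
events in total, the number of events in group j is hypergeometric.  Summing
observed-minus-expected counts over event times gives

    z_j = O_j - E_j,   O_j = sum_i d_ij,   E_j = sum_i d_i n_ij / n_i,

with conditional covariance (including the ties correction)

    V_jl = sum_i  d_i (n_i - d_i) / (n_i - 1) * (n_ij/n_i) (delta_jl - n_il/n_i),

terms with n_i = 1 contributing zero.  The statistic is T = z' V^-1 z with z
and V restricted to the first K-1 groups; under the null T is asymptotically
chi-square with K-1 degrees of freedom, giving the asymptotic p-value (AP).
When V is singular a pseudo-inverse is used and df drops to rank(V).

:class:`LogRankWorkspace` precomputes everything that does not depend on the
group labels, so the statistic can be re-evaluated cheaply for thousands of
permuted or random label vectors — the workhorse of the exact permutation
test and of the calibration diagnostics.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .datasets import SurvivalDataset

__all__ = ["LogRankResult", "LogRankWorkspace", "logrank_statistic", "asymptotic_pvalue"]

logger = logging.getLogger(__name__)

# relative tolerance for declaring V singular and for ">= T_obs" exceedance ties
_RANK_RTOL = 1e-10


@dataclasses.dataclass(frozen=True)
class LogRankResult:
    """Result of the conditional multi-group log-rank test."""

    statistic: float          # T >= 0
    df: int                   # K - 1, or rank(V) when V is singular
    p_value: float            # asymptotic (chi-square) p-value, AP
    observed: np.ndarray      # O_j per group, first-appearance order
    expected: np.ndarray      # E_j per group
    covariance: np.ndarray    # (K-1) x (K-1) covariance of (O - E)
    group_labels: tuple


def asymptotic_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability of the log-rank statistic."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if statistic < 0:
        raise ValueError(f"statistic must be >= 0, got {statistic}")
    return float(stats.chi2.sf(statistic, df))


def _solve_quadratic_form(V: np.ndarray, z: np.ndarray) -> tuple[float, int]:
    """T = z' V^-1 z for the restricted system; pseudo-inverse on singular V.

    Returns (T, rank).  rank == V.shape[0] means full rank.
    """
    k = V.shape[0]
    scale = np.abs(V).max()
    if scale <= 0.0:
        return 0.0, 0
    try:
        c, low = sla.cho_factor(V, check_finite=False)
        # Cholesky succeeds on positive-definite V; guard near-singular
        if np.min(np.abs(np.diag(c))) ** 2 > _RANK_RTOL * scale:
            x = sla.cho_solve((c, low), z, check_finite=False)
            return float(max(z @ x, 0.0)), k
    except sla.LinAlgError:
        pass
    w, U = np.linalg.eigh(V)
    keep = w > _RANK_RTOL * scale
    rank = int(keep.sum())
    if rank == 0:
        return 0.0, 0
    y = U[:, keep].T @ z
    return float(max(np.sum(y * y / w[keep]), 0.0)), rank


class LogRankWorkspace:
    """Risk-set structure of a fixed (time, event) sample.

    Everything label-independent is computed once; :meth:`statistics`
    evaluates T for a whole matrix of candidate label vectors with vectorised
    numpy, chunked to bound memory.
    """

    def __init__(self, time: Sequence[float], event: Sequence[bool]):
        t = np.asarray(time, dtype=float).ravel()
        e = np.asarray(event, dtype=bool).ravel()
        if not e.any():
            raise ValueError("no events: log-rank statistic undefined")
        self.n = t.size
        # descending time order; ties in any order (counts only depend on >=)
        self.order = np.argsort(-t, kind="stable")
        t_desc = t[self.order]
        e_desc = e[self.order]
        self.event_times = np.unique(t[e])            # ascending
        self.m = self.event_times.size
        t_asc = t_desc[::-1]
        # number at risk at each event time = #{time >= t_i}
        self.n_at_risk = self.n - np.searchsorted(t_asc, self.event_times, side="left")
        # positions (in descending order) of event patients and their table row
        self.ev_positions = np.nonzero(e_desc)[0]
        self.ev_rows = np.searchsorted(self.event_times, t_desc[self.ev_positions])
        self.d = np.bincount(self.ev_rows, minlength=self.m).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = self.d * (self.n_at_risk - self.d) / (self.n_at_risk - 1.0)
        c[self.n_at_risk <= 1] = 0.0
        self.tie_factor = c

    # ---- single-label evaluation with full detail ----------------------
    def detail(self, labels: np.ndarray, n_groups: int):
        """(T, df, O, E, V_full) for one label vector (codes 0..K-1)."""
        K = n_groups
        lab = np.asarray(labels)[self.order]
        onehot = lab[:, None] == np.arange(K)[None, :]
        cum = np.cumsum(onehot, axis=0)
        n_g = cum[self.n_at_risk - 1, :].astype(float)      # (m, K)
        d_g = np.zeros((self.m, K))
        np.add.at(d_g, (self.ev_rows, lab[self.ev_positions]), 1.0)
        P = n_g / self.n_at_risk[:, None]
        O = d_g.sum(axis=0)
        E = (self.d[:, None] * P).sum(axis=0)
        cP = self.tie_factor[:, None] * P
        V = -cP.T @ P
        V[np.diag_indices(K)] += cP.sum(axis=0)
        T, rank = _solve_quadratic_form(V[: K - 1, : K - 1], (O - E)[: K - 1])
        if rank == K - 1:
            df = K - 1
        else:
            logger.warning("singular log-rank covariance: rank %d < %d; "
                           "pseudo-inverse used, df = rank", rank, K - 1)
            df = max(rank, 1)   # rank 0 only in fully degenerate data (T = 0)
        return T, df, O, E, V[: K - 1, : K - 1]

    # ---- batched evaluation -------------------------------------------
    def statistics(self, labels_matrix: np.ndarray, n_groups: int,
                   max_elements: int = 20_000_000) -> np.ndarray:
        """T for each row of ``labels_matrix`` (shape (B, n), codes 0..K-1)."""
        L = np.atleast_2d(np.asarray(labels_matrix))
        B = L.shape[0]
        K = n_groups
        out = np.empty(B)
        chunk = max(1, int(max_elements // max(1, self.n * K)))
        for start in range(0, B, chunk):
            out[start:start + chunk] = self._statistics_chunk(L[start:start + chunk], K)
        return out

    def _statistics_chunk(self, L: np.ndarray, K: int) -> np.ndarray:
        B = L.shape[0]
        lab = L[:, self.order]
        onehot = lab[:, :, None] == np.arange(K)[None, None, :]
        cum = np.cumsum(onehot, axis=1)
        n_g = cum[:, self.n_at_risk - 1, :].astype(float)   # (B, m, K)
        d_g = np.zeros((B, self.m, K))
        np.add.at(d_g,
                  (np.arange(B)[:, None], self.ev_rows[None, :], lab[:, self.ev_positions]),
                  1.0)
        P = n_g / self.n_at_risk[None, :, None]
        z = d_g.sum(axis=1) - (self.d[None, :, None] * P).sum(axis=1)   # (B, K)
        cP = self.tie_factor[None, :, None] * P
        V = -np.einsum("bik,bil->bkl", cP, P)
        idx = np.arange(K)
        V[:, idx, idx] += cP.sum(axis=1)
        zr = z[:, : K - 1]
        Vr = V[:, : K - 1, : K - 1]
        try:
            sol = np.linalg.solve(Vr, zr[..., None])[..., 0]
            T = np.einsum("bk,bk->b", zr, sol)
        except np.linalg.LinAlgError:
            T = np.fromiter(
                (_solve_quadratic_form(Vr[b], zr[b])[0] for b in range(B)),
                dtype=float, count=B)
            return T
        # near-singular rows sneak past np.linalg.solve: repair individually
        bad = ~np.isfinite(T) | (T < -1e-8) | (T > 1e12)
        if bad.any():
            for b in np.nonzero(bad)[0]:
                T[b] = _solve_quadratic_form(Vr[b], zr[b])[0]
        return np.maximum(T, 0.0)


def logrank_statistic(data: SurvivalDataset) -> LogRankResult:
    """Conditional log-rank test of equal survival across the K groups."""
    ws = LogRankWorkspace(data.time, data.event)
    T, df, O, E, V = ws.detail(data.group, data.n_groups)
    return LogRankResult(statistic=T, df=df, p_value=asymptotic_pvalue(T, df),
                         observed=O, expected=E, covariance=V,
                         group_labels=data.group_labels)


def statistic_from_arrays(time: np.ndarray, event: np.ndarray,
                          group_codes: np.ndarray, n_groups: int) -> float:
    """Bare statistic from raw arrays; T = 0 when the sample has no events.

    Lean path used inside the conditional resampling loop, where every
    resample has different times and the workspace cannot be reused.
    """
    if not event.any():
        return 0.0
    ws = LogRankWorkspace(time, event)
    K = n_groups
    lab = group_codes[ws.order]
    onehot = lab[:, None] == np.arange(K)[None, :]
    cum = np.cumsum(onehot, axis=0)
    n_g = cum[ws.n_at_risk - 1, :].astype(float)
    d_g = np.zeros((ws.m, K))
    np.add.at(d_g, (ws.ev_rows, lab[ws.ev_positions]), 1.0)
    P = n_g / ws.n_at_risk[:, None]
    z = d_g.sum(axis=0) - (ws.d[:, None] * P).sum(axis=0)
    cP = ws.tie_factor[:, None] * P
    V = -cP.T @ P
    V[np.diag_indices(K)] += cP.sum(axis=0)
    T, _ = _solve_quadratic_form(V[: K - 1, : K - 1], z[: K - 1])
    return T
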