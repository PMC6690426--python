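"""Synthetic right-censored survival data and type-I-error calibration.

Latent event times are exponential with a per-group hazard; a per-group
censoring model (none / exponential / uniform / administrative cutoff)
produces a latent censoring time, and the observed record is
``time = min(event, censoring)``, ``event = (event <= censoring)``.
Exponential event times keep every summary checkable in closed form: mean
1/lambda, and under exponential censoring at rate lambda_c an expected
censored fraction lambda_c / (lambda_e + lambda_c).

The calibration harness runs many null replicates (equal hazards) and
reports the fraction rejected at level alpha for a chosen method — the
chi-square asymptotic p-value (AP) or the permutation EP under either
scheme — with its Monte Carlo standard error and a binomial confidence
interval.  This is the machinery that demonstrates where the chi-square
approximation holds (large balanced groups, many events) and where it
breaks (many small groups, few events, unequal follow-up).
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .datasets import SurvivalDataset, validate_dataset
from .logrank import logrank_statistic
from .permutation import ep_confidence_interval, permutation_pvalue

__all__ = [
    "Censoring",
    "ScenarioConfig",
    "generate_dataset",
    "type1_error",
    "Type1ErrorResult",
    "ap_uniformity",
    "UniformityResult",
]

logger = logging.getLogger(__name__)

_CENSORING_KINDS = ("none", "exponential", "uniform", "administrative")


@dataclasses.dataclass(frozen=True)
class Censoring:
    """Censoring model for one group.

    kind:
        ``none``; ``exponential`` (param = rate); ``uniform`` (param = tau,
        censoring ~ U(0, tau)); ``administrative`` (param = tau, fixed
        cutoff).
    """

    kind: str = "none"
    param: float = 0.0

    def __post_init__(self):
        if self.kind not in _CENSORING_KINDS:
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind == "exponential" and self.param <= 0:
            raise ValueError("exponential censoring needs rate > 0")
        if self.kind == "uniform" and self.param <= 0:
            raise ValueError("uniform censoring needs tau > 0")
        if self.kind == "administrative" and self.param < 0:
            raise ValueError("administrative cutoff must be >= 0")

    @classmethod
    def parse(cls, text: str) -> "Censoring":
        """Parse ``"none"`` or ``"kind:param"`` (e.g. ``exponential:0.5``)."""
        if ":" in text:
            kind, raw = text.split(":", 1)
            return cls(kind.strip(), float(raw))
        return cls(text.strip())

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.full(size, np.inf)
        if self.kind == "exponential":
            return rng.exponential(1.0 / self.param, size)
        if self.kind == "uniform":
            return rng.uniform(0.0, self.param, size)
        return np.full(size, float(self.param))       # administrative


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Design of one simulation scenario.

    ``hazards`` and ``censoring`` may be a single value applied to every
    group or one value per group.  Equal hazards = the null hypothesis.
    """

    group_sizes: tuple
    hazards: Union[float, tuple] = 1.0
    censoring: Union[Censoring, tuple] = Censoring("none")
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.group_sizes)
        object.__setattr__(self, "group_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("need K >= 2 groups")
        if any(s <= 0 for s in sizes):
            raise ValueError("group sizes must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        haz = self.hazards
        if np.isscalar(haz):
            haz = (float(haz),) * len(sizes)
        else:
            haz = tuple(float(h) for h in haz)
        if len(haz) != len(sizes):
            raise ValueError("hazards must be scalar or one per group")
        if any(h <= 0 for h in haz):
            raise ValueError("hazards must be positive")
        object.__setattr__(self, "hazards", haz)
        cen = self.censoring
        if isinstance(cen, Censoring):
            cen = (cen,) * len(sizes)
        else:
            cen = tuple(cen)
        if len(cen) != len(sizes):
            raise ValueError("censoring must be one model or one per group")
        object.__setattr__(self, "censoring", cen)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def is_null(self) -> bool:
        return len(set(self.hazards)) == 1


def generate_dataset(config: ScenarioConfig,
                     rng: np.random.Generator) -> SurvivalDataset:
    """Draw one dataset from the scenario; raises if it carries no events."""
    times, events, groups = [], [], []
    for j, (size, hazard, cen) in enumerate(
            zip(config.group_sizes, config.hazards, config.censoring)):
        latent_event = rng.exponential(1.0 / hazard, size)
        latent_cens = cen.draw(size, rng)
        times.append(np.minimum(latent_event, latent_cens))
        events.append(latent_event <= latent_cens)
        groups.append(np.full(size, j + 1))
    return validate_dataset(np.concatenate(times), np.concatenate(events),
                            np.concatenate(groups))


def _generate_nonempty(config: ScenarioConfig, rng: np.random.Generator,
                       max_tries: int = 100) -> SurvivalDataset:
    """Redraw until the sample has >= 1 event (heavy censoring scenarios)."""
    for _ in range(max_tries):
        try:
            return generate_dataset(config, rng)
        except ValueError:
            continue
    raise RuntimeError("scenario produced no events in 100 consecutive draws")


@dataclasses.dataclass(frozen=True)
class Type1ErrorResult:
    """Null rejection fraction of one method at level alpha."""

    method: str
    fraction: float
    ci_low: float
    ci_high: float
    mc_se: float
    n_reps: int
    alpha: float
    seed: int


_METHODS = ("ap", "ep-label", "ep-conditional")


def type1_error(config: ScenarioConfig,
                method: str = "ap",
                n_permutations: int = 199,
                n_imputations: int = 5,
                rng: Optional[np.random.Generator] = None) -> Type1ErrorResult:
    """Fraction of null replicates with p <= alpha, with binomial CI.

    With unequal hazards this measures power instead; a warning is issued
    and the computation proceeds.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    if not config.is_null:
        warnings.warn("scenario hazards are unequal: measuring power, "
                      "not type-I error", stacklevel=2)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rejections = 0
    for _ in range(config.n_reps):
        data = _generate_nonempty(config, rng)
        if method == "ap":
            p = logrank_statistic(data).p_value
        else:
            scheme = "label" if method == "ep-label" else "conditional"
            p = permutation_pvalue(
                data, n_permutations=n_permutations,
                seed=int(rng.integers(2 ** 31)), scheme=scheme,
                n_imputations=n_imputations).p_value
        if p <= config.alpha:
            rejections += 1
    frac = rejections / config.n_reps
    lo, hi = ep_confidence_interval(rejections, config.n_reps, 0.95)
    se = float(np.sqrt(config.alpha * (1 - config.alpha) / config.n_reps))
    logger.info("type1_error[%s]: %.4f (CI %.4f-%.4f) over %d reps",
                method, frac, lo, hi, config.n_reps)
    return Type1ErrorResult(method=method, fraction=frac, ci_low=lo, ci_high=hi,
                            mc_se=se, n_reps=config.n_reps, alpha=config.alpha,
                            seed=config.seed)


@dataclasses.dataclass(frozen=True)
class UniformityResult:
    """Departure of null asymptotic p-values from Uniform(0, 1)."""

    ks_distance: float
    fraction_le_alpha: float
    n_reps: int
    alpha: float
    p_values: np.ndarray


def ap_uniformity(config: ScenarioConfig,
                  n_reps: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None) -> UniformityResult:
    """KS distance of the null AP sample from uniform + tail fraction.

    Under a valid null the p-value distribution is uniform; an excess of
    small APs is exactly the anti-conservatism of the chi-square
    approximation.
    """
    reps = config.n_reps if n_reps is None else int(n_reps)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ap = np.empty(reps)
    for i in range(reps):
        ap[i] = logrank_statistic(_generate_nonempty(config, rng)).p_value
    ks = float(stats.kstest(ap, "uniform").statistic)
    return UniformityResult(ks_distance=ks,
                            fraction_le_alpha=float(np.mean(ap <= config.alpha)),
                            n_reps=reps, alpha=config.alpha, p_values=ap)
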