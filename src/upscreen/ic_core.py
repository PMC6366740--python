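"""Information-criterion arithmetic and model-summary containers.

This module holds the bookkeeping half of the toolkit: per-model summaries
(:class:`ModelRecord`), IC metrics (AIC, small-sample AICc, quasi-likelihood
QAIC/QAICc, or IC values reported verbatim in a table), model ranking with
delta values and Akaike weights, and McFadden's pseudo-R-squared.

Conventions
-----------
* ``K`` is the number of estimated parameters *as reported* (including the
  intercept and, where applicable, a dispersion/scale parameter).  The
  library never recounts K from term lists, because published tables often
  use conventions the term list cannot reveal (multi-level factors, scale
  parameters); a missing or implausible K is a reporting problem, which the
  linter flags, not something to silently repair.
* Lower IC is better.  ``delta`` is a model's IC minus the set minimum, and
  Akaike weights are ``exp(-delta/2)`` normalised over the set.
* IC values are compared at full floating-point precision internally and
  rounded only when tables are written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "INTERCEPT",
    "ParameterEstimate",
    "ModelRecord",
    "ICMetric",
    "RankedModelTable",
    "RankedRow",
    "compute_aic",
    "compute_aicc",
    "compute_qaic",
    "akaike_weights",
    "rank_models",
    "mcfadden_r2",
]

#: Sentinel term name for the intercept in estimate maps.
INTERCEPT = "(Intercept)"

_METRICS = ("AIC", "AICc", "QAIC", "QAICc", "reported")


@dataclass(frozen=True)
class ParameterEstimate:
    """A point estimate with its confidence interval, on the linear-predictor scale."""

    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"confidence interval ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the estimate {self.estimate}"
            )

    @property
    def contains_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high

    @property
    def null_ratio(self) -> float:
        """|estimate| relative to the CI half-width; small values mean 'near zero'."""
        half = (self.ci_high - self.ci_low) / 2.0
        if half == 0.0:
            return math.inf if self.estimate != 0.0 else 0.0
        return abs(self.estimate) / half


@dataclass(frozen=True)
class ModelRecord:
    """Summary of one fitted model as reported in a model-selection table.

    ``terms`` uses ``A:B`` for interactions and ``term=level`` for individual
    levels of a categorical term in the ``estimates`` map.  ``ic`` carries a
    verbatim reported IC value for use with the ``reported`` metric.
    """

    model_id: str
    terms: frozenset[str]
    K: int
    loglik: float
    gof: float | None = None
    ic: float | None = None
    estimates: Mapping[str, ParameterEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        if self.K < 1:
            raise ValueError(f"model {self.model_id!r}: K must be >= 1, got {self.K}")
        if not math.isfinite(self.loglik):
            raise ValueError(f"model {self.model_id!r}: log-likelihood must be finite")

    def estimates_for_term(self, term: str) -> list[ParameterEstimate]:
        """All estimates attached to ``term`` (the term itself plus any ``term=level``)."""
        out = [est for key, est in self.estimates.items()
               if key == term or key.startswith(term + "=")]
        return out


def compute_aic(loglik: float, K: int) -> float:
    """Akaike's Information Criterion, ``-2 log L + 2 K``."""
    if not math.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    if K < 0:
        raise ValueError(f"K must be non-negative, got {K}")
    return -2.0 * loglik + 2.0 * K


def compute_aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample corrected AIC: ``AIC + (2K^2 + 2K) / (n - K - 1)``.

    Requires ``n > K + 1``; the correction vanishes as n grows.
    """
    if n <= K + 1:
        raise ValueError(
            f"AICc undefined: sample size n={n} must exceed K+1={K + 1}"
        )
    return compute_aic(loglik, K) + (2.0 * K * K + 2.0 * K) / (n - K - 1)


def compute_qaic(loglik: float, K: int, c_hat: float, n: int | None = None) -> float:
    """Quasi-likelihood (Q)AIC(c): ``-2 log L / c_hat + 2 K``, plus the AICc
    correction when ``n`` is given.  ``c_hat`` is the overdispersion estimate."""
    if c_hat < 1.0:
        raise ValueError(f"overdispersion c_hat must be >= 1, got {c_hat}")
    if not math.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    qaic = -2.0 * loglik / c_hat + 2.0 * K
    if n is not None:
        if n <= K + 1:
            raise ValueError(f"QAICc undefined: n={n} must exceed K+1={K + 1}")
        qaic += (2.0 * K * K + 2.0 * K) / (n - K - 1)
    return qaic


@dataclass(frozen=True)
class ICMetric:
    """Which information criterion scores the model set.

    ``name`` is one of AIC, AICc, QAIC, QAICc, or ``reported`` (rank by the
    IC column supplied with each model — the screening posture when an
    article prints AICc values but not the sample size behind them).
    ``n`` is required for the small-sample variants, ``c_hat`` for the
    quasi-likelihood ones.
    """

    name: str = "AIC"
    n: int | None = None
    c_hat: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _METRICS:
            raise ValueError(f"unknown IC metric {self.name!r}; expected one of {_METRICS}")
        if self.name in ("AICc", "QAICc") and self.n is None:
            raise ValueError(f"{self.name} requires a sample size n")
        if self.name in ("QAIC", "QAICc") and self.c_hat is None:
            raise ValueError(f"{self.name} requires an overdispersion estimate c_hat")

    def ic_value(self, model: ModelRecord) -> float:
        if self.name == "AIC":
            return compute_aic(model.loglik, model.K)
        if self.name == "AICc":
            try:
                return compute_aicc(model.loglik, model.K, self.n)
            except ValueError as exc:
                raise ValueError(f"model {model.model_id!r}: {exc}") from None
        if self.name == "QAIC":
            return compute_qaic(model.loglik, model.K, self.c_hat)
        if self.name == "QAICc":
            return compute_qaic(model.loglik, model.K, self.c_hat, self.n)
        # reported
        if model.ic is None:
            raise ValueError(
                f"model {model.model_id!r} has no reported IC value "
                "(metric 'reported' needs an 'ic' column)"
            )
        return float(model.ic)

    def penalty(self, K: int) -> float:
        """The metric's complexity penalty at identical log-likelihood.

        The difference ``penalty(K_complex) - penalty(K_simple)`` is the exact
        IC gap two equally-fitting nested models show, which is the
        metric-aware cutoff for the first warning signal.
        """
        pen = 2.0 * K
        if self.name in ("AICc", "QAICc"):
            if self.n <= K + 1:
                raise ValueError(f"penalty undefined for K={K} at n={self.n}")
            pen += (2.0 * K * K + 2.0 * K) / (self.n - K - 1)
        if self.name == "reported":
            raise ValueError("metric 'reported' has no closed-form penalty")
        return pen


def akaike_weights(deltas: Sequence[float]) -> list[float]:
    """Akaike weights ``exp(-delta/2)`` normalised to sum to one.

    Expects deltas relative to the set minimum (all >= 0, at least one 0).
    """
    if len(deltas) == 0:
        raise ValueError("cannot compute Akaike weights of an empty model set")
    d = np.asarray(deltas, dtype=float)
    if np.any(d < 0):
        raise ValueError("deltas must be non-negative")
    if not np.any(d == 0):
        raise ValueError("at least one delta must be exactly 0 (the top model)")
    w = np.exp(-d / 2.0)
    w /= w.sum()
    return w.tolist()


@dataclass(frozen=True)
class RankedRow:
    model: ModelRecord
    ic_value: float
    delta: float
    weight: float


@dataclass(frozen=True)
class RankedModelTable:
    """A model set scored and sorted under one IC metric."""

    metric: ICMetric
    rows: tuple[RankedRow, ...]

    def __getitem__(self, model_id: str) -> RankedRow:
        for row in self.rows:
            if row.model.model_id == model_id:
                return row
        raise KeyError(f"model {model_id!r} not in ranked table")

    def __contains__(self, model_id: str) -> bool:
        return any(r.model.model_id == model_id for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def models(self) -> list[ModelRecord]:
        return [r.model for r in self.rows]


def rank_models(models: Sequence[ModelRecord], metric: ICMetric | None = None) -> RankedModelTable:
    """Score, sort and weight a candidate model set.

    Rows are sorted ascending by IC; ties break by smaller K (parsimony),
    then lexicographic model id, so output is deterministic across platforms.
    Deltas are relative to the minimum IC and weights are Akaike weights.
    """
    metric = metric or ICMetric("AIC")
    if len(models) == 0:
        raise ValueError("cannot rank an empty model set")
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate model ids: {dupes}")
    scored = sorted(
        ((metric.ic_value(m), m) for m in models),
        key=lambda t: (t[0], t[1].K, t[1].model_id),
    )
    best = scored[0][0]
    deltas = [ic - best for ic, _ in scored]
    weights = akaike_weights(deltas)
    rows = tuple(
        RankedRow(model=m, ic_value=ic, delta=d, weight=w)
        for (ic, m), d, w in zip(scored, deltas, weights)
    )
    return RankedModelTable(metric=metric, rows=rows)


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """McFadden's pseudo-R-squared, ``1 - log L(model) / log L(null)``.

    Defined for likelihoods below one (negative log-likelihoods); the null
    model's log-likelihood must be strictly negative.
    """
    if loglik_null == 0:
        raise ValueError("null model log-likelihood must be non-zero")
    if loglik_null > 0:
        raise ValueError("McFadden's R2 expects a negative null log-likelihood")
    if loglik_model < loglik_null:
        raise ValueError(
            "model log-likelihood is below the null's; the null must be nested"
        )
    return 1.0 - loglik_model / loglik_null
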