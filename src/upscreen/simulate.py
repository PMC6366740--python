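"""Monte-Carlo harness for the pretending-variable phenomenon.

The screen exists because a covariate whose true coefficient is exactly
zero still improves the maximised log-likelihood by a small random amount:
asymptotically, twice that improvement follows a chi-square distribution
with one degree of freedom (Wilks).  Consequently, under AIC,

* the model carrying the null covariate sits within 2 IC units of the
  simpler model whenever the chi-square draw is below 4 — about 95% of
  replicates — tripping warning signal 1;
* it is ranked *below* the simpler model whenever the draw is below 2 —
  about 84% — tripping warning signal 2;
* its Wald CI covers zero about 95% of the time, tripping signal 4.

This module manufactures exactly that situation: GLM data sets with known
true and true-zero ("null") coefficients, candidate fits for the simple and
augmented models, and replicate-level signal rates with Monte-Carlo
standard errors.  It both validates the screen's operating characteristics
and quantifies how often a null covariate looks competitive.

Randomness: one root seed; replicate ``r`` draws from an independent stream
keyed ``(seed, r)``, so runs are reproducible and order-independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ic_core import INTERCEPT, ICMetric, ModelRecord, ParameterEstimate, rank_models
from .model_set import NestedPair
from .screen import (ScreenConfig, signal1_close_ic, signal2_ranked_below,
                     signal3_similar_loglik, signal4_null_estimate)

__all__ = ["SimConfig", "SimResult", "generate_dataset", "fit_candidate",
           "run_experiment"]

_FAMILIES = ("gaussian", "binomial_logit", "poisson_log")
_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class SimConfig:
    """One simulation experiment.

    ``true_terms`` maps covariate names to nonzero coefficients on the
    linear-predictor scale; ``null_terms`` have coefficient exactly 0 and
    are the pretending-variable candidates.  Covariates are i.i.d. standard
    normal, optionally equicorrelated at ``rho`` (collinearity can change a
    parameter's status between models, so the knob exists).  Defaults mirror
    the reference operating point: n=500 gaussian observations, one true
    effect of 1 residual-SD per covariate-SD, one null covariate, 2000
    replicates.
    """

    n: int = 500
    family: str = "gaussian"
    true_terms: Mapping[str, float] = field(default_factory=lambda: {"x1": 1.0})
    null_terms: tuple[str, ...] = ("z1",)
    intercept: float = 0.0
    noise_sd: float = 1.0
    rho: float = 0.0
    replicates: int = 2000
    seed: int = 0
    metric: ICMetric = field(default_factory=lambda: ICMetric("AIC"))
    screen_config: ScreenConfig = field(default_factory=ScreenConfig)
    include_reduced_models: bool = True

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        overlap = set(self.true_terms) & set(self.null_terms)
        if overlap:
            raise ValueError(f"terms cannot be both true and null: {sorted(overlap)}")
        if self.n < 2 + len(self.true_terms) + len(self.null_terms):
            raise ValueError("sample size too small for the design")

    @property
    def all_terms(self) -> tuple[str, ...]:
        return tuple(self.true_terms) + tuple(self.null_terms)


def generate_dataset(config: SimConfig, replicate_index: int) -> pd.DataFrame:
    """One replicate's data: covariate columns plus response ``y``.

    Deterministic in ``(config.seed, replicate_index)``.
    """
    rng = np.random.default_rng([config.seed, replicate_index])
    terms = config.all_terms
    p = len(terms)
    X = rng.standard_normal((config.n, p))
    if config.rho > 0 and p > 1:
        shared = rng.standard_normal((config.n, 1))
        X = math.sqrt(config.rho) * shared + math.sqrt(1.0 - config.rho) * X
    eta = config.intercept + X @ np.array(
        [config.true_terms.get(t, 0.0) for t in terms]
    )
    if config.family == "gaussian":
        y = eta + config.noise_sd * rng.standard_normal(config.n)
    elif config.family == "binomial_logit":
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:  # poisson_log
        y = rng.poisson(np.exp(eta)).astype(float)
    data = pd.DataFrame(X, columns=list(terms))
    data["y"] = y
    return data


def _model_id(terms: Sequence[str]) -> str:
    return "+".join(sorted(terms)) if terms else "(null)"


def fit_candidate(data: pd.DataFrame, terms: Sequence[str] | set,
                  family: str = "gaussian") -> ModelRecord | None:
    """Maximum-likelihood fit of one candidate model.

    K counts all estimated parameters: the coefficients (intercept included)
    plus the residual-variance parameter for the gaussian family.  CIs are
    95% Wald intervals.  Returns ``None`` (with a warning) when the fit does
    not converge or the design is degenerate; callers drop that replicate.
    """
    terms = sorted(terms)
    y = data["y"].to_numpy()
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy() for t in terms])
    names = [INTERCEPT] + terms
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # treat convergence warnings as failures
            if family == "gaussian":
                res = sm.OLS(y, X).fit()
                K = len(names) + 1  # + residual variance
            elif family == "binomial_logit":
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                K = len(names)
            elif family == "poisson_log":
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                K = len(names)
            else:
                raise ValueError(f"unknown family {family!r}")
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
            raise RuntimeError("non-finite parameter estimates")
    except ValueError:
        raise
    except Exception as exc:  # separation, convergence failure, singular design
        warnings.warn(f"fit of {_model_id(terms)!r} failed ({exc}); replicate dropped")
        return None
    estimates = {
        name: ParameterEstimate(estimate=float(b), ci_low=float(b - _Z95 * s),
                                ci_high=float(b + _Z95 * s))
        for name, b, s in zip(names, params, bse)
    }
    return ModelRecord(model_id=_model_id(terms), terms=frozenset(terms),
                       K=K, loglik=float(res.llf), estimates=estimates)


def _mc_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n else float("nan")


@dataclass(frozen=True)
class SimResult:
    """Aggregate signal rates for null terms, false-flag rate for true
    terms, coefficient recovery, and raw likelihood-ratio draws.

    ``null_gains`` holds 2x the log-likelihood improvement from adding each
    null term (one value per null term per kept replicate) for distributional
    checks against chi-square(1).
    """

    config: SimConfig
    replicates_run: int
    dropped: int
    p_signal1: float
    p_signal2: float
    p_signal3: float
    p_signal4: float
    p_full_flag: float
    false_flag_rate: float
    null_gains: np.ndarray
    true_estimates: Mapping[str, np.ndarray]

    @property
    def coverage_null(self) -> float:
        """Share of replicates where the null coefficient's 95% CI covers 0
        (identical to the signal-4 rate by construction)."""
        return self.p_signal4

    def se(self, rate: float) -> float:
        return _mc_se(rate, len(self.null_gains))

    def summary(self) -> dict:
        """JSON-ready summary (rates, MC errors, recovery; no raw draws)."""
        n_pairs = len(self.null_gains)
        out = {
            "family": self.config.family,
            "n": self.config.n,
            "replicates_requested": self.config.replicates,
            "replicates_run": self.replicates_run,
            "dropped": self.dropped,
            "n_null_pairs": n_pairs,
            "rates": {},
            "true_coefficients": {},
        }
        for name in ("p_signal1", "p_signal2", "p_signal3", "p_signal4",
                     "p_full_flag", "false_flag_rate"):
            rate = getattr(self, name)
            out["rates"][name] = {"value": rate, "mc_se": _mc_se(rate, n_pairs)}
        for term, draws in self.true_estimates.items():
            out["true_coefficients"][term] = {
                "truth": self.config.true_terms[term],
                "mean_estimate": float(np.mean(draws)),
                "mc_se": float(np.std(draws, ddof=1) / math.sqrt(len(draws))),
            }
        return out


def run_experiment(config: SimConfig) -> SimResult:
    """Run the full experiment: per replicate, fit the simple model (all true
    terms), one augmented model per null term, and — for false-flag
    measurement — one reduced model per true term; rank under the metric and
    evaluate all four warning signals on each designed nested pair.

    Signals here are evaluated unconditionally (no short-circuit) so each
    rate is a marginal probability; the full flag is their conjunction,
    which coincides with the sequential decision-tree verdict.
    """
    cfg = config.screen_config
    s1_hits = s2_hits = s3_hits = s4_hits = full_hits = 0
    false_flags = 0
    n_null_pairs = n_true_pairs = 0
    dropped = 0
    gains: list[float] = []
    true_est: dict[str, list[float]] = {t: [] for t in config.true_terms}

    for rep in range(config.replicates):
        data = generate_dataset(config, rep)
        simple = fit_candidate(data, config.true_terms, config.family)
        if simple is None:
            dropped += 1
            continue
        candidates = {simple.model_id: simple}
        ok = True
        null_models, reduced_models = {}, {}
        for z in config.null_terms:
            m = fit_candidate(data, set(config.true_terms) | {z}, config.family)
            if m is None:
                ok = False
                break
            null_models[z] = m
            candidates[m.model_id] = m
        if ok and config.include_reduced_models:
            for t in config.true_terms:
                m = fit_candidate(data, set(config.true_terms) - {t}, config.family)
                if m is None:
                    ok = False
                    break
                reduced_models[t] = m
                candidates[m.model_id] = m
        if not ok:
            dropped += 1
            continue

        ranked = rank_models(list(candidates.values()), config.metric)
        for t in config.true_terms:
            true_est[t].append(simple.estimates[t].estimate)

        for z, complex_m in null_models.items():
            pair = NestedPair(simple_id=simple.model_id,
                              complex_id=complex_m.model_id,
                              extra_terms=frozenset({z}),
                              d=complex_m.K - simple.K)
            s1 = signal1_close_ic(pair, ranked, cfg)
            s2 = signal2_ranked_below(pair, ranked)
            s3 = signal3_similar_loglik(pair, candidates, cfg)
            s4 = signal4_null_estimate(complex_m.estimates_for_term(z))
            n_null_pairs += 1
            s1_hits += s1
            s2_hits += s2
            s3_hits += s3
            s4_hits += s4 is True
            full_hits += s1 and s2 and s3 and (s4 is True)
            gains.append(2.0 * max(complex_m.loglik - simple.loglik, 0.0))

        for t, simple_m in reduced_models.items():
            pair = NestedPair(simple_id=simple_m.model_id,
                              complex_id=simple.model_id,
                              extra_terms=frozenset({t}),
                              d=simple.K - simple_m.K)
            s1 = signal1_close_ic(pair, ranked, cfg)
            s2 = signal2_ranked_below(pair, ranked)
            s3 = signal3_similar_loglik(pair, candidates, cfg)
            s4 = signal4_null_estimate(simple.estimates_for_term(t))
            n_true_pairs += 1
            false_flags += s1 and s2 and s3 and (s4 is True)

    if n_null_pairs == 0:
        raise RuntimeError("all replicates were dropped; no rates to report")
    return SimResult(
        config=config,
        replicates_run=config.replicates - dropped,
        dropped=dropped,
        p_signal1=s1_hits / n_null_pairs,
        p_signal2=s2_hits / n_null_pairs,
        p_signal3=s3_hits / n_null_pairs,
        p_signal4=s4_hits / n_null_pairs,
        p_full_flag=full_hits / n_null_pairs,
        false_flag_rate=false_flags / n_true_pairs if n_true_pairs else float("nan"),
        null_gains=np.asarray(gains),
        true_estimates={t: np.asarray(v) for t, v in true_est.items()},
    )
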