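"""The four-warning-signal screen for uninformative parameters.

A covariate with no relationship to the response adds ~0 to the maximised
log-likelihood, so a nested model carrying it sits almost exactly one
penalty unit (2 IC points per parameter under AIC) behind its simpler twin —
close enough to look "competitive" in a ranked table.  The screen walks
every eligible nested pair through four signals, in sequence:

1. the pair's IC values are within the metric's cutoff of each other
   (2 per extra parameter under AIC, or the exact identical-fit penalty gap
   for the metric in use);
2. the complex model is ranked *below* the simple one (strictly larger IC);
3. the log-likelihoods are virtually identical (the improvement from the
   extra parameter(s) is below a configurable tolerance);
4. every extra parameter's estimate is near zero with a confidence interval
   overlapping zero.

All four true: the extra parameter is uninformative.  Signals 1-3 true but
no estimates to judge signal 4: very likely uninformative.  Signals are
short-circuited — once one fails the later ones are not asserted.

Pairs are screened for *all* model pairs, not just near the top of the
ranking, because a parameter need not be uninformative in every model in
which it appears (collinearity can change its status between models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ic_core import ICMetric, ModelRecord, RankedModelTable, rank_models
from .model_set import NestedPair, find_nested_pairs

__all__ = [
    "ScreenConfig",
    "PairScreenResult",
    "ScreenReport",
    "signal1_close_ic",
    "signal2_ranked_below",
    "signal3_similar_loglik",
    "signal4_null_estimate",
    "screen_pair",
    "screen_model_set",
]

UNASSESSABLE = "unassessable"


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the screen.

    ic_cutoff_mode
        ``fixed`` uses ``ic_cutoff`` IC units per extra parameter (the
        conventional "within 2 AIC" reading); ``exact_penalty`` uses the
        exact IC gap two identical-fit models show under the active metric,
        which matters for AICc at small n.
    loglik_tol
        "Virtually identical log L" has no canonical cutoff; the default of
        1.0 log-likelihood unit per extra parameter is deliberately generous
        — signals 1 and 2 already confine the improvement below the penalty
        — so the final word rests with the estimate check (signal 4).
    require_ci_overlap_zero
        If false, signal 4 is skipped and signals 1-3 alone decide (verdict
        is then at most ``very_likely``).
    respect_interactions
        Retain (do not flag) pairs whose extra term participates in an
        interaction present in the complex model: a main effect can be
        informative only through its interaction.
    include_null_pairs
        Whether pairs whose simple member is the intercept-only model are
        screened; they satisfy the nesting definition, so default true.
    """

    ic_cutoff_mode: str = "fixed"
    ic_cutoff: float = 2.0
    loglik_tol: float = 1.0
    require_ci_overlap_zero: bool = True
    respect_interactions: bool = True
    include_null_pairs: bool = True

    def __post_init__(self) -> None:
        if self.ic_cutoff_mode not in ("fixed", "exact_penalty"):
            raise ValueError("ic_cutoff_mode must be 'fixed' or 'exact_penalty'")
        if self.ic_cutoff <= 0:
            raise ValueError("ic_cutoff must be positive")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be positive")


@dataclass(frozen=True)
class PairScreenResult:
    """Outcome of one nested pair's walk through the decision tree.

    Signals not reached because an earlier one failed are ``None``.
    ``signal4`` is True/False/"unassessable".  ``verdict`` is one of
    ``uninformative``, ``very_likely``, ``not_uninformative``,
    ``not_applicable`` (interaction retention rule).
    """

    pair: NestedPair
    ic_diff: float
    loglik_gain: float | None
    signal1: bool | None
    signal2: bool | None
    signal3: bool | None
    signal4: bool | str | None
    verdict: str
    term_diagnostics: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ScreenReport:
    """All pair results for a model set, plus the per-model flag map and the
    set-level verdict (has_UP / very_likely_UP / no_UP / insufficient_info)."""

    pair_results: tuple[PairScreenResult, ...]
    flagged: Mapping[str, frozenset[str]]
    set_verdict: str


def _cutoff(pair: NestedPair, ranked: RankedModelTable, config: ScreenConfig) -> float:
    if config.ic_cutoff_mode == "fixed":
        return config.ic_cutoff * pair.d
    metric = ranked.metric
    if metric.name == "reported":
        # no closed form for a verbatim IC column; fall back to the fixed rule
        return config.ic_cutoff * pair.d
    k_s = ranked[pair.simple_id].model.K
    k_c = ranked[pair.complex_id].model.K
    return metric.penalty(k_c) - metric.penalty(k_s)


def signal1_close_ic(pair: NestedPair, ranked: RankedModelTable,
                     config: ScreenConfig | None = None) -> bool:
    """Signal 1: the pair's IC values are within the cutoff of each other."""
    config = config or ScreenConfig()
    for mid in (pair.simple_id, pair.complex_id):
        if mid not in ranked:
            raise KeyError(f"pair member {mid!r} missing from ranked table")
    diff = abs(ranked[pair.complex_id].ic_value - ranked[pair.simple_id].ic_value)
    cutoff = _cutoff(pair, ranked, config)
    if config.ic_cutoff_mode == "exact_penalty":
        # cutoff and diff are the same quantity computed along two float
        # paths for identical-fit pairs; absorb the rounding gap
        cutoff += 1e-9
    return diff <= cutoff


def signal2_ranked_below(pair: NestedPair, ranked: RankedModelTable) -> bool:
    """Signal 2: the complex model is ranked strictly below the simple one
    (larger IC); an exact tie does not trip the signal."""
    return ranked[pair.complex_id].ic_value > ranked[pair.simple_id].ic_value


def signal3_similar_loglik(pair: NestedPair, models: Mapping[str, ModelRecord],
                           config: ScreenConfig | None = None) -> bool:
    """Signal 3: the log-likelihood improvement from the extra parameter(s)
    is within the tolerance (per extra parameter)."""
    config = config or ScreenConfig()
    gain = models[pair.complex_id].loglik - models[pair.simple_id].loglik
    if gain < -1e-6:
        warnings.warn(
            f"complex model {pair.complex_id!r} has lower log-likelihood than "
            f"nested simple model {pair.simple_id!r} (gain {gain:.4g}); possible "
            "non-nested fit or optimizer failure",
            stacklevel=2,
        )
    gain = max(gain, 0.0)
    return gain <= config.loglik_tol * pair.d


def signal4_null_estimate(term_estimates: Sequence) -> bool | str:
    """Signal 4: every available estimate for the extra term(s) has a CI
    overlapping zero; ``"unassessable"`` when no estimates are available.

    With partial information the signal is False as soon as any CI excludes
    zero, and unassessable otherwise.
    """
    ests = [e for e in term_estimates if e is not None]
    if not ests:
        return UNASSESSABLE
    if any(not e.contains_zero for e in ests):
        return False
    if len(ests) < len(term_estimates):
        return UNASSESSABLE
    return True


def _interaction_retained(pair: NestedPair, complex_model: ModelRecord) -> bool:
    """Extra main effect participating in an interaction kept in the complex
    model: the pair is exempt from flagging (retention rule)."""
    for term in pair.extra_terms:
        if ":" in term:
            continue  # the interaction itself is screened normally
        for t in complex_model.terms:
            if ":" in t and term in t.split(":"):
                return True
    return False


def screen_pair(pair: NestedPair, ranked: RankedModelTable,
                models: Mapping[str, ModelRecord] | Sequence[ModelRecord],
                config: ScreenConfig | None = None) -> PairScreenResult:
    """Walk one nested pair through the decision tree."""
    config = config or ScreenConfig()
    if not isinstance(models, Mapping):
        models = {m.model_id: m for m in models}
    complex_model = models[pair.complex_id]
    ic_diff = ranked[pair.complex_id].ic_value - ranked[pair.simple_id].ic_value
    gain = max(complex_model.loglik - models[pair.simple_id].loglik, 0.0)

    if config.respect_interactions and _interaction_retained(pair, complex_model):
        return PairScreenResult(pair=pair, ic_diff=ic_diff, loglik_gain=gain,
                                signal1=None, signal2=None, signal3=None,
                                signal4=None, verdict="not_applicable")

    s1 = signal1_close_ic(pair, ranked, config)
    if not s1:
        return PairScreenResult(pair=pair, ic_diff=ic_diff, loglik_gain=gain,
                                signal1=False, signal2=None, signal3=None,
                                signal4=None, verdict="not_uninformative")
    s2 = signal2_ranked_below(pair, ranked)
    if not s2:
        return PairScreenResult(pair=pair, ic_diff=ic_diff, loglik_gain=gain,
                                signal1=True, signal2=False, signal3=None,
                                signal4=None, verdict="not_uninformative")
    s3 = signal3_similar_loglik(pair, models, config)
    if not s3:
        return PairScreenResult(pair=pair, ic_diff=ic_diff, loglik_gain=gain,
                                signal1=True, signal2=True, signal3=False,
                                signal4=None, verdict="not_uninformative")

    if not config.require_ci_overlap_zero:
        return PairScreenResult(pair=pair, ic_diff=ic_diff, loglik_gain=gain,
                                signal1=True, signal2=True, signal3=True,
                                signal4=UNASSESSABLE, verdict="very_likely")

    diagnostics: dict[str, float] = {}
    per_term: list[bool | str] = []
    for term in sorted(pair.extra_terms):
        ests = complex_model.estimates_for_term(term)
        if not ests:
            per_term.append(None)
            continue
        for key, est in complex_model.estimates.items():
            if key == term or key.startswith(term + "="):
                diagnostics[key] = est.null_ratio
        per_term.append(signal4_null_estimate(ests))

    if all(v is None for v in per_term):
        s4: bool | str = UNASSESSABLE
    elif any(v is False for v in per_term):
        s4 = False
    elif any(v is None or v == UNASSESSABLE for v in per_term):
        s4 = UNASSESSABLE
    else:
        s4 = True

    if s4 is True:
        verdict = "uninformative"
    elif s4 == UNASSESSABLE:
        verdict = "very_likely"
    else:
        verdict = "not_uninformative"
    return PairScreenResult(pair=pair, ic_diff=ic_diff, loglik_gain=gain,
                            signal1=True, signal2=True, signal3=True,
                            signal4=s4, verdict=verdict,
                            term_diagnostics=diagnostics)


def screen_model_set(models: Sequence[ModelRecord],
                     metric: ICMetric | None = None,
                     config: ScreenConfig | None = None,
                     max_d: int = 2) -> ScreenReport:
    """Screen every eligible nested pair in a model set and aggregate.

    A model set ``has_UP`` as soon as one pair yields an uninformative
    verdict; ``very_likely_UP`` when the best evidence stops at signals 1-3;
    ``no_UP`` otherwise (including sets with no nested pairs, where
    uninformative parameters are impossible).
    """
    if len(models) == 0:
        raise ValueError("cannot screen an empty model set")
    config = config or ScreenConfig()
    ranked = rank_models(models, metric)
    by_id = {m.model_id: m for m in models}
    pairs = find_nested_pairs(models, max_d=max_d)
    if not config.include_null_pairs:
        pairs = [p for p in pairs if by_id[p.simple_id].terms]
    results = tuple(screen_pair(p, ranked, by_id, config) for p in pairs)

    flagged: dict[str, set[str]] = {}
    for res in results:
        if res.verdict == "uninformative":
            flagged.setdefault(res.pair.complex_id, set()).update(res.pair.extra_terms)
    flagged_frozen = {m: frozenset(t) for m, t in flagged.items()}

    if flagged_frozen:
        set_verdict = "has_UP"
    elif any(r.verdict == "very_likely" for r in results):
        set_verdict = "very_likely_UP"
    else:
        set_verdict = "no_UP"
    return ScreenReport(pair_results=results, flagged=flagged_frozen,
                        set_verdict=set_verdict)
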