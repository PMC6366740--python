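"""Article-level outcomes, reporting-standards linting, and review aggregation.

A literature audit records, per article, what the article reports (IC table,
K, log L, delta column, estimates with CIs, absolute goodness-of-fit) and —
where the reported tables allow it — a screen of its model set.  Each
article lands in exactly one of four outcomes:

* ``UP`` — at least one model carries a confirmed uninformative parameter
  (all four warning signals);
* ``very_likely_UP`` — warning signals 1-3 hold but the estimates needed
  for signal 4 are not reported;
* ``no_UP`` — every nested pair fails at least one assessable signal (or no
  nested pairs exist, where uninformative parameters are impossible);
* ``insufficient`` — no IC table, or nothing assessable.

The linter enforces the minimum reporting standard for IC model selection:
tables must carry K, log L, delta-IC, an absolute goodness-of-fit measure,
and parameter estimates with confidence intervals for all models.  It also
warns about two practices known to aggravate the uninformative-parameter
problem: model averaging by summed IC weights and stepwise IC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ic_core import RankedModelTable
from .screen import ScreenReport

__all__ = [
    "OUTCOMES",
    "ArticleRecord",
    "ReviewSummary",
    "classify_article",
    "lint_reporting",
    "make_tables",
    "summarize_review",
    "second_opinion",
    "round_half_up",
]

OUTCOMES = ("UP", "very_likely_UP", "no_UP", "insufficient")

#: abbreviated main-text tables keep models with delta below this
ABBREVIATED_DELTA_CUTOFF = 8.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (published tables round 0.5 up,
    unlike Python's banker's rounding)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ArticleRecord:
    """What one audited article reports, plus (optionally) its screen."""

    article_id: str
    journal: str
    has_ic_table: bool
    reports_K: bool = False
    reports_loglik: bool = False
    reports_delta: bool = False
    reports_estimates_ci: bool = False
    reports_gof: bool = False
    screen: ScreenReport | None = None
    outcome: str | None = None  # pre-assigned outcome (e.g. from an audit file)
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.screen is not None and not self.has_ic_table:
            raise ValueError(
                f"article {self.article_id!r}: a screen requires an IC table"
            )
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise ValueError(
                f"article {self.article_id!r}: unknown outcome {self.outcome!r}"
            )
        bad = set(self.flags) - {"model_averaging_summed_weights", "stepwise_ic"}
        if bad:
            raise ValueError(f"article {self.article_id!r}: unknown flag(s) {sorted(bad)}")


def classify_article(record: ArticleRecord) -> str:
    """Map an article to one of the four outcomes (total function)."""
    if record.outcome is not None:
        return record.outcome
    if not record.has_ic_table or record.screen is None:
        return "insufficient"
    verdict = record.screen.set_verdict
    if verdict == "has_UP":
        return "UP"
    if verdict == "very_likely_UP":
        return "very_likely_UP"
    if verdict == "insufficient_info":
        return "insufficient"
    return "no_UP"


_REQUIRED_ELEMENTS = (
    ("has_ic_table", "IC table not reported"),
    ("reports_K", "number of estimated parameters (K) not reported"),
    ("reports_loglik", "log-likelihood not reported"),
    ("reports_delta", "delta-IC column not reported"),
    ("reports_gof", "absolute goodness-of-fit measure not reported"),
    ("reports_estimates_ci", "parameter estimates with confidence intervals not reported"),
)

_FLAG_WARNINGS = {
    "model_averaging_summed_weights":
        "model averaging by summed IC weights overstates parameter importance; "
        "report per-model estimates instead",
    "stepwise_ic":
        "stepwise IC selection runs counter to a-priori multi-model inference "
        "and tends to inflate uninformative parameters",
}


def lint_reporting(subject: ArticleRecord | RankedModelTable | Sequence) -> list[str]:
    """Check the minimum reporting standard; returns violation/warning strings.

    Accepts an :class:`ArticleRecord` (audit metadata) or a ranked table /
    list of model records (checks the data actually present).
    """
    issues: list[str] = []
    if isinstance(subject, ArticleRecord):
        for attr, message in _REQUIRED_ELEMENTS:
            if not getattr(subject, attr):
                issues.append(f"violation: {message}")
        for flag in sorted(subject.flags):
            issues.append(f"warning: {_FLAG_WARNINGS[flag]}")
        return issues

    models = subject.models if isinstance(subject, RankedModelTable) else list(subject)
    if not models:
        return ["violation: IC table not reported"]
    if any(m.gof is None for m in models):
        issues.append("violation: absolute goodness-of-fit measure not reported")
    if any(not m.estimates for m in models if m.terms):
        issues.append("violation: parameter estimates with confidence intervals "
                      "not reported for all models")
    return issues


def make_tables(ranked: RankedModelTable, screen: ScreenReport | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Publication tables: the full model set and the abbreviated main-text
    version (delta below 8), both marking flagged uninformative terms."""
    from .io import ranked_table_frame

    flagged = screen.flagged if screen is not None else {}
    full = ranked_table_frame(ranked, flagged=flagged)
    # cut on unrounded deltas so a model at exactly 8.004 is not let through
    deltas = [r.delta for r in ranked.rows]
    keep = [d < ABBREVIATED_DELTA_CUTOFF for d in deltas]
    abbreviated = full[keep].reset_index(drop=True)
    return full, abbreviated


@dataclass(frozen=True)
class ReviewSummary:
    """Per-journal and total outcome counts with printed-style percentages.

    ``table`` has one row per journal plus a ``Total`` row; count columns
    ``n_articles, n_with_ic, n_UP, n_very_likely, n_no_UP, n_insufficient``
    and integer percentage columns (of articles using IC, except
    ``pct_with_ic`` which is of all articles).  ``composite_pct`` is the
    share of IC articles with confirmed or very likely uninformative
    parameters, at one decimal.
    """

    table: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.table[self.table["journal"] == "Total"].iloc[0]

    @property
    def ic_usage_pct(self) -> float:
        return float(self.totals["pct_with_ic"])

    @property
    def composite_pct(self) -> float:
        t = self.totals
        return round_half_up(100.0 * (t["n_UP"] + t["n_very_likely"]) / t["n_with_ic"], 1)


_OUTCOME_COLS = {"UP": "n_UP", "very_likely_UP": "n_very_likely",
                 "no_UP": "n_no_UP", "insufficient": "n_insufficient"}


def summarize_review(records: Sequence[ArticleRecord],
                     journal_totals: Mapping[str, int]) -> ReviewSummary:
    """Aggregate per-article outcomes into the review summary table.

    ``records`` are the articles that applied IC metrics; ``journal_totals``
    gives each journal's full article count for the usage percentage.
    Percentage cells are round-half-up integers of the per-journal IC-using
    article count, matching how such tables are printed.
    """
    for rec in records:
        if rec.journal not in journal_totals:
            raise ValueError(f"article {rec.article_id!r}: journal "
                             f"{rec.journal!r} not in journal totals")
    rows = []
    order = list(journal_totals)
    counts: dict[str, dict[str, int]] = {
        j: {c: 0 for c in _OUTCOME_COLS.values()} | {"n_with_ic": 0} for j in order
    }
    for rec in records:
        outcome = classify_article(rec)
        counts[rec.journal]["n_with_ic"] += 1
        counts[rec.journal][_OUTCOME_COLS[outcome]] += 1

    def _row(journal: str, n_articles: int, c: Mapping[str, int]) -> dict:
        n_ic = c["n_with_ic"]
        row = {"journal": journal, "n_articles": n_articles, "n_with_ic": n_ic,
               "pct_with_ic": int(round_half_up(100.0 * n_ic / n_articles)) if n_articles else 0}
        for col in _OUTCOME_COLS.values():
            row[col] = c[col]
            row["pct" + col[1:]] = int(round_half_up(100.0 * c[col] / n_ic)) if n_ic else 0
        return row

    for journal in order:
        rows.append(_row(journal, journal_totals[journal], counts[journal]))
    total_counts = {k: sum(counts[j][k] for j in order)
                    for k in next(iter(counts.values()))}
    rows.append(_row("Total", sum(journal_totals.values()), total_counts))
    return ReviewSummary(table=pd.DataFrame(rows))


def second_opinion(first: Mapping[str, str] | Sequence[ArticleRecord],
                   second: Mapping[str, str] | Sequence[ArticleRecord]
                   ) -> list[tuple[str, str, str]]:
    """Compare two independent article classifications.

    Returns ``(article_id, outcome_first, outcome_second)`` for every
    disagreement (including articles present in only one file, shown with
    outcome ``"missing"``), sorted by article id.  Reconciliation itself is a
    human step; this only surfaces what needs a second read.
    """
    def as_map(x) -> dict[str, str]:
        if isinstance(x, Mapping):
            return dict(x)
        return {rec.article_id: classify_article(rec) for rec in x}

    a, b = as_map(first), as_map(second)
    out = []
    for key in sorted(set(a) | set(b)):
        va, vb = a.get(key, "missing"), b.get(key, "missing")
        if va != vb:
            out.append((key, va, vb))
    return out
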