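"""CSV/JSON input and output.

The table dialects mirror what model-selection papers print:

* model table — ``model,terms,K,loglik[,gof][,ic]`` with ``terms`` a
  ``+``-separated list (interactions as ``A:B``); an empty terms cell is the
  intercept-only model.
* estimates table (long format) — ``model,term,estimate,ci_low,ci_high[,level]``
  with ``term=level`` rows for individual levels of a categorical term.
* ranked-table output — ``model,terms,K,loglik,IC,delta,weight[,gof]`` with
  IC and delta at 2 d.p. and weights at 3 d.p. (full precision is kept
  in memory; rounding happens only here).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ic_core import ModelRecord, ParameterEstimate, RankedModelTable
from .screen import ScreenReport

__all__ = [
    "read_model_table",
    "read_estimates",
    "attach_estimates",
    "write_ranked_table",
    "ranked_table_frame",
    "screen_report_frame",
    "write_screen_report",
    "atomic_write_text",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _parse_terms(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text or text in ("1", "~1", "(null)"):
        return frozenset()
    return frozenset(t.strip() for t in text.split("+") if t.strip())


def read_model_table(path: str | Path) -> list[ModelRecord]:
    """Read a model-summary CSV into :class:`ModelRecord` objects."""
    df = pd.read_csv(path, encoding="utf-8")
    required = {"model", "K", "loglik"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ModelRecord(
                    model_id=str(row["model"]),
                    terms=_parse_terms(row.get("terms")),
                    K=int(row["K"]),
                    loglik=float(row["loglik"]),
                    gof=None if "gof" not in df.columns or pd.isna(row["gof"]) else float(row["gof"]),
                    ic=None if "ic" not in df.columns or pd.isna(row["ic"]) else float(row["ic"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from None
    return records


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    required = {"model", "term", "estimate", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def attach_estimates(models: Sequence[ModelRecord], estimates: pd.DataFrame) -> list[ModelRecord]:
    """Return copies of ``models`` with estimates from a long-format table."""
    from dataclasses import replace

    known = {m.model_id for m in models}
    unknown = set(estimates["model"].astype(str)) - known
    if unknown:
        raise ValueError(f"estimates reference unknown model id(s): {sorted(unknown)}")
    by_model: dict[str, dict[str, ParameterEstimate]] = {}
    for _, row in estimates.iterrows():
        level = float(row["level"]) if "level" in estimates.columns and not pd.isna(row.get("level")) else 0.95
        by_model.setdefault(str(row["model"]), {})[str(row["term"])] = ParameterEstimate(
            estimate=float(row["estimate"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
            level=level,
        )
    return [replace(m, estimates=by_model.get(m.model_id, {})) for m in models]


def ranked_table_frame(ranked: RankedModelTable, flagged: Mapping[str, frozenset] | None = None) -> pd.DataFrame:
    """Ranked table as a DataFrame at output precision; optionally marks
    flagged (uninformative) terms per model."""
    rows = []
    for r in ranked.rows:
        m = r.model
        rec = {
            "model": m.model_id,
            "terms": "+".join(sorted(m.terms)),
            "K": m.K,
            "loglik": m.loglik,
            "IC": round(r.ic_value, 2),
            "delta": round(r.delta, 2),
            "weight": round(r.weight, 3),
        }
        if m.gof is not None:
            rec["gof"] = m.gof
        if flagged is not None:
            rec["uninformative_terms"] = "+".join(sorted(flagged.get(m.model_id, ())))
        rows.append(rec)
    return pd.DataFrame(rows)


def write_ranked_table(ranked: RankedModelTable, path: str | Path) -> None:
    atomic_write_text(path, ranked_table_frame(ranked).to_csv(index=False))


def screen_report_frame(report: ScreenReport) -> pd.DataFrame:
    """Per-pair screen results: one row per nested pair."""
    def fmt(v):
        return "" if v is None else str(v).lower() if isinstance(v, bool) else str(v)

    rows = []
    for res in report.pair_results:
        rows.append({
            "simple": res.pair.simple_id,
            "complex": res.pair.complex_id,
            "extra_terms": "+".join(sorted(res.pair.extra_terms)),
            "d": res.pair.d,
            "ic_diff": round(res.ic_diff, 2),
            "loglik_gain": "" if res.loglik_gain is None else round(res.loglik_gain, 2),
            "s1": fmt(res.signal1),
            "s2": fmt(res.signal2),
            "s3": fmt(res.signal3),
            "s4": fmt(res.signal4),
            "verdict": res.verdict,
        })
    return pd.DataFrame(rows, columns=["simple", "complex", "extra_terms", "d",
                                       "ic_diff", "loglik_gain",
                                       "s1", "s2", "s3", "s4", "verdict"])


def write_screen_report(report: ScreenReport, csv_path: str | Path,
                        json_path: str | Path | None = None) -> None:
    """Write the per-pair CSV and a summary JSON (flag map + set verdict)."""
    atomic_write_text(csv_path, screen_report_frame(report).to_csv(index=False))
    if json_path is None:
        json_path = Path(csv_path).with_suffix(".json")
    summary = {
        "set_verdict": report.set_verdict,
        "flagged": {m: sorted(t) for m, t in sorted(report.flagged.items())},
        "n_pairs": len(report.pair_results),
    }
    atomic_write_text(json_path, json.dumps(summary, indent=2) + "\n")
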