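"""Nested-pair detection over a candidate model set.

Uninformative parameters can only arise where a model set contains more
complex versions of simpler models, i.e. nested pairs: the complex model's
term set strictly contains the simple model's.  This module finds every such
pair whose K difference is within the screening range (one or two extra
estimated parameters by default) and decides whether a set is screenable at
all — many published sets are not, e.g. a handful of mutually non-nested
hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .ic_core import ModelRecord

__all__ = ["NestedPair", "find_nested_pairs", "is_screenable", "expand_terms"]


@dataclass(frozen=True)
class NestedPair:
    """An ordered (simple, complex) model pair related by term-set inclusion.

    ``extra_terms`` are the complex model's terms absent from the simple one;
    ``d`` is the difference in K (which can exceed ``len(extra_terms)`` when
    an extra term is a multi-level factor).
    """

    simple_id: str
    complex_id: str
    extra_terms: frozenset[str]
    d: int

    def __post_init__(self) -> None:
        if not self.extra_terms:
            raise ValueError("a nested pair must have at least one extra term")
        if self.d < 1:
            raise ValueError("K difference d must be >= 1")


def expand_terms(terms: frozenset[str]) -> frozenset[str]:
    """Close a term set under interaction hierarchy: a model containing the
    interaction ``A:B`` is treated as containing A and B."""
    out = set(terms)
    for t in terms:
        if ":" in t:
            out.update(p for p in t.split(":") if p)
    return frozenset(out)


def find_nested_pairs(
    models: Sequence[ModelRecord],
    max_d: int = 2,
    respect_hierarchy: bool = True,
) -> list[NestedPair]:
    """All (simple, complex) pairs with subset terms and K difference <= max_d.

    Subset comparison uses hierarchy-expanded term sets when
    ``respect_hierarchy`` is set, so ``{A, A:B}`` nests ``{A, B}``-style
    supersets correctly.  ``extra_terms`` are reported on the raw term sets.
    Pairs come back sorted by (simple_id, complex_id).
    """
    if max_d < 1:
        raise ValueError("max_d must be >= 1")
    for m in models:
        if m.terms is None:
            raise ValueError(
                f"model {m.model_id!r} has no term set; pair detection needs "
                "terms — provide the 'terms' column (long-format input)"
            )
    pairs: list[NestedPair] = []
    for simple in models:
        s_terms = expand_terms(simple.terms) if respect_hierarchy else simple.terms
        for complex_ in models:
            if complex_.model_id == simple.model_id:
                continue
            c_terms = expand_terms(complex_.terms) if respect_hierarchy else complex_.terms
            if not (s_terms < c_terms):
                continue
            d = complex_.K - simple.K
            if d < 1 or d > max_d:
                continue
            extra = complex_.terms - simple.terms
            if not extra:
                continue
            pairs.append(
                NestedPair(
                    simple_id=simple.model_id,
                    complex_id=complex_.model_id,
                    extra_terms=frozenset(extra),
                    d=d,
                )
            )
    pairs.sort(key=lambda p: (p.simple_id, p.complex_id))
    return pairs


def is_screenable(models: Sequence[ModelRecord], max_d: int = 2) -> tuple[bool, str]:
    """Whether a model set can harbour uninformative parameters at all.

    Returns ``(False, reason)`` when no nested pair exists — e.g. non-nested
    hypothesis sets or an empty set — and ``(True, ...)`` otherwise.
    """
    if len(models) == 0:
        return False, "empty model set"
    if not find_nested_pairs(models, max_d=max_d):
        return False, "no nested pairs"
    return True, "nested pairs present"
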