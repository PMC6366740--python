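"""A deliberately naive re-implementation of the screen, used as an oracle.

Enumerates every ordered model pair, checks the subset relation and the K
difference directly, and evaluates all four warning signals without
short-circuiting, with plain loops and no shared code with the package's
screening path beyond the data containers.
"""

from __future__ import annotations


def naive_screen(models, ic_cutoff=2.0, loglik_tol=1.0, max_d=2):
    """Return (pair_verdicts, flagged, set_verdict) the slow way.

    pair_verdicts: {(simple_id, complex_id): verdict}
    """
    ic = {m.model_id: -2.0 * m.loglik + 2.0 * m.K for m in models}
    by_id = {m.model_id: m for m in models}

    pair_verdicts = {}
    for a in models:
        for b in models:
            if a.model_id == b.model_id:
                continue
            if not (set(a.terms) < set(b.terms)):
                continue
            d = b.K - a.K
            if d < 1 or d > max_d:
                continue
            extra = set(b.terms) - set(a.terms)

            s1 = abs(ic[b.model_id] - ic[a.model_id]) <= ic_cutoff * d
            s2 = ic[b.model_id] > ic[a.model_id]
            s3 = max(b.loglik - a.loglik, 0.0) <= loglik_tol * d

            statuses = []
            for term in extra:
                ests = [e for key, e in b.estimates.items()
                        if key == term or key.startswith(term + "=")]
                if not ests:
                    statuses.append("missing")
                elif all(e.ci_low <= 0.0 <= e.ci_high for e in ests):
                    statuses.append("zero")
                else:
                    statuses.append("nonzero")
            if all(s == "missing" for s in statuses):
                s4 = "unassessable"
            elif "nonzero" in statuses:
                s4 = False
            elif "missing" in statuses:
                s4 = "unassessable"
            else:
                s4 = True

            if not (s1 and s2 and s3):
                verdict = "not_uninformative"
            elif s4 is True:
                verdict = "uninformative"
            elif s4 == "unassessable":
                verdict = "very_likely"
            else:
                verdict = "not_uninformative"
            pair_verdicts[(a.model_id, b.model_id)] = verdict

    flagged = {}
    for (simple_id, complex_id), verdict in pair_verdicts.items():
        if verdict == "uninformative":
            extra = set(by_id[complex_id].terms) - set(by_id[simple_id].terms)
            flagged.setdefault(complex_id, set()).update(extra)

    if flagged:
        set_verdict = "has_UP"
    elif any(v == "very_likely" for v in pair_verdicts.values()):
        set_verdict = "very_likely_UP"
    else:
        set_verdict = "no_UP"
    return pair_verdicts, flagged, set_verdict
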