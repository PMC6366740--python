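# Methods

## The screening procedure

`upscreen` treats a candidate model set as data: one row per fitted model
with its term set, reported parameter count K, maximised log-likelihood, and
(optionally) per-term estimates with confidence intervals. The screen never
refits models — it judges what a table reports, which is the posture of a
reader, reviewer, or editor.

**Nesting.** A pair (simple, complex) is eligible when the simple model's
terms are a strict subset of the complex model's and the K difference `d`
is at most `max_d` (default 2). Nesting is decided on term sets, not K:
a multi-level categorical factor can make `d` exceed the number of extra
terms, and the IC cutoff then scales with `d`, not with the term count.
Term sets are closed under interaction hierarchy — a model containing `A:B`
is treated as containing `A` and `B` — so interaction models nest their
main-effect counterparts. K itself is taken as given in the input and never
recounted from the term list: published tables use conventions (scale
parameters, factor codings) the term list cannot reveal, and a missing or
implausible K is a reporting defect for the linter, not something to repair
silently.

**The four signals**, evaluated in sequence with short-circuiting (a pair
that fails signal *i* has signals *i*+1… unasserted):

1. *Close IC.* |IC(complex) − IC(simple)| ≤ cutoff, over **all** pairs, not
   just near the top of the ranking, because collinearity can make a
   parameter uninformative in one model and not another. In `fixed` mode
   the cutoff is `ic_cutoff × d` (default 2 per extra parameter); in
   `exact_penalty` mode it is the exact IC gap two identical-fit models
   would show under the active metric, which exceeds 2`d` for AICc at small
   n. A 1e-9 slack absorbs floating-point differences between the gap and
   the cutoff computed along different paths.
2. *Ranked below.* IC(complex) > IC(simple), strictly; a tie is treated as
   "not below" since an extra parameter that exactly pays for itself is
   already ambiguous evidence.
3. *Similar log-likelihood.* gain = log L(complex) − log L(simple) ≤
   `loglik_tol × d`. There is no canonical cutoff for "virtually
   identical"; the default tolerance of 1.0 per extra parameter is
   deliberately generous — signals 1–2 for d = 1 already confine the gain
   to [0, 1) — and exists mainly so that signal 4, the estimate check, gets
   the final word. A tighter default (e.g. 0.5) would contradict the
   packaged worked example, where a pair with gain 0.55 is correctly
   flagged. A negative gain (complex fitting worse than its nested simple
   model) indicates a non-nested fit or optimizer failure; it is floored at
   zero and a warning is emitted.
4. *Null estimate.* "Near zero" is operationalised as the testable half of
   the criterion: every extra term's CI contains 0. No numeric "near zero"
   threshold exists in practice, so the magnitude diagnostic
   |estimate| / CI-half-width is reported per term but does not decide the
   verdict. Multi-level categorical terms supply one estimate per level
   (`term=level` keys); the verdict requires *every* level's CI to contain
   0, and per-level diagnostics are preserved so mixed cases (one level
   informative, others not) stay visible. With no estimates at all the
   signal is *unassessable*; with partial estimates it is False as soon as
   any CI excludes zero, else unassessable.

**Verdicts.** All four signals true → `uninformative`; 1–3 true with
signal 4 unassessable → `very_likely`; any failure → `not_uninformative`.
Pairs whose extra main effect participates in an interaction retained by the
complex model are `not_applicable`: a main effect can be informative only
through its interaction, so it is exempt from flagging (the interaction term
itself, when it is the extra term, is screened normally). Pairs whose simple
member is the intercept-only model satisfy the nesting definition and are
screened by default (`include_null_pairs=False` excludes them).

A term is recorded in the flag map only for pairs with a full
`uninformative` verdict; the same term may simultaneously be informative in
another pair, and the per-pair report preserves both outcomes. The set-level
verdict is `has_UP` the moment one pair is uninformative, `very_likely_UP`
when the best evidence stops at signals 1–3, and `no_UP` otherwise —
including sets with no nested pairs, where uninformative parameters are
structurally impossible.

## IC metrics

AIC = −2 log L + 2K; AICc adds (2K² + 2K)/(n − K − 1) and requires
n > K + 1 (violations raise an error naming the model). QAIC divides
−2 log L by an overdispersion estimate ĉ ≥ 1 and QAICc adds the AICc
correction; no formula for the quasi-likelihood variants is universal, and
this choice follows standard practice with K taken as reported. The
`reported` metric ranks by an IC column supplied verbatim in the input —
needed because articles routinely print AICc values without the n behind
them, and the screen's job is to judge what is printed. Ranking ties break
by smaller K (parsimony) then lexicographic model id, so output is
deterministic across platforms. Akaike weights are exp(−Δ/2) normalised
over the set. IC values are carried at full precision and rounded only in
written tables (IC/Δ to 2 d.p., weights to 3 d.p.).

McFadden's pseudo-R² (1 − log L(model)/log L(null)) is provided as the
absolute goodness-of-fit measure for likelihood models; the packaged worked
example's printed pseudo-R² column is inconsistent with this formula applied
to its own printed log-likelihoods (likely a different variant or an
unprinted null), so tests assert the formula, not the printed column.

## Article outcomes and review aggregation

An audited article maps to exactly one of four outcomes: `UP` (some model
set pair shows all four signals), `very_likely_UP` (signals 1–3 but
estimates unreported), `no_UP` (every nested pair fails at least one
assessable signal, or no nested pairs exist), `insufficient` (no IC table or
nothing assessable). Review aggregation counts outcomes per journal against
the journal's AIC-using article count, with percentage cells as round-half-up
integers (matching how such tables are printed; banker's rounding would
disagree on ties like 1/22 = 4.5%) and composite headline rates at one
decimal. The two-reviewer reconciliation used in practice is a human step;
`second_opinion` diffs two classification files and lists the disagreements
needing a second read.

The linter enforces the minimum reporting standard — IC table with K,
log L, ΔIC, an absolute goodness-of-fit measure, and estimates with CIs for
all models — and warns on two practices that aggravate the problem: model
averaging by summed IC weights and stepwise IC selection. Neither practice
is implemented; the package flags them only. Abbreviated main-text tables
keep models with Δ < 8, with the full flagged table intended for a
supplement.

## The simulation engine

`simulate` manufactures the statistical situation the screen targets:
datasets with known true coefficients and "null" covariates whose
coefficient is exactly zero, candidate ML fits, and replicate-level signal
rates.

* **Design.** Covariates are i.i.d. standard normal; an optional
  equicorrelation `rho` introduces collinearity (which can change a
  parameter's status between models). Families: gaussian (identity link),
  binomial (logit), Poisson (log). Defaults define the reference operating
  point: n = 500 gaussian observations, one true effect of β = 1 (one
  residual SD per covariate SD), one null covariate, 2000 replicates —
  large enough that the Wilks asymptotics hold to Monte-Carlo precision and
  small enough to run in seconds.
* **Fitting.** Gaussian models are fit by OLS so the reported log-likelihood
  is the ML profile likelihood (2·Δlog L ~ χ²₁ under the null requires this;
  a moment-based scale estimate would break it); binomial and Poisson use
  IRLS GLM. K counts coefficients plus the gaussian residual variance. CIs
  are 95% Wald intervals (estimate ± z·SE) — cheap and the form most papers
  report; profile-likelihood intervals are a documented non-goal.
  Non-convergent or degenerate fits drop the whole replicate, which is
  counted and reported, never imputed.
* **Candidate sets.** Each replicate fits the simple model (all true
  terms), one augmented model per null term (measuring the null-term signal
  rates), and one reduced model per true term (measuring the false-flag
  rate on genuine effects).
* **Rates.** Signals are evaluated unconditionally (no short-circuit) so
  each rate is a marginal probability; the full-flag rate is their
  conjunction, which coincides with the sequential verdict. Monte-Carlo
  standard errors are √(p(1−p)/N). Expected values at the reference point:
  signal 1 ≈ P(χ²₁ ≤ 4) = 0.954, signal 2 ≈ P(χ²₁ < 2) = 0.843, signal 4
  ≈ 0.95 (nominal CI coverage).
* **Reproducibility.** One root seed; replicate r draws from the
  independent stream keyed (seed, r), so experiments are deterministic,
  order-independent and parallelisable.

What the generator does *not* emulate: model misspecification, non-linear
relationships, random effects, measurement error, or overdispersion beyond
the quasi-likelihood correction. Passing tests therefore demonstrate the
screen's behaviour when the model family is correct and effects are linear;
on real data a parameter flagged by all four signals can still be
informative through a non-linearity or an interaction, which is exactly why
the interaction-retention rule and the per-level categorical reporting
exist.

## Numerical and testing choices

Tolerances: weights sum to 1 within 1e-9; the worked example's delta column
is reproduced within 0.01 (the precision of its printed log-likelihoods);
the distributional check of 2·Δlog L against χ²₁ uses a Kolmogorov–Smirnov
test at α = 0.001 so that a correct implementation essentially never fails
it by chance. The screening path is verified against a deliberately naive
oracle — enumerate every ordered pair, test the subset relation directly,
evaluate all four rules without short-circuiting — on randomized model
sets. The simulation suite shares one 2000-replicate reference run across
its checks.

## Known limitations

* The screen consumes reported summaries; it cannot recover missing
  log-likelihoods or refit anything, and `reported`-metric screening trusts
  the printed IC column.
* Equivalent reparameterizations (same column space, different term names)
  are not detected; term naming must be consistent across models.
* Wald CIs can misbehave near boundaries (logistic separation); such fits
  are dropped in simulation but cannot be detected in reported tables.
* BIC/DIC/WAIC and model averaging of estimates are out of scope by design;
  the linter warns where averaging by summed weights is flagged.
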