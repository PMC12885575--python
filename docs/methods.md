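# Methods

## The problem

A binary time-varying covariate (TVC) switches 0 → 1 at most once per
subject, at an observable time (transplant after cell therapy, onset of
chronic graft-versus-host disease, treatment response). The estimand is the
hazard ratio `e^β` of the exposed state. Three estimators are implemented
side by side:

* **Naive Cox/KM** — classifies subjects by *ever-exposed* status
  `x_fix = 1{TVC ever changed}` as if it were known at baseline. Eventual
  changers cannot fail before their change time, so person-time that is
  really unexposed is credited to the exposed group ("immortal time"); the
  estimate is biased toward lower hazard for the exposed group, in every
  regime. It is included because it is what the toolkit warns against.
* **Landmark Cox/KM** — fixes a landmark `T*`, drops subjects not at risk
  strictly beyond `T*`, classifies by TVC status *at* `T*` (later changes
  ignored), restarts the clock at `T*`. Unbiased only in restricted
  settings; sensitive to the choice of `T*`. Defaults for `T*`: the median
  and the 0.95 quantile of observed change times (type-7 linear-interpolated
  quantiles).
* **TD Cox** — the covariate enters at its current value via
  counting-process intervals; consistent for an external TVC.

## Data model

Wide input is one row per subject: follow-up time `t > 0`, event indicator,
and an optional change time `s`. Normalization enforces `0 ≤ s < t`: a
change recorded at or after the end of follow-up can never contribute
exposed risk time and is coerced to "never changed" (with a warning and a
count). Intervals are half-open `(start, stop]`; the covariate value applies
at `stop` and the event is attributed to the interval containing it. A
changer becomes `(0, s]` unexposed + `(s, t]` exposed; `s = 0` yields a
single exposed interval. Subjects with `t == T*` are excluded from the
landmark cohort (they must be at risk strictly beyond the landmark). Times
are never rescaled or unit-converted.

## Cox engine

Single-covariate partial likelihood on `(start, stop]` rows; the risk set at
an event time `u` is `{start < u ≤ stop}`. Risk-set sums are computed by
suffix sums over stop- and start-sorted copies (`O(n log n)` per
evaluation), so each Newton iteration is vectorized. Ties: Efron by default
(essentially exact for the light tie patterns of continuous follow-up);
Breslow available and used in the hand-checked oracles. Newton starts at
`β = 0`, tolerance 1e-9 on the score, at most 25 iterations, with
step-halving whenever a step would decrease the likelihood.

Degenerate data fail loudly rather than silently:

* no events → error (the likelihood is undefined);
* covariate constant over all rows, or constant within every risk set
  (zero observed information at `β = 0`, which for a binary covariate
  implies a flat likelihood everywhere) → error;
* monotone or near-monotone likelihood → the fit is returned flagged
  `converged=False`. Detection: the score tolerance is not met within the
  iteration budget, **or** the iteration terminates beyond `|β| > 15`
  (a hazard ratio beyond `e^15`; on near-separated data Newton can satisfy
  the score tolerance at an arbitrarily large `|β|` that depends only on
  the iteration history, which is a silent wrong number, not an estimate).

Inference is Wald-only (SE from the inverse observed information; 95% CI on
the HR scale; two-sided p). The Breslow baseline cumulative hazard is
`H0(t) = Σ_{t_k ≤ t} d_k / Σ_{at risk} e^{β̂ x_i}`, reducing to Nelson–Aalen
at `β̂ = 0`. The proportional-hazards check is the 1-df score test of the
interaction `x·g(t)` with the identity transform `g(t) = t`, evaluated at
`(β̂, 0)` — equivalent to regressing Schoenfeld residuals on time. It is
reported, never used to auto-reject a model; under proportional hazards its
type-I error at α = 0.05 is verified by simulation to stay near nominal.

## Curves

Nonparametric curves carry Greenwood pointwise variance
(`S² Σ d/(n(n−d))`) and a 95% CI computed on the log-survival scale,
truncated to [0, 1]. Extended KM updates the group risk sets
`n_g(t) = #{(start, stop] ∋ t, tvc = g}` dynamically; its Greenwood-form
variance uses those dynamic counts and is approximate (group membership is
time-varying). Smith-Zee curves are evaluated as step functions at the
baseline event times (plus `t_change`), without smoothing; confidence bands
are not drawn for the hypothetical-patient curves. The default `t_change`
is the median observed change time, mirroring the landmark default.

## Simulator

Weibull throughout, **shape/rate convention**: survival
`S(t) = exp(-λ t^α)`. This is *not* numpy's or scipy's shape/scale
parameterization (`rate = scale^{-shape}`); the shape α governs timing
(α < 1 front-loads occurrences, α > 1 delays them), which is exactly the
axis that drives immortal-time bias. The change time
`T_TVC ~ Weibull(α_TVC, λ_TVC)` is independent of the latent event process
(external covariate). Event times invert the piecewise cumulative hazard in
closed form: with target `H = −ln U`,

    t = (H/λ_E)^{1/α_E}                                   if H ≤ λ_E s^{α_E}
    t = [s^{α_E} + (H − λ_E s^{α_E})/(λ_E e^β)]^{1/α_E}    otherwise.

Defaults are the standard study conditions for this design: `n = 1000`,
`λ_E = 0.005`, `λ_TVC = 0.05`, 100 replicates, **no censoring** (an
administrative horizon and an independent exponential rate are exposed as
options but off by default). A change is recorded only if it strictly
precedes the observed end of follow-up.

The bias experiment fits all three models per replicate; the landmark time
is recomputed from each replicate's own change times when the rule is
median/q95. Replicates where a method fails (non-convergence, empty
landmark cohort, constant covariate) are excluded *for that method* and
counted. Reported per method: mean log-HR bias, empirical SD, Monte-Carlo
SE = SD/√reps, and 95% CI coverage. The contour grid reports mean HR-scale
bias `mean(e^{β̂}) − e^{β_true}` per `(α_E, α_TVC)` cell. One master seed
spawns per-replicate (and per-cell) substreams, so experiments are
reproducible and order-independent.

What the generator does *not* emulate: covariate-dependent or informative
censoring, internal covariates (TVC influenced by treatment), multiple
switches per subject, non-Weibull hazards. Passing tests therefore
demonstrate correctness of the estimators under an external single-switch
TVC with independent censoring — not robustness to violations of those
assumptions.

## Parametric likelihood and MLE

The five-parameter likelihood follows from the generating process. With
`f_TVC(s) = λ_T α_T s^{α_T−1} e^{−λ_T s^{α_T}}` and baseline event hazard
`h0(t) = λ_E α_E t^{α_E−1}`:

| subject | contribution to the log likelihood |
|---|---|
| changer at `s`, event at `t` | `ln f_TVC(s) + β + ln h0(t) − [λ_E s^{α_E} + e^β λ_E (t^{α_E} − s^{α_E})]` |
| changer at `s`, censored at `t` | same without the `β + ln h0(t)` term |
| non-changer, event at `t` | `−λ_T t^{α_T} + ln h0(t) − λ_E t^{α_E}` |
| non-changer, censored at `t` | `−λ_T t^{α_T} − λ_E t^{α_E}` |

The non-changer term `−λ_T t^{α_T}` is `ln P(T_TVC > t)`: a change was
never observed during follow-up. Censoring is treated as noninformative and
its distribution is not modeled — it factors out of the likelihood. β
enters only through changer terms, so at least one changer (and one event)
is required for identifiability. A change time of exactly 0 is rejected:
the continuous change-time density is degenerate there (the
counting-process/Cox path accepts it).

Optimization is L-BFGS-B on `(ln α_E, ln λ_E, ln α_T, ln λ_T, β)` —
positivity by construction, β free — from a moment-based start (exponential
working models) plus four seeded perturbations; the best of five local
optima is returned. The likelihood is verified against numerical quadrature
of the hazard-based likelihood to 1e-6. Standard errors come from the
central-difference Hessian on the natural scale; a non-invertible Hessian
flags the SEs absent rather than fabricating them.

The scenario verdict maps the fitted shapes to the expected naive-bias
regime: `α_TVC ≤ 0.5` and `α_E ≥ 1.5` → minimal naive bias (TVC early,
events late); `α_TVC ≥ 1` or `α_E ≤ 1` → large naive bias, underestimating
the exposed-group hazard; estimates sitting exactly on a threshold are
flagged borderline, and a non-converged fit yields "indeterminate".

## Problem sizes used in the checks

The simulation checks run 100 replicates of n = 1,000 per scenario over
`(α_E, α_TVC) ∈ {(1.5, 0.5), (0.5, 1.5)}` and
`β ∈ {−0.7, 0, 0.7}`; MLE recovery uses 20 cohorts of n = 2,000; the
sampling-law check uses one cohort of n = 10,000; the grid-search oracle
uses 30 cohorts of n ≤ 8 with a β-grid step of 1e-4. These sizes give
Monte-Carlo standard errors small enough that the bias and coverage
assertions are informative (3-SE bands of about ±0.02 on the log-HR scale
in the well-behaved regime).

## Known limitations

* Single external binary TVC only: no multiple switches, no internal
  covariates, no multivariable adjustment, no delayed entry, no competing
  risks, no stratification or robust variance.
* Wald inference only; no likelihood-ratio or score intervals.
* The Extended KM variance is approximate (documented above).
* In the late-TVC/early-events regime with no censoring, almost all
  subjects eventually change; the naive fit is then frequently
  near-separated and is reported as non-converged — this is a property of
  the naive method in that regime, not of the engine.
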