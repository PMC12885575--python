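# survtvc

Survival analysis with a single **binary time-varying covariate (TVC)** —
an exposure that switches on at some point after baseline, or never:
a transplant received months after CAR-T infusion, chronic graft-versus-host
disease after allotransplant, treatment response, B-cell recovery.

Analyzing such an exposure as if it were known at baseline (the *naive*
Cox model or Kaplan-Meier curve by ever-exposed status) misclassifies the
pre-exposure period of eventual changers as exposed. During that period
they are necessarily event-free — "immortal" — so the naive hazard ratio is
systematically dragged toward *lower* hazard for the exposed group.
`survtvc` implements the full comparison toolkit:

* **Models** — naive Cox, landmark Cox (cohort re-based at a landmark time
  `T*`), and the time-dependent (TD) Cox model on counting-process
  `(start, stop]` data, all through one Newton–Raphson partial-likelihood
  engine (Efron or Breslow ties, Wald inference, Breslow baseline cumulative
  hazard, Schoenfeld-residual proportional-hazards score test).
* **Curves** — naive KM, landmark KM, Extended KM (risk sets updated
  dynamically as subjects' TVC status changes) and **Smith-Zee** curves:
  model-based survival for hypothetical patients whose TVC changes at a
  prespecified `t_change`,

  `S1(t) = exp(-[H0(min(t, t_change)) + e^β (H0(t) - H0(t_change))_+])`.

* **Simulator** — a Weibull data-generating process (`S(t) = exp(-λ t^α)`,
  shape/rate convention) with event hazard multiplied by `e^β` after an
  independently Weibull-distributed change time, plus Monte-Carlo bias and
  coverage experiments across the three models and `(α_E, α_TVC)` contour
  grids of naive HR bias.
* **Estimation** — a five-parameter maximum-likelihood fit
  `(α_E, λ_E, α_TVC, λ_TVC, β)` recovering the generating process directly
  from an observed cohort, with a diagnostic verdict on whether naive-method
  bias is expected to be minimal (TVC changes early, events late) or large
  (TVC late or events early).

## Worked example

A synthetic registry-like cohort in which the TVC changes late and events
occur early — the regime where immortal-time bias is worst:

```sh
survtvc fixtures --name cs_like_late_tvc --seed 0 --out cohort.csv
survtvc analyze --input cohort.csv --out results/
```

prints (and writes to `results/report.csv`):

```
      method  landmark_time       hr   ci_low   ci_high      p_value  n_used  n_events  converged         ph_p error
   naive_cox            NaN 0.206638 0.146646  0.291173 2.035081e-19     400       271       True 1.495013e-10  None
landmark_cox      23.330177 1.154306 0.690046  1.930920 5.846141e-01     202        73       True 3.662894e-01  None
landmark_cox      56.031574 2.537013 0.263895 24.390170 4.200980e-01     133         4       True 2.298690e-01  None
      td_cox            NaN 1.039332 0.704633  1.533010 8.457490e-01     400       271       True 1.768258e-01  None
```

The cohort was generated with **no true effect** (HR = 1). The TD Cox model
recovers that (HR 1.04, p = 0.85); the naive model reports a wildly
significant protective effect (HR 0.21, p ≈ 2e-19) — pure immortal-time
bias — and the landmark fits drift with the landmark time and discard up to
two thirds of the cohort. `results/curves.csv` holds all four curve
families (naive KM, landmark KM, Extended KM, Smith-Zee) in tidy form;
`--plot` renders them as PNGs.

The same comparison is available programmatically:

```python
import survtvc as sv

cohort = sv.read_subject_table("cohort.csv")      # id, time, status, tvc_time
report = sv.comparison_report(cohort)             # naive / landmark / TD rows
rows   = sv.to_counting_process(cohort)           # (start, stop] long format
fit    = sv.fit_cox(rows)                         # TD Cox log HR
mle    = sv.fit_weibull_tvc_mle(cohort)           # recover the Weibull-TVC DGP
print(sv.diagnose_scenario(mle))                  # expected naive-bias regime
```

Other subcommands: `survtvc simulate` (generate cohorts), `survtvc bias`
(bias/coverage experiments and contour grids), `survtvc estimate`
(parametric MLE + verdict).

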