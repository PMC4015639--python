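# Methods

## Model and assumptions

The package evaluates, per patient tested, the expected effectiveness and
third-party-payer cost of two diagnostic work-ups for hemodynamically
significant coronary artery disease (CAD), as expectations over a decision
tree driven by Bayes' theorem: the post-test composition of every branch is
determined by the pre-test likelihood `P_isch` and the test operating
characteristics. The model is deliberately a *diagnostic* cost model:
treatment ("downstream") costs, pre-test work-up ("upstream") costs,
radiation-induced malignancy risk, intangible costs of cardiac death, and
QALY/utility weighting are all out of scope. Effectiveness counts only
correct positive diagnoses (true positives with full coronary anatomy);
correct negatives enter indirectly through the avoided false-negative
complication costs.

Key structural assumptions, each of which shapes the closed forms:

* **Invasive reference accuracy.** CXA (≥50% diameter stenosis) and FFR
  (ischemia if ≤0.75) are the reference tests with accuracy 1, so strategy 2
  misclassifies nobody and its effectiveness is `P_isch` exactly. To the
  extent real FFR misclassifies, this biases against the CMR-first strategy.
* **Non-diagnostic cross-over.** A fraction `NDx` of CMR examinations is
  non-diagnostic, independent of disease status (the evidence base is silent
  on any dependence). Those patients pay the CMR fee plus the full invasive
  work-up and are diagnosed with reference accuracy; they do not face the
  false-negative pathway.
* **No FFR after a positive CMR.** Ischemia is already established; the CXA
  supplies anatomy only. False positives of strategy 1 incur exactly one
  unnecessary CXA (fee plus procedural risk) and no further cascade.
* **One complication type.** Both procedure-related events (per-CXA risk
  `R_CXA`) and late events in false negatives (risk `R_F` per 10-year
  follow-up) are myocardial infarctions with a single cost `C` (PCI, one
  week in hospital, four weeks of rehabilitation). Procedural complications
  are costed undiscounted (they happen at test time).
* **Timing of false-negative complications.** Only a cumulative 10-year rate
  and annual discounting are specified by the evidence base, so the event
  year is taken uniform over years 1..H, giving the annuity-average discount
  factor `(1/H)·Σ_{t=1..H}(1+d)^−t` (0.85302 at d = 3%, H = 10). This is the
  simplest assumption consistent with a per-horizon rate and annual
  discounting; with d = 0 the term collapses exactly to `C·R_F`.
* **Cost equation reconstruction.** The per-branch cost decomposition
  (first-line fee; unnecessary CXA for false positives; CXA procedure
  complications; cross-over; discounted false-negative complications) is
  reconstructed from the published cost taxonomy rather than transcribed
  equations; `strategy1_cost_components` reports each component separately
  so alternative reconstructions can be compared term by term.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `sn_cmr`, `sp_cmr` | per-patient CMR accuracy vs FFR ≤ 0.75 | 0.88 / 0.90 | probability |
| `ndx` | non-diagnostic CMR rate | 0.05 | probability |
| `r_cxa` | major complication per invasive CXA | 0.0005 | probability |
| `r_f` | complication per 10-year follow-up in false negatives | 0.15 | probability |
| `f_cmr`, `f_cxa_*`, `f_ffr` | payer fees (FFR incremental on CXA) | user-supplied | money |
| `c_complication` | cost of one myocardial infarction | user-supplied | money |
| `discount_rate` | annual discount on future complication costs | 0.03 | /year |
| `horizon_years` | false-negative follow-up horizon | 10 | years |
| `cxa_setting` | outpatient vs inpatient CXA fee | outpatient | — |

Fees are deliberately not defaulted in code: they differ by health-care
system and must come from a config whose mandatory `provenance_note` states
whether they are transcribed or synthetic. The shipped schedule is synthetic
(round numbers: 1000/2000/3500/600/10000) chosen so that every qualitative
behaviour of interest occurs on (0,1): a CE crossing (~0.43), a cost crossing
(~0.67), and non-degenerate sensitivity shifts.

## The stenosis link

Strategy 2's FFR referral fraction is the ≥50%-stenosis prevalence
`P_sten(P_isch)`, a monotone map calibrated on study-level points
(`p_isch`, `p_sten`, study size as weight). The published calibration data
(five studies, one set per FFR threshold 0.75/0.80) are supplementary
material not shipped here; the default is the identity link, the shipped
point table is synthetic and labelled so, and a non-identity link is an
explicit opt-in. Two forms are available beyond identity: a weighted
least-squares straight line with [0,1] clipping, and a logit-logit line
(monotone by construction, boundary points excluded from the fit). A fitted
negative slope fails calibration rather than being clipped. The FFR-threshold
sensitivity analysis is realised as a swap between two calibrated link
objects. Every FFR-positive lesion is a ≥50% stenosis, so `P_sten ≥ P_isch`
is expected; the microsimulation refuses a link violating it.

## Crossing-point numerics

The difference curve (ΔCER or Δcost) is scanned on a step-1e-3 grid over the
domain ((0.01, 1] for CE ratios, which are undefined at 0; [0, 1] for costs)
and each bracketing sign change is refined with Brent's method (xtol 1e-9).
No sign change reports `none_in_domain`; a curve that is zero within relative
tolerance 1e-6 everywhere reports `degenerate_equal`. With multiple sign
changes the smallest root is reported with a warning — the model's curves
cross at most once for sensible parameters, but pathological configurations
are not forbidden. One-way sensitivity analysis recomputes the base and
perturbed crossings independently (no incremental updates), reports signed
shifts in percentage points unrounded, clips probability perturbations that
leave [0,1] with a warning, and marks structurally invalid scenarios
`invalid` without aborting the run. Both absolute-set and relative-scale
perturbations are supported because published one-way analyses use both
(e.g. "sensitivity reduced by 10%" realised as an absolute set to 0.80).

## Microsimulation

The microsimulation is a verification layer: the unique minimal patient-level
stochastic model whose expectations equal the closed forms. Per patient it
samples disease (Bernoulli `P_isch`; stenosis deterministic for ischemic
patients, otherwise Bernoulli at the conditional rate that reproduces the
marginal `P_sten`), the CMR outcome, per-CXA complications, and for false
negatives a complication with a uniform event year whose cost is discounted
to present value. A single seeded `numpy` Generator stream drives everything;
the seed is recorded in every estimate and identical seeds reproduce
byte-identical patient tables. It emulates none of the features of real
registries — no correlated test errors, no cost heterogeneity, no covariates,
no time-to-event structure beyond the uniform year — so oracle agreement
validates the algebra and the sampling rules, not the model's fidelity to any
real cohort.

Verification runs use N = 200,000 patients per condition, at which the
Monte-Carlo standard errors (~0.001 on effectiveness, a few currency units on
cost) make the 3-standard-error agreement bands tight while a full grid of
conditions completes in seconds.

## Design choices that were genuinely open

* The link's functional form is a config knob (identity default) because the
  published calibration specifies neither form nor data in the main text.
* The link direction is fixed as `P_isch → P_sten`; the same calibration
  points would support the inverse tabulation.
* Whether "intermediate stenoses" means all ≥50% stenoses or a sub-fraction
  is unresolved; the link output is used as the FFR referral fraction, so a
  sub-fraction interpretation corresponds to a smaller-valued link.
* Currency is a label only; the model never converts or compares across
  currencies.
* Crossing shifts are rounded to whole percentage points only in report
  output, never internally.

## Limitations

Average (not incremental) cost-effectiveness ratios are compared; no
probabilistic sensitivity analysis or acceptability curves; two strategies
only; per-patient homogeneous costs. Published per-country results can only
be replicated after the user transcribes the corresponding payer fee
schedules into a config — the shipped synthetic schedules are not presented
as any country's data and the package never silently substitutes them.
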