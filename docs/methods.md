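# Methods

`alkcea` implements a model-based cost-effectiveness analysis of adjuvant
alectinib versus platinum-based chemotherapy in completely resected
ALK-positive stage IB-IIIA NSCLC, from the Chinese health-care-system
perspective. This note documents the model, its parameters and defaults,
the numerical choices, and what the synthetic data do and do not show.

## Cohort model

A Markov cohort model with monthly cycles and five reported health states:
disease-free survival (DFS), nonmetastatic (locoregional) recurrence,
first-line (1L) metastatic recurrence, subsequent-line metastatic
recurrence, and death. Internally the engine tracks twelve substates: DFS
splits into *at-risk* and *cured*; each recurrence state splits into
active-treatment substates (one per regimen in the treatment mix) and
supportive care. Substate expansion keeps the chain Markovian while
letting costs, utilities and exit rates differ by regimen and care status.

The cohort starts 100% in DFS at-risk at age 56 (configurable; the source
population's mean age is not printed). The default horizon is 600 months
(lifetime; <1% of the cohort is alive at the end).

**Within-cycle order of operations** (fixed convention): (1) age-specific
background mortality is applied to every alive substate, with cured
patients at a 1.25x excess-mortality multiplier; (2) disease transitions
are applied to survivors; (3) the incremental cure flow moves DFS at-risk
survivors to the cured substate. Composing the steps multiplicatively
makes every cycle's transition matrix row-stochastic by construction.

**Transitions.** DFS at-risk patients exit at the monthly probability
implied by the arm's extrapolated DFS curve; exits split into distant
metastases (35.7% alectinib, 55.1% chemotherapy) routed to 1L metastatic
recurrence, and locoregional recurrences routed to the nonmetastatic
state. Entering patients are allocated to active treatment (83.9%
nonmetastatic, 90.9% 1L, 87.5% subsequent line) or supportive care, and
active patients to regimens (1L: 50% lorlatinib / 50% alectinib;
subsequent line: 36.3/27.2/36.3 alectinib/brigatinib/chemo+bevacizumab —
these proportions print to a sum of 0.998 and are renormalized). Active
nonmetastatic patients progress to 1L metastatic recurrence at
0.018/month and do not die of disease; active 1L patients progress to the
subsequent line at their regimen's fitted progression rate; active
subsequent-line patients die at the fitted subsequent-line survival rate
(brigatinib and chemo+bevacizumab inherit the alectinib curve under
configurable hazard ratios defaulting to 1). Supportive care implies
death-only exits at 0.0762/month (nonmetastatic) or 0.1036/month (both
metastatic states).

**Cure.** Patients free of a DFS event at 24 months begin to be
considered cured, ramping linearly to a maximum cure rate of 97.5% at ten
years (ultra-late recurrence risk ~2.5%). The ramp c(t) is realized as a
per-cycle one-way flow phi(t) = (c(t+1) - c(t)) / (1 - c(t)) applied to
DFS at-risk survivors, so that in the absence of other exits the cured
share of DFS occupants equals c(t) exactly. Cured patients face only
1.25x background mortality, never disease transitions, and never un-cure.

**Waning.** The alectinib arm's DFS exit hazard equals its own fitted
hazard before month 28, blends linearly into the chemotherapy hazard over
months 28-60, and equals the chemotherapy hazard thereafter — the
simplest monotone scheme consistent with a gradual loss of treatment
effect. Hazards are blended on the integrated-monthly-hazard scale
h(t) = -ln(S(t+1)/S(t)).

**Clock.** All curves are evaluated on the model clock. For the
recurrence-state curves this is the memoryless-clock approximation: a
cohort matrix cannot condition on state-entry time without tunnel states,
and the substate expansion carries regimen mix, not entry time. The
approximation understates early-progression risk for late entrants and
overstates it for early entrants; it is the standard simplification in
spreadsheet cohort models of this design.

## Survival extrapolation

Five standard parametric families (generalized gamma, Weibull, Gompertz,
log-logistic, log-normal), mixture cure models S(t) = pi + (1-pi)S_u(t),
and Royston-Parmar restricted-cubic-spline models (3-5 knots; hazard,
odds or normal link) are fitted to pseudo-IPD by maximum likelihood under
right censoring. Parameterizations are fixed and documented in
`alkcea.survival` (e.g. Gompertz S(t) = exp(-(b/a)(e^{at}-1)) with the
shape a free in sign, so a negative shape gives a plateau — the natural
family for a curve with a cured-looking tail). Model selection is lowest
AIC, ties broken by parsimony then declaration order; the base-case DFS
families are pre-specified (Gompertz for alectinib, log-normal for
chemotherapy) with the full AIC ranking reported alongside. Fit adequacy
is summarized by a KM-overlay plot plus the maximum absolute deviation
between fitted survival and the KM step function; there is no automatic
rejection rule.

Optimization: multi-start Nelder-Mead from method-of-moments initial
values (plus seeded perturbations) with a BFGS polish; log-likelihood
tolerance 1e-10; positives are log-transformed. Non-convergence is
reported on the returned fit object, never silently replaced. RP-spline
knots sit at the min/max uncensored log event times (boundary) and
equally spaced quantiles (interior); spline fits are initialized by
regressing the transformed KM estimate on the basis. The monthly
transition probability of any fit is p(t) = 1 - S(t+1)/S(t), clamped to
[0, 1], returning 1 with a warning if the support is exhausted.

## Pseudo-IPD reconstruction

Digitized KM coordinates plus a numbers-at-risk table are converted to
subject-level records by the iterative interval algorithm: within each
risk-table interval, the number of censorings is solved so that the
implied number at risk matches the next anchor, events are read off the
KM drops, and censoring times are placed deterministically (allocated
among coordinate gaps by greedy KM-tracking with a
proportional-placement tie-break, so reconstruction has no randomness).
When the total event count is supplied it pins down censoring in the
final, unanchored interval and is honored exactly. Digitization noise is
repaired by a running-minimum monotonization; survival values outside
[0, 1] by more than 0.02 are rejected as bad digitization. Round trips on
noiseless synthetic fixtures reproduce the curve within ~0.01 max-abs
deviation; terminal drops to S = 0 at very small numbers at risk can
exceed this slightly (the information is genuinely not in the published
materials).

## Economics

Costs are 2024 USD (1 USD = 7.23 CNY). Accumulation uses
half-cycle-corrected occupancy (mean of cycle start and end) with
mid-cycle discounting at (1+r)^(-(t+0.5)/12); both rates default to 5%/yr.

- DFS: follow-up 24.42/month for five years and 12.21/month after, plus
  adjuvant drug cost — alectinib for months 0-24 (oral, no administration
  fee), or four 21-day chemotherapy cycles (412.87 + 43.36 administration
  per cycle) prorated by calendar days over the first three model months.
- Active recurrence substates carry their regimen's per-cycle treatment
  cost (nonmetastatic 334.95/338.15 by arm; 1L blend 1855.02; subsequent
  line 2659.42/2719.49 by arm); supportive substates carry follow-up only.
- End-of-life cost 1967.49 attaches to deaths leaving recurrence states
  through disease pathways (the source study surveyed terminal cancer
  care); background deaths, including cured patients', carry none.
- Severe (grade >=3, incidence >=5%) adverse events enter as expectations
  in the first treatment cycle: CPK elevation (risk 0.062, cost 0.40,
  annual disutility 0.062) for alectinib; neutropenia (risk 0.102, cost
  17.65, disutility 0.200) for chemotherapy. The arm assignment follows
  the regimens' known toxicity profiles; disutilities apply for one month.
- Annual utilities: DFS 0.845 on / 0.872 off treatment, nonmetastatic
  0.845, 1L metastatic 0.805, subsequent line 0.741.

The alectinib price row is blank in the published main-text table; the
config carries a synthetic placeholder (CNY 54.40 per 150 mg capsule, 8
capsules/day -> 1832.14 USD/month) that should be replaced with the
negotiated price for any real reanalysis. Scenario 1 needs per-drug 1L
costs where only the 50/50 blend is published: the alectinib 1L cost is
set to the adjuvant monthly price (same drug and dose) and the lorlatinib
cost to twice the blend minus that, preserving the blend. A
`units_required` ceiling helper supports re-deriving per-cycle costs from
unit prices with vial/capsule waste; the base case takes the published
per-cycle costs as given.

## Uncertainty analysis

- **DSA**: every ledger parameter is set to its published low and high
  bound in turn (discount rates 0-8%; +/-10% for utilities and AE risks
  lacking bounds, +/-20% otherwise) and the model re-run; parameters are
  ranked by the width of the ICER interval. Bounds that make alectinib
  dominant are flagged rather than plotted as ratios.
- **PSA**: 5000 draws; gamma for costs, beta for probabilities,
  proportions and utilities, parameterized by method of moments from
  mean = base and SD = (high - low)/3.92 (bounds read as a 95% interval);
  parameters are drawn independently; discount rates are held constant.
  Survival-curve coefficient uncertainty is off by default (the published
  ledger lists no distributions for them); an optional mode draws
  coefficients from their asymptotic normal where a fit carries a
  covariance. The CEAC reports, for each willingness-to-pay on a 0-50,000
  grid (step 250, including the 12,367 and 37,100 thresholds exactly),
  the fraction of draws with positive incremental net monetary benefit.
- **Scenarios**: (1) 100% lorlatinib or 100% alectinib in 1L;
  (2) horizons of 10/20/30 years (accumulation truncated, no re-fitting);
  (3) active-treatment proportions (0.9, 0.8, 0.5) and (0.8, 0.6, 0.4).

## Synthetic data

The generator draws event times by inverse transform from a stated
family, applies uniform-accrual administrative censoring and optional
exponential random censoring, and emits digitized-KM fixtures (exact or
jittered) with risk tables, a Gompertz-Makeham lifetable (ages 18-100;
annual q(age) = 1 - exp(-(2e-4 + 2.7e-5 e^{0.092 age})), a smooth
stand-in for a national census table, swappable by CSV), and a fully
populated config.

The five survival ground truths are synthetic stand-ins for the study's
supplementary fitted parameters, calibrated once from public trial-level
anchors: adjuvant-arm DFS Gompertz through S(24m)=0.938 and S(48m)=0.885;
comparator DFS log-normal through a 41.3-month median and S(24m)=0.63;
1L lorlatinib-like PFS log-logistic through S(36m)=0.64 and S(60m)=0.60;
1L alectinib-like PFS Weibull through a 35-month median and S(60m)=0.25;
subsequent-line survival Weibull through a 20-month median and
S(36m)=0.25. Arm sizes mirror the adjuvant trial (130/128).

What this does and does not show: the pipeline's structural properties
(conservation, oracle equivalence, round trips, recovery) are fully
exercised, and the effectiveness increments it produces are close to the
published ones (dLY ~2.0, dQALY ~1.8). The *cost* side is sensitive to
metastatic-state dwell times, and the plateau-heavy 1L PFS stand-in keeps
both arms in the expensive 1L state longer than the study's own curves
did — long enough that adjuvant alectinib becomes cost-saving (dominant)
here rather than carrying an ICER of ~$8,800/QALY. Reproducing the
published cost results requires loading the study's supplementary fitted
parameters into the config's survival block, which the pipeline supports
directly. The stand-ins were not adjusted toward the published numbers.

## Numerical choices and limitations

- Time unit is months; day-scale inputs convert at 30.4375 days/month.
- Generalized-gamma Q is median-unbiased but mean-biased at n=250 (heavy
  right tail of the MLE); AIC-based family identification from a single
  censored dataset of a few hundred patients is unreliable whenever the
  truth is nested in the generalized gamma — selection should be read
  together with the fit-adequacy overlay, not alone.
- Probabilities from curves are clamped to [0, 1]; exhausted support
  (S = 0) maps to probability 1 with a warning.
- The engine broadcasts probabilistic draws through the occupancy tensor,
  so a 5000-draw PSA is a single vectorized run (~10 s); survival curves
  are shared across draws in the default mode.
- No covariate adjustment, no Bayesian or registry-blended extrapolation,
  no patient-level simulation, no societal perspective or budget impact.
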