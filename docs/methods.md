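# Methods

This note documents the statistical model, the synthetic study conditions,
and the numerical and design choices behind the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Discrete-time hazard model

Follow-up is partitioned into K right-open intervals `[b_{k-1}, b_k)` with
`b_0 = 0` and `b_K` at the maximum observed follow-up; interior boundaries
sit at the 1/K..(K−1)/K quantiles of observed follow-up times so at-risk
counts are balanced across intervals. Tied quantiles (for example an atom
of administrative censoring at the horizon) are merged, reducing K with a
warning. Times at or beyond `b_K` are absorbed into interval K.

A record with follow-up `t` and event indicator `d` expands into Bernoulli
targets: death in interval k yields at-risk intervals 1..k with the event
at k; censoring inside interval k yields at-risk intervals 1..k−1 and no
target for the partial interval (censoring exactly on a boundary counts
every completed interval). This is the standard discrete-time likelihood
expansion; the hazard network is a partial-logistic ANN in the Biganzoli
tradition, realized as one network with K sigmoid output nodes (one
conditional hazard per interval) over a single logistic hidden layer —
the architecture that matches an accounting of "p inputs, H hidden nodes,
K time intervals" — rather than the time-as-input replication variant.

Survival is `S_k = Π_{j≤k}(1 − h_j)`; between boundaries the survival
curve is interpolated linearly (the median is interpolated within its
crossing interval), and beyond the grid it is extrapolated at the constant
continuous-time rate equivalent to the final interval's hazard,
`r = −ln(1 − h_K)/Δ_K`, with the value flagged as extrapolated. A zero
tail rate caps the median at twice the grid end (flagged).

### Training

The loss is the cross-entropy averaged over at-risk person-intervals plus
`λ · Σ w²` over weights (biases excluded). Averaging rather than summing
the cross-entropy makes λ comparable across cohort sizes; rprop updates
depend only on gradient signs, so this rescaling does not otherwise alter
the optimization. The optimizer is full-batch iRprop− with the standard
constants (η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.01, Δ ∈ [10⁻⁶, 50]); weights start
from a seeded uniform (±0.5/√fan-in), and output biases start at the logit
of the pooled per-interval hazard, which removes most burn-in. Training
keeps the best-loss parameters and stops early on a loss plateau
(default patience 40 epochs, cap 400 epochs). Identical seeds give
identical weights.

Duplicate (design, target) rows are collapsed to weighted rows before
training; the loss is algebraically unchanged, and saturated designs (few
covariate patterns) train in near-constant time regardless of n. The same
mechanism powers the bootstrap: resampling patients is equivalent to
multinomial reweighting of the collapsed patterns, so all B bootstrap
refits train simultaneously as one batched rprop run warm-started from
the fitted weights.

Hyperparameters (hidden count H, decay λ) can be chosen by seeded k-fold
cross-validation (default 5 folds) on the Harrell C of predicted median
survival, ties resolved toward smaller H then larger λ, with a final refit
on all data. A fold without events is repartitioned once, then rejected.

### Ensemble over imputations

Missing items are filled by hot-deck imputation stratified by transplant
era: each missing cell is replaced, independently per imputation, by a
uniform draw from the values observed for that variable among other
records of the same era (pooled fallback when a stratum has no donor
value, logged). Draws are per-cell, with replacement, independent across
cells, imputations and variables. M complete cohorts (default 10) train M
committee members (member seed = base seed + index); the ensemble hazard
is the arithmetic mean of member hazards, which stays in (0, 1) and is
invariant to member order. Imputation uncertainty therefore reaches
predictions through committee disagreement; no coefficient pooling is
performed.

## Design matrix

The default inventory is 43 columns: 32 recipient and 11 donor variables.
Multi-level categoricals are reference-coded (recipient blood group
reference AB; donor blood group reference A; era reference 1991–1995;
HLA-DR 0/1 mismatches pooled into the reference with a single 2-mismatch
indicator; diagnoses valvular and "other" pooled into the reference).
Continuous columns are standardized with statistics stored in the fitted
design and applied identically to new data; recipient/donor weight and
height ratios (recipient ÷ donor) are appended as derived columns.

Each continuous column carries a half-IQR increment in native units
(type-7 quartiles), rounded half-up to the nearest integer when ≥ 1 —
reproducing steps such as 22 µmol/l for creatinine and 11 years for donor
age from the corresponding quartiles — and to two significant figures
below 1 so small-scale variables (bilirubin, body-size ratios) keep a
usable step. A zero spread marks the column degenerate and excludes it
from hazard-ratio perturbation.

## Time-dependent hazard ratios

For a chosen variable, every patient is predicted twice: indicators are
forced 0 ("absent") and 1 ("present") regardless of the observed value;
continuous variables move from the observed value to observed + ½ IQR.
The per-interval ratio of ensemble hazards (floored at 10⁻⁸ before
division) is the patient's tHR; the cohort tHR is `exp(mean(log HR))` per
interval, and the value "at one year" is the ratio of the interval
containing that time (boundary times take the right-adjacent interval).

The bootstrap CI resamples patients with replacement B times (default
1,000, configurable upward; percentile interval at the stated level). By
default each resample re-trains the committee, warm-started from the
fitted weights with the preprocessing held fixed, so the CI reflects
sampling variability of the full estimation procedure; a cheap
composition-only mode (`refit=False`) resamples precomputed patient
ratios and is appropriate only when per-patient ratios genuinely vary.
For a one-covariate model the composition-only CI degenerates to zero
width, which is why refitting is the default.

Because the model is piecewise-constant in time, the discrete-interval
ratio of a true proportional-hazards effect is `(1 − e^{−HR·x})/(1 −
e^{−x})` with x the within-interval cumulative baseline hazard — slightly
below HR for coarse intervals. The grid should therefore be fine relative
to the hazard when tHR recovery matters; the acceptance checks use K = 15
on a 0.03/yr baseline, where the residual discretization bias is well
inside sampling noise and the bootstrap se matches the empirical sampling
sd.

## Variable ranking

Backward elimination with the 13 recipient–donor match variables
(recipient and donor age, gender, weight, blood-group indicators, plus
recipient height) exempt. Each round trains the committee with k-fold
cross-validation on the active columns, then scores each non-mandatory
variable by the drop in validation C when its column is neutralized —
set to its training mean (zero for standardized columns, the prevalence
for indicators) — against the round's trained model. The cheapest
variable is removed (ties by column order) and the procedure repeats
until only mandatory variables remain. Scoring omissions against the
round's model rather than retraining per candidate keeps the procedure
linear in the variable count; an exhaustive `mode="retrain"` exists for
small problems. `select_model_size` returns the smallest subset whose
trajectory C is within a tolerance (default 0.002) of the maximum.

## CART in survival years

Targets are each patient's model-predicted median survival with the era
fixed to the latest level, so the tree reads in current-practice years.
Growth is greedy binary partitioning minimizing within-node SSE
(continuous splits at observed midpoints; categorical splits by
exhaustive subset search up to 10 levels, mean-ordering above). Pruning
is weakest-link cost-complexity: a subtree collapses while its per-split
SSE reduction, normalized by the root total sum of squares, is below
`cc_alpha` (default 0.0035); zero returns the tree unchanged. Importance
is each variable's summed SSE reduction divided by the root SST, so
values read as fractions of explained variance; the displayed per-leaf SD
is the SD of training targets in the leaf. Node ids use heap numbering so
leaf labels survive pruning. Leaves are validated by Kaplan–Meier curves
of observed survival per leaf per cohort and a derivation-vs-validation
log-rank test within each leaf.

## Allocation simulation

A waiting list of NW recipients is drawn from a pool; donors stream in
with replacement. A donor is offered only when at least one ABO-compatible
recipient is listed. Policies: (1) survival-model — the ABO-compatible
candidate with the best predicted median survival of the hypothetical
pair; (2) clinical — eligibility requires ABO compatibility and donor
weight within ±20% of the recipient's, tightened under recipient PVR > 3
Wood units to a 0–15% heavier donor and no female-to-male donation; tier 1
is identical blood group with both ages ≤ 35, tier 2 identical group with
donor age < recipient age + 15, tier 3 any remaining eligible match;
(3) random — uniform among ABO-compatible (the control). Equal priority
resolves by a seeded draw. A matched recipient leaves the list and is
replaced from a seeded replacement sequence; the pool running out
truncates the run with a warning.

Hypothetical pairs substitute the donor's age, sex, weight, height, blood
group and cause of death into the candidate's record and recompute the
body-size ratios; ischemia time, unknown before allocation, is fixed at
the pool median. By default policies run on separate list copies under
common random numbers (shared donor and replacement streams, independent
tie-break streams) so policy contrasts are not sampling noise; a
`randomize` mode assigns each donor to one policy on a shared list,
mirroring a between-policy randomized design. Tier 3 closes a gap the
priority rules leave open for compatible non-identical groups, so the
clinical policy is total over its eligible set.

A note on emergent dynamics: because ineligible or unpreferred recipients
are never removed, each policy's list composition drifts away from the
pool marginals (the clinical list accumulates hard-to-match patients).
This is a property of the queueing process, not a bug; the comparisons of
interest — transplant counts and predicted survival across policies —
are made under common random numbers.

## Synthetic registry: what it emulates, what it does not

Covariate marginals default to published recipient/donor summary tables of
a large international registry: continuous variables as two-piece
log-normals anchored exactly at the three printed quartiles (a single
log-normal cannot reproduce asymmetric quartiles such as donor age
22/34/44); categoricals at the printed frequencies (renormalized); donor
height, which has no printed quartiles, uses a realistic adult
distribution. Covariates are independent by default; a single Gaussian
copula knob (`copula_rho`) adds exchangeable dependence when needed.

Event times follow a piecewise-exponential hazard
`λ0(t)·exp(linear predictor)`. The default baseline (0.20/yr in year one,
0.065/yr to year five, 0.042/yr after) gives a reference patient roughly
18% first-year mortality and a median survival near 11 years, the scale
of the registry figures. Default planted effects mirror the direction and
rough per-increment size of the published time-dependent hazard ratios:
donor age raises the early hazard and fades, recipient age acts late,
ECMO/ventilation/previous transplant carry large early effects that
decline (changepoint 5 years), plus constant effects for creatinine,
diabetes, infection and era. Censoring combines an 18-year administrative
horizon with an independent exponential (default 0.10/yr) emulating
staggered entry. Missingness defaults are MCAR with hemodynamic and
laboratory items least complete (5–30%); a MAR(era) mechanism multiplies
rates by era-specific factors. Deliberately not emulated: center effects,
reporting lags, joint covariate structure beyond the copula knob, and
waiting-list arrival or mortality processes.

Passing tests on this generator demonstrate that the machinery recovers
known truth under registry-like marginals and censoring; they do not
certify performance on real registry data, whose correlation structure,
informative missingness and reporting artifacts are richer.

## Problem sizes and statistical checks

The acceptance suite fixes its study conditions as follows. Life-table
equivalence uses a saturated one-indicator design at n = 5,000, K = 5
(agreement within 0.02 of events/at-risk). Proportional-hazards recovery
plants HR 2.0 on a balanced indicator at n = 2,000 over a 0.03/yr
baseline with an 18-year horizon, K = 15, and checks the median tHR
profile across 300 seeded runs against [1.7, 2.3] and the 95% bootstrap
CI (B = 200, warm-started refits) for 93–97% coverage of 2.0. The
time-varying check plants ln 2 before year five and zero after at
n = 5,000. Metric oracles compare against O(n²) enumeration (n ≤ 200) and
a B = 2,000 bootstrap. The Hosmer–Lemeshow type-I simulation follows the
applied procedure — logistic recalibration first, then the test — because
the g − 2 reference distribution presupposes predictions fitted on the
data; with external predictions the statistic is approximately χ²(g).
Ranking recovery plants five HR-1.6 indicators among fifteen noise
variables at n = 3,000 with a 3-member committee and 2-fold CV. The CART
check plants a 4-year survival step at donor age 38 with Gaussian noise
of SD 0.3 years — noise small enough that the planted split carries above
95% of target variance, as the importance bound requires. Allocation runs
NW = 50 with 1,000 donor draws over 10 simulation seeds.

## Known limitations

- The bootstrap refit warm-starts from the fitted weights with a fixed
  epoch budget; for very flexible networks this can underdisperse the CI.
  The batched path also fixes the preprocessing statistics across
  resamples.
- The discrete-time grid biases hazard ratios toward 1 in coarse
  intervals (see above); K should grow with the event density.
- Hot-deck imputation is per-cell and ignores within-record dependence, so
  imputed records can mix values from different donors.
- The clinical allocation tiers implement the stated rules only; urgency
  status, waiting time and multi-organ listings are out of scope, as are
  waiting-list mortality and arrival processes.
- Rejected imputation alternatives (nearest-neighbour imputation,
  case-wise deletion before imputation, unstratified draws) are
  documented but deliberately not implemented; era-stratified hot-deck
  was the retained technique.
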