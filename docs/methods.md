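# Methods

## The task and its idealized clock

The sequential patch depletion procedure offers a water-restricted rat a
concurrent choice between two "patches" (snout-poke receptacles). Entering a
patch delivers 150 µL immediately; each further "stay" delivers 80% of the
previous volume (150, 120, 96, 76.8, … µL) on a fixed 4-s interval.
"Leaving" imposes a changeover delay (COD; 0, 6, 12, 18 or 24 s within a
session) that stands in for travel cost, after which the alternative patch
pays the full 150 µL again and the abandoned patch replenishes. Sessions end
at 10 min or 5 mL earned, whichever comes first. A test week runs the COD
sequence 0, 0, 6, 12, 18, 24 s (the first 0-s session is a warm-up, excluded
from analysis); four weekly cycles give 24 sessions, and per-rat measures
average the analyzed sessions of the last two cycles — two sessions per COD.

The simulator idealizes timing: every reward is claimed at the earliest
permitted instant, patch entry coincides with the first delivery, and a leave
choice is made immediately after each delivered reward. These are exactly the
times the optimality arithmetic uses (denominators COD, COD + 4, COD + 8, …),
so the Marginal Value Theorem (MVT) reference agent achieves *exactly* zero
deviation — a closure property the test suite asserts. Two consequences are
worth knowing:

* tied timestamps are legal (entry/first reward; last reward/leave); event
  order is carried by the event index;
* at COD 0, an agent that leaves after every reward completes patch cycles in
  zero simulated time. Such sessions report an undefined (missing) water rate
  — the denominator is genuinely zero under the abstraction — and are
  propagated as missing, never as zero or infinity.

The session volume cap is applied after each delivery: the terminating reward
is delivered in full, so logged totals may overshoot 5 000 µL by at most one
reward, matching how an operant controller would detect "earned a total of
5 mL".

## MVT optimality

For `n` rewards collected per patch the cycle-average rate is

    R(n; COD) = Σ_{i=1..n} A·f^(i−1) / (COD + IRI·(n−1))

with A = 150 µL, f = 0.8, IRI = 4 s. The optimal stay count `n*` maximizes
R (exhaustive argmax over n = 1..100; the geometric schedule makes R
unimodal, and ties break toward the smaller n). The **optimal rejection
volume** is the volume scheduled next at the optimal leave point,
`A·f^(n*)`. At COD 6 s: R = 25, 27, 26.14 µL/s for n = 1, 2, 3, so n* = 2
and the optimal rejection volume is 96 µL. At COD 0 the first reward arrives
with zero elapsed time, R(1; 0) = +∞, and the optimal policy is to leave
after every reward.

**Optimal time in patch** is defined as `IRI·(n* − 1)` — the span from first
delivery to the earliest leave opportunity, mirroring the rate denominators.
This convention makes the optimal time 0 s at COD 0, so the percent *time*
deviation is undefined there and is reported missing; composites over delays
therefore sum TD over the positive CODs only. Users preferring a different
convention (e.g. counting the final 4-s interval) can recompute times from
`n*`.

## Dependent measures

Per session: patch changes (PC; leaves that terminate complete visits), time
in patch (TIP; mean stay over complete visits), rejection volume (mean next-
scheduled volume at leaving — the task's indifference point), and water rate
(WR; total µL earned ÷ minutes from session start to the last reward ÷ body
weight in kg). A session's first and final patches, with their bounding patch
changes, are excluded: the first predates any experienced COD, the last is
truncated by termination. Deviations from optimality:

    VD = (optimal − observed rejection volume) / optimal × 100
    TD = (observed − optimal time in patch) / optimal × 100

Positive VD and positive TD both mean overharvesting (staying past the
MVT-optimal leave point); for deterministic agents the two signs agree
whenever both are defined and nonzero. Harvest classification uses the sign
of VD with a 10⁻⁹ optimality band (relevant only for deterministic
simulations; noisy cohorts effectively classify by sign).

The WR time base ("time required to earn those reinforcers") is the elapsed
time to the final reward, not the full cap when the volume cap ends the
session early; this is a documented choice and easy to switch.

## Discounting model

Rejection volumes across CODs form an indifference curve fitted by the
anchored hyperbolic function

    V(D) = b·A / (1 + k·D)

with b fixed to IP(0)/A (so the 0-delay point carries no residual) and
k ≥ 0 the single free parameter, found by bounded deterministic least
squares in log₁₀ k over [10⁻⁶, 10²] with an explicit k = 0 candidate. The
normalized AUC is the model-free companion: delays scaled by the maximum
delay, points clipped into [0, A] and scaled by A, trapezoidal area.

**Quantization floor.** Simulated (and real) rejection volumes exist only on
the schedule grid {120, 96, 76.8, …}, whose steps are 20%. A deterministic
threshold agent's observed indifference point therefore underestimates its
latent threshold by up to one grid step, and the per-animal relative error of
the recovered k has an irreducible floor — about 8–18% median magnitude for
realistic parameter ranges (measured against the closed-form rejection-volume
oracle). The recovery is nevertheless nearly *unbiased*: the cohort median of
the signed relative error stays within a few percent, because the anchor b
and the later points are quantized in the same direction and the errors
largely cancel in the fit. The recovery report exposes both numbers (signed
median = bias; absolute median; RMSE), and the acceptance suite checks the
bias at a cohort size (300/sex) chosen so Monte-Carlo scatter of the median
is small against the 5% criterion. Where thresholds happen to sit just above
grid volumes the per-animal error is within 5% as well (asserted at
k = 0.05, b = 0.9). Injected logistic choice noise *dithers* the
quantization: small noise (≈3 µL) reduces the RMSE below the deterministic
floor before noise degradation takes over, so RMSE-vs-noise monotonicity
holds over positive noise levels (3, 10, 30 µL), not from zero.

## Cohort statistics

Composite scores sum each measure across delays per rat (TD over the defined
delays; rats with other missing cells are excluded and logged) and carry k,
b and AUC through. Pearson matrices are computed per sex over
{k, AUC, VD, TD, TIP, PC, WR} with pairwise-complete observations.
Correlations sharing a variable are compared with the Meng–Rosenthal–Rubin
(1992) z for dependent overlapping correlations:

    z = (z_jx − z_jy) · √[ (n − 3) / (2(1 − r_xy)·h) ],
    h = (1 − f·r̄²)/(1 − r̄²),  f = min{ (1 − r_xy) / (2(1 − r̄²)), 1 },

with z_· Fisher transforms and r̄² the mean squared correlation. The
implementation is validated against an independent re-derivation of the
published formula (10⁻⁶ agreement on a parameter grid) and by frequentist
calibration: under a simulated trivariate-normal null with equal overlapping
correlations (n = 100), the empirical type-I rate over 2 000 replicates is
0.05 ± 0.01.

The delay × sex analysis is a two-way **mixed** ANOVA (delay within-subject,
sex between-subject) with partial eta squared per effect; Greenhouse–Geisser
corrected p-values are reported alongside, the uncorrected F being primary.
(The analysis description in some places of the source literature labels
this a "between-subject" ANOVA while describing a within-subject delay
factor; the mixed design is what the factors describe.) Post-hocs: per-delay
independent-samples t with pooled-SD Cohen's d, Bonferroni family = the five
delay levels; within-subject pairwise paired t over all 10 delay pairs,
Bonferroni-corrected. A skewness screen (bias-corrected g₁, pass at
|skew| < 1) mirrors the normality gate used for such data. The mixed ANOVA
is delegated to pingouin; the test suite cross-checks it against a hand
sums-of-squares decomposition on a balanced fixture.

## Synthetic cohorts

Agents decide stay/leave by comparing the next scheduled volume with a
threshold: `b·A/(1 + k·COD)` for hyperbolic discounters (the generative twin
of the fitted equation), a fixed volume for threshold agents, or the exact
n* rule for MVT reference agents. Decision noise passes the µL value
difference through a logistic of scale `choice_noise`; a `lapse` flips the
outcome with fixed probability. Patch sides alternate deterministically (two
receptacles); mid-COD reversals are not modeled.

Defaults (all overridable, see `CohortSpec`): 100 rats/sex (full-scale
preset: 896 males + 898 females); k ~ lognormal(median 0.03 s⁻¹, σ_log 0.5)
in both sexes; b ~ truncated normal on (0, 1], males 0.68, females 0.62
(sd 0.10); body weight ~ normal, males 0.40 (0.04) kg, females 0.25
(0.025) kg; choice noise 5 µL, lapse 0.02. The k range is chosen so that
agent thresholds decay more slowly than the optimal rejection-volume curve
(≈0.06 s⁻¹ equivalent), which yields the characteristic crossover from
overharvesting at short CODs toward optimal/underharvesting at long CODs;
b < 0.8 puts the 0-delay threshold below the optimal 120 µL (overharvesting
at COD 0). Sex differences are injected through b (stay tendency) and body
weight only, not k: in V = bA/(1+kD) a *lower* b is a lower rejection
threshold, hence longer stays, fewer patch changes and lower indifference
points, while the weight difference alone drives the higher female per-kg
water rate.

What the generator does **not** emulate: estrous cycles, batch/test-order
effects, reaction and drinking times, within-session satiation or learning,
and any genetic structure. Passing tests on these cohorts therefore
demonstrate correctness of the task arithmetic, the measure definitions and
the statistical machinery — not quantitative claims about real rats; the
printed F/t/r values of the motivating dataset are expressly out of scope.

## Numerical and design notes

* Volumes are carried at full float precision (no pump-resolution rounding);
  event-log CSVs print 6 decimals and round-trip byte-identically.
* Argmax ties in the solver break toward smaller n (leave earlier);
  the search bound n ≤ 100 is far past where volumes fall below 0.1 µL.
* Per-session RNG streams derive from (protocol seed, session index); per-rat
  protocol seeds derive from the cohort master seed; a whole study run is
  bit-reproducible and independent of execution order.
* Degenerate inputs: sessions with no complete visit report missing measures
  (not zero); zero-variance variables get missing correlation rows with a
  warning; |r| = 1 or n ≤ 3 are rejected by the Meng test with explicit
  errors; indifference points above A are flagged and clipped only for AUC.
* Problem sizes in the test suite (cohorts of 8–600 rats, 2 000-replicate
  calibration) were chosen to keep Monte-Carlo error well inside each
  criterion's tolerance while remaining desk-interactive.
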