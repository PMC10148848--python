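# patchforage

Analysis pipeline for the **sequential patch depletion** procedure — an
operant foraging task in which a rat chooses between *staying* at a water
"patch" whose rewards shrink geometrically (150, 120, 96, … µL, 20% per
reward, one every 4 s) and *leaving* for the alternative patch, which pays
the full 150 µL again but only after a changeover delay (COD: 0–24 s)
standing in for travel cost. The task yields, in one paradigm, both
optimal-foraging measures (patch changes, time in patch, deviation from the
Marginal Value Theorem optimum) and classical delay-discounting measures
(indifference points, hyperbolic k, normalized AUC).

The package is aimed at behavioral scientists who want to simulate the task,
analyze event logs (simulated or, in principle, real), and run the
cohort-level statistics end-to-end:

* **task_core** — the reward schedule and the MVT solver. The cycle-average
  rate for `n` rewards is `Σ A·fⁱ⁻¹ / (COD + 4(n−1))`; the optimal stay
  count `n*` maximizes it, and the *optimal rejection volume* is the volume
  scheduled next at the optimal leave point, `A·f^{n*}`.
* **simulator** — discrete-event simulation of single sessions and the full
  24-session protocol (weekly COD sequence 0, 0, 6, 12, 18, 24 s × 4
  cycles) for MVT-optimal, fixed-threshold and hyperbolic-discounter agents
  with logistic choice noise and lapses.
* **metrics** — the five dependent measures (patch changes, time in patch,
  rejection volume, water rate µL/min/kg, deviation from optimality) with
  the first/final-patch exclusion and last-two-cycles averaging rules.
* **discounting** — anchored hyperbolic fits `V = bA/(1+kD)` (b fixed by the
  0-delay indifference point) and normalized AUC.
* **cohort_stats** — composite scores, per-sex Pearson matrices, the
  Meng–Rosenthal–Rubin z-test for dependent overlapping correlations, mixed
  ANOVA (delay × sex) with partial η², Bonferroni post-hocs with Cohen's d.
* **cohort** — synthetic cohorts with per-rat heterogeneity (two sexes,
  lognormal k, truncated-normal stay bias b, body weights), the one-call
  study harness, and parameter-recovery experiments.
* **io / cli** — CSV event logs that round-trip byte-identically, YAML/JSON
  configs, checksummed run manifests, and a `patchforage` command-line
  pipeline.

See `docs/methods.md` for the model conventions (including the time-in-patch
convention and the reward-grid quantization floor on k recovery) and the
generator's default cohort.

## Worked example

The optimality computation at a 6-s changeover delay:

```python
import patchforage as pf

config = pf.TaskConfig()          # 150 uL, f=0.8, 4-s interval
for n in (1, 2, 3):
    print(f"R({n}; COD=6) = {pf.cumulative_rate(n, 6.0, config):.2f} uL/s")
policy = pf.solve_optimal_policy(6.0, config)
print(f"n* = {policy.n_star}, optimal rejection volume = "
      f"{policy.optimal_rejection_volume:.0f} uL")
```

```
R(1; COD=6) = 25.00 uL/s
R(2; COD=6) = 27.00 uL/s
R(3; COD=6) = 26.14 uL/s
n* = 2, optimal rejection volume = 96 uL
```

150/6 = 25 µL/s for the first reward, (150+120)/10 = 27 for the second,
366/14 ≈ 26.14 for the third: the rate peaks at two rewards, so an optimal
forager leaves after the second reward, rejecting the scheduled 96 µL.

A small synthetic study, end-to-end:

```python
spec = pf.CohortSpec(n_male=25, n_female=25, seed=2)
res = pf.run_study(spec)
print(res.delay_curves.query("measure == 'pc'")
      .pivot(index="cod_s", columns="sex", values="mean").round(2))
print(res.fits[["k", "b", "auc"]].median().round(4))
```

```
sex    female   male
cod_s
0.0     14.72  17.94
6.0     12.22  12.88
12.0    10.66  10.92
18.0     9.66   9.86
24.0     9.18   9.26
k      0.0245
b      0.6040
auc    0.4715
```

Patch changes fall as the travel delay grows (the MVT direction), females
switch less than males (they carry the lower stay-bias b under the default
generator), and the median fitted k ≈ 0.0245 s⁻¹ sits near the generating
median of 0.03 (the gap reflects the 20% reward-grid quantization documented
in the methods note). `res.correlations`, `res.comparisons`, `res.anova` and
`res.posthoc` hold the full statistical output; e.g. the male composite
matrix gives r(k, AUC) = −0.35 and r(TIP, PC) = −0.89.

The same pipeline from the shell:

```bash
patchforage solve-optimal --cod 6
patchforage cohort run --seed 2 --out runs/demo      # writes manifest.json
patchforage cohort recover --seed 5 --noise-grid 3,10,30 --out recover.csv
```

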