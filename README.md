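# imptrobust

Worst-case robustness evaluation for intensity-modulated proton therapy
(IMPT) plans.

IMPT dose distributions are sensitive to patient setup errors and proton
range errors. Clinics therefore evaluate a plan not only on its nominal dose
but on a set of perturbed *uncertainty scenarios*: rigid shifts of a fixed
magnitude along each anatomical axis (±L/R, ±A/P, ±S/I), each combined with
a ±range error — 12 scenarios in total, typically 5 mm setup for prostate
and 3 mm for head and neck, with a 3.5% range uncertainty. `imptrobust`
implements the standard worst-case evaluation methods on top of such a
scenario set and compares them against each other:

- **ebDD** (error-bar dose distribution): per voxel,
  `max_{i=0..12} D_i − min_{i=0..12} D_i`, the spread of dose across the
  nominal (i = 0) and 12 uncertainty scenarios.
- **RMSED** (root-mean-square error dose): per voxel,
  `sqrt((1/12) Σ_{i=1..12} (D_0 − D_i)²)`, the RMS deviation from nominal.
- **Voxel-wise worst case**: per-voxel min (for target coverage) and max
  (for hotspots) over i = 0..12 — a conservative, generally non-physical
  composite distribution.
- **Physical scenario worst case**: for each DVH metric, the worst value
  attained by any single realizable scenario.
- **DVH band**: the family of 13 cumulative DVHs and its pointwise envelope;
  the bandwidth at a metric point quantifies the plan's sensitivity.
- **EVH / RVH**: cumulative volume histograms of ebDD / RMSED within an ROI;
  their area under the curve (AUC, in Gy with a fractional volume axis)
  summarizes per-ROI variation — smaller AUC, less variation.

DVH-point metrics (D95%, D0.01cc, Dmean, Vx% of prescription) are computed
from exact sorted voxel doses. Per-ROI results across a cohort are pooled as
percent of prescription (%Rx), OARs are split into low-dose (<50% Rx) and
high-dose (≥50% Rx) groups, and the five methods are compared with a Pearson
correlation matrix plus a conservativeness summary of voxel-wise vs physical
scenario worst-case values.

Because clinical scenario doses come from a treatment planning system, the
package includes a synthetic phantom-cohort generator: analytic plans with a
near-uniform CTV plateau, a robust margin sized so worst-case excursions keep
the target covered, a logistic penumbra, and OARs spanning the high-gradient
and low-dose regimes; scenario doses are recomputed analytically under each
shift/range perturbation. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import imptrobust as ir
from imptrobust.dvh_engine import MetricSpec

plan = ir.generate_cohort(1, "prostate", seed=7)[0]
maps = ir.compute_maps(plan.scenario_set)

d95 = MetricSpec.d_percent(95)           # CTV coverage, lower is worse
s = ir.band_metric_summary(plan.scenario_set, plan.ctv.mask, d95)
vw = ir.worstcase_metric(maps, plan.ctv.mask, d95)
print(f"nominal D95 = {s.nominal_value:.2f} Gy")
print(f"band worst  = {s.band_worst:.2f} Gy at {s.worst_scenario_id}")
print(f"voxel-wise  = {vw:.2f} Gy (bandwidth {s.bandwidth:.2f} Gy)")
```

prints

```
nominal D95 = 36.98 Gy
band worst  = 36.76 Gy at U4
voxel-wise  = 36.72 Gy (bandwidth 0.22 Gy)
```

i.e. the worst single scenario (U4: −5 mm L/R shift with −3.5% range) lowers
CTV D95 by 0.22 Gy, and the voxel-wise minimum distribution is — as it must
be — slightly more conservative than the worst physical scenario.

The same reduction applied to published per-scenario mean doses of a head
and neck case (constrictor: nominal 28.6, U2 31.1, U4 28.2 Gy) identifies
U2 as the worst scenario at 31.1 Gy:

```python
from imptrobust.dvh_engine import summarize_metric_values
s = summarize_metric_values({"nominal": 28.6, "U2": 31.1, "U4": 28.2},
                            "higher_is_worse")
print(s.band_worst, s.worst_scenario_id)   # 31.1 U2
```

## Command line

```
imptrobust simulate-cohort --n-plans 2 --site prostate --seed 7 --out runs/sim
imptrobust compute-maps --manifest runs/sim/prostate-00/plan.yaml --out runs/maps
imptrobust compute-dvh  --manifest runs/sim/prostate-00/plan.yaml --out runs/dvh
imptrobust evaluate-vvh --manifest runs/sim/prostate-00/plan.yaml --out runs/vvh
imptrobust run-all --n-plans 20 --seed 42 --out runs/full
```

`run-all` writes the four robustness-map volumes per plan, the method table,
correlation and conservativeness CSVs, and a manifest with the config hash,
seed, and a checksum of every output file; reruns with the same config are
bit-identical. Exit codes: 0 success, 2 validation error, 3 internal
consistency error.

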