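# Methods

## Scenario model

Robustness is evaluated against systematic setup and range errors. The
scenario grid is the cross-product of one rigid shift of fixed magnitude `s`
along each anatomical axis and sign (±L/R, ±A/P, ±S/I) with each sign of a
range error of magnitude `r`: 12 scenarios, labelled U1..U12 in a frozen
order (axis-major, shift sign before range sign), plus the unperturbed
nominal scenario with index 0. There are deliberately no pure-range and no
diagonal-shift scenarios. The defaults are `s = 5 mm` for the prostate
profile, `s = 3 mm` for head and neck, and `r = 3.5%` for both. Positive
shift is the positive direction along the named grid axis (axis 0 = L/R,
axis 1 = A/P, axis 2 = S/I); only the symmetry of the ± pairs matters to the
evaluation layer. Scenario ids are load-bearing — reports name the worst
scenario — so the ordering is validated, not inferred.

## Per-voxel robustness fields

With `D_i(x,y,z)` the dose in scenario `i`:

- ebDD `= max_{i=0..12} D_i − min_{i=0..12} D_i`
- RMSED `= sqrt((1/12) Σ_{i=1..12} (D_0 − D_i)²)`
- voxel-wise min/max `= extrema over i = 0..12`

The extrema and ebDD include the nominal scenario in their index set; RMSED
measures deviation *from* nominal and sums over i = 1..12 only. The "mean"
in the RMSED name is taken literally: squared deviations are averaged over
the 12 scenarios before the root. The root-sum-square convention (larger by
exactly √12, so no correlation or ranking can change) remains available via
`compute_rmsed(..., mean=False)` and the `--rmsed-no-mean` flag.

All reductions accumulate one scenario grid at a time in the fixed order
nominal, U1..U12. This keeps the memory footprint at one grid and makes the
result bit-identical to a per-voxel loop in the same precision — which is
how the test suite checks the formulas, against independent brute-force
loops on small random scenario sets.

## DVH engine

Cumulative DVHs report the percent of ROI volume receiving at least each
dose level, evaluated on a regular edge grid (default bin 0.05 Gy) whose
last edge exceeds the maximum dose so the curve reaches 0%. The 13-curve
family for an ROI shares one edge grid spanning the global scenario maximum;
its pointwise max/min envelopes form the DVH band, and the band area is the
integral of (upper − lower) with the volume axis as a fraction (units Gy).

Headline metrics are never read off binned curves:

- `Dp%` is the ⌈p·N/100⌉-th largest voxel dose — equivalently the largest
  dose d with at least p% of the volume at or above d;
- `Dv cc` is the ⌈v / voxel volume⌉-th hottest voxel (a conservative ceiling
  rule with no sub-voxel interpolation: it errs toward hotter doses);
- `Dmean` is the arithmetic voxel mean;
- `Vt%` is the percent of voxels at or above `t/100 × Rx` (thresholds are
  percent-of-prescription; an absolute-Gy threshold can be expressed by
  scaling the parameter).

Curve-based reads of Dp% and Dmean exist for plotting workflows and agree
with the exact values within one bin width and half a bin width
respectively; the tests pin both consistency bounds.

For each metric, the *physical scenario worst case* is the worst of the 13
per-scenario values (minimum for coverage metrics, maximum for OAR metrics);
its bandwidth is max − min of the 13 values, nominal included; ties for the
worst value resolve to the lowest scenario index. The *voxel-wise worst
case* evaluates the metric on the voxel-wise min (coverage) or max (OAR)
field. Because the voxel-wise min is ≤ every scenario dose voxel-by-voxel,
its DVH lies at or below every scenario DVH pointwise, and every coverage
metric extracted from it is at most the band worst (symmetrically for the
max field). This dominance is exact, holds for every ROI, metric, and seed,
and is asserted over the whole synthetic cohort.

## EVH / RVH and the AUC identity

EVH and RVH are cumulative-descending histograms of the in-ROI ebDD and
RMSED values, built like DVHs but over variation dose, with the last edge
capped at the exact in-ROI maximum. The AUC integrates the curve
trapezoidally with the volume axis as a fraction, so its unit is Gy and it
is comparable across ROIs of different volume (a percent-axis variant,
×100, is available). By the survival-function identity
`∫ P(X ≥ t) dt = E[X]`, the exact AUC equals the ROI-mean variation; the
trapezoidal approximation differs from the mean by at most half a bin width
(the sum of survival-jump contributions is bounded by bin/2), which the
tests assert for every ROI in the cohort. Exact scale equivariance and
monotonicity hold in the bin → 0 limit; the property tests use bin-scaled
tolerances accordingly.

## Cohort comparison

One row per (plan, ROI, metric) joins the five quantities: EVH AUC, RVH AUC,
bandwidth, voxel-wise worst, band worst. Dose-valued quantities (including
the Gy-valued AUCs) are normalized to %Rx before pooling so prostate
(Rx ≈ 36–45 Gy) and head-and-neck (Rx ≈ 54–66 Gy) plans share one scale;
V-metric values are already percentages and pass through. OAR rows are
grouped by the nominal metric value against 50% Rx; V-metric rows, whose
value is a volume rather than a dose, are grouped by the ROI's nominal mean
dose instead. The Pearson matrix (all 10 pairs among the five columns) is
computed per stratum (CTV rows / OAR rows) with two-sided p-values from the
t distribution on n − 2 df, reported unadjusted; a clearly labelled
Holm-adjusted column is emitted alongside. A constant column yields a
flagged degenerate result instead of a silent NaN. Conservativeness is
summarized as box-plot quartiles of the paired gap in %Rx:
band worst − voxel-wise worst for coverage rows, the reverse for OAR rows.

## Synthetic phantom cohort

The generator replaces TPS scenario recalculation with an analytic model
chosen for testability: every scenario dose has a closed form, so oracles
(translation checks, edge-displacement probes, coverage bounds) are exact.

Nominal dose: `D_0(v) = Rx · S(d(v)) + ε(v)`, where `d` is the approximate
signed distance from the CTV-plus-robust-margin ellipsoid surface (first
order estimate `(ρ − 1)/|∇ρ|` on the normalized elliptic radius, accurate
near the surface where the falloff lives), `S` is a logistic falloff with
scale `penumbra_sigma` (default 2 mm), and `ε` is one zero-mean Gaussian
calculation-noise field per plan (default SD 0.02 Gy), clipped so doses stay
non-negative. Scenario doses re-evaluate the same model at coordinates
translated by −shift (the patient moves +shift, so a voxel samples the
anatomy shifted the other way) and with the depth coordinate along the
plan's single beam axis rescaled about the beam entry plane by
`1/(1 + range%/100)` — a positive range error pushes the distal falloff
deeper, in proportion to depth. Masks stay fixed: evaluation is in the
planning anatomy. The noise field is scenario-independent, so zero-magnitude
scenarios reproduce the nominal grid bitwise, which the degenerate-collapse
tests rely on.

Robust optimization is emulated geometrically: the margin is sized by a
fixed-point rule to absorb the setup shift plus the range-driven edge
excursion at the plan's depth plus a 3.25-sigma plateau buffer, so the CTV
surface stays above ≈96% of Rx in the worst combined scenario and worst-case
CTV D95 stays within 5% of nominal on every generated plan. OARs are *not*
protected, reproducing the familiar pattern: small variation inside the
target, large variation in the peri-target gradient shell.

Cohort defaults: 48³ voxels at 3 mm spacing (a 144 mm cube — large enough
for a CTV with 10–18 mm semi-axes plus margin, falloff, and distant OARs,
small enough that a 20-plan cohort evaluates in seconds on one CPU);
prescription drawn uniformly from the site range; per-plan geometry jitter;
prostate plans carry rectum (straddling the distal falloff, evaluated with
V90%/V65%) and bladder (beyond the gradient, low dose); head-and-neck plans
carry constrictor and larynx straddling the falloff (Dmean), oral cavity and
parotid mostly in the gradient tail (Dmean), and spinal cord, brainstem, and
optic chiasm as distant serial structures (D0.01cc). Each plan therefore
populates both the high-dose (≥50% Rx) and low-dose (<50% Rx) OAR groups.
All randomness flows from one root seed through per-plan spawned seed
sequences; plan ids, prescriptions, and noise seeds are recorded in the
cohort manifest.

What the phantom does *not* emulate — and hence what passing tests do not
show about clinical data: multi-field dose composition, entrance-channel
dose, tissue heterogeneity and Hounsfield-unit scaling, anatomical
deformation, inter-fraction random errors, and any specific optimizer's
dose shape. The analytic model is smooth and symmetric, so cross-method
correlations on synthetic cohorts are structural floors, not predictions of
clinical correlation values.

## Numerical choices and degenerate inputs

- Lattices must agree within 1e-6 mm; there is no resampling path, because
  every formula is defined voxel-by-voxel across scenarios and silent
  resampling would corrupt them.
- Doses must be finite and non-negative at ingestion; a NaN anywhere is an
  error before any computation, never a propagated value.
- Sub-voxel scenario shifts are exact by construction (analytic evaluation),
  so no interpolation scheme enters the synthetic pipeline.
- An empty ROI, a Dcc request beyond the ROI volume, fewer than 12
  scenarios, duplicate or out-of-order scenario ids, and a constant column
  in the correlation input each raise a distinct, named error (or a flagged
  result where a partial answer is still meaningful).
- `compute_maps` re-checks its own output (extrema bracket nominal,
  ebDD ≡ vw_max − vw_min, non-negativity) and raises an internal-consistency
  error rather than returning a violated invariant.

## Known limitations

- DICOM RT Dose import requires an uncompressed transfer syntax and a
  uniform frame spacing; RTSTRUCT contour rasterization is out of scope
  (masks arrive as label volumes).
- NIfTI-1 stores spacing/origin as 32-bit floats; round-trips are exact for
  the clean spacings clinical grids use, and NRRD round-trips are exact
  generally.
- The D0.01cc ceiling rule and the exact-sorted Dp% rule are deterministic
  conventions; other systems interpolate and may differ within one voxel or
  one bin.
- Probabilistic robustness (scenario sampling with error distributions,
  confidence maps) and percentile dose maps are out of scope.
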