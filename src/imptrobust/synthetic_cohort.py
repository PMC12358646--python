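"""Synthetic phantom plans with perturbed scenario doses.

This module stands in for a treatment planning system: it generates, for each
phantom plan, a nominal 3-D dose, ROI masks (CTV + OARs), and the 12 scenario
doses that a TPS would recalculate under combined setup/range uncertainty.

Dose model
----------
The nominal dose emulates a robustly optimized IMPT plan: a near-uniform
prescription-level plateau over the CTV expanded by a robust margin, with a
logistic falloff of scale ``penumbra_sigma`` outside it,

    D0(v) = rx * S(d(v)) + noise,      S(d) = 1 / (1 + exp(d / sigma)),

where d(v) is the (approximate) signed distance of the voxel centre from the
CTV-plus-margin ellipsoid surface (negative inside).  Scenario doses are
recomputed from the same analytic model with

* the dose field translated by -shift: the patient moving by +shift means
  each voxel samples the dose at the unshifted anatomy position - shift;
* the depth coordinate along ``beam_axis`` rescaled about the beam entry
  plane by 1/(1 + range_pct/100), so a positive range error pushes the
  distal falloff edge deeper (single-field emulation).

Because the model is analytic, scenario doses are exact for arbitrary
sub-voxel shifts; no resampling or interpolation is involved.  Calculation
noise is one Gaussian field per plan, re-used identically in every scenario,
so zero-magnitude scenarios reproduce the nominal dose bitwise.

The robust margin is sized so that the worst combined setup+range excursion
still leaves the CTV surface on the dose plateau, emulating robust
optimization on the CTV; OARs are not protected (optimized on the nominal
scenario only), so steep-gradient regions just outside the target remain
sensitive to the scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._errors import DegenerateGeometryError, ValidationError
from .dvh_engine import MetricSpec
from .grids_io import DoseGrid, ROIMask
from .scenario_model import (
    ScenarioSet,
    UncertaintyScenario,
    assemble_scenario_set,
    build_scenario_table,
)

SiteProfile = Literal["prostate", "head_neck", "mixed"]

#: per-site study conditions: setup magnitude (mm) and prescription range (Gy)
SITE_PROFILES: dict[str, dict] = {
    "prostate": {"setup_mm": 5.0, "range_pct": 3.5, "rx_range": (36.25, 45.0), "beam_axis": 0},
    "head_neck": {"setup_mm": 3.0, "range_pct": 3.5, "rx_range": (54.0, 66.0), "beam_axis": 1},
}

#: plateau-retention buffer in penumbra sigmas: S(-3.25) ~ 0.963, so the CTV
#: surface stays above ~96% of Rx in the worst combined scenario
_MARGIN_BUFFER_SIGMA = 3.25


@dataclass(frozen=True)
class OARSpec:
    """One organ-at-risk primitive: an ellipsoid offset from the CTV."""

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    metrics: tuple[MetricSpec, ...]
    abutting: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom plan's geometry and dose model."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    ctv_center: tuple[float, float, float]
    ctv_semi_axes: tuple[float, float, float]
    rx: float
    robust_margin: float
    oars: tuple[OARSpec, ...] = ()
    penumbra_sigma: float = 2.0
    beam_axis: int = 0
    noise_sd: float = 0.0
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rx <= 0:
            raise ValidationError(f"prescription must be > 0, got {self.rx}")
        if self.robust_margin < 0:
            raise ValidationError("robust margin must be >= 0")
        if self.penumbra_sigma <= 0:
            raise ValidationError("penumbra sigma must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")
        if self.beam_axis not in (0, 1, 2):
            raise ValidationError(f"beam axis must be 0, 1 or 2, got {self.beam_axis}")

    @property
    def entry_mm(self) -> float:
        """Physical coordinate of the beam entry plane (low face, beam axis)."""
        return self.origin[self.beam_axis] - self.spacing[self.beam_axis] / 2.0

    def lattice(self) -> DoseGrid:
        return DoseGrid(np.zeros(self.grid_shape), self.spacing, self.origin)


# ---------------------------------------------------------------------------
# Analytic model
# ---------------------------------------------------------------------------


def _axis_coords(spec: PhantomSpec) -> list[np.ndarray]:
    return [
        spec.origin[a] + spec.spacing[a] * np.arange(spec.grid_shape[a], dtype=np.float64)
        for a in range(3)
    ]


def _signed_distance_open(
    coords: Sequence[np.ndarray],
    center: Sequence[float],
    semi_axes: Sequence[float],
) -> np.ndarray:
    """Approximate signed distance (mm) to an ellipsoid surface, <0 inside.

    Uses the first-order estimate (rho - 1)/|grad rho| with rho the
    normalized elliptic radius; accurate near the surface, which is where the
    logistic falloff lives.
    """
    u = [
        (coords[a].reshape([-1 if i == a else 1 for i in range(3)]) - center[a]) / semi_axes[a]
        for a in range(3)
    ]
    rho_sq = u[0] ** 2 + u[1] ** 2 + u[2] ** 2
    rho = np.sqrt(rho_sq)
    g_sq = (u[0] / semi_axes[0]) ** 2 + (u[1] / semi_axes[1]) ** 2 + (u[2] / semi_axes[2]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (rho - 1.0) * rho / np.sqrt(g_sq)
    return np.where(rho < 1e-12, -float(min(semi_axes)), d)


def _analytic_dose(
    spec: PhantomSpec, shift: Sequence[float] = (0.0, 0.0, 0.0), range_pct: float = 0.0
) -> np.ndarray:
    """Noise-free dose array for one scenario of the analytic model."""
    coords = _axis_coords(spec)
    # patient moves by +shift => the voxel samples anatomy at (position - shift)
    coords = [c - s for c, s in zip(coords, shift)]
    eps = range_pct / 100.0
    if eps != 0.0:
        b = spec.beam_axis
        coords[b] = spec.entry_mm + (coords[b] - spec.entry_mm) / (1.0 + eps)
    semi = tuple(a + spec.robust_margin for a in spec.ctv_semi_axes)
    d = _signed_distance_open(coords, spec.ctv_center, semi)
    expo = np.clip(d / spec.penumbra_sigma, -60.0, 60.0)
    return spec.rx / (1.0 + np.exp(expo))


def _noise_field(spec: PhantomSpec) -> np.ndarray | float:
    if spec.noise_sd == 0.0:
        return 0.0
    rng = np.random.default_rng(spec.seed)
    return rng.normal(0.0, spec.noise_sd, spec.grid_shape)


def _ellipsoid_mask(
    spec: PhantomSpec, center: Sequence[float], semi_axes: Sequence[float]
) -> np.ndarray:
    """Center-of-voxel rasterization of an ellipsoid."""
    coords = _axis_coords(spec)
    u = [
        (coords[a].reshape([-1 if i == a else 1 for i in range(3)]) - center[a]) / semi_axes[a]
        for a in range(3)
    ]
    return (u[0] ** 2 + u[1] ** 2 + u[2] ** 2) <= 1.0


def rasterize_rois(spec: PhantomSpec) -> list[ROIMask]:
    """CTV and OAR masks for a phantom spec (CTV first)."""
    ctv = _ellipsoid_mask(spec, spec.ctv_center, spec.ctv_semi_axes)
    if not ctv.any():
        raise DegenerateGeometryError("CTV rasterizes to no voxels")
    for a in range(3):
        lo = spec.ctv_center[a] - spec.ctv_semi_axes[a]
        hi = spec.ctv_center[a] + spec.ctv_semi_axes[a]
        lo_edge = spec.origin[a] - spec.spacing[a] / 2.0
        hi_edge = spec.origin[a] + spec.spacing[a] * (spec.grid_shape[a] - 0.5)
        if lo < lo_edge or hi > hi_edge:
            raise DegenerateGeometryError(f"CTV extends outside the grid along axis {a}")
    rois = [ROIMask(ctv, name="CTV", role="target", rx=spec.rx)]
    for oar in spec.oars:
        m = _ellipsoid_mask(spec, oar.center, oar.semi_axes)
        if not m.any():
            raise DegenerateGeometryError(f"OAR '{oar.name}' rasterizes to no voxels")
        rois.append(ROIMask(m, name=oar.name, role="oar", rx=spec.rx))
    return rois


def generate_phantom(spec: PhantomSpec) -> tuple[DoseGrid, list[ROIMask]]:
    """Nominal dose and ROI masks for one phantom plan; deterministic by seed."""
    rois = rasterize_rois(spec)
    values = np.clip(_analytic_dose(spec) + _noise_field(spec), 0.0, None)
    return DoseGrid(values, spec.spacing, spec.origin), rois


def generate_scenario_doses(
    spec: PhantomSpec, scenarios: Sequence[UncertaintyScenario]
) -> ScenarioSet:
    """Recompute the analytic dose under each of the 12 scenario perturbations.

    Masks are not moved: evaluation happens in the planning anatomy frame.
    The same per-plan noise field is added to every scenario, so zero-magnitude
    descriptors reproduce the nominal grid bitwise.
    """
    extent = [spec.spacing[a] * spec.grid_shape[a] for a in range(3)]
    for s in scenarios:
        for a in range(3):
            if abs(s.shift[a]) >= extent[a]:
                raise ValidationError(
                    f"scenario {s.id}: shift {s.shift[a]} mm exceeds grid extent {extent[a]} mm"
                )
    noise = _noise_field(spec)
    nominal = DoseGrid(
        np.clip(_analytic_dose(spec) + noise, 0.0, None), spec.spacing, spec.origin
    )
    doses = [
        DoseGrid(
            np.clip(_analytic_dose(spec, s.shift, s.range_pct) + noise, 0.0, None),
            spec.spacing,
            spec.origin,
        )
        for s in scenarios
    ]
    return assemble_scenario_set(nominal, doses, list(scenarios))


def robust_margin_for(
    setup_mm: float,
    range_pct: float,
    depth_to_edge_mm: float,
    penumbra_sigma: float,
    buffer_sigma: float = _MARGIN_BUFFER_SIGMA,
) -> float:
    """Margin keeping the CTV on the plateau in the worst combined scenario.

    Accounts for the setup shift, the range-driven distal-edge excursion at
    the given depth, and a plateau buffer of ``buffer_sigma`` penumbra widths.
    """
    eps = range_pct / 100.0
    m = 0.0
    for _ in range(4):  # fixed-point: the margin itself adds depth
        m = setup_mm + eps / (1.0 - eps) * (depth_to_edge_mm + m) + buffer_sigma * penumbra_sigma
    return m


def ctv_shell_mask(spec: PhantomSpec, inner_mm: float, outer_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose distance outside the CTV surface lies in
    [inner_mm, outer_mm] — the peri-target gradient shell."""
    d = _signed_distance_open(_axis_coords(spec), spec.ctv_center, spec.ctv_semi_axes)
    return (d >= inner_mm) & (d <= outer_mm)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiEval:
    """An ROI together with the metrics it is evaluated on."""

    mask: ROIMask
    metrics: tuple[MetricSpec, ...]
    abutting: bool = False

    @property
    def name(self) -> str:
        return self.mask.name

    @property
    def role(self) -> str:
        return self.mask.role


@dataclass(frozen=True)
class PlanRecord:
    """One synthetic plan: spec, scenario doses, and evaluable ROIs."""

    plan_id: str
    site: str
    spec: PhantomSpec
    setup_mm: float
    range_pct: float
    scenario_set: ScenarioSet
    rois: tuple[RoiEval, ...]
    seed: int

    @property
    def rx(self) -> float:
        return self.spec.rx

    @property
    def ctv(self) -> RoiEval:
        return self.rois[0]

    @property
    def oars(self) -> tuple[RoiEval, ...]:
        return self.rois[1:]


def _prostate_oars(rng: np.random.Generator, c, a, margin: float) -> list[OARSpec]:
    """Rectum straddles the distal falloff (high-dose, wide DVH band);
    bladder sits beyond the gradient (low-dose)."""
    v_metrics = (MetricSpec.v_percent_rx(90.0), MetricSpec.v_percent_rx(65.0))
    rect_semi = (9 + rng.uniform(-1, 1), 8 + rng.uniform(-1, 1), 16 + rng.uniform(-2, 2))
    rect_off = a[1] + margin - 4.0 + rng.uniform(-1, 1)
    blad_semi = (11 + rng.uniform(-1, 1), 10 + rng.uniform(-1, 1), 11 + rng.uniform(-1, 1))
    blad_off = a[1] + margin + blad_semi[1] + 8.0
    return [
        OARSpec("rectum", (c[0], c[1] + rect_off, c[2]), rect_semi, v_metrics, abutting=True),
        OARSpec("bladder", (c[0], c[1] - blad_off, c[2]), blad_semi, v_metrics, abutting=False),
    ]


def _head_neck_oars(rng: np.random.Generator, c, a, margin: float) -> list[OARSpec]:
    """Constrictor and larynx straddle the falloff (high-dose group);
    oral cavity and parotid sit mostly in the gradient tail (low-dose group);
    cord, brainstem, and chiasm are distant serial structures (low-dose)."""
    dmean = (MetricSpec.d_mean(),)
    dcc = (MetricSpec.d_cc(0.01),)
    j = lambda w: rng.uniform(-w, w)  # noqa: E731 - small jitter helper
    con_semi = (11 + j(1), 5 + j(0.5), 14 + j(1))
    lar_semi = (9 + j(1), 8 + j(1), 9 + j(1))
    oc_semi = (13 + j(1), 11 + j(1), 9 + j(1))
    par_semi = (7 + j(0.5), 9 + j(1), 13 + j(1))
    return [
        OARSpec(
            "constrictor",
            (c[0], c[1] + a[1] + margin - 3.0 + j(1), c[2]),
            con_semi, dmean, abutting=True,
        ),
        OARSpec(
            "larynx",
            (c[0], c[1], c[2] - a[2] - margin + 2.0 + j(1)),
            lar_semi, dmean, abutting=False,
        ),
        OARSpec(
            "oral_cavity",
            (c[0], c[1] - a[1] - margin - 6.0 + j(1), c[2]),
            oc_semi, dmean, abutting=False,
        ),
        OARSpec(
            "parotid_r",
            (c[0] + a[0] + margin + 4.0 + j(1), c[1], c[2]),
            par_semi, dmean, abutting=False,
        ),
        OARSpec(
            "spinal_cord",
            (c[0], c[1] + a[1] + margin + 12.0, c[2]),
            (4.0, 4.0, 26.0), dcc, abutting=False,
        ),
        OARSpec(
            "brainstem",
            (c[0], c[1] + a[1] + margin + 10.0, c[2] + 24.0),
            (6.0, 6.0, 11.0), dcc, abutting=False,
        ),
        OARSpec(
            "optic_chiasm",
            (c[0], c[1], c[2] + a[2] + margin + 15.0),
            (5.0, 6.0, 3.0), dcc, abutting=False,
        ),
    ]


def generate_plan(
    site: str,
    seed_seq: np.random.SeedSequence,
    plan_id: str,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    noise_sd: float = 0.02,
    setup_mm: float | None = None,
    range_pct: float = 3.5,
    penumbra_sigma: float = 2.0,
) -> PlanRecord:
    """One randomized phantom plan for a site profile, deterministic by seed."""
    profile = SITE_PROFILES[site]
    setup = profile["setup_mm"] if setup_mm is None else float(setup_mm)
    rng = np.random.default_rng(seed_seq)
    noise_seed = int(seed_seq.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)

    grid_center = tuple(
        spacing[a] * (grid_shape[a] - 1) / 2.0 for a in range(3)
    )
    c = tuple(grid_center[a] + rng.uniform(-3.0, 3.0) for a in range(3))
    lo, hi = (10.0, 16.0) if site == "prostate" else (12.0, 18.0)
    a = tuple(rng.uniform(lo, hi) for _ in range(3))
    rx = float(rng.uniform(*profile["rx_range"]))
    beam_axis = profile["beam_axis"]

    entry = 0.0 - spacing[beam_axis] / 2.0
    depth = c[beam_axis] + a[beam_axis] - entry
    margin = robust_margin_for(setup, range_pct, depth, penumbra_sigma)

    oars = (
        _prostate_oars(rng, c, a, margin)
        if site == "prostate"
        else _head_neck_oars(rng, c, a, margin)
    )
    spec = PhantomSpec(
        grid_shape=grid_shape,
        spacing=spacing,
        ctv_center=c,
        ctv_semi_axes=a,
        rx=rx,
        robust_margin=margin,
        oars=tuple(oars),
        penumbra_sigma=penumbra_sigma,
        beam_axis=beam_axis,
        noise_sd=noise_sd,
        seed=noise_seed,
    )
    scenarios = build_scenario_table(setup, range_pct)
    sset = generate_scenario_doses(spec, scenarios)
    rois = rasterize_rois(spec)
    evals = [RoiEval(rois[0], (MetricSpec.d_percent(95.0, "lower_is_worse"),))]
    for mask, oar in zip(rois[1:], spec.oars):
        evals.append(RoiEval(mask, oar.metrics, abutting=oar.abutting))
    return PlanRecord(
        plan_id=plan_id,
        site=site,
        spec=spec,
        setup_mm=setup,
        range_pct=range_pct,
        scenario_set=sset,
        rois=tuple(evals),
        seed=noise_seed,
    )


def generate_cohort(
    n_plans: int,
    site_profile: SiteProfile = "mixed",
    seed: int = 0,
    **plan_kwargs,
) -> list[PlanRecord]:
    """A cohort of phantom plans; 'mixed' alternates prostate and head_neck.

    All randomness derives from one root seed via per-plan spawned seed
    sequences, so any cohort is reproducible bit-for-bit.
    """
    if n_plans < 1:
        raise ValidationError(f"n_plans must be >= 1, got {n_plans}")
    if site_profile not in ("prostate", "head_neck", "mixed"):
        raise ValidationError(f"unknown site profile {site_profile!r}")
    children = np.random.SeedSequence(seed).spawn(n_plans)
    plans = []
    for i, child in enumerate(children):
        site = (
            site_profile
            if site_profile != "mixed"
            else ("prostate" if i % 2 == 0 else "head_neck")
        )
        plans.append(
            generate_plan(site, child, plan_id=f"{site}-{i:02d}", **plan_kwargs)
        )
    return plans
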