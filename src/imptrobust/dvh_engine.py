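"""Cumulative DVHs, DVH-point metrics, DVH bands, and worst-case values.

A cumulative DVH gives, for each dose level d, the percentage of ROI volume
receiving at least d.  Robustness evaluation builds the family of 13 DVHs
(nominal + U1..U12) for each ROI; the pointwise envelope of that family is the
DVH band, the spread of a metric across the family is its bandwidth, and the
worst member value is the physical-scenario worst case.  Metrics may also be
evaluated on the voxel-wise min/max dose distributions (the voxel-wise
worst case), which is always at least as conservative.

Headline metrics (Dx%, Dcc, Dmean, Vx%) are computed from exact sorted voxel
doses, never from the binned curve, so they carry no bin-width sensitivity;
curves are for banding and plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from ._errors import MetricParameterError, ValidationError
from .grids_io import DoseGrid, ROIMask
from .robustness_maps import RobustnessMaps
from .scenario_model import ScenarioSet

DEFAULT_BIN_WIDTH_GY = 0.05

Direction = Literal["higher_is_worse", "lower_is_worse"]

MetricKind = Literal["D_percent_volume", "D_absolute_volume", "D_mean", "V_percent_rx"]


@dataclass(frozen=True)
class MetricSpec:
    """One DVH-point evaluation metric.

    ``direction`` states which extreme is clinically worst: target-coverage
    metrics (CTV D95%) are ``lower_is_worse``; OAR dose/volume metrics are
    ``higher_is_worse``.
    """

    kind: MetricKind
    parameter: float | None
    direction: Direction

    def __post_init__(self) -> None:
        if self.kind not in ("D_percent_volume", "D_absolute_volume", "D_mean", "V_percent_rx"):
            raise ValidationError(f"unknown metric kind {self.kind!r}")
        if self.direction not in ("higher_is_worse", "lower_is_worse"):
            raise ValidationError(f"unknown metric direction {self.direction!r}")
        if self.kind != "D_mean" and self.parameter is None:
            raise ValidationError(f"metric {self.kind} requires a parameter")
        if self.kind == "D_percent_volume" and not 0 < self.parameter <= 100:
            raise MetricParameterError(f"Dx% volume parameter must be in (0, 100], got {self.parameter}")
        if self.kind == "D_absolute_volume" and not self.parameter > 0:
            raise MetricParameterError(f"Dcc volume parameter must be > 0, got {self.parameter}")

    # -- constructors -------------------------------------------------------
    @classmethod
    def d_percent(cls, percent_volume: float, direction: Direction = "lower_is_worse") -> "MetricSpec":
        """D<p>%: minimum dose received by the hottest p% of the ROI volume."""
        return cls("D_percent_volume", float(percent_volume), direction)

    @classmethod
    def d_cc(cls, cc: float, direction: Direction = "higher_is_worse") -> "MetricSpec":
        """D<v>cc: minimum dose received by the hottest v cm^3."""
        return cls("D_absolute_volume", float(cc), direction)

    @classmethod
    def d_mean(cls, direction: Direction = "higher_is_worse") -> "MetricSpec":
        return cls("D_mean", None, direction)

    @classmethod
    def v_percent_rx(cls, percent_rx: float, direction: Direction = "higher_is_worse") -> "MetricSpec":
        """V<t>%: percent of ROI volume receiving at least t% of the prescription."""
        return cls("V_percent_rx", float(percent_rx), direction)

    @property
    def label(self) -> str:
        if self.kind == "D_percent_volume":
            return f"D{self.parameter:g}%"
        if self.kind == "D_absolute_volume":
            return f"D{self.parameter:g}cc"
        if self.kind == "D_mean":
            return "Dmean"
        return f"V{self.parameter:g}%"

    @property
    def unit(self) -> str:
        return "%" if self.kind == "V_percent_rx" else "Gy"


def parse_metric(label: str, direction: Direction | None = None) -> MetricSpec:
    """Parse a metric label such as 'D95%', 'D0.01cc', 'Dmean', 'V90%'.

    Default direction: D-percent metrics are coverage (lower_is_worse) and all
    others are higher_is_worse; pass ``direction`` to override.
    """
    s = label.strip()
    if s.lower() == "dmean":
        return MetricSpec.d_mean(direction or "higher_is_worse")
    if s[0] in "Dd" and s.endswith("cc"):
        return MetricSpec.d_cc(float(s[1:-2]), direction or "higher_is_worse")
    if s[0] in "Dd" and s.endswith("%"):
        return MetricSpec.d_percent(float(s[1:-1]), direction or "lower_is_worse")
    if s[0] in "Vv" and s.endswith("%"):
        return MetricSpec.v_percent_rx(float(s[1:-1]), direction or "higher_is_worse")
    raise ValidationError(f"cannot parse metric label {label!r}")


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH evaluated at ascending dose bin edges.

    ``volume_fraction[k]`` is the percentage (0..100) of ROI volume receiving
    at least ``dose_edges[k]``; the curve is monotone non-increasing, starts
    at 100% for dose 0 and ends at 0% beyond the maximum dose.
    """

    dose_edges: np.ndarray
    volume_fraction: np.ndarray
    roi_volume_cc: float
    scenario_id: str = "nominal"


@dataclass(frozen=True)
class DVHBand:
    """The 13-curve DVH family for one ROI with its pointwise envelope."""

    curves: tuple[DVHCurve, ...]
    upper: np.ndarray
    lower: np.ndarray
    dose_edges: np.ndarray

    def band_area(self) -> float:
        """Integral of (upper - lower) over dose, volume axis as fraction (Gy)."""
        return float(np.trapezoid((self.upper - self.lower) / 100.0, self.dose_edges))


def _roi_doses(dose: DoseGrid, roi: ROIMask) -> np.ndarray:
    roi.require_compatible(dose)
    return dose.values[roi.mask]


def _survival_percent(sorted_doses: np.ndarray, edges: np.ndarray) -> np.ndarray:
    n = sorted_doses.size
    below = np.searchsorted(sorted_doses, edges, side="left")
    return 100.0 * (n - below) / n


def _dose_edges(max_dose: float, bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be > 0, got {bin_width}")
    # final edge strictly beyond max so the curve reaches 0% on the grid
    n_bins = int(math.floor(max_dose / bin_width)) + 2
    return np.arange(n_bins + 1) * bin_width


def compute_dvh(
    dose: DoseGrid, roi: ROIMask, bin_width: float = DEFAULT_BIN_WIDTH_GY, scenario_id: str = "nominal"
) -> DVHCurve:
    """Cumulative DVH of the in-ROI voxel doses on a regular edge grid."""
    d = np.sort(_roi_doses(dose, roi))
    edges = _dose_edges(float(d[-1]), bin_width)
    return DVHCurve(
        dose_edges=edges,
        volume_fraction=_survival_percent(d, edges),
        roi_volume_cc=roi.volume_cc(dose),
        scenario_id=scenario_id,
    )


def compute_dvh_band(
    sset: ScenarioSet, roi: ROIMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> DVHBand:
    """The 13 scenario DVHs on shared dose edges, with pointwise envelopes."""
    roi.require_compatible(sset.nominal)
    samples = {s.id: np.sort(g.values[roi.mask]) for s, g in sset.iter_all()}
    global_max = max(float(v[-1]) for v in samples.values())
    edges = _dose_edges(global_max, bin_width)
    vol_cc = roi.volume_cc(sset.nominal)
    curves = tuple(
        DVHCurve(edges, _survival_percent(v, edges), vol_cc, sid) for sid, v in samples.items()
    )
    stack = np.stack([c.volume_fraction for c in curves], axis=0)
    return DVHBand(curves=curves, upper=stack.max(axis=0), lower=stack.min(axis=0), dose_edges=edges)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _metric_from_doses(doses: np.ndarray, spec: MetricSpec, roi: ROIMask, voxel_cc: float) -> float:
    n = doses.size
    if spec.kind == "D_mean":
        return float(np.mean(doses))
    if spec.kind == "D_percent_volume":
        # the ceil(p*N/100)-th largest dose: largest d with >= p% of volume at or above d
        k = math.ceil(spec.parameter * n / 100.0)
        k = min(max(k, 1), n)
        return float(np.partition(doses, n - k)[n - k])
    if spec.kind == "D_absolute_volume":
        roi_cc = n * voxel_cc
        if spec.parameter > roi_cc:
            raise MetricParameterError(
                f"requested volume {spec.parameter} cc exceeds ROI volume {roi_cc:.4f} cc"
            )
        k = math.ceil(spec.parameter / voxel_cc)
        k = min(max(k, 1), n)
        return float(np.partition(doses, n - k)[n - k])
    # V_percent_rx
    threshold = spec.parameter / 100.0 * roi.rx
    return float(100.0 * np.count_nonzero(doses >= threshold) / n)


def extract_metric(
    target: DVHCurve | tuple[DoseGrid, ROIMask], spec: MetricSpec
) -> float:
    """Evaluate a DVH-point metric.

    With a ``(DoseGrid, ROIMask)`` pair the metric is exact (sorted voxel
    doses).  With a :class:`DVHCurve`, D-percent metrics are read off the
    binned curve (within one bin width of the exact value) and Dmean is
    recovered from the differential histogram; Dcc and Vx% need voxel data.
    """
    if isinstance(target, DVHCurve):
        return _metric_from_curve(target, spec)
    dose, roi = target
    return _metric_from_doses(_roi_doses(dose, roi), spec, roi, dose.voxel_volume_cc)


def _metric_from_curve(curve: DVHCurve, spec: MetricSpec) -> float:
    vf, edges = curve.volume_fraction, curve.dose_edges
    if spec.kind == "D_percent_volume":
        ok = np.nonzero(vf >= spec.parameter)[0]
        if ok.size == 0:
            raise MetricParameterError(f"curve never reaches {spec.parameter}% volume")
        return float(edges[ok[-1]])
    if spec.kind == "D_mean":
        # differential volume in each bin times the bin midpoint
        dv = -np.diff(vf) / 100.0
        mids = 0.5 * (edges[:-1] + edges[1:])
        return float(np.sum(dv * mids))
    raise ValidationError(f"{spec.label} requires voxel data, not a binned curve")


# ---------------------------------------------------------------------------
# Band summaries and worst cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandMetricSummary:
    """A metric across the 13-scenario family.

    ``band_worst`` is the physical-scenario worst case for the metric: the
    minimum member value for coverage metrics, the maximum for OAR metrics;
    ``worst_scenario_id`` names the scenario attaining it (ties go to the
    lowest scenario index, nominal first).
    """

    values: dict[str, float]
    bandwidth: float
    band_worst: float
    worst_scenario_id: str

    @property
    def nominal_value(self) -> float:
        return self.values["nominal"]


def summarize_metric_values(
    values: Mapping[str, float], direction: Direction
) -> BandMetricSummary:
    """Reduce per-scenario metric values to bandwidth and the worst member.

    ``values`` maps scenario id to metric value in evaluation order (nominal
    first, then U1..U12); insertion order resolves ties toward the lowest
    scenario index.
    """
    if not values:
        raise ValidationError("no per-scenario metric values given")
    ids = list(values.keys())
    vals = np.asarray([values[i] for i in ids], dtype=np.float64)
    bandwidth = float(vals.max() - vals.min())
    idx = int(np.argmin(vals)) if direction == "lower_is_worse" else int(np.argmax(vals))
    return BandMetricSummary(
        values=dict(values),
        bandwidth=bandwidth,
        band_worst=float(vals[idx]),
        worst_scenario_id=ids[idx],
    )


def band_metric_summary(sset: ScenarioSet, roi: ROIMask, spec: MetricSpec) -> BandMetricSummary:
    """Evaluate a metric on each of the 13 scenario doses and reduce."""
    values = {s.id: extract_metric((g, roi), spec) for s, g in sset.iter_all()}
    return summarize_metric_values(values, spec.direction)


def worstcase_metric(maps: RobustnessMaps, roi: ROIMask, spec: MetricSpec) -> float:
    """The metric evaluated on the voxel-wise worst-case dose distribution.

    Coverage metrics (lower_is_worse) use the voxel-wise minimum; OAR metrics
    (higher_is_worse) use the voxel-wise maximum.  By DVH dominance this is
    always at least as conservative as the physical-scenario worst case.
    """
    grid = maps.vw_min if spec.direction == "lower_is_worse" else maps.vw_max
    return extract_metric((grid, roi), spec)
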