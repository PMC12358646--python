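"""Cross-method comparison over a cohort: %Rx normalization, dose grouping,
Pearson correlation matrix, and conservativeness summaries.

Five quantities are compared per (plan, ROI, metric) row: EVH AUC, RVH AUC,
DVH bandwidth, the voxel-wise worst-case metric value, and the physical
scenario worst-case (the worst member of the DVH band).  Rows are pooled
across plans after normalizing dose-valued quantities to percent of the
prescription (%Rx), and OAR rows are split into a low-dose (<50% Rx) and a
high-dose (>=50% Rx) group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError

#: the five method columns entering the correlation matrix (in %Rx scale)
METHOD_COLUMNS = ("evh_auc", "rvh_auc", "bandwidth", "vw_worst", "band_worst")

REQUIRED_ROW_FIELDS = (
    "plan", "roi", "roi_role", "metric", "metric_kind", "direction", "rx",
    "nominal", "evh_auc", "rvh_auc", "bandwidth", "vw_worst", "band_worst",
    "worst_scenario", "roi_nominal_dmean",
)

Stratum = Literal["ctv", "oar"]


def normalize_to_rx(value: float, rx: float) -> float:
    """Express a dose (Gy) as percent of the prescription dose."""
    if rx <= 0:
        raise ValidationError(f"prescription must be > 0, got {rx}")
    return 100.0 * value / rx


def _dose_group(row: pd.Series) -> str:
    if row["roi_role"] == "target":
        return "target"
    # V-metrics are percent volume, not dose: group those rows by the ROI's
    # nominal mean dose; dose-valued metrics use their own nominal value.
    ref = row["roi_nominal_dmean"] if row["metric_kind"] == "V_percent_rx" else row["nominal"]
    return "high" if normalize_to_rx(ref, row["rx"]) >= 50.0 else "low"


def build_method_table(rows) -> pd.DataFrame:
    """Validated per-(plan, roi, metric) comparison table.

    Adds the dose group and the %Rx-normalized method columns (``*_pct``):
    dose-valued metrics and the Gy-valued AUCs are scaled by 100/Rx; V-metric
    values are already percentages and pass through unchanged.
    """
    table = pd.DataFrame(list(rows)) if not isinstance(rows, pd.DataFrame) else rows.copy()
    missing = [c for c in REQUIRED_ROW_FIELDS if c not in table.columns]
    if missing:
        raise ValidationError(f"method table is missing columns: {missing}")
    if table[list(REQUIRED_ROW_FIELDS)].isna().any().any():
        bad = table.columns[table[list(REQUIRED_ROW_FIELDS)].isna().any()].tolist()
        raise ValidationError(f"method table has missing cells in columns: {bad}")
    table["dose_group"] = table.apply(_dose_group, axis=1)
    is_volume_metric = table["metric_kind"] == "V_percent_rx"
    scale = 100.0 / table["rx"]
    for col in ("nominal", "vw_worst", "band_worst", "bandwidth"):
        table[f"{col}_pct"] = np.where(is_volume_metric, table[col], table[col] * scale)
    for col in ("evh_auc", "rvh_auc"):
        table[f"{col}_pct"] = table[col] * scale
    return table


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two method columns within one stratum."""

    stratum: Stratum
    method_pair: tuple[str, str]
    r: float
    p: float
    p_holm: float
    n: int
    degenerate: bool = False


def _stratum_frame(table: pd.DataFrame, stratum: Stratum) -> pd.DataFrame:
    if stratum == "ctv":
        return table[table["roi_role"] == "target"]
    if stratum == "oar":
        return table[table["roi_role"] == "oar"]
    raise ValidationError(f"stratum must be 'ctv' or 'oar', got {stratum!r}")


def pearson_matrix(table: pd.DataFrame, stratum: Stratum) -> list[CorrelationResult]:
    """All 10 pairwise Pearson correlations among the five method columns.

    Values are correlated on the %Rx scale so plans with different
    prescriptions pool coherently.  p-values are two-sided (t distribution,
    n-2 df) and reported unadjusted; a Holm-adjusted p accompanies each pair.
    A constant column yields a flagged (degenerate) result rather than NaN
    propagating silently.
    """
    sub = _stratum_frame(table, stratum)
    n = len(sub)
    if n < 3:
        raise ValidationError(f"stratum {stratum!r} has {n} rows; need >= 3")
    cols = {m: sub[f"{m}_pct"].to_numpy(dtype=float) for m in METHOD_COLUMNS}
    raw: list[tuple[tuple[str, str], float, float, bool]] = []
    for a, b in combinations(METHOD_COLUMNS, 2):
        xa, xb = cols[a], cols[b]
        if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
            raw.append(((a, b), float("nan"), float("nan"), True))
            continue
        res = stats.pearsonr(xa, xb)
        raw.append(((a, b), float(res.statistic), float(res.pvalue), False))
    # Holm step-down over the valid pairs
    valid = [(i, p) for i, (_, _, p, deg) in enumerate(raw) if not deg]
    holm = {i: float("nan") for i in range(len(raw))}
    order = sorted(valid, key=lambda t: t[1])
    m = len(order)
    running = 0.0
    for rank, (i, p) in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p))
        holm[i] = running
    return [
        CorrelationResult(stratum, pair, r, p, holm[i], n, deg)
        for i, (pair, r, p, deg) in enumerate(raw)
    ]


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [c.stratum for c in results],
            "method_a": [c.method_pair[0] for c in results],
            "method_b": [c.method_pair[1] for c in results],
            "r": [c.r for c in results],
            "p": [c.p for c in results],
            "p_holm": [c.p_holm for c in results],
            "n": [c.n for c in results],
            "degenerate": [c.degenerate for c in results],
        }
    )


def conservativeness_gaps(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row conservativeness gap of the voxel-wise worst case, in %Rx.

    For coverage rows the voxel-wise value is expected at or below the band
    worst (gap = band_worst - vw_worst >= 0); for OAR rows at or above
    (gap = vw_worst - band_worst >= 0).
    """
    t = table.copy()
    sign = np.where(t["direction"] == "lower_is_worse", 1.0, -1.0)
    t["gap_pct"] = sign * (t["band_worst_pct"] - t["vw_worst_pct"])
    return t


def summarize_conservativeness(table: pd.DataFrame) -> pd.DataFrame:
    """Box-plot style quartile summary of the gap per dose group.

    One row per group (target / high / low) with n, min, q1, median, q3, max
    of (band_worst - vw_worst) for coverage rows and (vw_worst - band_worst)
    for OAR rows, both in %Rx.
    """
    t = conservativeness_gaps(table)
    out = []
    for group, sub in t.groupby("dose_group"):
        g = sub["gap_pct"].to_numpy(dtype=float)
        if g.size == 0:
            raise ValidationError(f"dose group {group!r} is empty")
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        out.append(
            {
                "group": group,
                "n": int(g.size),
                "min": float(g.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(g.max()),
            }
        )
    order = {"target": 0, "high": 1, "low": 2}
    out.sort(key=lambda r: order.get(r["group"], 9))
    return pd.DataFrame(out)
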