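"""End-to-end evaluation pipeline: cohort -> maps -> DVH/VVH -> comparison.

``evaluate_plan``/``evaluate_cohort`` produce the per-(plan, roi, metric)
rows consumed by :mod:`imptrobust.cohort_comparison`; ``run_pipeline`` wires
the whole chain with deterministic seeding, file outputs, and a manifest.
Plans come either from the synthetic generator or from plan manifest YAML
files pointing at volumes on disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import MissingScenarioError, ValidationError
from .cohort_comparison import (
    build_method_table,
    correlations_frame,
    pearson_matrix,
    summarize_conservativeness,
)
from .dvh_engine import (
    MetricSpec,
    band_metric_summary,
    compute_dvh_band,
    extract_metric,
    parse_metric,
    worstcase_metric,
)
from .grids_io import DoseGrid, read_mask, read_volume, write_volume
from .robustness_maps import RobustnessMaps, compute_maps
from .scenario_model import SCENARIO_IDS, UncertaintyScenario, assemble_scenario_set
from .synthetic_cohort import PlanRecord, RoiEval, generate_cohort
from .volume_histograms import compute_vvh


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults reflect the usual evaluation settings: 3.5% range uncertainty,
    site-profile setup magnitudes (5 mm prostate, 3 mm head and neck), and a
    0.05 Gy DVH bin.  The seed is recorded in every output manifest.
    """

    site_profile: str = "mixed"
    n_plans: int = 4
    seed: int = 0
    setup_mm: float | None = None  # None = per-site default
    range_pct: float = 3.5
    bin_width: float = 0.05
    rmsed_mean: bool = True
    noise_sd: float = 0.02
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    output_dir: str = "imptrobust-run"
    manifests: tuple[str, ...] = ()  # real-data mode: plan manifest YAMLs
    write_doses: bool = False
    force: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Row evaluation
# ---------------------------------------------------------------------------


def evaluate_plan(plan: PlanRecord, bin_width: float = 0.05, rmsed_mean: bool = True):
    """Method-comparison rows and artifacts (maps, VVHs) for one plan."""
    maps = compute_maps(plan.scenario_set, rmsed_mean=rmsed_mean)
    rows = []
    vvhs = {}
    dmean = MetricSpec.d_mean()
    for roi in plan.rois:
        evh = compute_vvh(maps.ebdd, roi.mask, "ebdd", bin_width)
        rvh = compute_vvh(maps.rmsed, roi.mask, "rmsed", bin_width)
        vvhs[roi.name] = (evh, rvh)
        roi_nominal_dmean = extract_metric((plan.scenario_set.nominal, roi.mask), dmean)
        for spec in roi.metrics:
            summary = band_metric_summary(plan.scenario_set, roi.mask, spec)
            vw = worstcase_metric(maps, roi.mask, spec)
            rows.append(
                {
                    "plan": plan.plan_id,
                    "site": plan.site,
                    "roi": roi.name,
                    "roi_role": roi.role,
                    "abutting": roi.abutting,
                    "metric": spec.label,
                    "metric_kind": spec.kind,
                    "direction": spec.direction,
                    "rx": plan.rx,
                    "nominal": summary.nominal_value,
                    "evh_auc": evh.auc,
                    "rvh_auc": rvh.auc,
                    "bandwidth": summary.bandwidth,
                    "vw_worst": vw,
                    "band_worst": summary.band_worst,
                    "worst_scenario": summary.worst_scenario_id,
                    "roi_nominal_dmean": roi_nominal_dmean,
                }
            )
    return rows, maps, vvhs


def evaluate_cohort(
    plans: Sequence[PlanRecord], bin_width: float = 0.05, rmsed_mean: bool = True
) -> pd.DataFrame:
    """The validated method table for a cohort of plans."""
    rows = []
    for plan in plans:
        plan_rows, _, _ = evaluate_plan(plan, bin_width=bin_width, rmsed_mean=rmsed_mean)
        rows.extend(plan_rows)
    return build_method_table(rows)


# ---------------------------------------------------------------------------
# Plan manifests (real-data entry point)
# ---------------------------------------------------------------------------


def load_plan_manifest(path: str | Path) -> PlanRecord:
    """Load a plan from a manifest YAML naming the 13 volumes and the ROIs.

    Schema::

        plan_id: p0
        site: prostate
        rx: 36.25
        setup_mm: 5.0
        range_pct: 3.5
        nominal: nominal.nrrd
        scenarios:
          - {id: U1, shift_mm: [5, 0, 0], range_pct: 3.5, path: u1.nrrd}
          - ...
        rois:
          - {name: CTV, role: target, path: ctv.nrrd, metrics: [D95%]}
          - {name: rectum, role: oar, path: rectum.nrrd, metrics: [V90%, V65%],
             abutting: true}
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    base = path.parent
    for key in ("plan_id", "rx", "nominal", "scenarios", "rois"):
        if key not in data:
            raise ValidationError(f"plan manifest {path} is missing key {key!r}")
    entries = {str(s["id"]): s for s in data["scenarios"]}
    missing = [sid for sid in SCENARIO_IDS if sid not in entries]
    if missing:
        raise MissingScenarioError(
            f"plan manifest {path} is missing scenario(s): {', '.join(missing)}"
        )
    nominal = read_volume(base / data["nominal"])
    descriptors, doses = [], []
    for sid in SCENARIO_IDS:
        e = entries[sid]
        descriptors.append(
            UncertaintyScenario(sid, tuple(e["shift_mm"]), float(e["range_pct"]))
        )
        doses.append(read_volume(base / e["path"]))
    sset = assemble_scenario_set(nominal, doses, descriptors)
    rx = float(data["rx"])
    rois = []
    for r in data["rois"]:
        mask = read_mask(base / r["path"], name=r["name"], role=r["role"], rx=rx)
        metrics = tuple(parse_metric(m) for m in r.get("metrics", []))
        rois.append(RoiEval(mask, metrics, abutting=bool(r.get("abutting", False))))
    if not rois or rois[0].role != "target":
        raise ValidationError(f"plan manifest {path}: first ROI must be the target")
    # a minimal spec stand-in is not needed for evaluation: PlanRecord only
    # uses the scenario set and ROIs downstream, plus rx via spec
    from .synthetic_cohort import PhantomSpec

    spec = PhantomSpec(
        grid_shape=nominal.shape,
        spacing=nominal.spacing,
        ctv_center=tuple(
            nominal.origin[a] + nominal.spacing[a] * (nominal.shape[a] - 1) / 2 for a in range(3)
        ),
        ctv_semi_axes=(1.0, 1.0, 1.0),
        rx=rx,
        robust_margin=float(data.get("setup_mm", 0.0)),
        origin=nominal.origin,
    )
    return PlanRecord(
        plan_id=str(data["plan_id"]),
        site=str(data.get("site", "unknown")),
        spec=spec,
        setup_mm=float(data.get("setup_mm", 0.0)),
        range_pct=float(data.get("range_pct", 0.0)),
        scenario_set=sset,
        rois=tuple(rois),
        seed=int(data.get("seed", 0)),
    )


def write_plan_files(plan: PlanRecord, out_dir: Path, write_doses: bool = True) -> dict:
    """Write a plan's volumes and manifest YAML; returns the manifest dict."""
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "plan_id": plan.plan_id,
        "site": plan.site,
        "rx": plan.rx,
        "setup_mm": plan.setup_mm,
        "range_pct": plan.range_pct,
        "seed": plan.seed,
        "scenarios": [],
        "rois": [],
    }
    if write_doses:
        write_volume(plan.scenario_set.nominal, out_dir / "nominal.nrrd")
        manifest["nominal"] = "nominal.nrrd"
        for s, g in plan.scenario_set.scenarios:
            fname = f"{s.id.lower()}.nrrd"
            write_volume(g, out_dir / fname)
            manifest["scenarios"].append(
                {"id": s.id, "shift_mm": list(s.shift), "range_pct": s.range_pct, "path": fname}
            )
        from .grids_io import write_mask

        for roi in plan.rois:
            fname = f"roi_{roi.name.lower()}.nrrd"
            write_mask(roi.mask, plan.scenario_set.nominal, out_dir / fname)
            manifest["rois"].append(
                {
                    "name": roi.name,
                    "role": roi.role,
                    "path": fname,
                    "abutting": roi.abutting,
                    "metrics": [m.label for m in roi.metrics],
                }
            )
    (out_dir / "plan.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


def write_maps(maps: RobustnessMaps, out_dir: Path, stem: str) -> list[str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for field_name in ("ebdd", "rmsed", "vw_min", "vw_max"):
        suffix = field_name.replace("_", "")
        fname = f"{stem}_{suffix}.nrrd"
        write_volume(getattr(maps, field_name), out_dir / fname)
        names.append(fname)
    return names


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full chain and write volumes, CSVs, and a run manifest.

    Synthetic mode (no manifests): generates the cohort from the config seed.
    Real-data mode: loads each plan manifest.  Rerunning with the same config
    reproduces all CSVs bit-identically.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise ValidationError(
            f"output directory {out} is not empty; pass force=True (--force) to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    if config.manifests:
        plans = [load_plan_manifest(m) for m in config.manifests]
    else:
        plans = generate_cohort(
            config.n_plans,
            site_profile=config.site_profile,  # type: ignore[arg-type]
            seed=config.seed,
            grid_shape=tuple(config.grid_shape),
            spacing=tuple(config.spacing),
            noise_sd=config.noise_sd,
            setup_mm=config.setup_mm,
            range_pct=config.range_pct,
        )

    all_rows = []
    band_rows = []
    vvh_rows = []
    files: list[str] = []
    for plan in plans:
        rows, maps, vvhs = evaluate_plan(plan, config.bin_width, config.rmsed_mean)
        all_rows.extend(rows)
        for row in rows:
            band_rows.append(row)
        for roi_name, (evh, rvh) in vvhs.items():
            vvh_rows.append(
                {
                    "plan": plan.plan_id,
                    "roi": roi_name,
                    "evh_auc": evh.auc,
                    "rvh_auc": rvh.auc,
                    "roi_volume_cc": evh.roi_volume_cc,
                }
            )
        plan_dir = out / plan.plan_id
        files.extend(f"{plan.plan_id}/{f}" for f in write_maps(maps, plan_dir, plan.plan_id))
        if config.write_doses:
            write_plan_files(plan, plan_dir, write_doses=True)
            files.append(f"{plan.plan_id}/plan.yaml")

    table = build_method_table(all_rows)
    corr_frames = []
    for stratum, role in (("ctv", "target"), ("oar", "oar")):
        if (table["roi_role"] == role).sum() >= 3:
            corr_frames.append(correlations_frame(pearson_matrix(table, stratum)))
    corrs = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(
            columns=["stratum", "method_a", "method_b", "r", "p", "p_holm", "n", "degenerate"]
        )
    )
    cons = summarize_conservativeness(table)

    outputs = {
        "method_table.csv": table,
        "correlations.csv": corrs,
        "conservativeness.csv": cons,
        "vvh_summary.csv": pd.DataFrame(vvh_rows),
    }
    for fname, frame in outputs.items():
        frame.to_csv(out / fname, index=False)
        files.append(fname)

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "flags": {
            "rmsed_divisor": "mean over 12" if config.rmsed_mean else "root-sum-square",
            "vvh_auc_axis": "fraction (Gy)",
            "bin_width_gy": config.bin_width,
        },
        "n_plans": len(plans),
        "files": {f: _sha256(out / f) for f in sorted(files)},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
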