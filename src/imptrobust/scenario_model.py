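"""The 12-scenario setup/range uncertainty model.

Worst-case robustness evaluation perturbs the plan with rigid setup shifts of
a fixed magnitude along each anatomical axis (L/R, A/P, S/I), each sign,
combined with a signed proton range uncertainty.  That cross-product of
{±axis shift} x {±range} yields 12 scenarios U1..U12 (no pure-range and no
diagonal-shift scenarios); the unperturbed plan is the nominal scenario,
index 0.  Scenario ids are load-bearing (reports name the worst scenario),
so the ordering is frozen:

    U1  = (+s, 0, 0) +r      U5  = (0, +s, 0) +r      U9  = (0, 0, +s) +r
    U2  = (+s, 0, 0) -r      U6  = (0, +s, 0) -r      U10 = (0, 0, +s) -r
    U3  = (-s, 0, 0) +r      U7  = (0, -s, 0) +r      U11 = (0, 0, -s) +r
    U4  = (-s, 0, 0) -r      U8  = (0, -s, 0) -r      U12 = (0, 0, -s) -r

with s the setup magnitude (mm) and r the range magnitude (%).  Positive
shift means the positive direction along the named grid axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._errors import (
    DuplicateScenarioError,
    LatticeMismatchError,
    ScenarioCountError,
    ValidationError,
)
from .grids_io import DoseGrid

N_SCENARIOS = 12

SCENARIO_IDS = tuple(f"U{i}" for i in range(1, N_SCENARIOS + 1))


@dataclass(frozen=True)
class UncertaintyScenario:
    """One setup+range perturbation: a rigid shift (mm) and a range error (%)."""

    id: str
    shift: tuple[float, float, float]
    range_pct: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", tuple(float(v) for v in self.shift))
        object.__setattr__(self, "range_pct", float(self.range_pct))
        if len(self.shift) != 3:
            raise ValidationError("scenario shift must be a 3-vector (L/R, A/P, S/I)")
        if self.id == "nominal":
            if any(self.shift) or self.range_pct:
                raise ValidationError("nominal scenario must have zero shift and zero range")
        elif sum(1 for v in self.shift if v != 0.0) > 1:
            raise ValidationError(f"scenario {self.id}: at most one nonzero shift component")

    @property
    def is_nominal(self) -> bool:
        return self.id == "nominal"

    def to_dict(self) -> dict:
        return {"id": self.id, "shift_mm": list(self.shift), "range_pct": self.range_pct}

    @classmethod
    def from_dict(cls, d: dict) -> "UncertaintyScenario":
        return cls(str(d["id"]), tuple(d["shift_mm"]), float(d["range_pct"]))


NOMINAL = UncertaintyScenario("nominal", (0.0, 0.0, 0.0), 0.0)


def build_scenario_table(setup_mm: float, range_pct: float) -> list[UncertaintyScenario]:
    """The 12 uncertainty scenarios for given setup (mm) and range (%) magnitudes.

    Clinically, 5 mm setup is used for prostate and 3 mm for head and neck,
    both with a 3.5% range uncertainty.
    """
    if setup_mm < 0 or range_pct < 0:
        raise ValidationError(
            f"setup/range magnitudes must be non-negative, got ({setup_mm}, {range_pct})"
        )
    out: list[UncertaintyScenario] = []
    n = 0
    for axis in range(3):
        for shift_sign in (1.0, -1.0):
            for range_sign in (1.0, -1.0):
                n += 1
                shift = [0.0, 0.0, 0.0]
                shift[axis] = shift_sign * setup_mm
                out.append(
                    UncertaintyScenario(f"U{n}", tuple(shift), range_sign * range_pct)
                )
    return out


@dataclass(frozen=True)
class ScenarioSet:
    """Nominal dose plus the 12 scenario doses, all on one lattice.

    Index 0 is the nominal scenario; indices 1..12 are U1..U12 in order.
    """

    nominal: DoseGrid
    scenarios: tuple[tuple[UncertaintyScenario, DoseGrid], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple((s, g) for s, g in self.scenarios))
        if len(self.scenarios) != N_SCENARIOS:
            raise ScenarioCountError(
                f"expected {N_SCENARIOS} uncertainty scenarios, got {len(self.scenarios)}"
            )
        ids = [s.id for s, _ in self.scenarios]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateScenarioError(f"duplicate scenario ids: {dupes}")
        if tuple(ids) != SCENARIO_IDS:
            raise ValidationError(f"scenario ids must be U1..U12 in order, got {ids}")
        for s, g in self.scenarios:
            if not self.nominal.same_lattice(g):
                raise LatticeMismatchError(
                    f"scenario {s.id} dose grid does not share the nominal lattice"
                )

    @property
    def grid(self) -> DoseGrid:
        """Lattice carrier (the nominal grid)."""
        return self.nominal

    def iter_all(self):
        """Yield (scenario, grid) for i = 0..12, nominal first."""
        yield NOMINAL, self.nominal
        yield from self.scenarios

    def grid_for(self, scenario_id: str) -> DoseGrid:
        for s, g in self.iter_all():
            if s.id == scenario_id:
                return g
        raise KeyError(scenario_id)

    def stacked(self) -> np.ndarray:
        """All 13 dose arrays stacked on a new leading axis (nominal first)."""
        return np.stack([g.values for _, g in self.iter_all()], axis=0)


def assemble_scenario_set(
    nominal: DoseGrid,
    doses: Sequence[DoseGrid],
    descriptors: Sequence[UncertaintyScenario],
) -> ScenarioSet:
    """Validate and bundle 12 scenario doses with their descriptors."""
    if len(doses) != N_SCENARIOS or len(descriptors) != N_SCENARIOS:
        raise ScenarioCountError(
            f"expected {N_SCENARIOS} doses and descriptors, got "
            f"{len(doses)} doses / {len(descriptors)} descriptors"
        )
    return ScenarioSet(nominal, tuple(zip(descriptors, doses)))


def scenarios_to_yaml(scenarios: Sequence[UncertaintyScenario], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump([s.to_dict() for s in scenarios], sort_keys=False))
    return path


def scenarios_from_yaml(path: str | Path) -> list[UncertaintyScenario]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ValidationError(f"scenario config {path} must be a list of descriptors")
    return [UncertaintyScenario.from_dict(d) for d in data]
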