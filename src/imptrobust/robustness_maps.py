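"""Per-voxel robustness maps: ebDD, RMSED, and voxel-wise extrema.

Writing D_i(x,y,z) for the dose at a voxel in scenario i (i = 0 nominal,
i = 1..12 the uncertainty scenarios):

* ebDD  = max_{i=0..12} D_i - min_{i=0..12} D_i    (error-bar dose distribution)
* RMSED = sqrt( (1/12) * sum_{i=1..12} (D_0 - D_i)^2 )
* voxel-wise min / max = extrema over i = 0..12

The voxel-wise extrema and ebDD include the nominal scenario in their index
set; RMSED measures deviation *from* nominal and therefore sums i = 1..12
only.  The RMSED name implies a mean inside the root, so we divide by 12
before taking the square root; ``mean=False`` restores the root-sum-square
convention (the two differ only by the constant sqrt(12), which cannot change
any correlation or ranking).

All reductions accumulate scenario-by-scenario in a fixed order (nominal,
U1..U12), so results are bit-identical to a per-voxel loop in the same
precision, and only one scenario grid needs to be resident at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import InternalConsistencyError
from .grids_io import DoseGrid
from .scenario_model import N_SCENARIOS, ScenarioSet


@dataclass(frozen=True)
class RobustnessMaps:
    """The four derived per-voxel fields of one scenario set."""

    ebdd: DoseGrid
    rmsed: DoseGrid
    vw_min: DoseGrid
    vw_max: DoseGrid
    n_scenarios: int = N_SCENARIOS
    includes_nominal_in_extrema: bool = True
    rmsed_mean: bool = True


def compute_ebdd(sset: ScenarioSet) -> DoseGrid:
    """Error-bar dose distribution: per-voxel max minus min over i = 0..12."""
    vw_min, vw_max = compute_voxelwise_extrema(sset)
    return vw_min.with_values(vw_max.values - vw_min.values)


def compute_rmsed(sset: ScenarioSet, mean: bool = True) -> DoseGrid:
    """Per-voxel RMS deviation of the 12 scenario doses from nominal.

    With ``mean=True`` (default) the squared deviations are averaged over the
    12 scenarios before the square root; ``mean=False`` gives the
    root-sum-square variant (values larger by exactly sqrt(12)).
    """
    d0 = sset.nominal.values
    acc = np.zeros_like(d0)
    for _, g in sset.scenarios:
        diff = d0 - g.values
        acc += diff * diff
    if mean:
        acc = acc / N_SCENARIOS
    return sset.nominal.with_values(np.sqrt(acc))


def compute_voxelwise_extrema(sset: ScenarioSet) -> tuple[DoseGrid, DoseGrid]:
    """Per-voxel (min, max) dose over i = 0..12, nominal included."""
    vmin = sset.nominal.values.copy()
    vmax = sset.nominal.values.copy()
    for _, g in sset.scenarios:
        np.minimum(vmin, g.values, out=vmin)
        np.maximum(vmax, g.values, out=vmax)
    return sset.nominal.with_values(vmin), sset.nominal.with_values(vmax)


def compute_maps(sset: ScenarioSet, rmsed_mean: bool = True) -> RobustnessMaps:
    """All four robustness fields, with internal-consistency checks.

    Raises :class:`InternalConsistencyError` if the computed fields violate
    their structural invariants (vw_min <= nominal <= vw_max, the identity
    ebDD = vw_max - vw_min, non-negativity).
    """
    vw_min, vw_max = compute_voxelwise_extrema(sset)
    ebdd = compute_ebdd(sset)
    rmsed = compute_rmsed(sset, mean=rmsed_mean)

    d0 = sset.nominal.values
    if np.any(vw_min.values > d0) or np.any(vw_max.values < d0):
        raise InternalConsistencyError("voxel-wise extrema do not bracket the nominal dose")
    if not np.array_equal(ebdd.values, vw_max.values - vw_min.values):
        raise InternalConsistencyError("ebDD != vw_max - vw_min")
    if float(ebdd.values.min()) < 0 or float(rmsed.values.min()) < 0:
        raise InternalConsistencyError("negative values in ebDD or RMSED map")
    return RobustnessMaps(
        ebdd=ebdd, rmsed=rmsed, vw_min=vw_min, vw_max=vw_max, rmsed_mean=rmsed_mean
    )
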