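import numpy as np
import pytest

import imptrobust as ir
from imptrobust.pipeline import evaluate_cohort
from imptrobust.synthetic_cohort import generate_plan

#: root seed of the study cohort used across the suite (20 plans, 10+10)
COHORT_SEED = 42


def make_random_scenario_set(seed: int, shape=(8, 8, 8), spacing=(2.5, 2.5, 2.5)):
    """A random (unstructured) scenario set for formula-level oracles."""
    rng = np.random.default_rng(seed)
    mk = lambda: ir.DoseGrid(rng.uniform(0.0, 70.0, shape), spacing)  # noqa: E731
    descriptors = ir.build_scenario_table(5.0, 3.5)
    return ir.assemble_scenario_set(mk(), [mk() for _ in range(12)], descriptors)


def single_voxel_set(nominal: float, scenario_doses):
    """A 1-voxel scenario set with prescribed per-scenario doses."""
    descriptors = ir.build_scenario_table(5.0, 3.5)
    mk = lambda v: ir.DoseGrid(np.full((1, 1, 1), float(v)), (2.5, 2.5, 2.5))  # noqa: E731
    return ir.assemble_scenario_set(mk(nominal), [mk(v) for v in scenario_doses], descriptors)


@pytest.fixture(scope="session")
def cohort():
    """The 20-plan synthetic study cohort: 10 prostate + 10 head and neck."""
    return ir.generate_cohort(20, "mixed", seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_table(cohort):
    return evaluate_cohort(cohort)


@pytest.fixture(scope="session")
def prostate_plan():
    return generate_plan("prostate", np.random.SeedSequence(7), "prostate-fix")


@pytest.fixture(scope="session")
def hn_plan():
    return generate_plan("head_neck", np.random.SeedSequence(11), "hn-fix")
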