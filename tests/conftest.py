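import numpy as np
import pytest

from alignersim.archframe import fit_arch_curve
from alignersim.dentition import generate_synthetic_dentition
from alignersim.staging import build_v_pattern_plan


@pytest.fixture(scope="session")
def dentition():
    return generate_synthetic_dentition(jitter_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def arch_curve(dentition):
    return fit_arch_curve(dentition.crown_points()[:, :2])


@pytest.fixture(scope="session")
def default_plan():
    return build_v_pattern_plan()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_single_group_plan(total: float = 0.5):
    """Short plan: only the second molars move (total/0.1 steps)."""
    totals = {"second_molar": total, "first_molar": 0.0, "second_premolar": 0.0,
              "first_premolar": 0.0, "canine": 0.0, "incisor": 0.0}
    return build_v_pattern_plan(totals)
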