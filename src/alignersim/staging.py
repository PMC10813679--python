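"""V-pattern staging: the step-by-tooth prescription schedule.

Activation sweeps anteriorly — second molars first, then first molars, second
premolars, first premolars, canines and finally the incisor block — with each
group starting once the previous one has completed ``1 - overlap_fraction``
of its steps. Posterior teeth get a fixed distal increment along the arch
curve per active step; incisors get a fixed palatal (posterior, +Y)
increment. Left and right quadrants are synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archframe import ArchCurve, distal_direction
from .dentition import FDI_ORDER, DentitionModel
from .errors import StagingError

#: Activation order: group name -> member FDI codes (both quadrants).
GROUP_SEQUENCE: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("second_molar", (17, 27)),
    ("first_molar", (16, 26)),
    ("second_premolar", (15, 25)),
    ("first_premolar", (14, 24)),
    ("canine", (13, 23)),
    ("incisor", (12, 11, 21, 22)),
)

GROUP_NAMES: tuple[str, ...] = tuple(name for name, _ in GROUP_SEQUENCE)

INCISOR_FDIS = frozenset((11, 12, 21, 22))

#: Default per-tooth totals (mm): 20 posterior steps at 0.1, 20 incisor steps
#: at 0.15, reconstructing the published 70-step schedule.
DEFAULT_TOTALS: dict[str, float] = {
    "second_molar": 2.0,
    "first_molar": 2.0,
    "second_premolar": 2.0,
    "first_premolar": 2.0,
    "canine": 2.0,
    "incisor": 3.0,
}

DEFAULT_STEP_SIZES: tuple[float, float] = (0.1, 0.15)


@dataclass
class StagingPlan:
    """Deterministic step x tooth prescription matrix (scalar magnitudes, mm)."""

    n_steps: int
    prescriptions: np.ndarray  # (n_steps, 14) scalar magnitude per tooth
    activation_windows: dict[int, tuple[int, int]] = field(default_factory=dict)
    step_sizes: tuple[float, float] = DEFAULT_STEP_SIZES

    def magnitudes(self, step: int) -> dict[int, float]:
        """Per-FDI prescribed magnitude at 1-based ``step``."""
        if not 1 <= step <= self.n_steps:
            raise IndexError(f"step {step} outside [1, {self.n_steps}]")
        row = self.prescriptions[step - 1]
        return {fdi: float(row[i]) for i, fdi in enumerate(FDI_ORDER)}

    def active_fdis(self, step: int) -> list[int]:
        return [fdi for fdi, m in self.magnitudes(step).items() if m > 0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.prescriptions, columns=[str(f) for f in FDI_ORDER])
        df.insert(0, "step", np.arange(1, self.n_steps + 1))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_v_pattern_plan(totals: dict[str, float] | None = None,
                         step_sizes: tuple[float, float] = DEFAULT_STEP_SIZES,
                         overlap_fraction: float = 0.5) -> StagingPlan:
    """Build the staged prescription schedule.

    ``totals`` maps each group name in :data:`GROUP_NAMES` to its per-tooth
    total prescription (mm); totals must be integer multiples of the group's
    step size. ``overlap_fraction`` in [0, 1] controls how early each group
    starts relative to its predecessor.
    """
    totals = dict(DEFAULT_TOTALS if totals is None else totals)
    if not totals:
        raise StagingError("totals must not be empty")
    unknown = set(totals) - set(GROUP_NAMES)
    if unknown:
        raise StagingError(f"unknown staging groups: {sorted(unknown)}")
    missing = set(GROUP_NAMES) - set(totals)
    if missing:
        raise StagingError(f"missing staging groups: {sorted(missing)}")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise StagingError("overlap_fraction must be in [0, 1]")
    posterior_step, incisor_step = step_sizes
    if posterior_step <= 0 or incisor_step <= 0:
        raise StagingError("step sizes must be positive")

    windows: dict[str, tuple[int, int]] = {}
    start = 1
    n_steps = 0
    prev_count = None
    for name, _ in GROUP_SEQUENCE:
        size = incisor_step if name == "incisor" else posterior_step
        total = totals[name]
        if total < 0:
            raise StagingError(f"{name}: negative total")
        count_f = total / size
        count = int(round(count_f))
        if abs(count_f - count) > 1e-9:
            raise StagingError(
                f"{name}: total {total} mm is not divisible by step size {size} mm")
        if prev_count is not None:
            start += int(round((1.0 - overlap_fraction) * prev_count))
        if count > 0:
            windows[name] = (start, start + count - 1)
            n_steps = max(n_steps, start + count - 1)
            prev_count = count
        # zero-length groups neither occupy a window nor delay successors

    prescriptions = np.zeros((n_steps, len(FDI_ORDER)))
    tooth_windows: dict[int, tuple[int, int]] = {}
    for name, members in GROUP_SEQUENCE:
        if name not in windows:
            continue
        first, last = windows[name]
        size = incisor_step if name == "incisor" else posterior_step
        for fdi in members:
            col = FDI_ORDER.index(fdi)
            prescriptions[first - 1:last, col] = size
            tooth_windows[fdi] = (first, last)

    return StagingPlan(n_steps=n_steps, prescriptions=prescriptions,
                       activation_windows=tooth_windows,
                       step_sizes=(posterior_step, incisor_step))


def step_prescriptions(plan: StagingPlan, step: int,
                       dentition: DentitionModel,
                       curve: ArchCurve) -> dict[int, np.ndarray]:
    """Resolve step magnitudes into occlusal-frame 3-vector targets.

    Posterior teeth move along the arch-curve tangent (distally); incisors
    translate palatally, i.e. straight posterior (+Y). Inactive teeth map to
    the zero vector.
    """
    out: dict[int, np.ndarray] = {}
    for fdi, magnitude in plan.magnitudes(step).items():
        if magnitude == 0.0:
            out[fdi] = np.zeros(3)
        elif fdi in INCISOR_FDIS:
            out[fdi] = np.array([0.0, magnitude, 0.0])
        else:
            tangent = distal_direction(curve, dentition.tooth(fdi))
            out[fdi] = np.array([tangent[0] * magnitude, tangent[1] * magnitude, 0.0])
    return out
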