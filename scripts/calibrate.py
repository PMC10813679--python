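"""Calibration sweep that produced the shipped default stiffness constants.

Runs the default control-group simulation (and optionally all four anchorage
groups) over a small grid of coupling/PDL surrogate parameters and reports,
for each candidate:

* the maximum diagnostic third-iteration PDL strain (steadiness; must stay
  below 0.1%),
* the maximum aligner gap (must stay below 1.2 mm),
* whole-run molar distalization efficiencies and incisor retraction,
* arch-width changes,

so that the frozen defaults in ``alignersim.mechanics`` can be re-derived or
re-tuned. The shipped values are::

    CouplingConstants(k_interface=8000, k_interface_rot=50, k_chain=60000,
                      k_chain_rot=2e6, attachment_rot_multiplier=10)
    PDLConstants(pdl_thickness=0.85, confinement_factor=20)

Usage: python scripts/calibrate.py [--full] [--seed N]
"""

from __future__ import annotations

import argparse
import itertools

from alignersim.archframe import fit_arch_curve
from alignersim.dentition import generate_synthetic_dentition
from alignersim.mechanics import AnchorageConfig, CouplingConstants, PDLConstants
from alignersim.metrics import (achieved_distal_displacement, arch_width_change,
                                incisor_retraction)
from alignersim.remodeling import run_simulation


def evaluate(coupling: CouplingConstants, constants: PDLConstants,
             groups: tuple[str, ...], seed: int) -> list[dict]:
    dentition = generate_synthetic_dentition(seed=seed)
    curve = fit_arch_curve(dentition.crown_points()[:, :2])
    rows = []
    for group in groups:
        trace = run_simulation(dentition=dentition, coupling=coupling,
                               constants=constants,
                               anchorage=AnchorageConfig(group=group), seed=seed)
        gap, gap_fdi, gap_step = trace.max_gap()
        rows.append({
            "group": group,
            "third_iter_strain_pct": 100 * trace.max_third_iteration_strain(),
            "max_gap_mm": gap,
            "gap_argmax": (gap_fdi, gap_step),
            "incisor_retraction_mm": incisor_retraction(trace),
            "eff_m1_pct": achieved_distal_displacement(trace, dentition, 16, curve) / 2.0 * 100,
            "eff_m2_pct": achieved_distal_displacement(trace, dentition, 17, curve) / 2.0 * 100,
            "width_molar_mm": arch_width_change(trace, "molar"),
            "width_premolar_mm": arch_width_change(trace, "premolar"),
        })
    return rows


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--full", action="store_true",
                        help="run all four anchorage groups per candidate")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    groups = AnchorageConfig.GROUPS if args.full else ("control",)
    k_interface_grid = (4000.0, 8000.0)
    confinement_grid = (10.0, 20.0, 30.0)

    for k_int, conf in itertools.product(k_interface_grid, confinement_grid):
        coupling = CouplingConstants(k_interface=k_int)
        constants = PDLConstants(confinement_factor=conf)
        rows = evaluate(coupling, constants, groups, args.seed)
        print(f"\nk_interface={k_int:.0f} confinement={conf:.0f}")
        for r in rows:
            print(f"  {r['group']:15s} it3={r['third_iter_strain_pct']:.4f}% "
                  f"gap={r['max_gap_mm']:.2f} "
                  f"inc={r['incisor_retraction_mm']:+.2f} "
                  f"effM1={r['eff_m1_pct']:+.1f}% effM2={r['eff_m2_pct']:+.1f}% "
                  f"width=({r['width_molar_mm']:+.2f}, {r['width_premolar_mm']:+.2f})")


if __name__ == "__main__":
    main()
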