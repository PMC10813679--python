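# alignersim

Reduced-order, desk-scale simulator of long-term maxillary whole-arch
distalization with clear aligners. The simulator reproduces, at the level of
rigid-tooth landmarks and spring fields, a staged "4D" treatment loop:

* a **synthetic maxillary dentition** (14 teeth, FDI 17–27) laid out by arc
  length along a quartic arch template, with crown points, crown margins,
  centers of resistance, apices and long axes;
* an **occlusal coordinate frame** (origin at the central incisors' midpoint,
  +X toward the patient's left, +Y posterior, +Z apical) and a fourth-order
  polynomial **arch-form fit** providing distal tangent directions;
* a 70-step **V-pattern staging plan** (0.1 mm/step distal along the arch for
  canine–second molar, 0.15 mm/step palatal for the incisor block, groups
  activated sequentially with 50% overlap);
* a segment-chain **aligner** whose programmed shape is advanced each step by
  the temperature-changing bookkeeping `U = k (d + ΣΔ) t` and
  `(X,Y)ₙ = (X,Y)ₙ₋₁ + U·e·λ` inside interdental deformation regions, seated
  onto the dentition by least-squares rigid **wear-in** registration;
* a quasi-static **mechanics** model: bilinear periodontal-ligament spring
  fields sampled on paraboloid root surfaces, interface and chain springs for
  the shell, and point loads for the anchorage groups (control, Class II
  elastics, buccal TAD, palatal TAD; 150 gf);
* an iterative **remodeling engine**: per step the shell is regenerated and
  seated, two equilibrium+remodeling iterations are run, and a diagnostic
  third equilibrium verifies steadiness (<0.1% residual PDL strain);
* **metrics**: per-tooth displacements and long-axis rotations, distalization
  efficiency, movement classification (bodily / controlled / uncontrolled
  tipping / root movement), arch-width change and aligner gap.

## CLI

```bash
alignersim generate --out dentition.json          # synthetic dentition (JSON + CSV)
alignersim plan --out plan.csv                    # 70-step staging schedule
alignersim simulate --group palatal_tad           # one run: trace CSV + summary JSON
alignersim report runs/trace_control.csv          # metrics from a saved trace
alignersim compare --out-dir runs                 # all four anchorage groups + comparison table
```

All behavior is configured through a YAML/JSON file (`--config`); an empty
file means the all-default control-group 70-step run. See
`alignersim/config.py` for the schema; every output embeds the config hash.

## Conventions and caveats

* Units: mm, N, N·mm; degrees in reports, radians internally. Intrusion is +Z
  (apical) crown-point displacement; incisor retraction is +Y (posterior).
* The default staging totals (2.0 mm per posterior tooth, 3.0 mm incisor
  retraction, 50% overlap) are a reconstruction that reproduces the published
  70-step total with both molars co-active during steps 11–20; the exact
  per-cell schedule of the source figure is not published numerically.
* The PDL surrogate uses an effective compliance-layer thickness (0.85 mm) and
  a volumetric-confinement force factor (20×) calibrated so that staged
  displacement-driven movement and the 150 gf anchorage-force response are
  both on clinically plausible scales; the bilinear stress-strain constants
  (e1 = 0.05 MPa, ε₁₂ = 0.075, e2 = 0.22 MPa) are conventional literature
  values and fully config-overridable.
* The aligner/attachment shell moduli (1500 / 20000 MPa) and contact friction
  (0.2) of the source appliance are carried as provenance metadata; the actual
  couplings are calibrated spring constants.
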