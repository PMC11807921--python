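# tavrgen

A scriptable virtual-patient authoring toolkit for transcatheter aortic
valve replacement (TAVR) training. Simulation-based TAVR education needs a
steady supply of anatomically plausible, *varied* patient cases, but
real segmented datasets are scarce, hard to modify and slow to turn into
scenarios. `tavrgen` instead generates patients parametrically: a
procedural, fully labelled aortic-root/heart model whose anatomy is
controlled by per-vertex-animation (PVA) morphs, a constraint-aware random
generator coupled to the EuroSCORE II surgical-risk model, and a simulated
fluoroscopy renderer that images the result from arbitrary C-arm poses.

Intended users: developers of medical-training software, simulation
researchers, and educators who want reproducible, seed-controlled TAVR
cases without patient data.

## What it computes

**Morphable anatomy.** The heart model is built as watertight labelled
submeshes (aorta, three valve leaflets, left ventricle, myocardium, left
and right coronary arteries). Each anatomical feature *f* with implemented
range [lo, hi] drives a PVA group: vertex positions are

    v_i(w) = v_i(0) + w · d_i ,    w = (value − lo) / (hi − lo)

with d_i the per-vertex displacement spanning the full range, so morphing
is linear, superposable, and exactly invertible by the built-in measuring
tool (cross-section diameters, landmark heights relative to the virtual
basal ring).

**Constrained generation.** Features are drawn uniformly in dependency
order: independent ones (aortic diameter, sinotubular height, valve
diameter) from their implemented ranges, dependent ones (coronary ostium
distances, effective heights, ventriculoarterial height, basal-ring
diameter, leaflet openings) from ranges dynamically tightened by linear
bound rules — e.g. the ST junction may never be narrower than the valve,
and the VA height must reach the tallest leaflet's effective height.

**Surgical risk.** EuroSCORE II predicted mortality
`p = 100·e^y/(1+e^y)`, `y = β₀ + Σ βᵢxᵢ`, over the published 18-item
profile; risk profiles are sampled from documented base prevalences scaled
by per-item probability multipliers.

**Simulated fluoroscopy.** Beer–Lambert projection `I = I₀·exp(−Σ μ_s L_s)`
with per-structure path lengths from watertight ray casting, bolus-shaped
contrast injection per compartment (coronaries, or ventricle + aorta),
Gaussian grain, and digital subtraction angiography.

## Worked example

```sh
$ tavrgen generate --seed 42 --out patient42.json
EuroSCORE II: 0.68 %
  aorta_diameter                        28.84 mm
  basal_ring_diameter                   17.45 mm
  lca_distance                           4.93 mm
  leaflet_effective_height_left          8.08 mm
  ...
  st_height                             19.93 mm
  va_height                             18.22 mm
  valve_diameter                        26.77 mm
saved patient42.json
```

The printed block is the patient's anatomy (drawn inside the implemented
ranges and their dependency constraints) and the EuroSCORE II predicted
in-hospital mortality of the sampled risk profile (0.68 % — an elective,
low-risk presentation). The same seed always reproduces the same record,
byte for byte.

Realise and verify the anatomy:

```python
from tavrgen import (build_base_mesh, generate_patient, patient_to_mesh,
                     measure_feature, FeatureName)
rec = generate_patient(42)
mesh = patient_to_mesh(rec, build_base_mesh())
measure_feature(mesh, FeatureName.AORTA_DIAMETER)   # 28.82 mm vs 28.84 recorded
```

Image it:

```sh
tavrgen fluoro patient42.json --out frame.png --lao 30 --cranial -10 \
        --contrast coronaries --dsa
tavrgen vitals patient42.json     # HR 73 bpm  BP 121/82 mmHg  SpO2 98 %
```

Other subcommands: `morph` (export the patient's mesh as OBJ/PLY with one
named group per structure), `measure` (feature table, `--json` for
machine-readable output), `euroscore`.

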