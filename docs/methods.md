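# Methods

## The anatomical model

The heart is generated procedurally as eight watertight, labelled triangle
submeshes in a right-handed patient coordinate system (mm): origin at the
centre of the virtual basal ring, +z superior toward the aortic arch, +x
toward patient left. The *virtual basal ring* — the reference for every
height measurement — is the plane through the three lowest leaflet-hinge
points, the standard imaging convention for the aortic annulus (the
anatomical boundary itself is not sharply defined).

* **Aorta.** A surface of revolution: a sinus segment from the annulus
  (z = 0, radius = valve radius) to the sinotubular (ST) ridge at
  z = ST height, carrying a three-lobed bulge (up to +20 % of the valve
  radius, one lobe per sinus), then an 8 mm transition to the tubular
  ascending aorta (radius = aorta radius, 32 mm long), capped at both
  ends. The profile is exactly cylindrical in small margins at the
  annulus and at the measurement plane, so cross-sections recover the
  configured diameters exactly.
* **Leaflets.** Each leaflet attaches along a crown-shaped hinge curve
  (z = VA height at the commissures, 0 at the sector centre). The free
  edge sweeps the same 120° angular fan as the hinge, dipping linearly
  from the commissures to the coaptation point (radius r_c, height =
  effective height) at the sector centre; a ruled surface between hinge
  and free edge forms the mid-surface, thickened ±0.3 mm along its
  normals and stitched around the boundary. Keeping every grid column at
  its own angle makes the mid-surface injective, which is what protects
  the offset sheets from self-intersection at morph extremes (a free
  edge that doubles back through a single coaptation point folds, and
  its offset sheets cross; the suite's triangle-crossing oracle guards
  this property at every morph endpoint).
* **Left ventricle / myocardium.** The LV is a revolve from a cylindrical
  LVOT neck (radius = basal-ring radius, where the basal-ring diameter is
  measured) through a 24 mm belly to an apex point; the myocardium is a
  static enclosing shell. Structures are solid and may overlap — the
  renderer adds attenuations, which is the intended composite behaviour.
* **Coronaries.** Capped cylindrical stubs (radius 1.5 mm, length 14 mm)
  emerging radially at the right/left sinus centres, with the inner cap
  centre at the ostium height above the basal plane.

### Exact affine landmarks

Every measurable length is realised so that its defining landmark
coordinate is a *linear* function of its own feature value and independent
of all others (e.g. the ST ridge ring sits at z = ST height exactly; the
coaptation mid-point of a leaflet sits at z = effective height). The
leaflet sheets are offset along normals — which are *not* affine in the
features — but every landmark is the mean of a top/bottom vertex pair, so
the offsets cancel identically. Consequences:

* morphing a feature to any value and measuring it back is exact up to
  cross-section polygonisation (≤ 0.1 % at the default resolution);
* combined morphs never couple measurements, so a random patient's mesh
  reproduces its record within the 2 % contract on all length features.

Leaflet opening is the exception by design: it is a percentage of the
free-edge excursion between a fixed shut radius (1.5 mm) and a fixed
fully-open reference radius (6.8 mm, chosen as 75 % of the smallest valve
radius so the excursion is realisable for every anatomy).

## Morphing (PVA)

Displacement fields are generated analytically by the builder — the mesh
is constructed at a feature's lower and upper range endpoint and the
difference is the field — not sculpted. The base (reference) pose places
every feature at the *lower* end of its implemented range, so an absolute
weight w = (value − lo)/(hi − lo) satisfies simultaneously: weight 0 =
base pose = range bottom, weight 1 = range top, and an all-zero morph
state is the identity. A mesh built at a different neutral configuration
records per-group neutral weights and missing weights default to them.
Weights outside [0, 1] are applied with a warning rather than clamped:
going beyond the implemented ranges is allowed, but the risk signal is
preserved.

Directional ostium groups (up/down/left/right per coronary) are rigid
translations of 2 mm per unit weight. The heartbeat is four keyframes per
track (end-diastole, peak systole, end-systole, diastasis) driving radial
contraction fields per structure (10 % LV, 8 % myocardium/coronaries, 3 %
aorta); tracks are independently addressable and linearly interpolated
with wrap-around, period 60/heart-rate. Keyframe count and phases are this
package's choice of the smallest periodic cycle that looks like a beat.

## Parameter space

The registry stores, per feature, the implemented range, the literature
range (documentation only), the dependency list and the PVA groups. The
effective-height default range is 7.5–12.2 mm, bracketing the published
mean of 8.5 ± 1.4 mm; the LCA-distance default (0.1–5.9 mm) sits well
below published ostium-height measurements (14.4 ± 2.9 mm) and is kept as
a deliberately conservative, flagged default — both are plain registry
entries, replaceable through the YAML serialisation.

Range limiting uses declarative linear bound rules,
`lo' = max(lo, c + Σ aᶠ·ctxᶠ)` (and symmetrically for upper bounds). A
full multivariate regression over all parameters would need a large
clinical dataset; linear bounds with documented coefficients are the
smallest mechanism that enforces the qualitative constraints while keeping
every implemented range attainable somewhere in the anatomy space:

| rule | bound | coefficients |
|---|---|---|
| ST junction ≥ valve | valve ≤ aorta diameter | slope 1 |
| leaflet span | effective height ≤ 0.45·valve | reaches 12.2 at valve ≥ 27.1 |
| commissure height | VA ≥ each effective height; VA ≤ 0.75·valve | |
| LVOT size | basal ring ≤ 0.55·valve + (1/12)·Σ eff + 0.35·VA | max 24.4 attainable |
| coronary ostia | lo shifts +0.3·(ST−17.3) +0.2·(valve−18.1) (RCA), +0.15/+0.1 (LCA); RCA ≤ ST − 1 | ostia stay below the ST ridge |
| calcification | opening ≤ 100·(1 − 0.8·extent) | a fully calcified leaflet opens ≤ 20 % |

An infeasible combination collapses, flagged, to the nearest feasible
point (non-strict callers) or raises (the generator, which then redraws).
Because the dependency *columns* of the registry stay as declared, the
topological order keeps the three independent anatomical parameters in a
prefix; constraint-rule context edges only ever reference features drawn
earlier.

## Patient generation

Independent parameters are drawn uniformly over their implemented ranges,
dependent ones uniformly over their effective ranges, in dependency order
("pseudo-random" is made concrete as seeded uniform sampling — it
maximises coverage of the anatomy space, which is the point of a training
generator; the distribution is overridable). A draw that leaves a later
feature infeasible restarts the anatomy, bounded at 20 attempts with
diagnostics — resampling was chosen over clamping so the emitted
population is unbiased within the admissible region. Records serialise to
sorted-key JSON with a format version; equality and byte-level
reproducibility per seed are contractual.

EuroSCORE II coefficients ship as a data file keyed to the published
model; the minimal profile evaluates to 0.50 %. Sampling uses documented
round base prevalences for an elderly TAVR-referral population (age ~
N(72, 8²) clipped to [18, 95]) times per-item multipliers with neutral
defaults — the expert multiplier values used in clinical deployments are
not public, so the table is configuration, not a reconstruction.
The vitals monitor is a deliberately simple deterministic stub (baseline
120/80 mmHg, 72 bpm, 98 % SpO₂, rule-based offsets for critical state,
poor LV function, lung disease, NYHA class, pulmonary hypertension, plus
a seeded periodic waveform). It stands in for a physiology engine and
makes no haemodynamic claims.

## Fluoroscopy

Rays are cast from a point source through each detector pixel;
per-submesh inside-path lengths come from sorted entry/exit intersections
(Möller–Trumbore, shared-edge duplicates merged within a 1e-6 mm pairing
tolerance; a grazing ray is re-cast with a tiny perpendicular jitter, and
a persistently odd crossing count is reported as a non-watertight
structure, naming it). Pixel intensity is I₀·exp(−Σ μ_s·L_s), clipped to
[0, I₀]; high attenuation renders dark. Scatter is not modelled —
absorption alone reproduces the visual contract of a fluoroscopic frame at
a fraction of the cost of Monte-Carlo transport.

Angulation follows catheter-lab convention: LAO positive about the
patient-superior axis, cranial positive about the patient-left axis,
applied LAO-then-cranial; source-to-detector 1000 mm and
source-to-isocenter 700 mm by default. Contrast injection multiplies the
injected compartment's attenuation by a bolus factor (linear rise to an
8× peak over 1 s, exponential washout, time constant 2 s); the coronary
and ventricle+aorta compartments are triggered independently. DSA maps
(mask − live)/2 around mid-grey. Grain is seeded zero-mean Gaussian noise
with σ = amount·I₀ — a declared choice, not an inference about any
specific detector's noise texture. Calcification is rendered as seeded
random surface patches per leaflet (extent slider = area fraction around
three random seed faces, thickness slider = added µ·path per crossing)
rather than as a material shader.

## Default sizes, tolerances, degenerate inputs

* Mesh resolution 64 circumferential × 96 axial segments (≈ 19.5 k
  vertices); measurement error from cross-section polygonisation ≤ 0.1 %,
  against a 2 % measurement contract. Unit tests run at 32 × 48.
* Intersection pairing tolerance 1e-6 mm; ray–triangle edge inclusion
  1e-9 (barycentric), so conforming shared edges never open cracks.
* Zero-area triangles are rejected at build time (threshold 1e-10 mm²);
  collapsed leaflet commissure columns are welded by construction, not by
  positional merging, so topology is identical across configurations —
  which is what makes displacement fields valid for every build.
* A registry queried with partial context applies only the rules whose
  context is complete; missing *declared* dependencies are an error.
* The acceptance script uses the default mesh resolution and 2000
  generated patients — the sizes at which the measured endpoints and
  population extrema are reported.

## What the generator does and does not emulate

Generated anatomies cover the implemented ranges and satisfy the
dependency constraints; they do not reproduce population correlations
beyond those constraints (e.g. body-surface-area scaling of root
dimensions), leaflet asymmetry statistics, or real calcification
morphology. Passing tests demonstrate geometric and statistical
self-consistency of the pipeline — ranges, constraints, risk-model
arithmetic, projection physics on analytic fixtures — not clinical
fidelity of any individual virtual patient.

## Known limitations

* The aortic root is the only anatomically detailed region; the ventricle,
  myocardium and coronary stubs are stylised (no trabeculae, no coronary
  tree, no arch branches).
* The ST-junction diameter is geometrically tied to the valve diameter;
  an independent ST-diameter slider would require decoupling the sinus
  profile from the annulus.
* Leaflet opening is a static morph; no kinematic opening over the beat.
* Beer–Lambert only: no scatter, beam hardening, detector MTF or dose.
* The linear bound coefficients are plausibility guards, not fitted
  clinical regressions.
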