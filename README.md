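# npwtox

Multiscale simulation of **negative pressure wound therapy (NPWT)** on a
trans-femoral residual limb: limb-scale hyperelastic mechanics of the wound
and foam filler under suction, coupled to capillary-scale (Krogh cylinder)
oxygen transport, predicting how the therapy changes the oxygenated tissue
area around the wound bed.

It is written for biomechanics and wound-care modellers who want a
self-contained, scriptable re-implementation of this coupling chain without a
commercial FE package: everything runs on numpy/scipy.

## The model

Four stages, each a module with its own API:

1. **Macro mechanics** (`geometry`, `macro`, `fem`) — a 2D axisymmetric
   residual limb (rigid femur core, muscle sleeve, distal wound cavity of
   radius 3.6 cm and depth 0.8 cm filled with polyurethane foam). Muscle is
   nearly incompressible Mooney–Rivlin,

   *W = C₁(Ī₁−3) + C₂(Ī₂−3) + κ/2 (J−1)²*, with C₁ = 0.0094, C₂ = 0.082 MPa;

   the foam is a single-term compressible Ogden hyperfoam
   (μ = 0.907e−2, α = 0.213e−2, β = 0.844e−2). Suction (70/125/150 mmHg,
   exact 133.322 Pa/mmHg) acts as an outward traction on the wound faces with
   the atmospheric differential pressing the foam top inward; loads are
   follower pressures, the proximal end is encastre, the bone is rigid.
   Solved with bilinear quads, mean-dilatation volumetric treatment and
   Newton iteration (relative residual 1e−8).

2. **ROI statistics** (`roi`) — per tissue layer at 0/10/15 mm beneath (and
   0/5/10 mm beside) the wound bed, the maximum/minimum principal Cauchy
   stresses are histogrammed and the **modal** pair (σ*₁, σ*₃) extracted as
   the boundary condition for the capillary model.

3. **Capillary mechanics** (`capillary`) — a plane-strain Krogh cross-section
   (lumen 5 µm, wall 0.5 µm, tissue to 40 µm, embedded in a square tissue
   frame) loaded by 0.5 kPa luminal pressure and the modal stresses as normal
   tractions on perpendicular edge pairs. Output: the equivalent pressure
   stress field *p = −tr σ/3*.

4. **Oxygen transport** (`krogh`, `diffusion`) — an axial Krogh balance fixes
   the capillary-wall concentration (120 µM inlet, V_max = 0.5 mm/s,
   calibrated consumption → 40.32 µM at mid-length); radial transport in the
   annulus follows the extended Fick law

   *J = −D ∇C + s K_P ∇p*,

   with D = 2e−5 (tissue) / 1e−5 (wall) cm²/s and solubility
   s = 3.89e−5 ml O₂·ml⁻¹·mmHg⁻¹. The **oxygenated area** is the tissue
   fraction with C ≥ 10 µM at a fixed dimensionless time τ = D t/R² = 0.1,
   compared between the coupled run and the uncoupled baseline. The pressure
   stress factor K_P has no literature value; it is calibrated once so the
   0 mm beneath-wound layer reproduces a 73% decrease at 125 mmHg, then held
   fixed everywhere (calibrate-on-one, predict-the-rest).

## Worked example

```python
from npwtox import NPWTModel, PipelineConfig

model = NPWTModel(PipelineConfig(suction_levels=(125.0,)))
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Pressure stress factor K_P = 1.577e-05 cm^2/s (calibrated)
Baseline oxygenated tissue-area fraction = 0.1978 (threshold 10 uM at tau=0.1)
Macro deformation and wound contraction:
 suction_mmHg  max_deformation_mm  wound_area_change_pct
      125.000               0.636                  2.956
Oxygenated-area change per ROI layer (negative = decrease):
 suction_mmHg     direction  offset_mm  change_pct
      125.000 beneath_wound       0.00      -72.98
      125.000 beneath_wound      10.00      -60.01
      125.000 beneath_wound      15.00      -47.88
```

Read: at −125 mmHg the wound mouth contracts by ~3% and the tissue directly
under the foam loses ~73% of its oxygenated area (the calibration anchor),
with the deficit shrinking to ~48% at 15 mm depth. `results.save("out/")`
writes CSV/JSON tables, VTU fields and the binary oxygenation masks;
`results.plot_contraction()` / `plot_oxygenation()` give the standard plots.

The same chain is scriptable from the shell:

```bash
npwtox simulate -s 70 -s 125 -s 150 -o out/
npwtox sweep --aspect-ratio 1 --aspect-ratio 2 --edges round --edges sharp -s 125
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole chain from scratch — the three-level suction study, the
wound-geometry parametric study (edge shape; radius-to-depth ratio at
constant cavity volume), and the calibrated oxygenation pipeline — and writes
the headline quantities (wound-area reductions, maximum deformations,
parametric effect sizes, the 15 mm oxygenation decrease) as a JSON map.
Runtime ≈ 2 min on one CPU.
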