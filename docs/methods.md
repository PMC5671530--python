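# Methods

This note documents the models, the numerical choices behind them, and what
the test suite does and does not establish. Parameter values are given with
their defaults; everything listed is configurable through `PipelineConfig`.

## 1. Macro-scale model

### Geometry surrogate

The limb is an axisymmetric cylinder: muscle radius 7 cm, length 18 cm
(resection 18 cm distal to the greater trochanter), rigid femur core of
radius 1.5 cm whose resected tip sits 3 cm proximal to the distal face. A
circumferential wound cavity (radius 3.6 cm, depth 0.8 cm, ≈ 40 cm² opening)
is cut into the distal face and filled with an identically sized foam block.
Muscle and bone radii and the bone-tip offset are not published quantities;
they are documented surrogate defaults. Wound edges are `sharp` by default
(a plain cylindrical cavity); `round` fillets the cavity-floor rim with a
2 mm arc (fillet radius also unpublished, default documented here).

The mesh is a structured, graded quadrilateral grid whose lines pass exactly
through all material breakpoints, so muscle/filler/bone interfaces are
conforming (tied contact = shared nodes). Target element sizes: 1 mm at the
wound interface, 5 mm in the far field, and ≤ 1.8 mm throughout a 2 cm band
around the wound so that 2 mm ROI layers always contain a full row of
element centroids. Fillet arcs are sampled at ≥ 8 chords; the inscribed
polyline under-removes cavity volume by a few percent at default resolution
(verified against the analytic fillet ring volume in the tests).

### Materials

| Component | Model | Constants |
|---|---|---|
| muscle (macro + capillary tissue) | Mooney–Rivlin | C₁ = 0.0094, C₂ = 0.082 MPa, D = 0 |
| capillary wall | Mooney–Rivlin | C₁ = 0.257, C₂ = 0.00257 MPa, D = 1e−6 |
| foam filler | one-term Ogden hyperfoam | μ = 0.907e−2 MPa, α = 0.213e−2, β = 0.844e−2 |

The incompressibility parameter D maps to the penalty bulk modulus as
κ = 2/D, capped at 1000·μ₀ (μ₀ = 2(C₁+C₂)); D = 0 uses the cap directly,
because exact incompressibility is ill-posed in a displacement formulation.
The source cites a "second-order" hyperfoam but prints a single (μ, α, β)
triple, so one term is implemented. With α ≈ 2e−3 the foam energy is an
O(α²) residue of O(1) terms; it is evaluated with `expm1`/`log` to keep full
precision (the naive power form loses ~8 digits and breaks derivative
checks). The foam's initial Poisson ratio is β/(1+2β) ≈ 0.008 — an almost
freely compressible open-cell foam, ~20× softer in shear than muscle.

### Loads and boundary conditions

Suction levels are positive mmHg magnitudes converted exactly
(133.322 Pa/mmHg); the paper's rounded MPa figures are not used. The sealed
dressing transmits the vacuum, which is modelled as

* an outward (tensile) follower traction of the suction magnitude on the
  wound's lateral and bottom faces, and
* an inward (compressive) follower pressure of the same magnitude on the
  exposed foam top (the drape's atmospheric differential; configurable
  separately).

The proximal end is encastre, the bone boundary fixed (rigid femur), the
symmetry axis constrains u_r. At zero suction both loads vanish and the
solution is identically zero.

### Discretisation and solver

Total-Lagrangian bilinear quadrilaterals, 2×2 Gauss quadrature, with
Simo-style **mean dilatation** for the nearly incompressible materials: a
single element pressure p̄ = κ(J̄−1) from the volume-averaged Jacobian acts
through the pointwise J F⁻ᵀ, integrated with full quadrature. This passes
the hydrostatic patch test to < 1% and avoids Q1 volumetric locking; plain
selective reduced integration (volumetric term at the centroid) was tried
first and failed the patch test, because the centroid rule misses the
r-quadratic part of the axisymmetric volume integral.

Element tangents are central finite differences of the analytic internal and
surface force vectors (step 1e−7·√(element area), i.e. a fixed strain-scale
perturbation); follower-pressure load stiffness is included the same way.
Newton iteration uses a relative residual tolerance of 1e−8, backtracking
line search, 10 uniform load increments with adaptive halving (floor 1/160).
Axisymmetric hoop kinematics use λ_θ = 1 + u_r/R evaluated at Gauss points
(never on the axis itself).

Outputs: nodal displacements; per-element centroid Cauchy stress; principal
stresses (3D triple including the hoop component); equivalent pressure
stress p = −tr σ/3 (tension-positive convention, p positive in
compression). Wound contraction is 100·(A₀−A)/A₀ from the displaced rim node
at (r_w, 0); maximum deformation is taken over muscle nodes.

## 2. ROI modal stresses

Each ROI layer is the set of muscle elements whose centroid distance from
the nominal wound-bed surface lies in [offset, offset+thickness), measured
along +z beneath the wound and radially beside it (thickness default 2 mm).
Per-element σ_max and σ_min samples (unweighted by default; revolved-volume
weighting available) are histogrammed with a Freedman–Diaconis bin width and
a grid **anchored so one bin is centred on zero stress**. The anchoring
matters: these distributions peak at the unloaded state with a heavy tail,
and with free bin placement the *sign* of the modal value flips between mesh
refinements. Ties are broken toward the bin of smaller absolute stress, and
the reported mode is clamped into the sample range. The modal pair per layer
is the entire hand-off to the capillary stage.

## 3. Capillary structural model

Plane strain (a capillary is long and axially constrained — the choice is
ours, the source is silent). The wall+tissue annulus is embedded in tissue
filling a square frame of half-side 1.1·R_out (side 2.2·R_out), so the modal
tractions can be applied as uniform normal loads on the frame edges without
edge artefacts: σ*₁ on the x-normal pair, σ*₃ on the y-normal pair, tension
positive; 0.5 kPa luminal pressure on the lumen surface. Loads and geometry
are symmetric about both axes, so u_x = 0 on x = 0 and u_y = 0 on y = 0
remove rigid modes without constraining the physics. The mesh is a polar
ring grid with an O-grid transition to the square (n_θ = 48, a multiple of 8
so mesh lines lie on the axes and diagonals); the solver and materials are
the same code as the macro stage. Verified against the compound (two-layer)
plane-strain Lamé solution at small load and against the plane-strain
equibiaxial limit p → +a.

## 4. Axial Krogh balance

C(z) = C_in − M·(R_t²−R_c²)·z/(R_c²·v̄) with C_in = 120 µM, parabolic flow
v̄ = V_max/2 = 0.25 mm/s (plug flow switchable), R_c = 5 µm, R_t = 40 µm,
capillary length 1 mm. The tissue consumption rate M is not published; it is
obtained in closed form so that the mid-length wall concentration equals a
prescribed value — 40.32 µM by default, which then serves as the Dirichlet
wall value of the diffusion stage. This keeps the downstream chain
self-consistent without inventing an unverifiable constant.

## 5. Oxygen diffusion and coupling

Transient diffusion on the wall+tissue annulus (the frame is structural
only): ∂C/∂t = ∇·(D∇C − s K_P ∇p), the extended Fick law taken literally
with its **+s K_P ∇p** flux term, so oxygen drifts *up* pressure-stress
gradients; for a compressed capillary (p maximal at the lumen, decaying
outward) the drift opposes outward Fickian transport and the oxygenated area
shrinks — matching the direction of the published beneath-wound results. At
zero total flux the steady state satisfies C = const + (sK_P/D)(p − p_ref)
per region, which the tests verify on a radius-only p field.

Boundary and initial conditions: C = 40.32 µM held at the lumen surface,
zero total flux at the Krogh radius, C = 0 initially in wall and tissue.
The structural p field (element-wise) is projected to nodes by area-weighted
averaging; the drift enters as a source term ∫ sK_P ∇p·∇N. Unit bridge:
p [MPa] → mmHg (×7500.6), times solubility → ml O₂/ml, times 44615 µM per
(ml/ml) at STP; K_P therefore carries diffusivity units (cm²/s).

Discretisation: bilinear quads, lumped mass, implicit Euler with Δτ = 1e−3
in the dimensionless time τ = D_tissue·t/R_out². **Evaluation time τ = 0.1**
(≈ 0.08 s): the true steady state with zero-flux boundary and no tissue
consumption is spatially uniform, hence threshold-degenerate, so the
oxygenated-area metric is evaluated at a fixed τ where a radial gradient
exists — identically for baseline and coupled runs. This is the largest
interpretive choice in the package and is deliberately configurable.

Oxygenated area = tissue-annulus fraction with element-mean C ≥ 10 µM;
reported changes are 100·(coupled−baseline)/baseline against the *uncoupled*
baseline. At zero suction the macro stress vanishes and the change is
defined as exactly zero (the luminal-pressure p field exists pre-therapy and
is not counted as an NPWT effect).

**K_P calibration.** The PDE is linear, so the coupled field is
C_base + K_P·C_unit for a unit-drift solve; area-change-vs-K_P is then a
cheap scalar function and Brent's method pins K_P so the 0 mm beneath-wound
layer loses 73% of its oxygenated area at 125 mmHg. K_P is then held fixed
for all other layers and suction levels. The calibrated default lands at
K_P ≈ 1.6e−5 cm²/s; the achieved anchor value is within the element-area
granularity of the metric (~±2 points).

**Heterogeneity classification.** Layers are labelled homogeneous or
heterogeneous from a per-element linearised estimate: three unit capillary
responses (unit σ₁ traction, unit σ₃ traction, luminal pressure) are
precomputed and superposed per ROI element — justified because the capillary
strains are ≪ 1%. A layer is heterogeneous when element-level area changes
of both signs exceed 5%. The per-layer headline number always comes from the
full nonlinear modal-pair solve; the linearised map only supplies the label
and the signed increase/decrease components.

## 6. What the synthetic world does and does not emulate

Emulated: the published cavity dimensions, materials, suction levels,
capillary geometry and transport constants; conforming tied interfaces;
graded meshing near the wound. Not emulated: patient-specific 3D anatomy
(the limb is a 2D axisymmetric surrogate — the source itself validated one
against its 3D model), skin/fascia layering, adhesive drape mechanics, foam
pore microstructure, contact or slip at interfaces, tissue oxygen
consumption inside the diffusion solve, exudate flow, and any healing-time
evolution. A green suite therefore establishes internal correctness of each
stage and desk-scale agreement with the published deformation/contraction
numbers — not patient-level predictive validity.

## 7. Known limitations

* The depth decay of the oxygenation decrease is sensitive to the unpublished
  bone-tip offset: the rigid femur tip sits only ~5 mm beyond the deepest
  (15 mm) ROI layer and partially confines the sub-wound stress field.
* The round-vs-sharp edge effect (~13% in max deformation) is controlled by
  the unpublished fillet radius; the published ~4% figure is not reproduced
  quantitatively, only the ordering (edge shape ≪ aspect ratio) holds.
* The modal hand-off compresses each layer's stress distribution to one
  biaxial pair; the linearised heterogeneity map partially restores the
  within-layer spread but is itself a small-strain approximation.
* Baseline oxygenated fractions (~0.20 of the annulus at τ = 0.1) make
  percent changes large; beside-wound layers can report increases > 100%.
* The area metric is a step function of K_P at element granularity, so
  calibration reproduces its target only to ~±2 percentage points.
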