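# Methods

## Model

The mechanical model is small-strain linear elastostatics on four-node
(constant-strain) tetrahedra, the standard element for comparative skull
FEA. Bone is a single homogeneous isotropic material per model; the
default properties, E = 15 000 MPa and ν = 0.29, are crocodilian skull
bone values commonly applied to fossil archosaurs. Teeth are not modeled
as a separate material: for *relative* stress comparisons between models
a second material changes little, and the comparative statistics are the
point of the pipeline. Units are N–mm–MPa throughout; adductor areas
enter in cm² and are converted (1 cm² = 100 mm²) at the loading boundary.

Per element, `K_e = V_e Bᵀ D B` with the constant-strain B-matrix derived
from the element Jacobian and the isotropic D(E, ν) in Voigt order
(xx, yy, zz, xy, yz, zx). The global sparse system is solved after
row/column elimination of the Dirichlet-constrained degrees of freedom,
so constrained displacements are exactly zero and reactions are recovered
as `r = K u − f` on the eliminated rows. A direct sparse LU factorization
is used by default, with a Jacobi-preconditioned conjugate-gradient
fallback (relative residual 1e-10) above 300 000 free DOF. After the
solve, element strain ε = B u_e and stress σ = D ε are constant per
element; von Mises stress is computed from the stress components and the
maximum principal strain as the largest eigenvalue of the strain tensor
(engineering shears halved when forming the tensor).

## Loading model

Total adductor force = adductor-chamber cross-sectional area × specific
muscle tension (31.5 N/cm², the standard amniote jaw-muscle value). The
total is split across named muscle groups (default: equal left/right
adductor patches), each group's resultant direction is resolved either
from an explicit vector or as the averaged unit vector from insertion
nodes toward a target point (default: the bite-row midpoint, giving an
anteroventral line of action), and the group force is divided evenly over
its insertion nodes. Joint nodes (three per quadrate/articular hinge, six
total) are constrained in all three translations — 18 constrained DOF.

Bite points admit two treatments, selected in config:

* `bite=load` (default for single solves): external point loads at the
  ten tooth-row nodes, total magnitude and direction user-supplied. The
  magnitude is a free parameter of this mode; with zero magnitude the
  model is muscle-loaded only.
* `bite=constrain` (used by the packaged comparative study): the tooth
  nodes are constrained vertically and the bite force emerges as their
  reaction. This closes the lever between muscle, jaw joint and tooth row
  without requiring an assumed bite-force magnitude, which is why the
  packaged family study uses it — under muscle-only loading with free
  bite points, nearly all stress concentrates at the six joint
  constraints and the comparison degenerates to a point-singularity
  measurement.

**Surface-area equalization.** In `sa_equalized` mode each model's
per-group forces are `F_ref,g × SA_model / SA_ref`: every model carries
the reference's force-to-surface-area ratio, so stress differences that
survive equalization are attributable to shape, not size. For isometric
copies this makes the stress field identical (forces scale with L², areas
with L², so stress is invariant) — the operational test of "size
removed". An alternative reading — applying the reference's forces
verbatim to every model — is implemented behind
`ScalingPolicy(equalize="reference_force")` but is not the default, since
it re-introduces a size effect of the loading rather than removing one.

## Sensitivity analysis

Muscle forces are perturbed ±10 % and the model re-solved; the statistic
is the symmetric percent difference |a−b|/((a+b)/2)×100 between baseline
and perturbed mesh-weighted mean von Mises stress. Two modes:

* `global` — all muscle loads scaled together. For a linear model this is
  a closed-form oracle: the field scales by exactly 1.1 or 0.9, so the
  percent differences are 100·0.1/1.05 = 9.5238 % (up) and
  100·0.1/0.95 = 10.5263 % (down) regardless of geometry or load
  magnitude. Any deviation flags a solver defect.
* `per_muscle` (default) — each group perturbed in its own run with the
  others at baseline; perturbed MWAMs are averaged across groups per
  direction before the percent difference. This is the mode that can
  produce non-trivial, model-dependent sensitivities, and the default
  because published sensitivity tables for real skulls are inconsistent
  with pure global scaling of a linear model (some report stress
  *decreases* under uniformly increased forces, impossible under global
  linearity), implying per-group re-application. How such runs were
  aggregated in prior work is not documented; averaging across group-wise
  runs is the reading adopted here and is flagged in the result metadata.

## Synthetic skull proxies

`synthetic_skull` generates deterministic tapered-wedge solids standing in
for cranium and mandible scans. The geometry is a loft of rectangular
cross-sections shrinking linearly to `anterior_taper` (default 0.35) of
the posterior dimensions over the length; a hex grid (resolution elements
along the length, transverse counts proportional to the aspect ratio,
minimum 4) is split by the fixed 6-tet Kuhn decomposition, which is
conforming and orientation-uniform. Because the lofted faces are planar,
the tet mesh fills the wedge exactly and the total volume matches the
analytic value to round-off — a strong generator self-check. Proxies are
solid (no internal cavities), matching the infilled models that
surface-scan reconstructions produce. The optional `fenestra` parameter
removes a transverse window of hexes. `seed` only drives optional node
jitter (default 0), so default geometry is fully analytic and
byte-reproducible.

Node sets reproduce the loading topology of a skull feeding analysis:

* **bite**: 10 nodes, the nearest distinct nodes to five anchor points
  per side along the ventral lateral edge of the anterior 18 % of the
  wedge (the premaxillary tooth row). Anchor spacing is a free parameter;
  the default spreads the row over the anterior snout.
* **joints**: 6 nodes, nearest to three anchors per side at the
  posterolateral ventral corners (quadrate/articular hinges).
* **muscle patches**: dorsolateral node bands at 0.35–0.60 of the length
  (the temporal/coronoid region), left and right, disjoint from the joint
  and bite sets. Mid-length insertions are both closer to real adductor
  geometry and mechanically essential: they make the skull work as a
  lever spanning joints → insertion → tooth row, so overall shape
  (section depth) governs the stress field.

The `mandible` preset is a shallower (×0.45 depth), narrower (×0.8) wedge
with identical topology.

**The packaged family** (`example_family` / `family_study_config`) fixes
the study conditions: a gracile morph (100 × 40 × 30 mm wedge, adductor
area 20 cm², resolution 12), its exact ×2 isometric copy (adductor area
×4), and a robust morph with posterior depth ×1.6 at the same length —
spanning a pure size axis and a pure shape axis. These defaults are the
conditions under which the package's comparative claims are tested; they
are not tuning knobs.

What the proxies do **not** emulate: real cranial topology (fenestrae,
curvature, sutures), heterogeneous bone, dentine, articulated jaw
mechanics, or realistic muscle wrapping. Passing tests therefore
demonstrate that the *pipeline* — solver, scaling, statistics — behaves
correctly and that shape/size effects separate as designed; they do not
reproduce any real specimen's absolute stress values, which depend on
scanned geometry and muscle vectors not available here.

## Verification

* **Patch test**: block under uniform uniaxial consistent end loads with
  minimal symmetric constraints reproduces σ = F/A in every element to
  machine precision (measured ~1e-15 relative).
* **Cantilever**: slender 100 × 5 × 5 mm clamped box, transverse tip
  load, vs the Timoshenko deflection PL³/3EI + PL/(κGA),
  κ = 10(1+ν)/(12+11ν). Constant-strain tets are stiff in bending, so the
  error falls monotonically with refinement (36 % → 14 % → 7 % → 4.5 %
  over the packaged ladder (40r, r, 3r), r = 1…4). The packaged
  verification level r = 4 (≈31 000 DOF) was chosen from this convergence
  study as the point where the discretization supports a ±5 % check at
  modest cost.
* **Element stiffness** is cross-checked in the tests against an
  independent construction that derives shape-function gradients from the
  4×4 Vandermonde system rather than the Jacobian inverse.
* **Invariants** asserted in the suite: equilibrium of reactions vs
  applied loads, linearity and superposition, rotational frame
  indifference, MWAM identity/conservation/reordering properties, and
  determinism of generator and pipeline.

## Numerical choices and edge cases

* Vertex merge tolerance for STL import: 1e-6 mm (grid snap), configurable;
  degenerate triangles produced by merging are dropped.
* Negative-orientation tets are repaired by swapping two node indices;
  zero-volume tets are a validation error naming the element indices.
* Volume-weighted quantiles use the left-continuous inverse of the
  volume-CDF over elements sorted by value (ties kept stable).
* The per-part scaling reference in a study falls back to the
  largest-surface-area model of a part when the configured reference
  label belongs to another part.
* Percent difference is undefined for a non-positive mean; the
  sensitivity runner returns 0 for the all-zero (unloaded) case.

## Limitations

Linear elasticity only (no contact, no geometric or material
nonlinearity); single material per model; tet4 elements are stiff in
bending, so absolute stresses are resolution-dependent — all comparisons
in the package are made at fixed or volume-weighted-equalized
discretizations and interpreted relatively, never as failure predictions.
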