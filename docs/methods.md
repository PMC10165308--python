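# Methods

This note documents the models and procedures implemented in
`phantomforge`, the defaults they ship with, and what the synthetic
stand-ins do and do not emulate.

## The voxel phantom and its synthetic stand-in

The source geometry is a labelled 3-D integer volume in the style of
the reference adult voxel phantoms: one organ id per voxel, 0 outside,
voxel spacing in mm, and a table mapping ids to names and *compartment
roles* (liver, spleen, tumour, cortex-L/R, medulla-L/R, body). The
world convention is fixed throughout the package: voxel index
(i, j, k), 0-based, has its center at ((i+0.5)·sx, (j+0.5)·sy,
(k+0.5)·sz) mm. Raw volumes are little-endian with a YAML sidecar
carrying shape, dtype, spacing and the organ table.

Because reference anatomies cannot be redistributed, the package
generates a deterministic synthetic phantom instead: an elliptical
body housing (internal semi-axes 129 × 99 mm, height 268 mm — the
dimensions of the physical background housing) containing ellipsoidal
organs scaled so their continuum volumes equal the design volumes of
the printed compartments (liver 1306.7 mL with an embedded 15.9 mL
spherical tumour, spleen 124.9 mL, kidney cortices 90.9/75.7 mL with
nested medullas 42.9/35.7 mL). Placement constants were chosen once so
that every organ lies inside the housing, kidneys are nested
cortex/medulla pairs, the tumour sphere sits strictly inside the liver,
and no two organs touch; the seed drives a ±0.5 mm placement jitter so
distinct seeds give distinct rasterizations while any fixed seed is
bit-reproducible. At the default 2 mm grid the voxel-count volumes land
within ~0.3% of the targets and converge towards them as the grid is
refined.

What the stand-in does **not** emulate: real organ shapes (lobes,
concavities, the renal pelvis geometry), inter-organ contact, printed
wall displacement of the background volume, ports, joins or caps.
Passing tests on it demonstrate the correctness of the *pipeline* —
meshing, bookkeeping, filling arithmetic — not anatomical fidelity.

### Label surgery

`merge_labels` relabels voxels (used to fold the renal pelvis into the
medulla, giving two-compartment kidneys). `clean_label_region` makes a
label a single 6-connected component and absorbs interior cavities
smaller than 27 voxels (3³, i.e. below the scale marching cubes can
represent cleanly at one voxel wall thickness); detached voxels are
reassigned to a caller-chosen label. The physical workflow did this by
manual voxel edits; the automatic morphological rule is a stand-in, so
the exact voxels moved differ. Cavities of the background (air) are
only absorbed on request, because filling them changes the total
labelled volume; with the default setting both operations conserve the
total number of labelled voxels exactly.

### Mesh → voxel rasterization

`voxelize_mesh` classifies a voxel as inside iff its center is inside
the closed surface, by z-column ray parity: for every grid column the
surface crossing heights are accumulated and a center is inside iff an
odd number of crossings lies below it. Ray origins are nudged by ~1e-6
voxel off exact edge alignments so shared-edge ties resolve uniquely.
This inverts `extract_surface` essentially exactly (Dice 1.000 for
every organ of the default phantom); the acceptance bound is ≥ 0.99.
The rasterizer is hand-written because the installed mesh library's
ray/containment queries require an unavailable spatial index; it is
validated against axis-aligned closed forms (a 10 mm cube on a 1 mm
grid fills exactly 1000 voxels).

## Meshing and shells

Surfaces are extracted with marching cubes at the 0.5 iso-level of the
binary mask (mask padded by one voxel so boundary-touching regions
close), producing watertight 2-manifolds with outward winding; mesh
volume is the divergence-theorem sum of signed tetrahedra (exact for
polyhedra; 1 mL = 1000 mm³).

**Smoothing.** Uniform-weight Laplacian smoothing,
v ← v + λ(mean(neighbours) − v), default λ = 0.5 for 20 iterations.
The defaults remove the 2 mm voxel staircase while losing < 1% of the
liver volume (< 5% is the documented budget for any organ); both
parameters are exposed. Smoothing strictly decreases surface area per
iteration and never touches connectivity.

**Shell extrusion.** The outer surface displaces every vertex along its
area-weighted normal by the wall thickness (2 mm for organs and the
tumour, 1 mm for the medullas). The normal field is first smoothed a
few iterations (neighbour averaging + renormalisation), which is the
standard programmatic substitute for the interactive offset/repair
passes of commercial mesh tools and suppresses local self-intersections
in concave spots. The mean outer-vertex-to-inner-surface distance is
within 5% of the nominal thickness on all default organs (1.999 mm for
the 2 mm liver shell). Point-to-surface distances use exact
point–triangle projection on k = 8 KD-tree candidate triangles.
Filling/support ports, interlocking joins and caps are recorded as
per-part metadata, not cut into the mesh: boolean CSG robustness is out
of proportion to the validation value of this package, and is listed as
a limitation.

**Overlap resolution and assembly.** Mesh separation is measured as the
minimum signed vertex-to-surface distance in both directions (sign from
the nearest face normal; exact surface contact counts as penetration).
This vertex-sampled metric can miss sub-facet edge crossings of very
coarse meshes but is exact in the limit of dense sampling and is
validated on sphere pairs. `resolve_overlap` translates the movable
part along a given direction by the minimal multiple of 0.1 mm that
achieves a 0.5 mm clearance (both configurable); `assemble_scene`
verifies pairwise non-overlap and preserves part geometry and naming.

**STL.** Binary STL is little-endian, 80-byte header + 4-byte count +
50-byte facets; reads validate the facet count against the file size
and report the byte offset of any truncation. ASCII follows the
`solid … endsolid` grammar, one solid per part. STL carries no units;
payloads are mm, asserted in sidecar metadata. Round trips preserve
geometry at 32-bit float precision and are bit-idempotent after the
first write.

## Pharmacokinetic model

A linear compartment system over {rest of body, kidneys, liver, spleen,
tumour, excreted}: dA/dt = K·A with K[i,j] ≥ 0 the transfer rate j → i
(h⁻¹) and diagonals the negative outflow sums, so columns of K sum to
zero and biological mass is conserved identically. The administered
bolus (default A₀ = 7400 MBq) starts in the central rest-of-body
compartment.

**Solver.** Classical fixed-step RK4, default step 1 min over 100 days.
For this autonomous linear system the four stages collapse into the
constant propagator M = I + hK + (hK)²/2 + (hK)³/6 + (hK)⁴/24, applied
step by step — algebraically identical to evaluating k1…k4 every step,
and it makes the 144 000-step horizon sub-second. Because 1ᵀK = 0
implies 1ᵀM = 1ᵀ, the total activity is conserved to machine precision
at every step (checked against a 1e-9 relative tolerance). Fourth-order
convergence is verified against the closed-form exponential.

**Decay.** The solved series is biological (decay-corrected); the
physical series multiplies by 2^(−t/T½), exactly equivalent to adding
λ_phys to every diagonal of K, and chosen so that decay-apply and
decay-correct (×2^(∓Δt/T½)) invert each other exactly. The Lu-177
half-life is a required configuration value with a documented default
of 6.6443 d (external nuclear data). Both biological and physical
concentration tables can be exported; neither is asserted to be "the"
published plotting convention, which is ambiguous.

**Rates.** The fitted patient transfer rates behind the original
schedule are not published. The shipped defaults are *illustrative*:
fast renal clearance of the central pool (0.14 h⁻¹ to excreted, central
biological half-life ≈ 4.5 h), organ uptake rates of 0.0012–0.006 h⁻¹,
organ washout of 0.006–0.014 h⁻¹ (effective half-lives of tens of
hours, organ peaks at roughly half a day to a day, tumour the hottest
compartment per mL). Every rate, volume and the administered activity
are config-overridable; a self-consistency test verifies that a
mono-exponential fit to any organ's late phase recovers the model's
slowest washout eigenmode within 1%.

**Concentrations.** Compartment activity ÷ compartment solution volume
(the design volumes of the shells), linearly interpolated on the 1-min
grid (negligible interpolation error at that resolution; grid-point
queries reproduce stored values exactly). The kidneys are one kinetic
compartment shared by four anatomical sub-compartments: the cortex
concentration is A_kidneys / (V_cortexL + V_cortexR + (V_medL +
V_medR)/3), the medulla concentration is fixed at one third of the
cortex value, and left/right sides are identical. The background
(housing) concentration is the rest-of-body activity divided by a
configured distribution volume (default 60 L, an illustrative
whole-body soft-tissue volume).

**Time-integrated activity.** Trapezoid over the grid plus an analytic
tail A(t_end)/λ_eff, with λ_eff fitted log-linearly over the last 10%
of the horizon — by then the slowest eigenmode dominates under linear
kinetics. A non-decaying tail raises an explicit divergence error
rather than returning a truncated integral.

## Filling metrology

`plan_dispense` implements the bench protocol: required activity =
target concentration × compartment volume, decay-corrected from scan
time back to dispensing time; draw 110% of it from the stock
(volume = draw activity / stock concentration at dispensing time);
pre-dilute to 105% of the compartment volume; top up to the solution
volume at which the concentration is exactly on model — 110% of the
compartment volume, since the beaker holds 110% of the required
activity — within 0.01 mL. Dispensing exactly one compartment volume
then realises the target concentration identically; the test suite
checks this closed loop to 1e-10 relative through simulated exact
weighings.

Numerical conventions, all configurable:

* solution density 1.000 g/mL (dilute HCl carrier; < 0.1% from truth),
* balance readability d → standard uncertainty d/√12 (rectangular),
  two independent readings per volume: u_V = √2·(d/√12)/ρ,
* stock calibrator relative standard uncertainty 3% (a traceable
  calibration factor is assumed; no published figure exists),
* dispensing timestamp defaults to the stock reference time,
* all propagation is first-order quadrature on relative uncertainties
  (doubling every input uncertainty doubles every output uncertainty).

**Concise notation.** `409(14)` means 409 with standard uncertainty 14
in units of the last displayed digits. Rendering shows the uncertainty
to one significant digit, keeping a second digit when the leading digit
is 1 and the second is informative (0.014 → "(14)", an exact 0.01 stays
"(1)" as metrology tables commonly print it); the value is rounded
half-even to the same place, and u = 0 renders bare. Formatting then
parsing is the identity at the displayed precision across magnitudes
1e-3–1e4.

## Reports

* **Fill fractions:** 100 × dispensed volume / design (STL) volume;
  values over 100% are flagged as overfill, not rejected (a cap seating
  differently than modelled can legitimately overfill).
* **Underfill range:** per compartment, (min, max) of 100 − fill
  fraction over the scans, rounded half-even to 2 decimals; overfilled
  scans are excluded from the range and listed separately, since an
  overfill is a different failure mode than the systematic underfill
  caused by trapped air or manufacturing tolerances.
* **Deviation report:** per (compartment, scan), 100 × (achieved −
  model)/model with an agreement flag at a configurable coverage factor
  (default k = 2); the summary mean carries the *sample standard
  deviation* of the deviations (the spread statement matters more than
  the mean's precision here), with the standard error available as an
  option.
* **Activity map:** per-voxel concentration painted from the per-role
  table onto the phantom grid, written as NIfTI with mm spacing and the
  voxel-center origin. Total activity is conserved by construction.
  No imaging-system blurring is applied — this is the digital ground
  truth, not a simulated image.

## Problem sizes and test design

Tests run the full default phantom at 2 mm spacing (grid 133 × 103 ×
138) and the full 100-day, 1-min-step kinetic horizon; the heaviest
single check (voxelize∘extract Dice over all eight compartments,
including the ~235 k-triangle housing surface) takes a few seconds, and
the whole suite runs in well under a minute. Property tests
(hypothesis) are derandomized for reproducibility.

## Known limitations

* Synthetic anatomy is ellipsoidal; printed-volume agreement beyond the
  few-percent level with any real anatomy is out of scope.
* Shell offset is a vertex-normal displacement, not a true Minkowski
  offset; pathological concavities could still self-intersect after
  normal smoothing (detected as a failed watertightness/volume check).
* Mesh separation is vertex-sampled; guaranteed-exact minimum distances
  between coarse meshes are not computed.
* The SPECT/CT acquisition and reconstruction chain, DICOM handling,
  partial-volume recovery and Monte Carlo dose computation are
  deliberately out of scope: this package produces and verifies the
  phantom-side ground truth those steps consume.
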