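# Methods

This note records the modeling and numerical choices behind `sensmap`, what
the synthetic data emulate, and what the tests do and do not establish.

## Volume conductor

The head phantom is a set of concentric spherical shells meshed as one
conforming tetrahedral mesh.  The mesher extrudes a subdivided icosahedron
radially: every radial layer shares the same spherical triangulation, prisms
between layers are split into three tetrahedra with the minimum-vertex
diagonal rule (which makes neighbouring prisms agree on quad-face
diagonals), and the innermost layer is closed with a fan to the center
node.  Two consequences matter for accuracy:

- compartment interfaces coincide exactly with node layers, so thin shells
  (the 2 mm CSF layer) are resolved by at least one element layer no matter
  how coarse the target edge length is;
- element quality is uniform by construction; there are no slivers.

The 6-shell reference geometry is 60 / 78 / 80 / 83 / 86 / 92 mm
(white|gray, gray|CSF, CSF|skull, spongiosa|compacta, compacta|scalp,
scalp|air), standard 4-layer phantom radii with the brain and skull shells
split for the detailed variant.  The three model variants never remesh:
**3CI** and **4CI** are produced by merging labels of the same mesh
(CSF→brain for 3CI, skull sublayers→skull, brain sublayers→brain), so SNR
differences between variants isolate conductivity modeling from geometry.

Conductivities (S/m): scalp 0.43, skull 0.01 (compacta 0.008 / spongiosa
0.025 in 6CA), CSF 1.79, brain 0.33 (gray 0.33, white 0.14 in 6CA).  The
white-matter tensors are axially symmetric with a 10:1
longitudinal:transversal ratio and a locally *radial* fiber axis — a
synthetic stand-in for diffusion-derived fiber fields that a sphere phantom
cannot have — constrained so the mean of the three eigenvalues equals the
0.14 S/m isotropic reference ("fit the mean" constraint).

## Source spaces

The synthetic cortex is a radially perturbed sphere
`r(u) = base + amp · f(u)` where `f` sums 24 random spherical plane waves of
wavenumber `π · fold_frequency` (wavelength ≈ 2·base/frequency along the
surface) and is passed through a tanh waveshaper (sharpness 3).  The
waveshaping flattens crests and troughs and steepens the transitions,
mimicking gyral crowns and sulcal valleys joined by steep walls; it is what
produces genuinely tangential surface normals on a star-shaped surface,
which caps achievable normal tilt at atan(|∇r|).  Defaults (base 60 mm, amp
14 mm, frequency 8, icosphere subdivision 4 → 2562 vertices) give source
depths of roughly 2–20 mm below the inner skull and angles up to ~75°.  Two
features of real cortices are *not* emulated: overhanging folds (so no
angles beyond 90°, and the last angle bin stays empty — orientation flips
would only mirror the first bin), and the 30–50 mm depth range of a real
inflated cortex (the gray shell is 18 mm thick, so depth bins beyond ~20 mm
are empty).  Directional tests therefore compare occupied bins only.

Cortical dipoles sit at the centroid of the gray-matter element nearest to
each cortex vertex (several vertices may share a centroid; each keeps its
own normal as orientation — no aggregation).  Subcortical regions are nine
balls named after the anatomical structures, placed inside the brain shell
with radii 4–14 mm; each region-mesh node carries an x/y/z Cartesian
orientation triplet, reflecting the absence of a preferred dendritic
orientation in deep nuclei.

Depth and angle are *nearest-vertex* quantities against the inner-skull
surface (the CSF|skull interface, sampled at ≤ 2 mm vertex spacing): depth
is the distance to the closest surface vertex, angle is measured against
that vertex's outward normal.  Surface sampling density therefore bounds
the metric accuracy (±half the vertex spacing).  Binning is equal-width,
right-open except the last bin; depth range [0, 50] mm, angle range
[0°, 180°], five bins; quartiles by linear interpolation of order
statistics.

## Forward solver

First-order Lagrangian FEM; element matrices `vol · G σ Gᵀ` with constant
per-element gradients; assembly is symmetrized against round-off.  Dipoles
enter through partial integration: the moment-weighted basis gradients of
the host element (located by centroid k-d tree + barycentric test, ties to
the lowest element index).  All internal computation is SI (m, S/m, A·m, V,
T); mesh coordinates and configuration are mm/nAm/µV/fT with conversion at
the module boundary, because the SNR formula mixes µV and fT scales and a
single internal unit system prevents silent 10³/10⁻¹⁵ slips.

The pure-Neumann nullspace (potentials defined up to a constant) is handled
by zero-mean right-hand sides; EEG leadfields are average-referenced, which
makes every reported value reference-independent.  Transfer matrices solve
the adjoint system per sensor row.  The default linear solver is a direct
sparse LU on the system with one grounded node (exact for compatible
right-hand sides, and one factorization serves all sensors); a
Jacobi-preconditioned conjugate-gradient path with zero-mean projection
(relative residual 1e-8) is available as `solver="cg"` and is cross-checked
against the direct path in the tests.  At the study's mesh sizes (≤ ~10⁵
nodes) the direct factorization is both faster and more accurate than
iterating.

MEG: point coils, one row per coil after projecting onto the coil axis
(matching an axial-gradiometer channel count), radially oriented on a
sphere 20 mm outside the scalp.  The secondary field integrates
`−(µ0/4π) σ∇u × (r−x)/|r−x|³` element-wise with a fixed 4-point quadrature;
a guard raises if any coil comes closer to an element than that element's
own diameter (near-singular kernel).  The primary field uses the
infinite-medium closed form.  EEG electrodes are snapped to scalp mesh
nodes, making the restriction matrix a 0/1 row per electrode.

## Analytic oracles

The EEG oracle is the multilayer concentric-sphere Legendre series.  Per
harmonic degree the radial transmission problem is solved as a small linear
system in radius-normalized bases `(r/r_out)^n` and `(r_in/r)^(n+1)`, whose
entries stay O(1) at any degree — the stabilization that makes degrees in
the hundreds usable.  Truncation is adaptive (stop after 10 consecutive
degrees change nothing beyond 1e-8 relative, cap 200); dipole
eccentricities above 0.95 are rejected rather than mis-summed.  An
independently coded single-shell closed form (surface factor
`(2n+1)/n · b^(n-1)/R^(n+1)`) serves as the oracle's own oracle.  The MEG
oracle is the Sarvas closed form, cross-checked in the tests against a
finite-difference gradient of the independently coded magnetic scalar
potential and against the FEM.

Forward accuracy at the default validation resolution (4-layer sphere,
~6 mm edge): EEG RDM ≤ ~0.04 and |lnMAG| ≤ ~0.03 for radial and tangential
dipoles up to eccentricity 0.8; MEG RDM ~1e-4 with the radial-source field
below 0.2% of a co-located tangential source's — the spherical-model null
reproduced numerically.

## Noise and SNR

Baselines are zero-mean white Gaussian, ~10 µV² (EEG) and ~1e4 fT² (MEG)
per channel with ±20% log-uniform per-channel jitter; variances are
recovered by the unbiased sample variance.  White noise matches how noise
enters the SNR formula (only per-channel variances); real baseline spectra
and channel covariance are not emulated, so nothing here tests robustness
to correlated noise.  Absolute SNR levels in dB depend on these synthetic
scales and on the phantom geometry; only *relative* and *directional*
statements (variant orderings, bin trends, modality gaps) are meaningful,
and only those are asserted.

The SVD projection operates on the raw (unwhitened) MEG leadfield; a
whitened variant exists behind a flag and is used for the
energy-conservation check (orthogonal projections conserve Σ b²/s² exactly
only when noise is channel-constant).  Component SNRs apply the 10 nAm
amplitude to each unit-norm projected orientation, the same convention as
cortical sources.  Zero leadfield columns map to a −∞ sentinel, kept in
maps but excluded from summaries.

## Determinism and sizes

A single global seed expands into per-stage seeds by hashing the stage name
(`crc32("stage:seed")`), so adding a stage never perturbs another stage's
randomness; reruns with the same config produce byte-identical CSV
summaries, and every output embeds a key-order-independent config hash.

Problem sizes were chosen so the full default study is a laptop-scale
computation: the 6-shell reference mesh at 6 mm target edge has ~44k nodes
/ ~251k elements; the directional comparison study uses 32 electrodes and
64 coils with ~2.6k cortical and ~1.2k subcortical dipoles and completes in
a few minutes per variant; validation meshes range from ~4k elements
(transfer-equivalence checks) to ~235k (EEG oracle).

## Known limitations

- Sphere phantoms: no skull holes/sutures, no realistic sensor layouts, no
  dura or vessels; CSF thickness is uniform.
- The cortex is a radial graph surface (no overhangs, no true 180° normal
  spread) and its depth range is bounded by the gray shell thickness.
- Point sensors only — no complete-electrode model, no pickup-coil
  integration, no gradiometer baselines.
- Partial integration is the only dipole model; accuracy decays for sources
  within one element of a conductivity interface (eccentric dipoles near
  the gray/CSF boundary).
- In a perfect sphere the radial-source MEG null is exact, so the
  subcortical radial EEG-vs-MEG gap comes out far larger (tens of dB) than
  in realistically shaped heads, where the null is only attenuated.  The
  *direction* of the effect is the transferable statement, not its size.
- No inverse modeling: the maps quantify detectability, not localizability.
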