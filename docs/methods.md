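# Methods

This note records the models behind `soctmi`, the defaults and why they
were chosen, the numerical decisions, and the limits of what the
synthetic experiments can show.

## Digital mouse phantom

The phantom is a prone mouse built from analytic primitives — spheres,
ellipsoids and capsules — voxelized by the center-in-shape rule on a
regular grid (axes: x left–right, y ventral–dorsal, z caudal–cranial;
default spacing 0.5 mm, planning studies use 1.0 mm).  Analytic shapes
were chosen over an atlas because they give closed-form volumes to test
against.  Each voxel belongs to the innermost structure by a fixed
priority (bone > spleen > kidneys > lungs > heart > liver > bowel >
body), so masks are disjoint and the density field is the material
density of the owning structure: soft tissue 1.00, lung 0.26, cortical
bone 1.85 g/cm³ (standard tissue values).

The anatomy is schematic but preserves the load-bearing geometry of
marrow irradiation:

* the vertebral column is a dorsal capsule chain spanning ~75 mm of the
  ~84 mm body, with skull, shoulder, pelvis, femur and tibia bones;
* each kidney abuts the lumbar spine (reference gap ≈ 0.1 mm, and the
  generator guarantees at least one kidney voxel within 1 mm of bone);
* the lungs flank the thoracic spine; heart, liver and bowel fill the
  ventral cavity; the spleen sits left-lateral in the upper abdomen.

A per-subject jitter (uniform, ≤ 0.5 mm per axis; one rigid shift for
the skeleton, independent shifts per soft organ) emulates
subject-to-subject contour variability for cohort studies.  It is a
stand-in for real biological variability, chosen small enough that the
anatomy class is preserved; nothing in the package depends on its exact
law.  Generation is a pure function of (config, seed).

What the phantom does **not** emulate: CT/CBCT noise and artifacts,
HU-to-density calibration, realistic murine organ shapes, respiratory
or positioning variation.  Results on it demonstrate the *planning
geometry* — how collimation strategy interacts with organ adjacency —
not absolute murine dosimetry.

The PTV is skeleton ∪ spleen, optionally expanded by an isotropic
margin.  Margin expansion thresholds the Euclidean distance transform
at `margin + spacing/4`; the quarter-voxel term compensates the
half-sample bias of measuring distances to center-sampled surfaces
(without it, dilated volumes systematically undershoot their continuum
values by a quarter voxel of radius).  The integral-dose region is body
minus skeleton minus spleen.

## Kilovoltage dose engine

The engine models the 225 kV beam (78.8 keV effective energy) as a
mono-energetic divergent primary with a Gaussian lateral scatter
kernel:

    d(v,b) = C · (SID/|v−S|)² · exp(−(μ/ρ)_w · t(v)) · E(m(v)) · K_r · K_c

* `t(v)`: radiological depth from the source, the exact Siddon sum of
  density × intersection length over traversed voxels (symmetric in its
  endpoints by canonical ordering; validated against a brute-force
  voxel-clipping oracle at 1e-9 relative).
* `(μ/ρ)_w = 0.1835 cm²/g`: the water mass attenuation coefficient at
  ~79 keV from standard tables.
* `E(m)`: dose-to-medium enhancement by material class (from density
  thresholds): soft tissue 1.0, lung 1.0, bone 2.8.  The bone value is
  a configuration default chosen to represent the strong photoelectric
  absorption of cortical bone at this energy — bone then absorbs ~280%
  of the soft-tissue dose, consistent with the >250% figure reported
  for kV marrow irradiation.  It is an engine parameter, not a physics
  claim.
* `K`: the beamlet cell's unit fluence integrated under an isotropic
  Gaussian (σ = 0.8 mm at the isocenter plane, a placeholder for an
  uncommissioned scatter kernel).  Because the per-cell integrals
  telescope, the sum of all beamlets equals the closed-form open field;
  fixed collimators (40/20/10 mm squares, 10/5 mm circles) are
  evaluated with that closed form directly.
* `C`: output calibration, unit weight → 1 Gy under reference
  conditions by default.  Absolute gray is conventional; every reported
  metric is a percentage of prescription.

Default geometry follows the irradiator: SID 305.4 mm, 1 × 1 mm
beamlets at the isocenter, fields up to 120 × 120 mm, seven coplanar
gantry angles k·360°/7 about the cranio-caudal axis.

The influence matrix stores one column per beamlet over the support
body ∪ (PTV + 2 mm), with each voxel coupled to beamlets within a
3σ-widened window (the truncated Gaussian tail bounds the error at
~5·10⁻⁴ of the open-field maximum) and entries below 10⁻⁴ of their
column maximum dropped.  The engine's accuracy contract is 2% against
its own closed forms (in practice ~10⁻³ %); it makes no Monte Carlo
claim.  Out of scope: poly-energetic spectra, electron transport,
collimator leakage.

## Inverse planning (SOC)

Objective over non-negative beamlet weights `x`:

    F(x) = Σ_s (w_s/n_s) ‖penalty_s(D_s x)‖² + λ (TV_rows + TV_cols)

One-sided quadratics: the target penalizes underdose below the
prescription (12 Gy default); each organ at risk penalizes overdose
above its goal (0 by default); the integral-dose region enters as a
low-weight overdose term, which supplies the global downward pressure a
pure underdose target objective otherwise lacks.  Default weights: PTV
100, lungs/kidneys 10, liver/heart/bowel 3, integral region 1.  Because
the target goal applies to dose-to-medium, bone reaches prescription at
roughly 1/2.8 of the fluence the spleen needs — the optimizer exploits
this, which is exactly the physical situation.

λ defaults to 0.05 × the estimated Lipschitz constant of the smooth
part, making its effect invariant to the matrix's overall scale; an
absolute λ can be set instead.  TV is anisotropic along the two leaf
axes because the collimator's rectangles are axis-aligned: flat fluence
plateaus decompose into few rectangles.

The solver is FISTA with:

* backtracking on the Lipschitz estimate (power-iteration start);
* the monotone (MFISTA) safeguard, so the recorded objective trace is
  non-increasing by construction;
* gradient-based adaptive restart (momentum dropped when the update
  opposes it — the restart resets the extrapolation point to the new
  iterate);
* cold start at zero; convergence when the relative objective change
  over a 10-iteration window falls below 1e-6; iteration cap 2000
  (pipeline runs cap at 300, which reaches the plateau that matters for
  the comparative dosimetry).

The prox of λ·TV plus the non-negativity constraint is computed
*exactly* by cyclic Dykstra splitting over three operators: exact 1-D
TV along rows (Condat's direct algorithm), along columns, and the
clamp.  A single alternating pass was not sufficient: its fixed point
depends on the step size, which caps agreement with an independent
long-run solver at ~10⁻⁵; with the exact prox, FISTA and a 40k-iteration
plain proximal-gradient run agree to 10⁻⁶ relative objective, which is
the tested contract.

**Rectangle decomposition.**  Greedy peeling: each step selects, by
exhaustive search over all rectangles, the pair (rectangle, weight =
residual minimum inside it) maximizing the L1 residual reduction
(weight × area); ties prefer larger area, then smallest (r0, c0)
row-major — fully deterministic.  The residual stays non-negative, so
the reconstruction never overshoots the fluence map.  Stopping: L1
residual ≤ 2% of the map's L1 norm, budget 128 rectangles per field
(flagged, not fatal, if hit).  Weights are continuous
(fluence-modulated delivery).  Rectangle counts are emergent — they
grow with target size and complexity; on the synthetic phantom the
TV-flattened maps need only a handful per field.

## Parallel-opposed 3D baseline

Auto-placement partitions the PTV's cranio-caudal extent into seven
contiguous slabs at fixed anatomic fractions of its length (boundary
planes are shared exactly by construction).  If one fixed collimator
covers the entire PTV, a single region is returned instead.  Per
region: isocenter and normalization point at the slab's PTV centroid;
collimator = smallest of the five fixed shapes covering the slab's PTV
cross-section; beam axis lateral (left–right) for axial-skeleton
regions and dorso-ventral for femurs, tibias and the spleen-bearing
region.  A config override can replace any placement field.

Each region's opposed pair is weighted so the **dose-to-tissue** at its
normalization point equals the prescription (the local medium
enhancement is divided out).  Normalizing dose-to-medium at a bone
centroid would cap bone at 100% and contradict the defining kV
phenomenon of bone absorbing several times the tissue prescription;
prescriptions in this setting refer to soft-tissue dose.

With five fixed sizes, an interior field whose collimator exceeds its
slab overlaps its neighbours, and dorso-ventral pairs cross lateral
ones; the junction report lists the connected voxel clusters
(26-connectivity) above 110% of prescription — threshold configurable,
110% chosen as the conventional hot-spot cutoff.  Exact edge matching
is achievable (and tested) when slab lengths equal collimator sides;
the auto-placed default deliberately reproduces the overlap/hot-spot
behaviour characteristic of the technique.

## Dose metrics and cohort statistics

* Median dose D50 = 50th percentile with midpoint interpolation for
  even counts, as % of prescription.
* Integral dose = unit-mass mean dose over body minus skeleton minus
  spleen, as % of prescription (mass weighting deliberately off: the
  region is near-uniform soft tissue and the reference convention is a
  volume mean).
* DVHs are exact cumulative curves on uniform bins (V(0) = 1,
  non-increasing, 0 beyond the maximum); cohort averaging is pointwise
  on shared bins and preserves monotonicity.
* Cohort summaries use the sample SD (n−1) — required to reproduce the
  reference table's SD row (the population SD gives 8.8 instead of 9.8
  for the bowel column).
* Report rounding is one decimal, round-half-away-from-zero (matching
  the reference tables; numpy's half-to-even differs at e.g. 2.25).
* Paired comparisons report per-subject differences, their mean and SD,
  `reduction vs prescription = 100 − mean(modulated)`, and a two-sided
  paired t-test p-value (Wilcoxon optional).  The choice of test is
  exposed rather than fixed because the test behind the reference
  p-values is not identifiable from the printed data; the self-test
  therefore checks means, SDs and reductions, not p-values.

The bundled reference cohort (five subjects × two plans × five organs)
is a transcription of previously reported per-subject median doses; one
garbled heart cell was read as 11.1, the only value consistent with the
printed column average (10.0) and SD (1.1).  Two aggregate figures
quoted alongside that table are not reproducible from its per-subject
values — a heart SD of 11.3 (the per-subject values give 6.9) and a
kidney paired reduction of 80.6 (the values give 80.0) — so the
self-test asserts only the recomputable cells.

## Study conditions for the synthetic comparison

Chosen once, as the package's standard desk-scale conditions: cohort of
five subjects (seeds master+0 … master+4), prescription 12 Gy, 1.0 mm
planning grid, default phantom jitter 0.5 mm, optimizer cap 300
iterations, decomposition tolerance 2%/budget 128.  On these conditions
the acceptance suite asserts *orderings*, not absolute values: the
modulated plan's kidney and lung median doses and the integral dose are
below the baseline's in every subject.  Absolute organ percentages on
the synthetic phantom (e.g. kidneys ~31% vs ~114%) are not comparable
to values measured on real mice with commissioned engines and tuned
constraint weights; the constraint weights behind the reference plans
are not public, so only the direction of the contrast is a claim.

## Known limitations

* Mono-energetic primary + Gaussian kernel; no Monte Carlo benchmark.
* The scatter σ and output calibration are uncommissioned placeholders.
* The objective weights are illustrative defaults; no attempt is made
  to reproduce any specific plan's constraint set.
* The baseline's beam placement is an automated convention; manual
  clinical-style placement can be injected via overrides but is not the
  default.
* Wall-clock planning-time comparisons are out of scope.
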