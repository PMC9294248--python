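# Methods

This note documents the models implemented in lvshapeflow, the defaults
and why, the numerical choices, and what the synthetic fixtures do and do
not establish about real data.

## Geometric measures

Volumes are computed by the divergence theorem over watertight triangle
meshes (absolute value, so orientation does not matter) and reported in
ml; coordinates are mm throughout, pressures Pa internally and mmHg at the
reporting layer. A mesh with boundary edges is rejected for volume
computation with the boundary-edge count in the error.

The sphericity index is defined here as cavity volume divided by the
volume of the sphere whose diameter is the apex-to-mitral-centroid
long-axis length. Several sphericity definitions circulate in the
echocardiography literature; this one uses only landmarks the pipeline
already carries, equals 1 for a sphere whose diameter is its long axis,
and decreases with elongation. Users with a preferred definition can
compute it from the same primitives.

Closest-point queries (displacement field ED→ES, wall thickness against
the epicardium) use exact point-to-triangle distance with a KD-tree over
triangle centroids for candidate search; the per-query radius
(nearest-vertex distance plus the largest centroid-to-corner extent)
guarantees the true nearest triangle is among the candidates. Ties take
the smallest triangle index, making results deterministic. The wall-motion
metric aggregated per segment is the displacement magnitude, not its
normal projection — the two differ only by the tangential sliding
component, which is small for near-normal contraction.

Annulus rings are fitted in their total-least-squares plane: the aortic
ring by a direct algebraic ellipse fit (area πab), the mitral ring by
nonlinear least squares to a cardioid r = a(1+cos(θ−θ₀)) with a free pole,
8 angular multi-starts to avoid the orientation local minima (area
(3/2)πa²).

Rigid alignment is landmark Procrustes (apex, RCA ostium, two annulus
centroids) without scaling: deterministic, size-preserving — cohort size
variation is anatomy, not nuisance. An ICP refinement is deliberately not
the default.

## AHA 17-segment parcellation

All cuts derive from landmarks: the base plane is fitted to the pooled
annulus points, the long axis runs from the base-plane centroid to the
apex, the RCA–apex plane fixes the azimuthal origin. Axial height is
measured along the straight axis (not arc length) and clipped to [0,1].
Slab borders sit at 1/3 and 2/3 of the height; basal and mid slabs carry
six 60° sectors, the apical slab four 90° sectors. Where the convention is
under-determined we fix: the RCA–apex plane is the segment 1/2 border,
sectors advance counterclockwise viewed from the base, segment 13 is
centered on the anterior azimuth, and the apex cap (segment 17) covers the
most apical 10% of the axial height (configurable — no standard defines
the cap extent on a surface mesh).

## Correspondence and the shape model

Each segment patch is flattened to the unit disc: the boundary loop maps
to the circle by cumulative arc length starting from the boundary vertex
nearest the patch's canonical basal/sector-start corner (this anchor is
what makes the parameterization comparable across cases), and interior
vertices solve a mean-value-coordinates Laplace system — convex
combination weights, so the flattening is bijective for the convex-ish
patches an LV produces. The fixed template samples each disc on a polar
grid (default 7 radii × 24 angles + center, i.e. m = 2873 vertices over 17
patches); barycentric coordinates map samples back to 3D and carry any
per-vertex field with identical weights. Patches that are not topological
discs (holes, handles, multiple boundary loops) are rejected by an Euler
and boundary-loop check naming the offending segment. The resampled
surface duplicates patch borders rather than welding them — correct for
feature stacking, not meant for volume computation.

The feature vector stacks coordinates, displacement, thickness and the
RCA landmark raw, all in mm, with no per-channel weighting by default: the
channels live on comparable scales and raw stacking keeps mode loadings
interpretable (a weighting option exists). PCA is a thin SVD of the
centered matrix — never the explicit (7m+3)² covariance — with 1/(n−1)
normalization; the normalization choice scales eigenvalues but not mode
directions. Each mode's sign is fixed by making its largest-magnitude
loading positive, so fits are bit-reproducible across platforms. Synthesis
is S̄ + X·b, with an optional ±3σ clamp per mode used when exporting
meshes, where extreme weights can self-intersect.

Subcohort labels: A0/A1 by aneurysm absence/presence, ML/MH by MR grade
below / at-or-above grade II (the grade is continuous, so 1.99 is ML);
aneurysmatic cases additionally carry T/I/HK for true / intermediate /
hypokinetic morphology, and cases with unclassified aneurysm shape are
excluded from that secondary grouping. A subcohort mean case is the
component-wise mean feature vector, identical to a subcohort model's S̄.

## Volume curve and motion prescription

The shipped normalized volume curve is a parametric stand-in (a
cohort-averaged curve is not publicly available): monotone cubic (PCHIP)
segments through control points spanning systolic ejection, E-wave,
diastasis and A-wave at 0.36/0.25/0.21/0.18 of the cycle, with f(0)=f(1)=1
and min f = 0 at end-systole. Any user curve with that normalization is
accepted from CSV. Scaling: V(t) = EDV·(1 − EF·(1 − f(t/T))), T = 60/HR;
75 bpm gives T = 0.8 s.

The cavity volume of x_ED + λ·d is an exact cubic polynomial in λ; the
solver fits its four coefficients from four exact volume evaluations and
then solves V(λ) = V_target per time step by Newton iteration warm-started
from the previous step's λ, with automatic bisection whenever a Newton
step leaves the maintained bracket — robust even if the field makes V(λ)
locally flat. Default residual 1e-6·EDV, default Δt 2 ms (400 steps at
0.8 s). Diastolic refilling runs the same field backwards (λ returns to
0): the motion derives from two states only, so no torsion and no
independent diastolic kinematics are represented. Grid velocity uses
forward differences of λ (last step backward), so the discrete integral
of v_g·dt exactly reproduces the displacement history.

## Valves, regurgitation, rheology

Only the baffle pressure-drop law Δp = −ρ(α|vₙ|+β)vₙ and the orifice
areas/ramp durations are canonical. Area ramps are linear in time (a
smoothstep option exists); the published description says only "smooth".
The α/β schedules are stand-ins chosen so a closed valve is effectively
impermeable (β = 10⁶) and an open one free (α = β = 0). The intermediate
mitral orifice outline shipped in `data/` is a synthetic kidney-shaped
polygon normalized to unit area — a stand-in for the published
intermediate state, swappable by CSV. The regurgitant orifice area is
regurgitant flow rate divided by a 4.0 m/s target jet velocity (middle of
the regurgitant-jet speeds such simulations report; configurable).

## Hemodynamic post-processing

SKE is reported in J/m³ (kinetic energy per unit cavity volume).
Dissipation uses Φ = 2η(γ̇)·D:D with D the symmetric velocity gradient
(central differences on the voxel grid) and γ̇ = √(2D:D); the antisymmetric
part of ∇v drops out of σ:∇v, so rigid rotation dissipates nothing —
a property the tests verify to discretization error.

The transport integrator is first-order upwind finite volume in flux
form on a uniform voxel grid: exactly conservative (closed-box mass drifts
only by floating-point rounding, < 1e-10 per step) and monotone for
discretely divergence-free face velocities. Velocities can be supplied
cell-centered (faces average neighbours) or staggered on faces — the
stirred-box generator builds its face velocities from stream-function
differences at cell corners, which makes the discrete divergence exactly
zero and hence the maximum principle exact. CFL ≤ 0.5 is enforced by
sub-stepping with a hard cap (error beyond it, never an unstable run).
First-order upwinding is diffusive; that is acceptable here because the
washout metrics integrate over whole cycles, and a flux-limited
second-order scheme remains an extension point.

Washout metrics: the fresh-blood half-life is the first time the LV fresh
volume fraction reaches 50%, linearly interpolated between samples and
reported in seconds and cycles; never reaching 50% sets an explicit flag
rather than a number. Direct flow integrates the fresh inflow over the
release diastole and the fresh outflow over the immediately following
systole; the relative value divides by the entered fresh volume (not EDV)
— a documented, configurable convention. The apex–base pressure gradient
averages pressure on planes orthogonal to the axis at axial fractions
0.25 (basal) and 0.75 (apical) by default — the plane placement is not
standardized, so it is a parameter — and positive ΔP means apical exceeds
basal pressure (pushing blood toward the outflow tract).

## Synthetic fixtures: what they are and are not

The generator produces truncated prolate-spheroid endocardia on a fixed
(48 rings × 52 azimuth) grid closed by an apex vertex and flat basal lid
(~2,500 vertices), so cohorts are corresponded by construction and
shape-model tests isolate PCA behavior from correspondence error; the
correspondence operator is exercised separately on independently meshed
spheres. Defaults emulate a dilated ischemic ventricle: 100 mm long axis,
sphericity 0.65 (EDV ≈ 250 ml), 8 mm walls, EF 0.25, heart rate 75 bpm.
Contraction is inward-normal motion tapered to zero at the fixed base,
modulated per AHA segment by a hypokinesis map and globally scaled by a
root find so the achieved EF matches the target within 0.5%.

Aneurysm classes are realized morphologically: the "true" sac is a necked
cylindrical-radial bulge beside the apex whose meridian flips curvature
twice; the "intermediate" class is an apex-merged sphere-radial flare
(bump centered beyond the pole, so only its rising shoulder lies on the
wall) flipping curvature once; "hypokinetic" has no bulge but carries the
motion deficit and moderate thinning. Wall thinning saturates over the
bulge core so the whole aneurysmal wall, not just its peak, loses the
configured thickness fraction.

Cohorts plant k smooth, mutually orthonormal feature-space modes
(low-order harmonics in the surface parameters driving the coordinate,
displacement or thickness channel) with Gaussian weights, plus optional
i.i.d. noise; the generating directions are returned so recovery tests
have ground truth. Same seed, same cohort, bit-identical.

What passing tests show: the operators implement their definitions
(analytic fixtures), the pipeline composes, and planted structure is
recovered at cohort sizes of tens of cases. What they do not show:
segmentation quality on real images, correspondence fidelity on strongly
non-convex patient anatomies, or clinical validity of any marker — the
synthetic anatomy is smooth and symmetric in ways patient data are not.

## Problem sizes

Defaults are desk-scale by design: ~2,500-vertex surfaces, 40-case
cohorts, 400-step cycles, and 20×20×4 transport grids over 8 cycles keep
the full suite in tens of seconds while leaving every contract sharp
(volume-following to 1e-6·EDV, conservation to rounding error). All
resolutions are parameters, and all operators are vectorized, so scaling
up is a matter of compute, not code.
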