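# Methods

This note documents the models implemented in `uteromag`, the choices made
where the design was genuinely open, and what the package's synthetic test
conditions do and do not establish about real recordings.

## Cell model

Each myocyte follows a generalized FitzHugh–Nagumo system in the
transmembrane potential `v_m` (V) and recovery variable `w` (V):

    dv_m/dt = [ k (v_m − v1)(v2 − v_m)(v_m − v3) − w + ν h(t) ] / (ε1 c_m)
    dw/dt   = ε2 (β v_m − γ w + δ)

with defaults `c_m = 0.01 F/m²`, `ε1 = 10 Ω·m²`, `ε2 = 10 S⁻¹`,
`v1 = −0.02 V`, `v2 = −0.04 V`, `v3 = −0.065 V`, `k = 7000 V⁻²`, `β = 1`,
`γ = 0.1`, `δ = 0.052 V`.  The stimulus amplitude `ν` is the bifurcation
parameter.  Eliminating `w` on its nullcline inverts the equilibrium
condition to `ν(v*) = −k(v*−v1)(v2−v*)(v*−v3) + (βv* + δ)/γ`, and two
closed-form discriminants organize the phase structure:

* `Δ1 = (v1+v2+v3)² − 3(v1v2+v1v3+v2v3) − 3β/(kγ) < 0` makes `ν(v*)`
  strictly monotone, so the equilibrium is unique for every stimulus;
* `Δ2 = (v1+v2+v3)² − 3(v1v2+v1v3+v2v3) − 3ε1ε2c_mγ/k > 0` opens an interval
  of equilibrium potentials, `v* ∈ ((S−√Δ2)/3, (S+√Δ2)/3)` with
  `S = v1+v2+v3`, on which the Jacobian trace is positive (Hopf
  instability).  Evaluating `ν(v*)` at the interval ends gives the
  limit-cycle stimulus window; for the default set it is (0.012, 0.207) and
  the resting potential is −55.65 mV.

A structural fact worth recording: at any equilibrium,
`det J = (ε2/(ε1 c_m))(β − γ k g'(v*))`, and `det J ≤ 0` for some reachable
equilibrium is *equivalent* to `Δ1 ≥ 0`.  Under the unique-equilibrium
precondition the linearization therefore always has a well-defined natural
frequency `ω = √(det J)`.  `hopf_frequency` returns this quantity — the
modulus of the complex eigenvalue pair, equal to its imaginary part exactly
at the bifurcation — because, unlike the damped imaginary part, it exists
throughout the stimulus range and obeys the exact `√(ε2/ε1)` scaling (the
equilibrium itself depends only on `ν`).

Spike detection uses upward crossings of −35 mV (midway between rest and
the ~−25 mV spike plateau) with a 0.2 s refractory lockout; rates are
reported as the reciprocal mean inter-spike interval `(n−1)/(t_n − t_1)`
after discarding the first 20 % of a trace, which is insensitive to where
the analysis window cuts the train.  Burst onsets are spikes preceded by
more than 30 s of silence.  Under the 1-minute-on / 7-minute-period
heaviside drive at `ν = 0.11` the inter-burst interval locks to the drive at
420 s.  Under constant `ν = 0.15` the measured steady rates are 0.155 /s for
`ε1 = ε2 = 1` and 0.990 /s for `ε1 = ε2 = 10`; the reference values for the
same protocol are about 5 % and 3 % higher, a spread consistent with the
unstated counting convention, and the package's convention is fixed as
above.

Integration is adaptive LSODA (rtol 1e−8, atol 1e−10) — explicit where the
system is non-stiff with automatic switching to BDF — restarted at stimulus
discontinuities so step control never smears a heaviside edge.

## Fiber and conductivity model

The myometrium lacks global fiber order but is locally coherent.  The
surface is partitioned into 25 regions by rejection-sampled seed elements
(uniform over elements, resampled until all pairwise Euclidean separations
are ≥ 4 cm, every element then joining its nearest seed) and one fiber
angle per region is drawn from N(0, π/4).  An angle `α` becomes a unit
tangent via the orthonormal basis at surface normal `n = (nx, ny, nz)`,
`s = √(nx² + nz²)`:

    t1 = (nx·ny, −s², nz·ny)/s      (steepest descent of the vertical y)
    t2 = (−nz, 0, nx)/s             (horizontal tangent)
    a3 = cos(α) t1 + sin(α) t2

This is the unique sign/grouping reading that is unit-norm and tangent for
all normals; at the two poles (`s → 0`) the fixed pair `t1=(1,0,0)`,
`t2=(0,0,1)` is substituted.  Conductivity is transversely isotropic,
`G = (σ_l − σ_t) a3 a3ᵀ + σ_t I`, with `σ_el = 0.68 S/m` published, the
transverse-to-longitudinal ratio configurable (default 1/5 — the order of
magnitude typical of smooth muscle), and `Gi' = ζ Ge'` by the
equal-anisotropy-ratio assumption that underlies the monodomain reduction
(`ζ = 0.518` for speed analysis, 0.818 in the validation compartment set).

## Analytic front speed

Freezing `w` at its resting value `(β v_mr + δ)/γ` reduces the monodomain
equation along the fiber to a scalar cubic bistable reaction–diffusion
equation, whose classical traveling front has speed

    c = |r1 − 2 r2 + r3| / c_m · √( k σ_el ζ / (2 ε1 a_m (ζ + 1)) )

where `r1 ≤ r2 ≤ r3` are the roots of
`(v − v1)(v2 − v)(v − v3) = (β v_mr + δ)/(kγ)` and `a_m = 575 870 m⁻¹` is
the surface-to-volume ratio.  When `v_mr` is the model's own resting
potential it satisfies this equation exactly (it is the `ν = 0` equilibrium
condition), so the cubic always has a real root at rest and, for the
default parameters, three real roots giving c = 0.0428 m/s.  Rounding
`v_mr` to −0.056 V pushes the cubic just past its fold: one real root and a
complex pair remain.  The `root_policy` parameter controls the behaviour —
`auto` (default) recomputes with the consistent rest value and reports the
path taken, `strict` raises, `real_parts` sorts the real parts (yielding
0.0469 m/s).  All paths are exposed and the result object records which was
used.

## Monodomain propagation

The 1 cm wall is thin relative to the 16 cm organ, so the myometrium is a
2-D mid-wall surface: tensors are projected onto each element's tangent
plane (`P G P`, `P = I − nnᵀ`) and assembled into a P1 finite-element
stiffness matrix for `∇·(ζ/(ζ+1)) Ge' ∇v_m / (a_m c_m)`.  Stiffness rows
sum to zero, so a constant field is in the kernel and, the surface being
closed, the zero-flux condition holds by construction (the mass-weighted
integral of `v_m` is conserved under pure diffusion to solver precision).
`J_ion ≡ (w − k(v_m−v1)(v2−v_m)(v_m−v3))/ε1` so the space-clamped limit
reproduces the cell ODEs exactly; the pacemaker drive
`V_stim · cos(2π·0.05(t − T_stim))`, gated to `t ∈ [0, T_stim=5 s]` and to a
5 cm ball around the pacemaker (defaults `V_stim = 0.11 V`), enters as
`J_stim/c_m` with the same 1/ε1 scaling.

Time stepping is Lie splitting: RK4 for the pointwise reaction and backward
Euler for diffusion with a pre-factorized sparse system, Δt = 1 ms (halving
Δt moves the measured front speed by ~0.15 %).  The **consistent** P1 mass
matrix is used rather than the lumped one: the activation front is ~1 mm
wide against 5 mm (level-5 icosphere) or 2.5 mm (level-6) edges, and in this
under-resolved regime lumping retards the front severely (measured
0.0323 m/s at level 6 versus 0.0409 m/s consistent, against the 0.0421 m/s
reference) and below roughly 10 mm edges pins it entirely.  With consistent
mass the fundus-to-equator speed on the 15.5 cm mid-wall sphere with
vertical fibers is 0.0406 m/s (level 5) and 0.0409 m/s (level 6) — a 0.8 %
change between levels and within 3 % of the reference.  Arc length on exact
spheres (graph geodesics otherwise) over first-crossing times of −35 mV
defines the measured speed; the measurement points are 25° from the fundus
(just outside the stimulated patch) and the equator.

Strongly transverse fronts (width `∝ √σ_t`) pin at any desk-scale sphere
resolution, so the anisotropy-ratio property (speed ratio `√(σ_l/σ_t)`) is
verified on a flat strip meshed at 0.5 mm, which resolves both widths; the
observed ratio is within 2 % of `√5`.

Region-specific dynamics assign the excitable (limit-cycle-capable)
parameter set within 10 cm of the pacemaker and a stable-equilibrium set
(`ε1 = 200`, `ε2 = 0.09`, `k = 10000`, others shared) outside, confining
activation.  Because `v_m` is continuous, the diffusive skirt at the zone
boundary necessarily exceeds a few mV in the first ring of outside
vertices; confinement is asserted as no threshold crossing anywhere outside
plus sub-2 mV deviation beyond a 2 cm margin.

## Magnetic forward model and sensors

The quasi-static source density is `J_s = −ζ Ge' ∇v_m` per element (exact
P1 tangential gradients); each element contributes a current dipole
`Q = J_s · area · thickness`.  The default field is the primary-current
Biot–Savart sum `B(r) = (μ0/4π) Σ Q_e × (r − r_e)/|r − r_e|³` with an
evaluation exclusion radius of 1.5 mean edge lengths.  Volume (return)
currents are available through an optional coarse boundary-element solve:
interface potentials expanded constant-per-triangle, collocated at
centroids with the double-layer (solid-angle) operator, the self-surface
diagonal fixed by the 2π row-sum identity and the insulated-exterior gauge
by mean deflation; the secondary field follows from the surface-integral
(Geselowitz) form.  Against the closed-form Legendre series for a radial
dipole in a homogeneous sphere the level-3 solve is accurate to 0.6 %, and
the radial component of the secondary field from a tangential dipole in a
spherically symmetric conductor vanishes to ~1e−4 relative — the expected
exact null.  Default forward maps omit volume
currents: the sensor-map questions this package targets concern pattern
rather than absolute amplitude, and the corrected evaluator remains
available wherever the secondary contribution is of interest.

Sensors follow the 151-channel SQUID array geometry: hardware gradiometers
whose outer coil sits 8 cm behind the inner along the local surface normal.
The true coil coordinates are not public; a deterministic ring lattice
(ring counts 1, 6, 12, 18, 24, 30, 60, staggered azimuths) is used on
either abdomen shape.  The concave device surface is modeled as a spherical
bowl of 30 cm curvature radius whose curvature center lies inside the body,
so the bowl hugs the abdomen; both the bowl and the spherical-abdomen
layouts span a common 18 cm lateral aperture, keeping maps sensor-wise
comparable across abdomen shapes.

## Scenario comparisons

The configuration matrix (uterus sphere/pear, abdomen sphere/bowl, fibers
fixed-angle(π/4)/random, pacemaker fundus/lateral/back, sensor model
normal-component/gradiometer) is expressible purely through `ScenarioConfig`
fields; a fixed master seed makes runs bit-reproducible and every run emits
a manifest sufficient for exact re-execution.  The pear stand-in is a
radial modulation `1 + 0.15 cosθ − 0.10 sin(θ/2)` of the sphere — a mild
near-term ovoid (fundus/cervix radial multipliers 1.15/0.76).

Because the wall sits ~2 cm from the inner coils and the activation front
is effectively a line source, raw sensor maps carry structure at the
sensor-spacing scale that decorrelates under any perturbation.  Pattern
comparisons therefore use maps Gaussian-smoothed over lateral sensor
position at a 5 cm scale — the scale of the broad field lobes that
qualitative map comparisons are about.  Under that observable, on level-5
meshes with 15 s runs and snapshots every 2 s, geometry substitutions leave
the map highly correlated with the baseline (pear uterus 0.76, device-shaped
abdomen 0.91) while physiological substitutions decorrelate it (random
fibers 0.38, lateral pacemaker 0.09) — the ordering that motivates using
spherical geometry with carefully modeled fibers and pacemakers.

## Signal preprocessing

The acquisition chain is mirrored as: polyphase resampling from the
simulation rate (default 250 Hz) to 32 Hz, then a 4th-order Butterworth
band-pass 0.1–1 Hz and a 4th-order Butterworth band-stop 0.25–0.35 Hz (the
maternal-breathing band), each applied forward-backward for zero phase.
Only the band edges are prescribed by the acquisition description; filter
family and order are package defaults recorded in every manifest.

## Problem sizes and limitations

Default test and acceptance runs use icosphere levels 5–6 (10 242–40 962
vertices), 9–15 s of propagation at Δt = 1 ms, 150 s cell traces, and
level-3 BEM interfaces — sizes chosen so the full pipeline runs on a
single desk-scale CPU.  The synthetic conditions emulate the published
study protocol, not real tissue: one homogeneous cell type, region-wise
constant fibers with no transmural rotation, a thin-wall (2-D) myometrium,
no SQUID noise or cryostat geometry, and no real anatomy (the pear surface
is a synthetic stand-in for an anatomical mesh).  Passing tests establish
internal consistency with the stated models and tolerances at these sizes;
they do not validate against patient recordings, which the package does not
ingest.
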