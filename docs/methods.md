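# Methods

`fiberdep` simulates the transport and deposition of fiber-shaped
(prolate-spheroid) aerosols in synthetic models of the conducting
airways during a dry-powder-inhaler (DPI) inspiration. This note
describes the model, its assumptions, the synthetic domains and flow
fields that stand in for anatomical CFD, the numerical scheme, and what
results computed on these surrogates do and do not say about real lungs.

## Particle model

A fiber is a rigid prolate spheroid of density ρ_p = 1000 kg/m³,
described by the volume-equivalent sphere diameter d_p and aspect ratio
AR = b_p/a_p ≥ 1 of major to minor semi-axis. Volume equivalence gives
a_p = (d_p/2)·AR^(−1/3), b_p = AR·a_p. The Stokes-equivalent diameter

    d_Stk = 2 a_p sqrt( AR · ln(AR + sqrt(AR² − 1)) / sqrt(AR² − 1) )

(limit d_p at AR = 1) summarises the Stokes-regime aerodynamics; the
relaxation time is t₀ = ρ_p d_Stk² / (18 μ_air) and the Stokes number
Stk = t₀ u₀ / D, with u₀ the peak inlet centreline velocity and D the
inlet diameter of a domain. Elongation at fixed volume always lowers
d_Stk, t₀ and Stk: high-AR fibers behave as flow tracers.

Forces on a particle: orientation-dependent Stokes drag through the
Oberbeck translational resistance tensor of a prolate spheroid
(K∥, K⊥ both reduce to 6πa for a sphere; a near-sphere series is used
below eccentricity² = 1e−4 where the closed form cancels numerically);
Saffman-type shear lift evaluated with d_Stk as length scale, F =
1.615 μ d_Stk² (u_rel × ω)/sqrt(ν|ω|), behind a pluggable interface so
an orientation-resolved lift model can be substituted; and gravity.
Buoyancy (ρ_air/ρ_p ≈ 0.1%), Brownian motion, electrostatics,
hygroscopic growth and particle–particle interactions are neglected;
coupling to the flow is one-way. Rotation follows the quasi-steady
Jeffery equation dp̂/dt = W p̂ + λ(S p̂ − (p̂ᵀS p̂)p̂), λ = (AR²−1)/(AR²+1):
the rotational relaxation time of micron fibers is far below the flow
timescales, so rotational inertia is dropped — a deliberate modelling
choice, validated against the closed-form Jeffery orbit period
2π(AR + 1/AR)/γ̇ in simple shear.

Deposition is on contact: any touch of the airway wall removes the
particle (entrapment by mucus). For contact purposes a fiber is the
segment [x − b_p p̂, x + b_p p̂] of radius a_p, sampled at both tips and
every a_p/2 along the axis (≤ 64 samples); a sphere reduces to the
centre-distance test. Tip-only contact — centre clearance above a_p —
is tagged "interception"; otherwise the event is "sedimentation" when
the gravity-aligned velocity component exceeds half the speed, else
"impaction". The mechanism tags are diagnostic conventions, not physics:
the 0.5 velocity-fraction split is a labelling choice.

## Synthetic domains

Anatomical meshes and RANS turbulence are out of scope; the domains are
unions of straight tapered cylinders with analytic wall distances.

**Bronchial tree.** A symmetric dichotomous tree spanning ten airway
generations (labelled 7–16, nine bifurcation stages) whose diameters
follow the geometric progression solved so the first generation is
2.45 mm and the last 0.5 mm. Branch length is 3.5 diameters
(Weibel-like L/D); the bifurcation half-angle starts at 35° and shrinks
by a factor 0.85 per level, with the branching plane rotated by 90° plus
a 30° twist at successive levels. The shrinking angle keeps each deep
subtree inside its own solid-angle sector: with a constant angle the
512 terminal branches of a nine-level tree unavoidably collide, and the
twist breaks the exact reflection symmetry that otherwise makes distant
branches coincide. Construction validates global non-overlap with a
sampled-centreline KD-tree query. Gravity is the +z axis, which is also
the root axis.

**Upper-airway surrogate.** A generic conducting-airway analog with no
claim of anatomical fidelity: a horizontal mouth tube (D = 2 cm), a
co-axial contraction into a laryngeal-analog constriction (half the
inlet radius, so the mean velocity quadruples), a 90° bend discretised
into 15° elbow pieces, a co-axial diffuser into a vertical trachea, and
five outlet branches, one per lung lobe (LU/LL/RU/RM/RL). Default
dimensions give a lumen volume of ≈0.1 L, a plausible mouth-to-mid-
bronchi conducting volume, which sets the bolus hand-off delay (≈0.1 s
at the mean DPI flow). Gravity is −y.

**Junction geometry.** Two features make the piecewise-cylinder union
traversable by inertialess tracers, which a naive union is not:

* *Transition cones.* Over the entry of each segment the wall radius
  holds the parent radius across the miter-wedge depth
  (R_parent·tan(tilt/2)) and then tapers linearly to the segment radius
  over one diameter. The taper delay matters: flow direction switches
  at the junction's miter plane, which different azimuths cross at
  different axial depths, and starting the taper before the last
  crossing systematically squeezes near-wall particles outward
  (≈2% of the radius per junction — enough to deposit every marginal
  particle in a nine-junction cascade).
* *Carina ridges.* The union of two daughter cones has no dividing
  ridge, so nothing would ever impact at a bifurcation. Each two-child
  junction therefore carries a rounded rod along the dividing line of
  the bifurcation (perpendicular to the branching plane). Its radius is
  0.7× the clearance that the kinked flow itself generates at the apex
  (R_parent·tan(θ/2)·sinθ), so tracers just clear it while particles
  that lag the turn strike its upstream face — carinal impaction — and
  fiber tips can graze it — interception. The 0.7 sharpness factor is a
  surrogate parameter (`carina_sharpness`), chosen once: 1.0 would
  capture tracers, ≪1 would make carinas invisible.

## Flow fields

The DPI maneuver is parameterised by its printed characteristics: tidal
volume 2.95 L, peak inspiratory flow 90 L/min, inspiration 3 s. The
waveform shape is a sin² ramp (rise time 0.4 s, a typical sharp DPI
onset), a plateau whose end t_h = 2·TV/P + t_r − T = 4/3 s is solved in
closed form from the volume constraint, and a cosine decay — any smooth
profile matching the three printed constraints is admissible, and this
one reproduces them exactly. The particle bolus spans 0.45–0.6 s.

Each segment carries a fixed share of the inlet flow: the chain carries
everything, tree bifurcations split evenly, and the five upper outlets
receive the physiological lobar fractions (LU 15%, LL 31%, RU 14%,
RM 7%, RL 33%). The profile is parabolic (Poiseuille) with no-slip
walls, scaled in time by the waveform. In transition cones the
self-similar parabolic profile carries the exact mass-consistent radial
velocity u_r = u_z · r R′(z)/R(z), which funnels particles through
contractions instead of sweeping them into junction faces. Flow
direction is piecewise constant between junction miter (bisector)
planes: parallel to the parent axis upstream of a segment's miter
plane, to the segment axis between its own and its children's planes,
and to a child's axis beyond that child's plane — as in a mitred elbow,
streamlines kink at the planes and never cross walls. Velocity
gradients are analytic everywhere off the (measure-zero) kink planes
and verified against central finite differences to better than 1e−4.

This laminar analytic construction deliberately replaces the
realizable k–ε RANS solution of the anatomical problem. Consequences:
no turbulent dispersion, no secondary (Dean) flows, no laryngeal-jet
turbulence — upper-domain deposition of mid-size particles is therefore
substantially lower than anatomical values, and all upper-domain
results are surrogate-labelled. The Reynolds diagnostic still spans the
physiological ordering: ≈6300 at the mouth inlet at peak flow down
through ≈430 at the tree root to ≈4 at the terminal generations.

**Hand-off.** Particles exiting the upper surrogate re-enter the tree
inlet individually: delayed by the upper lumen filling time
(volume / mean flow ≈ 0.1 s), velocity scaled by the ratio of
time-averaged inlet mean velocities of the two domains (0.556 with the
default geometry), radial position and azimuth mapped proportionally
onto the tree inlet disc, orientation retained (rotated with the axis
change). The tree waveform is the DPI waveform scaled so the tree inlet
mean velocity equals the mean upper-outlet exit velocity at every
instant (velocity continuity across the hand-off).

## Numerical scheme

Translation uses an exponential integrator that solves
m dv/dt = μK(p̂)(u_f − v) + F_lift + m g exactly for coefficients frozen
over the step, split along/across the fiber axis where the drag tensor
is diagonal. The flow is evaluated at the step midpoint (one predictor
substep). Because the scheme is exact for linear drag, the step does
not need to resolve t₀ — only the flow and geometry scales. Particles
are one-way coupled and therefore independent: each carries its own
clock and an adaptive step of at most `dt_upper_s`/`dt_tree_s`
(default 5e−4 s), shortened to keep travel below 10% of the local
segment radius, to keep |∇u|·Δt below 0.25 for fibers (rotation
resolution), and to land exactly on the first junction kink plane the
step would cross, continuing with a freshly evaluated field. Landing on
the planes matters: stepping across a kink overshoots the turn by
|v|Δt·sinθ, which near walls masquerades as deposition. Orientation
uses a midpoint Jeffery update with renormalisation (unit norm
preserved to 1e−9 per step). A "fidelity" mode instead caps the step at
the reference 2e−7 s. Halving the default step cap changes a 1 s
benchmark trajectory endpoint by <1e−4 relative.

Contact is checked every step against the current segment
neighbourhood (self, parent, children) — incremental relocation avoids
global searches; the fiber sampling (≤64 points) runs only when the
centre is within b_p + a_p of a wall.

## Sweep and statistics

The default study conditions are the 36-group grid d_p ∈ {1–7, 10,
20} µm × AR ∈ {1, 3, 10, 30} with 3000 particles per group (108,000
total), released uniformly in time across the 0.45–0.6 s bolus,
round-robin over a uniform Cartesian seed grid clipped to the mouth
inlet (count within 10% of the request), initially streamwise-aligned
and moving at the local flow velocity. The desk-scale trend tests use
500 particles per group, a size at which binomial errors (≈±2% on a DE
of 0.2) still resolve the qualitative trends; the `--fidelity` flag
restores the full counts. The random seed governs only the stochastic
seed-grid subsampling; the physics is deterministic, and identical
seeds reproduce output files byte for byte.

Reported quantities per group: upper DE = deposited_upper/injected;
bronchial DE = deposited_tree/entered_tree (undefined — and signalled —
when nothing entered), plus the "reduced" form deposited_tree/injected
that folds in upper-airway screening. The reduced form is where the
bronchial optimum appears: conditional-on-entry DE increases
monotonically with d_p (every large particle that enters, deposits),
while screening removes large particles upstream; their product rises
to an interior optimum and falls. The dispersion index is the
per-deposited-particle count of neighbouring deposits within 10 mm
(upper domain) or 5 mm (tree), computed with a KD-tree and
cross-checked against O(n²) enumeration.

A particle-conservation ledger enforces, in exact integer arithmetic,
injected = airborne + Σdeposited + Σexited for every group at every
event, and rejects double retirement of a particle id.

## What the surrogate shows — and what it does not

Passing trends on these domains demonstrate that the implemented
particle physics responds correctly to size and shape: upper deposition
grows with d_p (impaction at the constriction/bend, Stk up to ≈0.6 at
10 µm), elongation at fixed d_p lowers d_Stk and delays that growth
(fibers are screened less), small particles convect through everything,
and the tree exhibits an interior deposition optimum in d_p that shifts
to larger sizes for high AR. These match the qualitative structure
reported for anatomical geometries. The magnitudes do not transfer:
laminar surrogate fields lack turbulent dispersion (upper DE of 2–6 µm
particles is far below anatomical values), the tree is symmetric with a
single fixed gravity direction, exhalation is not simulated, and
carina capture strength is set by one sharpness parameter.

## Known limitations

* Junction flow is miter-kinked rather than smoothly turning; particle
  rotation through bends sees no turning gradient.
* The factor-2 mean-velocity discontinuity across tree junction planes
  (child flux halves while the cone base area matches the parent) is a
  bounded artifact of the overlapping-cone construction.
* Saffman lift uses d_Stk as an isotropic length scale; an
  orientation-resolved lift tensor can be plugged in.
* Wall distance in transition cones is radial (exact for cylinders,
  slightly conservative for cones).
* No resuspension, bounce, mucus thickness or clearance kinetics.
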