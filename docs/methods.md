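# Methods

## Scope and conventions

The package computes mechanical energetics of overground walking at the limb
and joint level, for comparisons between a prosthetic and an intact limb and
between prosthetic interfaces (socket suspension vs osseointegration, OI).
All internal computation uses a right-handed lab frame with +X anterior,
+Y vertical up, +Z to the subject's right; file readers map file axes into
this frame so the energetics code is axis-free. Units are SI throughout
(TRC files declaring millimetres are converted on read). Powers are signed
so that energy absorption is negative; works are reported per stride,
normalized to body mass including the prosthesis (J kg⁻¹).

## Signal conditioning and events

Kinematic channels are low-pass filtered at 6 Hz and force channels at
15 Hz before differentiation or event detection, using 4th-order Butterworth
filters applied forward and backward (zero phase; the net magnitude response
is 8th-order). "4th order" is read as the design order of the single pass —
the most common convention — and the design order is a parameter, so the
alternative reading (2nd-order passes) is also reproducible.

Foot contacts are detected with a 40 N threshold on the vertical GRF:
foot-strike at the first rise through threshold, toe-off at the next fall.
Stance or swing intervals shorter than 50 ms are merged (debounce), which
suppresses threshold chatter without affecting walking-timescale events. A
stride runs from one ipsilateral strike to the next; its speed is the mean
anteroposterior whole-body COM velocity over the stride; speeds are binned
into slow [0.6, 1.1) and fast [1.1, 1.6] m s⁻¹, the shared 1.1 m s⁻¹ edge
going to the fast bin so the rule is deterministic. Per-stride curves are
linearly resampled to 101 points (0–100 % of the gait cycle) for display;
ensemble averages are two-stage (mean within participant, then mean ± sample
s.d. across participants) so stride counts do not weight participants.

## Limb and joint energetics

Limb external power is **F**_GRF·**v**_COM per limb. Gravity is deliberately
absent from this term: it is shared by the body as a whole, and whole-body
energy bookkeeping accounts for it separately (the sum of both limbs'
external powers equals d/dt(½m|**v**_COM|² + m g h_COM) on dynamically
consistent data). Peripheral power is the time derivative of the limb
segments' kinetic energy relative to the COM; total limb power is the sum.
The whole-body COM is the mass-weighted aggregation of segment COM states.

Joint rotational power sums moment × angular velocity over the joint's
degrees of freedom (the hip is summed over 3 DOFs even for planar data,
where the out-of-plane DOFs contribute zero). Translational DOFs contribute
force × linear velocity; the socket pistoning DOF is one such, with
compression displacement positive proximal, so a rising load doing work on
the interface shows as a burst of negative power in load acceptance.

Unified deformable (UD) ankle-foot power lumps everything distal to the
shank: P_UD = **F**·[**v**_shank + **ω**_shank × (**r**_COP − **r**_shank)] +
**M**_free·**ω**_shank, i.e. the GRF acts at the centre of pressure treated
as a point rigidly attached to the shank. The free moment is optional (zero
when absent). Swing samples are zero; a defined load with an undefined COP
raises an error.

Work components integrate power with the composite trapezoid on the native
(unnormalized) time base — integrating on resampled 0–100 % curves would
distort work by stride duration. Positive and negative parts are integrated
separately from the pointwise-clipped power, so positive + negative equals
net exactly under the shared quadrature. Numerical differentiation is
2nd-order central differences with 2nd-order one-sided stencils at the
endpoints. The late-stance window for the peak hip flexion moment is
30–60 % of the gait cycle (configurable; "late stance" has no standard
bounds).

## The cubic socket-work model

The socket of a socket-suspended transfemoral prosthesis pistons proximally
along the residual femur under load. With displacement x(t) and axial load
F(t) modelled as cubic smoothstep profiles on the compression window [0, T]
— s(t) = s_peak(3(t/T)² − 2(t/T)³), which has zero velocity and zero load
rate at both ends — the work absorbed is

  W = −∫₀ᵀ F ẋ dt = −F_peak d_peak ∫₀¹ s s′ du = −½ F_peak d_peak,

independent of T (and hence of cycle duration and phase fraction). The
implementation returns the signed closed form together with an adaptive
quadrature of the integral and requires agreement to 1e-9 relative. With
the representative inputs d_peak = 1.6 cm, F_peak = 769 N (90 % body
weight), T = 20 % of a 1.36 s cycle, the model gives −6.152 J ≈ −6 J per
stride. The load profile starts at 0 N at initial contact; nonzero initial
loads are out of scope. Parameters can also be extracted from a measured
trial: d_peak as the pistoning range within a stride, F_peak as the vGRF at
the sample of peak displacement, and the phase fraction from that sample's
position in the stride.

## Synthetic gait generators

The generators exist so that every pipeline stage can be verified against
exact ground truth; they emulate steady-state overground walking at the
study's conditions (targeted speeds 0.7/1.0/1.4 m s⁻¹, GRFs at 1200 Hz,
kinematics at 120 Hz, ~85 kg adult, stride duration 1.36 s at 1 m s⁻¹
scaled by v^-1/2, stance fraction 0.62), not to be biofidelic in every
detail.

**Point-mass walker.** The body is a point mass with massless legs, so
peripheral power is exactly zero and limb power reduces to the external
term. Per-limb vertical GRFs are quintic-ramped plateaus with a
speed-scaled mid-stance dip (peak ≈ 1.17–1.25 body weight), scaled by the
imposed intact:prosthetic loading ratio and normalized so the mean total
vGRF carries body weight; fore-aft GRFs are windowed braking-propulsion
waves with zero net impulse per stance whose amplitude grows with speed.
COM acceleration is defined by Newton's law from the total force, velocity
by trapezoidal integration (centred with the trapezoid mean so the
work-integral bookkeeping is consistent), and the stride duration is
snapped to an integer sample count so every stride spans an exact period
of the force pattern. The emitted trial carries the exact COM acceleration,
so Σ **F**_limb + m**g** = m**a**_COM holds to machine precision, per-limb
peak vGRF equals the imposed asymmetry exactly, and symmetric configurations
yield per-limb net work below 5 × 10⁻³ J kg⁻¹ per stride (in practice
~10⁻⁷).

**Planar linkage walker.** A sagittal 7-segment chain (head-arms-trunk plus
thigh, shank, foot per limb, adult anthropometric masses, lengths and
gyration radii). The pelvis translates at the target speed with a small
vertical oscillation; the stance foot is flat and exactly stationary; the
swing ankle follows a C² quintic-blended trajectory; thigh and shank
configurations come from two-link inverse kinematics (anterior knee
solution). One central-difference operator produces all linear velocities
and accelerations from positions, and angular rates come from the segment
unit vectors (ω = u × u̇), which keeps the rigid-body relations between the
emitted channels consistent to O(dt²). Total GRF follows from whole-body
Newton-Euler; the double-support hand-off between limbs is a quintic
smoothstep whose two weights sum to one (the loading-asymmetry ratio only
redistributes double-support load here — asymmetry oracles use the
point-mass model). Joint moments come from bottom-up Newton-Euler inverse
dynamics per limb with that limb's GRF applied at a COP that progresses
heel-to-toe.

For a rigid ankle-foot the UD power and the ankle rotational power are
analytically identical when the stance foot is stationary and massless (a
foot of mass m_f adds a gravity term ω_s·[(**r**_COM,f − **r**_ankle) ×
m_f **g**] that separates the two by ~0.1 J per stride). The rigid-ankle
equivalence oracle therefore sets the foot mass to zero and runs at 1200 Hz
kinematics, where the O(dt²) differencing residual integrates to
~2 × 10⁻⁴ J per stance, inside the 10⁻³ J acceptance bound. The
energy-bookkeeping check (Σ limb external power vs numerical d/dt of COM
mechanical energy) is likewise evaluated at 1200 Hz, where the
central-difference truncation residual is ~2 × 10⁻⁴ W kg⁻¹.

**Socket pistoning.** The interface displacement is compliance × axial load
(rigid socket: compliance 0, the OI case). Hysteresis is imposed by an
asymmetric force path F(u) = (δ(u)/c)(1 + β cos πu) over the stance phase u
— stiffer while loading, softer while unloading — and β is solved (secant
on a piecewise-linear function) so that the dissipated energy of the
discrete loop is *exactly* the configured fraction of the stored energy,
both measured with the same trapezoidal quadrature and difference scheme the
analysis pipeline uses. The ground truth is thus internally consistent with
the emitted channels by construction, and the pipeline's −∫P_socket dt
matches the recorded dissipation to ~10⁻¹² J. The pistoning displacement is
recorded at the interface and not fed back into the linkage kinematics
(amplitudes are ~2 cm; the simplification leaves all whole-body identities
exact).

**Noise.** Measurement noise is additive i.i.d. Gaussian per channel class
(defaults: 2 N on forces, 2 mm on positions with the matched
differentiated-noise s.d. σ·rate/√2 on velocities, 0.5 N·m on moments),
reproducible from a single seed. Generation itself is deterministic.

What the generators do *not* emulate: soft-tissue wobble, true M-shaped
vGRF individuality, 3-D (frontal/transverse) dynamics, foot rocker and COP
lateral excursion, marker soft-tissue artefact structure (noise is white),
or muscle-driven dynamics. Passing tests therefore demonstrate correctness
of the computational pipeline on dynamically consistent data, not validity
of any physiological claim about real gait.

## Statistics

Per-stride work values are averaged within participant and cell (limb or
interface × speed bin); strides outside [0.6, 1.6] m s⁻¹ are excluded. The
2×2 repeated-measures ANOVA is implemented by contrast decomposition: each
effect is the within-participant contrast of the four cell means, tested
with a one-sample t (F = t², df = (1, n−1)); this is exact for the balanced
2×2 design and is cross-checked against statsmodels' AnovaRM in the tests.
A zero-residual contrast is flagged degenerate rather than reported as a
spurious F. Post-hoc paired t-tests are two-tailed with Bonferroni
correction (p_adj = min(1, k·p)). The normality screen computes sample
skewness and both raw and excess kurtosis, applying the configured
convention (default: excess) with limits |skew| < 1.7 and |kurt| < 3.6.
Type-I error of the ANOVA is calibrated on null simulations at the
observation-table level (participant random intercept + stride noise
through the aggregation step): per-effect rejection at α = 0.05 falls in
[0.03, 0.07] over 500 simulated 8-participant studies.

## Problem sizes and numerical tolerances

Default test problems use 3–6 strides per trial at 120 Hz kinematics
(1200 Hz for the two differentiation-sensitive oracles above), 3–8
synthetic participants per study, and 500 replicate null studies for the
calibration check; the full suite runs in well under a minute. Key
tolerances: storage round-trips and resampling of linear channels are exact
to 1e-12; closed-form vs quadrature socket work 1e-9 relative; work
decomposition identity 1e-12; dynamic consistency 1e-6 N kg⁻¹; socket
energy audit 1e-6 J.

## Known limitations

- The planar linkage prescribes kinematics and derives kinetics; it cannot
  represent flight phases, uneven terrain, or stance-knee compliance, and
  its loading asymmetry acts only during double support.
- The UD-vs-ankle equivalence is exact only in the massless-rigid-foot
  limit; with a massive foot the two legitimately differ by the foot
  gravity/inertia terms.
- The ANOVA layer handles balanced complete 2×2 designs only; unbalanced
  or mixed-effects designs are out of scope.
- Real-data ingestion assumes the exporter's axes are declared; no attempt
  is made to auto-detect coordinate conventions.
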