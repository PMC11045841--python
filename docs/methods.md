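# Methods

This note records the models, conventions and numerical choices behind
`rotordyn`, and what the synthetic study conditions do and do not establish
about real trajectory data.

## Coordinates and conventions

All angles are degrees, times fs, lengths Å. Dihedrals use the standard
two-plane atan2 construction with the IUPAC sign convention (positive =
clockwise looking along the central bond); collinear bonded triples raise
rather than returning an arbitrary value. Angle time series are unwrapped
(consecutive differences < 180°) before any differentiation, because the
counterclockwise isomerization runs 0 → −90 → −180 and would otherwise
alias at the ±180 branch cut.

The wag coordinate is defined as δ_op = α − β and the orbital-overlap
dihedral as τ = α − ½ δ_op = (α + β)/2. This choice reproduces the three
calibration points of the twist picture (τ = 0 at the planar cis reactant,
−90 where the p-orbital overlap vanishes, −180 at the trans product) and
makes the velocity decomposition dτ/dt = dα/dt − ½ dδ_op/dt an exact
identity at every frame for any finite-difference scheme, which the
statistics module relies on.

Velocities are forward differences over the actual frame spacing (nominally
1 fs); the last frame's velocity is undefined (NaN). Decay-point velocities
instead use the backward difference into the last S1 frame, so they are
defined before the ground-state force field acts. A hop at frame 0 or 1
leaves the decay velocity undefined; such records are flagged and excluded
from velocity statistics.

## Decay detection and classification

The decay point is the first S1→S0 transition, read from the per-frame
state sequence or, failing that, from the hop sidecar; nothing is inferred
silently. Re-crossings after the first hop are ignored: each trajectory
contributes exactly one decay point.

Reactivity is read from the unwrapped α at the final frame: within ±45°
of −180 (mod 360) → reactive; within ±45° of 0 → unreactive; otherwise
the trajectory is *undecided*, excluded from fraction denominators and
reported separately. The ±45° window separates the three basins
unambiguously; classification is invariant to shifting the whole series by
full turns. Fewer than 5 post-hop frames flags the record as unstable. An
optional hook accepts a second twist series and counts simultaneous
double-bond isomerization as reactive (off by default). Trajectories that
never decay within the horizon are excluded and counted; a switch recounts
undecided/undecayed as unreactive, since it is not documented whether
published tables use the full or the classified population as denominator —
both variants are emitted.

## Ensemble statistics

Φ_iso is the reactive fraction of classified trajectories. The
velocity-phase analysis conditions on the sign of dτ/dt at decay and on the
low-amplitude band (default −0.8 to 0 deg/fs, configurable); an exact tie
dτ/dt = 0 counts as non-negative. All fractions carry 95% Wilson score
intervals (via statsmodels) — the source tables report none, but interval
arithmetic is needed to call differences between ensembles significant.
The law of total probability, Φ = P(R|neg)·P(neg) + P(R|pos)·P(pos), holds
exactly over classified records and is asserted in tests.

Ensemble-average curves are *survivor-only*: at each time bin only
trajectories still on the selected state contribute, so averages track the
undecayed population and bins with no survivors are masked, never
zero-filled. This matches the usual visual convention for such curves but
is a documented choice, not a published formula. Decay-window statistics
are IDT = earliest hop time and DTL = latest − earliest; 5th/95th
percentile variants are reported alongside because extremes of a
200-sample ensemble are noisy.

## Kinetic and oscillation fits

The S1 population (fraction of trajectories on S1 or S2; undecayed
trajectories count as excited throughout) is fitted with

    f(t) = a1·exp(−((t−t1)/t2)²) + y0 + (1 − a1 − y0)·exp(−(t−t1)/t2)

a lag time t1 shared by a Gaussian and an exponential term with a common
decay constant t2. The formula is implemented exactly as printed in its
source even though the sharing of t2 is probably a typo for a second
constant; an optional flag frees a third parameter t3 for the exponential.
For t < t1 the exponential factor is clamped to 1 so the curve cannot grow
before the lag. Fitting is bounded nonlinear least squares with multi-start
(t1 seeded from the onset, t2 from the 1/e crossing, several a1/y0/scale
starts); non-convergence from all starts raises with diagnostics. The
characteristic "fitted lifetime" is reported as t1 + t2 — an interpretive
choice, flagged as such — and the mean hop time is reported independently.

Sinusoid fits (A·sin(2πt/T + φ) + c, A ≥ 0) seed the period from the
dominant discrete-spectrum component and refine by least squares over a
grid of phase/period starts. The average-twist decomposition α = α_I + α_II
first fits a robust Theil–Sen line, then a sinusoid to the residual, then
refines both jointly (the two-stage estimate is biased when the oscillation
does not average out over the window); a residual rms above 5° keeps the
result but flags it poor. Oscillation fits on ensemble averages are
truncated once fewer than 25% of trajectories survive, where the average
becomes dominated by a handful of stragglers.

Spectral wavenumbers convert the strongest magnitude-spectrum peaks of a
mean-removed series via ν̃ = 1/(T·c); up to two peaks are returned and a
peak below 4× the median spectral magnitude is flagged unstable.

## Synthetic study conditions

The generator prescribes per trajectory
α(t) = α₀ + v·t + c_α·osc(t), δ_op(t) = osc(t), β = α − δ_op, where osc is
a fast wag plus an optional slow promoter sinusoid, v is a truncated-normal
drift and c_α = 0.2 places a small share of the oscillation in the twist
itself (the α_II component). The hop is the first grid crossing of α below
the jittered crossing angle (−90° ± 3°); the outcome rule is deterministic
outside the speed threshold θ = 1 deg/fs and Bernoulli(q) inside it,
encoding the observation that low-amplitude crossings randomize. After the
hop, α relaxes exponentially to the labelled basin and the wag is damped on
the same 30–40 fs constant; crossings within 3 relaxation constants of the
horizon are rejected (trajectory left undecayed) so every decayed
trajectory can settle into a basin before classification.

Preset conditions (200 trajectories, 1 fs grid):

* `rh_like` — drift −1.35 ± 0.5 deg/fs (clipped to [−3, −0.45]), wag 29° /
  40 fs with 0.4 rad phase jitter, no slow promoter, horizon 290 fs. Gives
  mean Φ_iso ≈ 0.70, IDT ≈ 25–30 fs, DTL ≈ 150–160 fs, and a coherent
  ≈2.3 deg/fs survivor-averaged wag-velocity amplitude.
* `naip_like` — drift −0.4 ± 0.2 (clipped to [−0.65, −0.2]), weak
  incoherent wag 8° / 45 fs, slow promoter 25° / 250 fs, q = 0.42,
  horizon 720 fs. Gives mean Φ_iso ≈ 0.42, IDT ≳ 100 fs, DTL ≳ 300 fs.
  q sits below ½ because a slow rotor arriving at the crossing with the
  wrong velocity phase re-forms the reactant slightly more often than the
  product; the symmetric rule would center Φ_iso at the top of the
  realistic range.
* `naip_gas_like` — as `naip_like` with a stronger, phase-coherent ring
  promoter (30° / 250 fs, 0.15 rad jitter), emulating the isolated rotor
  whose ring inversion survives.

A ring-inversion-like series proportional to the promoter component is
recorded in the ledger (scale 2 per unit promoter) so promoter-correlation
analyses run on synthetic data; it is not embedded in the 6-atom frames.

The 6-atom embedding (C1, C2, C3, C4, R1, R4; bonds 1.45/1.40/1.45 Å,
1.08 Å to R, 120° angles) carries exactly the two mapped dihedrals and
reads back α and β to ≤ 1e-6°. Bond lengths are rigid, so the BLA channel
of synthetic data is constant — intentional, since BLA dynamics is not part
of the generated kinematics.

What passing on these conditions shows: the pipeline's bookkeeping
(detection, classification, conditioning, fitting) is exact against a
ground-truth ledger, and its statistics behave correctly under realistic
ensemble sizes, phase jitter and timing. What it does not show: anything
about real electronic-structure dynamics — the generator has no forces, no
energy conservation, no S2, no bond-length dynamics, and its outcome rule
is the hypothesis itself, inserted by construction.

## Surface-hopping model

The `fssh_model` module is an independent, physics-based source of
ensembles: two nuclear modes (periodic twist θ, inertia 2.5e5 a.u.;
harmonic wag q, mass 2000 a.u., 40 fs period) and two diabatic states with
cosine torsional potentials and a linear coupling V12 = λq (λ = 0.005).
Choosing the excited-state offset e0 = w0 + w1 puts the diabatic crossing
exactly at θ = ±90°, giving a barrierless upper surface from the −10°
pre-twisted Franck–Condon region to the gap minimum. Initial conditions
are Gaussian thermal samples (300 K harmonic estimates) on the lower
surface, promoted vertically.

Numerics: velocity-Verlet on the current adiabatic surface (default
0.25 fs); electronic amplitudes advance in 20 substeps per nuclear step
using the exact 2×2 unitary propagator with linearly interpolated adiabatic
energies, so the norm is machine-precision conserved before decoherence;
the coupling term is the finite-difference rate of the diabatic→adiabatic
mixing angle (the two-state equivalent of an overlap scheme). Hops follow
the fewest-switches probability; accepted hops rescale the velocity along
the analytic coupling vector ∇χ, frustrated hops reverse the component
along it (one of the standard conventions). Decoherence is the energy-based
damping of the inactive amplitude with lifetime (1/|ΔE|)(1 + C/E_kin),
C = 0.1 hartree by default. Total energy is monitored between hops
(tolerance 1e-4 hartree) and raises on drift.

On a 1-D linear crossing the engine reproduces the closed-form
Landau–Zener switching probability within Monte-Carlo error in the
high-velocity/weak-coupling regime; at low velocity frustrated hops make
the simulated fraction undershoot the formula, which is expected behavior
of the algorithm, not a defect. Exported trajectories map θ → α and
q → δ_op (60°/bohr) through the same 6-atom embedding, decimated to a 1 fs
grid, so the entire analysis pipeline consumes them unchanged.

## Problem sizes

Default test and reproduction runs use 200-trajectory ensembles on 1 fs
grids (290–720 fs horizons), 10–12 seeds for windowed statistics, and 200
single-passage trajectories for the Landau–Zener comparison; these sizes
keep every statistic well inside its sampling tolerance while the full
suite runs in minutes on one core.

## Known limitations

* The reader handles the two XYZ dialects described above; adapters for
  other deposited layouts are meant to be added as thin plug-ins after
  inspecting the archive, not guessed in advance.
* BLA analysis requires a bond partition in the dihedral map; no chemistry
  is hard-coded.
* The surface-hopping model is two-state/two-mode by design: no S2, no
  solvent, no ab initio surfaces.
* Undecided trajectories near the classification window boundary are
  excluded rather than resolved by energy- or charge-based criteria.
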