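# Methods

`photospawn` studies the first photoinduced electron-transfer (ET) step in a
light-sensing cryptochrome at desk scale: photoexcitation of the flavin
(FAD) chromophore, ultrafast S2→S1 nonradiative decay through the
locally-excited/charge-transfer (LE/CT) crossing seam, stabilization of the
radical-pair CT state, and the slower adiabatic ET route over the S1
barrier.  The electronic structure of the real pigment–protein complex is
replaced by a calibrated analytic diabatic model; every dynamical and
analytical method in the package (multiple spawning, Born–Oppenheimer
dynamics, spectra, landscape optimization) operates on that model exactly
as the corresponding production methods operate on on-the-fly quantum
chemistry.

## The diabatic model

Three diabatic states — ground `G`, locally-excited `LE` (bright, low
dipole), charge-transfer `CT` (dark, large dipole, donor charge +1) — are
defined over two abstract mass-weighted reaction coordinates and an
eight-mode harmonic bath:

* `q1`, the flavin ring-distortion surrogate (inertia 40 in internal mass
  units, so the slide from the Franck–Condon region to the crossing seam
  takes the few femtoseconds that set the S2 lifetime);
* `q2`, the donor–acceptor/solvation surrogate (inertia 1);
* bath modes `x_j`, bilinearly coupled to `q1` or `q2`.

Functional forms (energies in eV):

    V_G  = kg1/2 q1² + kg2/2 q2² + V_bath
    V_LE = f(q1) + k2ᴸᴱ/2 q2² + V_bath             f = quartic double well
    V_CT = e0 + ε_env[protein] + k1/2 (q1−w1)²
           + k2ᶜᵀ/2 (q2−w2)² + w4·max(q2−w2,0)⁴ + V_bathᶜᵀ

`f(q1)` carries the two LE minima: `LE_high` near the Franck–Condon (FC)
point and the lower `LE_low` displaced along `q1`; the barrier between them
is calibrated to 6 kcal/mol from `LE_low`.  The CT profile along `q2` is a
Marcus-like parabola toward the FC side with a one-sided quartic wall
beyond its minimum; the wall bounds thermal excursions on the side where
the ground surface outruns the CT surface and so protects the ≥ 0.6 eV
S0–S1 gap floor at the charge-separated minimum.  Three gap-erosion
channels had to be closed during calibration, and each fixes a parameter
range: the CT-side `q2` excursions (the wall), the LE-state `q2` softness
(`k2ᴸᴱ` must stay within a factor of ~6 of the ground-state curvature or
hot LE packets see the gap collapse at large `q2`), and the CT-displaced
bath modes (their reorganization energy is capped at 0.015 eV because the
gap erosion of a hot bath scales as 2·sqrt(λ_b·E_bath)).  The same
LE-state `q2` curvature is, within its allowed range, the main control of
the thermal LE→CT attempt rate.

Only LE and CT are electronically coupled, with a constant (Condon)
coupling λ; G is uncoupled from both, so the model has no S1→S0
nonradiative channel by construction.  Adiabatic energies, analytic
gradients, nonadiabatic coupling vectors and adiabatic Hessians follow from
the closed-form two-level diagonalization of the LE/CT block; using the
closed form keeps the mixing angle globally smooth so the coupling-vector
sign is continuous along trajectories.  State dipoles and the donor charge
are diabatic-weight-weighted expectations (μ_LE = 8 D, μ_CT = 31 D,
μ_G = 5 D); the only nonzero transition dipole is G→LE (1.6 a.u.), so
oscillator strengths are f = (2/3)·ΔE·w(LE)·|μ_trans|² in atomic units.

The bath has two roles.  All modes enter every diabat identically
(bilinear, equilibrium shifted with `q1`/`q2`), providing vibrational
energy exchange without touching any electronic observable; because the
shifted-oscillator form integrates out of the thermal marginals exactly,
the FC statistics of `(q1,q2)` are those of the bare two-dimensional model.
In addition, the four solvation modes are displaced for the CT diabat
(Marcus polarization shifts, reorganization energy 0.015 eV), which
broadens the LE/CT gap and dephases electronic coherence during the
nonadiabatic dynamics — without it, parent and spawned basis functions
exchange population coherently for tens of femtoseconds and the S2 decay
stalls.

The `protein` environment mode destabilizes the CT diabat by
ε_env = 1.0 eV; `vacuum` removes that term and nothing else.  The value is
chosen so that (i) single-point re-evaluation of protein-optimized LE
geometries in vacuum flips their S1 character to CT, and (ii) no LE basin
survives anywhere on the vacuum S1 surface, so free vacuum optimization
reaches only CT minima.

### Calibration

The shipped parameter file `data/fwd_mimic.toml` is a frozen calibration
artifact.  Static targets (LE_low emission gap 2.65 eV, CT-minimum gap
1.0 eV, NEB barriers 6.0 and 0.6 kcal/mol, backward CT barrier > 5
kcal/mol) were met by a damped fixed-point loop over the quartic
coefficients, the CT baseline and the LE q2-curvature, with the quartic
rebuilt in closed form each iteration.  Ensemble targets (bright-S2
fraction 35 % of a 300-member 300 K ensemble; absorption maximum 3.25 eV)
were met by shifting the LE vertical offset and the CT reorganization
term against a fixed sampled ensemble.  Dynamical targets (S2 lifetime,
decay completion, ET quantum yield, adiabatic transition fraction) were
tuned through the LE–CT coupling λ = 0.013 eV, the `q1` inertia, the bath
coupling strengths, and the initial-condition selection window; these are
part of the study conditions and are fixed in the packaged defaults.  The
coupled CT parameters (curvature, displacement, baseline) are solved in
closed form from the gap/barrier/vertical-energy targets so that static
calibration is exact by construction and only the sampled ensemble
quantile is iterated.
`calibrate_model` re-runs the generic derivative-free stage against any
constraint list and verifies the result by direct re-evaluation.

## Multiple spawning with stochastic selection

The nuclear wavefunction is expanded in frozen Gaussians (TBFs) whose
centroids follow classical trajectories (velocity Verlet, nuclear step
0.25 fs) on the occupied adiabatic surface; the semiclassical phase
accumulates the classical Lagrangian.  Complex amplitudes obey the
time-dependent Schrödinger equation in the moving nonorthogonal basis,
integrated with ten Runge–Kutta sub-steps per nuclear step and linear
interpolation of the overlap, time-derivative and Hamiltonian matrices
between nuclear steps.  Potential matrix elements use the
bra-ket-averaged second-order saddle-point expansion about the two
centroids (exact for the polynomial test surfaces); interstate elements
contract the coupling vector at the centroid midpoint with the momentum
operator.  The nuclear step is refined threefold whenever a TBF's pair gap
is below 0.12 eV, because at small λ the coupling spike of a fast seam
passage lasts a fraction of a femtosecond.

Spawning follows the classic prescription: when a TBF's effective coupling
|d·v| passes a local maximum above threshold, a child is placed at the
maximum on the partner surface with an energy-conserving momentum
adjustment along the coupling vector (upward spawns without sufficient
kinetic energy along d are rejected), and the bundle is rewound to the
moment the coupling region was entered so parent and child traverse the
region together.  A TBF that lingers in the coupling region keeps feeding
children at a 2 fs cooldown (downward only); near-duplicate children are
suppressed by an overlap check.

TBF widths are a method parameter: the default is 5.5× the ground-state
width of each mode.  Benchmarks against exact split-operator grid
propagation on one-dimensional crossing models showed that the base
(ground-state) widths are far wider than the coupling zones of this model
and systematically under-transfer on slide-through passages; the scaled
widths reproduce the exact final populations to a few percent in both the
fast-crossing and the slide-from-rest regimes.

Stochastic selection is overlap-based: live TBFs are grouped by
|S| > 10⁻³ (same state) or interstate |H| > 10⁻⁵ eV; when several
decoupled groups exist, one is drawn with probability equal to its
Mulliken population and renormalized.  Housekeeping keeps the basis
compact and the surviving-TBF count meaningful as a branch count:
persistently negligible TBFs (< 5 % population for 30 fs) are pruned, and
after the nonadiabatic window (50 fs) nearly parallel same-state TBFs
(|S| > 0.6) are coalesced by projecting the weaker member onto the
stronger.  Ill-conditioned overlap matrices are Tikhonov-regularized and
logged.

Initial conditions for the campaign are the bright-S2 members of the
thermal FC ensemble (LE-dominant S2 with larger oscillator strength than
S1) closest to an ordering gap of ΔE ≈ −0.6 eV: geometries photoexcited a
few tenths of an eV above the crossing seam, so the packet slides into the
seam over ~2–3 fs and crosses at speed.  Each of the 15 ICs is promoted
vertically to S2 as a single unit-amplitude TBF and propagated for 500 fs
with five independent selection seeds.

### What the campaign does and does not reproduce

The packaged campaign reproduces the headline statistics — sub-10-fs
completion of the S2→S1 decay, a fitted S2 lifetime of ~3 fs, a final CT
fraction of the surviving S1 TBFs near 28 %, retention of both characters
in stable S1 minima — but the *route* to the CT population differs in
emphasis from the high-dimensional original: here a larger share of the
final CT weight is acquired during the first ~100 fs by hot S1 packets
crossing the low LE_high→CT saddle before the bath cools them into the
protected basins, rather than exclusively during the first 10 fs of
nonadiabatic decay.  With only two reaction coordinates there is no
entropic bottleneck at the saddle, so kinetic character stability is
provided by vibrational cooling; the bath couplings are chosen to freeze
the LE/CT branching within ~100 fs.

## Born–Oppenheimer dynamics and analytics

NVE continuations restart from surviving S1 TBF centroids (velocity
Verlet); NVT stability runs use a BAOAB Langevin integrator (friction
1 ps⁻¹) with Maxwell–Boltzmann initial velocities.  Character transitions
are counted with a hysteresis detector: LE below 20 D, CT above 25 D, the
band in between ambiguous, and a new character must persist for 10 fs
(dwell) to register — without the dwell rule, boundary chatter
double-counts events.  A TBF's final label is its last unambiguous frame.
The dipole-time maps convolve each TBF's dipole trace with 2-D Gaussians
(1.91 D × 0.75 fs) weighted by its time-dependent Mulliken population.
Lifetimes are least-squares fits of P(t) = exp(−t/τ) from t = 0 to the
first crossing of 0.01 (or the horizon), with uncertainties from bootstrap
replicate curves; decay-completion times interpolate the first crossing of
the 0.10 level of the bootstrap-mean curve (1000 resamples over initial
conditions, not over selection seeds).

## Landscape methods

Minima are found by L-BFGS-B with analytic gradients after a short capped
steepest-descent pre-phase, optionally inside a trust box — sub-kcal/mol
barriers separate the S1 basins and an unconstrained quasi-Newton first
step can hop them.  Frozen coordinates are held exactly (no restraint
springs).  MEPs use improved-tangent NEB (20 images, climbing image,
per-image QuickMin relaxation with step caps); the spring constant is
auto-scaled to the path's energy span.  The minimal-energy crossing point
of the S1/S2 pair minimizes the mean pair energy under a quadratic penalty
on the squared gap in excess of the model's minimal attainable splitting —
2λ for the Condon-coupled pair, zero for uncoupled test surfaces — with
geometric penalty growth until the residual is below 10⁻³ eV.  Because the
coupling is constant, the model has no true conical intersection; the
"MECI" is a point of minimal splitting on the seam, and its energy is
reported relative to the vertical S2 energy of thermal FC points.  The
search is local (trust box of 1.5 coordinate units), as practical
crossing-point optimizers are: from an FC starting point it converges to
the funnel adjacent to the FC region rather than sliding along the
connected seam to its global bottom (which, in a two-coordinate model, is
the same seam that carries the low S1 LE/CT saddle).  The
environment comparison constrained-optimizes snapshots on S1 in protein
mode with the bath frozen (the surrogate of a frozen QM/MM boundary),
re-evaluates the identical geometry in vacuum, and additionally optimizes
freely in vacuum.

## Numerical choices and conventions

* ħ = 0.6582119 eV fs, k_B = 8.617333 × 10⁻⁵ eV/K,
  1 eV = 23.0605 kcal/mol, Hartree = 27.2114 eV.
* FC sampling: BAOAB Langevin on S0 at 300 K (dt 0.25 fs, friction
  0.05 fs⁻¹), a bank of up to 400 walkers with 1.5 ps burn-in and 150 fs
  stride; bit-reproducible per seed.  Zero-point motion is excluded by
  default; a Wigner-distribution option exists but is off.
* Coupling-vector magnitudes at exact uncoupled degeneracies are capped at
  10³ per unit coordinate and flagged.
* The barrier saddle between `LE_high` and the CT basin is additionally
  refined by a Newton search on the analytic Hessian when the climbing
  image cannot track the sharp avoided-crossing ridge.
* Character dominance = larger diabatic weight, ties toward CT; with a
  two-level excited block exactly one adiabat is LE-dominant and one
  CT-dominant, so the CT−LE ordering gap ΔE is always defined.  Because
  the adiabatic splitting is bounded below by 2λ, the ΔE distribution has
  an empty band of width 2λ ≈ 0.026 eV around zero — an artifact of the
  Condon coupling; "near-zero" mass in the ensemble tests means
  |ΔE| < 0.25 eV.
* Stage seeds derive from the global seed as SHA-256("seed:stage") mod
  2³¹−1; the SSAIMS run seed combines the campaign seed with the IC and
  repetition indices.

## Problem sizes

The packaged campaigns use the study's stated sizes: 300 FC samples, 15
ICs × 5 selection seeds × 500 fs spawning runs, 75 NVE continuations of
1 ps, 15 NVT runs of 0.9 ps, 50 FC-launched S1 trajectories of 1 ps, five
seeded FC anchors for the seam search.  The synthetic-data generator's
defaults are these conditions; tests that exercise machinery rather than
campaign statistics run on smaller bundles and shorter horizons.

## Known limitations

* Two reaction coordinates cannot reproduce Cartesian observables (no
  RMSD-type quantities) and provide no entropic barriers; character
  stability is cooling-limited rather than dimensionality-limited (see
  above).  One measurable consequence the calibration could not remove:
  thermal bright-S1 trajectories cross the ~0.6 kcal/mol LE_high→CT saddle
  more often than in the high-dimensional original (≈15–20 % per ps
  instead of ≈8 %); the saddle height is pinned by its own barrier target
  and the LE q2-curvature is pinned from below by the gap floor, leaving
  no honest parameter to suppress the rate further.
* The Condon coupling leaves a 2λ splitting floor: no true conical
  intersection, and an empty band in the ΔE distribution.
* The frozen-Gaussian propagator is validated against exact grid dynamics
  on one-dimensional crossings; in the full model its branching ratios are
  method-converged choices (width scale, spawn thresholds) rather than
  exact quantum results.
* Vacuum-mode energetics are only constrained qualitatively (majority
  characters); vacuum gaps and the constrained-vacuum optimization split
  between characters are not calibrated.
* Absorption spectra include only S0→S1 and S0→S2 of the three-state
  model; a third excited state is outside the model's scope.
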