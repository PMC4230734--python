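# Methods

## Model

The cortical module consists of an excitatory (pyramidal) and an inhibitory
population, all-to-all coupled, each receiving unspecific excitatory
background input (Fig.-1-style wiring: four intracortical pathways e→e,
e→i, i→e, i→i plus the two background pathways).  The state vector has 11
components: two membrane voltages, four second-order synaptic pairs
(activation and derivative), and the excitatory intracellular sodium
concentration.  All internal computation uses mV, ms, ms⁻¹ and mM; API
surfaces accept rates in s⁻¹.

Population rate: logistic sigmoid `Q(V) = Qmax/(1+exp(-C(V-θ)/σ))` with
`C = π/√3`, which makes the inverse gain σ exactly the standard deviation of
the logistic distribution underlying the rate curve — the gain is tied
directly to the spread of the population's firing response.

Synapses: alpha-function kinetics, `s̈ = γ²(u - s) - 2γṡ`, driven by the
summed presynaptic rate `u = N·Q_pre (+ background)`.  AMPA (γ = 70 s⁻¹,
E = 0 mV) carries excitation, a generic GABA type (γ = 58.6 s⁻¹,
E = −70 mV) inhibition.

Membranes: conductance-based with a leak and the two synaptic currents,
time constant 30 ms for both populations (leak conductance normalized to 1
mS/cm²); leak reversals −66 mV (e) and −64 mV (i).

Adaptation: `I_KNa = g_KNa·w(Na)·(V_e - E_K)` with the saturating gating
`w(Na) = 0.37/(1+(38.7/Na)^3.5)`, coupled through C_m = 1 µF/cm² (the
dimensionally consistent reading of the printed unit), on the excitatory
population only — adaptation currents concentrate in pyramidal cells.
Sodium obeys `Ṅa = (α_Na Q_e − R_pump·(P(Na) − P(Na_eq)))/τ_Na` with
`P(c) = c³/(c³+15³)`: influx is linear in the firing rate (α_Na = 2 mM·ms
per unit rate), extrusion is an active cubic pump with equilibrium
Na_eq = 9.5 mM.  With firing silenced the pump drives Na monotonically back
to Na_eq, making the adaptation a pure activity-dependent negative feedback
with an effective relaxation time of a few hundred milliseconds — the slow
variable of the slow–fast structure.

### Parameter provenance

The regime-defining values are σ_e = 4.6 mV, g_KNa = 1.33 mS/cm² (N2) and
σ_e = 6.7 mV, g_KNa = 2 mS/cm² (N3).  All remaining constants follow the
established sodium-adaptation cortical lineage (Compte-type models and the
neural mass variant built on them); each value is listed with a comment in
`src/sleepcortex/presets/*.cfg`.  Four quantities are this package's own
calibration, fixed once against the qualitative anchors of the modeled
phenomena and not revisited:

* `τ_Na = 1.5 ms` (sodium-balance scale): places the Hopf curve so that N2
  and N3 are both stable foci *close to* their oscillatory borders — N2
  0.21 mS/cm² below the Hopf of its gain slice, N3 0.02 below — which is
  the configuration that yields isolated noise-triggered K-complexes at N2
  and continuous ~0.8 Hz slow oscillations at N3.
* `N_bg = 30` (background-pathway connection count, both populations):
  scales per-synapse background rates into pathway drive; chosen so that
  the 5–100 s⁻¹, 50 ms stimulus protocol straddles the N2 canard threshold.
* `φ_sd = 400 s⁻¹·√ms` (pathway white-noise intensity; mean φ = 0): the
  level at which wake stays quiet (sub-mV fluctuations), N2 produces on the
  order of one to three K-complexes per 30 s, and N3 is driven into
  sustained large-amplitude slow oscillations.
* Wake (4.0, 0.5) and N1 (4.3, 1.0) preset coordinates: not tabulated
  anywhere; placed on the wake→N3 route and validated by classification
  (region I; wake's least-damped complex pair at Re ≈ −0.05 ms⁻¹, far from
  the imaginary axis — the passive-response regime).

## Integration

The stochastic scheme is a 4th-order Runge–Kutta for additive noise: per
step the Wiener increment ΔW is drawn once per noise stream and the
effective drive `φ_sd·ΔW/dt` is held constant through the four classical
stages.  Consequences: (i) with φ_sd = 0 the scheme *is* classical RK4
(verified: equilibrium preserved to ≤10⁻⁸ mV over 30 s; endpoint error
falls ~16× per dt halving); (ii) on the linear Ornstein–Uhlenbeck test
problem the stationary variance matches σ²τ/2 up to O(dt/τ) corrections
(verified within Monte-Carlo error).  Noise streams are generated per
integration step from a seeded generator, so the recording stride can never
change a trajectory; both populations get independent streams (their
correlation is unspecified in the underlying biology; independence is the
assumption).  Negative instantaneous drive values are passed through
unclipped — clipping would bias the mean of a zero-mean background.

Defaults: dt = 0.1 ms, 30 s duration, 5 s onset discarded from analysis,
output decimated to 1 kHz.  A 200 mV guard aborts diverging runs naming the
first bad step.  Stimuli are rectangular per-synapse rate offsets resolved
to step boundaries; disjoint protocols compose additively in the drive.

## Bifurcation analysis

Equilibria: at a fixed point every synaptic variable equals its input, Na
inverts the cubic pump analytically, and V_i solves its own scalar balance,
leaving one scalar equation F(V_e) = 0.  Scanning F over −90…−20 mV
(701-point grid, bisection + Brent refinement) enumerates *all* equilibria,
including disconnected branches — the reason this design was preferred over
pseudo-arclength stepping, which must be seeded per branch.  Every root is
re-verified against the full 11-dimensional vector field (residual < 10⁻⁹).
Jacobians use central differences with per-variable scaled step 10⁻⁶;
eigenvalues classify stability (node/focus/saddle).

Folds are bisected on equilibrium-count transitions; Hopf points are
bisected on the sign of the leading eigenvalue's real part along the top or
bottom branch, accepting only complex crossings (|Re| < 10⁻⁶ ms⁻¹ at the
refined point).  Each Hopf can be probed by a deterministic simulation just
past the crossing and flagged *cycle-bearing* if an attracting cycle
(peak-to-peak ≥ 0.5 mV after transient discard) exists there.  The
distinction matters: inside the fold wedge the upper branch also loses
stability through a complex pair, but subcritically — no attracting cycle
emerges and the trajectory falls to the silent state.  That crossing is the
bistable→excitable (V→VI) boundary, not an oscillatory onset, and the
one-dimensional diagrams of the steep-gain slice accordingly show folds
only.  The cusp is bisected on fold existence across gain slices; the
fold–Hopf intersection is read off the assembled curves.

Regions I–VI are assigned by a decision tree: attracting cycle found →
II or III (split by fold existence on that gain slice); three equilibria →
V (two stable) or VI (only the hyperpolarized one stable); one stable
equilibrium → I (depolarized) or IV (hyperpolarized), with −65 mV as the
fixed depolarized/hyperpolarized convention.  Ambiguous probes are flagged
rather than silently resolved.

Limit cycles are characterized by direct simulation with branch following
(each grid point starts from the previous final state), 40 s per point with
15 s discarded; amplitude is peak-to-peak V_e and the period comes from
peak detection at 30% prominence.  Two diagnostics are defined
operationally, since "exponentially small" is not measurable on a grid:
the *canard interval* is the smallest parameter interval (≤ 0.025 mS/cm²)
over which the amplitude grows ≥5×; the *homoclinic signature* is monotone
period growth over the trailing half of the branch with the final period
exceeding 3× the onset period.  Measured at the N2 gain slice: amplitude
grows 7× between g_KNa 1.560 and 1.568, and the period stretches from
0.62 s at onset to 3.7 s before the branch dies at the left fold (ratio 6).

## Evoked responses and event analysis

Stimulus families start exactly at the deterministic equilibrium (enforced;
a non-equilibrium start would contaminate latencies), apply one 50 ms burst
to both populations, and measure peak-to-peak V_e in a 2 s post-onset
window.  Morphology extraction finds local extrema with a 10 ms refractory
margin on the unfiltered deterministic trace; a response is KC-like when a
dominant trough ≥10 mV below baseline is followed by a positive rebound,
with dominance requiring the main trough to be at least twice as deep as
any other — which rules out periodic waveforms.  The P200/N550/P900
comparison is qualitative ordering (the strong N2 response measures
53/539/1367 ms).

The K-complex detector works on z-scored traces (stages z-scored
independently): a trough ≤ −3 z inside a ≥0.25 s excursion below −1 z,
followed within 1 s by a rebound ≥ +1 z, after 50 ms moving-average
smoothing; events merge within a 1 s refractory window.  The dwell
requirement encodes the physiology — a KC down state (0.3–1 s) outlasts any
half-cycle of the 1.5–2 Hz background rhythm — and the depth threshold is
set where false positives vanish on wake-regime traces (0 events in 200
seeds) while N2 retains a median of 2 events per 30 s.  Pure white noise
can never fire the detector (the dwell would require hundreds of
consecutive sub-threshold samples).  All thresholds are keyword arguments.

Spectra are Welch averages with 10 s windows and 50% overlap (sub-Hz
resolution on 25 s of usable data); the spectral peak is the band-limited
argmax, scale- and offset-invariant.  Up/down fractions threshold raw V_e
at the −65 mV convention.

## What the tests show — and what they do not

All verification runs on the model's own synthetic output; no human EEG is
bundled or fitted.  Passing tests therefore demonstrate the *mechanistic*
claims — the bifurcation skeleton, the canard-mediated KC, the
near-threshold origin of the 0.8 Hz slow oscillation, burst suppression in
the excitable regime — under the model's idealizations: two point
populations (no spatial propagation or traveling waves), white background
noise, a single additive adaptation current (no synaptic depression,
calcium-dependent currents or multiplicative gain modulation), and a linear
V_e→EEG map.  Quantitative agreement with recorded sleep EEG beyond these
qualitative signatures is outside what this package can or does claim.

Problem sizes used throughout (10 seeds × 30 s for spectral statistics,
61-point continuation grids, 16-point cycle branches) are the package's
standard working resolution; every quantity is recomputed from scratch by
`scripts/acceptance.py`.

## Known limitations

* Limit-cycle characterization is simulation-based; unstable cycles are
  invisible, so Hopf criticality is inferred from the attractor probe
  rather than normal-form coefficients (no Lyapunov coefficient
  computation, no two-parameter homoclinic continuation).
* Near-degenerate slices (within ~10⁻³ of the cusp) can defeat the
  fold-count bisection's grid bracketing; the atlas warns rather than
  guesses.
* The homoclinic orbit itself is not continued; only its period-blow-up
  approach signature is measured.
* EDF file export is not provided; `Trajectory.to_mne_raw()` hands the
  z-scored output channel to MNE for EEG-viewer workflows, and CSV/NPZ
  writers cover plain interchange.
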