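# sleepcortex

A neural mass model of the sleeping cortex, built to explain the two
hallmarks of NREM sleep EEG — the K-complex (KC) of stage N2 and the
0.5–2 Hz slow oscillation (SO) of stage N3 — as two faces of one
bifurcation structure, together with the numerical toolkit needed to
demonstrate it: a stochastic integrator, a bifurcation/continuation engine,
evoked-response experiments and EEG-style analysis.  It is aimed at
computational neuroscientists and sleep researchers who want a compact,
fully reproducible population-level model of slow-wave activity.

## The model

Two all-to-all coupled populations — excitatory pyramidal cells (e) and
inhibitory interneurons (i) — are described by their mean membrane voltages
V_k.  Voltage maps to population firing rate through a logistic sigmoid

    Q_k(V_k) = Q_max / (1 + exp(-C (V_k - θ) / σ_k)),   C = π/√3,

where σ_k is the inverse gain (the scale constant C makes σ the standard
deviation of the underlying firing-rate distribution).  Incoming spikes open
synaptic channels with alpha-function kinetics, giving one second-order
filter per pathway,

    s̈ = γ² (N·Q_pre + φ - s) - 2γ ṡ,

where N is the mean connection count and φ the unspecific background drive
(zero-mean Gaussian white noise, plus a rectangular rate offset during
stimulation).  The membrane equations are conductance-based,

    τ_e V̇_e = -(V_e - E_L) - g_AMPA s_ee (V_e - E_AMPA)
              - g_GABA s_ie (V_e - E_GABA) - (τ_e/C_m)·I_KNa,

and the sleep-specific ingredient is the sodium-activated potassium current
on the excitatory population,

    I_KNa = g_KNa · w(Na) · (V_e - E_K),   w(Na) = 0.37 / (1 + (38.7/Na)^3.5),
    Ṅa ∝ α_Na Q_e - pump(Na),

a slow, additive, activity-dependent negative feedback: firing accumulates
sodium, sodium activates a hyperpolarizing current, an active pump restores
rest.  The two bifurcation parameters are the excitatory inverse gain σ_e
and the adaptation strength g_KNa; both track the neuromodulatory changes of
the sleep–wake cycle.

In the (σ_e, g_KNa) plane the model carries a fold wedge (two saddle-node
curves meeting in a cusp) and a Hopf curve.  The shipped presets walk the
wake→N3 route: `wake` (4.0 mV, 0.5 mS/cm²) deep in the monostable active
regime, `n1` (4.3, 1.0), `n2` (4.6, 1.33) just below the Hopf bordering the
relaxation-cycle regime, `n3` (6.7, 2.0) beyond the cusp near the pure
limit-cycle regime.  A KC is a single noise- or stimulus-triggered excursion
along the homoclinic relaxation orbit (reachable from N2 through a canard
explosion); SOs are noise-driven oscillations around the weakly damped N3
focus.  The model's output variable is V_e; the EEG is a linear scaling of
it, so traces are compared z-scored.

## Worked example

`python examples/simulate_sleep_stages.py` — 30 s noisy runs per preset,
5 s onset discarded:

    wake: V_e sd  0.27 mV | spectral peak 2.00 Hz | 0 KC events | up fraction 1.00
      n2: V_e sd  3.40 mV | spectral peak 0.40 Hz | 1 KC events | up fraction 0.97
      n3: V_e sd  5.54 mV | spectral peak 1.10 Hz | 3 KC events | up fraction 0.90

Wake fluctuates by a fraction of a millivolt and never produces an event;
N2 is up-state dominated with rare, isolated K-complexes over a quiet
background; N3 oscillates continuously at high amplitude in the slow band
(median spectral peak over ten seeds: 0.9 Hz).

`python examples/bifurcation_structure.py` — the organizing skeleton:

    sigma_e = 3.5 mV:
       fold  at g_KNa = 0.655 mS/cm^2
       hopf  at g_KNa = 1.406 mS/cm^2, 1.65 Hz, no attracting cycle
       fold  at g_KNa = 3.230 mS/cm^2
    sigma_e = 4.6 mV:
       hopf  at g_KNa = 1.544 mS/cm^2, 1.65 Hz, with attracting cycle
       fold  at g_KNa = 2.130 mS/cm^2
       fold  at g_KNa = 3.539 mS/cm^2
    sigma_e = 6.7 mV:
       hopf  at g_KNa = 2.022 mS/cm^2, 1.66 Hz, with attracting cycle
    cusp: the folds coalesce at sigma_e = 6.38 mV (g_KNa = 4.44 mS/cm^2)

At steep gain only the bistable/excitable fold wedge exists (the upper
branch destabilizes without shedding a stable cycle); at the N2 gain a
cycle-bearing Hopf appears below the folds; beyond the cusp (N3 gain) the
folds are gone and the Hopf alone remains.  All three presets classify as
region I (single stable depolarized state) — sleep lives *close to* the
oscillatory border, not inside it.

`python examples/evoked_kcomplex.py` — 50 ms bursts, 5–100 s⁻¹, noise-free:

    n2:  1.3  2.4 ... 10.3  32.0  33.1 ... 34.4   (span 26.7x, sharpest step 3.11x)
    n3:  2.3  4.6   8.1  24.4  26.9 ... 33.3      (span 14.6x, sharpest step 3.03x)
    strong-stimulus N2 morphology: bump 53 ms, trough 539 ms (23.2 mV deep),
    overshoot 1367 ms -> KC-like: True

The N2 family explodes from damped ringing to a full K-complex within one
rate step (the canard), and the strong response reproduces the classic
P200/N550/P900 ordering of the evoked KC; the N3 family fills the amplitude
range more gradually.  `examples/burst_suppression.py` shows the
excitable-regime burst-suppression pattern (quiescent baseline, rare large
excursions, none without noise).

A thin CLI wraps the same library calls and writes a re-run manifest next to
every output: `sleepcortex simulate --preset n2 --seed 17 --duration 30
--out run.csv`, plus `evoked`, `bifurcate`, `atlas` and `analyze`
subcommands (`sleepcortex --help`).

## Layout

    src/sleepcortex/
      params.py       parameter containers, presets (wake/n1/n2/n3), config I/O
      model.py        sigmoid rate, I_KNa, sodium pump, full vector field
      integrate.py    SRK4 integrator, stimulus protocols, trajectories
      bifurcation.py  equilibria, folds/Hopf/cusp, regions I-VI, cycle branches
      evoked.py       stimulus families, KC morphology, burst suppression
      eeg.py          z-score, Welch spectra, KC detector, up/down fractions
      cli.py          command-line interface and run manifests
    examples/         narrative scripts, one per capability
    docs/methods.md   modeling and numerical methods note
    tests/            pytest suite (unit, property and end-to-end)
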