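"""Simulate the wake, N2 and N3 regimes and summarize their EEG-like output.

Runs the stochastic model for 30 s per preset (5 s onset discarded), then
prints the fluctuation size of the excitatory voltage, the spectral peak in
the slow band, the number of detected K-complex events, and the fraction of
time spent in the depolarized up state.  Expected picture: wake is quiet and
event-free, N2 shows a quiet background with a few isolated K-complexes, and
N3 shows continuous high-amplitude slow oscillations near 0.8 Hz.
"""

import sleepcortex as sc

for name in ("wake", "n2", "n3"):
    p = sc.resolve_preset(name)
    cfg = sc.SimulationConfig(duration=30.0, onset=5.0, seed=1)
    tr = sc.integrate(p, cfg).post_onset()
    peak = sc.spectral_peak(tr.V_e, tr.fs, band=(0.1, 5.0))
    events = sc.detect_kc(sc.zscore(tr.V_e), tr.fs)
    up, down = sc.state_fractions(tr.V_e)
    print(f"{name:>4}: V_e sd {tr.V_e.std():5.2f} mV | spectral peak "
          f"{peak:.2f} Hz | {len(events)} KC events | up fraction {up:.2f}")
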