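"""Evoked K-complexes: the canard explosion versus a graded response.

Applies 50 ms excitatory bursts of increasing spike rate to the noise-free
model at rest, at the N2 and the N3 operating points, and prints the
response amplitude of each.  Expected picture: at N2 the amplitudes jump
nearly discontinuously from a few mV (damped ringing) to >30 mV (a full
K-complex excursion) within one 5 s^-1 step — the canard explosion; at N3
the same protocol yields a graded increase.  The strong-stimulus N2
response carries the classic evoked K-complex morphology: a small positive
bump, a deep trough near 550 ms, and a positive overshoot.
"""

import numpy as np

import sleepcortex as sc

rates = np.linspace(5.0, 100.0, 20)
for name in ("n2", "n3"):
    p = sc.resolve_preset(name)
    fam = sc.stimulus_family(p, rates)
    ratio, at = fam.max_adjacent_ratio()
    print(f"{name}: amplitudes (mV) vs rate (s^-1)")
    print("   " + " ".join(f"{a:5.1f}" for a in fam.amplitudes))
    print(f"   span {fam.amplitude_ratio():.1f}x; sharpest adjacent step "
          f"{ratio:.2f}x at {at:.0f} s^-1")

m = sc.stimulus_family(sc.resolve_preset("n2"), [100.0]).responses[0].morphology
print("strong-stimulus N2 morphology:",
      f"bump {m['positive_bump_latency_ms']:.0f} ms,",
      f"trough {m['trough_latency_ms']:.0f} ms ({m['trough_depth_mv']:.1f} mV deep),",
      f"overshoot {m['rebound_latency_ms']:.0f} ms -> KC-like: {m['kc_like']}")
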