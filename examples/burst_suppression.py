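"""Burst suppression in the excitable regime (region VI).

Locates an excitable operating point from the slice structure itself (between
the upper-branch destabilization and the upper fold at steep gain), then runs
the noisy model from the stable silent state.  Expected picture: a quiescent
hyperpolarized baseline interrupted by a handful of large excursions around
the unstable active state — and no excursions at all without noise.
"""

import sleepcortex as sc

p = sc.ModelParameters()
q = p.with_overrides(sigma_e=4.0)
_, pts = sc.continue_1d(q, "g_KNa", (0.0, 6.0), n=61)
folds = sorted(b.g_KNa for b in pts if b.kind == "fold")
hopfs = sorted(b.g_KNa for b in pts if b.kind == "hopf")
g_vi = 0.5 * (max(hopfs[0], folds[0]) + folds[1])
print(f"slice sigma_e = 4.0: folds at {folds[0]:.2f} and {folds[1]:.2f}, "
      f"upper branch destabilizes at {hopfs[0]:.2f}; probing g_KNa = {g_vi:.2f}")

pvi = p.with_overrides(sigma_e=4.0, g_KNa=g_vi)
stats = sc.burst_suppression_probe(
    pvi, sc.SimulationConfig(duration=30.0, onset=5.0, seed=3))
print(f"with noise:  down-state fraction {stats['down_fraction']:.2f}, "
      f"{stats['excursion_count']} excursions in {stats['duration_s']:.0f} s")

pvi0 = pvi.copy()
pvi0.noise.phi_sd = 0.0
quiet = sc.burst_suppression_probe(
    pvi0, sc.SimulationConfig(duration=20.0, onset=2.0, seed=0))
print(f"noise-free:  down-state fraction {quiet['down_fraction']:.2f}, "
      f"{quiet['excursion_count']} excursions (stays on the silent state)")
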