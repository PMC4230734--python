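"""Map the bifurcation structure that organizes the sleep stages.

Continues the equilibrium set in the adaptation strength g_KNa at three
levels of the excitatory inverse gain sigma_e, then locates the cusp where
the fold wedge closes.  Expected picture: at steep gain (sigma_e = 3.5) only
the two saddle-node folds matter (bistable/excitable wedge); at the N2 gain
(4.6) a limit-cycle-bearing Hopf point appears below the folds; at the N3
gain (6.7) the folds are gone — beyond the cusp — and the Hopf alone
remains, with a crossing frequency in the slow-oscillation band.
"""

import sleepcortex as sc

p = sc.ModelParameters()
for sigma_e, g_range in [(3.5, (0.0, 6.0)), (4.6, (0.0, 4.5)), (6.7, (0.0, 3.0))]:
    q = p.with_overrides(sigma_e=sigma_e)
    _, points = sc.continue_1d(q, "g_KNa", g_range, n=61, probe_cycles=True)
    print(f"sigma_e = {sigma_e} mV:")
    for b in points:
        extra = ""
        if b.kind == "hopf":
            extra = (f", {b.frequency_hz:.2f} Hz, "
                     f"{'with' if b.cycle_bearing else 'no'} attracting cycle")
        print(f"   {b.kind:5s} at g_KNa = {b.g_KNa:.3f} mS/cm^2{extra}")

atlas = sc.trace_curves_2d(p, sigma_range=(5.8, 7.0), g_range=(0.0, 6.0),
                           n_sigma=4, n_g=41)
print(f"cusp: the folds coalesce at sigma_e = {atlas.cusp.sigma_e:.2f} mV "
      f"(g_KNa = {atlas.cusp.g_KNa:.2f} mS/cm^2)")

for name in ("wake", "n2", "n3"):
    q = sc.resolve_preset(name)
    reg = sc.classify_region(q.excitatory.sigma, q.adaptation.g_KNa, q)
    print(f"{name:>4} preset -> region {reg.label} "
          f"({reg.n_equilibria} equilibria, {reg.n_stable} stable)")
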