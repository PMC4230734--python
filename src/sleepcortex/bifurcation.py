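"""Bifurcation analysis of the noise-free cortical model.

Equilibria of the 11-dimensional system reduce analytically to a scalar root
problem: at a fixed point every synaptic variable equals its presynaptic
input, the sodium concentration balances the pump against the influx (an
invertible cubic), and the inhibitory voltage solves its own scalar membrane
equation given the excitatory rate.  What remains is one equation
``F(V_e) = 0``.  Scanning ``F`` over the physiological voltage range
enumerates *all* equilibria — including disconnected branches — which makes
fold detection a matter of counting roots and Hopf detection a matter of
tracking the leading eigenvalue pair of the Jacobian along a branch.

Limit cycles are characterized by direct simulation with transient discard
rather than by periodic-orbit collocation; amplitudes, periods, the canard
explosion and the homoclinic period blow-up are all read off the simulated
attractor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from . import model
from .params import ModelParameters

__all__ = [
    "Equilibrium",
    "BifurcationPoint",
    "EquilibriumBranch",
    "CycleBranch",
    "Atlas",
    "find_equilibria",
    "depolarized_equilibrium",
    "continue_1d",
    "trace_curves_2d",
    "classify_region",
    "cycle_branch",
]

#: Voltage convention separating the depolarized (up) from the
#: hyperpolarized (down) branch.
DEPOLARIZED_THRESHOLD = -65.0

#: |Re(lambda)| below which an eigenvalue pair counts as purely imaginary at
#: a refined bifurcation point (ms^-1).
IMAG_AXIS_TOL = 1e-6

_RESIDUAL_TOL = 1e-9
_V_SCAN = (-90.0, -20.0)
_N_SCAN = 701


# ---------------------------------------------------------------------------
# Scalar reduction of the equilibrium problem
# ---------------------------------------------------------------------------

def _rate_e(V, p: ModelParameters):
    e = p.excitatory
    return (e.Qmax * 1e-3) / (1.0 + np.exp(-e.sigmoid_scale * (V - e.theta) / e.sigma))


def _rate_i(V, p: ModelParameters):
    i = p.inhibitory
    return (i.Qmax * 1e-3) / (1.0 + np.exp(-i.sigmoid_scale * (V - i.theta) / i.sigma))


def _vi_balance(Vi, s_ei, p: ModelParameters):
    s = p.synapses
    i = p.inhibitory
    return (-(Vi - i.E_leak)
            - s.g_ampa * s_ei * (Vi - s.E_ampa)
            - s.g_gaba * s.N_ii * _rate_i(Vi, p) * (Vi - s.E_gaba))


def _vi_star(s_ei, p: ModelParameters):
    """Inhibitory equilibrium voltage(s) for given AMPA input; vectorized.

    The inhibitory balance is strictly decreasing at its root over the
    physiological range, so bisection on [-110, 10] mV suffices.
    """
    s_ei = np.asarray(s_ei, dtype=float)
    lo = np.full(s_ei.shape, -110.0)
    hi = np.full(s_ei.shape, 10.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        pos = _vi_balance(mid, s_ei, p) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def _na_star(qe_ms, p: ModelParameters):
    a = p.adaptation
    h = a.Na_half ** 3
    p0 = a.Na_eq ** 3 / (a.Na_eq ** 3 + h)
    target = p0 + a.alpha_Na * qe_ms / a.R_pump
    target = np.minimum(target, 1.0 - 1e-12)
    return (h * target / (1.0 - target)) ** (1.0 / 3.0)


def _mean_drive_ms(p: ModelParameters):
    base = p.noise.phi_mean * 1e-3
    return p.synapses.N_bg_e * base, p.synapses.N_bg_i * base


def _reduced_F(Ve, p: ModelParameters):
    """Excitatory equilibrium residual as a function of V_e alone."""
    s = p.synapses
    e = p.excitatory
    a = p.adaptation
    de, di = _mean_drive_ms(p)
    qe = _rate_e(Ve, p)
    s_ee = s.N_ee * qe + de
    s_ei = s.N_ei * qe + di
    Vi = _vi_star(s_ei, p)
    s_ie = s.N_ie * _rate_i(Vi, p)
    Na = _na_star(qe, p)
    w = a.w_max / (1.0 + (a.Na_gate / Na) ** a.gate_exponent)
    return ((-(Ve - e.E_leak)
             - s.g_ampa * s_ee * (Ve - s.E_ampa)
             - s.g_gaba * s_ie * (Ve - s.E_gaba)) / e.tau
            - a.g_KNa * w * (Ve - a.E_K) / a.C_m)


def _assemble_state(Ve: float, p: ModelParameters) -> np.ndarray:
    s = p.synapses
    de, di = _mean_drive_ms(p)
    qe = float(_rate_e(Ve, p))
    s_ei = s.N_ei * qe + di
    Vi = float(_vi_star(s_ei, p))
    qi = float(_rate_i(Vi, p))
    x = np.zeros(model.NSTATE)
    x[0], x[1] = Ve, Vi
    x[2], x[4] = s.N_ee * qe + de, s_ei
    x[6], x[8] = s.N_ie * qi, s.N_ii * qi
    x[10] = float(_na_star(qe, p))
    return x


def _root_voltages(p: ModelParameters) -> list[float]:
    grid = np.linspace(*_V_SCAN, _N_SCAN)
    f = _reduced_F(grid, p)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(float(grid[i]))
        elif f[i] * f[i + 1] < 0:
            r = brentq(lambda v: float(_reduced_F(v, p)), grid[i], grid[i + 1],
                       xtol=1e-12)
            roots.append(float(r))
    # dedupe (roots straddling grid nodes)
    out: list[float] = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-6:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Equilibria with stability
# ---------------------------------------------------------------------------

@dataclass
class Equilibrium:
    """A fixed point of the deterministic field with its linearization."""

    state: np.ndarray
    eigenvalues: np.ndarray
    residual: float

    @property
    def V_e(self) -> float:
        return float(self.state[0])

    @property
    def max_real(self) -> float:
        return float(self.eigenvalues.real.max())

    @property
    def is_stable(self) -> bool:
        return self.max_real < 0

    @property
    def leading(self) -> complex:
        return complex(self.eigenvalues[np.argmax(self.eigenvalues.real)])

    @property
    def leading_complex_real(self) -> float | None:
        """Largest real part among complex eigenvalue pairs (None if all real)."""
        mask = np.abs(self.eigenvalues.imag) > 1e-9
        if not mask.any():
            return None
        return float(self.eigenvalues.real[mask].max())

    @property
    def oscillation_frequency(self) -> float | None:
        """Frequency (Hz) of the leading complex pair, if any."""
        mask = np.abs(self.eigenvalues.imag) > 1e-9
        if not mask.any():
            return None
        ev = self.eigenvalues[mask]
        lead = ev[np.argmax(ev.real)]
        return abs(lead.imag) / (2.0 * np.pi) * 1000.0

    @property
    def stability(self) -> str:
        if self.is_stable:
            lead = self.leading
            return "stable focus" if abs(lead.imag) > 1e-9 else "stable node"
        lead = self.leading
        return "unstable focus" if abs(lead.imag) > 1e-9 else "saddle"

    @property
    def is_depolarized(self) -> bool:
        return self.V_e > DEPOLARIZED_THRESHOLD


def _make_equilibrium(Ve: float, p: ModelParameters) -> Equilibrium:
    x = _assemble_state(Ve, p)
    f = model.vector_field(x, p, drive=p.noise.phi_mean)
    eig = np.linalg.eigvals(model.jacobian(x, p, drive=p.noise.phi_mean))
    return Equilibrium(x, eig, float(np.abs(f).max()))


def find_equilibria(p: ModelParameters) -> list[Equilibrium]:
    """All equilibria of the deterministic model, sorted by V_e ascending.

    Depending on the regime the model has one to three equilibria.  Each is
    verified against the full vector field (residual below 1e-9 per
    component) independently of the reduction used to locate it.
    """
    eqs = [_make_equilibrium(v, p) for v in _root_voltages(p)]
    if not eqs:
        raise RuntimeError("no equilibrium found in the scan range "
                           f"[{_V_SCAN[0]}, {_V_SCAN[1]}] mV")
    bad = [e for e in eqs if e.residual > _RESIDUAL_TOL]
    if bad:
        raise RuntimeError(f"equilibrium residual above {_RESIDUAL_TOL}: "
                           f"{[e.residual for e in bad]}")
    return eqs


def depolarized_equilibrium(p: ModelParameters) -> Equilibrium:
    """The equilibrium nearest the depolarized branch (stable preferred)."""
    eqs = find_equilibria(p)
    stable = [e for e in eqs if e.is_stable]
    pool = stable if stable else eqs
    return max(pool, key=lambda e: e.V_e)


# ---------------------------------------------------------------------------
# One-parameter continuation
# ---------------------------------------------------------------------------

@dataclass
class BifurcationPoint:
    kind: str  # "fold" | "hopf" | "cusp"
    sigma_e: float
    g_KNa: float
    frequency_hz: float | None = None  # Hopf crossing frequency
    cycle_bearing: bool | None = None  # attracting cycle past the Hopf?
    diagnostic: float = 0.0  # |Re| of the defining eigenvalue at the point


@dataclass
class EquilibriumBranch:
    """Equilibria on a grid of one parameter (all coexisting branches)."""

    param: str
    values: np.ndarray
    equilibria: list[list[Equilibrium]]

    def counts(self) -> np.ndarray:
        return np.array([len(e) for e in self.equilibria])


def _with_param(p: ModelParameters, param: str, value: float) -> ModelParameters:
    return p.with_overrides(**{param: float(value)})


def _branch_eq(eqs: list[Equilibrium], branch: str) -> Equilibrium:
    return max(eqs, key=lambda e: e.V_e) if branch == "top" else \
        min(eqs, key=lambda e: e.V_e)


def _stability_re(p: ModelParameters, param: str, value: float, branch: str) -> float:
    eqs = find_equilibria(_with_param(p, param, value))
    return _branch_eq(eqs, branch).max_real


def _n_roots(p: ModelParameters, param: str, value: float) -> int:
    return len(_root_voltages(_with_param(p, param, value)))


def _probe_cycle(p: ModelParameters, kick_mv: float = 3.0, sim_s: float = 30.0,
                 tail_s: float = 8.0, amp_tol: float = 0.5) -> float:
    """Peak-to-peak V_e amplitude of the attractor reached from a kicked
    depolarized start (0.0 if it settles to a fixed point)."""
    from .integrate import SimulationConfig, integrate

    x0 = depolarized_equilibrium(p).state.copy()
    x0[0] += kick_mv
    q = p.copy()
    q.noise.phi_sd = 0.0
    cfg = SimulationConfig(duration=sim_s, onset=0.0, record_stride=10, seed=0)
    tr = integrate(q, cfg, x0)
    tail = tr.V_e[tr.times >= sim_s - tail_s]
    amp = float(tail.max() - tail.min())
    return amp if amp >= amp_tol else 0.0


def continue_1d(p: ModelParameters, param: str = "g_KNa",
                prange: tuple[float, float] = (0.0, 4.0), n: int = 81,
                probe_cycles: bool = False,
                ) -> tuple[EquilibriumBranch, list[BifurcationPoint]]:
    """Continue the equilibrium set along one parameter; detect folds and
    Hopf points.

    Folds are located by bisection on the equilibrium count (the scalar
    reduction enumerates the whole S-shaped branch, so a count change brackets
    a tangent point).  Hopf points are located where the leading eigenvalue
    of the top or bottom branch crosses the imaginary axis as a complex pair.
    With ``probe_cycles=True`` each Hopf point is additionally probed by
    deterministic simulation just past the crossing and flagged
    ``cycle_bearing`` if an attracting limit cycle exists there (the
    supercritical side of the paper's oscillatory regimes; the subcritical
    stability change of the upper branch inside the fold wedge carries no
    cycle and marks the bistable-to-excitable boundary instead).
    """
    lo, hi = map(float, prange)
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError("prange must be a finite increasing interval")
    values = np.linspace(lo, hi, n)
    all_eqs: list[list[Equilibrium]] = []
    for v in values:
        try:
            all_eqs.append(find_equilibria(_with_param(p, param, v)))
        except RuntimeError as err:
            warnings.warn(f"continuation stalled at {param}={v:g}: {err}")
            values = values[: len(all_eqs)]
            break
    branch = EquilibriumBranch(param, values, all_eqs)
    points: list[BifurcationPoint] = []

    # folds: equilibrium-count transitions
    counts = branch.counts()
    for i in np.flatnonzero(np.diff(counts) != 0):
        a, b = values[i], values[i + 1]
        na = counts[i]
        for _ in range(40):
            mid = 0.5 * (a + b)
            if _n_roots(p, param, mid) == na:
                a = mid
            else:
                b = mid
        points.append(_finish_point(p, param, 0.5 * (a + b), "fold"))

    # Hopf: stability change of the outer branches with a complex leading pair
    for side in ("top", "bottom"):
        re = np.array([_branch_eq(e, side).max_real for e in all_eqs])
        for i in np.flatnonzero(np.sign(re[:-1]) * np.sign(re[1:]) < 0):
            if counts[i] != counts[i + 1]:
                continue  # stability change caused by a fold, handled above
            g_h = brentq(lambda v: _stability_re(p, param, v, side),
                         values[i], values[i + 1], xtol=1e-8)
            eq = _branch_eq(find_equilibria(_with_param(p, param, g_h)), side)
            if abs(eq.leading.imag) <= 1e-9:
                continue  # real crossing: tangency, not a Hopf
            pt = _finish_point(p, param, g_h, "hopf",
                               frequency=eq.oscillation_frequency,
                               diagnostic=abs(eq.max_real))
            if probe_cycles:
                unstable_side = g_h + 0.01 if re[i + 1] > 0 else g_h - 0.01
                amp = _probe_cycle(_with_param(p, param, unstable_side))
                pt.cycle_bearing = amp > 0.0
            points.append(pt)

    # single-equilibrium stretches are seen by both the top and bottom track
    deduped: list[BifurcationPoint] = []
    for pt in sorted(points, key=lambda b: (b.kind, b.g_KNa, b.sigma_e)):
        if deduped and deduped[-1].kind == pt.kind and \
                abs(deduped[-1].g_KNa - pt.g_KNa) < 1e-5 and \
                abs(deduped[-1].sigma_e - pt.sigma_e) < 1e-5:
            continue
        deduped.append(pt)
    deduped.sort(key=lambda b: (b.g_KNa, b.sigma_e))
    return branch, deduped


def _finish_point(p: ModelParameters, param: str, value: float, kind: str,
                  frequency: float | None = None,
                  diagnostic: float = 0.0) -> BifurcationPoint:
    sig = p.excitatory.sigma if param != "sigma_e" else value
    g = p.adaptation.g_KNa if param != "g_KNa" else value
    if param == "sigma_e":
        sig = value
    elif param == "g_KNa":
        g = value
    return BifurcationPoint(kind, float(sig), float(g),
                            frequency_hz=frequency, diagnostic=diagnostic)


# ---------------------------------------------------------------------------
# Two-parameter atlas
# ---------------------------------------------------------------------------

@dataclass
class Atlas:
    """Fold and Hopf curves in the (sigma_e, g_KNa) plane."""

    sigma_grid: np.ndarray
    fold_curves: list[tuple[float, list[float]]]  # (sigma_e, fold g values)
    hopf_curve: list[tuple[float, float]]  # (sigma_e, hopf g)
    cusp: BifurcationPoint | None
    fold_hopf_intersection: tuple[float, float] | None  # (sigma_e, g)

    def folds_at(self, sigma_e: float) -> list[float]:
        best = min(self.fold_curves, key=lambda t: abs(t[0] - sigma_e))
        return best[1]


def _slice_points(p: ModelParameters, sigma_e: float,
                  g_range: tuple[float, float], n: int = 61):
    q = p.with_overrides(sigma_e=sigma_e)
    _, pts = continue_1d(q, "g_KNa", g_range, n=n)
    folds = sorted(b.g_KNa for b in pts if b.kind == "fold")
    hopfs = sorted(b.g_KNa for b in pts if b.kind == "hopf")
    return folds, hopfs


def trace_curves_2d(p: ModelParameters,
                    sigma_range: tuple[float, float] = (3.0, 7.5),
                    g_range: tuple[float, float] = (0.0, 6.0),
                    n_sigma: int = 19, n_g: int = 61) -> Atlas:
    """Assemble the fold and Hopf curves slice by slice and locate the cusp.

    The cusp is the inverse-gain value where the two fold branches coalesce
    (fold count per slice drops from 2 to 0); it is refined by bisection on
    fold existence.  The fold-Hopf intersection is the slice where the Hopf
    point crosses the lower fold branch.
    """
    sigmas = np.linspace(*sigma_range, n_sigma)
    fold_curves: list[tuple[float, list[float]]] = []
    hopf_curve: list[tuple[float, float]] = []
    for sig in sigmas:
        folds, hopfs = _slice_points(p, sig, g_range, n_g)
        fold_curves.append((float(sig), folds))
        if hopfs:
            hopf_curve.append((float(sig), hopfs[0]))

    # cusp: bisect on fold existence between the last foldful slice and the
    # first foldless one (light scan: only the equilibrium count is needed)
    def _fold_gs(sig: float) -> list[float]:
        q = p.with_overrides(sigma_e=sig)
        gs = np.linspace(*g_range, 2 * n_g)
        cnt = np.array([_n_roots(q, "g_KNa", g) for g in gs])
        return [float(0.5 * (gs[i] + gs[i + 1]))
                for i in np.flatnonzero(np.diff(cnt) != 0)]

    cusp = None
    has_folds = [bool(f) for _, f in fold_curves]
    for i in range(len(sigmas) - 1):
        if has_folds[i] and not has_folds[i + 1]:
            a, b = sigmas[i], sigmas[i + 1]
            last_folds = fold_curves[i][1]
            for _ in range(16):
                mid = 0.5 * (a + b)
                f = _fold_gs(mid)
                if f:
                    a, last_folds = mid, f
                else:
                    b = mid
            cusp = BifurcationPoint("cusp", 0.5 * (a + b),
                                    float(np.mean(last_folds)))
            break
    if cusp is None:
        warnings.warn("no cusp found in the scanned window; widen the ranges")

    # fold-Hopf intersection: sign change of (g_hopf - g_fold_low)
    inter = None
    prev = None
    for sig, g_h in hopf_curve:
        folds = dict(fold_curves).get(sig, [])
        if not folds:
            continue
        d = g_h - folds[0]
        if prev is not None and prev[1] * d < 0:
            inter = (0.5 * (prev[0] + sig), g_h)
            break
        prev = (sig, d)
    return Atlas(sigmas, fold_curves, hopf_curve, cusp, inter)


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

@dataclass
class RegionClassification:
    label: str  # "I" .. "VI"
    ambiguous: bool
    n_equilibria: int
    n_stable: int
    cycle_amplitude: float  # 0.0 if no attracting cycle was found
    equilibria: list[Equilibrium] = field(repr=False, default_factory=list)


def classify_region(sigma_e: float, g_KNa: float, p: ModelParameters | None = None,
                    g_scan: tuple[float, float] = (0.0, 6.0),
                    ) -> RegionClassification:
    """Map a point of the (sigma_e, g_KNa) plane onto the regimes I-VI.

    Decision tree: count equilibria and their stabilities; probe for an
    attracting cycle by deterministic simulation from a kicked depolarized
    start; oscillatory regimes II and III are split by whether the slice at
    this inverse gain still carries folds (III has relaxation cycles bounded
    by the homoclinic orbit at the fold; II lies beyond the cusp).
    """
    p = (p or ModelParameters()).with_overrides(sigma_e=sigma_e, g_KNa=g_KNa)
    eqs = find_equilibria(p)
    stable = [e for e in eqs if e.is_stable]
    amp = _probe_cycle(p)

    ambiguous = False
    if amp > 0.0:
        counts = np.array([_n_roots(p, "g_KNa", v)
                           for v in np.linspace(*g_scan, 41)])
        label = "III" if (np.diff(counts) != 0).any() else "II"
    elif len(eqs) == 3:
        if len(stable) == 2:
            label = "V"
        elif len(stable) == 1 and stable[0].V_e == min(e.V_e for e in eqs):
            label = "VI"
        else:
            label, ambiguous = "VI", True
    elif len(eqs) == 1 and stable:
        label = "I" if stable[0].is_depolarized else "IV"
    else:
        # no attracting set found by the probe although nothing is stable
        label, ambiguous = "II", True
    return RegionClassification(label, ambiguous, len(eqs), len(stable), amp, eqs)


# ---------------------------------------------------------------------------
# Limit-cycle branch, canard and homoclinic diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CycleBranch:
    """Attracting periodic orbits on a parameter grid (simulation-based)."""

    param: str
    values: np.ndarray
    amplitude: np.ndarray  # peak-to-peak V_e (mV); 0 where no cycle
    period: np.ndarray  # seconds; nan where no cycle
    exists: np.ndarray  # bool

    def canard_interval(self, ratio: float = 5.0, max_width: float = 0.025
                        ) -> tuple[float, float] | None:
        """Smallest parameter interval over which the cycle amplitude grows
        by at least ``ratio`` (None if amplitudes grow gradually everywhere).

        Operational definition of the canard explosion; ``max_width`` bounds
        the interval so that ordinary amplitude growth over a wide range does
        not qualify.
        """
        idx = np.flatnonzero(self.exists)
        best = None
        for a in idx:
            for b in idx[idx > a]:
                width = self.values[b] - self.values[a]
                if width > max_width:
                    break
                if self.amplitude[a] > 0 and \
                        self.amplitude[b] / self.amplitude[a] >= ratio:
                    if best is None or width < best[1] - best[0]:
                        best = (float(self.values[a]), float(self.values[b]))
        return best

    def homoclinic_diagnostic(self, period_factor: float = 3.0,
                              tol: float = 1e-3) -> dict:
        """Signature of the approach to a homoclinic orbit.

        Returns the onset (first-cycle) period, the final period before the
        branch terminates, whether the period grows monotonically over the
        second half of the branch, and whether the final period exceeds
        ``period_factor`` times the onset period.
        """
        idx = np.flatnonzero(self.exists)
        if len(idx) < 3:
            return {"detected": False}
        periods = self.period[idx]
        onset, final = float(periods[0]), float(periods[-1])
        tail = periods[len(periods) // 2:]
        monotone = bool(np.all(np.diff(tail) >= -tol))
        return {
            "detected": monotone and final >= period_factor * onset,
            "onset_period_s": onset,
            "final_period_s": final,
            "period_ratio": final / onset,
            "monotone_growth": monotone,
            "terminal_param": float(self.values[idx[-1]]),
        }


def _cycle_metrics(ve: np.ndarray, fs: float) -> tuple[float, float, bool]:
    amp = float(ve.max() - ve.min())
    if amp < 0.1:
        return 0.0, np.nan, False
    peaks, _ = find_peaks(ve, prominence=0.3 * amp, distance=int(0.05 * fs))
    if len(peaks) < 2:
        return amp, np.nan, False
    period = float(np.mean(np.diff(peaks)) / fs)
    return amp, period, True


def cycle_branch(p: ModelParameters, param: str = "g_KNa",
                 values: np.ndarray | None = None,
                 sim_s: float = 40.0, discard_s: float = 15.0) -> CycleBranch:
    """Follow the attracting periodic orbit over a parameter grid.

    Each point is integrated deterministically for ``sim_s`` seconds starting
    from the previous point's final state (branch following), the first
    ``discard_s`` seconds are discarded, and amplitude/period are measured on
    the remainder.  Points where the trajectory settles to a fixed point are
    flagged as cycle-free.
    """
    from .integrate import SimulationConfig, integrate

    if values is None:
        values = np.linspace(1.5, 2.2, 29)
    values = np.asarray(values, dtype=float)
    q0 = _with_param(p, param, values[0])
    x = depolarized_equilibrium(q0).state.copy()
    x[0] += 3.0
    amps = np.zeros(len(values))
    periods = np.full(len(values), np.nan)
    exists = np.zeros(len(values), dtype=bool)
    for k, v in enumerate(values):
        q = _with_param(p, param, v)
        q.noise.phi_sd = 0.0
        cfg = SimulationConfig(duration=sim_s, onset=0.0, record_stride=10, seed=0)
        tr = integrate(q, cfg, x)
        x = tr.states[-1].copy()
        ve = tr.V_e[tr.times >= discard_s]
        amps[k], periods[k], exists[k] = _cycle_metrics(ve, tr.fs)
    return CycleBranch(param, values, amps, periods, exists)
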