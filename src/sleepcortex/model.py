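"""Deterministic vector field of the two-population cortical model.

State layout (fixed; trajectories are stable across versions)::

    index  variable   meaning
    0      V_e        excitatory membrane voltage (mV)
    1      V_i        inhibitory membrane voltage (mV)
    2, 3   s_ee, s'_ee    AMPA input onto excitatory (e->e + background)
    4, 5   s_ei, s'_ei    AMPA input onto inhibitory (e->i + background)
    6, 7   s_ie, s'_ie    GABA input onto excitatory (i->e)
    8, 9   s_ii, s'_ii    GABA input onto inhibitory (i->i)
    10     Na         excitatory intracellular sodium (mM)

Each synaptic pair obeys the second-order alpha-function filter
``s'' = gamma^2 (u - s) - 2 gamma s'`` driven by the summed presynaptic rate
``u`` (connection count times firing rate, plus the background drive on the
AMPA-type pairs).  Membrane equations are conductance-based with a leak, the
two synaptic currents, and — on the excitatory population only — the
sodium-activated potassium current ``I_KNa`` coupled through the membrane
capacity.  Derivatives are per millisecond.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import AdaptationParameters, ModelParameters, PopulationParameters

__all__ = [
    "NSTATE",
    "firing_rate",
    "i_kna",
    "na_rate",
    "pump_rate",
    "na_equilibrium",
    "vector_field",
    "default_state",
]

NSTATE = 11

# indices into the packed parameter array (see ModelParameters.to_array)
_QE, _THE, _SIGE, _CE, _TAUE, _ELE = 0, 1, 2, 3, 4, 5
_QI, _THI, _SIGI, _CI, _TAUI, _ELI = 6, 7, 8, 9, 10, 11
_GAMA, _GAMG, _GA, _GG, _EA, _EG = 12, 13, 14, 15, 16, 17
_NEE, _NEI, _NIE, _NII, _NBGE, _NBGI = 18, 19, 20, 21, 22, 23
_GKNA, _EK, _CM, _ANA, _TNA = 24, 25, 26, 27, 28
_RP, _NAEQ, _NAH, _WMAX, _NAG, _GEXP = 29, 30, 31, 32, 33, 34


@njit(cache=True)
def _sigmoid_rate(V, Qmax, theta, sigma, scale):
    return Qmax / (1.0 + math.exp(-scale * (V - theta) / sigma))


@njit(cache=True)
def _rhs(x, pa, drive_e, drive_i, out):
    """Deterministic right-hand side; drives in ms^-1 at the pathway level."""
    Ve = x[0]
    Vi = x[1]
    Na = x[10]
    qe = _sigmoid_rate(Ve, pa[_QE], pa[_THE], pa[_SIGE], pa[_CE])
    qi = _sigmoid_rate(Vi, pa[_QI], pa[_THI], pa[_SIGI], pa[_CI])

    w = pa[_WMAX] / (1.0 + (pa[_NAG] / Na) ** pa[_GEXP])
    i_adapt = pa[_GKNA] * w * (Ve - pa[_EK])

    out[0] = (-(Ve - pa[_ELE])
              - pa[_GA] * x[2] * (Ve - pa[_EA])
              - pa[_GG] * x[6] * (Ve - pa[_EG])) / pa[_TAUE] - i_adapt / pa[_CM]
    out[1] = (-(Vi - pa[_ELI])
              - pa[_GA] * x[4] * (Vi - pa[_EA])
              - pa[_GG] * x[8] * (Vi - pa[_EG])) / pa[_TAUI]

    ga = pa[_GAMA]
    gg = pa[_GAMG]
    out[2] = x[3]
    out[3] = ga * ga * (pa[_NEE] * qe + drive_e - x[2]) - 2.0 * ga * x[3]
    out[4] = x[5]
    out[5] = ga * ga * (pa[_NEI] * qe + drive_i - x[4]) - 2.0 * ga * x[5]
    out[6] = x[7]
    out[7] = gg * gg * (pa[_NIE] * qi - x[6]) - 2.0 * gg * x[7]
    out[8] = x[9]
    out[9] = gg * gg * (pa[_NII] * qi - x[8]) - 2.0 * gg * x[9]

    h = pa[_NAH] ** 3
    pump = pa[_RP] * (Na ** 3 / (Na ** 3 + h) - pa[_NAEQ] ** 3 / (pa[_NAEQ] ** 3 + h))
    out[10] = (pa[_ANA] * qe - pump) / pa[_TNA]


@njit(cache=True)
def _rhs_alloc(x, pa, drive_e, drive_i):
    out = np.empty(NSTATE)
    _rhs(x, pa, drive_e, drive_i, out)
    return out


# ---------------------------------------------------------------------------
# Public, unit-carrying operations
# ---------------------------------------------------------------------------

def firing_rate(V, pop: PopulationParameters):
    """Population firing rate (s^-1) for membrane voltage ``V`` (mV).

    Sigmoidal (logistic) voltage-to-rate mapping; strictly increasing and
    bounded in (0, Qmax).  Accepts scalars or arrays.
    """
    pop.validate()
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane voltage must be finite")
    out = pop.Qmax / (1.0 + np.exp(-pop.sigmoid_scale * (V - pop.theta) / pop.sigma))
    return float(out) if out.ndim == 0 else out


def i_kna(V: float, Na: float, adapt: AdaptationParameters) -> float:
    """Sodium-activated potassium current density (uA/cm^2).

    ``g_KNa * w(Na) * (V - E_K)`` with the saturating Hill-type gating
    ``w(Na) = w_max / (1 + (Na_gate/Na)^q)``.
    """
    if Na <= 0:
        raise ValueError("sodium concentration must be positive")
    w = adapt.w_max / (1.0 + (adapt.Na_gate / Na) ** adapt.gate_exponent)
    return adapt.g_KNa * w * (V - adapt.E_K)


def pump_rate(Na: float, adapt: AdaptationParameters) -> float:
    """Active sodium extrusion (mM/ms), zero at ``Na_eq``.

    Cubic saturating pump: ``R_pump * (P(Na) - P(Na_eq))`` with
    ``P(c) = c^3/(c^3 + Na_half^3)``.
    """
    if Na <= 0:
        raise ValueError("sodium concentration must be positive")
    h = adapt.Na_half ** 3
    p = Na ** 3 / (Na ** 3 + h)
    p0 = adapt.Na_eq ** 3 / (adapt.Na_eq ** 3 + h)
    return adapt.R_pump * (p - p0)


def na_rate(Na: float, rate_e: float, adapt: AdaptationParameters) -> float:
    """Sodium balance dNa/dt (mM/ms) at firing rate ``rate_e`` (s^-1)."""
    if rate_e < 0:
        raise ValueError("firing rate must be non-negative")
    return (adapt.alpha_Na * rate_e * 1e-3 - pump_rate(Na, adapt)) / adapt.tau_Na


def na_equilibrium(rate_e: float, adapt: AdaptationParameters) -> float:
    """Sodium concentration (mM) balancing influx at ``rate_e`` (s^-1).

    Analytic inversion of the cubic pump; raises if the influx exceeds the
    pump's capacity.
    """
    if rate_e < 0:
        raise ValueError("firing rate must be non-negative")
    h = adapt.Na_half ** 3
    p0 = adapt.Na_eq ** 3 / (adapt.Na_eq ** 3 + h)
    target = p0 + adapt.alpha_Na * rate_e * 1e-3 / adapt.R_pump
    if target >= 1.0:
        raise ValueError("firing rate exceeds the sodium pump capacity")
    return (h * target / (1.0 - target)) ** (1.0 / 3.0)


def vector_field(x, p: ModelParameters, drive: float = 0.0) -> np.ndarray:
    """Deterministic time derivative of the full state (per ms).

    ``drive`` is a per-synapse background rate (s^-1) fed through the
    background connectivity into the AMPA-type synapses of both populations.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (NSTATE,):
        raise ValueError(f"state must have shape ({NSTATE},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state must be finite")
    if drive < 0:
        raise ValueError("background drive must be non-negative")
    pa = p.to_array()
    d_ms = drive * 1e-3
    return _rhs_alloc(x, pa, pa[_NBGE] * d_ms, pa[_NBGI] * d_ms)


def default_state(p: ModelParameters) -> np.ndarray:
    """A generic depolarized starting state (used before settling)."""
    x = np.zeros(NSTATE)
    x[0], x[1] = -55.0, -60.0
    qe = firing_rate(-55.0, p.excitatory) * 1e-3
    qi = firing_rate(-60.0, p.inhibitory) * 1e-3
    s = p.synapses
    x[2], x[4] = s.N_ee * qe, s.N_ei * qe
    x[6], x[8] = s.N_ie * qi, s.N_ii * qi
    x[10] = p.adaptation.Na_eq + 0.5
    return x


def jacobian(x, p: ModelParameters, drive: float = 0.0, step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the vector field at ``x``.

    The step is scaled per variable so voltages (tens of mV) and synaptic
    variables (order one) are perturbed comparably.
    """
    x = np.asarray(x, dtype=float)
    J = np.empty((NSTATE, NSTATE))
    for j in range(NSTATE):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (vector_field(xp, p, drive) - vector_field(xm, p, drive)) / (2.0 * h)
    return J
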