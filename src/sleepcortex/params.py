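"""Model parameters: typed containers, presets, and flat-file serialization.

The model is a two-population (excitatory pyramidal / inhibitory interneuron)
cortical neural mass with conductance-based membrane equations, alpha-function
synaptic kinetics, and a sodium-activated potassium current ``I_KNa`` on the
excitatory population that provides slow, activity-dependent negative
feedback.  The two bifurcation parameters of interest are the inverse gain of
the excitatory sigmoid (``sigma``) and the maximal ``I_KNa`` conductivity
(``g_KNa``); everything else is held fixed by the presets.

Unit conventions
----------------
Voltages are in mV, time constants in ms, rates in s^-1 at the API surface
(converted to ms^-1 internally), conductivities in mS/cm^2, concentrations in
mM.  The sigmoid scale constant ``pi/sqrt(3)`` makes ``sigma`` equal to the
standard deviation of the underlying logistic firing-rate distribution, which
ties the gain of the population directly to the spread of its firing response.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "PopulationParameters",
    "SynapseParameters",
    "AdaptationParameters",
    "NoiseParameters",
    "ModelParameters",
    "resolve_preset",
    "available_presets",
]

#: Scale constant of the firing-rate sigmoid.  With this factor the inverse
#: gain ``sigma`` is exactly the standard deviation of the logistic
#: distribution whose CDF the sigmoid is.
SIGMOID_SCALE = math.pi / math.sqrt(3.0)


@dataclass
class PopulationParameters:
    """Intrinsic constants of one neural population."""

    Qmax: float = 30.0  # maximal firing rate (s^-1)
    theta: float = -58.5  # firing threshold (mV)
    sigma: float = 4.0  # inverse gain / sigmoid width (mV)
    sigmoid_scale: float = SIGMOID_SCALE  # dimensionless
    tau: float = 30.0  # membrane time constant (ms)
    E_leak: float = -66.0  # leak reversal potential (mV)

    def validate(self) -> None:
        if not (self.Qmax > 0 and self.sigma > 0 and self.tau > 0):
            raise ValueError("PopulationParameters requires Qmax, sigma, tau > 0")


@dataclass
class SynapseParameters:
    """Alpha-function synaptic kinetics, reversal potentials and connectivity.

    ``N_*`` entries are mean synaptic connection counts per target neuron.
    The background pathway (``N_bg_e``, ``N_bg_i``) carries the unspecific
    excitatory drive (mean + stimulus + white noise) into the AMPA-type
    synapses of both populations.
    """

    gamma_ampa: float = 70.0  # inverse rise time (s^-1)
    gamma_gaba: float = 58.6  # inverse rise time (s^-1)
    g_ampa: float = 1.0  # maximal conductivity (mS/cm^2)
    g_gaba: float = 1.0  # maximal conductivity (mS/cm^2)
    E_ampa: float = 0.0  # (mV)
    E_gaba: float = -70.0  # (mV)
    N_ee: float = 120.0  # excitatory -> excitatory
    N_ei: float = 72.0  # excitatory -> inhibitory
    N_ie: float = 90.0  # inhibitory -> excitatory
    N_ii: float = 90.0  # inhibitory -> inhibitory
    N_bg_e: float = 30.0  # background pathway -> excitatory
    N_bg_i: float = 30.0  # background pathway -> inhibitory

    def validate(self) -> None:
        if not (self.gamma_ampa > 0 and self.gamma_gaba > 0):
            raise ValueError("synaptic rise rates must be positive")
        for name in ("g_ampa", "g_gaba", "N_ee", "N_ei", "N_ie", "N_ii",
                     "N_bg_e", "N_bg_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class AdaptationParameters:
    """Sodium-activated potassium current and sodium pump.

    ``I_KNa = g_KNa * w(Na) * (V - E_K)`` with the saturating gating function
    ``w(Na) = 0.37 / (1 + (38.7/Na)^3.5)``.  Intracellular sodium accumulates
    with firing (``alpha_Na`` mM.ms of influx per unit ms^-1 rate) and is
    extruded by an active pump with half-saturation at ``Na_half`` and
    equilibrium concentration ``Na_eq``.
    """

    g_KNa: float = 1.33  # maximal conductivity (mS/cm^2)
    E_K: float = -100.0  # potassium Nernst potential (mV)
    C_m: float = 1.0  # membrane capacity (uF/cm^2)
    alpha_Na: float = 2.0  # sodium influx per spike (mM ms)
    tau_Na: float = 1.5  # time scale of the sodium balance (ms)
    R_pump: float = 0.09  # maximal pump rate (mM/ms)
    Na_eq: float = 9.5  # pump equilibrium concentration (mM)
    Na_half: float = 15.0  # pump half-saturation concentration (mM)
    w_max: float = 0.37  # gating saturation (dimensionless)
    Na_gate: float = 38.7  # gating half-activation concentration (mM)
    gate_exponent: float = 3.5  # gating Hill exponent

    def validate(self) -> None:
        if self.g_KNa < 0:
            raise ValueError("g_KNa must be non-negative")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.Na_eq <= 0 or self.Na_half <= 0:
            raise ValueError("sodium concentrations must be positive")


@dataclass
class NoiseParameters:
    """Background drive: mean rate, white-noise intensity, stimulus offset.

    ``phi_sd`` is the intensity of the Gaussian white noise added to the
    summed background input of each population (units s^-1 sqrt(ms)); the two
    populations receive independent streams.  ``phi_mean`` and
    ``stimulus_offset`` are per-synapse rates multiplied by the background
    connectivity.
    """

    phi_mean: float = 0.0  # mean background spike rate (s^-1)
    phi_sd: float = 400.0  # white-noise intensity (s^-1 sqrt(ms))
    stimulus_offset: float = 0.0  # extra mean rate during stimulation (s^-1)

    def validate(self) -> None:
        if self.phi_sd < 0:
            raise ValueError("phi_sd must be non-negative")


@dataclass
class ModelParameters:
    """All constants of the cortical module."""

    excitatory: PopulationParameters = field(default_factory=PopulationParameters)
    inhibitory: PopulationParameters = field(
        default_factory=lambda: PopulationParameters(Qmax=60.0, sigma=6.0, E_leak=-64.0)
    )
    synapses: SynapseParameters = field(default_factory=SynapseParameters)
    adaptation: AdaptationParameters = field(default_factory=AdaptationParameters)
    noise: NoiseParameters = field(default_factory=NoiseParameters)

    def validate(self) -> None:
        self.excitatory.validate()
        self.inhibitory.validate()
        self.synapses.validate()
        self.adaptation.validate()
        self.noise.validate()

    # -- flat key access -------------------------------------------------
    _SECTIONS = ("excitatory", "inhibitory", "synapses", "adaptation", "noise")

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for sec in self._SECTIONS:
            obj = getattr(self, sec)
            for key, val in vars(obj).items():
                out[f"{sec}.{key}"] = val
        return out

    @classmethod
    def from_dict(cls, flat: dict[str, float]) -> "ModelParameters":
        p = cls()
        for full_key, val in flat.items():
            sec, _, key = full_key.partition(".")
            if sec not in cls._SECTIONS:
                raise KeyError(f"unknown parameter section {sec!r}")
            obj = getattr(p, sec)
            if not hasattr(obj, key):
                raise KeyError(f"unknown parameter {full_key!r}")
            setattr(obj, key, float(val))
        p.validate()
        return p

    def with_overrides(self, **flat: float) -> "ModelParameters":
        """Return a copy with flat ``section.key`` or shorthand overrides.

        Shorthands: ``sigma_e`` (excitatory.sigma) and ``g_KNa``
        (adaptation.g_KNa), the two bifurcation parameters.
        """
        alias = {"sigma_e": "excitatory.sigma", "g_KNa": "adaptation.g_KNa"}
        d = self.to_dict()
        for key, val in flat.items():
            key = alias.get(key, key)
            if key not in d:
                raise KeyError(f"unknown parameter {key!r}")
            d[key] = float(val)
        return ModelParameters.from_dict(d)

    def copy(self) -> "ModelParameters":
        return ModelParameters.from_dict(self.to_dict())

    # -- serialization ---------------------------------------------------
    def to_file(self, path: str | Path, header: str = "") -> None:
        lines = []
        if header:
            lines.extend(f"# {ln}" for ln in header.splitlines())
        for key, val in self.to_dict().items():
            lines.append(f"{key} = {val!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        flat: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            flat[key.strip()] = float(val.strip())
        return cls.from_dict(flat)

    def digest(self) -> str:
        """Stable hash of the full parameter set (run provenance)."""
        text = ";".join(f"{k}={v!r}" for k, v in sorted(self.to_dict().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    # -- packed representation for the numerical kernels -----------------
    def to_array(self) -> np.ndarray:
        """Pack into the flat float64 layout used by the compiled kernels.

        Rates are converted from s^-1 to ms^-1 here; the kernel works purely
        in (mV, ms, mM) units.
        """
        e, i, s, a = self.excitatory, self.inhibitory, self.synapses, self.adaptation
        return np.array([
            e.Qmax * 1e-3, e.theta, e.sigma, e.sigmoid_scale, e.tau, e.E_leak,
            i.Qmax * 1e-3, i.theta, i.sigma, i.sigmoid_scale, i.tau, i.E_leak,
            s.gamma_ampa * 1e-3, s.gamma_gaba * 1e-3,
            s.g_ampa, s.g_gaba, s.E_ampa, s.E_gaba,
            s.N_ee, s.N_ei, s.N_ie, s.N_ii, s.N_bg_e, s.N_bg_i,
            a.g_KNa, a.E_K, a.C_m, a.alpha_Na, a.tau_Na,
            a.R_pump, a.Na_eq, a.Na_half, a.w_max, a.Na_gate, a.gate_exponent,
        ])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_PRESET_FILES = {"wake": "wake.cfg", "n1": "n1.cfg", "n2": "n2.cfg", "n3": "n3.cfg"}


def available_presets() -> list[str]:
    return sorted(_PRESET_FILES)


def resolve_preset(name: str | Path) -> ModelParameters:
    """Return the parameters of a named regime or load a custom config file.

    Shipped presets place the cortex on the wake-to-deep-sleep route in the
    (sigma_e, g_KNa) plane: ``wake`` deep in the monostable active regime,
    ``n1`` nearer the oscillatory boundary, ``n2`` (sigma_e = 4.6 mV,
    g_KNa = 1.33 mS/cm^2) just below the Hopf bifurcation bordering the
    relaxation-cycle regime, and ``n3`` (sigma_e = 6.7 mV, g_KNa = 2 mS/cm^2)
    beyond the cusp, close to the limit-cycle regime.
    """
    key = str(name).lower()
    if key in _PRESET_FILES:
        ref = resources.files("sleepcortex.presets") / _PRESET_FILES[key]
        with resources.as_file(ref) as path:
            return ModelParameters.from_file(path)
    path = Path(name)
    if path.exists():
        return ModelParameters.from_file(path)
    raise KeyError(
        f"unknown preset {name!r}; available: {', '.join(available_presets())} "
        "or a path to a parameter file"
    )


def _default_like(**overrides: float) -> ModelParameters:
    return ModelParameters().with_overrides(**overrides)
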