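"""Time integration: stochastic Runge-Kutta of 4th order, stimulus scheduling.

The stochastic scheme treats the white-noise background as an additive,
piecewise-constant drive: for each step the Wiener increment ``dW`` is drawn
once and the effective drive ``phi_sd * dW / dt`` is held fixed through the
four classical Runge-Kutta stages.  For additive noise this gives the exact
classical RK4 flow in the deterministic limit (``phi_sd = 0``) and the
correct stationary statistics of linear test systems up to O(dt/tau)
corrections.  Seeds fully determine the noise stream; the recording stride
never changes it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from . import model
from .params import ModelParameters

__all__ = [
    "StimulusProtocol",
    "SimulationConfig",
    "Trajectory",
    "SimulationDiverged",
    "integrate",
    "apply_stimulus",
    "ou_trajectory",
]


class SimulationDiverged(RuntimeError):
    """Raised when a membrane voltage exceeds the divergence guard."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Rectangular elevation of the mean background rate.

    Emulates an excitatory afferent burst: for ``duration_ms`` starting at
    ``onset_time`` (s) the per-synapse background rate is raised by
    ``rate_offset`` (s^-1) on the chosen populations.
    """

    onset_time: float  # s
    duration_ms: float = 50.0
    rate_offset: float = 0.0  # s^-1
    targets: str = "both"  # "both" | "e" | "i"

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.rate_offset < 0:
            raise ValueError("stimulus rate offset must be non-negative")
        if self.targets not in ("both", "e", "i"):
            raise ValueError("targets must be 'both', 'e' or 'i'")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``duration`` and ``onset`` are in seconds; the onset segment is simulated
    but flagged for exclusion from analysis.  ``record_stride`` decimates the
    stored output without affecting the noise stream.
    """

    dt: float = 0.1  # ms
    duration: float = 30.0  # s
    onset: float = 5.0  # s
    seed: int = 0
    record_stride: int = 10
    stimuli: tuple[StimulusProtocol, ...] = ()
    divergence_guard: float = 200.0  # mV

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.onset < self.duration:
            raise ValueError("onset must satisfy 0 <= onset < duration")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        for st in self.stimuli:
            end = st.onset_time + st.duration_ms * 1e-3
            if st.onset_time < 0 or end > self.duration:
                raise ValueError(
                    f"stimulus window [{st.onset_time}, {end}] s lies outside "
                    f"the simulated interval [0, {self.duration}] s"
                )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


def apply_stimulus(cfg: SimulationConfig, protocol: StimulusProtocol) -> SimulationConfig:
    """Return a config with ``protocol`` added; drives compose additively."""
    new = replace(cfg, stimuli=cfg.stimuli + (protocol,))
    return new


@dataclass
class Trajectory:
    """Recorded state history with config provenance.

    ``times`` are in seconds on a uniform grid; ``states`` has one row per
    recorded sample in the fixed state layout of :mod:`sleepcortex.model`.
    The excitatory membrane voltage ``V_e`` is the model's output variable
    (the EEG is approximated by a linear scaling of it).
    """

    times: np.ndarray
    states: np.ndarray
    config: SimulationConfig
    params_digest: str

    @property
    def V_e(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def V_i(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def Na(self) -> np.ndarray:
        return self.states[:, 10]

    @property
    def fs(self) -> float:
        """Sampling rate of the recorded output (Hz)."""
        return 1000.0 / (self.config.dt * self.config.record_stride)

    def post_onset(self) -> "Trajectory":
        """View restricted to t >= onset (the analysis segment)."""
        keep = self.times >= self.config.onset
        return Trajectory(self.times[keep], self.states[keep], self.config,
                          self.params_digest)

    # -- writers ---------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        header = "time_s,V_e_mV,V_i_mV,Na_mM"
        cols = np.column_stack([self.times, self.V_e, self.V_i, self.Na])
        np.savetxt(path, cols, delimiter=",", header=header, comments="")

    def to_npz(self, path: str | Path) -> None:
        meta = json.dumps({
            "params_digest": self.params_digest,
            "config": _config_dict(self.config),
        })
        np.savez_compressed(path, times=self.times, states=self.states,
                            meta=np.array(meta))

    def to_mne_raw(self, zscored: bool = True):
        """Package the V_e channel as an MNE Raw object for EEG viewers."""
        import mne  # optional dependency

        x = self.post_onset().V_e.copy()
        if zscored:
            x = (x - x.mean()) / x.std()
        info = mne.create_info(["Ve"], sfreq=self.fs, ch_types="misc")
        return mne.io.RawArray(x[None, :] * 1e-6, info, verbose="error")


def _config_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["stimuli"] = [dataclasses.asdict(s) for s in cfg.stimuli]
    return d


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _srk4_loop(x0, pa, dt, n_steps, de_mean, di_mean, noise, sd_e, sd_i,
               stride, guard):
    """SRK4 integration; returns (records, first_bad_step)."""
    nrec = n_steps // stride + 1
    out = np.empty((nrec, model.NSTATE))
    x = x0.copy()
    k1 = np.empty(model.NSTATE)
    k2 = np.empty(model.NSTATE)
    k3 = np.empty(model.NSTATE)
    k4 = np.empty(model.NSTATE)
    xs = np.empty(model.NSTATE)
    out[0] = x
    rec = 1
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    for n in range(n_steps):
        de = de_mean[n] + sd_e * noise[n, 0] * inv_sqrt_dt
        di = di_mean[n] + sd_i * noise[n, 1] * inv_sqrt_dt
        model._rhs(x, pa, de, di, k1)
        for j in range(model.NSTATE):
            xs[j] = x[j] + 0.5 * dt * k1[j]
        model._rhs(xs, pa, de, di, k2)
        for j in range(model.NSTATE):
            xs[j] = x[j] + 0.5 * dt * k2[j]
        model._rhs(xs, pa, de, di, k3)
        for j in range(model.NSTATE):
            xs[j] = x[j] + dt * k3[j]
        model._rhs(xs, pa, de, di, k4)
        for j in range(model.NSTATE):
            x[j] = x[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if abs(x[0]) > guard or abs(x[1]) > guard or not np.isfinite(x[0]):
            return out[:rec], n
        if (n + 1) % stride == 0:
            out[rec] = x
            rec += 1
    return out[:rec], -1


def _mean_drives(p: ModelParameters, cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-step deterministic pathway drives (ms^-1) for both populations."""
    n = cfg.n_steps
    s = p.synapses
    base = p.noise.phi_mean * 1e-3
    de = np.full(n, s.N_bg_e * base)
    di = np.full(n, s.N_bg_i * base)
    t_ms = np.arange(n) * cfg.dt
    for st in cfg.stimuli:
        t0 = st.onset_time * 1000.0
        t1 = t0 + st.duration_ms
        mask = (t_ms >= t0) & (t_ms < t1)
        off = st.rate_offset * 1e-3
        if st.targets in ("both", "e"):
            de[mask] += s.N_bg_e * off
        if st.targets in ("both", "i"):
            di[mask] += s.N_bg_i * off
    return de, di


def integrate(p: ModelParameters, cfg: SimulationConfig,
              x0: np.ndarray | str = "auto") -> Trajectory:
    """Integrate the model and return a :class:`Trajectory`.

    With ``x0="auto"`` the run starts from the deterministic equilibrium
    nearest the depolarized branch (the premise being that the cortex sits in
    the active state); otherwise pass a full state vector.
    """
    p.validate()
    if isinstance(x0, str):
        if x0 != "auto":
            raise ValueError("x0 must be a state vector or 'auto'")
        from .bifurcation import depolarized_equilibrium

        x0 = depolarized_equilibrium(p).state
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.NSTATE,):
        raise ValueError("x0 has wrong dimension")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_steps
    if p.noise.phi_sd > 0:
        noise = rng.standard_normal((n, 2))
    else:
        noise = np.zeros((n, 2))
    de, di = _mean_drives(p, cfg)
    sd = p.noise.phi_sd * 1e-3  # pathway intensity in ms^-1 sqrt(ms)
    states, bad = _srk4_loop(x0, p.to_array(), cfg.dt, n, de, di, noise,
                             sd, sd, cfg.record_stride, cfg.divergence_guard)
    if bad >= 0:
        raise SimulationDiverged(
            f"membrane voltage exceeded {cfg.divergence_guard} mV at step {bad} "
            f"(t = {bad * cfg.dt / 1000.0:.4f} s)"
        )
    times = np.arange(states.shape[0]) * (cfg.dt * cfg.record_stride) / 1000.0
    return Trajectory(times, states, cfg, p.digest())


# ---------------------------------------------------------------------------
# Scheme validation on a 1-D Ornstein-Uhlenbeck test problem
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ou_loop(x0, tau, sigma, dt, n_steps, noise):
    out = np.empty(n_steps + 1)
    out[0] = x0
    x = x0
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    for n in range(n_steps):
        c = sigma * noise[n] * inv_sqrt_dt
        k1 = -x / tau + c
        k2 = -(x + 0.5 * dt * k1) / tau + c
        k3 = -(x + 0.5 * dt * k2) / tau + c
        k4 = -(x + dt * k3) / tau + c
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[n + 1] = x
    return out


def ou_trajectory(tau: float, sigma: float, dt: float, duration_ms: float,
                  seed: int = 0, x0: float = 0.0) -> np.ndarray:
    """Integrate ``dx = -x/tau dt + sigma dW`` with the same SRK4 stepping.

    Validation utility: the stationary variance of this process is
    ``sigma**2 * tau / 2``, which the scheme must reproduce.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / dt))
    return _ou_loop(x0, tau, sigma, dt, n, rng.standard_normal(n))
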