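"""Deterministic evoked responses and excitability probes.

The central experiment: apply a 50 ms excitatory burst of varying spike rate
to both populations of the noise-free model resting at its equilibrium, and
measure the response of the excitatory voltage.  Near the relaxation-cycle
border (N2) the response family splits sharply into small damped
oscillations and full-blown K-complex-like excursions — the canard
explosion.  Beyond the cusp (N3) the same protocol produces a graded
amplitude increase instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .bifurcation import classify_region, depolarized_equilibrium
from .integrate import SimulationConfig, StimulusProtocol, Trajectory, integrate
from .params import ModelParameters

__all__ = [
    "EvokedResponse",
    "EvokedResponseFamily",
    "stimulus_family",
    "kc_morphology",
    "burst_suppression_probe",
]

_PRE_S = 0.5  # quiet pre-stimulus segment (s)
_WINDOW_S = 2.0  # response-measurement window after stimulus onset (s)


@dataclass
class EvokedResponse:
    rate: float  # stimulus spike rate (s^-1)
    trajectory: Trajectory
    amplitude: float  # peak-to-peak V_e in the response window (mV)
    morphology: dict


@dataclass
class EvokedResponseFamily:
    """One deterministic response per stimulus rate, with summaries."""

    responses: list[EvokedResponse]

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.responses])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([r.amplitude for r in self.responses])

    def amplitude_ratio(self) -> float:
        """max/min response amplitude across the family."""
        a = self.amplitudes
        return float(a.max() / a.min())

    def max_adjacent_ratio(self) -> tuple[float, float]:
        """Largest amplitude ratio between adjacent rates and the rate at
        which it occurs — the operational canard-vs-graded contrast."""
        a = self.amplitudes
        ratios = a[1:] / a[:-1]
        k = int(np.argmax(ratios))
        return float(ratios[k]), float(self.rates[k + 1])


def stimulus_family(p: ModelParameters, rates, duration_ms: float = 50.0,
                    x0: np.ndarray | None = None,
                    record_stride: int = 10) -> EvokedResponseFamily:
    """Evoked responses of the noise-free model over a grid of burst rates.

    Each run starts exactly at the deterministic depolarized equilibrium
    (anything else would contaminate the latencies) and applies one
    rectangular burst to both populations.  The response amplitude is the
    peak-to-peak excursion of V_e within 2 s of stimulus onset.
    """
    q = p.copy()
    q.noise.phi_sd = 0.0
    eq = depolarized_equilibrium(q)
    if x0 is None:
        x0 = eq.state
    else:
        x0 = np.asarray(x0, dtype=float)
        resid = np.abs(model_residual(q, x0))
        if resid > 1e-6:
            raise ValueError(
                "stimulus_family requires an equilibrium start "
                f"(|f| = {resid:.2e}); latencies would be contaminated"
            )
    duration = _PRE_S + _WINDOW_S + 1.5
    responses = []
    for rate in np.asarray(rates, dtype=float):
        cfg = SimulationConfig(duration=duration, onset=0.0, seed=0,
                               record_stride=record_stride)
        if rate > 0:
            cfg = SimulationConfig(
                duration=duration, onset=0.0, seed=0,
                record_stride=record_stride,
                stimuli=(StimulusProtocol(_PRE_S, duration_ms, rate),))
        tr = integrate(q, cfg, x0)
        win = (tr.times >= _PRE_S) & (tr.times <= _PRE_S + _WINDOW_S)
        ve = tr.V_e[win]
        amp = float(ve.max() - ve.min())
        responses.append(EvokedResponse(float(rate), tr, amp,
                                        kc_morphology(tr, onset_time=_PRE_S)))
    return EvokedResponseFamily(responses)


def model_residual(p: ModelParameters, x: np.ndarray) -> float:
    from . import model

    return float(np.abs(model.vector_field(x, p, drive=p.noise.phi_mean)).max())


def kc_morphology(tr: Trajectory, onset_time: float,
                  kc_depth_mv: float = 10.0, window_s: float = 2.0,
                  refractory_ms: float = 10.0) -> dict:
    """Extract the K-complex morphology of a single deterministic response.

    Looks for the stereotyped sequence after stimulus onset: an initial
    positive bump, a dominant negative trough, and a positive rebound
    (the evoked K-complex's P200 / N550 / P900 components).  The event is
    classified KC-like when the trough is a dominant, isolated deflection at
    least ``kc_depth_mv`` below baseline followed by a rebound above
    baseline; damped small oscillations and periodic waveforms do not
    qualify (result ``"no event"``).
    """
    t = tr.times
    ve = tr.V_e
    pre = ve[t < onset_time]
    baseline = float(pre[-1]) if pre.size else float(ve[0])
    win = (t >= onset_time) & (t <= onset_time + window_s)
    seg = ve[win] - baseline
    ts = (t[win] - onset_time) * 1000.0  # ms from onset
    fs = tr.fs
    dist = max(1, int(round(refractory_ms * fs / 1000.0)))

    troughs, _ = find_peaks(-seg, distance=dist, prominence=0.05)
    if troughs.size == 0:
        return {"kc_like": False, "reason": "no event"}
    main = troughs[np.argmin(seg[troughs])]
    depth = -float(seg[main])
    # dominance: deepest trough must clearly stand out from the others
    others = [tr_ for tr_ in troughs if tr_ != main]
    dominant = all(depth >= 2.0 * max(0.0, -float(seg[o])) for o in others) \
        if others else True

    peaks, _ = find_peaks(seg, distance=dist, prominence=0.05)
    first_pos = next((int(k) for k in peaks if k < main and seg[k] > 0), None)
    rebound = next((int(k) for k in peaks if k > main and seg[k] > 0), None)

    out = {
        "baseline_mv": baseline,
        "trough_latency_ms": float(ts[main]),
        "trough_depth_mv": depth,
        "positive_bump_latency_ms": float(ts[first_pos]) if first_pos is not None else None,
        "rebound_latency_ms": float(ts[rebound]) if rebound is not None else None,
        "rebound_height_mv": float(seg[rebound]) if rebound is not None else None,
    }
    out["kc_like"] = bool(depth >= kc_depth_mv and dominant
                          and rebound is not None)
    if not out["kc_like"] and (depth < 0.05 or not dominant):
        out["reason"] = "no event"
    return out


def burst_suppression_probe(p: ModelParameters, cfg: SimulationConfig | None = None,
                            excursion_level: float = -55.0,
                            down_level: float = -65.0) -> dict:
    """Noise-driven statistics at an excitable (region VI) operating point.

    The deterministic system rests on the stable silent branch; background
    noise intermittently triggers large excursions around the unstable
    active state — the burst-suppression pattern.  Raises if the supplied
    parameters are not in region VI.
    """
    reg = classify_region(p.excitatory.sigma, p.adaptation.g_KNa, p)
    if reg.label != "VI":
        raise ValueError(
            f"burst suppression requires a region VI point, got {reg.label}"
        )
    cfg = cfg or SimulationConfig(duration=30.0, onset=5.0, seed=0)
    silent = min((e for e in reg.equilibria if e.is_stable), key=lambda e: e.V_e)
    tr = integrate(p, cfg, silent.state).post_onset()
    ve = tr.V_e
    crossings = int(np.sum((ve[1:] > excursion_level)
                           & (ve[:-1] <= excursion_level)))
    down_fraction = float((ve < down_level).mean())
    return {
        "region": reg.label,
        "silent_state_mv": silent.V_e,
        "down_fraction": down_fraction,
        "excursion_count": crossings,
        "duration_s": float(tr.times[-1] - tr.times[0]),
    }
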