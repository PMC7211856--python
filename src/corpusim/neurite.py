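"""Stage 3 — conductance-based point neuron driven by the channel current.

A classic sodium-potassium-leak excitable membrane (squid-axon parameter
set) integrated with a fixed-step fourth-order Runge-Kutta scheme.  All
gating rate constants are multiplied by the temperature factor
``phi = 3^((T - 6.3)/10)``.  The default operating point is T = 5.3 °C
(phi ~ 0.9): together with the transduction saturation it places the
afferent's best 1:1 entrainment band where the calibrated cat pipeline
requires it.  Raising phi speeds the kinetics and raises the entrainment
ceiling until, near phi ~ 8, the equations lose excitability altogether
(heat block) — see docs/methods.md.

The same neuron is used for every species; cross-species differences enter
only through Stage 1 geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import IntegrationError, ValidationError

__all__ = ["NeuronParams", "SpikeTrain", "integrate", "detect_spikes", "firing_rate"]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane constants (µF/cm², mS/cm², mV) and operating temperature."""

    c_m: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.387
    temperature_c: float = 5.3
    membrane_area_cm2: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_k, self.g_leak) < 0:
            raise ValidationError("conductances must be non-negative")
        if self.c_m <= 0 or self.membrane_area_cm2 <= 0:
            raise ValidationError("c_m and membrane_area_cm2 must be positive")

    @property
    def phi(self) -> float:
        """Q10 = 3 rate scaling relative to the 6.3 °C reference."""
        return 3.0 ** ((self.temperature_c - 6.3) / 10.0)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (s) over a recording of known duration."""

    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError("spike times must increase strictly")

    def to_csv(self, path) -> None:
        np.savetxt(path, self.spike_times, header="spike_time_s", comments="")


@njit(cache=True, error_model="numpy")
def _hh_rk4(i_density, dt_ms, phi, c_m, g_na, g_k, g_leak, e_na, e_k, e_leak):
    """RK4 integration of the four-state membrane; returns V (mV) per step."""
    v = -65.0
    am = 0.1 * (v + 40.0) / (1.0 - np.exp(-(v + 40.0) / 10.0))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * (v + 55.0) / (1.0 - np.exp(-(v + 55.0) / 10.0))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)

    nsteps = i_density.shape[0]
    out = np.empty(nsteps)
    y0 = np.empty(4)
    y0[0] = v; y0[1] = m; y0[2] = h; y0[3] = n
    k1 = np.empty(4); k2 = np.empty(4); k3 = np.empty(4); k4 = np.empty(4)
    yt = np.empty(4)

    for step in range(nsteps):
        current = i_density[step]
        _hh_deriv(y0, current, phi, c_m, g_na, g_k, g_leak, e_na, e_k, e_leak, k1)
        for j in range(4):
            yt[j] = y0[j] + 0.5 * dt_ms * k1[j]
        _hh_deriv(yt, current, phi, c_m, g_na, g_k, g_leak, e_na, e_k, e_leak, k2)
        for j in range(4):
            yt[j] = y0[j] + 0.5 * dt_ms * k2[j]
        _hh_deriv(yt, current, phi, c_m, g_na, g_k, g_leak, e_na, e_k, e_leak, k3)
        for j in range(4):
            yt[j] = y0[j] + dt_ms * k3[j]
        _hh_deriv(yt, current, phi, c_m, g_na, g_k, g_leak, e_na, e_k, e_leak, k4)
        for j in range(4):
            y0[j] = y0[j] + (dt_ms / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        for j in range(1, 4):
            if y0[j] < 0.0:
                y0[j] = 0.0
            elif y0[j] > 1.0:
                y0[j] = 1.0
        out[step] = y0[0]
    return out


@njit(cache=True, error_model="numpy")
def _hh_deriv(y, current, phi, c_m, g_na, g_k, g_leak, e_na, e_k, e_leak, out):
    v = y[0]; m = y[1]; h = y[2]; n = y[3]
    dv = v + 40.0
    if np.abs(dv) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * dv / (1.0 - np.exp(-dv / 10.0))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    dn = v + 55.0
    if np.abs(dn) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * dn / (1.0 - np.exp(-dn / 10.0))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    i_ion = (g_na * m * m * m * h * (v - e_na)
             + g_k * n * n * n * n * (v - e_k)
             + g_leak * (v - e_leak))
    out[0] = (current - i_ion) / c_m
    out[1] = phi * (am * (1.0 - m) - bm * m)
    out[2] = phi * (ah * (1.0 - h) - bh * h)
    out[3] = phi * (an * (1.0 - n) - bn * n)


def integrate(i_drive_na: np.ndarray, params: NeuronParams,
              dt: float = 1e-5, duration: float | None = None) -> np.ndarray:
    """Integrate the membrane under a sampled current drive.

    ``i_drive_na`` is the injected current in nA sampled at ``dt`` seconds;
    it is converted to a density via ``membrane_area_cm2``.  Returns the
    membrane voltage (mV) at every step.  Raises
    :class:`IntegrationError` if the state becomes non-finite (reduce dt).
    """
    if dt > 2.5e-5:
        raise ValidationError("dt must be <= 0.025 ms for a stable fourth-order step")
    drive = np.ascontiguousarray(i_drive_na, dtype=float)
    if duration is not None:
        nsteps = int(round(duration / dt))
        if nsteps > drive.size:
            drive = np.concatenate([drive, np.zeros(nsteps - drive.size)])
        else:
            drive = drive[:nsteps]
    density = drive * 1e-3 / params.membrane_area_cm2  # nA -> µA/cm²
    v = _hh_rk4(density, dt * 1e3, params.phi, params.c_m, params.g_na,
                params.g_k, params.g_leak, params.e_na, params.e_k, params.e_leak)
    if not np.isfinite(v[-1]) or not np.isfinite(v).all():
        raise IntegrationError("membrane state became non-finite; use a smaller dt")
    return v


def detect_spikes(v: np.ndarray, dt: float, threshold_mv: float = 0.0,
                  min_isi: float = 1e-3) -> SpikeTrain:
    """Upward threshold crossings, with crossings closer than ``min_isi`` discarded."""
    v = np.asarray(v, dtype=float)
    crossings = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv)) + 1
    times = crossings * dt
    kept: list[float] = []
    last = -np.inf
    for t in times:
        if t - last >= min_isi - 1e-12:
            kept.append(float(t))
            last = t
    return SpikeTrain(spike_times=np.array(kept), duration=v.size * dt)


def firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in ``[t0, t1)`` divided by the window length (Hz)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValidationError("analysis window must satisfy t1 > t0")
    t = train.spike_times
    count = int(np.sum((t >= t0) & (t < t1)))
    return count / (t1 - t0)
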