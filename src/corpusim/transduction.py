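"""Stage 2 — inner-core displacement to mechanosensitive channel current.

The finite-element inner core with its strain-gated filopodial channels is
replaced by a two-step analytic surrogate: a geometric strain reduction

    ``eps(t) = G * max(u_inner(t), 0) / r_core``

(half-wave rectified relative compression of the core; only the compressive
phase gates the channels, which keeps one spike per stimulus cycle the
natural entrainment mode), followed by a hyperbolic saturation converting
strain into cation current

    ``I = I_max * eps / (eps + eps_sat)``.

The saturation ceiling is what limits following at high frequencies: short
compression pulses cannot be compensated by ever-larger amplitudes once the
channel current saturates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["ChannelCurrentParams", "neurite_strain", "channel_current"]


@dataclass(frozen=True)
class ChannelCurrentParams:
    """Saturating strain-to-current conversion.

    ``i_max_na`` is the saturating current (nA), ``eps_sat`` the strain at
    half saturation and ``gain`` the dimensionless strain produced per unit
    relative core compression.  Defaults are fixed, together with the
    neuron's operating temperature, by the single end-to-end calibration of
    the cat pipeline (48 Hz optimum, thresholds in the 0.01-100 µm decade).
    """

    i_max_na: float = 10.0
    eps_sat: float = 0.01
    gain: float = 0.3
    rectification: str = "half"

    def __post_init__(self) -> None:
        if self.i_max_na <= 0 or self.eps_sat <= 0 or self.gain <= 0:
            raise ValidationError("i_max_na, eps_sat and gain must be positive")
        if self.rectification not in ("half", "full"):
            raise ValidationError("rectification must be 'half' or 'full'")


def neurite_strain(u_inner: np.ndarray, r_core: float, gain: float = 0.3,
                   rectification: str = "half") -> np.ndarray:
    """Convert core-surface displacement (m) into neurite membrane strain.

    Linear in the displacement before rectification; non-negative after.
    """
    if r_core <= 0:
        raise ValidationError("r_core must be > 0")
    u = np.asarray(u_inner, dtype=float)
    if rectification == "full":
        u = np.abs(u)
    else:
        u = np.maximum(u, 0.0)
    return gain * u / r_core


def channel_current(eps: np.ndarray | float, params: ChannelCurrentParams) -> np.ndarray | float:
    """Saturating mechanosensitive current (nA) for a non-negative strain."""
    eps_arr = np.asarray(eps, dtype=float)
    if np.any(eps_arr < 0):
        raise ValidationError("strain must be non-negative (rectification happens upstream)")
    out = params.i_max_na * eps_arr / (eps_arr + params.eps_sat)
    return float(out) if np.isscalar(eps) else out
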