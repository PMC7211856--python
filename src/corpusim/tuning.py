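"""End-to-end vibrotactile tuning curves, peak frequency and bandwidth.

For every stimulus frequency the three stages are run in series and the
minimal outer-surface displacement amplitude producing 1:1 entrainment
(steady-state firing rate equal to the stimulus frequency, within
tolerance) is found by bisection over a log-amplitude bracket.  The
threshold-versus-frequency curve is U-shaped: slow stimuli leak through
the fluid films (mechanical high-pass) and fast ones exceed what the
saturating channel current can drive through the afferent, so a best
frequency exists in between.

Features extracted from a curve follow the tuning conventions of the
comparative analysis: the peak frequency is the curve minimum (refined by
golden-section search between the two grid neighbours), and the bandwidth
is the frequency range over which the threshold stays below ``3.5 * A_min``
(lower limit reported as 0 Hz when the lowest tested frequency is already
below the cut-off; upper limit as the highest tested frequency when no
upper crossing exists).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import (NoDetectableBandError, NonMonotoneError,
                         ValidationError)
from .mechanics import transfer_ratio
from .neurite import NeuronParams, detect_spikes, firing_rate, integrate
from .species import CorpuscleGeometry, MaterialParams
from .transduction import ChannelCurrentParams, channel_current, neurite_strain

__all__ = [
    "TuningConfig",
    "TuningCurve",
    "TuningFeatures",
    "Pipeline",
    "threshold_at_frequency",
    "tuning_curve",
    "extract_features",
]

#: Documentation constant: lamellar-count scaling exponent reported for the
#: original finite-element implementation of Stage 1.  Used by property
#: tests as a reference magnitude, never as a model input.
REFERENCE_LAMELLA_EXPONENT = 3.475


def default_freq_grid(n: int = 40) -> np.ndarray:
    """Log-spaced stimulus grid spanning the 2-1000 Hz test range."""
    return np.geomspace(2.0, 1000.0, n)


@dataclass(frozen=True)
class TuningConfig:
    """Search and analysis settings for tuning-curve construction."""

    freq_grid: np.ndarray = field(default_factory=default_freq_grid)
    bandwidth_cutoff: float = 3.5
    entrainment_tol: float = 0.1
    amplitude_bracket_um: tuple[float, float] = (1e-4, 1e3)
    bisection_rel_tol: float = 0.01
    refine_resolution_hz: float = 0.5
    n_cycles: int = 25
    skip_cycles: int = 5
    scan_points: int = 13
    dt: float = 1e-5

    def __post_init__(self) -> None:
        grid = np.asarray(self.freq_grid, dtype=float)
        object.__setattr__(self, "freq_grid", grid)
        if grid.min() < 2.0 - 1e-9 or grid.max() > 1000.0 + 1e-9:
            raise ValidationError("frequency grid must lie within [2, 1000] Hz")
        if self.bandwidth_cutoff <= 1:
            raise ValidationError("bandwidth cutoff must exceed 1")
        lo, hi = self.amplitude_bracket_um
        if not (0 < lo < hi):
            raise ValidationError("invalid amplitude bracket")
        if self.skip_cycles >= self.n_cycles:
            raise ValidationError("need more cycles than discarded transient cycles")


@dataclass(frozen=True)
class TuningCurve:
    """Entrainment threshold (µm) per stimulus frequency.

    Undetectable thresholds (no entrainment within the amplitude bracket)
    are carried as NaN sentinels.
    """

    frequencies_hz: np.ndarray
    thresholds_um: np.ndarray
    species: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        t = np.asarray(self.thresholds_um, dtype=float)
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "thresholds_um", t)
        if f.size != t.size:
            raise ValidationError("frequency and threshold arrays differ in length")
        finite = t[np.isfinite(t)]
        if finite.size and np.any(finite <= 0):
            raise ValidationError("detectable thresholds must be positive")

    @property
    def detectable(self) -> np.ndarray:
        return np.isfinite(self.thresholds_um)

    def is_u_shaped(self) -> bool:
        """True when the curve has a detectable interior minimum.

        Requires a finite minimum that is not at either end of the tested
        grid and that rises on both sides of it.
        """
        t = self.thresholds_um
        if not np.isfinite(t).any():
            return False
        i = int(np.nanargmin(t))
        if i == 0 or i == t.size - 1:
            return False
        left = t[:i][np.isfinite(t[:i])]
        right = t[i + 1:][np.isfinite(t[i + 1:])]
        return (left.size > 0 and right.size > 0
                and left.max() > t[i] and right.max() > t[i])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("frequency_hz,threshold_um,detectable\n")
            for f, t in zip(self.frequencies_hz, self.thresholds_um):
                det = bool(np.isfinite(t))
                t_txt = repr(float(t)) if det else ""
                fh.write(f"{float(f)!r},{t_txt},{str(det).lower()}\n")

    @classmethod
    def from_csv(cls, path: str | Path, species: str | None = None) -> "TuningCurve":
        freqs, ths = [], []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip().split(",")
            if header[:2] != ["frequency_hz", "threshold_um"]:
                raise ValidationError(f"{path}: unexpected tuning-curve header")
            for line in fh:
                parts = line.strip().split(",")
                freqs.append(float(parts[0]))
                ths.append(float(parts[1]) if parts[1] else float("nan"))
        return cls(np.array(freqs), np.array(ths), species=species)


@dataclass(frozen=True)
class TuningFeatures:
    """Summary features of one tuning curve."""

    a_min_um: float
    peak_frequency_hz: float
    band_lo_hz: float
    band_hi_hz: float
    species: str | None = None

    def __post_init__(self) -> None:
        if not (self.band_lo_hz <= self.peak_frequency_hz <= self.band_hi_hz):
            raise ValidationError("band limits must straddle the peak frequency")

    @property
    def band_width_hz(self) -> float:
        return self.band_hi_hz - self.band_lo_hz

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "a_min_um": self.a_min_um,
            "peak_hz": self.peak_frequency_hz,
            "band_lo_hz": self.band_lo_hz,
            "band_hi_hz": self.band_hi_hz,
            "band_width_hz": self.band_width_hz,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class Pipeline:
    """The three stages assembled for one corpuscle.

    Holds the geometry, material, channel and neuron parameters and exposes
    the per-(frequency, amplitude) firing-rate evaluation that the
    threshold search drives.
    """

    def __init__(self, geometry: CorpuscleGeometry,
                 materials: MaterialParams | None = None,
                 channel: ChannelCurrentParams | None = None,
                 neuron: NeuronParams | None = None) -> None:
        self.geometry = geometry
        self.materials = materials or MaterialParams()
        self.channel = channel or ChannelCurrentParams()
        self.neuron = neuron or NeuronParams()

    def with_materials(self, materials: MaterialParams) -> "Pipeline":
        return Pipeline(self.geometry, materials, self.channel, self.neuron)

    def steady_rate(self, frequency_hz: float, amplitude_um: float,
                    cfg: TuningConfig, _transfer: complex | None = None) -> float:
        """Steady-state firing rate for one sinusoidal surface stimulus."""
        T = (_transfer if _transfer is not None else
             transfer_ratio(self.geometry, self.materials, frequency_hz).transfer)
        t = np.arange(0.0, cfg.n_cycles / frequency_hz, cfg.dt)
        u_inner = (amplitude_um * 1e-6 * abs(T)
                   * np.sin(2.0 * math.pi * frequency_hz * t + np.angle(T)))
        eps = neurite_strain(u_inner, self.geometry.core_radius,
                             self.channel.gain, self.channel.rectification)
        i_na = channel_current(eps, self.channel)
        v = integrate(i_na, self.neuron, dt=cfg.dt)
        train = detect_spikes(v, cfg.dt)
        window = (cfg.skip_cycles / frequency_hz, cfg.n_cycles / frequency_hz)
        return firing_rate(train, window)


def threshold_at_frequency(pipeline: Pipeline, frequency_hz: float,
                           cfg: TuningConfig | None = None) -> float:
    """Minimal displacement amplitude (µm) giving 1:1 entrainment at ``f``.

    A coarse log-spaced amplitude scan brackets the lowest crossing of
    ``(1 - tol) * f``; bisection then shrinks the bracket to
    ``bisection_rel_tol``.  Returns NaN when no amplitude inside the bracket
    entrains (the not-detectable sentinel).

    Below the crossing the rate may climb through sub-harmonic locking
    plateaus (1 spike per 2, 3, ... cycles) and need not increase strictly;
    that does not affect the first-crossing semantics.  What would break
    them is a rate *above* the entrainment band at a smaller amplitude than
    the accepted threshold; that raises :class:`NonMonotoneError` naming
    the frequency.
    """
    cfg = cfg or TuningConfig()
    T = transfer_ratio(pipeline.geometry, pipeline.materials, frequency_hz).transfer
    rate = lambda amp: pipeline.steady_rate(frequency_hz, amp, cfg, _transfer=T)
    target = (1.0 - cfg.entrainment_tol) * frequency_hz
    window_s = (cfg.n_cycles - cfg.skip_cycles) / frequency_hz

    lo, hi = cfg.amplitude_bracket_um
    grid = np.geomspace(lo, hi, cfg.scan_points)
    rates: list[float] = []
    hit = None
    for i, amp in enumerate(grid):
        r = rate(amp)
        rates.append(r)
        if r >= target:
            hit = i
            break
    if hit is None:
        return float("nan")
    # bisection premise: no scanned amplitude below the crossing may already
    # have overshot the entrainment band
    ceiling = (1.0 + cfg.entrainment_tol) * frequency_hz + 1.0 / window_s
    for j in range(hit):
        if rates[j] > ceiling:
            raise NonMonotoneError(
                f"rate {rates[j]:.3g} Hz overshoots the entrainment band below the "
                f"bracket at stimulus frequency {frequency_hz:g} Hz")
    if hit == 0:
        threshold = grid[0]
    else:
        a, b = grid[hit - 1], grid[hit]
        while b / a > 1.0 + cfg.bisection_rel_tol:
            mid = math.sqrt(a * b)
            if rate(mid) >= target:
                b = mid
            else:
                a = mid
        threshold = b
    # entrainment, not bursting: the rate at threshold must stay in band
    if rate(threshold) > (1.0 + cfg.entrainment_tol) * frequency_hz:
        return float("nan")
    return float(threshold)


def tuning_curve(pipeline: Pipeline, cfg: TuningConfig | None = None,
                 species: str | None = None) -> TuningCurve:
    """Evaluate the entrainment threshold over the configured grid."""
    cfg = cfg or TuningConfig()
    thresholds = np.array([
        threshold_at_frequency(pipeline, f, cfg) for f in cfg.freq_grid])
    name = species or (pipeline.geometry.species if pipeline else None)
    return TuningCurve(cfg.freq_grid.copy(), thresholds, species=name)


def _log_interp_crossing(f0: float, t0: float, f1: float, t1: float,
                         cutoff: float) -> float:
    """Frequency at which a log-log segment crosses the cut-off threshold."""
    lf0, lf1 = math.log(f0), math.log(f1)
    lt0, lt1 = math.log(t0), math.log(t1)
    lc = math.log(cutoff)
    if lt1 == lt0:
        return math.exp(0.5 * (lf0 + lf1))
    return math.exp(lf0 + (lc - lt0) * (lf1 - lf0) / (lt1 - lt0))


def _refine_peak(threshold_fn, f_lo: float, f_hi: float,
                 resolution_hz: float) -> float:
    """Golden-section minimisation of the threshold between two grid points."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = math.log(f_lo), math.log(f_hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = threshold_fn(math.exp(c)), threshold_fn(math.exp(d))
    while math.exp(b) - math.exp(a) > resolution_hz:
        if not math.isfinite(fc) or (math.isfinite(fd) and fd < fc):
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = threshold_fn(math.exp(d))
        else:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = threshold_fn(math.exp(c))
    return math.exp(0.5 * (a + b))


def extract_features(curve: TuningCurve, cfg: TuningConfig | None = None,
                     threshold_fn=None) -> TuningFeatures:
    """Peak frequency, minimum threshold and 3.5x bandwidth of a curve.

    ``threshold_fn(f) -> µm``, when given, refines the peak between the two
    grid neighbours of the argmin by golden-section search down to
    ``refine_resolution_hz``; otherwise the grid argmin is reported.  Band
    limits are located by log-log interpolation between grid neighbours at
    the ``bandwidth_cutoff * A_min`` crossing; the lower limit is 0 Hz when
    the lowest tested frequency is already below the cut-off, the upper
    limit the highest tested frequency when no crossing exists.
    """
    cfg = cfg or TuningConfig()
    f = curve.frequencies_hz
    t = curve.thresholds_um
    if not np.isfinite(t).any():
        raise NoDetectableBandError(
            f"tuning curve{' for ' + curve.species if curve.species else ''} "
            "has no detectable thresholds")
    i_min = int(np.nanargmin(t))
    a_min = float(t[i_min])
    peak = float(f[i_min])
    if threshold_fn is not None and 0 < i_min < f.size - 1:
        peak = _refine_peak(threshold_fn, f[i_min - 1], f[i_min + 1],
                            cfg.refine_resolution_hz)
    cutoff = cfg.bandwidth_cutoff * a_min

    # lower limit: walk outward from the minimum
    band_lo = 0.0
    for j in range(i_min, 0, -1):
        prev = t[j - 1]
        if not math.isfinite(prev) or prev >= cutoff:
            if math.isfinite(prev) and math.isfinite(t[j]):
                band_lo = _log_interp_crossing(f[j - 1], prev, f[j], t[j], cutoff)
            else:
                band_lo = float(f[j])
            break
    band_hi = float(f[-1])
    for j in range(i_min, f.size - 1):
        nxt = t[j + 1]
        if not math.isfinite(nxt) or nxt >= cutoff:
            if math.isfinite(nxt) and math.isfinite(t[j]):
                band_hi = _log_interp_crossing(f[j], t[j], f[j + 1], nxt, cutoff)
            else:
                band_hi = float(f[j])
            break
    band_lo = min(band_lo, peak)
    band_hi = max(band_hi, peak)
    return TuningFeatures(a_min_um=a_min, peak_frequency_hz=peak,
                          band_lo_hz=band_lo, band_hi_hz=band_hi,
                          species=curve.species)


def peak_evaluator(cfg: TuningConfig | None = None,
                   channel: ChannelCurrentParams | None = None,
                   neuron: NeuronParams | None = None):
    """Build the ``(geometry, materials) -> peak Hz`` closure used by
    :func:`corpusim.mechanics.calibrate_kappa`."""
    cfg = cfg or TuningConfig(freq_grid=np.geomspace(15.0, 200.0, 11))

    def evaluate(geometry: CorpuscleGeometry, materials: MaterialParams) -> float:
        pipe = Pipeline(geometry, materials, channel, neuron)
        curve = tuning_curve(pipe, cfg)
        try:
            return extract_features(
                curve, cfg,
                threshold_fn=lambda fr: threshold_at_frequency(pipe, fr, cfg),
            ).peak_frequency_hz
        except NoDetectableBandError:
            # nothing entrains inside the search window: the optimum lies
            # far above it (films too weak to transmit), so report +inf and
            # let the calibration bisection push kappa upward
            return float("inf")

    return evaluate
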