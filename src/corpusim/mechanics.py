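"""Stage 1 — frequency-domain transmission through the lamellated outer core.

The outer core is modelled as ``N`` thin spherical shells coupled by viscous
squeeze films.  Each shell contributes a membrane restoring stiffness per
unit area

    ``k = 2 E h / ((1 - nu^2) r^2)``

and each fluid film a squeeze-film damping per unit area

    ``c = kappa * mu * r^2 / g^3``

where ``g`` is the film width and ``r`` the film's mid radius; ``kappa`` is
a single dimensionless constant absorbing the mode-2 shape factors, fitted
once against the cat corpuscle (see :func:`calibrate_kappa`).  Shell inertia
is neglected (micrometre scale, fluid-dominated below 1 kHz), so the
harmonic balance for lamella ``i`` with complex amplitude ``U_i`` is

    ``k_i U_i + i*omega*[c_{i-1}(U_i - U_{i-1}) + c_i(U_i - U_{i+1})] = 0``

with the outer surface driven at the prescribed mode-2 displacement
amplitude ``A`` (``U_{N+1} = A``) and the core surface ``U_0`` resisted by a
nearly rigid core backing.  This is a tridiagonal complex linear system; its
solution gives the transfer ratio ``T = U_0 / A``, a high-pass filter: slow
indentations leak through the films while fast ones are transmitted to the
core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .exceptions import CalibrationError, NumericalError, ValidationError
from .species import CorpuscleGeometry, MaterialParams

__all__ = [
    "DriveSpec",
    "TransferResult",
    "shell_stiffness",
    "film_damping",
    "transfer_ratio",
    "calibrate_kappa",
]

#: Factor by which the core backing stiffness exceeds the stiffest lamella.
CORE_STIFFNESS_FACTOR = 10.0


@dataclass(frozen=True)
class DriveSpec:
    """Sinusoidal mode-2 displacement drive of the outermost surface."""

    frequency_hz: float
    amplitude_m: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValidationError("drive frequency must be > 0")
        if self.amplitude_m < 0:
            raise ValidationError("drive amplitude must be >= 0")


@dataclass(frozen=True)
class TransferResult:
    """Complex transfer ratio and per-layer amplitudes.

    ``layer_amplitudes[0]`` is the core-surface amplitude ``U_0`` (metres),
    followed by the ``N`` lamellae inner to outer.  ``transfer`` is the
    dimensionless ``U_0 / A``.
    """

    transfer: complex
    layer_amplitudes: np.ndarray
    residual: float


def shell_stiffness(youngs_modulus: float, thickness: float, radius: float,
                    poisson_ratio: float) -> float:
    """Membrane restoring stiffness per unit area of a thin spherical shell.

    ``k = 2 E h / ((1 - nu^2) r^2)`` — linear in modulus and thickness,
    inverse-square in radius.  Mode-shape factors are absorbed in the
    film constant ``kappa``.
    """
    if radius <= 0:
        raise ValidationError("shell radius must be > 0")
    if youngs_modulus <= 0 or thickness < 0:
        raise ValidationError("need E > 0 and h >= 0")
    return 2.0 * youngs_modulus * thickness / ((1.0 - poisson_ratio ** 2) * radius ** 2)


def film_damping(viscosity: float, radius: float, gap: float, kappa: float) -> float:
    """Squeeze-film damping per unit area of a thin fluid layer.

    ``c = kappa * mu * r^2 / g^3`` — the lubrication scaling for fluid
    squeezed over a lateral length ~``r`` out of a gap ``g``.
    """
    if gap <= 0:
        raise ValidationError("film gap must be > 0")
    if viscosity < 0 or radius <= 0 or kappa <= 0:
        raise ValidationError("need mu >= 0, r > 0, kappa > 0")
    return kappa * viscosity * radius ** 2 / gap ** 3


def _film_radii(geometry: CorpuscleGeometry) -> np.ndarray:
    """Mid radius of every film, core film first, outer film last."""
    surfaces = np.concatenate((
        [geometry.core_radius], geometry.mid_radii, [geometry.outer_radius]))
    return 0.5 * (surfaces[:-1] + surfaces[1:])


def stiffness_damping_arrays(
        geometry: CorpuscleGeometry, materials: MaterialParams,
        core_stiffness: float | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-lamella stiffnesses, per-film dampings and the core stiffness."""
    k = np.array([
        shell_stiffness(materials.youngs_modulus, h, r, materials.poisson_ratio)
        for h, r in zip(geometry.thicknesses, geometry.mid_radii)])
    c = np.array([
        film_damping(materials.viscosity, r, g, materials.kappa)
        for r, g in zip(_film_radii(geometry), geometry.gap_widths)])
    if core_stiffness is None:
        core_stiffness = CORE_STIFFNESS_FACTOR * float(k.max())
    return k, c, core_stiffness


def transfer_ratio(geometry: CorpuscleGeometry, materials: MaterialParams,
                   frequency_hz: float, amplitude_m: float = 1.0,
                   core_stiffness: float | None = None) -> TransferResult:
    """Solve the shell/film harmonic balance at one frequency.

    Returns the complex core/outer displacement ratio ``T`` and all layer
    amplitudes.  The assembled tridiagonal system is verified to a relative
    residual below 1e-10.
    """
    if frequency_hz <= 0:
        raise ValidationError("frequency must be > 0")
    k, c, k_core = stiffness_damping_arrays(geometry, materials, core_stiffness)
    n = geometry.n_lamellae
    omega = 2.0 * math.pi * frequency_hz
    jwc = 1j * omega * c

    diag = np.empty(n + 1, dtype=complex)
    upper = np.empty(n, dtype=complex)
    lower = np.empty(n, dtype=complex)
    rhs = np.zeros(n + 1, dtype=complex)
    diag[0] = k_core + jwc[0]
    upper[:] = -jwc[:-1]
    lower[:] = -jwc[:-1]
    diag[1:] = k + jwc[:-1] + jwc[1:]
    rhs[-1] = jwc[-1] * amplitude_m

    if np.all(np.abs(diag) == 0.0):
        raise NumericalError("singular shell/film system: all impedances vanish")
    ab = np.zeros((3, n + 1), dtype=complex)
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    u = solve_banded((1, 1), ab, rhs)

    # residual of the assembled equations, relative to the drive term
    resid = diag * u
    resid[:-1] += upper * u[1:]
    resid[1:] += lower * u[:-1]
    resid -= rhs
    scale = float(np.abs(rhs[-1])) or 1.0
    residual = float(np.max(np.abs(resid)) / scale)
    if residual > 1e-10:
        raise NumericalError(f"linear solve residual {residual:.2e} exceeds 1e-10")

    amp = amplitude_m if amplitude_m != 0 else 1.0
    return TransferResult(transfer=complex(u[0] / amp), layer_amplitudes=u, residual=residual)


def transfer_magnitude(geometry: CorpuscleGeometry, materials: MaterialParams,
                       frequencies_hz: np.ndarray, **kw) -> np.ndarray:
    """|T| sampled over a frequency grid (convenience for sweeps and export)."""
    return np.array([
        abs(transfer_ratio(geometry, materials, f, **kw).transfer)
        for f in np.asarray(frequencies_hz, dtype=float)])


def export_transfer_sweep(geometry: CorpuscleGeometry, materials: MaterialParams,
                          frequencies_hz, path, **kw) -> None:
    """Write a frequency sweep as CSV (``frequency_hz,T_abs,T_phase_rad``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frequency_hz,T_abs,T_phase_rad\n")
        for f in np.asarray(frequencies_hz, dtype=float):
            t = transfer_ratio(geometry, materials, f, **kw).transfer
            fh.write(f"{f!r},{abs(t)!r},{math.atan2(t.imag, t.real)!r}\n")


def calibrate_kappa(geometry: CorpuscleGeometry, materials: MaterialParams,
                    peak_evaluator, target_peak_hz: float,
                    bracket: tuple[float, float] = (1e-3, 1e2),
                    rel_tol: float = 0.02, max_iter: int = 60) -> float:
    """Fit the single squeeze-film constant against a target peak frequency.

    ``peak_evaluator(geometry, materials) -> Hz`` must run the full
    three-stage pipeline and return the tuning-curve peak; the peak must be
    monotone non-increasing in ``kappa`` over the bracket (stronger films
    transmit lower frequencies).  Bisection on ``log kappa`` stops when the
    evaluated peak is within ``rel_tol`` of the target.

    Raises :class:`CalibrationError`, reporting the achievable range, when
    the bracket does not straddle the target.
    """
    if not (2.0 <= target_peak_hz <= 1000.0):
        raise ValidationError("target peak must lie within the 2-1000 Hz stimulus range")
    from dataclasses import replace

    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValidationError("invalid kappa bracket")

    def peak_at(kappa: float) -> float:
        return float(peak_evaluator(geometry, replace(materials, kappa=kappa)))

    p_lo, p_hi = peak_at(lo), peak_at(hi)
    if not (p_lo >= target_peak_hz >= p_hi):
        raise CalibrationError(
            f"target {target_peak_hz} Hz outside achievable peak range "
            f"[{p_hi:.3g}, {p_lo:.3g}] Hz for kappa in [{lo:g}, {hi:g}]")
    a, b = math.log(lo), math.log(hi)
    kappa = math.sqrt(lo * hi)
    for _ in range(max_iter):
        kappa = math.exp(0.5 * (a + b))
        peak = peak_at(kappa)
        if abs(peak - target_peak_hz) <= rel_tol * target_peak_hz:
            return kappa
        if peak > target_peak_hz:
            a = math.log(kappa)
        else:
            b = math.log(kappa)
    raise CalibrationError(
        f"bisection did not reach {target_peak_hz} Hz within {max_iter} iterations "
        "(peak may be insensitive to kappa near the target)")
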