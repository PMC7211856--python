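"""Synthetic corpuscle populations, regression data and analytic fixtures.

The population generator emulates the statistical structure observed across
the 19-animal table: outer radii spread log-uniformly over roughly two
orders of magnitude (4-320 µm), lamella counts increasing with radius with
enough scatter to land the population r² near the reported 0.43, lamellar
thickness proportional to radius with a wide lognormal scatter (weak
correlation, target near 0.23), and body mass independent of every
corpuscle measurement (no mass-structure correlation).  All generators are
pure functions of their spec, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .mechanics import film_damping, shell_stiffness
from .species import (CorpuscleGeometry, LayoutPolicy, MaterialParams,
                      SpeciesRecord, layered_geometry)

__all__ = [
    "PopulationSpec",
    "gen_population",
    "gen_regression_dataset",
    "single_layer_fixture",
    "SingleLayerFixture",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional assumptions for a synthetic corpuscle population."""

    n: int
    seed: int = 0
    radius_range_um: tuple[float, float] = (4.0, 320.0)
    lamellae_intercept: float = 15.0
    lamellae_per_um: float = 0.05
    lamellae_noise_sd: float = 6.0
    thickness_fraction: float = 0.02
    thickness_log_sd: float = 0.8
    log10_mass_range: tuple[float, float] = (-2.0, 4.6)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("population size must be >= 0")
        lo, hi = self.radius_range_um
        if not (0 < lo < hi):
            raise ValidationError("invalid radius range")


def gen_population(spec: PopulationSpec) -> list[SpeciesRecord]:
    """Draw a validated synthetic species table (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.radius_range_um
    radii = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.n))
    n_lam = np.round(
        spec.lamellae_intercept + spec.lamellae_per_um * radii
        + rng.normal(0.0, spec.lamellae_noise_sd, spec.n)).astype(int)
    n_lam = np.clip(n_lam, 5, None)
    thick = (spec.thickness_fraction * radii
             * np.exp(rng.normal(0.0, spec.thickness_log_sd, spec.n)))
    mass = 10.0 ** rng.uniform(*spec.log10_mass_range, spec.n)
    records = []
    for i in range(spec.n):
        records.append(SpeciesRecord(
            common_name=f"synthetic-{i:04d}",
            species_name=f"Simulatus corpusculi {i:04d}",
            mass_kg=float(mass[i]),
            outer_radius=float(radii[i]),
            radius_unit="um",
            n_lamellae=int(n_lam[i]),
            lamellar_thickness=float(thick[i]),
            thickness_unit="um",
            taxonomic_class="mammal",
            habitat="terrestrial",
            source_note="synthetic population draw",
        ))
    return records


def gen_regression_dataset(slope: float, intercept: float, sigma: float,
                           n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Straight line plus Gaussian noise: ``y = slope*x + intercept + N(0, sigma)``."""
    if n < 3:
        raise ValidationError("need n >= 3")
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 10.0, n)
    y = slope * x + intercept + rng.normal(0.0, sigma, n)
    return x, y


@dataclass(frozen=True)
class SingleLayerFixture:
    """Single-lamella geometry with its closed-form transfer magnitude.

    The core backing stiffness is set to zero so the core rides rigidly
    with the single lamella; the solver's transfer must then equal the
    one-pole high-pass ``|T| = omega*c / sqrt(k^2 + (omega*c)^2)``.
    """

    geometry: CorpuscleGeometry
    materials: MaterialParams
    core_stiffness: float
    k: float
    c: float

    def closed_form(self, frequency_hz: float) -> float:
        w = 2.0 * math.pi * frequency_hz
        return w * self.c / math.hypot(self.k, w * self.c)

    @property
    def corner_frequency_hz(self) -> float:
        """Frequency at which the closed form equals 1/sqrt(2)."""
        return self.k / (2.0 * math.pi * self.c)


def single_layer_fixture(k: float, c: float) -> SingleLayerFixture:
    """Construct an N=1 oracle geometry realising given k (Pa/m) and c (Pa·s/m).

    The lamella thickness is chosen so the shell stiffness equals ``k`` and
    the film constant kappa so the outer film damping equals ``c``.
    """
    if k <= 0 or c <= 0:
        raise ValidationError("k and c must be positive")
    R_um, nu, E, mu = 100.0, 0.49, 1400.0, 3.5e-3
    layout = LayoutPolicy(core_fraction=0.2)
    r_mid = (layout.core_fraction * R_um + R_um) / 2.0 * 1e-6  # single mid radius
    h = k * (1.0 - nu ** 2) * r_mid ** 2 / (2.0 * E)
    geometry = layered_geometry(R_um, 1, h * 1e6, layout)
    outer_film_r = 0.5 * (geometry.mid_radii[-1] + geometry.outer_radius)
    g = geometry.gap_widths[-1]
    kappa = c * g ** 3 / (mu * outer_film_r ** 2)
    materials = MaterialParams(youngs_modulus=E, viscosity=mu,
                               poisson_ratio=nu, kappa=kappa)
    k_real = shell_stiffness(E, float(geometry.thicknesses[0]),
                             float(geometry.mid_radii[0]), nu)
    c_real = film_damping(mu, float(outer_film_r), float(g), kappa)
    return SingleLayerFixture(geometry=geometry, materials=materials,
                              core_stiffness=0.0, k=k_real, c=c_real)
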