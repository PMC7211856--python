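"""Species morphometry records and layered corpuscle geometry.

A lamellar corpuscle (Pacinian corpuscle in mammals and other tetrapods,
Herbst corpuscle in birds) is described here by the three structural
parameters that comparative histology provides: outer radius ``R``, number
of outer-core lamellae ``N`` and average lamellar thickness ``h``.  From
those this module builds the concentric-layer geometry consumed by
:mod:`corpusim.mechanics`: ``N`` elastic shells at uniformly spaced mid
radii between the inner-core surface and the outer surface, separated by
viscous fluid films whose widths are the residual spacing.

Records measured from micrographs without a scale bar carry lengths in
pixels.  Absolute lengths are then unknown, but the simulator only depends
on the thickness/radius ratio, so pixel records can be simulated at a
nominal radius (see :class:`LayoutPolicy.nominal_radius_um`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import GeometryError, ValidationError

__all__ = [
    "SpeciesRecord",
    "LayoutPolicy",
    "CorpuscleGeometry",
    "MaterialParams",
    "load_species_table",
    "save_species_table",
    "build_geometry",
    "packaged_species_table",
]

_CLASSES = {"mammal", "bird", "reptile", "amphibian"}
_HABITATS = {"terrestrial", "aquatic"}
_UNITS = {"um", "px"}

#: Global squeeze-film calibration constant, fitted once so that the full
#: pipeline's peak frequency for the cat geometry matches the cat's reported
#: 48 Hz optimum (see :func:`corpusim.mechanics.calibrate_kappa`).  It is the
#: package's single fitted constant and is frozen for all species.
CALIBRATED_KAPPA = 0.0438


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' corpuscle morphometry plus reference outputs.

    ``reported_peak_hz`` / ``reported_bandwidth_hz`` are carried as
    reference data for comparison; they are never used as model inputs.
    """

    common_name: str
    species_name: str
    mass_kg: float
    outer_radius: float
    radius_unit: str
    n_lamellae: int
    lamellar_thickness: float
    thickness_unit: str
    taxonomic_class: str
    habitat: str | None = None
    reported_peak_hz: float | None = None
    reported_bandwidth_hz: float | None = None
    source_note: str = ""

    def __post_init__(self) -> None:
        ctx = f"record {self.common_name!r}"
        if not (self.mass_kg > 0):
            raise ValidationError(f"{ctx}: mass_kg must be > 0")
        if not (self.outer_radius > 0):
            raise ValidationError(f"{ctx}: outer_radius must be > 0")
        if not (self.lamellar_thickness > 0):
            raise ValidationError(f"{ctx}: lamellar_thickness must be > 0")
        if self.n_lamellae < 1:
            raise ValidationError(f"{ctx}: n_lamellae must be >= 1")
        if self.radius_unit not in _UNITS or self.thickness_unit not in _UNITS:
            raise ValidationError(f"{ctx}: units must be one of {sorted(_UNITS)}")
        if self.radius_unit != self.thickness_unit:
            # a micrograph without a scale bar affects both length fields
            raise ValidationError(f"{ctx}: radius and thickness unit flags disagree")
        if self.taxonomic_class not in _CLASSES:
            raise ValidationError(f"{ctx}: unknown taxonomic class {self.taxonomic_class!r}")
        if self.habitat is not None and self.habitat not in _HABITATS:
            raise ValidationError(f"{ctx}: unknown habitat {self.habitat!r}")

    @property
    def is_pixel_record(self) -> bool:
        return self.radius_unit == "px"

    @property
    def thickness_ratio(self) -> float:
        """Dimensionless lamellar thickness / outer radius (unit-free)."""
        return self.lamellar_thickness / self.outer_radius


@dataclass(frozen=True)
class LayoutPolicy:
    """How to place lamellae that morphometry does not localise.

    Per-lamella radial positions are not available from comparative
    histology, so lamella mid radii are spaced uniformly on
    ``[r_core, R]`` with ``r_core = core_fraction * R`` and fluid gaps set
    to the residual spacing.  ``min_gap_fallback`` rescues geometries whose
    lamellae are thicker than the uniform spacing by packing them inward
    from the outer surface with a fixed film width of
    ``min_gap_fraction * h``, letting the core shrink instead.
    """

    core_fraction: float = 0.2
    nominal_radius_um: float = 100.0
    min_gap_fallback: bool = False
    min_gap_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.core_fraction < 1):
            raise ValidationError("core_fraction must lie in (0, 1)")
        if self.nominal_radius_um <= 0:
            raise ValidationError("nominal_radius_um must be > 0")


@dataclass(frozen=True)
class CorpuscleGeometry:
    """Concentric-layer layout in SI metres, inner to outer.

    ``gap_widths[0]`` is the film above the core surface, ``gap_widths[i]``
    the film between lamellae ``i`` and ``i+1`` and ``gap_widths[-1]`` the
    film under the driven outer surface.
    """

    outer_radius: float
    core_radius: float
    mid_radii: np.ndarray
    thicknesses: np.ndarray
    gap_widths: np.ndarray
    species: str | None = None
    pixel_ratio_mode: bool = False

    def __post_init__(self) -> None:
        r = np.asarray(self.mid_radii, dtype=float)
        h = np.asarray(self.thicknesses, dtype=float)
        g = np.asarray(self.gap_widths, dtype=float)
        object.__setattr__(self, "mid_radii", r)
        object.__setattr__(self, "thicknesses", h)
        object.__setattr__(self, "gap_widths", g)
        n = r.size
        if h.size != n or g.size != n + 1:
            raise GeometryError("expected N mid radii, N thicknesses, N+1 gaps")
        if not (0 < self.core_radius < self.outer_radius):
            raise GeometryError("need 0 < core_radius < outer_radius")
        if np.any(h <= 0) or np.any(g <= 0):
            raise GeometryError("all thicknesses and gap widths must be positive")
        if np.any(np.diff(r) <= 0) or r[0] <= self.core_radius or r[-1] > self.outer_radius:
            raise GeometryError("mid radii must increase strictly within (core_radius, outer_radius]")
        span = self.outer_radius - self.core_radius
        if not math.isclose(float(h.sum() + g.sum()), span, rel_tol=1e-12, abs_tol=0.0):
            raise GeometryError("thicknesses plus gaps do not tile the annulus")

    @property
    def n_lamellae(self) -> int:
        return int(self.mid_radii.size)

    def scaled(self, factor: float) -> "CorpuscleGeometry":
        """Return the geometry with every length multiplied by ``factor``."""
        return replace(
            self,
            outer_radius=self.outer_radius * factor,
            core_radius=self.core_radius * factor,
            mid_radii=self.mid_radii * factor,
            thicknesses=self.thicknesses * factor,
            gap_widths=self.gap_widths * factor,
        )


@dataclass(frozen=True)
class MaterialParams:
    """Lamellar elasticity and interlamellar fluid properties.

    Defaults: lamellar Young's modulus 1.4 kPa (measured on human corpuscle
    capsules), interlamellar viscosity 3.5 mPa s (about five times water at
    body temperature), Poisson ratio 0.49 (nearly incompressible soft
    tissue) and the calibrated squeeze-film constant ``kappa``.
    """

    youngs_modulus: float = 1400.0
    viscosity: float = 3.5e-3
    poisson_ratio: float = 0.49
    kappa: float = CALIBRATED_KAPPA

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0 or self.viscosity <= 0 or self.kappa <= 0:
            raise ValidationError("E, mu and kappa must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValidationError("poisson_ratio must lie in [0, 0.5)")


_HEADER = [
    "common_name", "species_name", "mass_kg", "outer_radius", "radius_unit",
    "n_lamellae", "lamellar_thickness", "thickness_unit", "class", "habitat",
    "reported_peak_hz", "reported_bandwidth_hz", "source",
]


def packaged_species_table() -> Path:
    """Path of the packaged species morphometry table (19 animals)."""
    return Path(resources.files("corpusim").joinpath("data/species_table.csv"))


def _parse_float(value: str, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"row {row}, column {column!r}: non-numeric value {value!r}") from None


def load_species_table(path: str | Path | None = None) -> list[SpeciesRecord]:
    """Load and validate a species table CSV.

    With no argument, loads the packaged 19-animal table.  Raises
    :class:`ValidationError` naming the offending row and column on any
    missing column, non-numeric cell or non-positive measurement.
    """
    path = packaged_species_table() if path is None else Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        missing = set(_HEADER) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        records: list[SpeciesRecord] = []
        for i, row in enumerate(reader, start=2):
            try:
                rec = SpeciesRecord(
                    common_name=row["common_name"],
                    species_name=row["species_name"],
                    mass_kg=_parse_float(row["mass_kg"], i, "mass_kg"),
                    outer_radius=_parse_float(row["outer_radius"], i, "outer_radius"),
                    radius_unit=row["radius_unit"],
                    n_lamellae=int(_parse_float(row["n_lamellae"], i, "n_lamellae")),
                    lamellar_thickness=_parse_float(row["lamellar_thickness"], i, "lamellar_thickness"),
                    thickness_unit=row["thickness_unit"],
                    taxonomic_class=row["class"],
                    habitat=row["habitat"] or None,
                    reported_peak_hz=(
                        _parse_float(row["reported_peak_hz"], i, "reported_peak_hz")
                        if row["reported_peak_hz"] else None),
                    reported_bandwidth_hz=(
                        _parse_float(row["reported_bandwidth_hz"], i, "reported_bandwidth_hz")
                        if row["reported_bandwidth_hz"] else None),
                    source_note=row["source"],
                )
            except ValidationError as err:
                raise ValidationError(f"{path}, row {i}: {err}") from None
            records.append(rec)
    if not records:
        raise ValidationError(f"{path}: no data rows")
    return records


def save_species_table(records: list[SpeciesRecord], path: str | Path) -> None:
    """Write records in the same CSV dialect that :func:`load_species_table` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for r in records:
            writer.writerow([
                r.common_name, r.species_name, repr(r.mass_kg), repr(r.outer_radius),
                r.radius_unit, r.n_lamellae, repr(r.lamellar_thickness), r.thickness_unit,
                r.taxonomic_class, r.habitat or "",
                "" if r.reported_peak_hz is None else repr(r.reported_peak_hz),
                "" if r.reported_bandwidth_hz is None else repr(r.reported_bandwidth_hz),
                r.source_note,
            ])


def _layered(R_m: float, n: int, h_m: float, layout: LayoutPolicy,
             species: str | None, pixel_mode: bool) -> CorpuscleGeometry:
    r_core = layout.core_fraction * R_m
    spacing = (R_m - r_core) / (n + 1)
    if h_m < spacing:
        mid = r_core + spacing * np.arange(1, n + 1)
        gaps = np.empty(n + 1)
        gaps[0] = spacing - h_m / 2
        gaps[1:-1] = spacing - h_m
        gaps[-1] = spacing - h_m / 2
    elif layout.min_gap_fallback:
        # lamellae thicker than the uniform spacing: pack inward from the
        # outer surface with a fixed thin film, letting the core shrink
        g = layout.min_gap_fraction * h_m
        mid = R_m - g - h_m / 2 - (g + h_m) * np.arange(n - 1, -1, -1)
        r_core = mid[0] - h_m / 2 - g
        if r_core <= 0:
            raise GeometryError(
                f"{species or 'geometry'}: lamellar stack exceeds the outer radius "
                "even with the minimum-gap fallback")
        gaps = np.full(n + 1, g)
    else:
        raise GeometryError(
            f"{species or 'geometry'}: lamellar thickness {h_m:.3g} m is not smaller than "
            f"the uniform spacing {spacing:.3g} m (enable the minimum-gap fallback to pack inward)")
    return CorpuscleGeometry(
        outer_radius=R_m, core_radius=r_core, mid_radii=mid,
        thicknesses=np.full(n, h_m), gap_widths=gaps,
        species=species, pixel_ratio_mode=pixel_mode)


def build_geometry(record: SpeciesRecord, layout: LayoutPolicy | None = None) -> CorpuscleGeometry:
    """Construct the simulation geometry for one species record.

    Micrometre records use their measured lengths.  Pixel records are
    simulated through the unit-free thickness/radius ratio at
    ``layout.nominal_radius_um`` and flagged ``pixel_ratio_mode=True``.
    """
    layout = layout or LayoutPolicy()
    if record.is_pixel_record:
        R_m = layout.nominal_radius_um * 1e-6
        h_m = record.thickness_ratio * R_m
        pixel_mode = True
    else:
        R_m = record.outer_radius * 1e-6
        h_m = record.lamellar_thickness * 1e-6
        pixel_mode = False
    return _layered(R_m, record.n_lamellae, h_m, layout, record.common_name, pixel_mode)


def layered_geometry(outer_radius_um: float, n_lamellae: int, thickness_um: float,
                     layout: LayoutPolicy | None = None) -> CorpuscleGeometry:
    """Build a geometry directly from the three structural parameters (µm)."""
    layout = layout or LayoutPolicy()
    return _layered(outer_radius_um * 1e-6, n_lamellae, thickness_um * 1e-6,
                    layout, None, False)
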