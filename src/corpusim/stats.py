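"""Cross-species regression battery for corpuscle morphometry.

Ordinary least squares with a two-tailed t-test on the slope
(df = n - 2), applied to the structural relations of the comparative
analysis: corpuscle measurements against animal mass (no relation is
expected) and against corpuscle outer radius (lamellar organisation is
expected to follow corpuscle size).  Records whose lengths were measured in
pixels are excluded from any regression mixing absolute lengths; the
dimensionless thickness/radius ratio uses every record.

Animal mass enters untransformed by default.  The masses span more than
five orders of magnitude, so a log10 regressor is also provided
(``mass_transform='log10'``); the linear regressor is the one whose
sub-analysis p-values match the published values and is therefore the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError
from .species import SpeciesRecord

__all__ = ["RegressionResult", "ols", "structural_regressions", "results_to_frame"]


@dataclass(frozen=True)
class RegressionResult:
    """One fitted line with its significance test and exclusion bookkeeping."""

    x_name: str
    y_name: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_two_tailed: float
    excluded: tuple[tuple[str, str], ...] = ()  # (species, reason)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("regression needs n >= 3")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared outside [0, 1]")
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValidationError("p outside [0, 1]")


def ols(x, y, x_name: str = "x", y_name: str = "y",
        excluded: tuple[tuple[str, str], ...] = ()) -> RegressionResult:
    """Least-squares line with r² and the slope's two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y differ in length")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in regression input")
    if np.ptp(x) == 0.0:
        raise ValidationError("zero variance in x")
    fit = sps.linregress(x, y)
    return RegressionResult(
        x_name=x_name, y_name=y_name, n=int(x.size),
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), p_two_tailed=float(fit.pvalue),
        excluded=excluded)


def _mass(values: np.ndarray, transform: str) -> tuple[np.ndarray, str]:
    if transform == "linear":
        return values, "mass_kg"
    if transform == "log10":
        return np.log10(values), "log10_mass_kg"
    raise ValidationError(f"unknown mass transform {transform!r}")


def structural_regressions(records: list[SpeciesRecord],
                           mass_transform: str = "linear") -> list[RegressionResult]:
    """Run the full structural regression battery on a species table.

    Returns, in order: radius~mass, thickness~mass, thickness/radius~mass,
    n_lamellae~mass, thickness~radius, n_lamellae~radius, and the mammal
    sub-analyses radius~mass (all mammals, terrestrial mammals only).
    Pixel-unit records are excluded wherever an absolute length enters.
    """
    total = len(records)
    um = [r for r in records if not r.is_pixel_record]
    px_excl = tuple((r.common_name, "lengths measured in pixels")
                    for r in records if r.is_pixel_record)

    def masses(rs):
        return _mass(np.array([r.mass_kg for r in rs]), mass_transform)

    results: list[RegressionResult] = []

    def run(rs, x, y, x_name, y_name, excl):
        if len(rs) < 3:
            raise ValidationError(
                f"regression {y_name} ~ {x_name}: fewer than 3 usable records")
        results.append(ols(x, y, x_name=x_name, y_name=y_name, excluded=tuple(excl)))

    m_um, m_name = masses(um)
    run(um, m_um, [r.outer_radius for r in um], m_name, "outer_radius_um", px_excl)
    run(um, m_um, [r.lamellar_thickness for r in um], m_name, "lamellar_thickness_um", px_excl)

    m_all, _ = masses(records)
    run(records, m_all, [r.thickness_ratio for r in records], m_name, "thickness_radius_ratio", ())
    run(records, m_all, [r.n_lamellae for r in records], m_name, "n_lamellae", ())

    radii = np.array([r.outer_radius for r in um])
    run(um, radii, [r.lamellar_thickness for r in um],
        "outer_radius_um", "lamellar_thickness_um", px_excl)
    run(um, radii, [r.n_lamellae for r in um], "outer_radius_um", "n_lamellae", px_excl)

    mammals = [r for r in um if r.taxonomic_class == "mammal"]
    mam_excl = px_excl + tuple(
        (r.common_name, "not a mammal") for r in records
        if not r.is_pixel_record and r.taxonomic_class != "mammal")
    m_mam, _ = masses(mammals)
    run(mammals, m_mam, [r.outer_radius for r in mammals],
        m_name, "outer_radius_um_mammals", mam_excl)

    terrestrial = [r for r in mammals if r.habitat == "terrestrial"]
    terr_excl = mam_excl + tuple(
        (r.common_name, "aquatic mammal") for r in mammals if r.habitat != "terrestrial")
    m_ter, _ = masses(terrestrial)
    run(terrestrial, m_ter, [r.outer_radius for r in terrestrial],
        m_name, "outer_radius_um_terrestrial_mammals", terr_excl)

    # bookkeeping: usable plus excluded covers the whole table
    for res in results:
        if res.n + len(res.excluded) != total:
            raise ValidationError(
                f"{res.y_name} ~ {res.x_name}: n ({res.n}) plus exclusions "
                f"({len(res.excluded)}) does not cover the {total}-row table")
    return results


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    """Regression battery as a tidy frame (columns x,y,n,slope,intercept,r2,p,excluded)."""
    return pd.DataFrame([
        {
            "x": r.x_name, "y": r.y_name, "n": r.n, "slope": r.slope,
            "intercept": r.intercept, "r2": r.r_squared, "p": r.p_two_tailed,
            "excluded": ";".join(f"{s}({why})" for s, why in r.excluded),
        }
        for r in results])
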