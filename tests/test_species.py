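"""Species table loading, validation and geometry construction."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corpusim as cs
from corpusim.exceptions import GeometryError, ValidationError

PIXEL_SPECIES = {"dog", "monkey", "rooster", "snake"}


class TestLoadSpeciesTable:
    def test_packaged_table_has_19_animals(self, records):
        assert len(records) == 19

    def test_cat_row_values(self, by_name):
        cat = by_name["cat"]
        assert cat.outer_radius == 255.6
        assert cat.n_lamellae == 30
        assert cat.lamellar_thickness == 0.24
        assert cat.radius_unit == "um"

    def test_pixel_flags_consistent(self, records):
        px = {r.common_name for r in records if r.is_pixel_record}
        assert px == PIXEL_SPECIES
        for r in records:
            assert r.radius_unit == r.thickness_unit

    def test_round_trip_is_exact(self, records, tmp_path):
        path = tmp_path / "table.csv"
        cs.save_species_table(records, path)
        reloaded = cs.load_species_table(path)
        assert reloaded == records

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValidationError):
            cs.load_species_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("common_name,mass_kg\ncat,4.04\n")
        with pytest.raises(ValidationError, match="missing columns"):
            cs.load_species_table(path)

    def test_bad_cell_names_row_and_column(self, records, tmp_path):
        path = tmp_path / "bad.csv"
        cs.save_species_table(records[:3], path)
        text = path.read_text().replace("255.6", "huge")
        path.write_text(text)
        with pytest.raises(ValidationError, match="outer_radius"):
            cs.load_species_table(path)

    def test_negative_measurement_rejected(self, records, tmp_path):
        path = tmp_path / "bad.csv"
        cs.save_species_table(records[:3], path)
        path.write_text(path.read_text().replace("255.6", "-255.6"))
        with pytest.raises(ValidationError, match="row 2"):
            cs.load_species_table(path)


class TestRecordValidation:
    def test_mixed_units_rejected(self, by_name):
        with pytest.raises(ValidationError, match="unit flags"):
            dataclasses.replace(by_name["cat"], radius_unit="px")

    def test_zero_mass_rejected(self, by_name):
        with pytest.raises(ValidationError):
            dataclasses.replace(by_name["cat"], mass_kg=0.0)


class TestBuildGeometry:
    def test_single_lamella_sits_at_annulus_midpoint(self):
        geom = cs.layered_geometry(100.0, 1, 1.0)
        assert geom.core_radius == pytest.approx(20e-6)
        assert geom.mid_radii[0] == pytest.approx(60e-6)
        assert geom.gap_widths.size == 2
        assert np.all(geom.gap_widths > 0)

    def test_cat_geometry_spans_annulus_with_positive_gaps(self, cat_geometry):
        g = cat_geometry
        assert g.n_lamellae == 30
        assert g.core_radius == pytest.approx(0.2 * 255.6e-6)
        assert g.outer_radius == pytest.approx(255.6e-6)
        assert np.all(g.gap_widths > 0)
        # thicknesses and gaps tile the annulus
        total = g.thicknesses.sum() + g.gap_widths.sum()
        assert total == pytest.approx(g.outer_radius - g.core_radius, rel=1e-12)

    def test_overthick_lamellae_rejected_without_fallback(self):
        # 17 lamellae of 3.2 um cannot fit in 0.8 * 37.5 um
        with pytest.raises(GeometryError, match="spacing"):
            cs.layered_geometry(37.5, 17, 3.2)

    def test_min_gap_fallback_packs_inward(self):
        layout = cs.LayoutPolicy(min_gap_fallback=True)
        geom = cs.layered_geometry(100.0, 10, 8.0, layout)  # 8 um > 80/11 um spacing
        assert geom.n_lamellae == 10
        assert np.all(geom.gap_widths > 0)
        assert geom.core_radius < 0.2 * 100e-6

    def test_min_gap_fallback_rejects_impossible_stack(self):
        layout = cs.LayoutPolicy(min_gap_fallback=True)
        with pytest.raises(GeometryError, match="exceeds the outer radius"):
            cs.layered_geometry(37.5, 17, 3.2, layout)

    def test_pixel_record_uses_ratio_at_nominal_radius(self, by_name):
        dog = by_name["dog"]
        geom = cs.build_geometry(dog)
        assert geom.pixel_ratio_mode
        assert geom.outer_radius == pytest.approx(100e-6)
        ratio = geom.thicknesses[0] / geom.outer_radius
        assert ratio == pytest.approx(dog.thickness_ratio)

    def test_all_micrometre_species_build(self, records):
        for rec in records:
            geom = cs.build_geometry(rec)
            assert geom.n_lamellae == rec.n_lamellae

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        factor=st.floats(0.1, 50.0),
        n=st.integers(1, 30),
        radius=st.floats(10.0, 400.0),
    )
    def test_scale_covariance(self, factor, n, radius):
        """Multiplying all lengths by a constant scales the layout linearly."""
        h = 0.5 * 0.8 * radius / (n + 1)
        base = cs.layered_geometry(radius, n, h)
        scaled = cs.layered_geometry(radius * factor, n, h * factor)
        np.testing.assert_allclose(scaled.mid_radii, base.mid_radii * factor, rtol=1e-12)
        np.testing.assert_allclose(scaled.gap_widths, base.gap_widths * factor, rtol=1e-12)

    def test_scaled_method_matches_rebuild(self, cat_geometry):
        doubled = cat_geometry.scaled(2.0)
        np.testing.assert_allclose(doubled.mid_radii, cat_geometry.mid_radii * 2)
        assert doubled.outer_radius == cat_geometry.outer_radius * 2
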