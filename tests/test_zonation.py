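"""Zone construction, tiling, standardized distances, profiles, deconvolution."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon

from capsulezone.errors import ValidationError
from capsulezone.zonation import (
    BIN_MIDS,
    StainVectors,
    ZoneSet,
    bin_and_average,
    build_zones,
    color_deconvolve,
    rolling_smooth,
    standardize_distance,
    subtract_autofluorescence,
    tile_zone,
)


def annulus(r_in, r_out, center=(0, 0), n=256):
    return Point(center).buffer(r_out, quad_segs=n).difference(
        Point(center).buffer(r_in, quad_segs=n)
    )


class TestBuildZones:
    def test_annulus_plp_area_matches_analytic(self):
        tumor = Point(0, 0).buffer(1000, quad_segs=256)
        dr = annulus(1000, 1200)
        zones = build_zones(dr, tumor, expansion_um=1500)
        analytic = np.pi * (2700**2 - 1200**2)
        assert zones.plp.area == pytest.approx(analytic, rel=0.005)

    def test_zone_disjointness(self):
        tumor = Point(0, 0).buffer(1000, quad_segs=128)
        dr = annulus(1000, 1300)
        zones = build_zones(dr, tumor, expansion_um=1000)
        for a, b in [(zones.dr, zones.plp), (zones.dr, zones.tc), (zones.plp, zones.tc)]:
            assert a.intersection(b).area < 1e-6 * min(a.area, b.area)

    def test_no_pt_is_identity(self):
        tumor = Point(0, 0).buffer(500, quad_segs=128)
        dr = annulus(500, 700)
        z0 = build_zones(dr, tumor, expansion_um=1000)
        z1 = build_zones(dr, tumor, pt_polygons=[], expansion_um=1000)
        assert z0.dr.area == pytest.approx(z1.dr.area)

    def test_pt_disc_subtracts_its_area(self):
        tumor = Point(0, 0).buffer(500, quad_segs=256)
        dr = annulus(500, 800)
        pt = Point(0, 650).buffer(40, quad_segs=64)
        z = build_zones(dr, tumor, pt_polygons=[pt], expansion_um=1000)
        assert z.dr.area == pytest.approx(dr.area - pt.area, rel=0.005)

    def test_pt_outside_ignored_with_warning(self, caplog):
        tumor = Point(0, 0).buffer(500, quad_segs=64)
        dr = annulus(500, 700)
        far = Point(10_000, 10_000).buffer(50)
        z = build_zones(dr, tumor, pt_polygons=[far], expansion_um=1000)
        assert z.dr.area == pytest.approx(dr.area, rel=1e-9)

    def test_extensive_necrosis_flags_tc(self):
        tumor = Point(0, 0).buffer(500, quad_segs=64)
        dr = annulus(500, 600)
        necrosis = Point(0, 0).buffer(450, quad_segs=64)
        z = build_zones(dr, tumor, necrosis=[necrosis], expansion_um=1000)
        assert z.tc_excluded

    def test_degenerate_dr_error(self):
        tumor = Point(0, 0).buffer(500)
        with pytest.raises(ValidationError):
            build_zones(Polygon(), tumor, expansion_um=1000)


class TestTileZone:
    def test_square_tile_counts(self):
        assert len(tile_zone(Polygon([(0, 0), (100, 0), (100, 100), (0, 100)]))) == 16
        assert len(tile_zone(Polygon([(0, 0), (25, 0), (25, 25), (0, 25)]))) == 1

    def test_annulus_matches_brute_force_centroid_scan(self):
        zone = annulus(200, 400, n=64)
        tiles = tile_zone(zone)
        # oracle: exhaustive centroid test over the bounding grid
        count = 0
        for i in range(-20, 20):
            for j in range(-20, 20):
                if shapely.intersects_xy(zone, (i + 0.5) * 25.0, (j + 0.5) * 25.0):
                    count += 1
        assert len(tiles) == count

    def test_no_tile_in_two_zones(self):
        tumor = Point(0, 0).buffer(300, quad_segs=128)
        dr = annulus(300, 500)
        zones = build_zones(dr, tumor, expansion_um=500)
        seen = set()
        for z in (zones.plp, zones.dr, zones.tc):
            for t in tile_zone(z):
                assert t.centroid not in seen
                seen.add(t.centroid)


class TestStandardizeDistance:
    @pytest.mark.parametrize(
        "raw,maximum,zone,expected",
        [
            (750, 1500, "PLP", 50.0),
            (1500, 1500, "PLP", 100.0),
            (300, 300, "DR", -100.0),
            (150, 300, "DR", -50.0),
            (400, 400, "TC", -200.0),
            (0, 400, "TC", -100.0),
        ],
    )
    def test_conventions(self, raw, maximum, zone, expected):
        assert standardize_distance(raw, maximum, zone) == pytest.approx(expected)

    def test_clamps_overshoot(self):
        assert standardize_distance(1600, 1500, "PLP") == pytest.approx(100.0)

    def test_zero_max_error(self):
        with pytest.raises(ValidationError):
            standardize_distance(10, 0, "PLP")


class TestBinAndAverage:
    def _case(self, s_values, intensities, marker="m"):
        return pd.DataFrame({"standardized_distance": s_values, marker: intensities})

    def test_constant_field(self):
        s = np.linspace(-199, 99, 400)
        cases = {f"c{i}": self._case(s, np.full(400, 7.0)) for i in range(3)}
        prof = bin_and_average(cases, ["m"])["m"]
        assert np.allclose(prof.cohort_mean, 7.0)
        assert np.allclose(prof.smoothed, 7.0)
        assert np.allclose(prof.ci_lower, 7.0)  # identical cases -> zero-width CI
        assert np.allclose(prof.ci_upper, 7.0)

    def test_linear_field_recovers_bin_midpoints(self):
        s = np.linspace(-199.99, 99.99, 60_000)
        cases = {"c0": self._case(s, s)}
        prof = bin_and_average(cases, ["m"])["m"]
        assert np.all(np.abs(prof.cohort_mean - BIN_MIDS) <= 2.5 + 1e-6)

    def test_tile_permutation_invariance(self, rng):
        s = rng.uniform(-200, 100, 500)
        v = rng.uniform(0, 50, 500)
        p1 = bin_and_average({"c": self._case(s, v)}, ["m"])["m"]
        perm = rng.permutation(500)
        p2 = bin_and_average({"c": self._case(s[perm], v[perm])}, ["m"])["m"]
        np.testing.assert_allclose(p1.cohort_mean, p2.cohort_mean, equal_nan=True)

    def test_empty_bins_stay_missing(self):
        s = np.linspace(1, 99, 100)  # PLP only
        prof = bin_and_average({"c": self._case(s, s)}, ["m"])["m"]
        dr_bins = (BIN_MIDS > -100) & (BIN_MIDS < 0)
        assert np.isnan(prof.cohort_mean[dr_bins]).all()

    def test_ci_brackets_mean(self, rng):
        cases = {
            f"c{i}": self._case(rng.uniform(-200, 100, 300), rng.uniform(0, 50, 300))
            for i in range(5)
        }
        prof = bin_and_average(cases, ["m"])["m"]
        ok = ~np.isnan(prof.cohort_mean)
        assert np.all(prof.ci_lower[ok] <= prof.cohort_mean[ok] + 1e-12)
        assert np.all(prof.cohort_mean[ok] <= prof.ci_upper[ok] + 1e-12)

    def test_zero_cases_error(self):
        with pytest.raises(ValidationError):
            bin_and_average({}, ["m"])


class TestRollingSmooth:
    def test_ramp_interior_values_are_window_means(self):
        ramp = np.arange(1.0, 11.0)
        sm = rolling_smooth(ramp, window=5, center=True)
        # oracle: direct 5-term means in the interior
        for i in range(2, 8):
            assert sm[i] == pytest.approx(np.mean(ramp[i - 2 : i + 3]))

    def test_edges_shrink(self):
        ramp = np.arange(1.0, 11.0)
        sm = rolling_smooth(ramp, window=5, center=True)
        assert sm[0] == pytest.approx(np.mean(ramp[:3]))
        assert len(sm) == len(ramp)


class TestColorDeconvolution:
    def _vectors(self):
        return StainVectors(
            np.array([[0.65, 0.70, 0.29], [0.27, 0.57, 0.78], [0.0, 0.0, 1.0]]),
            ("hematoxylin", "DAB", "residual"),
        )

    def test_blank_pixel(self):
        out = color_deconvolve([1.0, 1.0, 1.0], self._vectors())
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_pure_stain_recovered(self):
        v = self._vectors()
        amount = 0.8
        rgb = 10.0 ** (-(amount * v.vectors[0]))
        out = color_deconvolve(rgb, v)
        np.testing.assert_allclose(out, [amount, 0, 0], atol=1e-9)

    def test_compose_invert_round_trip(self, rng):
        v = self._vectors()
        for _ in range(20):
            amounts = rng.uniform(0, 1.0, 3)
            rgb = 10.0 ** (-(amounts @ v.vectors))
            np.testing.assert_allclose(color_deconvolve(rgb, v), amounts, atol=1e-9)

    def test_two_stains_get_residual(self):
        v = StainVectors(np.array([[1.0, 0, 0], [0, 1.0, 0]]), ("a", "b"))
        assert v.vectors.shape == (3, 3)
        assert v.stain_names[-1] == "residual"

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValidationError):
            StainVectors(np.array([[1, 0, 0], [1, 0, 0], [0, 1, 0]]), ("a", "b", "c"))


class TestAutofluorescence:
    def test_zero_af_identity(self, rng):
        sig = rng.uniform(0, 10, 50)
        np.testing.assert_array_equal(subtract_autofluorescence(sig, np.zeros(50)), sig)

    def test_af_dominates_clamps_to_zero(self):
        assert subtract_autofluorescence(np.array([1.0]), np.array([5.0]))[0] == 0.0

    def test_elementwise_oracle(self, rng):
        sig, af = rng.uniform(0, 10, 100), rng.uniform(0, 10, 100)
        expected = np.array([max(s - a, 0.0) for s, a in zip(sig, af)])
        np.testing.assert_allclose(subtract_autofluorescence(sig, af), expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            subtract_autofluorescence(np.zeros(3), np.zeros(4))
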