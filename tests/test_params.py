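"""Clinical parameters against analytic oracles and hand computations."""

import numpy as np
import pytest

from cmrcompare.annotation import Contour, ImageGeometry, SliceAnnotation
from cmrcompare.params import (
    ParameterError,
    aha_segments,
    atrial_area,
    atrial_volume,
    atrial_volume_from_case,
    chamber_volume,
    compute_parameters,
    global_mapping_value,
    myocardial_mass,
    papillary_mass,
    refpoint_distance,
    scar_mass_fraction,
    sv_ef,
)

from conftest import UNIT_GEOM, circle, make_case, slice_with, square


def disk_stack(r, n_slices=5, epi_r=None, phase="ED"):
    slices = []
    for i in range(n_slices):
        cmap = {"lv_endo": [circle(60, 60, r)]}
        if epi_r is not None:
            cmap["lv_epi"] = [circle(60, 60, epi_r)]
        slices.append(slice_with(cmap, slice_index=i, phase=phase))
    return make_case(slices)


class TestChamberVolume:
    def test_disk_stack_analytic(self):
        # 5 slices, circle r=20 mm, D=10 mm: V = 5 * pi*400 * 10 / 1000
        case = disk_stack(20)
        assert chamber_volume(case, "lv_endo", "ED") == pytest.approx(62.83, abs=0.1)

    def test_no_contours_zero(self):
        case = make_case([slice_with({"lv_epi": [circle(60, 60, 30)]})])
        assert chamber_volume(case, "lv_endo", "ED") == 0.0

    def test_missing_phase_raises(self):
        with pytest.raises(ParameterError, match="phase"):
            chamber_volume(disk_stack(20), "lv_endo", "ES")

    def test_linear_in_slice_distance(self):
        geom8 = ImageGeometry(1, 1, 8.0, 0.0)
        geom16 = ImageGeometry(1, 1, 8.0, 8.0)
        v8 = chamber_volume(disk_stack(20).__class__(
            "c1", "r1", "sax_cine", geom8, disk_stack(20).slices), "lv_endo", "ED")
        v16 = chamber_volume(disk_stack(20).__class__(
            "c1", "r1", "sax_cine", geom16, disk_stack(20).slices), "lv_endo", "ED")
        assert v16 == pytest.approx(2 * v8)

    def test_quadratic_in_pixel_spacing(self):
        geom2 = ImageGeometry(2.0, 2.0, 8.0, 2.0)
        base = disk_stack(20)
        scaled = make_case(base.slices, geom=geom2)
        assert chamber_volume(scaled, "lv_endo", "ED") == pytest.approx(
            4 * chamber_volume(base, "lv_endo", "ED"), rel=1e-9
        )

    def test_papillary_exclusion_flag(self):
        s = slice_with({"lv_endo": [circle(60, 60, 20)], "papmu": [circle(60, 60, 5)]})
        case = make_case([s])
        v_incl = chamber_volume(case, "lv_endo", "ED")
        v_excl = chamber_volume(case, "lv_endo", "ED", papillary_in_cavity=False)
        assert v_incl - v_excl == pytest.approx(np.pi * 25 * 10 / 1000, rel=1e-3)


class TestMasses:
    def test_annulus_analytic(self):
        # endo r=20, epi r=30, 5 slices, D=10: vol = 5*pi*500*10/1000 = 78.54 ml
        case = disk_stack(20, epi_r=30)
        assert myocardial_mass(case, "ED") == pytest.approx(78.54 * 1.05, abs=0.2)

    def test_endo_equals_epi_zero_mass(self):
        case = disk_stack(25, epi_r=25)
        assert myocardial_mass(case, "ED") == pytest.approx(0.0, abs=1e-9)

    def test_endo_larger_than_epi_clamped(self):
        case = disk_stack(30, epi_r=20)
        assert myocardial_mass(case, "ED") == 0.0

    def test_papillary_mass_arithmetic(self):
        # 100 mm^2 square on 2 slices, D=10 -> 2 ml -> 2.1 g
        slices = [
            slice_with({"papmu": [square(10, 10, 10)]}, slice_index=i) for i in (0, 1)
        ]
        assert papillary_mass(make_case(slices), "ED") == pytest.approx(2.1)


class TestSvEf:
    @pytest.mark.parametrize(
        "edv,esv,sv,ef",
        [(160, 80, 80, 50.0), (120, 48, 72, 60.0), (100, 100, 0, 0.0)],
    )
    def test_examples(self, edv, esv, sv, ef):
        got_sv, got_ef = sv_ef(edv, esv)
        assert got_sv == pytest.approx(sv) and got_ef == pytest.approx(ef)

    def test_zero_edv_ef_undefined(self):
        assert sv_ef(0.0, 0.0) == (0.0, None)

    def test_negative_sv_returned(self):
        sv, ef = sv_ef(80, 100)
        assert sv == -20 and ef == pytest.approx(-25.0)


class TestScar:
    def _lge_case(self, scar_side=6.0, n_scar=3):
        slices = []
        for i in range(5):
            cmap = {
                "lv_endo": [circle(60, 60, 20)],
                "lv_epi": [circle(60, 60, 30)],
            }
            if i < n_scar:
                # square scar fully inside the ring: radial extent 22..28.2 mm
                cmap["scar"] = [square(60 - scar_side / 2, 60 + 22, scar_side)]
            slices.append(slice_with(cmap, slice_index=i, phase="single"))
        return make_case(slices, sequence="sax_lge")

    def test_arithmetic_chain(self):
        case = self._lge_case()
        scarm, scarf = scar_mass_fraction(case)
        lvm = myocardial_mass(case, "single")
        assert scarm == pytest.approx(36 * 3 * 10 / 1000 * 1.05, rel=1e-3)
        assert scarf == pytest.approx(100 * scarm / lvm, rel=1e-9)

    def test_no_scar_zero(self):
        assert scar_mass_fraction(self._lge_case(n_scar=0)) == (0.0, 0.0)

    def test_scar_clipped_to_ring(self):
        # scar square straddling the endo boundary: only the ring part counts
        slices = [
            slice_with(
                {
                    "lv_endo": [circle(60, 60, 20)],
                    "lv_epi": [circle(60, 60, 30)],
                    "scar": [square(58, 58, 4)],  # centred in the cavity
                },
                phase="single",
            )
        ]
        scarm, _ = scar_mass_fraction(make_case(slices, sequence="sax_lge"))
        assert scarm == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance_of_fraction(self):
        _, f1 = scar_mass_fraction(self._lge_case())
        big = make_case(self._lge_case().slices, geom=ImageGeometry(2, 2, 8, 2),
                        sequence="sax_lge")
        _, f2 = scar_mass_fraction(big)
        assert f1 == pytest.approx(f2, rel=1e-6)


class TestAtria:
    def test_rectangle_area(self):
        s = slice_with({"la": [np.array([[0, 0], [20, 0], [20, 10], [0, 10]], float)]},
                       phase="ES")
        case = make_case([s], sequence="lax_2cv")
        assert atrial_area(case, "la", "ES") == pytest.approx(2.0)

    def test_missing_distinguished_from_zero(self):
        case = make_case([slice_with({}, phase="ES")], sequence="lax_2cv")
        assert atrial_area(case, "la", "ES") is None

    def test_fragmented_additivity(self):
        s = slice_with({"la": [square(0, 0, 10), square(30, 30, np.sqrt(50))]}, phase="ES")
        case = make_case([s], sequence="lax_2cv")
        assert atrial_area(case, "la", "ES") == pytest.approx(1.5, rel=1e-6)

    def test_formula_arithmetic(self):
        assert atrial_volume(20.0, 5.0) == pytest.approx(67.91, abs=0.01)
        assert atrial_volume(0.0, 5.0) == 0.0
        with pytest.raises(ParameterError):
            atrial_volume(20.0, 0.0)

    def test_sphere_consistency(self):
        # circle radius r: A=pi r^2, L=2r  ->  V = (4/3) pi r^3; r = 3 cm
        s = slice_with({"la": [circle(60, 60, 30, n=720)]}, phase="ES")
        case = make_case([s], sequence="lax_2cv")
        assert atrial_volume_from_case(case, "la", "ES") == pytest.approx(113.10, abs=0.1)


class TestMapping:
    def _map_slice(self, values, r_endo=10, r_epi=20, shape=(120, 120), refpt=True):
        cmap = {
            "lv_endo": [circle(60, 60, r_endo)],
            "lv_epi": [circle(60, 60, r_epi)],
        }
        if refpt:
            cmap["refpoint"] = [np.array([[60.0 - r_epi - 2, 60.0]])]
        return slice_with(cmap, phase="single", value_map=values)

    def test_constant_field(self):
        vm = np.full((120, 120), 1000.0)
        assert global_mapping_value(self._map_slice(vm), UNIT_GEOM) == 1000.0

    def test_half_plane_symmetry(self):
        vm = np.full((120, 120), 900.0)
        vm[:, 60:] = 1100.0  # voxels at col >= 60
        vm2 = np.full((120, 120), 1100.0)
        vm2[:, 60:] = 900.0
        g1 = global_mapping_value(self._map_slice(vm), UNIT_GEOM)
        g2 = global_mapping_value(self._map_slice(vm2), UNIT_GEOM)
        assert (g1 + g2) / 2 == pytest.approx(1000.0)

    def test_brute_force_membership(self):
        rng = np.random.default_rng(0)
        vm = rng.normal(1000, 50, (120, 120))
        slc = self._map_slice(vm)
        got = global_mapping_value(slc, UNIT_GEOM)
        # independent oracle: radial membership of voxel centres
        jj, ii = np.meshgrid(np.arange(120), np.arange(120))
        dist = np.hypot(jj - 60, ii - 60)
        mask = (dist < 20) & (dist > 10)
        # exclude voxels within half a pixel of either polygon boundary where
        # the 360-gon and the exact circle may disagree
        safe = mask & (np.abs(dist - 20) > 0.5) & (np.abs(dist - 10) > 0.5)
        assert abs(vm[mask].mean() - got) < 3 * vm.std() / np.sqrt(mask.sum())
        assert got == pytest.approx(
            np.mean(vm[safe]), abs=5 * np.std(vm) / np.sqrt(safe.sum()) + 5
        )

    def test_aha_partition_identity(self):
        rng = np.random.default_rng(1)
        vm = rng.normal(1000, 30, (120, 120))
        slc = self._map_slice(vm)
        segs = aha_segments(slc, UNIT_GEOM)
        assert len(segs) == 6
        total = sum(s.voxel_count for s in segs)
        weighted = sum(s.mean * s.voxel_count for s in segs) / total
        assert weighted == pytest.approx(global_mapping_value(slc, UNIT_GEOM), rel=1e-12)

    def test_aha_constant_field_all_equal(self):
        vm = np.full((120, 120), 1234.0)
        for s in aha_segments(self._map_slice(vm), UNIT_GEOM):
            assert s.mean == pytest.approx(1234.0) and s.sd == 0.0

    def test_aha_sector_values_recovered(self):
        # value the field by angular sector about the centre, matching the
        # partition geometry (sector 1 starts at the refpoint ray, CCW on
        # screen). Off-lattice centre and refpoint keep every voxel centre a
        # finite angular distance away from the sector boundaries.
        n = 6
        cx, cy = 60.3, 60.7
        refpt = np.array([[37.9, 55.2]])
        cmap = {
            "lv_endo": [circle(cx, cy, 10)],
            "lv_epi": [circle(cx, cy, 20)],
            "refpoint": [refpt],
        }
        jj, ii = np.meshgrid(np.arange(120), np.arange(120))
        theta = np.arctan2(-(ii - cy), jj - cx)
        theta0 = np.arctan2(-(refpt[0, 1] - cy), refpt[0, 0] - cx)
        rel = np.mod(theta - theta0, 2 * np.pi)
        sector = np.minimum((rel / (2 * np.pi / n)).astype(int), n - 1)
        vm = 1000.0 + 10.0 * sector
        slc = slice_with(cmap, phase="single", value_map=vm)
        segs = aha_segments(slc, UNIT_GEOM)
        for s in segs:
            assert s.mean == pytest.approx(1000.0 + 10.0 * (s.segment_index - 1))
            assert s.sd == 0.0

    def test_missing_refpoint_raises(self):
        vm = np.full((120, 120), 1000.0)
        with pytest.raises(ParameterError, match="refpoint"):
            aha_segments(self._map_slice(vm, refpt=False), UNIT_GEOM)

    def test_empty_ring_raises(self):
        vm = np.full((4, 4), 1000.0)  # grid far away from the ring
        with pytest.raises(ParameterError, match="no voxel"):
            global_mapping_value(self._map_slice(vm), UNIT_GEOM)


class TestRefpointDistance:
    def _slc(self, col, row):
        return slice_with({"refpoint": [np.array([[col, row]], float)]}, phase="single")

    def test_euclidean(self):
        assert refpoint_distance(self._slc(0, 0), self._slc(3, 4), UNIT_GEOM) == pytest.approx(5.0)

    def test_same_point_zero(self):
        assert refpoint_distance(self._slc(2, 2), self._slc(2, 2), UNIT_GEOM) == 0.0

    def test_spacing_scales(self):
        geom = ImageGeometry(2.0, 2.0, 8.0)
        assert refpoint_distance(self._slc(0, 0), self._slc(3, 4), geom) == pytest.approx(10.0)

    def test_missing_undefined(self):
        empty = slice_with({}, phase="single")
        assert refpoint_distance(self._slc(0, 0), empty, UNIT_GEOM) is None


class TestComputeParameters:
    def test_cine_identities(self, cine_pair):
        r1, _, _ = cine_pair
        p = {k: v.value for k, v in compute_parameters(r1).items()}
        assert p["LVSV"] == pytest.approx(p["LVEDV"] - p["LVESV"], rel=1e-12)
        assert p["LVEF"] * p["LVEDV"] == pytest.approx(100 * p["LVSV"], rel=1e-12)
        assert p["RVSV"] == pytest.approx(p["RVEDV"] - p["RVESV"], rel=1e-12)
        assert 0 <= p["LVEF"] <= 100 and p["LVM"] > 0
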