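"""Phantom generator: determinism, analytic truth, perturbation closed forms."""

import numpy as np
import pytest

from cmrcompare.annotation import pair_cases, save_case
from cmrcompare.metrics import compare_slice
from cmrcompare.params import compute_parameters, sv_ef
from cmrcompare.phantom import (
    PhantomParams,
    Perturbation,
    generate_case,
    generate_cohort,
    perturb_reader,
    write_cohort,
)


class TestGenerateCase:
    def test_exact_matches_analytic_volumes(self):
        _, truth = generate_case(PhantomParams(), seed=1)
        for name in ("LVEDV", "LVESV", "RVEDV", "LVM", "PAPMU_ED"):
            assert truth.exact[name] == pytest.approx(
                truth.analytic[name], rel=2e-3
            ), name

    def test_ef_internal_consistency(self):
        params = PhantomParams(es_scale=0.7)
        _, truth = generate_case(params, seed=2)
        sv, ef = sv_ef(truth.exact["LVEDV"], truth.exact["LVESV"])
        assert truth.exact["LVSV"] == pytest.approx(sv, rel=1e-12)
        assert truth.exact["LVEF"] == pytest.approx(ef, rel=1e-12)
        # radii scale by 0.7, slice set unchanged: EF = 100 (1 - 0.7^2)
        assert truth.analytic["LVEF"] == pytest.approx(100 * (1 - 0.49), rel=1e-12)

    def test_same_seed_identical_files(self, tmp_path):
        for k in (1, 2):
            case, _ = generate_case(PhantomParams(sequence="sax_t1"), seed=99)
            save_case(case, tmp_path / f"case{k}.json")
        assert (tmp_path / "case1.json").read_text() == (tmp_path / "case2.json").read_text()

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError):
            PhantomParams(apex_taper=1.2)

    @pytest.mark.parametrize("sequence", ["sax_lge", "sax_t1", "sax_t2", "lax_2cv", "lax_4cv"])
    def test_other_sequences_consistent_with_truth(self, sequence):
        params = PhantomParams(sequence=sequence, n_slices=4)
        case, truth = generate_case(params, seed=11)
        computed = {k: v.value for k, v in compute_parameters(case).items()}
        assert computed == truth.exact
        for name, analytic in truth.analytic.items():
            tol = 0.02 if sequence in ("sax_t1", "sax_t2") else 5e-3
            assert computed[name] == pytest.approx(analytic, rel=tol), name


class TestPerturbReader:
    def test_zero_perturbation_identity(self):
        r1, _ = generate_case(PhantomParams(n_slices=4), seed=3)
        r2 = perturb_reader(r1, Perturbation(seed=44))
        assert r2.reader_id == "reader2"
        for p in pair_cases(r1, r2):
            for ctype in ("lv_endo", "myo", "rv_endo"):
                m = compare_slice(p.s1, p.s2, ctype, r1.geometry)
                assert m.dice == pytest.approx(1.0, abs=1e-12)
                assert m.hd == pytest.approx(0.0, abs=1e-12)

    def test_pure_dilation_closed_forms(self):
        delta = 1.0
        params = PhantomParams(n_slices=4)
        r1, _ = generate_case(params, seed=3)
        r2 = perturb_reader(r1, Perturbation(dilation_mm={"lv_endo": delta}, seed=0))
        from cmrcompare.params import polygon_area

        for p in pair_cases(r1, r2):
            a = polygon_area(p.s1.polygons("lv_endo"), r1.geometry)
            r = np.sqrt(a / np.pi)
            m = compare_slice(p.s1, p.s2, "lv_endo", r1.geometry)
            assert m.dice == pytest.approx(
                2 * r**2 / (r**2 + (r + delta) ** 2), abs=1e-3
            )
            assert m.hd == pytest.approx(delta, abs=0.01)

    def test_miss_basal_certain(self):
        r1, _ = generate_case(PhantomParams(n_slices=4), seed=3)
        r2 = perturb_reader(r1, Perturbation(p_miss_basal=1.0, seed=1))
        idx1 = {s.slice_index for s in r1.phase_slices("ED")}
        idx2 = {s.slice_index for s in r2.phase_slices("ED")}
        assert min(idx1) not in idx2 and idx2 == idx1 - {min(idx1)}

    def test_extra_basal_certain(self):
        r1, _ = generate_case(PhantomParams(n_slices=4), seed=3)
        r2 = perturb_reader(r1, Perturbation(p_extra_basal=1.0, seed=1))
        idx1 = {s.slice_index for s in r1.phase_slices("ED")}
        assert {s.slice_index for s in r2.phase_slices("ED")} == idx1 | {min(idx1) - 1}

    def test_fragmentation_splits_polygons(self):
        r1, _ = generate_case(PhantomParams(n_slices=4), seed=3)
        r2 = perturb_reader(r1, Perturbation(p_fragment=1.0, seed=6))
        n_pieces = [len(s.polygons("rv_endo")) for s in r2.phase_slices("ED")]
        assert max(n_pieces) >= 2

    def test_refpoint_shift_magnitude(self):
        params = PhantomParams(sequence="sax_t1")
        r1, _ = generate_case(params, seed=3)
        r2 = perturb_reader(r1, Perturbation(refpoint_shift=12.0, seed=9))
        from cmrcompare.params import refpoint_distance

        d = refpoint_distance(r1.slices[0], r2.slices[0], r1.geometry)
        assert d == pytest.approx(12.0, rel=1e-9)

    def test_deterministic_given_seed(self):
        r1, _ = generate_case(PhantomParams(n_slices=4), seed=3)
        pert = Perturbation(radial_sigma=0.5, p_fragment=0.5, seed=21)
        a, b = perturb_reader(r1, pert), perturb_reader(r1, pert)
        assert a == b


class TestCohort:
    def test_master_seed_determinism(self, small_params, tmp_path):
        pert = Perturbation(radial_sigma=0.3, seed=0)
        t1 = write_cohort(generate_cohort(3, small_params, pert, seed=5), tmp_path / "a")
        t2 = write_cohort(generate_cohort(3, small_params, pert, seed=5), tmp_path / "b")
        assert t1.equals(t2)
        f1 = sorted((tmp_path / "a").glob("*.json"))
        f2 = sorted((tmp_path / "b").glob("*.json"))
        assert [p.read_text() for p in f1] == [p.read_text() for p in f2]

    def test_dilation_bias_recovery(self, small_params):
        # pure endo dilation: per-case LVEDV diff = -sum(2 pi r_i d + pi d^2) D/1000
        delta = 1.0
        pert = Perturbation(dilation_mm={"lv_endo": delta}, seed=0)
        pairs = generate_cohort(12, small_params, pert, seed=17)
        diffs, expected = [], []
        from cmrcompare.params import polygon_area

        for pair in pairs:
            d1 = {k: v.value for k, v in compute_parameters(pair.reader1).items()}
            d2 = {k: v.value for k, v in compute_parameters(pair.reader2).items()}
            diffs.append(d1["LVEDV"] - d2["LVEDV"])
            dd = pair.reader1.geometry.slice_distance
            exp = 0.0
            for s in pair.reader1.phase_slices("ED"):
                a = polygon_area(s.polygons("lv_endo"), pair.reader1.geometry)
                r = np.sqrt(a / np.pi)
                exp -= (2 * np.pi * r * delta + np.pi * delta**2) * dd / 1000.0
            expected.append(exp)
        assert np.mean(diffs) == pytest.approx(np.mean(expected), rel=5e-3)

    def test_zero_perturbation_no_outliers(self, small_params):
        from cmrcompare.stats import ToleranceRange, detect_outliers

        pairs = generate_cohort(5, small_params, Perturbation(seed=0), seed=23)
        diffs = {}
        for pair in pairs:
            d1 = {k: v.value for k, v in compute_parameters(pair.reader1).items()}
            d2 = {k: v.value for k, v in compute_parameters(pair.reader2).items()}
            diffs[pair.case_id] = d1["LVEDV"] - d2["LVEDV"]
        assert detect_outliers(diffs, ToleranceRange("LVEDV", 1e-9, 30)) == []

    def test_truth_table_written(self, small_params, tmp_path):
        pairs = generate_cohort(2, small_params, Perturbation(seed=0), seed=1)
        truth = write_cohort(pairs, tmp_path)
        assert (tmp_path / "truth.csv").exists()
        assert set(truth.columns) == {"case_id", "parameter", "exact", "analytic"}
        assert truth["case_id"].nunique() == 2
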