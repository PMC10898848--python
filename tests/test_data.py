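"""Data model, CSV I/O, coverage-factor inversion, packaged fixtures."""

import math

import numpy as np
import pytest
from scipy import stats

from kctree.data import (
    KCStudy,
    MeasurementResult,
    ValidationError,
    dof_from_coverage_factor,
    load_kc_csv,
    write_kc_csv,
)
from kctree.fixtures import FIXTURE_NAMES, fixture, p3krbin_result


class TestMeasurementResult:
    def test_rejects_nonpositive_uncertainty(self):
        with pytest.raises(ValidationError, match="std_unc"):
            MeasurementResult("A", 1.0, 0.0)

    def test_rejects_nonpositive_dof(self):
        with pytest.raises(ValidationError, match="dof"):
            MeasurementResult("A", 1.0, 1.0, dof=-1)

    def test_default_dof_is_infinite(self):
        assert math.isinf(MeasurementResult("A", 1.0, 1.0).dof)


class TestKCStudy:
    def test_duplicate_labels_rejected(self):
        rows = (MeasurementResult("A", 1, 1), MeasurementResult("A", 2, 1))
        with pytest.raises(ValidationError, match="duplicate"):
            KCStudy("s", "", rows)

    def test_counts(self, k45):
        assert k45.N == 5
        assert k45.n_included == 4

    def test_including_all(self):
        st = fixture("K88")
        assert st.n_included == 5
        assert st.including_all().n_included == 10

    def test_json_roundtrip(self, k45):
        back = KCStudy.from_json(k45.to_json())
        assert back == k45


class TestCSV:
    def test_expanded_uncertainty_conversion(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("lab,value,U,k\nLGC,224.6,3.0,2\nKRISS,226.26,1.94,2.45\n")
        st = load_kc_csv(p)
        by = {r.lab: r for r in st.results}
        assert by["LGC"].std_unc == pytest.approx(1.5)
        assert by["KRISS"].std_unc == pytest.approx(1.94 / 2.45)

    def test_direct_std_unc_unchanged(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("lab,value,u\nNIST,456.2,2.0\nX,4,2.0\n")
        st = load_kc_csv(p)
        assert st.results[0].std_unc == 2.0

    def test_u_over_k_trivial(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("lab,value,U,k\nA,1.0,4.0,2\nB,2.0,4.0,2\n")
        assert load_kc_csv(p).results[0].std_unc == pytest.approx(2.0)

    def test_nonpositive_uncertainty_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("lab,value,u\nGOOD,1,1\nBAD,2,-1\n")
        with pytest.raises(ValidationError, match="BAD"):
            load_kc_csv(p)

    def test_missing_uncertainty_errors(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("lab,value\nA,1\nB,2\n")
        with pytest.raises(ValidationError):
            load_kc_csv(p)

    def test_roundtrip_bitwise(self, tmp_path, k145_ni):
        p = tmp_path / "ni.csv"
        write_kc_csv(k145_ni, p)
        back = load_kc_csv(p)
        for a, b in zip(k145_ni.results, back.results):
            assert a.lab == b.lab
            assert a.value == b.value
            assert a.std_unc == b.std_unc
            assert a.dof == b.dof
            assert a.include_in_kcrv == b.include_in_kcrv

    def test_dialect_remap(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("Laboratory,w,uc\nA,1,0.5\nB,2,0.7\n")
        st = load_kc_csv(p, dialect={"lab": "Laboratory", "value": "w", "u": "uc"})
        assert st.results[1].std_unc == 0.7


class TestDofFromCoverageFactor:
    def test_k245_gives_six(self):
        assert dof_from_coverage_factor(2.45) == 6

    def test_gaussian_limit(self):
        assert math.isinf(dof_from_coverage_factor(1.96))

    def test_matches_grid_search_oracle(self):
        # brute-force scan over integer dof for the best t-quantile match
        k = 2.36
        grid = np.arange(1, 500)
        q = stats.t.ppf(0.975, grid)
        oracle = grid[np.argmin(np.abs(q - k))]
        assert dof_from_coverage_factor(k) == oracle

    def test_monotone_in_k(self):
        ks = [2.1, 2.2, 2.45, 2.8, 3.2]
        dofs = [dof_from_coverage_factor(k) for k in ks]
        assert dofs == sorted(dofs, reverse=True)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValidationError):
            dof_from_coverage_factor(0.0)


class TestFixtures:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(KeyError, match="K45"):
            fixture("nope")

    def test_k45_flags(self, k45):
        assert k45.N == 5
        excluded = [r.lab for r in k45.results if not r.include_in_kcrv]
        assert excluded == ["UME"]
        kriss = next(r for r in k45.results if r.lab == "KRISS")
        assert kriss.dof == 6
        assert kriss.std_unc == pytest.approx(1.94 / 2.45)

    def test_zn_included_count(self, k145_zn):
        assert k145_zn.n_included == 19

    def test_sr90_all_included(self, sr90):
        assert sr90.N == 11
        assert sr90.n_included == 11

    def test_zn65_exclusions(self, zn65):
        excluded = {r.lab for r in zn65.results if not r.include_in_kcrv}
        assert excluded == {"BEV", "ENEA", "SMU"}
        assert zn65.n_included == 18

    def test_inmc_uncertainty_full_precision(self, k145_ni):
        inmc = next(r for r in k145_ni.results if r.lab == "INMC")
        assert inmc.std_unc == 0.06387

    def test_p3krbin(self, zn65):
        extra = zn65.add(p3krbin_result())
        assert extra.n_included == 19
        assert extra.results[-1].value == 28540.0

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_all_fixtures_valid(self, name):
        st = fixture(name)
        assert st.n_included >= 2
        assert all(r.std_unc > 0 for r in st.results)
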