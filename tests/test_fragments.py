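import numpy as np
import pytest

from siderokit.fragments import (
    FragmentLadder,
    LipopeptideStructure,
    PeakList,
    b_ladder,
    homolog_offset,
    match_peaks,
    precursor_mz,
    y_ladder,
)
from siderokit.masscore import MONOISOTOPIC, NOMINAL, acyl_from_description, residue_by_name
from siderokit.synthetic import SimConfig, random_lipopeptide

from conftest import POTASHCHELIN_A_B_SERIES, POTASHCHELIN_A_Y_SERIES, POTASHCHELIN_CALCD_MH


class TestStructure:
    def test_cyclization_requires_lactam_capable_terminus(self):
        with pytest.raises(ValueError, match="lactam"):
            LipopeptideStructure(
                residues=((residue_by_name("Ser"), "L"),),
                c_terminal_cyclized=True,
            )

    def test_empty_residues_rejected(self):
        with pytest.raises(ValueError):
            LipopeptideStructure(residues=())

    def test_neutral_formula_of_potashchelin_a(self, pota):
        # protonated formula C43H73N10O23 minus one proton H
        assert pota["A"].neutral_formula().hill() == "C43H72N10O23"


class TestLadders:
    def test_potashchelin_a_y_series(self, pota):
        mz = y_ladder(pota["A"], NOMINAL).mz_values
        assert mz[1:8] == POTASHCHELIN_A_Y_SERIES

    def test_cyclized_terminal_y1(self, pota):
        # lactamized N-OH-Orn: residue 130, water suppressed, +1 proton
        assert y_ladder(pota["A"], NOMINAL).mz_values[0] == 131

    def test_free_single_gly_y1(self):
        s = LipopeptideStructure(residues=((residue_by_name("Gly"), "achiral"),))
        assert y_ladder(s, NOMINAL).mz_values == (76,)

    def test_potashchelin_a_b_series(self, pota):
        assert b_ladder(pota["A"], NOMINAL).mz_values == POTASHCHELIN_A_B_SERIES

    def test_free_amine_b_series_adds_proton(self):
        s = LipopeptideStructure(
            residues=((residue_by_name("Gly"), "achiral"), (residue_by_name("Ser"), "L"))
        )
        assert b_ladder(s, NOMINAL).mz_values == (58,)

    def test_ladder_mz_strictly_increase(self, pota):
        for series in (y_ladder, b_ladder):
            mz = series(pota["A"], NOMINAL).mz_values
            assert all(b > a for a, b in zip(mz, mz[1:]))

    def test_nonmonotone_ladder_rejected(self):
        with pytest.raises(ValueError):
            FragmentLadder("y", ((1, 200.0), (2, 150.0)), NOMINAL, 500.0)


class TestPrecursor:
    @pytest.mark.parametrize("which", "ABCD")
    def test_monoisotopic_mh_matches_calcd(self, pota, which):
        _, calcd = POTASHCHELIN_CALCD_MH[which]
        assert precursor_mz(pota[which], "[M+H]+", MONOISOTOPIC) == pytest.approx(
            calcd, abs=5e-4
        )

    def test_nominal_precursor(self, pota):
        assert precursor_mz(pota["A"], "[M+H]+", NOMINAL) == 1097


class TestHomologOffsets:
    def test_b_series_tail_offsets(self, pota):
        a = b_ladder(pota["A"], NOMINAL)
        assert homolog_offset(a, b_ladder(pota["B"], NOMINAL)).offset == 18
        assert homolog_offset(a, b_ladder(pota["C"], NOMINAL)).offset == 16

    def test_y_series_identical_across_homologs(self, pota):
        a = y_ladder(pota["A"], NOMINAL)
        for other in "BCD":
            res = homolog_offset(a, y_ladder(pota[other], NOMINAL))
            assert res.constant and res.offset == 0

    def test_nonconstant_offset_reports_positions(self):
        a = FragmentLadder("b", ((1, 100.0), (2, 200.0)), NOMINAL, 500.0)
        b = FragmentLadder("b", ((1, 90.0), (2, 195.0)), NOMINAL, 500.0)
        res = homolog_offset(a, b)
        assert not res.constant and res.offset is None
        assert [i for i, _ in res.deviations] == [2]

    def test_series_mismatch_is_an_error(self, pota):
        with pytest.raises(ValueError):
            homolog_offset(y_ladder(pota["A"]), b_ladder(pota["A"]))


class TestMatchPeaks:
    def test_exact_self_match(self, pota, observed_y_peaks):
        theo = y_ladder(pota["A"], NOMINAL)
        res = match_peaks(theo, observed_y_peaks)
        assert res.n_matched == 7
        assert all(d == 0 for _, _, d in res.matched)
        assert set(res.unmatched_indices) == {1, 9}

    def test_empty_peaklist_matches_nothing(self, pota):
        res = match_peaks(y_ladder(pota["A"]), PeakList((), tolerance=0.5))
        assert res.n_matched == 0

    def test_peak_beyond_tolerance_left_unmatched(self, pota):
        peaks = list(POTASHCHELIN_A_Y_SERIES)
        peaks[3] += 1.0  # 2x the 0.5 Da tolerance
        res = match_peaks(y_ladder(pota["A"]), PeakList.from_mz(peaks))
        matched_indices = {i for i, _, _ in res.matched}
        assert 5 not in matched_indices  # index of the perturbed y value
        assert res.n_matched == 6

    def test_one_observed_peak_serves_one_index(self):
        theo = FragmentLadder("y", ((1, 100.0), (2, 100.4)), NOMINAL, 500.0)
        res = match_peaks(theo, PeakList.from_mz([100.2], tolerance=0.5))
        assert res.n_matched == 1


class TestComplementarity:
    """b_k + y_{n-k} equals the protonated precursor plus one proton."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_structures_nominal(self, seed):
        cfg = SimConfig(seed=seed)
        rng = cfg.rng()
        s = random_lipopeptide(cfg, rng)
        n = len(s)
        b = b_ladder(s, NOMINAL).mz_values
        y = y_ladder(s, NOMINAL).mz_values
        target = precursor_mz(s, "[M+H]+", NOMINAL) + 1
        assert all(b[k - 1] + y[n - k - 1] == target for k in range(1, n))

    def test_potashchelin_a_monoisotopic(self, pota):
        s = pota["A"]
        n = len(s)
        b = b_ladder(s, MONOISOTOPIC).mz_values
        y = y_ladder(s, MONOISOTOPIC).mz_values
        target = precursor_mz(s, "[M+H]+", MONOISOTOPIC) + 1.00783
        for k in range(1, n):
            assert b[k - 1] + y[n - k - 1] == pytest.approx(target, abs=1e-6)

    def test_acyl_swap_shifts_b_only(self, pota):
        a, c = pota["A"], pota["C"]
        diff = a.acyl.nominal - c.acyl.nominal
        assert homolog_offset(b_ladder(a), b_ladder(c)).offset == diff
        assert homolog_offset(y_ladder(a), y_ladder(c)).offset == 0
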