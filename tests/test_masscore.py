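import pytest
from hypothesis import given, settings, strategies as st

from siderokit.masscore import (
    ElementalFormula,
    FormulaError,
    MONOISOTOPIC,
    NOMINAL,
    acyl_from_description,
    adduct_mz,
    builtin_residue_table,
    formula_arith,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
    residue_by_name,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C43H73N10O23", {"C": 43, "H": 73, "N": 10, "O": 23}),
            ("H2O", {"H": 2, "O": 1}),
            ("C2H2", {"C": 2, "H": 2}),
            ("C_43_H_73_N_10_O_23_", {"C": 43, "H": 73, "N": 10, "O": 23}),
            ("CH4", {"C": 1, "H": 4}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text).counts == expected

    @pytest.mark.parametrize("bad", ["", "C43Q7", "c43", "C-3", "Xy2"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    @pytest.mark.parametrize("text", ["C43H73N10O23", "H2O", "C2H2", "CH4NaCl"])
    def test_roundtrip_through_canonical_serialization(self, text):
        f = parse_formula(text)
        assert parse_formula(f.hill()) == f


class TestMasses:
    def test_water_monoisotopic(self):
        assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(18.0106, abs=5e-4)

    def test_empty_formula_is_massless(self):
        assert monoisotopic_mass(ElementalFormula()) == 0.0
        assert nominal_mass(ElementalFormula()) == 0

    @pytest.mark.parametrize(
        "formula,nominal", [("H2O", 18), ("C43H73N10O23", 1097), ("C2H2", 26)]
    )
    def test_nominal(self, formula, nominal):
        assert nominal_mass(parse_formula(formula)) == nominal

    @given(
        counts_a=st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 50), max_size=5),
        counts_b=st.dictionaries(st.sampled_from("CHNOS"), st.integers(0, 50), max_size=5),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mass_additivity(self, counts_a, counts_b):
        a, b = ElementalFormula(counts_a), ElementalFormula(counts_b)
        total = a + b
        assert nominal_mass(total) == nominal_mass(a) + nominal_mass(b)
        assert monoisotopic_mass(total) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
        )


class TestFormulaArith:
    def test_hydrogenation_relation(self):
        unsaturated = parse_formula("C43H71N10O22")
        assert formula_arith(unsaturated, parse_formula("H2"), "add") == parse_formula(
            "C43H73N10O22"
        )

    def test_identity(self):
        f = parse_formula("C3H5NO2")
        assert formula_arith(f, ElementalFormula(), "add") == f

    def test_negative_count_rejected(self):
        with pytest.raises(FormulaError, match="H"):
            formula_arith(parse_formula("H"), parse_formula("H2"), "subtract")


class TestAdducts:
    def test_nominal_protonation(self):
        assert adduct_mz(parse_formula("H2O"), "[M+H]+", NOMINAL) == 19

    def test_sodiation_vs_protonation_differ_by_22(self):
        f = parse_formula("C6H12O6")
        assert adduct_mz(f, "[M+Na]+", NOMINAL) - adduct_mz(f, "[M+H]+", NOMINAL) == 22

    def test_unsupported_adduct_lists_options(self):
        with pytest.raises(ValueError, match=r"\[M\+H\]\+"):
            adduct_mz(parse_formula("H2O"), "[M+K]+", NOMINAL)


class TestResidueTable:
    EXPECTED_NOMINAL = {
        "Gly": 57,
        "Ser": 87,
        "Thr": 101,
        "allo-Thr": 101,
        "Asp": 115,
        "beta-OH-Asp": 131,
        "Orn": 114,
        "N-OH-Orn": 130,
    }

    def test_nominal_residue_masses(self):
        table = {r.name: r for r in builtin_residue_table()}
        assert {n: table[n].nominal for n in self.EXPECTED_NOMINAL} == self.EXPECTED_NOMINAL

    def test_ser_monoisotopic(self):
        assert residue_by_name("Ser").monoisotopic == pytest.approx(87.0320, abs=5e-4)

    def test_nominal_equals_mass_number_sum_for_all(self):
        for r in builtin_residue_table():
            assert r.nominal == r.formula.nominal()
            # integer nominal never exceeds the monoisotopic by more than the
            # per-atom mass-defect budget
            assert abs(r.nominal - r.monoisotopic) < 0.2

    def test_allo_thr_is_isobaric_with_thr(self):
        assert residue_by_name("allo-Thr").formula == residue_by_name("Thr").formula

    def test_lactam_capability_flags(self):
        assert residue_by_name("N-OH-Orn").lactam_capable
        assert residue_by_name("Orn").lactam_capable
        assert not residue_by_name("Ser").lactam_capable

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(KeyError, match="Bogus"):
            residue_by_name("Bogus")


class TestAcyl:
    @pytest.mark.parametrize(
        "carbons,dbs,ohs,nominal",
        [
            (12, (), (3,), 199),  # 3-hydroxydodecanoyl
            (12, ((5, "Z"),), (), 181),  # (Z)-dodec-5-enoyl
            (12, (), (), 183),  # dodecanoyl
            (14, ((7, "Z"),), (), 209),  # (Z)-tetradec-7-enoyl
        ],
    )
    def test_nominal_acyl_masses(self, carbons, dbs, ohs, nominal):
        assert acyl_from_description(carbons, dbs, ohs).nominal == nominal

    def test_formula_follows_cn_rule(self):
        a = acyl_from_description(12, ((5, "Z"),), (3,))
        assert a.formula == parse_formula("C12H21O2")

    def test_one_double_bond_costs_two_hydrogens(self):
        saturated = acyl_from_description(12)
        unsaturated = acyl_from_description(12, ((5, "Z"),))
        assert saturated.nominal - unsaturated.nominal == 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(carbons=1),
            dict(carbons=12, double_bonds=((12, "Z"),)),
            dict(carbons=12, hydroxyls=(15,)),
            dict(carbons=12, double_bonds=((5, "cis"),)),
        ],
    )
    def test_invalid_descriptions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            acyl_from_description(
                kwargs.get("carbons"),
                kwargs.get("double_bonds", ()),
                kwargs.get("hydroxyls", ()),
            )
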