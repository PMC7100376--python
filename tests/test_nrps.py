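import numpy as np
import pytest

from siderokit.nrps import (
    DomainParseError,
    HydroxylaseContext,
    assign_hydroxylation,
    parse_domain_string,
    predict_backbone,
    reconcile,
)
from siderokit.presets import MARFEY_INVENTORY, PTC_DOMAIN_STRING


@pytest.fixture
def ptc_arch():
    return parse_domain_string(PTC_DOMAIN_STRING)


@pytest.fixture
def ptc_ctx():
    return HydroxylaseContext(standalone=(("PtcA", "3R"),), fused=((1, "3S"),))


class TestParsing:
    def test_ptc_string_segments_into_one_plus_nine(self, ptc_arch):
        assert ptc_arch.loading.kinds() == ("FAAL", "ACP")
        assert ptc_arch.n_extensions == 9
        assert not ptc_arch.warnings

    def test_interrupted_c_taud_c_is_one_module(self, ptc_arch):
        m1 = ptc_arch.extensions[0]
        assert m1.kinds() == ("C", "TauD", "C", "A", "PCP")
        assert m1.has_fused_taud
        assert m1.a_substrate == "Asp"

    def test_substrates_in_order(self, ptc_arch):
        subs = [m.a_substrate for m in ptc_arch.extensions]
        assert subs == ["Asp", "Ser", "Gly", "Ser", "Ser", "Asp", "Thr", "Ser", "Orn"]

    def test_single_extension_module(self):
        arch = parse_domain_string("C_LCL-A_Ser-PCP")
        assert arch.loading.kinds() == ()
        assert arch.n_extensions == 1

    def test_loading_only(self):
        arch = parse_domain_string("FAAL-ACP")
        assert arch.n_extensions == 0

    def test_case_insensitive_tokens(self):
        arch = parse_domain_string("faal-acp-c_lcl-a_ser_-pcp-te")
        assert arch.n_extensions == 1
        assert arch.extensions[0].a_substrate == "Ser"

    def test_unknown_token_reported_with_position(self):
        with pytest.raises(DomainParseError, match="position 3"):
            parse_domain_string("FAAL-ACP-WAT-PCP")

    def test_a_without_pcp_is_a_warning_not_an_error(self):
        arch = parse_domain_string("C_LCL-A_Ser")
        assert any("without PCP" in w for w in arch.warnings)

    def test_serialize_parse_roundtrip(self, ptc_arch):
        assert parse_domain_string(ptc_arch.to_string()) == ptc_arch


class TestBackbonePrediction:
    def test_ptc_configurations(self, ptc_arch):
        pred = predict_backbone(ptc_arch)
        assert pred.configurations() == (
            "L", "D", "achiral", "D", "L", "L", "D", "D", "L",
        )

    def test_position_8_cdcl_conflict_flagged(self, ptc_arch):
        pred = predict_backbone(ptc_arch)
        assert pred.conflict_positions == (8,)
        assert "C_DCL" in pred.conflicts[0]

    def test_d_ser_positions(self, ptc_arch):
        pred = predict_backbone(ptc_arch)
        unconflicted_d_ser = [
            r.position for r in pred.residues
            if r.substrate == "Ser" and r.configuration == "D"
            and r.position not in pred.conflict_positions
        ]
        assert unconflicted_d_ser == [2, 4]

    def test_terminal_residue_assumed_l(self, ptc_arch):
        last = predict_backbone(ptc_arch).residues[-1]
        assert last.configuration == "L" and last.assumed

    def test_all_lcl_gives_all_l(self):
        arch = parse_domain_string(
            "C_LCL-A_Ser-PCP-C_LCL-A_Thr-PCP-C_LCL-A_Asp-PCP-TE"
        )
        assert predict_backbone(arch).configurations() == ("L", "L", "L")

    def test_all_dual_gives_all_non_gly_d(self):
        arch = parse_domain_string(
            "C_Dual-A_Ser-PCP-C_Dual-A_Gly-PCP-C_Dual-A_Thr-PCP-C_Dual-A_Asp-PCP-TE"
        )
        # last residue is terminal (assumed L); all upstream non-Gly are D
        assert predict_backbone(arch).configurations() == ("D", "achiral", "D", "L")

    def test_prediction_length_equals_extension_count(self, ptc_arch):
        assert len(predict_backbone(ptc_arch).residues) == ptc_arch.n_extensions

    @pytest.mark.parametrize("seed", range(8))
    def test_every_d_traceable_to_downstream_c_dual_or_dcl(self, seed):
        """Audit-trail completeness on randomly generated architectures."""
        rng = np.random.default_rng(seed)
        subs = rng.choice(["Ser", "Gly", "Thr", "Asp", "Orn"], size=rng.integers(2, 8))
        ctypes = rng.choice(["C_LCL", "C_Dual", "C_DCL"], size=len(subs))
        text = "FAAL-ACP-" + "-".join(
            f"{c}-A_{s}_-PCP" for c, s in zip(ctypes, subs)
        ) + "-TE"
        arch = parse_domain_string(text)
        pred = predict_backbone(arch)
        for r in pred.residues:
            if r.configuration == "D":
                downstream = arch.extensions[r.position].c_subtype
                assert downstream in ("C_Dual", "C_DCL")


class TestHydroxylation:
    def test_ptc_diastereomer_assignment(self, ptc_arch, ptc_ctx):
        pred = assign_hydroxylation(ptc_arch, predict_backbone(ptc_arch), ptc_ctx)
        by_pos = {r.position: r.hydroxylation for r in pred.residues}
        assert "L-threo" in by_pos[1]  # fused TauD (3S) on the tail-adjacent Asp
        assert "L-erythro" in by_pos[6]  # stand-alone 3R enzyme
        assert all(not by_pos[p] for p in (2, 3, 4, 5, 7, 8, 9))

    def test_no_context_leaves_asp_unannotated(self, ptc_arch):
        pred = assign_hydroxylation(
            ptc_arch, predict_backbone(ptc_arch), HydroxylaseContext()
        )
        assert all(not r.hydroxylation for r in pred.residues)

    def test_3s_standalone_gives_l_threo(self, ptc_arch):
        ctx = HydroxylaseContext(standalone=(("X", "3S"), ("Y", "3S")))
        pred = assign_hydroxylation(ptc_arch, predict_backbone(ptc_arch), ctx)
        for r in pred.residues:
            if r.substrate == "Asp":
                assert "L-threo" in r.hydroxylation

    def test_more_asp_than_hydroxylases(self, ptc_arch):
        ctx = HydroxylaseContext(standalone=(("X", "3R"),))
        pred = assign_hydroxylation(ptc_arch, predict_backbone(ptc_arch), ctx)
        annotations = [r.hydroxylation for r in pred.residues if r.substrate == "Asp"]
        assert "diastereomer unknown" in " ".join(annotations)

    def test_invalid_stereo_class_rejected(self):
        with pytest.raises(ValueError):
            HydroxylaseContext(standalone=(("X", "3Z"),))


class TestReconcile:
    def test_ptc_vs_marfey_inventory(self, ptc_arch, ptc_ctx):
        pred = assign_hydroxylation(ptc_arch, predict_backbone(ptc_arch), ptc_ctx)
        report = reconcile(pred, MARFEY_INVENTORY)
        assert report.verdict == "consistent_with_conflicts"
        assert any("C_DCL" in n for n in report.notes)

    def test_empty_inventory_is_vacuous(self, ptc_arch):
        report = reconcile(predict_backbone(ptc_arch), [])
        assert report.verdict == "vacuous"

    def test_gross_mismatch_is_inconsistent(self, ptc_arch):
        report = reconcile(predict_backbone(ptc_arch), [("Ser", "D", 4)])
        assert report.verdict == "inconsistent"
        assert report.deltas
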