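import numpy as np
import pytest

from renalivive.domain import PhysiologyConstants
from renalivive.ivive import (ScalerSet, compute_raf, compute_ref,
                              fraction_transported, predict_renal_clearance,
                              renal_clearance, scale_to_invivo_clint,
                              well_stirred_cl_sec)


@pytest.fixture
def phys():
    return PhysiologyConstants()


class TestScalers:
    @pytest.mark.parametrize("invivo,invitro,expected", [
        (10.2, 1.28, 8.0), (9.6, 0.30, 32.0), (5.0, 5.0, 1.0),
    ])
    def test_ref(self, invivo, invitro, expected):
        assert compute_ref(invivo, invitro) == pytest.approx(expected, rel=0.005)

    @pytest.mark.parametrize("invivo,invitro,expected,rel", [
        (35.2, 17.6, 2.0, 1e-12), (36.2, 0.23, 157.4, 0.005),
        (3.3, 3.3, 1.0, 1e-12),
    ])
    def test_raf(self, invivo, invitro, expected, rel):
        assert compute_raf(invivo, invitro) == pytest.approx(expected, rel=rel)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            compute_ref(1.0, 0.0)
        with pytest.raises(ValueError):
            compute_raf(1.0, 0.0)


class TestScaling:
    def test_chain_arithmetic(self, phys):
        """17.6 uL/min/mg x 0.30 mg/1e6 cells x REF 8.0 x 99.4e6 cells/g x
        169 g of cortex is about 710 mL/min."""
        out = scale_to_invivo_clint(17.6, 8.0, 0.30, phys)
        assert out == pytest.approx(709.6, abs=0.5)

    def test_zero_clearance(self, phys):
        assert scale_to_invivo_clint(0.0, 8.0, 0.30, phys) == 0.0

    def test_linear_in_ptcpgk(self, phys):
        base = scale_to_invivo_clint(5.0, 8.0, 0.30, phys)
        for ptc in (60.0, 209.0):
            alt = PhysiologyConstants(ptcpgk=ptc)
            assert scale_to_invivo_clint(5.0, 8.0, 0.30, alt) == pytest.approx(
                base * ptc / phys.ptcpgk, rel=1e-12)

    def test_missing_protein_content_rejected(self, phys):
        with pytest.raises(ValueError, match="protein"):
            scale_to_invivo_clint(5.0, 8.0, 0.0, phys)


class TestWellStirred:
    def test_flow_limit(self):
        assert well_stirred_cl_sec(1e12, 0.8, 1008.0) == pytest.approx(
            1008.0, rel=1e-3)

    def test_zero_clint(self):
        assert well_stirred_cl_sec(0.0, 0.5, 1008.0) == 0.0

    def test_hand_evaluation(self):
        out = well_stirred_cl_sec(709.6, 0.8, 1008.0)
        assert out == pytest.approx(1008 * 0.8 * 709.6 / (1008 + 0.8 * 709.6),
                                    rel=1e-12)
        assert out == pytest.approx(363.6, abs=1.0)

    def test_monotone_concave_below_flow(self):
        cl = np.linspace(0, 5000, 200)
        out = np.array([well_stirred_cl_sec(c, 0.5, 1008.0) for c in cl])
        assert np.all(np.diff(out) > 0)
        assert np.all(np.diff(np.diff(out)) < 1e-9)
        assert np.all(out < 1008.0)


class TestRenalClearance:
    def test_filtration_only(self, phys):
        assert renal_clearance(0.0, 1.0, phys) == pytest.approx(120.0)

    def test_filtration_plus_secretion(self, phys):
        assert renal_clearance(361.0, 0.01, phys) == pytest.approx(362.2)

    def test_full_reabsorption_not_allowed_but_near(self):
        phys = PhysiologyConstants(f_reabs=0.99)
        assert renal_clearance(100.0, 0.5, phys) == pytest.approx(
            (0.5 * 120 + 100) * 0.01)


class TestFractions:
    def test_single_transporter_dominates_when_no_filtration(self):
        fr = fraction_transported({"OAT1": 99.999}, 100.0)
        assert fr["OAT1"] == pytest.approx(1.0, rel=1e-3)

    def test_fractions_sum_with_filtration(self, phys):
        cl_sec = {"OAT1": 50.0, "OAT3": 150.0}
        cl_r = renal_clearance(sum(cl_sec.values()), 0.1, phys)
        fr = fraction_transported(cl_sec, cl_r)
        filtration_fraction = 0.1 * phys.gfr / cl_r
        assert sum(fr.values()) + filtration_fraction == pytest.approx(1.0)

    def test_zero_clr_rejected(self):
        with pytest.raises(ValueError):
            fraction_transported({"OAT1": 1.0}, 0.0)


class TestPredictChain:
    def _scalers(self, ref=8.0, raf=8.0):
        # abundances/probes chosen so REF and RAF take the requested values
        return {
            "OAT1": ScalerSet("OAT1", ref, 1.0, raf, 1.0),
            "OAT3": ScalerSet("OAT3", ref * 2, 2.0, raf * 3, 3.0),
        }

    def test_ref_equals_raf_modes_coincide(self, phys):
        scalers = self._scalers(ref=8.0, raf=8.0)
        clint = {"OAT1": 5.0, "OAT3": 2.0}
        a = predict_renal_clearance("x", clint, scalers, 0.1, phys, mode="REF")
        b = predict_renal_clearance("x", clint, scalers, 0.1, phys, mode="RAF")
        assert a.cl_r == pytest.approx(b.cl_r, rel=1e-12)

    def test_doubling_clint_doubles_clint_sec_sublinear_cl_sec(self, phys):
        scalers = self._scalers()
        base = predict_renal_clearance("x", {"OAT1": 5.0}, scalers, 0.1, phys)
        doubled = predict_renal_clearance("x", {"OAT1": 10.0}, scalers, 0.1, phys)
        assert doubled.clint_sec == pytest.approx(2 * base.clint_sec, rel=1e-12)
        assert doubled.cl_sec < 2 * base.cl_sec

    def test_dual_substrate_sums_transporters(self, phys):
        scalers = self._scalers()
        both = predict_renal_clearance("x", {"OAT1": 5.0, "OAT3": 2.0},
                                       scalers, 0.1, phys)
        only1 = predict_renal_clearance("x", {"OAT1": 5.0}, scalers, 0.1, phys)
        only3 = predict_renal_clearance("x", {"OAT3": 2.0}, scalers, 0.1, phys)
        assert both.clint_sec == pytest.approx(
            only1.clint_sec + only3.clint_sec, rel=1e-12)

    def test_known_split(self, phys):
        scalers = {"OAT1": ScalerSet("OAT1", 1.0, 1.0, 1.0, 1.0),
                   "OAT3": ScalerSet("OAT3", 1.0, 1.0, 1.0, 1.0)}
        # equal protein content to make the split exactly 1:3
        phys.protein_per_million_cells = {"OAT1": 0.3, "OAT3": 0.3}
        pred = predict_renal_clearance("x", {"OAT1": 1.0, "OAT3": 3.0},
                                       scalers, 0.5, phys)
        f1 = pred.per_transporter_cl_sec["OAT1"]
        f3 = pred.per_transporter_cl_sec["OAT3"]
        assert f3 == pytest.approx(3 * f1, rel=1e-12)
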