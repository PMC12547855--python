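"""UF derivation, AET arithmetic, semiquantitation, and reportability."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrfkit.calibrate import build_series, rrf_from_slope
from rrfkit.chem import apply_adduct, monoisotopic_fraction
from rrfkit.popstats import PopulationSummary, summarize
from rrfkit.quantify import QuantModel, compute_response, quantify
from rrfkit.simulate import CampaignConfig, simulate_campaign, simulate_nte_sample
from rrfkit.thresholds import (
    ModelMismatchError,
    NTEQuantResult,
    ThresholdError,
    ThresholdInputs,
    ThresholdResult,
    UFResult,
    compute_aet,
    compute_uf,
    reportable_set,
    semiquantitate,
)


def _summary(rsd, mean=1.0, n=10):
    sd = rsd * mean
    return PopulationSummary(
        n=n, mean=mean, sd=sd, rsd=rsd, p16=mean - sd, p50=mean, p84=mean + sd,
        min=mean - 2 * sd, max=mean + 2 * sd,
    )


class TestUncertaintyFactor:
    def test_no_variability_no_adjustment(self):
        for strategy in ("rsd_reciprocal", "percentile_ratio"):
            assert compute_uf(_summary(0.0), strategy).uf == 1.0

    def test_reciprocal_closed_form(self):
        assert compute_uf(_summary(0.5)).uf == pytest.approx(2.0)

    def test_cap_applies(self):
        assert compute_uf(_summary(0.9), cap=0.8).uf == pytest.approx(5.0)

    def test_degenerate_rsd_without_cap_errors(self):
        with pytest.raises(ThresholdError, match="degenerate"):
            compute_uf(_summary(1.2), cap=None)

    def test_percentile_ratio_at_least_one(self):
        uf = compute_uf(_summary(0.3), "percentile_ratio")
        assert uf.uf == pytest.approx(1.0 / 0.7)
        assert compute_uf(_summary(0.0), "percentile_ratio").uf >= 1.0

    def test_fixed_strategy(self):
        assert compute_uf(_summary(0.3), "fixed", fixed_value=3.0).uf == 3.0
        with pytest.raises(ThresholdError):
            compute_uf(_summary(0.3), "fixed", fixed_value=0.5)


class TestAET:
    def test_unit_example(self):
        inputs = ThresholdInputs(100.0, 1, 100.0, 1.0)
        res = compute_aet(inputs, UFResult("fixed", 0.0, 1.0))
        assert res.aet_initial == pytest.approx(1.0)
        assert res.aet_final == pytest.approx(1.0)
        res2 = compute_aet(inputs, UFResult("fixed", 0.0, 2.0))
        assert res2.aet_final == pytest.approx(0.5)

    def test_extraction_parameter_arithmetic(self):
        inputs = ThresholdInputs(1.5, 10, 500.0, 1.0)
        res = compute_aet(inputs, UFResult("fixed", 0.0, 3.0))
        assert res.aet_initial == pytest.approx(0.03)
        assert res.aet_final == pytest.approx(0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ThresholdError):
            ThresholdInputs(1.0, 1, 0.0, 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        dbt=st.floats(0.1, 1000.0),
        uf1=st.floats(1.0, 9.0),
        duf=st.floats(0.01, 5.0),
    )
    def test_aet_decreasing_in_uf_and_linear_in_dbt(self, dbt, uf1, duf):
        inputs = ThresholdInputs(dbt, 5, 250.0, 2.0)
        lo = compute_aet(inputs, UFResult("fixed", 0.0, uf1))
        hi = compute_aet(inputs, UFResult("fixed", 0.0, uf1 + duf))
        assert hi.aet_final < lo.aet_final
        doubled = compute_aet(ThresholdInputs(2 * dbt, 5, 250.0, 2.0), UFResult("fixed", 0.0, uf1))
        assert doubled.aet_final == pytest.approx(2 * lo.aet_final, rel=1e-9)


def _accepted_estimate(rrf=0.5, model="ecc"):
    from rrfkit.calibrate import RRFEstimate

    return RRFEstimate(
        run_id="run001", compound_id="surrogate", model=model, rrf=rrf,
        method="slope", weighting="inv_x", conc_range=(0.025, 1.0),
        r_squared=0.999, n_levels=6, injection_rsd_max=0.02, accepted=True,
    )


class TestSemiquant:
    def test_arithmetic_example(self):
        res = semiquantitate(50.0, 100.0, 1.0, _accepted_estimate(0.5), "ecc")
        assert res.concentration == pytest.approx(1.0)

    def test_model_mismatch_rejected(self):
        with pytest.raises(ModelMismatchError):
            semiquantitate(50.0, 100.0, 1.0, _accepted_estimate(0.5, model="ecc"), "eic_multi")

    def test_rejected_surrogate_rejected(self):
        est = replace(_accepted_estimate(), accepted=False, rejection_reason="injection RSD")
        with pytest.raises(ThresholdError, match="injection RSD"):
            semiquantitate(50.0, 100.0, 1.0, est, "ecc")

    def test_self_quantitation_is_unbiased(self, fixtures):
        """Noiseless linear: an NTE that is the surrogate itself recovers its
        true concentration exactly under every model."""
        sur = replace(fixtures["chrysene"], dispersion=0.0)
        istd = replace(fixtures["dbp_d4_istd"], dispersion=0.0)
        cfg = CampaignConfig(seed=4, runs=1, noise_cv=0.0)
        camp = simulate_campaign([sur], cfg, [istd])
        model = QuantModel("ecc")
        resp = quantify(camp.features, camp.design, [model])
        est = rrf_from_slope(build_series(resp, camp.design)[0], weighting="inv_x2")
        feats, truth = simulate_nte_sample(camp, sur, 0.33, "run001")
        raw = compute_response(feats[feats.compound_id == "unknown"], model)
        istd_raw = float(feats[feats.compound_id == istd.id]["intensity"].sum())
        res = semiquantitate(
            raw, istd_raw, cfg.istd_level, est, "ecc", true_concentration=truth["true_concentration"]
        )
        assert res.relative_bias == pytest.approx(0.0, abs=1e-9)

    def test_isotope_envelope_bias_closed_form(self, fixtures):
        """Single-ion monoisotopic EIC semiquant bias between a one- and
        two-chlorine compound equals m_nte / m_surrogate - 1 exactly in the
        noiseless linear limit."""
        sur = replace(fixtures["tinuvin326_like"], dispersion=0.0)
        nte = replace(fixtures["tinuvin326_2cl_like"], dispersion=0.0)
        istd = replace(fixtures["istd_lc"], dispersion=0.0)
        cfg = CampaignConfig(seed=0, runs=1, noise_cv=0.0, adduct_drift_concentration=math.inf)
        camp = simulate_campaign([sur], cfg, [istd])
        model = QuantModel("eic_single", isotope=0)
        resp = quantify(camp.features, camp.design, [model])
        est = rrf_from_slope(build_series(resp, camp.design)[0], weighting="inv_x")
        feats, truth = simulate_nte_sample(camp, nte, 0.150, "run001")
        raw = compute_response(feats[feats.compound_id == "unknown"], model)
        istd_raw = float(feats[feats.compound_id == istd.id]["intensity"].sum())
        res = semiquantitate(
            raw, istd_raw, cfg.istd_level, est, model.name,
            true_concentration=truth["true_concentration"],
        )
        m_n = monoisotopic_fraction(apply_adduct(nte.formula, "[M+H]+").formula)
        m_s = monoisotopic_fraction(apply_adduct(sur.formula, "[M+H]+").formula)
        assert res.relative_bias == pytest.approx(m_n / m_s - 1.0, abs=1e-9)
        assert res.relative_bias < 0  # two chlorines: negatively biased


def _nte(conc, name="x"):
    return NTEQuantResult(name, "sur", "ecc", conc, conc)


class TestReportableSet:
    def _threshold(self, uf):
        return compute_aet(ThresholdInputs(100.0, 1, 100.0, 1.0), UFResult("fixed", 0.0, uf))

    def test_all_below_threshold(self):
        thr = self._threshold(1.0)  # AET 1.0 ug/mL
        assert reportable_set([_nte(0.1), _nte(0.9)], thr) == []

    def test_boundary_is_inclusive(self):
        thr = self._threshold(2.0)  # AET 0.5
        hits = reportable_set([_nte(0.5, "exact"), _nte(0.4999, "below")], thr)
        assert [r.nte_id for r in hits] == ["exact"]

    def test_ordering_descending(self):
        thr = self._threshold(10.0)
        hits = reportable_set([_nte(0.2, "a"), _nte(0.8, "b"), _nte(0.5, "c")], thr)
        assert [r.nte_id for r in hits] == ["b", "c", "a"]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        concs=st.lists(st.floats(0.001, 2.0), min_size=1, max_size=20),
        uf_lo=st.floats(1.0, 5.0),
        d_uf=st.floats(0.0, 5.0),
    )
    def test_count_non_decreasing_in_uf(self, concs, uf_lo, d_uf):
        results = [_nte(c, str(i)) for i, c in enumerate(concs)]
        n_lo = len(reportable_set(results, self._threshold(uf_lo)))
        n_hi = len(reportable_set(results, self._threshold(uf_lo + d_uf)))
        assert n_hi >= n_lo
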