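"""Quantitation models: definitions, orderings, ISTD correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rrfkit.chem import isotopologue_distribution
from rrfkit.quantify import (
    IstdError,
    QuantError,
    QuantModel,
    compute_response,
    istd_correct,
    model_bias_ratio,
    quantify,
)
from rrfkit.simulate import CampaignConfig, simulate_campaign


def _cmp_rows(toy_features):
    return toy_features[toy_features.compound_id == "cmp"]


def test_model_definitions_on_worked_example(toy_features):
    rows = _cmp_rows(toy_features)
    assert compute_response(rows, QuantModel("ecc")) == 180.0
    assert compute_response(rows, QuantModel("eic_multi")) == 150.0
    assert compute_response(rows, QuantModel("eic_single", species="[M+H]+", isotope=0)) == 100.0
    assert compute_response(rows, QuantModel("bpc")) == 100.0
    # TIC spans the whole sample record set, background included
    assert compute_response(rows, QuantModel("tic"), sample_rows=toy_features) == 257.0


def test_eic_single_variants(toy_features):
    rows = _cmp_rows(toy_features)
    # whole-envelope EIC of one adduct
    assert compute_response(rows, QuantModel("eic_single", species="[M+Na]+", isotope=None)) == 60.0
    # base-species auto-selection picks the most intense adduct
    assert compute_response(rows, QuantModel("eic_single", species=None, isotope=0)) == 100.0
    # mass-based selection
    assert compute_response(rows, QuantModel("eic_single", species=None, isotope=None, mz=123.0)) == 50.0


def test_single_peak_degenerate_case_all_models_agree(toy_features):
    rows = _cmp_rows(toy_features).iloc[:1]
    values = {
        kind: compute_response(rows, QuantModel(kind), sample_rows=rows)
        for kind in ("tic", "bpc", "eic_multi", "ecc")
    }
    values["eic_single"] = compute_response(rows, QuantModel("eic_single", species="[M+H]+"))
    assert set(values.values()) == {100.0}


def test_unmatched_selection_errors_name_the_species(toy_features):
    rows = _cmp_rows(toy_features)
    with pytest.raises(QuantError, match=r"\[M\+K\]\+"):
        compute_response(rows, QuantModel("eic_single", species="[M+K]+"))
    with pytest.raises(QuantError):
        compute_response(rows.iloc[0:0], QuantModel("eic_single", species="[M+H]+"))
    assert compute_response(rows.iloc[0:0], QuantModel("ecc")) == 0.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["[M+H]+", "[M+Na]+", "[M+NH4]+"]),
            st.integers(0, 3),
            st.floats(0.0, 1e6, allow_nan=False),
        ),
        min_size=1,
        max_size=12,
        unique_by=lambda t: (t[0], t[1]),
    )
)
def test_model_response_ordering(peaks):
    """Set inclusion: ECC >= EIC_multi >= EIC_single(base@0), ECC >= BPC, TIC >= ECC."""
    rows = pd.DataFrame(
        [
            ("r", "s", "c", sp, 100.0 + i, 1, iso, inten, 1.0)
            for i, (sp, iso, inten) in enumerate(peaks)
        ],
        columns=["run_id", "sample_id", "compound_id", "species", "mz", "charge", "isotope", "intensity", "rt"],
    )
    ecc = compute_response(rows, QuantModel("ecc"))
    multi = compute_response(rows, QuantModel("eic_multi"))
    bpc = compute_response(rows, QuantModel("bpc"))
    tic = compute_response(rows, QuantModel("tic"), sample_rows=rows)
    assert tic >= ecc >= multi >= 0.0
    assert ecc >= bpc
    if (rows.isotope == 0).any():
        try:
            single = compute_response(rows, QuantModel("eic_single", species=None, isotope=0))
        except QuantError:
            # the auto-selected base species has no monoisotopic peak
            single = 0.0
        assert multi >= single >= 0.0


def test_istd_correct():
    assert istd_correct(100.0, 100.0) == 1.0
    assert istd_correct(200.0, 100.0) == 2.0
    assert istd_correct(0.0, 50.0) == 0.0
    with pytest.raises(IstdError):
        istd_correct(10.0, 0.0)


def test_corrected_response_is_scale_invariant(noiseless_lc_campaign):
    camp = noiseless_lc_campaign
    models = [QuantModel("ecc"), QuantModel("eic_multi")]
    base = quantify(camp.features, camp.design, models)
    scaled_features = camp.features.assign(intensity=camp.features.intensity * 37.5)
    scaled = quantify(scaled_features, camp.design, models)
    assert np.allclose(base["corrected"], scaled["corrected"], rtol=1e-12)
    assert np.allclose(scaled["raw"], base["raw"] * 37.5, rtol=1e-12)


def test_model_bias_ratio(toy_features, fixtures):
    rows = _cmp_rows(toy_features)
    assert model_bias_ratio(rows, QuantModel("ecc"), QuantModel("ecc")) == 1.0
    with pytest.raises(QuantError):
        model_bias_ratio(rows.assign(intensity=0.0), QuantModel("ecc"), QuantModel("ecc"))
    # multi-adduct ESI compound: single-adduct EIC underestimates ECC
    cfg = CampaignConfig(seed=1, runs=1, noise_cv=0.0)
    camp = simulate_campaign([fixtures["dtdpp_like"]], cfg, [fixtures["istd_lc"]])
    sample = camp.features[camp.features.sample_id == camp.features.sample_id.iloc[0]]
    dt = sample[sample.compound_id == "dtdpp_like"]
    ratio = model_bias_ratio(dt, QuantModel("eic_single", isotope=None), QuantModel("ecc"))
    assert ratio < 1.0


def test_high_fragmentation_single_ion_bias(fixtures):
    """Base-fragment EIC of a 40-fragment EI profile captures < 1/4 of the full response."""
    cfg = CampaignConfig(seed=1, runs=1, noise_cv=0.0)
    camp = simulate_campaign(
        [fixtures["methyl_oleate_like"], fixtures["bht_like"]],
        cfg,
        [fixtures["acetophenone_d8"]],
    )
    sample = camp.features[camp.features.sample_id == camp.features.sample_id.iloc[0]]
    mo = sample[sample.compound_id == "methyl_oleate_like"]
    ratio_mo = model_bias_ratio(mo, QuantModel("eic_single", isotope=None), QuantModel("ecc"))
    assert ratio_mo < 0.25
    # minimal fragmentation: the same selection loses much less for the BHT-like profile
    bht = sample[sample.compound_id == "bht_like"]
    ratio_bht = model_bias_ratio(bht, QuantModel("eic_single", isotope=None), QuantModel("ecc"))
    assert ratio_bht > ratio_mo


def test_d8_monoisotopic_eic_under_half_of_ecc(fixtures):
    cfg = CampaignConfig(seed=1, runs=1, noise_cv=0.0)
    camp = simulate_campaign([fixtures["d8_like"]], cfg, [fixtures["acetophenone_d8"]])
    sample = camp.features[camp.features.sample_id == camp.features.sample_id.iloc[0]]
    d8 = sample[sample.compound_id == "d8_like"]
    ratio = model_bias_ratio(d8, QuantModel("eic_single", isotope=0), QuantModel("ecc"))
    assert ratio < 0.5
    expected = isotopologue_distribution("C16H48O8Si8", 1e-12).monoisotopic_abundance
    assert ratio == pytest.approx(expected, rel=1e-9)


def test_quantify_batch_flags_problem_rows(toy_features):
    design = pd.DataFrame(
        [
            ("run001", "s1", "cmp", 1.0, "bkg", 0.5),
            ("run001", "s1", "ghost", 1.0, "bkg", 0.5),
            ("run001", "s1", "bkg", 1.0, "", 0.5),
        ],
        columns=["run_id", "sample_id", "compound_id", "concentration", "istd_id", "istd_concentration"],
    )
    out = quantify(toy_features, design, [QuantModel("ecc")])
    by_cmp = out.set_index("compound_id")
    assert by_cmp.loc["cmp", "corrected"] == pytest.approx(180.0 / 77.0)
    assert by_cmp.loc["ghost", "flag"] == "empty feature set"
    assert by_cmp.loc["bkg", "flag"] == "no internal standard"
    assert np.isnan(by_cmp.loc["bkg", "corrected"])


def test_quantmodel_name_parse_round_trip():
    for model in [
        QuantModel("ecc"),
        QuantModel("eic_single", species="[M+H]+", isotope=1),
        QuantModel("eic_single", species=None, isotope=None),
    ]:
        assert QuantModel.parse(model.name) == model
    with pytest.raises(QuantError):
        QuantModel("chromatogram")
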