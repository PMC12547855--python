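import math
import sys
from dataclasses import replace
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rrfkit.simulate import CampaignConfig, packaged_fixtures, simulate_campaign


@pytest.fixture(scope="session")
def fixtures():
    return packaged_fixtures()


@pytest.fixture
def toy_features():
    """Two-adduct feature set matching the worked arithmetic example:
    [M+H]+ iso0 100 / iso1 20, [M+Na]+ iso0 50 / iso1 10, plus a background
    feature from another compound in the same sample."""
    rows = [
        ("run001", "s1", "cmp", "[M+H]+", 101.0, 1, 0, 100.0, 5.0),
        ("run001", "s1", "cmp", "[M+H]+", 102.0, 1, 1, 20.0, 5.0),
        ("run001", "s1", "cmp", "[M+Na]+", 123.0, 1, 0, 50.0, 5.0),
        ("run001", "s1", "cmp", "[M+Na]+", 124.0, 1, 1, 10.0, 5.0),
        ("run001", "s1", "bkg", "[M+H]+", 200.0, 1, 0, 77.0, 6.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["run_id", "sample_id", "compound_id", "species", "mz", "charge", "isotope", "intensity", "rt"],
    )


@pytest.fixture(scope="session")
def noiseless_lc_campaign(fixtures):
    """One-run noiseless linear LC campaign over the nominal low range."""
    analyte = replace(fixtures["triethyl_citrate_like"], dispersion=0.0, saturation_k=0.0)
    istd = replace(fixtures["istd_lc"], dispersion=0.0)
    config = CampaignConfig(
        seed=7,
        runs=1,
        noise_cv=0.0,
        adduct_drift_concentration=math.inf,
    )
    return simulate_campaign([analyte], config, [istd])
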