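"""Uncertainty factors, analytical evaluation thresholds, and semiquantitation.

The analytical evaluation threshold (AET) is the concentration above which
every extractable must be identified and quantified. It is set first by the
extraction parameters —

    AET_initial [ug/mL] = (DBT [ug/day] / clinical devices per day)
                          * (devices extracted / extraction volume [mL])

— and then divided by an uncertainty factor (UF) derived from the relative
standard deviation of the RRF population of authentic reference standards
analyzed on the day. The default UF strategy is the reciprocal form
UF = 1 / (1 - RSD) with the RSD capped (default 0.9, so UF <= 10); a
percentile-ratio alternative (mean / 16th percentile) and a fixed constant
are available behind the same interface.

Nontarget extractables (NTEs) are semiquantitated against a surrogate's RRF:

    C_NTE = (A_NTE / A_ISTD) * C_ISTD / RRF_surrogate

The quantitation model used for the NTE response must be the one the
surrogate RRF was built with — mixing models silently imports the model's
bias into the reported concentration, so a mismatch raises. RRFs and UFs are
day-of-analysis quantities: they apply only to the run in which the
calibration was collected unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .calibrate import RRFEstimate
from .popstats import PopulationSummary

__all__ = [
    "ThresholdError",
    "ModelMismatchError",
    "ThresholdInputs",
    "UFResult",
    "ThresholdResult",
    "NTEQuantResult",
    "compute_uf",
    "compute_aet",
    "semiquantitate",
    "reportable_set",
]

UF_STRATEGIES = ("rsd_reciprocal", "percentile_ratio", "fixed")


class ThresholdError(ValueError):
    """Raised for invalid threshold inputs or degenerate populations."""


class ModelMismatchError(ValueError):
    """Raised when an NTE response and a surrogate RRF use different models."""


@dataclass(frozen=True)
class ThresholdInputs:
    """Extraction and clinical-exposure parameters seeding the AET."""

    dbt_ug_per_day: float
    devices_extracted: int
    extraction_volume_ml: float
    clinical_devices_per_day: float

    def __post_init__(self) -> None:
        for name in (
            "dbt_ug_per_day",
            "devices_extracted",
            "extraction_volume_ml",
            "clinical_devices_per_day",
        ):
            if getattr(self, name) <= 0:
                raise ThresholdError(f"{name} must be > 0")


@dataclass(frozen=True)
class UFResult:
    strategy: str
    rsd: float
    uf: float
    source: str = ""


@dataclass(frozen=True)
class ThresholdResult:
    aet_initial: float  # ug/mL
    uf: UFResult
    aet_final: float  # ug/mL = aet_initial / uf


@dataclass(frozen=True)
class NTEQuantResult:
    nte_id: str
    surrogate_id: str
    model: str
    corrected_response: float
    concentration: float  # ug/mL
    true_concentration: float | None = None
    relative_bias: float | None = None


def compute_uf(
    summary: PopulationSummary,
    strategy: str = "rsd_reciprocal",
    cap: float | None = 0.9,
    fixed_value: float | None = None,
    source: str = "",
) -> UFResult:
    """Derive the uncertainty factor from an RRF population summary.

    * ``rsd_reciprocal`` — UF = 1 / (1 - min(RSD, cap)); an RSD >= 1 with no
      cap is a degenerate population and raises.
    * ``percentile_ratio`` — UF = mean / p16, the spread of the protective
      lower tail; clamped to >= 1.
    * ``fixed`` — the given constant (must be >= 1).
    """
    if strategy not in UF_STRATEGIES:
        raise ThresholdError(f"unknown UF strategy {strategy!r}")
    if strategy == "fixed":
        if fixed_value is None or fixed_value < 1:
            raise ThresholdError("fixed strategy needs fixed_value >= 1")
        return UFResult(strategy, rsd=summary.rsd if summary else float("nan"), uf=float(fixed_value), source=source)
    if summary.n < 2:
        raise ThresholdError("RSD-based UF needs a population with n >= 2")
    rsd = summary.rsd
    if strategy == "rsd_reciprocal":
        if cap is not None:
            rsd_used = min(rsd, cap)
        else:
            if rsd >= 1:
                raise ThresholdError(f"RSD {rsd:.3f} >= 1 with no cap: degenerate population")
            rsd_used = rsd
        uf = 1.0 / (1.0 - rsd_used)
    else:  # percentile_ratio
        if summary.p16 <= 0:
            raise ThresholdError("percentile_ratio needs a positive 16th percentile")
        uf = summary.mean / summary.p16
        rsd_used = rsd
    return UFResult(strategy, rsd=rsd_used, uf=max(uf, 1.0), source=source)


def compute_aet(inputs: ThresholdInputs, uf: UFResult) -> ThresholdResult:
    """AET from extraction parameters, then divided by the uncertainty factor."""
    aet_initial = (inputs.dbt_ug_per_day / inputs.clinical_devices_per_day) * (
        inputs.devices_extracted / inputs.extraction_volume_ml
    )
    if uf.uf < 1:
        raise ThresholdError("uncertainty factor must be >= 1")
    return ThresholdResult(aet_initial=aet_initial, uf=uf, aet_final=aet_initial / uf.uf)


def semiquantitate(
    nte_response: float,
    istd_response: float,
    istd_concentration: float,
    surrogate: RRFEstimate,
    model: str,
    nte_id: str = "unknown",
    true_concentration: float | None = None,
) -> NTEQuantResult:
    """Semiquantitate an NTE response against a surrogate RRF.

    ``model`` names the quantitation model the NTE response was computed
    with; it must equal the surrogate estimate's model, and the surrogate
    estimate must have passed acceptance.
    """
    if model != surrogate.model:
        raise ModelMismatchError(
            f"NTE response model {model!r} != surrogate RRF model {surrogate.model!r}"
        )
    if not surrogate.accepted:
        raise ThresholdError(
            f"surrogate RRF for {surrogate.compound_id} was rejected: "
            f"{surrogate.rejection_reason or 'unspecified'}"
        )
    if istd_response <= 0:
        raise ThresholdError("internal standard response must be > 0")
    if istd_concentration <= 0 or surrogate.rrf <= 0:
        raise ThresholdError("ISTD concentration and surrogate RRF must be > 0")
    corrected = nte_response / istd_response
    conc = corrected * istd_concentration / surrogate.rrf
    bias = None
    if true_concentration is not None:
        bias = (conc - true_concentration) / true_concentration
    return NTEQuantResult(
        nte_id=nte_id,
        surrogate_id=surrogate.compound_id,
        model=model,
        corrected_response=corrected,
        concentration=conc,
        true_concentration=true_concentration,
        relative_bias=bias,
    )


def reportable_set(
    results: Sequence[NTEQuantResult], threshold: ThresholdResult
) -> list[NTEQuantResult]:
    """NTEs at or above the UF-adjusted AET, ordered by concentration descending.

    The comparison is inclusive (>=): a compound exactly at the threshold is
    reportable, the protective reading of "above which all must be
    identified".
    """
    hits = [r for r in results if r.concentration >= threshold.aet_final]
    return sorted(hits, key=lambda r: (-r.concentration, r.nte_id))


def nte_table(results: Sequence[NTEQuantResult]) -> pd.DataFrame:
    rows = [
        (
            r.nte_id,
            r.surrogate_id,
            r.model,
            r.corrected_response,
            r.concentration,
            r.true_concentration,
            r.relative_bias,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "nte_id",
            "surrogate_id",
            "model",
            "corrected_response",
            "concentration",
            "true_concentration",
            "relative_bias",
        ],
    )
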