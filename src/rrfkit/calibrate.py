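"""RRF estimation: single-point values and weighted slopes over qualified ranges.

The relative response factor of an analyte against an internal standard is

    RRF = (A_analyte / C_analyte) / (A_ISTD / C_ISTD)

at a single concentration, or — preferably — the first-order coefficient of
a weighted linear least-squares fit of the ISTD-corrected response against
concentration over the qualified dynamic range, multiplied by the ISTD
concentration so the two conventions coincide for an origin-passing line.

Weighting options are none, 1/x and 1/x² (x = concentration), matching the
heteroscedasticity of MS responses whose noise is roughly proportional to
signal. Data acceptance follows routine system-suitability practice:
injection replicate RSD below 20% at every level, and a weighted R² above
0.95 (GC-MS, 1/x²) or 0.97 (LC-MS, 1/x). Replicate injections are averaged
per level before fitting; the injection RSD is retained as a diagnostic
rather than used as a fit weight. The intercept is always fitted, never
forced through zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "WEIGHTINGS",
    "FitResult",
    "AcceptanceCriteria",
    "CalibrationSeries",
    "RRFEstimate",
    "weighted_linear_fit",
    "rrf_single_point",
    "rrf_from_slope",
    "rrf_at_max",
    "apply_acceptance",
    "build_series",
    "rrf_table",
]

WEIGHTINGS = ("none", "inv_x", "inv_x2")


class CalibrationError(ValueError):
    """Raised for degenerate calibration inputs."""


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    weighting: str
    n: int


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if np.any(x <= 0):
        raise CalibrationError(f"non-positive concentration with {weighting} weighting")
    return 1.0 / x if weighting == "inv_x" else 1.0 / x**2


def weighted_linear_fit(
    x: Sequence[float], y: Sequence[float], weighting: str = "none"
) -> FitResult:
    """Weighted least-squares line minimizing sum of w_i (y_i - a - b x_i)^2.

    ``weighting`` is one of ``none`` (w=1), ``inv_x`` (w=1/x) or ``inv_x2``
    (w=1/x²). The coefficient of determination is computed on weighted
    residuals about the weighted mean. Requires at least two distinct x.
    """
    if weighting not in WEIGHTINGS:
        raise CalibrationError(f"unknown weighting {weighting!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise CalibrationError("need at least two (x, y) points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise CalibrationError("non-finite calibration data")
    if np.unique(x).size < 2:
        raise CalibrationError("all concentrations identical")
    w = _weights(x, weighting)
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    fitted = intercept + slope * x
    ybar = np.sum(w * y) / np.sum(w)
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(slope, intercept, r2, weighting, int(x.size))


@dataclass(frozen=True)
class AcceptanceCriteria:
    """Dynamic-range qualification thresholds.

    Acceptance requires max per-level injection RSD strictly below
    ``max_injection_rsd``, weighted R² strictly above ``min_r_squared``, and
    the fit performed with ``required_weighting``.
    """

    max_injection_rsd: float = 0.20
    min_r_squared: float = 0.97
    required_weighting: str = "inv_x"

    def __post_init__(self) -> None:
        for name, v in (("max_injection_rsd", self.max_injection_rsd), ("min_r_squared", self.min_r_squared)):
            if not 0.0 < v <= 1.0:
                raise CalibrationError(f"{name} must be in (0, 1], got {v}")
        if self.required_weighting not in WEIGHTINGS:
            raise CalibrationError(f"unknown weighting {self.required_weighting!r}")

    @classmethod
    def gcms(cls) -> "AcceptanceCriteria":
        return cls(max_injection_rsd=0.20, min_r_squared=0.95, required_weighting="inv_x2")

    @classmethod
    def lcms(cls) -> "AcceptanceCriteria":
        return cls(max_injection_rsd=0.20, min_r_squared=0.97, required_weighting="inv_x")

    @classmethod
    def for_technique(cls, technique: str) -> "AcceptanceCriteria":
        return cls.gcms() if technique.upper().startswith("GC") else cls.lcms()


@dataclass(frozen=True)
class CalibrationSeries:
    """ISTD-corrected responses of one compound in one run under one model."""

    run_id: str
    compound_id: str
    model: str
    levels: tuple[tuple[float, tuple[float, ...]], ...]  # (conc, replicate corrected)
    istd_concentration: float

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _ in self.levels):
            raise CalibrationError("concentrations must be > 0")
        if self.istd_concentration <= 0:
            raise CalibrationError("ISTD concentration must be > 0")


@dataclass(frozen=True)
class RRFEstimate:
    """One RRF with its method, weighting, range and fit diagnostics."""

    run_id: str
    compound_id: str
    model: str
    rrf: float
    method: str  # single_point | slope
    weighting: str
    conc_range: tuple[float, float]
    r_squared: float
    n_levels: int
    injection_rsd_max: float
    accepted: bool = True
    rejection_reason: str = ""
    slope: float = float("nan")
    intercept: float = float("nan")


def rrf_single_point(
    corrected: float, analyte_concentration: float, istd_concentration: float
) -> float:
    """Single-point RRF: corrected response scaled by C_ISTD / C_analyte."""
    if analyte_concentration <= 0 or istd_concentration <= 0:
        raise CalibrationError("concentrations must be > 0")
    if corrected < 0:
        raise CalibrationError("corrected response must be >= 0")
    return corrected * istd_concentration / analyte_concentration


def _level_stats(series: CalibrationSeries, conc_range: tuple[float, float] | None):
    low, high = conc_range if conc_range else (-np.inf, np.inf)
    concs, means, rsds = [], [], []
    for conc, reps in series.levels:
        if not low <= conc <= high:
            continue
        arr = np.asarray(reps, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            continue
        m = float(arr.mean())
        concs.append(conc)
        means.append(m)
        if arr.size >= 2 and m > 0:
            rsds.append(float(arr.std(ddof=1)) / m)
        else:
            rsds.append(0.0)
    return np.asarray(concs), np.asarray(means), np.asarray(rsds)


def rrf_from_slope(
    series: CalibrationSeries,
    conc_range: tuple[float, float] | None = None,
    weighting: str = "inv_x",
    criteria: AcceptanceCriteria | None = None,
) -> RRFEstimate:
    """Slope-based RRF over a concentration range.

    Replicates are averaged per level, a weighted line is fitted to the means
    within [low, high], and RRF = slope * C_ISTD. Fewer than two in-range
    levels yields a rejected estimate with reason "insufficient levels". When
    ``criteria`` is given, acceptance is evaluated via
    :func:`apply_acceptance`.
    """
    concs, means, rsds = _level_stats(series, conc_range)
    rng = (
        conc_range
        if conc_range is not None
        else ((float(concs.min()), float(concs.max())) if concs.size else (np.nan, np.nan))
    )
    base = dict(
        run_id=series.run_id,
        compound_id=series.compound_id,
        model=series.model,
        method="slope",
        weighting=weighting,
        conc_range=rng,
    )
    if concs.size < 2 or np.unique(concs).size < 2:
        return RRFEstimate(
            rrf=float("nan"),
            r_squared=float("nan"),
            n_levels=int(concs.size),
            injection_rsd_max=float(rsds.max()) if rsds.size else float("nan"),
            accepted=False,
            rejection_reason="insufficient levels",
            **base,
        )
    fit = weighted_linear_fit(concs, means, weighting)
    rrf = fit.slope * series.istd_concentration
    est = RRFEstimate(
        rrf=rrf,
        r_squared=fit.r_squared,
        n_levels=int(concs.size),
        injection_rsd_max=float(rsds.max()),
        accepted=rrf > 0,
        rejection_reason="" if rrf > 0 else "non-positive slope",
        slope=fit.slope,
        intercept=fit.intercept,
        **base,
    )
    if criteria is not None:
        est = apply_acceptance(est, criteria)
    return est


def rrf_at_max(series: CalibrationSeries, conc_range: tuple[float, float] | None = None) -> RRFEstimate:
    """Single-point RRF at the highest in-range level (the "RRF at max conc" convention)."""
    concs, means, rsds = _level_stats(series, conc_range)
    if concs.size == 0:
        raise CalibrationError("no in-range levels")
    i = int(np.argmax(concs))
    rrf = rrf_single_point(means[i], concs[i], series.istd_concentration)
    return RRFEstimate(
        run_id=series.run_id,
        compound_id=series.compound_id,
        model=series.model,
        rrf=rrf,
        method="single_point",
        weighting="none",
        conc_range=(float(concs[i]), float(concs[i])),
        r_squared=float("nan"),
        n_levels=1,
        injection_rsd_max=float(rsds[i]),
        accepted=rrf > 0,
        rejection_reason="" if rrf > 0 else "non-positive response",
    )


def apply_acceptance(estimate: RRFEstimate, criteria: AcceptanceCriteria) -> RRFEstimate:
    """Evaluate the acceptance criteria against an estimate's diagnostics.

    Structural rejections (insufficient levels, non-positive slope) are
    preserved; threshold checks append their reasons. Acceptance requires
    injection RSD < max, R² > min, and the required weighting — all strict,
    so boundary values reject.
    """
    reasons = [estimate.rejection_reason] if estimate.rejection_reason else []
    if estimate.method == "slope" and estimate.weighting != criteria.required_weighting:
        reasons.append(
            f"weighting {estimate.weighting} != required {criteria.required_weighting}"
        )
    if not (estimate.injection_rsd_max < criteria.max_injection_rsd):
        reasons.append("injection RSD")
    if estimate.method == "slope" and not (estimate.r_squared > criteria.min_r_squared):
        reasons.append("r_squared")
    return replace(
        estimate,
        accepted=not reasons,
        rejection_reason="; ".join(reasons),
    )


def build_series(
    responses: pd.DataFrame, design: pd.DataFrame
) -> list[CalibrationSeries]:
    """Assemble calibration series from a responses table and its design.

    Joins on (run_id, sample_id, compound_id) and groups by
    (run, compound, model). Rows with NaN corrected responses are dropped
    (they carry flags upstream).
    """
    merged = responses.merge(
        design[["run_id", "sample_id", "compound_id", "concentration", "istd_concentration"]],
        on=["run_id", "sample_id", "compound_id"],
        how="inner",
    )
    merged = merged[np.isfinite(merged["corrected"])]
    out: list[CalibrationSeries] = []
    for (run_id, cid, model), grp in merged.groupby(
        ["run_id", "compound_id", "model"], sort=True
    ):
        levels = tuple(
            (float(conc), tuple(sub["corrected"].tolist()))
            for conc, sub in grp.groupby("concentration", sort=True)
        )
        istd_conc = float(grp["istd_concentration"].iloc[0])
        out.append(CalibrationSeries(run_id, cid, model, levels, istd_conc))
    return out


def rrf_table(
    responses: pd.DataFrame,
    design: pd.DataFrame,
    conc_range: tuple[float, float] | None = None,
    weighting: str = "inv_x",
    criteria: AcceptanceCriteria | None = None,
    method: str = "slope",
) -> pd.DataFrame:
    """Per-(run, compound, model) RRF estimates as a flat table."""
    rows = []
    for series in build_series(responses, design):
        if method == "slope":
            est = rrf_from_slope(series, conc_range, weighting, criteria)
        elif method == "single_point":
            est = rrf_at_max(series, conc_range)
            if criteria is not None:
                est = apply_acceptance(est, criteria)
        else:
            raise CalibrationError(f"unknown method {method!r}")
        rows.append(
            (
                est.run_id,
                est.compound_id,
                est.model,
                est.method,
                est.weighting,
                est.conc_range[0],
                est.conc_range[1],
                est.rrf,
                est.r_squared,
                est.n_levels,
                est.injection_rsd_max,
                est.accepted,
                est.rejection_reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "compound_id",
            "model",
            "method",
            "weighting",
            "range_low",
            "range_high",
            "rrf",
            "r2",
            "n_levels",
            "injection_rsd_max",
            "accepted",
            "rejection_reason",
        ],
    )
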