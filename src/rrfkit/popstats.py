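"""Population statistics of per-run RRFs.

A response factor measured once says nothing about where it falls in the
distribution a method actually produces day to day. This module aggregates
per-run RRF estimates into population summaries (mean, sample SD, RSD,
percentiles) and compares populations with Welch's unequal-variance t-test —
the appropriate comparison when per-compound RRF variances differ, which
they demonstrably do even within a chemical class.

Conventions: sample (n-1) standard deviation throughout, because populations
are finite samples of an ongoing measurement process and an uncertainty
factor built from them must not be anti-conservative; percentiles by linear
interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsError",
    "PopulationSummary",
    "WelchResult",
    "summarize",
    "welch_test",
    "variance_inequality_report",
    "populations_from_rrf_table",
    "summary_table",
]


class StatsError(ValueError):
    """Raised for degenerate population inputs."""


REPORT_COLUMNS = [
    "a",
    "b",
    "rsd_a",
    "rsd_b",
    "rsd_ratio",
    "welch_t",
    "welch_df",
    "welch_p_raw",
    "mean_significant",
    "levene_p_raw",
    "variance_significant",
]


@dataclass(frozen=True)
class PopulationSummary:
    n: int
    mean: float
    sd: float
    rsd: float
    p16: float
    p50: float
    p84: float
    min: float
    max: float


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def summarize(values: Sequence[float]) -> PopulationSummary:
    """Moments and percentiles of an RRF population.

    Uses the sample (n-1) standard deviation; a single-value population has
    sd = rsd = 0. Percentiles interpolate linearly between order statistics.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise StatsError("empty population")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
    rsd = sd / mean if mean != 0 else float("inf")
    p16, p50, p84 = (float(v) for v in np.percentile(arr, [16, 50, 84]))
    return PopulationSummary(
        n=int(arr.size),
        mean=mean,
        sd=sd,
        rsd=rsd,
        p16=p16,
        p50=p50,
        p84=p84,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def welch_test(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> WelchResult:
    """Two-tailed Welch unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # degenerate but well-defined: identical constants
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0, alpha=alpha)
        raise StatsError("both group variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), alpha=alpha)


def populations_from_rrf_table(
    rrf_table: pd.DataFrame, accepted_only: bool = True
) -> dict[tuple[str, str, str], np.ndarray]:
    """Group an rrf_table into per-(compound, model, method) populations of run RRFs.

    By default only accepted estimates enter the population (the
    qualification filters exist to keep bad days out of the UF); pass
    ``accepted_only=False`` to keep everything finite.
    """
    df = rrf_table
    if accepted_only and "accepted" in df.columns:
        df = df[df["accepted"].astype(bool)]
    df = df[np.isfinite(df["rrf"])]
    out: dict[tuple[str, str, str], np.ndarray] = {}
    for (cid, model, method), grp in df.groupby(["compound_id", "model", "method"], sort=True):
        if grp["run_id"].duplicated().any():
            raise StatsError(f"multiple RRFs per run for {cid}/{model}/{method}")
        out[(cid, model, method)] = grp["rrf"].to_numpy()
    return out


def summary_table(populations: Mapping[tuple[str, str, str], Sequence[float]]) -> pd.DataFrame:
    rows = []
    for (cid, model, method), values in populations.items():
        s = summarize(values)
        rows.append((cid, model, method, s.n, s.mean, s.sd, s.rsd, s.p16, s.p50, s.p84, s.min, s.max))
    return pd.DataFrame(
        rows,
        columns=["compound_id", "model", "method", "n", "mean", "sd", "rsd", "p16", "p50", "p84", "min", "max"],
    )


def variance_inequality_report(
    populations: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise RSD ratios, Welch mean tests, and Levene variance tests.

    Welch compares population means; Brown-Forsythe/Levene (median-centered)
    compares variances — the relevant check for "unequal variance even within
    a chemical class". P-values are reported raw (no multiple-testing
    correction) and flagged as such in the column names.
    """
    if len(populations) < 2:
        raise StatsError("need at least two populations to compare")
    rows = []
    for name_a, name_b in combinations(populations, 2):
        va, vb = np.asarray(populations[name_a], float), np.asarray(populations[name_b], float)
        sa, sb = summarize(va), summarize(vb)
        w = welch_test(va, vb, alpha)
        if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0:
            lev_p = 1.0
        else:
            _, lev_p = stats.levene(va, vb, center="median")
        rows.append(
            (
                name_a,
                name_b,
                sa.rsd,
                sb.rsd,
                sa.rsd / sb.rsd if sb.rsd > 0 else np.inf,
                w.t,
                w.df,
                w.p,
                w.significant,
                float(lev_p),
                lev_p < alpha,
            )
        )
    return pd.DataFrame(
        rows,
        columns=REPORT_COLUMNS,
    )
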