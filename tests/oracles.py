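"""Independent brute-force / closed-form oracles used only by tests.

These deliberately avoid the package's computational routes: the isotope
oracle enumerates every isotope assignment combinatorially instead of
convolving; the weighted-fit oracle solves the 2x2 normal equations in
closed form instead of least squares; the Welch oracle evaluates the
textbook formulas directly.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy import stats


def _compositions(n: int, k: int):
    """All k-tuples of non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)


def brute_force_envelope(
    counts: dict[str, int], isotopes: dict[str, list[tuple[int, float, float]]]
) -> dict[int, float]:
    """Exhaustive isotopologue distribution by multinomial enumeration.

    For each element, every composition of its atoms over its isotopes is
    enumerated with the multinomial probability; elements are combined by
    exhaustive cross-product over their shift distributions.
    """
    total: dict[int, float] = {0: 1.0}
    for el, n in counts.items():
        rows = isotopes[el]
        k = len(rows)
        el_dist: dict[int, float] = {}
        for comp in _compositions(n, k):
            prob = math.factorial(n)
            shift = 0
            for c, (off, _, p) in zip(comp, rows):
                prob = prob / math.factorial(c) * (p**c)
                shift += c * off
            el_dist[shift] = el_dist.get(shift, 0.0) + prob
        merged: dict[int, float] = {}
        for s1, p1 in total.items():
            for s2, p2 in el_dist.items():
                merged[s1 + s2] = merged.get(s1 + s2, 0.0) + p1 * p2
        total = merged
    return total


def wls_normal_equations(x, y, weighting: str) -> tuple[float, float, float]:
    """Closed-form weighted least squares: slope, intercept, weighted R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if weighting == "none":
        w = np.ones_like(x)
    elif weighting == "inv_x":
        w = 1.0 / x
    elif weighting == "inv_x2":
        w = 1.0 / x**2
    else:
        raise ValueError(weighting)
    sw = w.sum()
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    slope = (sw * swxy - swx * swy) / (sw * swxx - swx**2)
    intercept = (swy - slope * swx) / sw
    ybar = swy / sw
    ss_res = (w * (y - intercept - slope * x) ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def welch_formula(a, b) -> tuple[float, float, float]:
    """Textbook Welch t statistic, Welch-Satterthwaite df, two-tailed p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
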