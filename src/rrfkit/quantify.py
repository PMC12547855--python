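"""Quantitation models over centroided feature tables.

The response of a compound depends on which ions you integrate. The models
implemented here mirror standard practice:

* **TIC** — total ion chromatogram: every feature in the sample record set.
* **BPC** — base peak chromatogram: the single most intense peak.
* **EIC (single)** — one selected (species, isotope) peak, optionally the
  species' whole envelope.
* **EIC (multi)** — the monoisotopic peak of every adduct species.
* **ECC** — extracted compound chromatogram: all ions attributed to the
  compound (all adducts/fragments, multimers, charge states, isotopes).

Feature-to-compound attribution is taken from the feature table's
``compound_id`` column (upstream grouping or the simulator); this module does
not re-deconvolute. Internal-standard correction divides the analyte response
by the ISTD response; the ISTD is always integrated as its full ECC, which
cancels in relative quantities and so cannot bias model comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantError",
    "IstdError",
    "QuantModel",
    "compute_response",
    "istd_correct",
    "model_bias_ratio",
    "quantify",
]

MODEL_KINDS = ("tic", "bpc", "eic_single", "eic_multi", "ecc")


class QuantError(ValueError):
    """Raised for unresolvable quantitation-model selections."""


class IstdError(ValueError):
    """Raised when the internal-standard response is unusable."""


@dataclass(frozen=True)
class QuantModel:
    """A quantitation model specification.

    For ``eic_single``: ``species`` selects the adduct/fragment label
    (``None`` = the compound's base species, i.e. the most intense one in the
    sample — the "base peak EIC" strategy) and ``isotope`` selects the
    isotope index (``None`` = the species' whole envelope; default 0, the
    monoisotopic peak). ``mz``/``tol_ppm`` allow mass-based selection instead
    of a label.
    """

    kind: str
    species: str | None = None
    isotope: int | None = 0
    mz: float | None = None
    tol_ppm: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise QuantError(f"unknown quantitation model kind {self.kind!r}")
        if self.tol_ppm <= 0:
            raise QuantError("mass tolerance must be > 0 ppm")

    @property
    def name(self) -> str:
        if self.kind != "eic_single":
            return self.kind
        sel = self.species if self.species is not None else (
            f"mz={self.mz:.4f}" if self.mz is not None else "base"
        )
        iso = "env" if self.isotope is None else str(self.isotope)
        return f"eic_single[{sel}@{iso}]"

    @classmethod
    def parse(cls, name: str) -> "QuantModel":
        """Inverse of :attr:`name` for the CLI (``ecc``, ``eic_single[base@0]``...)."""
        name = name.strip()
        if "[" not in name:
            return cls(kind=name)
        kind, _, rest = name.partition("[")
        sel, _, iso = rest.rstrip("]").rpartition("@")
        isotope = None if iso == "env" else int(iso)
        species = None if sel in ("", "base") else sel
        return cls(kind=kind, species=species, isotope=isotope)


def _select_species(rows: pd.DataFrame, model: QuantModel) -> pd.DataFrame:
    if model.species is not None:
        sel = rows[rows["species"] == model.species]
        if sel.empty:
            raise QuantError(f"EIC selection {model.species!r} not found in feature rows")
        return sel
    if model.mz is not None:
        tol = model.mz * model.tol_ppm * 1e-6
        sel = rows[(rows["mz"] - model.mz).abs() <= tol]
        if sel.empty:
            raise QuantError(f"no feature within {model.tol_ppm} ppm of m/z {model.mz}")
        return sel
    # base species: largest summed intensity
    totals = rows.groupby("species", sort=True)["intensity"].sum()
    return rows[rows["species"] == totals.idxmax()]


def compute_response(
    rows: pd.DataFrame,
    model: QuantModel,
    sample_rows: pd.DataFrame | None = None,
) -> float:
    """Raw response of one (run, sample, compound) record set under a model.

    ``rows`` are the features attributed to the compound; ``sample_rows``,
    when given, is the full sample record set used by TIC (defaults to
    ``rows``). Empty ``rows`` yield 0.0 for the TIC-family models and raise
    :class:`QuantError` for EIC models, whose selections cannot resolve.
    """
    if model.kind == "tic":
        pool = sample_rows if sample_rows is not None else rows
        return float(pool["intensity"].sum()) if len(pool) else 0.0
    if rows is None or rows.empty:
        if model.kind in ("bpc", "ecc"):
            return 0.0
        raise QuantError(f"no feature rows to resolve {model.name}")
    if model.kind == "ecc":
        return float(rows["intensity"].sum())
    if model.kind == "bpc":
        return float(rows["intensity"].max())
    if model.kind == "eic_multi":
        return float(rows.loc[rows["isotope"] == 0, "intensity"].sum())
    sel = _select_species(rows, model)
    if model.isotope is not None:
        sel = sel[sel["isotope"] == model.isotope]
        if sel.empty:
            raise QuantError(
                f"EIC selection {model.name} matched no isotope-{model.isotope} peak"
            )
    return float(sel["intensity"].sum())


def istd_correct(raw: float, istd_raw: float) -> float:
    """Internal-standard-corrected response: raw / ISTD raw."""
    if istd_raw <= 0:
        raise IstdError(f"internal standard response {istd_raw} is not positive")
    return float(raw) / float(istd_raw)


def model_bias_ratio(
    rows: pd.DataFrame,
    model_a: QuantModel,
    model_b: QuantModel,
    sample_rows: pd.DataFrame | None = None,
) -> float:
    """Ratio of responses under two models, A / B (the model-selection bias)."""
    b = compute_response(rows, model_b, sample_rows)
    if b <= 0:
        raise QuantError(f"denominator model {model_b.name} has non-positive response")
    return compute_response(rows, model_a, sample_rows) / b


def quantify(
    features: pd.DataFrame,
    design: pd.DataFrame,
    models: Sequence[QuantModel],
) -> pd.DataFrame:
    """Batch-compute corrected responses for every designed (run, sample, compound).

    Returns one row per design entry per model with columns ``run_id,
    sample_id, compound_id, model, raw, istd_raw, corrected, flag``. Rows
    whose features are missing or whose ISTD failed carry NaN responses and a
    non-empty ``flag`` rather than aborting the batch.
    """
    out_rows: list[tuple] = []
    sample_groups = dict(tuple(features.groupby(["run_id", "sample_id"], sort=False)))
    for _, d in design.iterrows():
        key = (d["run_id"], d["sample_id"])
        sample_df = sample_groups.get(key)
        if sample_df is None:
            for model in models:
                out_rows.append((*key, d["compound_id"], model.name, np.nan, np.nan, np.nan, "missing sample"))
            continue
        comp_df = sample_df[sample_df["compound_id"] == d["compound_id"]]
        istd_id = d.get("istd_id", "")
        istd_df = (
            sample_df[sample_df["compound_id"] == istd_id]
            if isinstance(istd_id, str) and istd_id
            else None
        )
        istd_raw = float(istd_df["intensity"].sum()) if istd_df is not None else np.nan
        for model in models:
            flag = ""
            try:
                raw = compute_response(comp_df, model, sample_rows=sample_df)
            except QuantError as exc:
                out_rows.append((*key, d["compound_id"], model.name, np.nan, istd_raw, np.nan, str(exc)))
                continue
            if comp_df.empty:
                flag = "empty feature set"
            if istd_df is None:
                corrected = np.nan
                flag = flag or "no internal standard"
            else:
                try:
                    corrected = istd_correct(raw, istd_raw)
                except IstdError as exc:
                    corrected = np.nan
                    flag = str(exc)
            out_rows.append(
                (*key, d["compound_id"], model.name, raw, istd_raw, corrected, flag)
            )
    return pd.DataFrame(
        out_rows,
        columns=[
            "run_id",
            "sample_id",
            "compound_id",
            "model",
            "raw",
            "istd_raw",
            "corrected",
            "flag",
        ],
    )
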