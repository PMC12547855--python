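"""Synthetic multi-day MS calibration campaigns for pipeline testing.

Real extractables/leachables calibration data carries structure that any
quantitation pipeline must survive: multi-adduct ESI ensembles whose relative
ratios drift between instrument calibrations, EI fragmentation of widely
varying extent, formula-derived isotope envelopes, concentration-dependent
nonlinearity of opposite signs (ESI droplet saturation vs GC column
overload), injection-replicate noise, isotopically labeled internal standards
spiked mid-range, and day-to-day response dispersion that is unequal across
compounds. This module generates centroided feature tables with exactly that
structure from explicit latent parameters, so every downstream stage can be
tested — and its estimators validated against ground truth — without
instrument data.

Generative model, per instrument calibration ("run"):

* A shared run factor ``z0 ~ N(0,1)`` and per-compound factors ``z_c``
  combine into a lognormal response multiplier
  ``exp(sigma_c * (sqrt(rho) * z0 + sqrt(1-rho) * z_c))`` where ``sigma_c``
  is the compound's day-to-day dispersion and ``rho`` (default 0.7) is the
  variance fraction shared across compounds. Internal standards use the same
  ``z0`` with their own (smaller) dispersion, so ISTD correction removes part
  but not all of the run effect.
* ESI adduct ratios are resampled per run from a Dirichlet distribution
  centered on each compound's propensities with concentration parameter
  ``kappa * propensities`` (``kappa -> inf`` recovers the propensities
  exactly); EI fragment fractions are held fixed.
* Expected total response at concentration C is
  ``coefficient * multiplier * g(C)`` with g one of linear C,
  saturating C/(1+kC), or overload-enhancing C*min(1+kC, cap).
* The total is spread over species by the run's adduct/fragment fractions
  and over isotopologue peaks by the chem-module envelope of the ion
  formula, then multiplied by a per-injection lognormal noise factor of the
  configured CV (mean 1).

All randomness is keyed deterministically by (seed, role, run, compound, ...)
so repeated calls are byte-identical and a nontarget extractable simulated
into an existing run context shares that run's latent draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    ElementalFormula,
    IonSpecies,
    NOMINAL_MASS_SPACING,
    apply_adduct,
    isotopologue_distribution,
    parse_formula,
)

__all__ = [
    "SimulationError",
    "CompoundSpec",
    "CampaignConfig",
    "Campaign",
    "simulate_campaign",
    "simulate_nte_sample",
    "packaged_fixtures",
    "fixture_sets",
]

TECHNIQUES = ("GCMS", "LCMS_pos", "LCMS_neg")

#: Default cap on the overload enhancement factor 1 + k*C.
OVERLOAD_CAP = 10.0


class SimulationError(ValueError):
    """Raised for invalid simulator specifications."""


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _rng(seed: int, role: str, *keys: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, _crc(role), *keys])


@dataclass(frozen=True)
class _Species:
    """One ion species of a compound: adduct or EI fragment."""

    label: str
    fraction: float  # propensity / fragment share of total ion current
    mz: float
    charge: int
    envelope: tuple[tuple[int, float], ...]  # (isotope index, abundance share)


@dataclass(frozen=True)
class CompoundSpec:
    """Latent description of one monitored compound (or internal standard).

    ``response_coefficient`` is the ideal-linear area per (ug/mL);
    ``adduct_propensities`` (ESI) or ``fragmentation_profile`` (EI) describe
    how the total ion current splits across species and must sum to 1;
    ``saturation_k`` is the per-compound curvature of the configured
    nonlinearity; ``dispersion`` is the lognormal sigma of the day-to-day
    response multiplier.
    """

    id: str
    formula: ElementalFormula
    technique: str
    response_coefficient: float = 1.0
    adduct_propensities: Mapping[str, float] | None = None
    fragmentation_profile: tuple[tuple[float, float], ...] | None = None
    saturation_k: float = 0.0
    dispersion: float = 0.0
    istd_id: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            object.__setattr__(self, "formula", parse_formula(self.formula))
        if self.technique not in TECHNIQUES:
            raise SimulationError(f"unknown technique {self.technique!r}")
        if self.response_coefficient <= 0:
            raise SimulationError(f"{self.id}: response coefficient must be > 0")
        if self.dispersion < 0:
            raise SimulationError(f"{self.id}: dispersion must be >= 0")
        if self.technique == "GCMS":
            if not self.fragmentation_profile:
                raise SimulationError(f"{self.id}: GCMS compound needs a fragmentation profile")
            object.__setattr__(
                self, "fragmentation_profile", tuple((float(m), float(f)) for m, f in self.fragmentation_profile)
            )
            total = sum(f for _, f in self.fragmentation_profile)
        else:
            if not self.adduct_propensities:
                raise SimulationError(f"{self.id}: ESI compound needs adduct propensities")
            object.__setattr__(self, "adduct_propensities", dict(self.adduct_propensities))
            total = sum(self.adduct_propensities.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"{self.id}: species fractions sum to {total}, not 1")

    def species(self, envelope_prune: float = 1e-12) -> list[_Species]:
        """Ion species with isotopologue envelopes.

        ESI species are the listed adducts applied to the neutral formula.
        EI fragments are modeled as singly charged species carrying the
        neutral molecule's envelope (fragment compositions are not tracked;
        see the methods note).
        """
        out: list[_Species] = []
        if self.technique == "GCMS":
            env = tuple(isotopologue_distribution(self.formula, envelope_prune).peaks)
            for mz, frac in self.fragmentation_profile:
                out.append(_Species(f"frag_{mz:.4f}", frac, mz, 1, env))
        else:
            for label, frac in self.adduct_propensities.items():
                ion: IonSpecies = apply_adduct(self.formula, label)
                env = tuple(isotopologue_distribution(ion.formula, envelope_prune).peaks)
                out.append(_Species(label, frac, ion.mz, ion.charge, env))
        return out


@dataclass(frozen=True)
class CampaignConfig:
    """Design of a simulated calibration campaign.

    ``adduct_drift_concentration`` is the Dirichlet concentration ``kappa``
    controlling day-level adduct-ratio resampling (``math.inf`` disables
    drift). ``noise_cv`` is the per-injection multiplicative noise CV.
    """

    levels: tuple[float, ...] = (0.025, 0.05, 0.1, 0.25, 0.5, 1.0)
    runs: int = 1
    injections_per_level: int = 3
    noise_cv: float = 0.05
    adduct_drift_concentration: float = 50.0
    nonlinearity: str = "linear"
    seed: int = 0
    istd_concentration: float | None = None
    istd_rho: float = 0.7
    envelope_prune: float = 1e-12

    def __post_init__(self) -> None:
        levels = tuple(float(c) for c in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels or any(c <= 0 for c in levels):
            raise SimulationError("levels must be positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise SimulationError("levels must be strictly increasing")
        if self.runs < 1:
            raise SimulationError("runs must be >= 1")
        if self.injections_per_level < 1:
            raise SimulationError("injections per level must be >= 1")
        if self.noise_cv < 0:
            raise SimulationError("noise CV must be >= 0")
        if self.nonlinearity not in ("linear", "saturating", "overload_enhancing"):
            raise SimulationError(f"unknown nonlinearity {self.nonlinearity!r}")
        if not 0.0 <= self.istd_rho <= 1.0:
            raise SimulationError("istd_rho must be in [0, 1]")

    @property
    def istd_level(self) -> float:
        """ISTD spiked concentration: configured value or the geometric midpoint."""
        if self.istd_concentration is not None:
            return self.istd_concentration
        return math.sqrt(self.levels[0] * self.levels[-1])


def _g(conc: np.ndarray | float, kind: str, k: float) -> np.ndarray | float:
    """Concentration-response shape: the nonlinearity families the campaign supports."""
    c = np.asarray(conc, dtype=float)
    if kind == "linear" or k == 0.0:
        out = c
    elif kind == "saturating":
        out = c / (1.0 + k * c)
    else:  # overload_enhancing
        out = c * np.minimum(1.0 + k * c, OVERLOAD_CAP)
    return out if isinstance(conc, np.ndarray) else float(out)


def _run_multiplier(spec: CompoundSpec, config: CampaignConfig, run: int) -> float:
    if spec.dispersion == 0.0:
        return 1.0
    z0 = _rng(config.seed, "run-shared", run).standard_normal()
    zc = _rng(config.seed, "run-compound", run, _crc(spec.id)).standard_normal()
    rho = config.istd_rho
    return float(np.exp(spec.dispersion * (math.sqrt(rho) * z0 + math.sqrt(1.0 - rho) * zc)))


def _day_fractions(spec: CompoundSpec, config: CampaignConfig, run: int) -> np.ndarray:
    """Per-run species fractions: Dirichlet drift for ESI adducts, fixed for EI."""
    if spec.technique == "GCMS":
        return np.array([f for _, f in spec.fragmentation_profile])
    p = np.array(list(spec.adduct_propensities.values()), dtype=float)
    kappa = config.adduct_drift_concentration
    if not math.isfinite(kappa):
        return p
    rng = _rng(config.seed, "adduct-drift", run, _crc(spec.id))
    return rng.dirichlet(kappa * p)


def _noise_factors(
    spec: CompoundSpec, config: CampaignConfig, run: int, n: int, tag: str = ""
) -> np.ndarray:
    if config.noise_cv == 0.0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    keys = [run, _crc(spec.id)] + ([_crc(tag)] if tag else [])
    rng = _rng(config.seed, "injection-noise", *keys)
    return np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma**2)


def _rt(compound_id: str) -> float:
    return round(2.0 + (_crc(compound_id) % 1000) / 100.0, 2)


_FEATURE_DTYPES = {
    "run_id": str,
    "sample_id": str,
    "compound_id": str,
    "species": str,
    "mz": float,
    "charge": int,
    "isotope": int,
    "intensity": float,
    "rt": float,
}


@dataclass
class Campaign:
    """Output bundle of :func:`simulate_campaign` (and the NTE run context)."""

    features: pd.DataFrame
    design: pd.DataFrame
    truth: dict
    compounds: tuple[CompoundSpec, ...]
    istds: tuple[CompoundSpec, ...]
    config: CampaignConfig

    def run_ids(self) -> list[str]:
        return list(self.truth["runs"].keys())


def _emit_compound(
    spec: CompoundSpec,
    config: CampaignConfig,
    run: int,
    run_id: str,
    sample_ids: Sequence[str],
    concentrations: np.ndarray,
    multiplier: float,
    fractions: np.ndarray,
    compound_id: str | None = None,
    noise_tag: str = "",
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Feature rows for one compound across the given samples of one run.

    Returns (column arrays, latent per-sample total responses before noise).
    """
    species = spec.species(config.envelope_prune)
    labels, mzs, charges, isotopes, shares = [], [], [], [], []
    for sp, frac in zip(species, fractions):
        for iso_index, (shift, ab) in enumerate(sp.envelope):
            labels.append(sp.label)
            mzs.append(sp.mz + shift * NOMINAL_MASS_SPACING / abs(sp.charge))
            charges.append(sp.charge)
            isotopes.append(iso_index)
            shares.append(frac * ab)
    shares_arr = np.array(shares)
    n_template = len(shares_arr)
    n_samples = len(sample_ids)

    latent = spec.response_coefficient * multiplier * _g(concentrations, config.nonlinearity, spec.saturation_k)
    noise = _noise_factors(spec, config, run, n_samples, noise_tag)
    totals = latent * noise
    intensities = np.outer(totals, shares_arr).ravel()

    cid = compound_id if compound_id is not None else spec.id
    cols = {
        "run_id": np.repeat(run_id, n_samples * n_template),
        "sample_id": np.repeat(np.asarray(sample_ids, dtype=object), n_template),
        "compound_id": np.repeat(cid, n_samples * n_template),
        "species": np.tile(np.asarray(labels, dtype=object), n_samples),
        "mz": np.tile(np.asarray(mzs), n_samples),
        "charge": np.tile(np.asarray(charges), n_samples),
        "isotope": np.tile(np.asarray(isotopes), n_samples),
        "intensity": intensities,
        "rt": np.repeat(_rt(spec.id), n_samples * n_template),
    }
    return cols, latent


def simulate_campaign(
    compounds: Sequence[CompoundSpec],
    config: CampaignConfig,
    istds: Sequence[CompoundSpec] = (),
) -> Campaign:
    """Simulate a multi-run calibration campaign.

    Every analyte in ``compounds`` is injected at every level with the
    configured number of replicate injections per run; internal standards in
    ``istds`` are spiked at the fixed ISTD concentration in every sample.
    Returns the feature table, the calibration design, and a truth record of
    all latent draws.
    """
    if not compounds:
        raise SimulationError("empty compound list")
    techniques = {c.technique for c in compounds} | {c.technique for c in istds}
    if len(techniques) > 1:
        raise SimulationError(f"compounds mix techniques: {sorted(techniques)}")
    istd_by_id = {s.id: s for s in istds}
    for c in compounds:
        if c.istd_id is not None and c.istd_id not in istd_by_id:
            raise SimulationError(f"{c.id}: internal standard {c.istd_id!r} not provided")

    levels = np.asarray(config.levels)
    n_inj = config.injections_per_level
    istd_conc = config.istd_level

    frames: list[dict[str, np.ndarray]] = []
    design_rows: list[tuple] = []
    truth: dict = {
        "seed": config.seed,
        "istd_concentration": istd_conc,
        "compounds": {
            c.id: {
                "response_coefficient": c.response_coefficient,
                "dispersion": c.dispersion,
                "saturation_k": c.saturation_k,
                "istd_id": c.istd_id,
                "true_rrf_vs_istd": (
                    c.response_coefficient / istd_by_id[c.istd_id].response_coefficient
                    if c.istd_id
                    else None
                ),
            }
            for c in compounds
        },
        "runs": {},
    }

    for run in range(config.runs):
        run_id = f"run{run + 1:03d}"
        sample_ids = [
            f"{run_id}_L{li + 1:02d}_r{inj + 1}"
            for li in range(len(levels))
            for inj in range(n_inj)
        ]
        concs = np.repeat(levels, n_inj)
        run_truth: dict = {"multipliers": {}, "species_fractions": {}}

        for spec in compounds:
            mult = _run_multiplier(spec, config, run)
            fracs = _day_fractions(spec, config, run)
            run_truth["multipliers"][spec.id] = mult
            run_truth["species_fractions"][spec.id] = {
                sp.label: float(f) for sp, f in zip(spec.species(config.envelope_prune), fracs)
            }
            cols, _ = _emit_compound(
                spec, config, run, run_id, sample_ids, concs, mult, fracs
            )
            frames.append(cols)
            for sid, conc in zip(sample_ids, concs):
                design_rows.append(
                    (run_id, sid, spec.id, float(conc), spec.istd_id or "", istd_conc)
                )

        for spec in istds:
            mult = _run_multiplier(spec, config, run)
            fracs = _day_fractions(spec, config, run)
            run_truth["multipliers"][spec.id] = mult
            cols, _ = _emit_compound(
                spec,
                config,
                run,
                run_id,
                sample_ids,
                np.full(len(sample_ids), istd_conc),
                mult,
                fracs,
            )
            frames.append(cols)

        truth["runs"][run_id] = run_truth

    features = pd.DataFrame(
        {name: np.concatenate([f[name] for f in frames]) for name in _FEATURE_DTYPES}
    ).astype(_FEATURE_DTYPES)
    design = pd.DataFrame(
        design_rows,
        columns=[
            "run_id",
            "sample_id",
            "compound_id",
            "concentration",
            "istd_id",
            "istd_concentration",
        ],
    )
    return Campaign(features, design, truth, tuple(compounds), tuple(istds), config)


def simulate_nte_sample(
    campaign: Campaign,
    nte: CompoundSpec,
    true_concentration: float,
    run_id: str,
    sample_id: str = "NTE01",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a nontarget-extractable sample inside an existing run.

    The NTE's features are generated with its own adduct/fragment ensemble
    and envelope but the run context's latent draws: the shared run factor,
    the day's adduct ratios (keyed by compound id, so an NTE that *is* a
    calibrated compound reproduces that compound's multiplier), and the same
    internal standards. Feature rows carry ``compound_id`` "unknown"; the
    returned truth record keeps the real identity and concentration for
    later bias evaluation.
    """
    if run_id not in campaign.truth["runs"]:
        raise SimulationError(f"run {run_id!r} not in campaign context")
    if true_concentration <= 0:
        raise SimulationError("true concentration must be > 0")
    config = campaign.config
    run = int(run_id.removeprefix("run")) - 1

    frames = []
    mult = _run_multiplier(nte, config, run)
    fracs = _day_fractions(nte, config, run)
    cols, _ = _emit_compound(
        nte,
        config,
        run,
        run_id,
        [sample_id],
        np.array([true_concentration]),
        mult,
        fracs,
        compound_id="unknown",
        noise_tag=f"nte:{sample_id}",
    )
    frames.append(cols)
    for spec in campaign.istds:
        mult_i = _run_multiplier(spec, config, run)
        fracs_i = _day_fractions(spec, config, run)
        cols, _ = _emit_compound(
            spec,
            config,
            run,
            run_id,
            [sample_id],
            np.array([config.istd_level]),
            mult_i,
            fracs_i,
            noise_tag=f"nte:{sample_id}",
        )
        frames.append(cols)

    features = pd.DataFrame(
        {name: np.concatenate([f[name] for f in frames]) for name in _FEATURE_DTYPES}
    ).astype(_FEATURE_DTYPES)
    truth = {
        "nte_id": nte.id,
        "run_id": run_id,
        "sample_id": sample_id,
        "true_concentration": float(true_concentration),
        "multiplier": mult,
        "istd_concentration": config.istd_level,
    }
    return features, truth


# -- packaged fixtures -------------------------------------------------------


def _rank_power_profile(n: int, exponent: float, mz0: float, spacing: float) -> tuple:
    """EI profile with rank-i fraction proportional to i**(-exponent)."""
    weights = np.arange(1, n + 1, dtype=float) ** (-exponent)
    fractions = weights / weights.sum()
    # renormalize exactly to 1 against float round-off
    fractions[-1] += 1.0 - fractions.sum()
    return tuple((mz0 + spacing * i, float(f)) for i, f in enumerate(fractions))


def packaged_fixtures() -> dict[str, CompoundSpec]:
    """Deterministic compound fixtures mirroring commonly monitored extractables.

    * ``bht_like`` — hindered-phenol antioxidant, minimal EI fragmentation
      (base-peak fraction 0.55).
    * ``methyl_oleate_like`` — fatty-acid methyl ester, extensive EI
      fragmentation: 40 fragments with rank-i intensity proportional to
      i^(-0.7), so the base peak carries ~14% of the ion current.
    * ``dtdpp_like`` — thioester stabilizer forming a positive-mode
      multi-adduct ensemble ([M+H]+, [M+NH4]+, [M+Na]+, [M+ACN+NH4]+).
    * ``d8_like`` — cyclic siloxane C16H48O8Si8 whose Si8 envelope puts less
      than half of the response in the monoisotopic peak.
    * ``eicosane`` / ``chrysene`` — heavily fragmenting alkane NTE and
      barely fragmenting PAH surrogate, with the labeled phthalate ISTD
      ``dbp_d4_istd``.
    * ``triethyl_citrate_like`` (ESI saturation) and ``dehp_like`` (GC
      overload) dynamic-range fixtures with their internal standards.
    * ``tinuvin326_like`` and ``tinuvin326_2cl_like`` — one- and
      two-chlorine benzotriazoles for isotope-envelope semiquant bias.
    """
    fx: dict[str, CompoundSpec] = {}
    fx["bht_like"] = CompoundSpec(
        id="bht_like",
        formula="C15H24O",
        technique="GCMS",
        fragmentation_profile=(
            (205.1587, 0.55),
            (220.1822, 0.25),
            (177.1274, 0.12),
            (145.1012, 0.08),
        ),
        istd_id="acetophenone_d8",
    )
    fx["methyl_oleate_like"] = CompoundSpec(
        id="methyl_oleate_like",
        formula="C19H36O2",
        technique="GCMS",
        fragmentation_profile=_rank_power_profile(40, 0.7, 55.0548, 5.5),
        istd_id="acetophenone_d8",
    )
    fx["dtdpp_like"] = CompoundSpec(
        id="dtdpp_like",
        formula="C30H58O4S",
        technique="LCMS_pos",
        adduct_propensities={
            "[M+H]+": 0.08,
            "[M+NH4]+": 0.38,
            "[M+Na]+": 0.34,
            "[M+ACN+NH4]+": 0.20,
        },
        dispersion=0.20,
        istd_id="istd_lc",
    )
    fx["d8_like"] = CompoundSpec(
        id="d8_like",
        formula="C16H48O8Si8",
        technique="GCMS",
        fragmentation_profile=((577.1519, 1.0),),  # [M-CH3]+ region; single species
        istd_id="acetophenone_d8",
    )
    fx["eicosane"] = CompoundSpec(
        id="eicosane",
        formula="C20H42",
        technique="GCMS",
        fragmentation_profile=_rank_power_profile(40, 0.7, 57.0699, 4.7),
        dispersion=0.15,
        istd_id="dbp_d4_istd",
    )
    fx["chrysene"] = CompoundSpec(
        id="chrysene",
        formula="C18H12",
        technique="GCMS",
        fragmentation_profile=(
            (228.0934, 0.75),
            (226.0777, 0.10),
            (114.0464, 0.08),
            (101.0386, 0.07),
        ),
        dispersion=0.15,
        istd_id="dbp_d4_istd",
    )
    fx["dbp_d4_istd"] = CompoundSpec(
        id="dbp_d4_istd",
        formula="C16H18D4O4",
        technique="GCMS",
        fragmentation_profile=((153.0484, 0.7), (227.1454, 0.3)),
        dispersion=0.05,
    )
    fx["acetophenone_d8"] = CompoundSpec(
        id="acetophenone_d8",
        formula="C8D8O",
        technique="GCMS",
        fragmentation_profile=((128.1101, 0.65), (110.0760, 0.35)),
        dispersion=0.05,
    )
    fx["triethyl_citrate_like"] = CompoundSpec(
        id="triethyl_citrate_like",
        formula="C12H20O7",
        technique="LCMS_pos",
        adduct_propensities={"[M+H]+": 0.5, "[M+NH4]+": 0.3, "[M+Na]+": 0.2},
        saturation_k=0.3,
        dispersion=0.15,
        istd_id="istd_lc",
    )
    fx["istd_lc"] = CompoundSpec(
        id="istd_lc",
        formula="C12H15D5O7",
        technique="LCMS_pos",
        adduct_propensities={"[M+H]+": 1.0},
        dispersion=0.05,
    )
    fx["dehp_like"] = CompoundSpec(
        id="dehp_like",
        formula="C24H38O4",
        technique="GCMS",
        fragmentation_profile=(
            (149.0233, 0.60),
            (167.0339, 0.20),
            (279.1591, 0.12),
            (390.2765, 0.08),
        ),
        saturation_k=0.05,
        dispersion=0.20,
        istd_id="acetophenone_d8",
    )
    fx["tinuvin326_like"] = CompoundSpec(
        id="tinuvin326_like",
        formula="C17H18ClN3O",
        technique="LCMS_pos",
        adduct_propensities={"[M+H]+": 1.0},
        istd_id="istd_lc",
    )
    fx["tinuvin326_2cl_like"] = CompoundSpec(
        id="tinuvin326_2cl_like",
        formula="C17H17Cl2N3O",
        technique="LCMS_pos",
        adduct_propensities={"[M+H]+": 1.0},
        istd_id="istd_lc",
    )
    return fx


def fixture_sets() -> dict[str, tuple[tuple[CompoundSpec, ...], tuple[CompoundSpec, ...]]]:
    """Named (analytes, internal standards) bundles for CLI simulation configs."""
    fx = packaged_fixtures()
    return {
        "gc_demo": (
            (fx["bht_like"], fx["methyl_oleate_like"], fx["d8_like"], fx["dehp_like"]),
            (fx["acetophenone_d8"],),
        ),
        "lc_demo": (
            (fx["dtdpp_like"], fx["triethyl_citrate_like"]),
            (fx["istd_lc"],),
        ),
        "semiquant_demo": (
            (fx["eicosane"], fx["chrysene"]),
            (fx["dbp_d4_istd"],),
        ),
    }
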