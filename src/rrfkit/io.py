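"""File schemas, configuration validation, and run manifests.

All tables travel as CSV with documented columns and dtypes; nested
configuration and manifests are JSON. Units are fixed per field (one unit per
column: concentrations in ug/mL, volumes in mL, doses in ug/day) so unit
mismatches are unrepresentable. Readers validate headers, collect malformed
rows into an error report instead of silently dropping them, and enforce the
feature-table uniqueness key. Writers use a fixed column order and a stable
float format so a fixed config + seed reproduces byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import AcceptanceCriteria
from .thresholds import ThresholdInputs

__all__ = [
    "SchemaError",
    "ConfigError",
    "FEATURE_SCHEMA",
    "DESIGN_SCHEMA",
    "RESPONSE_SCHEMA",
    "RRF_SCHEMA",
    "read_feature_table",
    "read_design",
    "read_responses",
    "read_rrf_table",
    "write_table",
    "config_hash",
    "write_manifest",
    "PipelineConfig",
]

FLOAT_FORMAT = "%.10g"

FEATURE_SCHEMA = {
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
FEATURE_KEY = ["run_id", "sample_id", "compound_id", "species", "isotope"]

DESIGN_SCHEMA = {
    "run_id": str,
    "sample_id": str,
    "compound_id": str,
    "concentration": float,
    "istd_id": str,
    "istd_concentration": float,
}

RESPONSE_SCHEMA = {
    "run_id": str,
    "sample_id": str,
    "compound_id": str,
    "model": str,
    "raw": float,
    "istd_raw": float,
    "corrected": float,
    "flag": str,
}

RRF_SCHEMA = {
    "run_id": str,
    "compound_id": str,
    "model": str,
    "method": str,
    "weighting": str,
    "range_low": float,
    "range_high": float,
    "rrf": float,
    "r2": float,
    "n_levels": int,
    "injection_rsd_max": float,
    "accepted": bool,
    "rejection_reason": str,
}


class SchemaError(ValueError):
    """Raised when a table does not match its published schema."""


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration, with the offending field path."""


def _read_csv(
    path: str | Path, schema: Mapping[str, type], key: list[str] | None = None, strict: bool = True
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise SchemaError(f"{path.name}: unknown column(s): {', '.join(extra)}")
    bad_rows: list[str] = []
    out: dict[str, Any] = {}
    for col, dtype in schema.items():
        if dtype is str:
            out[col] = df[col].astype(str)
            continue
        if dtype is bool:
            vals = df[col].str.lower().map({"true": True, "false": False, "1": True, "0": False})
            bad = vals.isna()
            out[col] = vals
        else:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & (df[col].str.strip() != "")
            if dtype is int:
                vals = vals.astype("Int64")
            out[col] = vals
        for i in df.index[bad][:20]:
            bad_rows.append(f"row {i + 2}: column {col!r} = {df.at[i, col]!r}")
    if bad_rows:
        report = "; ".join(bad_rows)
        if strict:
            raise SchemaError(f"{path.name}: {len(bad_rows)} malformed value(s): {report}")
    parsed = pd.DataFrame(out)
    if key:
        dup = parsed.duplicated(subset=key, keep=False)
        if dup.any():
            first = parsed.loc[dup.idxmax(), key].tolist()
            raise SchemaError(
                f"{path.name}: duplicated key {tuple(key)} = {tuple(first)}"
            )
    # final dtype normalization
    for col, dtype in schema.items():
        if dtype is int:
            parsed[col] = parsed[col].astype(int)
        elif dtype is float:
            parsed[col] = parsed[col].astype(float)
        elif dtype is bool:
            parsed[col] = parsed[col].astype(bool)
    return parsed


def read_feature_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read features.csv, enforcing the (run, sample, compound, species, isotope) key."""
    return _read_csv(path, FEATURE_SCHEMA, key=FEATURE_KEY, strict=strict)


def read_design(path: str | Path, strict: bool = True) -> pd.DataFrame:
    return _read_csv(
        path, DESIGN_SCHEMA, key=["run_id", "sample_id", "compound_id"], strict=strict
    )


def read_responses(path: str | Path, strict: bool = True) -> pd.DataFrame:
    return _read_csv(path, RESPONSE_SCHEMA, strict=strict)


def read_rrf_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    return _read_csv(path, RRF_SCHEMA, strict=strict)


def write_table(df: pd.DataFrame, path: str | Path, schema: Mapping[str, type] | None = None) -> Path:
    """Write a CSV with fixed column order and stable float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if schema is not None:
        df = df[[c for c in schema]]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def config_hash(config: Mapping[str, Any]) -> str:
    """Reproducible SHA-256 of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: Mapping[str, Any],
    seed: int | None,
    files: list[str],
    stage: str,
    created: str | None = None,
) -> Path:
    """Write (or extend) the run manifest listing every emitted file.

    ``created`` is optional and omitted by default so that a fixed
    config + seed produces a byte-identical bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    manifest: dict[str, Any] = {"version": __version__, "stages": {}}
    if path.exists():
        manifest = json.loads(path.read_text())
    entry: dict[str, Any] = {
        "config_hash": config_hash(config),
        "seed": seed,
        "files": sorted(files),
    }
    if created is not None:
        entry["created"] = created
    manifest["version"] = __version__
    manifest.setdefault("stages", {})[stage] = entry
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# -- pipeline configuration --------------------------------------------------

_ALLOWED_TOP = {
    "technique",
    "fixture_set",
    "compounds",
    "istds",
    "levels",
    "runs",
    "injections_per_level",
    "noise_cv",
    "adduct_drift_concentration",
    "nonlinearity",
    "istd_concentration",
    "models",
    "range",
    "weighting",
    "acceptance",
    "uf_strategy",
    "uf_cap",
    "threshold_inputs",
    "seed",
}
_ALLOWED_ACCEPTANCE = {"max_injection_rsd", "min_r_squared", "required_weighting"}
_ALLOWED_THRESHOLD = {
    "dbt_ug_per_day",
    "devices_extracted",
    "extraction_volume_ml",
    "clinical_devices_per_day",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(data) - _ALLOWED_TOP
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        acc = data.get("acceptance", {})
        if not isinstance(acc, Mapping):
            raise ConfigError("acceptance: must be an object")
        bad = set(acc) - _ALLOWED_ACCEPTANCE
        if bad:
            raise ConfigError(f"acceptance: unknown key(s): {', '.join(sorted(bad))}")
        thr = data.get("threshold_inputs", {})
        if not isinstance(thr, Mapping):
            raise ConfigError("threshold_inputs: must be an object")
        bad = set(thr) - _ALLOWED_THRESHOLD
        if bad:
            raise ConfigError(f"threshold_inputs: unknown key(s): {', '.join(sorted(bad))}")
        return cls(raw=dict(data))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path.name}: invalid JSON: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path.name}: top level must be an object")
        return cls.from_dict(data)

    def acceptance_criteria(self, default_technique: str = "LCMS_pos") -> AcceptanceCriteria:
        acc = self.raw.get("acceptance")
        if acc:
            base = AcceptanceCriteria.for_technique(
                self.raw.get("technique", default_technique)
            )
            return AcceptanceCriteria(
                max_injection_rsd=acc.get("max_injection_rsd", base.max_injection_rsd),
                min_r_squared=acc.get("min_r_squared", base.min_r_squared),
                required_weighting=acc.get("required_weighting", base.required_weighting),
            )
        return AcceptanceCriteria.for_technique(self.raw.get("technique", default_technique))

    def threshold_inputs(self) -> ThresholdInputs:
        thr = self.raw.get("threshold_inputs")
        if not thr:
            raise ConfigError("threshold_inputs: missing")
        try:
            return ThresholdInputs(
                dbt_ug_per_day=float(thr["dbt_ug_per_day"]),
                devices_extracted=int(thr["devices_extracted"]),
                extraction_volume_ml=float(thr["extraction_volume_ml"]),
                clinical_devices_per_day=float(thr["clinical_devices_per_day"]),
            )
        except KeyError as exc:
            raise ConfigError(f"threshold_inputs.{exc.args[0]}: missing") from exc
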