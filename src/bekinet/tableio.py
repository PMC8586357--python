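"""Tabular and config file I/O.

Variant tables are CSV or TSV (delimiter chosen by extension) with a
case-insensitive header; extra columns are ignored.  Configs are JSON
or YAML.  Reports are written as JSON (full precision) or TSV
(fractions to 4 decimal places), always accompanied by a provenance
record (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError, ValidationError
from .fitting import VariantObservation
from .params import ReducedParams

__all__ = [
    "RunConfig",
    "load_config",
    "read_variant_table",
    "read_candidate_table",
    "write_report",
    "provenance_record",
]

_REQUIRED_VARIANT_COLUMNS = ("variant_id", "ddem_kbt", "pt_obs", "pb_obs")
_OPTIONAL_VARIANT_COLUMNS = ("ddem_sem", "locus", "n_reps")
_REQUIRED_CANDIDATE_COLUMNS = ("name", "ddem_kbt")


@dataclass(frozen=True)
class RunConfig:
    """Validated, serializable description of one CLI run."""

    params: ReducedParams
    seed: int = 0
    grid_min: float = -5.0
    grid_max: float = 15.0
    grid_step: float = 0.05
    window_fraction: float = 0.9
    n_traj: int = 100_000
    n_cells: int = 10_000
    out_dir: str = "."
    log_level: str = "INFO"
    raw: Mapping[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.grid_min >= self.grid_max:
            raise ValidationError("grid requires grid_min < grid_max and step > 0")
        if not 0.0 < self.window_fraction <= 1.0:
            raise ValidationError("window_fraction must lie in (0, 1]")
        if self.n_traj < 0 or self.n_cells < 0:
            raise ValidationError("n_traj and n_cells must be >= 0")

    def to_mapping(self) -> dict[str, Any]:
        return {
            **self.params.to_mapping(),
            "seed": self.seed,
            "grid_min": self.grid_min,
            "grid_max": self.grid_max,
            "grid_step": self.grid_step,
            "window_fraction": self.window_fraction,
            "n_traj": self.n_traj,
            "n_cells": self.n_cells,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        params = ReducedParams.from_mapping(mapping)
        kwargs = {
            key: mapping[key]
            for key in (
                "seed",
                "grid_min",
                "grid_max",
                "grid_step",
                "window_fraction",
                "n_traj",
                "n_cells",
                "out_dir",
                "log_level",
            )
            if key in mapping
        }
        return cls(params=params, raw=dict(mapping), **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: config must be a mapping")
    return RunConfig.from_mapping(data)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}; "
            f"found: {', '.join(frame.columns)}"
        )


def _parse_float(value: Any, column: str, line: int, errors: list[str]) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and not value.strip()
    ):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        errors.append(f"line {line}: column {column!r}: unparseable number {value!r}")
        return None


def read_variant_table(path: str | Path) -> list[VariantObservation]:
    """Parse a per-variant observation table (CSV or TSV).

    Required columns (case-insensitive): ``variant_id``, ``ddEm_kBT``,
    ``pt_obs``, ``pb_obs``.  Optional: ``ddEm_sem``, ``locus``,
    ``n_reps``.  All malformed rows are reported together, with their
    line numbers (1-based, header = line 1).
    """
    path = Path(path)
    frame = _read_table(path)
    _require_columns(frame, _REQUIRED_VARIANT_COLUMNS, path)
    errors: list[str] = []
    records: list[VariantObservation] = []
    for i, row in frame.iterrows():
        line = int(i) + 2  # header is line 1
        ddEm = _parse_float(row["ddem_kbt"], "ddEm_kBT", line, errors)
        pt = _parse_float(row["pt_obs"], "pt_obs", line, errors)
        pb = _parse_float(row["pb_obs"], "pb_obs", line, errors)
        if None in (ddEm, pt, pb):
            errors.append(f"line {line}: missing required value(s)")
            continue
        sem = (
            _parse_float(row["ddem_sem"], "ddEm_sem", line, errors)
            if "ddem_sem" in frame.columns
            else None
        )
        n_reps_val = (
            _parse_float(row["n_reps"], "n_reps", line, errors)
            if "n_reps" in frame.columns
            else None
        )
        try:
            records.append(
                VariantObservation(
                    variant_id=str(row["variant_id"]),
                    ddEm=ddEm,
                    pt_obs=pt,
                    pb_obs=pb,
                    ddEm_sem=sem,
                    locus=str(row["locus"]) if "locus" in frame.columns and not pd.isna(row["locus"]) else "",
                    n_reps=int(n_reps_val) if n_reps_val is not None else None,
                )
            )
        except ValidationError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records


def read_candidate_table(path: str | Path) -> list[tuple[str, float, float | None]]:
    """Parse a candidate-mutation table with columns name, ddEm_kBT[, ddEm_sem]."""
    path = Path(path)
    frame = _read_table(path)
    _require_columns(frame, _REQUIRED_CANDIDATE_COLUMNS, path)
    errors: list[str] = []
    out: list[tuple[str, float, float | None]] = []
    for i, row in frame.iterrows():
        line = int(i) + 2
        ddEm = _parse_float(row["ddem_kbt"], "ddEm_kBT", line, errors)
        if ddEm is None:
            errors.append(f"line {line}: missing ddEm_kBT")
            continue
        sem = (
            _parse_float(row["ddem_sem"], "ddEm_sem", line, errors)
            if "ddem_sem" in frame.columns
            else None
        )
        out.append((str(row["name"]), ddEm, sem))
    if errors:
        raise SchemaError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return out


def write_variant_table(records: Sequence[VariantObservation], path: str | Path) -> None:
    """Write observations in the schema accepted by read_variant_table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "ddEm_kBT": [r.ddEm for r in records],
            "ddEm_sem": [r.ddEm_sem for r in records],
            "pt_obs": [r.pt_obs for r in records],
            "pb_obs": [r.pb_obs for r in records],
            "locus": [r.locus for r in records],
            "n_reps": [r.n_reps for r in records],
        }
    )
    frame.to_csv(path, sep=sep, index=False)


def provenance_record(config: Mapping[str, Any], seed: int) -> dict[str, Any]:
    """Config hash + seed + version, written alongside every output."""
    canonical = json.dumps(dict(config), sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }


def write_report(
    results: Mapping[str, Any] | pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, Any] | None = None,
) -> None:
    """Write a result record as JSON (mapping) or TSV (DataFrame).

    TSV output rounds fractional columns to 4 decimal places; JSON
    keeps full precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
        for col in frame.select_dtypes(include=["float"]).columns:
            frame[col] = frame[col].round(4)
        frame.to_csv(path, sep="\t", index=False)
        if provenance is not None:
            Path(str(path) + ".provenance.json").write_text(
                json.dumps(dict(provenance), indent=2) + "\n"
            )
        return
    payload = dict(results)
    if provenance is not None:
        payload["provenance"] = dict(provenance)
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
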