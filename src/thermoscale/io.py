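"""Reading, validating and writing ramping-assay tables.

Two canonical CSV schemas are used throughout the package:

* paired-acclimation table — one row per species:
  ``species, ta_low, tc_low, ta_high, tc_high, heating_rate`` (optionally
  ``phylum``), temperatures in °C, rate in °C/min;
* multi-rate table — one row per assay:
  ``species, ta, heating_rate, tc``.

Deposited datasets rarely use these exact labels, so ingest goes through a
:class:`ColumnMap` that renames source columns and declares the rate unit.
The shipped default maps are provisional placeholders pending comparison
with a real deposit; synthetic tables already use canonical names and pass
through unchanged.  Every row that fails a validation rule is rejected and
tallied under the rule's name — nothing is dropped silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnMap",
    "ValidationReport",
    "DEFAULT_PAIRED_MAP",
    "DEFAULT_RATE_MAP",
    "read_paired_table",
    "read_rate_table",
    "write_results",
]

PAIRED_FIELDS = ("species", "ta_low", "tc_low", "ta_high", "tc_high", "heating_rate")
RATE_FIELDS = ("species", "ta", "heating_rate", "tc")
OPTIONAL_FIELDS = ("phylum",)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source column labels, plus
    unit declarations.

    ``rate_unit`` is ``"per_min"`` or ``"per_h"`` (per-hour rates are
    divided by 60 on ingest).  Temperatures must be Celsius.
    """

    columns: dict
    rate_unit: str = "per_min"
    temperature_unit: str = "celsius"

    def __post_init__(self) -> None:
        if self.rate_unit not in ("per_min", "per_h"):
            raise ValueError(f"rate unit must be declared per_min or per_h, "
                             f"got {self.rate_unit!r}")
        if self.temperature_unit != "celsius":
            raise ValueError("only Celsius temperatures are supported")
        labels = list(self.columns.values())
        if len(set(labels)) != len(labels):
            raise ValueError("each source column may be mapped only once")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(columns=raw["columns"],
                   rate_unit=raw.get("rate_unit", "per_min"),
                   temperature_unit=raw.get("temperature_unit", "celsius"))


#: Identity maps for the canonical schemas (synthetic output reads as-is).
DEFAULT_PAIRED_MAP = ColumnMap(columns={f: f for f in PAIRED_FIELDS})
DEFAULT_RATE_MAP = ColumnMap(columns={f: f for f in RATE_FIELDS})


@dataclass
class ValidationReport:
    """Row accounting for one ingest: read = accepted + rejected, with a
    per-rule tally of rejections and free-form warnings."""

    n_read: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    rejections: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def reject(self, rule: str, n: int = 1) -> None:
        self.rejections[rule] = self.rejections.get(rule, 0) + n
        self.n_rejected += n

    def warn(self, message: str) -> None:
        logger.debug("validation warning: %s", message)
        self.warnings.append(message)

    def finalize(self) -> None:
        self.n_accepted = self.n_read - self.n_rejected
        assert self.n_accepted + self.n_rejected == self.n_read


def _load_and_rename(path: str | Path, colmap: ColumnMap,
                     required: tuple) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    missing_map = [f for f in required if f not in colmap.columns]
    if missing_map:
        raise ValueError(f"ColumnMap does not map required fields: {missing_map}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty input file: {path}")
    missing_cols = [colmap.columns[f] for f in required
                    if colmap.columns[f] not in df.columns]
    if missing_cols:
        raise ValueError(f"source columns missing from {path}: {missing_cols}")
    rename = {src: canon for canon, src in colmap.columns.items()
              if src in df.columns}
    df = df.rename(columns=rename)
    keep = [f for f in required + OPTIONAL_FIELDS if f in df.columns]
    df = df[keep]
    if colmap.rate_unit == "per_h":
        df = df.assign(heating_rate=df["heating_rate"] / 60.0)
    return df


def read_paired_table(path: str | Path,
                      colmap: ColumnMap = DEFAULT_PAIRED_MAP
                      ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a paired-acclimation table.

    Rules: finite numbers; heating rate > 0; T_c > T_a in both treatments;
    high T_a above low T_a; one row per species (duplicates rejected as
    ambiguous treatments).
    """
    df = _load_and_rename(path, colmap, PAIRED_FIELDS)
    report = ValidationReport(n_read=len(df))

    numeric = ["ta_low", "tc_low", "ta_high", "tc_high", "heating_rate"]
    df[numeric] = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    if bad.any():
        report.reject("non-numeric or missing value", int(bad.sum()))
        df = df[~bad]

    bad = df["heating_rate"] <= 0
    if bad.any():
        report.reject("non-positive heating rate", int(bad.sum()))
        df = df[~bad]

    bad = (df["tc_low"] <= df["ta_low"]) | (df["tc_high"] <= df["ta_high"])
    if bad.any():
        report.reject("invalid ordering (Tc <= Ta)", int(bad.sum()))
        df = df[~bad]

    bad = df["ta_high"] <= df["ta_low"]
    if bad.any():
        report.reject("acclimation temperatures not ordered", int(bad.sum()))
        df = df[~bad]

    dup = df["species"].duplicated(keep=False)
    if dup.any():
        report.reject("more than two acclimation treatments per species",
                      int(dup.sum()))
        df = df[~dup]

    report.finalize()
    return df.reset_index(drop=True), report


def read_rate_table(path: str | Path,
                    colmap: ColumnMap = DEFAULT_RATE_MAP
                    ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a multi-rate table.

    Row-level rules as for the paired table.  Species-level checks are
    warnings, not rejections: fewer than two distinct rates (unusable for
    slope fits), varying acclimation temperature within a species, and
    duplicated (species, rate) combinations (averaged on the log10 budget
    scale downstream).
    """
    df = _load_and_rename(path, colmap, RATE_FIELDS)
    report = ValidationReport(n_read=len(df))

    numeric = ["ta", "heating_rate", "tc"]
    df[numeric] = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    if bad.any():
        report.reject("non-numeric or missing value", int(bad.sum()))
        df = df[~bad]

    bad = df["heating_rate"] <= 0
    if bad.any():
        report.reject("non-positive heating rate", int(bad.sum()))
        df = df[~bad]

    bad = df["tc"] <= df["ta"]
    if bad.any():
        report.reject("invalid ordering (Tc <= Ta)", int(bad.sum()))
        df = df[~bad]

    for species, grp in df.groupby("species", sort=True):
        if grp["heating_rate"].nunique() < 2:
            report.warn(f"species {species!r} has a single distinct rate; "
                        "excluded from slope fits")
        if grp["ta"].nunique() > 1:
            report.warn(f"species {species!r} has varying acclimation "
                        "temperature across rates")
        if grp.duplicated(subset=["heating_rate"]).any():
            report.warn(f"species {species!r} has duplicated (species, rate) "
                        "records; budgets will be averaged on the log10 scale")

    report.finalize()
    return df.reset_index(drop=True), report


def write_results(tables: dict, out_dir: str | Path,
                  metadata: dict | None = None) -> list[str]:
    """Write result tables as CSV plus a JSON sidecar and manifest.

    Column order and row order are preserved as given; identical inputs
    produce byte-identical files.  Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, table in sorted(tables.items()):
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
        written.append(path.name)
        logger.debug("wrote %s (%d rows)", path, len(table))

    meta = dict(metadata or {})
    try:
        from importlib.metadata import version
        meta.setdefault("software_version", version("thermoscale"))
    except Exception:
        meta.setdefault("software_version", "unknown")
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()[:16]
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(meta_path.name)

    manifest_path = out_dir / "manifest.json"
    written.append(manifest_path.name)
    manifest_path.write_text(json.dumps(sorted(written), indent=2) + "\n")
    return written
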