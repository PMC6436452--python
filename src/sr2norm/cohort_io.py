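"""Reading, writing and validating the pipeline's tabular artifacts.

Cohort tables travel as comma-separated UTF-8 CSV with a header row and "."
decimals; audiogram columns are named ``<ear>_<freq-in-kHz>`` (``L_0.5``,
``R_4``).  Published spreadsheet supplements should be exported to this
schema (see :data:`COLUMN_DOC`); a ``schema`` mapping lets differently named
columns be adopted on read.  Normative models are stored as JSON, run
configurations as YAML.  Derived columns (PTA variants, asymmetry, run
averages, SRM) are always recomputed from the raw data on read; a stored
``pta_st`` column is cross-checked and a disagreement beyond 0.05 dB draws a
warning, since stored summaries may have been rounded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scoring import TRIAL_COLUMNS
from .types import (
    CohortTable,
    CohortValidationWarning,
    NormativeModel,
    OPTIONAL_COLUMNS,
    THRESHOLD_COLUMNS,
    audiogram_columns,
    required_columns,
)

MODEL_FILE_FORMAT = "sr2norm-models"
MODEL_FILE_VERSION = 1

#: One-line documentation of every canonical cohort column.
COLUMN_DOC: dict[str, str] = {
    "id": "participant identifier (string)",
    "age": "age in whole years",
    "gender": "optional categorical label (blank if not recorded)",
    "hearing_aid_user": "optional true/false (aids are not worn during testing)",
    "srt_left": "optional speech reception threshold, left ear (dB)",
    "srt_right": "optional speech reception threshold, right ear (dB)",
    "retest_delay_days": "optional days between run 1 and run 2",
    **{
        c: f"{'left' if c.startswith('L') else 'right'} ear threshold at "
        f"{c.split('_', 1)[1]} kHz (dB HL)"
        for c in audiogram_columns()
    },
    "colocated_1": "run-1 colocated TMR threshold (dB)",
    "colocated_2": "run-2 colocated TMR threshold (dB)",
    "separated_1": "run-1 separated TMR threshold (dB)",
    "separated_2": "run-2 separated TMR threshold (dB)",
}


class CohortSchemaError(KeyError):
    """A required cohort column is absent."""


class CohortParseError(ValueError):
    """A cell could not be parsed; the message names the row and column."""


_NUMERIC_REQUIRED = ["age", *audiogram_columns(), *THRESHOLD_COLUMNS]
_NUMERIC_OPTIONAL = ["srt_left", "srt_right", "retest_delay_days"]


def _parse_numeric(raw: pd.Series, col: str, required: bool) -> pd.Series:
    rep = raw.replace("", np.nan)
    probe = pd.to_numeric(rep, errors="coerce")
    bad = probe.index[probe.isna() & (raw != "")]
    if len(bad):
        i = bad[0]
        raise CohortParseError(
            f"row {i + 1}, column {col!r}: {raw.iloc[i]!r} is not numeric"
        )
    if required and probe.isna().any():
        i = probe.index[probe.isna()][0]
        raise CohortParseError(f"row {i + 1}, column {col!r}: value is missing")
    # astype(float) round-trips shortest-repr decimals exactly; to_numeric may not
    return rep.astype(float)


def _parse_bool(raw: pd.Series, col: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False, "": None}
    vals = []
    for i, v in enumerate(raw):
        key = str(v).strip().lower()
        if key not in mapping:
            raise CohortParseError(
                f"row {i + 1}, column {col!r}: {v!r} is not a boolean"
            )
        vals.append(mapping[key])
    return pd.Series(vals, index=raw.index, dtype=object)


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    ``schema`` optionally maps canonical column names to the names used in the
    file.  Missing required columns raise :class:`CohortSchemaError` naming
    the column; unparseable cells raise :class:`CohortParseError` naming row
    and column; soft-invariant violations (e.g. a threshold outside
    [−10, 10]) are reported as :class:`CohortValidationWarning` with row
    numbers and never dropped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required_columns() if c not in raw.columns]
    if missing:
        raise CohortSchemaError(
            f"cohort file {path.name} is missing required columns: {missing}"
        )
    df = pd.DataFrame({"id": raw["id"].astype(str)})
    for col in _NUMERIC_REQUIRED:
        df[col] = _parse_numeric(raw[col], col, required=True)
    df["age"] = df["age"].astype(int)
    for col in _NUMERIC_OPTIONAL:
        if col in raw.columns:
            df[col] = _parse_numeric(raw[col], col, required=False)
    if "gender" in raw.columns:
        df["gender"] = raw["gender"].replace("", None)
    if "hearing_aid_user" in raw.columns:
        df["hearing_aid_user"] = _parse_bool(raw["hearing_aid_user"], "hearing_aid_user")
    cohort = CohortTable(df)
    if "pta_st" in raw.columns:
        stored = _parse_numeric(raw["pta_st"], "pta_st", required=False)
        diff = (stored - cohort.df["pta_st"]).abs()
        bad = diff.index[diff > 0.05]
        if len(bad):
            warnings.warn(
                "stored pta_st disagrees with the value recomputed from the "
                f"audiogram by more than 0.05 dB in rows {[i + 1 for i in bad]}; "
                "the recomputed value is used",
                CohortValidationWarning,
                stacklevel=2,
            )
    return cohort


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort CSV with a stable column order and full float precision.

    Optional fields that are absent stay as empty cells; booleans are written
    as ``true``/``false``.  ``read_cohort(write_cohort(c))`` reproduces the
    stored columns exactly.
    """
    path = Path(path)
    cols = ["id", "age", *[c for c in OPTIONAL_COLUMNS if c in cohort.df.columns],
            *audiogram_columns(), *THRESHOLD_COLUMNS]
    out = cohort.df[cols].copy()
    if "hearing_aid_user" in out.columns:
        out["hearing_aid_user"] = out["hearing_aid_user"].map(
            lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v))
            else str(bool(v)).lower()
        )
    if "retest_delay_days" in out.columns:
        out["retest_delay_days"] = out["retest_delay_days"].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    out.to_csv(path, index=False, encoding="utf-8")
    return path


# --- trial-level tables -----------------------------------------------------


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-level CSV (one row per trial of a progressive track)."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortSchemaError(f"trial file {path.name} is missing columns: {missing}")
    df = pd.DataFrame({"id": raw["id"].astype(str), "condition": raw["condition"]})
    for col in ("run", "trial", "tmr"):
        df[col] = _parse_numeric(raw[col], col, required=True).astype(int)
    df["correct"] = _parse_bool(raw["correct"], "correct").astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = trials[list(TRIAL_COLUMNS)].copy()
    out["correct"] = out["correct"].map(lambda v: str(bool(v)).lower())
    out.to_csv(path, index=False, encoding="utf-8")
    return path


# --- model files ------------------------------------------------------------


@dataclass
class ModelFile:
    """A serialized set of normative models plus provenance metadata."""

    models: list[NormativeModel]
    metadata: dict = field(default_factory=dict)

    def get(self, condition: str, run: str) -> NormativeModel:
        for m in self.models:
            if m.condition == condition and m.run == run:
                return m
        raise KeyError(f"no model for ({condition!r}, {run!r}) in file")

    def as_mapping(self) -> dict:
        return {(m.condition, m.run): m for m in self.models}


def write_model_file(models: ModelFile | list[NormativeModel], path: str | Path,
                     metadata: dict | None = None) -> Path:
    """Serialize normative models to JSON (lossless float round-trip)."""
    if isinstance(models, ModelFile):
        mf = models
        if metadata:
            mf.metadata.update(metadata)
    else:
        mf = ModelFile(models=list(models), metadata=metadata or {})
    doc = {
        "format": MODEL_FILE_FORMAT,
        "version": MODEL_FILE_VERSION,
        "metadata": mf.metadata,
        "models": [m.to_dict() for m in mf.models],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    return path


def read_model_file(path: str | Path) -> ModelFile:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file {path.name} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FILE_FORMAT:
        raise ValueError(f"{path.name} is not a {MODEL_FILE_FORMAT} file")
    return ModelFile(
        models=[NormativeModel.from_dict(d) for d in doc.get("models", [])],
        metadata=dict(doc.get("metadata", {})),
    )


# --- run configuration ------------------------------------------------------


def load_config_yaml(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValueError(f"configuration {path} must be a mapping")
    return doc


def dump_config_yaml(config: object, path: str | Path) -> Path:
    path = Path(path)
    doc = asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config)
    # dataclass payloads may hold nested model dataclasses
    def clean(v):
        if hasattr(v, "__dataclass_fields__"):
            return {k: clean(x) for k, x in asdict(v).items()}
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    path.write_text(yaml.safe_dump(clean(doc), sort_keys=False), encoding="utf-8")
    return path
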