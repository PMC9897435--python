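"""Readers and writers for cohort tables, feature tables, and score models.

All artifacts are plain text: CSV/TSV for tables, JSON for models and
sidecar metadata. Every writer attaches a provenance sidecar (package
version, seed, config hash) so a run can be traced end to end.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .features import CONC_FEATURES, METADATA_COLUMNS, ValidationError
from .score import ProjectedScoreModel

MANDATORY_COLUMNS = ["sample_id", "subject_id", "fluid", "batch", "diagnosis"] + CONC_FEATURES


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (one row per sample).

    Checks: mandatory columns present, unique sample ids, parseable
    non-negative concentrations (offending rows are named).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValidationError(f"{path}: empty file")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate sample_id values {sorted(set(dup))[:5]}")
    for col in CONC_FEATURES:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad:
            raise ValidationError(
                f"{path}: malformed numeric cells in {col!r} at rows {bad[:5]}"
            )
        neg = df.index[vals < 0].tolist()
        if neg:
            raise ValidationError(f"{path}: negative concentration in {col!r} at rows {neg[:5]}")
        df[col] = vals
    return df


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "gagmced",
        "version": __version__,
        "seed": seed,
        "config_sha1": hashlib.sha1(cfg_json.encode()).hexdigest(),
    }


def write_table(df: pd.DataFrame, path, seed: int | None = None, config: dict | None = None):
    """Write a TSV plus a JSON provenance sidecar (<path>.json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(provenance(seed, config), indent=1))


def write_model(model: ProjectedScoreModel, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(model.to_json())


def read_model(path) -> ProjectedScoreModel:
    text = Path(path).read_text()
    try:
        return ProjectedScoreModel.from_json(text)
    except json.JSONDecodeError as e:
        raise ValidationError(f"{path}: not a valid model file ({e})") from e
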