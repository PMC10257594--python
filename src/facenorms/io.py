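"""File formats and run configuration.

CSV dialect: comma-separated, UTF-8, header required, ``NA``/empty for
missing values, decimal point (Italian-locale exports using decimal commas
must be converted before loading).  Norms are stored as versioned JSON so a
fitted model and its ES thresholds round-trip at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (
    ClinicalConfig,
    Cohort,
    CohortConfig,
    ScoreModel,
    Stratum,
    default_normative_config,
)
from .equivalent import ESThresholds
from .exceptions import SchemaError, ValidationError
from .regression import NormModel

NORMS_SCHEMA_VERSION = 1

_REQUIRED = ["id", "age", "education", "sex", "raw_score"]
_OPTIONAL = ["group", "impaired_label"]


def read_cohort_csv(path) -> Cohort:
    """Load a cohort table, validating every participant invariant.

    Failures name the offending 1-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")

    records = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        row = {"id": rec["id"].strip()}
        for col, lo, hi in (("age", 18, None), ("education", 0, None), ("raw_score", 0, 36)):
            text = rec[col].strip()
            try:
                val = int(text)
            except ValueError:
                raise ValidationError(f"{path.name} row {i}: {col} must be an integer, got {text!r}")
            if val < lo or (hi is not None and val > hi):
                bound = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
                raise ValidationError(f"{path.name} row {i}: {col} must be {bound}, got {val}")
            row[col] = val
        sex = rec["sex"].strip().lower()
        if sex not in ("female", "male"):
            raise ValidationError(f"{path.name} row {i}: sex must be female/male, got {rec['sex']!r}")
        row["sex"] = sex
        group = rec.get("group", "").strip()
        row["group"] = group if group and group.upper() != "NA" else None
        flag = rec.get("impaired_label", "").strip().lower()
        if flag in ("", "na"):
            row["impaired_label"] = None
        elif flag in ("true", "1", "yes"):
            row["impaired_label"] = True
        elif flag in ("false", "0", "no"):
            row["impaired_label"] = False
        else:
            raise ValidationError(
                f"{path.name} row {i}: impaired_label must be boolean-like, got {rec['impaired_label']!r}"
            )
        records.append(row)

    frame = pd.DataFrame(records, columns=_REQUIRED + _OPTIONAL)
    if frame.empty:
        frame = pd.DataFrame(columns=_REQUIRED + _OPTIONAL)
    return Cohort(frame, provenance="file", seed=None)


def write_cohort_csv(cohort: Cohort, path) -> None:
    df = cohort.data.copy()
    for col in _OPTIONAL:
        if col not in df.columns:
            df[col] = None
    out = df[_REQUIRED + _OPTIONAL].copy()
    out["impaired_label"] = out["impaired_label"].map(
        lambda v: "" if v is None or pd.isna(v) else str(bool(v)).lower()
    )
    out["group"] = out["group"].map(lambda v: "" if v is None or pd.isna(v) else v)
    out.to_csv(path, index=False)


def save_norms(path, model: NormModel, thresholds: ESThresholds | None = None) -> None:
    payload = {
        "schema_version": NORMS_SCHEMA_VERSION,
        "model": model.to_dict(),
        "thresholds": thresholds.to_dict() if thresholds is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_norms(path) -> tuple[NormModel, ESThresholds | None]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path.name}: not valid JSON ({exc})") from exc
    version = payload.get("schema_version")
    if version != NORMS_SCHEMA_VERSION:
        raise SchemaError(
            f"{path.name}: schema version {version!r} is incompatible "
            f"(expected {NORMS_SCHEMA_VERSION})"
        )
    model = NormModel.from_dict(payload["model"])
    thr = payload.get("thresholds")
    thresholds = ESThresholds.from_dict(thr) if thr is not None else None
    return model, thresholds


@dataclass
class RunConfig:
    """Run-level settings for the command-line pipeline."""

    seed: int = 0
    alpha: float = 0.05
    tost_bounds: tuple[float, float] = (-0.5, 0.5)
    output_dir: Path = Path(".")
    norms_path: Path | None = None
    cohort: CohortConfig | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        low, high = self.tost_bounds
        if not low < high:
            raise ValidationError(f"tost bounds must satisfy low < high, got {self.tost_bounds}")
        self.output_dir = Path(self.output_dir)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a parsed YAML/JSON mapping."""
    strata = [
        Stratum(
            age_lo=int(s["age_band"][0]),
            age_hi=int(s["age_band"][1]),
            edu_lo=int(s["education_band"][0]),
            edu_hi=int(s["education_band"][1]),
            n_female=int(s["n_female"]),
            n_male=int(s["n_male"]),
        )
        for s in d.get("strata", [])
    ]
    sm = ScoreModel(**d["score_model"]) if "score_model" in d else ScoreModel()
    clinical = ClinicalConfig(**d["clinical"]) if d.get("clinical") else None
    bounds = d.get("score_bounds", (0, 36))
    config = CohortConfig(
        strata=strata,
        score_model=sm,
        score_bounds=tuple(bounds) if bounds is not None else None,
        clinical=clinical,
    )
    if not config.strata and config.clinical is None:
        return default_normative_config()
    return config


def load_cohort_config(path) -> CohortConfig:
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    return cohort_config_from_dict(d or {})


def load_run_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    cohort = cohort_config_from_dict(d["cohort"]) if isinstance(d.get("cohort"), dict) else None
    return RunConfig(
        seed=int(d.get("seed", 0)),
        alpha=float(d.get("alpha", 0.05)),
        tost_bounds=tuple(d.get("tost_bounds", (-0.5, 0.5))),
        output_dir=Path(d.get("output_dir", ".")),
        norms_path=Path(d["norms_path"]) if d.get("norms_path") else None,
        cohort=cohort,
        log_level=str(d.get("log_level", "INFO")),
    )
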