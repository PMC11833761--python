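"""CSV data contracts and scenario/config parsing.

Two plain rectangular files carry a trial: long-format longitudinal data
(cluster_id, subject_id, period, time, treat, y) and per-subject survival
data (cluster_id, subject_id, time, event, crossover_time). Headers are the
contract; validation errors name the offending row and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TrialDesign, treatment_indicator

__all__ = [
    "read_long",
    "write_long",
    "read_surv",
    "write_surv",
    "load_config",
    "design_from_config",
]

LONG_COLUMNS = ["cluster_id", "subject_id", "period", "time", "treat", "y"]
SURV_COLUMNS = ["cluster_id", "subject_id", "time", "event", "crossover_time"]


class DataValidationError(ValueError):
    """A data file violated the CSV contract."""


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {missing}")


def read_long(path, design: TrialDesign | None = None) -> pd.DataFrame:
    """Read and validate long-format longitudinal data.

    With a design supplied, also checks that each record's treat flag agrees
    with the design's treatment indicator at the measurement time.
    """
    df = pd.read_csv(path)
    _check_columns(df, LONG_COLUMNS, path)
    df = df[LONG_COLUMNS]
    if df.empty:
        return df
    dup = df.duplicated(subset=["cluster_id", "subject_id", "period"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataValidationError(
            f"{path}: duplicate (cluster_id, subject_id, period) key at row {row}"
        )
    bad = ~df["treat"].isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataValidationError(f"{path}: column 'treat' invalid at row {row}")
    if design is not None:
        for row, rec in enumerate(df.itertuples()):
            expect = treatment_indicator(design, int(rec.cluster_id), float(rec.time))
            if int(rec.treat) != expect:
                raise DataValidationError(
                    f"{path}: column 'treat' inconsistent with design at row {row}"
                )
    return df


def write_long(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df)[LONG_COLUMNS].to_csv(path, index=False)


def read_surv(path, study_end: float | None = None) -> pd.DataFrame:
    """Read and validate per-subject survival data (one row per subject)."""
    df = pd.read_csv(path)
    _check_columns(df, SURV_COLUMNS, path)
    df = df[SURV_COLUMNS]
    if df.empty:
        return df
    dup = df.duplicated(subset=["cluster_id", "subject_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataValidationError(
            f"{path}: duplicate (cluster_id, subject_id) key at row {row}"
        )
    bad = ~df["event"].isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataValidationError(f"{path}: column 'event' invalid at row {row}")
    # t = 0 is legal for the period-level logistic mechanism (dropout before
    # the first measurement); negative times never are
    bad = df["time"] < 0
    if study_end is not None:
        bad = bad | (df["time"] > study_end)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataValidationError(f"{path}: column 'time' out of range at row {row}")
    return df


def write_surv(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df)[SURV_COLUMNS].to_csv(path, index=False)


def load_config(path) -> dict:
    """Structured config (YAML, which subsumes JSON) as a plain dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise DataValidationError(f"{path}: config must be a mapping")
    return cfg


def design_from_config(cfg: dict) -> TrialDesign:
    key = "design" if "design" in cfg else None
    return TrialDesign.from_dict(cfg[key] if key else cfg)
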