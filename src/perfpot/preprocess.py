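"""Reading and preparing longitudinal performance records.

Performance is recorded in "points" where LOWER is better (race-points
scales).  Atypically bad single results — counter-performances — are
neutralized by keeping only the best (minimum) score per individual per age
year; the model is trained on that filtered table after the scores are
centered, reduced and shifted to be strictly positive, and ages are centered
and reduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PerformanceRecord",
    "StandardizationSpec",
    "read_records",
    "best_per_age",
    "fit_standardization",
    "standardize",
    "destandardize",
    "records_to_frame",
]

DEFAULT_COLUMN_MAP = {"individual_id": "id", "age": "age", "score": "points"}
DEFAULT_AGE_BOUNDS = (10.0, 25.0)
POSITIVITY_EPS = 1e-3


@dataclass(frozen=True)
class PerformanceRecord:
    """One raw result: who, at what age, scoring how many points."""

    individual_id: str
    age: float
    score: float
    season: str | None = None
    discipline: str | None = None
    sex: str | None = None


@dataclass(frozen=True)
class StandardizationSpec:
    """Affine transforms taking raw ages/scores to the model scale.

    Ages are centered and reduced.  Scores are centered, reduced, then shifted
    by ``positivity_shift`` so every training value is strictly positive (the
    shift is ``-min(standardized scores) + eps`` fitted globally).
    """

    age_mean: float
    age_sd: float
    score_mean: float
    score_sd: float
    positivity_shift: float

    def __post_init__(self) -> None:
        if not (self.age_sd > 0 and self.score_sd > 0):
            raise ValueError("age_sd and score_sd must be strictly positive")

    # -- age ---------------------------------------------------------------
    def age_to_model(self, age):
        return (np.asarray(age, dtype=float) - self.age_mean) / self.age_sd

    def age_to_raw(self, t):
        return np.asarray(t, dtype=float) * self.age_sd + self.age_mean

    # -- score -------------------------------------------------------------
    def score_to_model(self, score):
        return (np.asarray(score, dtype=float) - self.score_mean) / self.score_sd + self.positivity_shift

    def score_to_raw(self, s):
        return (np.asarray(s, dtype=float) - self.positivity_shift) * self.score_sd + self.score_mean

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationSpec":
        return cls(**json.loads(Path(path).read_text()))


def read_records(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    age_bounds: tuple[float, float] = DEFAULT_AGE_BOUNDS,
) -> list[PerformanceRecord]:
    """Read long-format performance data from a CSV/TSV file.

    ``column_map`` maps record fields (``individual_id``, ``age``, ``score``
    and optionally ``season``, ``discipline``, ``sex``) to file columns.
    Rows with unparseable or missing age/score, non-positive scores, or ages
    outside ``age_bounds`` are dropped with a logged count.  Duplicate rows
    are kept: deduplication is the best-per-age filter's job.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={colmap["individual_id"]: str})

    for field in ("individual_id", "age", "score"):
        if colmap[field] not in df.columns:
            raise KeyError(
                f"mandatory column {colmap[field]!r} (for field {field!r}) "
                f"not found in {path.name}; available: {list(df.columns)}"
            )

    n_raw = len(df)
    age = pd.to_numeric(df[colmap["age"]], errors="coerce")
    score = pd.to_numeric(df[colmap["score"]], errors="coerce")
    lo, hi = age_bounds
    keep = (
        age.notna()
        & score.notna()
        & np.isfinite(age)
        & np.isfinite(score)
        & (score > 0)
        & (age >= lo)
        & (age <= hi)
    )
    n_dropped = int(n_raw - keep.sum())
    if n_dropped:
        logger.info("read_records: dropped %d of %d rows (unparseable, non-positive score, or age outside %s)",
                    n_dropped, n_raw, age_bounds)

    def _opt(field: str):
        col = colmap.get(field)
        if col and col in df.columns:
            return df[col].astype(str).where(df[col].notna(), None)
        return pd.Series([None] * n_raw)

    season, discipline, sex = _opt("season"), _opt("discipline"), _opt("sex")
    records = [
        PerformanceRecord(
            individual_id=str(df[colmap["individual_id"]].iloc[i]),
            age=float(age.iloc[i]),
            score=float(score.iloc[i]),
            season=season.iloc[i],
            discipline=discipline.iloc[i],
            sex=sex.iloc[i],
        )
        for i in np.flatnonzero(keep.to_numpy())
    ]
    logger.info("read_records: %d records read from %s", len(records), path.name)
    return records


def _age_bin(age: float) -> int:
    # Integer age-year bins: floor of decimal age.
    return int(np.floor(age))


def best_per_age(records: list[PerformanceRecord]) -> list[PerformanceRecord]:
    """Keep the best (minimum-score) record per individual per age year.

    Ages are binned to integer years by flooring.  Ties are broken by first
    occurrence, so the output is stable under input order.
    """
    best: dict[tuple[str, int], PerformanceRecord] = {}
    for rec in records:
        key = (rec.individual_id, _age_bin(rec.age))
        incumbent = best.get(key)
        if incumbent is None or rec.score < incumbent.score:
            best[key] = rec
    out = list(best.values())
    logger.info("best_per_age: %d records in, %d best-per-age records out", len(records), len(out))
    return out


def records_to_frame(records: list[PerformanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "age": [r.age for r in records],
            "score": [r.score for r in records],
        }
    )


def fit_standardization(records: list[PerformanceRecord], eps: float = POSITIVITY_EPS) -> StandardizationSpec:
    """Fit the global centering/reduction/positivity-shift transform.

    The shift is chosen as ``-min(standardized scores) + eps`` so every
    training score maps strictly above zero.  Requires at least two distinct
    ages and two distinct scores (zero variance is degenerate).
    """
    if not records:
        raise ValueError("cannot fit standardization on empty input")
    ages = np.array([r.age for r in records], dtype=float)
    scores = np.array([r.score for r in records], dtype=float)
    age_sd = float(np.std(ages, ddof=0))
    score_sd = float(np.std(scores, ddof=0))
    if age_sd == 0 or score_sd == 0:
        raise ValueError("degenerate data: zero variance in age or score")
    score_mean = float(np.mean(scores))
    std_scores = (scores - score_mean) / score_sd
    return StandardizationSpec(
        age_mean=float(np.mean(ages)),
        age_sd=age_sd,
        score_mean=score_mean,
        score_sd=score_sd,
        positivity_shift=float(-np.min(std_scores) + eps),
    )


def standardize(records: list[PerformanceRecord], spec: StandardizationSpec) -> pd.DataFrame:
    """Training table with columns individual_id, age_std, score_std."""
    df = records_to_frame(records)
    return pd.DataFrame(
        {
            "individual_id": df["individual_id"],
            "age_std": spec.age_to_model(df["age"].to_numpy()),
            "score_std": spec.score_to_model(df["score"].to_numpy()),
        }
    )


def destandardize(table: pd.DataFrame, spec: StandardizationSpec) -> pd.DataFrame:
    """Inverse of :func:`standardize` (columns individual_id, age, score)."""
    return pd.DataFrame(
        {
            "individual_id": table["individual_id"],
            "age": spec.age_to_raw(table["age_std"].to_numpy()),
            "score": spec.score_to_raw(table["score_std"].to_numpy()),
        }
    )
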