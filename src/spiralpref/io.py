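"""CSV schemas, validated loading, and report writing.

All tables are UTF-8, comma-separated with a header row and "." decimals.
Semicolon-separated files (common under German locales) are rejected loudly
rather than mis-parsed.  Errors name the offending row (1-based, counting the
header as row 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

RATING_MIN, RATING_MAX = 1.0, 100.0


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    validators: tuple[Callable[[pd.DataFrame], None], ...] = ()


class SchemaError(ValueError):
    pass


def _check_rating_range(df: pd.DataFrame) -> None:
    vals = pd.to_numeric(df["rating"], errors="coerce")
    bad = df.index[vals.isna() | (vals < RATING_MIN) | (vals > RATING_MAX)]
    if len(bad):
        raise SchemaError(
            f"rating outside [{RATING_MIN:g}, {RATING_MAX:g}] at row "
            f"{int(bad[0]) + 2} (value {df.loc[bad[0], 'rating']!r})"
        )


def _check_unique_cells(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["rater_id", "stimulus_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise SchemaError(f"duplicate (rater, stimulus) record at row {row + 2}")


def _check_unique_pairs(df: pd.DataFrame) -> None:
    key = [frozenset((l, r)) for l, r in zip(df["left"], df["right"])]
    seen: dict[tuple, int] = {}
    for i, (pid, k) in enumerate(zip(df["participant_id"], key)):
        if (pid, k) in seen:
            raise SchemaError(f"duplicate (participant, pair) record at row {i + 2}")
        seen[(pid, k)] = i


def _check_chosen_in_pair(df: pd.DataFrame) -> None:
    bad = df.index[
        ~df.apply(lambda r: r["chosen"] in (r["left"], r["right"]), axis=1)
    ]
    if len(bad):
        raise SchemaError(f"chosen stimulus not in its pair at row {int(bad[0]) + 2}")


RATINGS_SCHEMA = TableSchema(
    "ratings",
    ("rater_id", "stimulus_id", "rating"),
    (_check_rating_range, _check_unique_cells),
)
CHOICES_SCHEMA = TableSchema(
    "choices",
    ("participant_id", "left", "right", "chosen"),
    (_check_unique_pairs, _check_chosen_in_pair),
)
ASSOCIATIONS_SCHEMA = TableSchema(
    "associations", ("participant_id", "prompt", "response")
)
LEXICON_SCHEMA = TableSchema("lexicon", ("variant", "canonical"))


def load_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a schema; errors carry row numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = path.open(encoding="utf-8").readline()
    if ";" in header and "," not in header:
        raise SchemaError(
            f"{path.name}: semicolon-separated file; expected comma-separated CSV"
        )
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    df = df[list(schema.columns)]
    if "rating" in df.columns:
        # validated as text first so the row number survives coercion errors
        pass
    for validate in schema.validators:
        validate(df)
    if "rating" in df.columns:
        df["rating"] = pd.to_numeric(df["rating"])
    return df


def load_ratings_matrix(path: str | Path) -> pd.DataFrame:
    """Long ratings CSV -> complete raters x stimuli matrix."""
    long = load_table(path, RATINGS_SCHEMA)
    matrix = long.pivot(index="rater_id", columns="stimulus_id", values="rating")
    if matrix.isna().any().any():
        missing = matrix.isna().stack()
        rater, stim = missing.index[missing.to_numpy()][0]
        raise SchemaError(f"incomplete matrix: no rating for ({rater}, {stim})")
    return matrix


def write_ratings(matrix: pd.DataFrame, path: str | Path) -> None:
    long = matrix.stack().rename("rating").reset_index()
    long.columns = ["rater_id", "stimulus_id", "rating"]
    long.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
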