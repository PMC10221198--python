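"""Reading and writing the package's file formats.

Indicator matrices travel as UTF-8, comma-separated CSV with a header row
and no index column: the first column is ``subject_id``, followed by one
0/1 column per medication category.  Generating truths are stored as YAML
for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import IndicatorMatrix
from .errors import ValidationError
from .simulate import GenerativeTruth, truth_from_dict, truth_to_dict


def read_indicator_csv(path: str | Path) -> IndicatorMatrix:
    """Read an indicator CSV, validating that every cell is 0 or 1.

    Missing or non-binary cells are rejected with the subject and column
    named in the error message; duplicate subject identifiers are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "subject_id":
        raise ValidationError(
            f"{path}: first column must be 'subject_id', got {df.columns[0]!r}"
        )
    items = list(df.columns[1:])
    if not items:
        raise ValidationError(f"{path}: no item columns found")
    ids = df["subject_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate subject_id values {dup[:10]}")
    vals = df[items].to_numpy()
    mask = pd.isna(df[items]).to_numpy()
    if mask.any():
        i, j = map(int, np.argwhere(mask)[0])
        raise ValidationError(
            f"{path}: missing value at subject {ids.iloc[i]!r}, "
            f"column {items[j]!r} (complete cases required)"
        )
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"{path}: non-binary value {vals[i, j]!r} at subject "
            f"{ids.iloc[i]!r}, column {items[j]!r}"
        )
    return IndicatorMatrix(
        subject_ids=ids.to_numpy(),
        item_names=tuple(items),
        values=vals.astype(np.int8),
    )


def write_indicator_csv(data: IndicatorMatrix, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def write_truth_yaml(truth: GenerativeTruth, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(truth_to_dict(truth), sort_keys=False))


def read_truth_yaml(path: str | Path) -> GenerativeTruth:
    return truth_from_dict(yaml.safe_load(Path(path).read_text()))


def write_json(obj, path: str | Path) -> None:
    """JSON writer that tolerates numpy scalars/arrays and NaN/inf."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
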