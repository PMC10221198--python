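"""Core in-memory container for binary exposure data.

An :class:`IndicatorMatrix` holds a complete-case N x J matrix of 0/1
medication-exposure indicators, one row per subject and one column per
medication category, together with subject identifiers and item names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class IndicatorMatrix:
    """N subjects x J binary items, no missing entries.

    Parameters
    ----------
    subject_ids
        Length-N vector of unique subject identifiers.
    item_names
        J unique item (medication-category) names.
    values
        N x J array with entries in {0, 1}.
    """

    subject_ids: np.ndarray
    item_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.subject_ids)
        names = tuple(str(n) for n in self.item_names)
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValidationError(f"values must be 2-dimensional, got shape {vals.shape}")
        if ids.ndim != 1 or ids.shape[0] != vals.shape[0]:
            raise ValidationError(
                f"subject_ids has length {ids.shape}, values has {vals.shape[0]} rows"
            )
        if len(names) != vals.shape[1]:
            raise ValidationError(
                f"item_names has {len(names)} entries, values has {vals.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise ValidationError("item_names contains duplicates")
        if len(np.unique(ids)) != len(ids):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            raise ValidationError(f"subject_ids contains duplicates: {dup[:10]}")
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError(f"values must be numeric 0/1, got dtype {vals.dtype}")
        bad = ~np.isin(vals, (0, 1)) | ~np.isfinite(vals.astype(float))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-binary entry {vals[i, j]!r} at row {i} "
                f"(subject {ids[i]!r}), column {names[j]!r}"
            )
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "item_names", names)
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def n_subjects(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.values.shape[1])

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame with a leading ``subject_id`` column."""
        df = pd.DataFrame(self.values, columns=list(self.item_names))
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IndicatorMatrix":
        """Build from a DataFrame whose first column is ``subject_id``."""
        if "subject_id" not in df.columns:
            raise ValidationError("expected a 'subject_id' column")
        items = [c for c in df.columns if c != "subject_id"]
        return cls(
            subject_ids=df["subject_id"].to_numpy(),
            item_names=tuple(items),
            values=df[items].to_numpy(),
        )
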