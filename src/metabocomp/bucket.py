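"""The samples × features bucket table.

A bucket table is the central exchange object of comparative LC-MS
metabolomics: one row per sample, one column per consolidated feature, each
cell holding the feature's integration value in that sample (0 = the feature
was not detected there). Columns produced by this package are keyed
``"<mz>@<rt>"``; externally produced tables (e.g. presence–absence node
tables from molecular networking) may use arbitrary string keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Allowed values of :attr:`BucketTable.transform_tag`.
TRANSFORMS = ("raw", "log10p1", "tic", "presence_absence")


def make_key(mz: float, rt: float) -> str:
    """Render a consolidated feature's (m/z, rt) centroid as a column key."""
    return f"{mz:.4f}@{rt:.2f}"


def parse_key(key: str) -> tuple[float, float | None]:
    """Parse a column key back into (m/z, rt).

    Keys of the form ``"mz@rt"`` yield both coordinates; a bare numeric key
    is interpreted as an m/z with unknown rt (common for external tables
    keyed by precursor mass).
    """
    text = str(key)
    try:
        if "@" in text:
            mz_s, rt_s = text.split("@", 1)
            return float(mz_s), float(rt_s)
        return float(text), None
    except ValueError:
        raise ParseError(f"feature key {key!r} is not 'mz@rt' or a bare m/z") from None


@dataclass
class BucketTable:
    """Samples × features matrix of feature integration values.

    Parameters
    ----------
    data
        DataFrame with sample ids as index and feature keys as columns.
        Values must be finite and non-negative.
    transform_tag
        Which transformation has been applied; one of :data:`TRANSFORMS`.
    """

    data: pd.DataFrame
    transform_tag: str = "raw"
    feature_coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.transform_tag not in TRANSFORMS:
            raise ValidationError(f"unknown transform tag {self.transform_tag!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("bucket table contains non-finite values")
        if values.size and (values < 0).any():
            raise ValidationError("bucket table contains negative values")
        if self.transform_tag == "presence_absence" and values.size:
            if not np.isin(values, (0.0, 1.0)).all():
                raise ValidationError("presence_absence table must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_keys(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="sample_id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BucketTable({self.n_samples} samples x {self.n_features} features,"
            f" transform={self.transform_tag!r})"
        )
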