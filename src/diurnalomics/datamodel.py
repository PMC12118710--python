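"""Core containers for timed omics matrices.

A :class:`TimedSampleMatrix` binds a feature-by-sample abundance matrix to a
sample sheet carrying, for every column, the experimental group, the
zeitgeber time (ZT, hours after lights-on, in [0, 24)) and the replicate
index.  All downstream stages (rhythm detection, differential rhythm
comparison, differential expression) consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALUE_KINDS = ("counts", "continuous")

#: canonical sample-sheet column order
SHEET_COLUMNS = ("sample", "group", "time", "replicate")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample (one matrix column)."""

    sample_id: str
    group: str
    time: float  # zeitgeber hours in [0, 24)
    replicate: int

    def __post_init__(self) -> None:
        if not (0 <= self.time < 24):
            raise ValueError(
                f"sample {self.sample_id!r}: time {self.time} outside [0, 24)"
            )


@dataclass
class TimedSampleMatrix:
    """Feature-by-sample matrix plus aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame, features as rows (unique index) and samples as columns.
    samples
        DataFrame indexed by sample id with columns ``group``, ``time``,
        ``replicate``; rows aligned to the columns of ``values``.
    value_kind
        ``"counts"`` (non-negative integers) or ``"continuous"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("matrix columns and sample sheet rows are not aligned")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dupes}")
        if self.samples.index.duplicated().any():
            dupes = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dupes}")
        t = np.asarray(self.samples["time"], dtype=float)
        if np.any((t < 0) | (t >= 24)):
            bad = self.samples.index[(t < 0) | (t >= 24)].tolist()
            raise ValueError(f"times outside [0, 24) for samples: {bad}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("matrix contains non-finite values")
        if self.value_kind == "counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("counts matrix must contain non-negative integers")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.samples["group"]:
            seen.setdefault(str(g), None)
        return list(seen)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def times(self, group: str | None = None) -> np.ndarray:
        """Zeitgeber times of all samples, optionally restricted to a group."""
        if group is None:
            return self.samples["time"].to_numpy(dtype=float)
        mask = self.samples["group"].astype(str) == str(group)
        return self.samples.loc[mask, "time"].to_numpy(dtype=float)

    def subset_group(self, group: str) -> "TimedSampleMatrix":
        mask = self.samples["group"].astype(str) == str(group)
        if not mask.any():
            raise KeyError(f"no samples in group {group!r}")
        return TimedSampleMatrix(
            values=self.values.loc[:, mask.to_numpy()],
            samples=self.samples.loc[mask],
            value_kind=self.value_kind,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "TimedSampleMatrix":
        return TimedSampleMatrix(
            values=self.values.loc[list(feature_ids)],
            samples=self.samples,
            value_kind=self.value_kind,
        )

    # -- I/O -------------------------------------------------------------------

    def write(self, matrix_path: str | Path, sample_sheet_path: str | Path) -> None:
        """Write the matrix and sample sheet as UTF-8 TSV files."""
        out = self.values.copy()
        out.index.name = "feature"
        out.to_csv(matrix_path, sep="\t", float_format="%.10g")
        sheet = self.samples.reset_index()
        sheet.columns = list(SHEET_COLUMNS)
        sheet.to_csv(sample_sheet_path, sep="\t", index=False, float_format="%.10g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV (columns: sample, group, time, replicate)."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    sheet = sheet.set_index("sample")
    return sheet[["group", "time", "replicate"]]


def read_matrix(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    value_kind: str = "counts",
) -> TimedSampleMatrix:
    """Load an abundance matrix and bind it to its sample sheet.

    Columns of the matrix are reordered to the sheet's row order.  Sample ids
    must match exactly (order-insensitive); any mismatch raises with the
    symmetric difference.  A non-numeric cell raises with its row/column
    address, a duplicated feature id with the offending id.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    sheet = read_sample_sheet(sample_sheet_path)

    in_matrix = set(raw.columns)
    in_sheet = set(sheet.index)
    if in_matrix != in_sheet:
        only_m = sorted(in_matrix - in_sheet)
        only_s = sorted(in_sheet - in_matrix)
        raise ValueError(
            "sample ids differ between matrix and sheet: "
            f"matrix-only={only_m}, sheet-only={only_s}"
        )
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature ids in {matrix_path}: {dupes}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        bad = np.argwhere(numeric.isna().to_numpy() & raw.notna().to_numpy())
        if bad.size == 0:  # NaN came from an empty cell
            bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell at feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )

    numeric = numeric.loc[:, list(sheet.index)]
    if value_kind == "counts":
        arr = numeric.to_numpy(dtype=float)
        if np.allclose(arr, np.round(arr)) and (arr >= 0).all():
            numeric = numeric.round().astype(np.int64)
        else:
            raise ValueError("matrix declared as counts contains non-integer values")
    return TimedSampleMatrix(values=numeric, samples=sheet, value_kind=value_kind)


def matrix_from_arrays(
    values: np.ndarray,
    feature_ids: Sequence[str],
    meta: Iterable[SampleMeta],
    value_kind: str,
) -> TimedSampleMatrix:
    """Assemble a TimedSampleMatrix from raw arrays and SampleMeta records."""
    meta = list(meta)
    samples = pd.DataFrame(
        {
            "group": [m.group for m in meta],
            "time": [m.time for m in meta],
            "replicate": [m.replicate for m in meta],
        },
        index=pd.Index([m.sample_id for m in meta], name="sample"),
    )
    df = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature"),
                      columns=samples.index)
    return TimedSampleMatrix(values=df, samples=samples, value_kind=value_kind)
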