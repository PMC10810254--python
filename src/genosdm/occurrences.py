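"""Occurrence records and the record-cleaning rules applied before modelling.

Occurrences are point records (planar x, y) tagged with the range they were
observed in and, when the individual was genotyped, an individual identifier
linking the record to a genotype matrix. Cleaning mirrors standard
presence-data hygiene for niche modelling: drop records with large (or
unknown) coordinate uncertainty, de-duplicate identical coordinates, and thin
to at most one record per grid cell so dense sampling does not dominate the
fitted niche.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import EnvGrid

__all__ = ["OccurrenceSet", "filter_records", "thin_to_grid"]

_COLUMNS = ["x", "y", "range", "individual_id"]


class OccurrenceSet:
    """Point records with coordinates, range label and optional individual id.

    Thin wrapper over a pandas DataFrame with columns
    ``x, y, range, individual_id`` (plus any extras such as
    ``coord_uncertainty``).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        for col in ("x", "y"):
            if col not in df.columns:
                raise ValueError(f"occurrence table lacks required column {col!r}")
            df[col] = df[col].astype(float)
        if "range" not in df.columns:
            df["range"] = "all"
        if "individual_id" not in df.columns:
            df["individual_id"] = None
        ids = df["individual_id"].dropna()
        if len(ids):
            pairs = df.loc[ids.index, ["range", "individual_id"]]
            if pairs.duplicated().any():
                raise ValueError("(range, individual_id) pairs must be unique")
        self.df = df

    @classmethod
    def from_arrays(cls, x, y, range_label="all", individual_id=None, **extra):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        d = {"x": x, "y": y}
        d["range"] = (np.repeat(range_label, x.size)
                      if np.isscalar(range_label) or isinstance(range_label, str)
                      else range_label)
        d["individual_id"] = (np.repeat(None, x.size) if individual_id is None
                              else individual_id)
        d.update(extra)
        return cls(pd.DataFrame(d))

    @classmethod
    def read_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy()

    @property
    def range_labels(self) -> np.ndarray:
        return self.df["range"].to_numpy()

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy()

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.df.loc[np.asarray(mask)])

    def for_range(self, range_label) -> "OccurrenceSet":
        return self.subset(self.df["range"].to_numpy() == range_label)

    def env_at(self, grid: EnvGrid) -> pd.DataFrame:
        """Environmental values at each record (NaN off-grid/invalid)."""
        vals = grid.extract(self.x, self.y)
        return pd.DataFrame(vals, columns=grid.layer_names, index=self.df.index)


def filter_records(records: OccurrenceSet, max_uncertainty: float,
                   uncertainty=None) -> OccurrenceSet:
    """Drop uncertain and duplicated records.

    Keeps records whose coordinate uncertainty is strictly below
    ``max_uncertainty`` (records with missing uncertainty are dropped —
    unknown precision is treated as unacceptable precision) and retains
    exactly one record per distinct ``(x, y)`` pair (the first in input
    order).

    ``uncertainty`` may be an array aligned with the records; if omitted the
    ``coord_uncertainty`` column is used.
    """
    df = records.df
    if uncertainty is None:
        if "coord_uncertainty" not in df.columns:
            raise ValueError("no uncertainty values supplied")
        unc = df["coord_uncertainty"].to_numpy(dtype=float)
    else:
        unc = np.asarray(uncertainty, dtype=float)
        if unc.shape[0] != len(df):
            raise ValueError("uncertainty length does not match records")
    if np.nanmin(unc, initial=0.0) < 0:
        raise ValueError("uncertainty values must be non-negative")
    keep = np.isfinite(unc) & (unc < max_uncertainty)
    out = df.loc[keep]
    out = out.loc[~out.duplicated(subset=["x", "y"], keep="first")]
    return OccurrenceSet(out)


def thin_to_grid(records: OccurrenceSet, grid: EnvGrid) -> OccurrenceSet:
    """Thin to at most one record per grid cell (first in input order).

    Records falling outside the grid or on masked cells are dropped with a
    warning.
    """
    r, c = grid.cell_of(records.x, records.y)
    inside = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
    valid = inside.copy()
    valid[inside] &= grid.mask[r[inside], c[inside]]
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} record(s) outside the grid or on "
                      "invalid cells during thinning")
    cell_key = np.where(valid, r * grid.n_cols + c, -1)
    seen: set[int] = set()
    keep = np.zeros(len(records), dtype=bool)
    for i, key in enumerate(cell_key):
        if key >= 0 and key not in seen:
            seen.add(int(key))
            keep[i] = True
    return records.subset(keep)
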