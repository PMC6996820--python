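"""Survey data model: per-transect density records and annual series.

The unit of observation is one strip-transect underwater visual census:
a (location, year, transect_id, density) record, density in individuals/m².
Transects within one (location, year) stratum are the resampling unit of the
stratified bootstrap; their arithmetic mean is the annual density N_t that
the demographic models are fitted to.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "AnnualSeries", "SurveyDataset", "load_survey", "annual_means"]

COLUMNS = ("location", "year", "transect_id", "density")


@dataclass(frozen=True)
class AnnualSeries:
    """Mean density per year at one location.

    ``years`` are strictly increasing calendar years; ``values`` the matching
    mean densities (individuals/m²).  Years may have gaps; only transitions
    between consecutive calendar years enter a likelihood.
    """

    location: str
    years: np.ndarray
    values: np.ndarray
    n_transects: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if self.n_transects is None:
            object.__setattr__(self, "n_transects", np.ones(len(years), dtype=int))
        else:
            object.__setattr__(self, "n_transects", np.asarray(self.n_transects, dtype=int))
        if years.shape != values.shape or years.ndim != 1:
            raise ValueError("years and values must be 1-D arrays of equal length")
        if len(years) and np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("densities must be non-negative")

    def __len__(self) -> int:
        return len(self.years)

    def transitions(self) -> tuple[np.ndarray, np.ndarray]:
        """(N_t, N_{t+1}) pairs for consecutive-year transitions only.

        Transitions spanning a gap in the survey are excluded rather than
        mapped across multiple years.
        """
        if len(self.years) < 2:
            return np.empty(0), np.empty(0)
        step = np.diff(self.years) == 1
        return self.values[:-1][step], self.values[1:][step]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location": self.location,
                "year": self.years,
                "n_transects": self.n_transects,
                "mean_density": self.values,
            }
        )


class SurveyDataset:
    """Validated collection of per-transect density observations.

    Wraps a tidy :class:`pandas.DataFrame` with columns ``location`` (str),
    ``year`` (int), ``transect_id`` (str) and ``density`` (float ≥ 0,
    individuals/m²).  (location, year, transect_id) is unique; every
    (location, year) stratum present holds at least one transect.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate(frame)

    @property
    def frame(self) -> pd.DataFrame:
        """Copy of the underlying tidy table."""
        return self._frame.copy()

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(sorted(self._frame["location"].unique()))

    @property
    def year_range(self) -> tuple[int, int]:
        years = self._frame["year"]
        return int(years.min()), int(years.max())

    def __len__(self) -> int:
        return len(self._frame)

    def strata(self):
        """Iterate (location, year) strata as ((loc, year), density array)."""
        for key, grp in self._frame.groupby(["location", "year"], sort=True):
            yield key, grp["density"].to_numpy()

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurveyDataset":
        return cls(frame)


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = frame.loc[:, list(COLUMNS)].copy()
    if len(df) == 0:
        raise ValueError("dataset contains no observations")

    years = pd.to_numeric(df["year"], errors="coerce")
    bad_year = years.isna() | (years != np.floor(years))
    if bad_year.any():
        row = df.index[bad_year][0]
        raise ValueError(f"non-integer year at row {row}: {df.loc[row, 'year']!r}")
    df["year"] = years.astype(int)

    dens = pd.to_numeric(df["density"], errors="coerce")
    if dens.isna().any():
        row = df.index[dens.isna()][0]
        raise ValueError(f"non-numeric density at row {row}: {df.loc[row, 'density']!r}")
    if (dens < 0).any():
        row = df.index[dens < 0][0]
        raise ValueError(f"negative density at row {row}: {dens[row]}")
    df["density"] = dens.astype(float)

    df["location"] = df["location"].astype(str)
    df["transect_id"] = df["transect_id"].astype(str)
    dup = df.duplicated(subset=["location", "year", "transect_id"])
    if dup.any():
        row = df.index[dup][0]
        key = tuple(df.loc[row, ["location", "year", "transect_id"]])
        raise ValueError(f"duplicated (location, year, transect_id) {key} at row {row}")
    return df.reset_index(drop=True)


def load_survey(path) -> SurveyDataset:
    """Read a transect census CSV into a validated :class:`SurveyDataset`.

    The file must be UTF-8 with a header row and columns
    ``location,year,transect_id,density`` ("." decimal separator).
    """
    if isinstance(path, io.IOBase):
        frame = pd.read_csv(path)
    else:
        frame = pd.read_csv(path, encoding="utf-8")
    return SurveyDataset(frame)


def annual_means(data: SurveyDataset) -> dict[str, AnnualSeries]:
    """Aggregate transects to one mean density per (location, year).

    All transects of a stratum are pooled with an unweighted arithmetic
    mean; when a location was censused more than once in a calendar year the
    surveys are pooled the same way (the demographic maps run on an annual
    time step, so there is exactly one N_t per year).
    """
    out: dict[str, AnnualSeries] = {}
    g = data.frame.groupby(["location", "year"], sort=True)["density"].agg(["mean", "size"])
    for loc in data.locations:
        sub = g.loc[loc]
        out[loc] = AnnualSeries(
            location=loc,
            years=sub.index.to_numpy(dtype=int),
            values=sub["mean"].to_numpy(),
            n_transects=sub["size"].to_numpy(dtype=int),
        )
    return out
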