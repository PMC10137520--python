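"""Time-indexed data containers for the on-line monitoring pipeline.

Three streams come off a continuous food-production line:

* near-infrared absorbance spectra of the intermediate product
  (:class:`SpectraBlock`),
* RGB summary parameters from a vision camera watching the raw material
  (:class:`RGBSeries`),
* sparse off-line quality measurements of the finished product
  (:class:`QualitySeries`).

All three are thin dataclasses over numpy arrays with a shared
``pandas.DatetimeIndex`` timeline, plus plain-CSV round-trip I/O so that
pipeline stages can compose through the filesystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectraBlock", "RGBSeries", "QualitySeries"]


def _as_time_index(timestamps) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(timestamps)
    if len(idx) > 1 and not idx.is_monotonic_increasing:
        raise ValueError("timestamps must be increasing")
    return idx


@dataclass
class SpectraBlock:
    """Matrix of absorbance spectra: rows are time points, columns wavelengths."""

    timestamps: pd.DatetimeIndex
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = _as_time_index(self.timestamps)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.timestamps):
            raise ValueError(
                f"row count {n} does not match timestamp count {len(self.timestamps)}"
            )
        if m != len(self.wavelengths):
            raise ValueError(
                f"column count {m} does not match wavelength count {len(self.wavelengths)}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def take(self, indices) -> "SpectraBlock":
        """Row subset (pure; the original block is untouched)."""
        indices = np.asarray(indices)
        return SpectraBlock(
            self.timestamps[indices], self.wavelengths, self.values[indices]
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=self.timestamps,
            columns=[f"{w:g}" for w in self.wavelengths],
        )
        df.index.name = "timestamp"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpectraBlock":
        df = pd.read_csv(path, index_col=0, parse_dates=True)
        wavelengths = np.array([float(c) for c in df.columns])
        return cls(df.index, wavelengths, df.to_numpy(dtype=float))


_RGB_COLUMNS = ["R_mean", "G_mean", "B_mean", "R_sd", "G_sd", "B_sd"]


@dataclass
class RGBSeries:
    """Per-frame mean and standard deviation of the R, G, B camera channels.

    ``means`` and ``sds`` are ``(n, 3)`` arrays in channel order R, G, B,
    sampled on a fixed cadence (15 s at the plant).
    """

    timestamps: pd.DatetimeIndex
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = _as_time_index(self.timestamps)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        for name, arr in (("means", self.means), ("sds", self.sds)):
            if arr.shape != (len(self.timestamps), 3):
                raise ValueError(f"{name} must have shape (n_timestamps, 3)")

    @property
    def n_samples(self) -> int:
        return self.means.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.means, self.sds]),
            index=self.timestamps,
            columns=_RGB_COLUMNS,
        )
        df.index.name = "timestamp"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RGBSeries":
        df = pd.read_csv(path, index_col=0, parse_dates=True)
        return cls(
            df.index,
            df[_RGB_COLUMNS[:3]].to_numpy(dtype=float),
            df[_RGB_COLUMNS[3:]].to_numpy(dtype=float),
        )


@dataclass
class QualitySeries:
    """Sparse off-line quality responses: Bostwick consistency and total lipids.

    Consistency is the distance (cm) flowed in 30 s on a Bostwick
    consistometer; lipids is the solvent-extracted fat fraction in percent.
    Either column may carry NaN where a response was not assessed at that
    sampling time.
    """

    timestamps: pd.DatetimeIndex
    consistency_cm: np.ndarray
    lipids_pct: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = _as_time_index(self.timestamps)
        self.consistency_cm = np.asarray(self.consistency_cm, dtype=float)
        self.lipids_pct = np.asarray(self.lipids_pct, dtype=float)
        n = len(self.timestamps)
        if self.consistency_cm.shape != (n,) or self.lipids_pct.shape != (n,):
            raise ValueError("quality columns must be 1-D with one value per timestamp")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    def response(self, name: str) -> np.ndarray:
        if name == "consistency":
            return self.consistency_cm
        if name == "lipids":
            return self.lipids_pct
        raise KeyError(f"unknown response {name!r}; expected 'consistency' or 'lipids'")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"consistency_cm": self.consistency_cm, "lipids_pct": self.lipids_pct},
            index=self.timestamps,
        )
        df.index.name = "timestamp"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "QualitySeries":
        df = pd.read_csv(path, index_col=0, parse_dates=True)
        return cls(
            df.index,
            df["consistency_cm"].to_numpy(dtype=float),
            df["lipids_pct"].to_numpy(dtype=float),
        )
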