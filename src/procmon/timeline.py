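"""Timeline reconstruction: stop detection, RGB cleaning, stream alignment.

A continuous line produces three asynchronous streams (spectra of the
intermediate product, RGB parameters of the raw material, quality values of
the finished product).  Before any modelling the streams must be reduced to
one clean, synchronized analysis table:

* production stops are detected as runs of constant RGB values — when the
  conveyor stands still the camera keeps imaging the same material;
* anomalous RGB frames are removed by a robust (median/MAD) rule;
* quality records, measured at the end of the line, are matched back to the
  spectra through the process residence lag.

All operations are pure: masks and maps are returned, inputs never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import QualitySeries, RGBSeries, SpectraBlock

__all__ = [
    "StopInterval",
    "AlignmentMap",
    "detect_stops",
    "stop_mask",
    "clean_rgb",
    "align_quality",
    "assemble_dataset",
]


@dataclass(frozen=True)
class StopInterval:
    """One production stop; times are inclusive endpoints on the timeline."""

    start_time: pd.Timestamp
    end_time: pd.Timestamp
    start_index: int
    end_index: int  # inclusive
    source: str = "rgb_constant"

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ValueError("stop interval must have end >= start")


@dataclass
class AlignmentMap:
    """Matched (NIR index, quality index) pairs plus the unmatched records."""

    pairs: list[tuple[int, int]]
    residence_lag: pd.Timedelta
    unmatched_quality: list[int]

    @property
    def nir_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def quality_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def detect_stops(
    rgb: RGBSeries, tolerance: float = 0.0, min_duration: int = 4
) -> list[StopInterval]:
    """Find production stops as maximal runs of (near-)constant RGB values.

    A step between consecutive frames is "constant" when every channel's
    mean and standard deviation change by at most ``tolerance``; maximal
    runs of at least ``min_duration`` points become stop intervals.
    """
    if rgb.n_samples < 2:
        raise ValueError("need at least two RGB frames to detect stops")
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1 point")
    values = np.hstack([rgb.means, rgb.sds])
    step_const = np.all(np.abs(np.diff(values, axis=0)) <= tolerance, axis=1)
    intervals: list[StopInterval] = []
    i = 0
    n = rgb.n_samples
    while i < n - 1:
        if step_const[i]:
            j = i
            while j < n - 1 and step_const[j]:
                j += 1
            # run of constant frames covers points i .. j inclusive
            if j - i + 1 >= min_duration:
                intervals.append(
                    StopInterval(
                        start_time=rgb.timestamps[i],
                        end_time=rgb.timestamps[j],
                        start_index=i,
                        end_index=j,
                    )
                )
            i = j
        else:
            i += 1
    return intervals


def stop_mask(n: int, stops: list[StopInterval]) -> np.ndarray:
    """Boolean mask over the timeline: True where the process is stopped."""
    mask = np.zeros(n, dtype=bool)
    for s in stops:
        mask[s.start_index : s.end_index + 1] = True
    return mask


def clean_rgb(rgb: RGBSeries, k_mad: float = 5.0) -> np.ndarray:
    """Mask of retained frames after robust per-channel outlier screening.

    A channel flags a frame when it deviates from the channel median by more
    than ``k_mad`` normal-consistent MADs (1.4826 × median absolute
    deviation); a frame is dropped if any mean channel flags it.  When a
    channel's MAD is zero, only frames deviating from the exact median are
    flagged.
    """
    if rgb.n_samples == 0:
        raise ValueError("empty RGB series")
    if k_mad <= 0:
        raise ValueError("k_mad must be positive")
    X = rgb.means
    med = np.median(X, axis=0)
    mad = 1.4826 * np.median(np.abs(X - med), axis=0)
    dev = np.abs(X - med)
    flagged = np.zeros(X.shape, dtype=bool)
    for c in range(X.shape[1]):
        if mad[c] == 0:
            flagged[:, c] = dev[:, c] > 0
        else:
            flagged[:, c] = dev[:, c] > k_mad * mad[c]
    return ~flagged.any(axis=1)


def align_quality(
    nir_times,
    quality_times,
    residence_lag: pd.Timedelta | float,
    tolerance: pd.Timedelta | float | None = None,
) -> AlignmentMap:
    """Match each end-of-line quality record to its intermediate-product spectrum.

    A quality value measured at time ``t`` refers to material that passed
    the spectral probe at ``t − residence_lag``; each record is matched to
    the nearest NIR time within ``tolerance`` (default: half the NIR
    sampling period).  Matching is injective — a NIR point is consumed by at
    most one record — and unmatched records are reported, not dropped
    silently.
    """
    nir_times = pd.DatetimeIndex(nir_times)
    quality_times = pd.DatetimeIndex(quality_times)
    if isinstance(residence_lag, (int, float)):
        residence_lag = pd.Timedelta(seconds=float(residence_lag))
    if residence_lag < pd.Timedelta(0):
        raise ValueError("residence lag must be nonnegative")
    if tolerance is None:
        if len(nir_times) > 1:
            tolerance = (nir_times[1] - nir_times[0]) / 2
        else:
            tolerance = pd.Timedelta(0)
    elif isinstance(tolerance, (int, float)):
        tolerance = pd.Timedelta(seconds=float(tolerance))
    if tolerance < pd.Timedelta(0):
        raise ValueError("tolerance must be nonnegative")

    used = np.zeros(len(nir_times), dtype=bool)
    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    targets = quality_times - residence_lag
    for qi, target in enumerate(targets):
        deltas = np.abs((nir_times - target).to_numpy())
        deltas = np.where(used, np.timedelta64(2**62, "ns"), deltas)
        ni = int(np.argmin(deltas))
        if pd.Timedelta(deltas[ni]) <= tolerance and not used[ni]:
            pairs.append((ni, qi))
            used[ni] = True
        else:
            unmatched.append(qi)
    return AlignmentMap(pairs=pairs, residence_lag=residence_lag, unmatched_quality=unmatched)


def assemble_dataset(
    spectra: SpectraBlock,
    rgb: RGBSeries,
    quality: QualitySeries,
    stops: list[StopInterval],
    clean_mask: np.ndarray,
    alignment: AlignmentMap,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the analysis table: one row per matched, clean, non-stop point.

    Each surviving row carries the spectrum (wavelength-labelled columns),
    the RGB parameters, the matched quality values and any per-point
    metadata.  Raises with per-filter diagnostics when nothing survives.
    """
    n = spectra.n_samples
    if rgb.n_samples != n:
        raise ValueError("spectra and RGB streams disagree on timeline length")
    clean_mask = np.asarray(clean_mask, dtype=bool)
    if clean_mask.shape != (n,):
        raise ValueError("clean mask must have one entry per time point")
    in_stop = stop_mask(n, stops)

    rows = []
    for ni, qi in alignment.pairs:
        if in_stop[ni] or not clean_mask[ni]:
            continue
        rows.append((ni, qi))
    if not rows:
        raise ValueError(
            "no rows survive assembly: "
            f"{len(alignment.pairs)} matched, "
            f"{int(in_stop[alignment.nir_indices].sum())} in stops, "
            f"{int((~clean_mask[alignment.nir_indices]).sum())} flagged by RGB cleaning"
        )
    nir_idx = np.array([r[0] for r in rows])
    q_idx = np.array([r[1] for r in rows])
    df = pd.DataFrame(
        spectra.values[nir_idx],
        columns=[f"{w:g}" for w in spectra.wavelengths],
        index=spectra.timestamps[nir_idx],
    )
    df.index.name = "timestamp"
    for j, name in enumerate(["R_mean", "G_mean", "B_mean"]):
        df[name] = rgb.means[nir_idx, j]
    df["consistency_cm"] = quality.consistency_cm[q_idx]
    df["lipids_pct"] = quality.lipids_pct[q_idx]
    if labels is not None:
        for col in labels.columns:
            df[col] = labels.iloc[nir_idx][col].to_numpy()
    df["nir_index"] = nir_idx
    return df
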