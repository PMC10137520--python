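"""Latent-variable multivariate statistical process control (MSPC).

A PCA model is fitted to spectra acquired under Normal Operating Conditions
(NOC); new spectra are then judged by two complementary distances:

* Hotelling T² — the Mahalanobis distance of a sample *within* the model
  plane (extreme but describable behaviour),
* Q (squared prediction error) — the distance of a sample *from* the model
  plane (behaviour the NOC correlation structure cannot describe).

Control limits: T² uses the F-distribution form for new observations;
Q uses either the Jackson–Mudholkar normal approximation or Box's weighted
chi-square method, both driven by the eigenvalue spectrum of the residual
(discarded) components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .containers import SpectraBlock
from .latent import PCAModel, SplitResult, fit_pca
from .preprocess import PreprocessState

__all__ = [
    "MSPCModel",
    "ChartPoint",
    "hotelling_t2",
    "q_statistic",
    "t2_limit",
    "q_limit_jackson_mudholkar",
    "q_limit_box",
    "fit_mspc",
    "monitor",
    "chart_table",
    "noc_calibration_split",
    "flagged_episodes",
]


def hotelling_t2(scores: np.ndarray, eigenvalues: np.ndarray) -> np.ndarray:
    """T² = Σ_a t_a² / λ_a for one score row or a matrix of rows."""
    scores = np.asarray(scores, dtype=float)
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if np.any(eigenvalues <= 0):
        raise ValueError("all retained eigenvalues must be positive")
    if scores.shape[-1] != eigenvalues.size:
        raise ValueError("scores and eigenvalues disagree on component count")
    return np.sum(scores**2 / eigenvalues, axis=-1)


def q_statistic(x: np.ndarray, pca: PCAModel) -> np.ndarray:
    """Squared residual norm ‖x (I − P Pᵀ)‖² of preprocessed row(s)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != pca.loadings.shape[0]:
        raise ValueError(
            f"row has {x.shape[-1]} channels; model was fitted on {pca.loadings.shape[0]}"
        )
    resid = x - (x @ pca.loadings) @ pca.loadings.T
    return np.sum(resid**2, axis=-1)


def t2_limit(n_cal: int, n_components: int, alpha: float = 0.05) -> float:
    """T² control limit for new observations.

    ``a (n−1)(n+1) / (n (n−a)) · F_{1−α}(a, n−a)`` with a retained
    components and n calibration samples; the F form applies to samples
    projected onto a model they did not help build.
    """
    a, n = n_components, n_cal
    if n <= a:
        raise ValueError(f"need more calibration samples ({n}) than components ({a})")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    f = stats.f.ppf(1 - alpha, a, n - a)
    return float(a * (n - 1) * (n + 1) / (n * (n - a)) * f)


def _theta(eigs: np.ndarray, power: int) -> float:
    return float(np.sum(eigs**power))


def q_limit_jackson_mudholkar(
    residual_eigenvalues: np.ndarray, alpha: float = 0.05
) -> float:
    """Jackson–Mudholkar normal-approximation limit for the Q statistic."""
    eigs = np.asarray(residual_eigenvalues, dtype=float)
    if np.any(eigs < 0):
        raise ValueError("residual eigenvalues must be nonnegative")
    eigs = eigs[eigs > 0]
    if eigs.size == 0:
        return 0.0
    th1, th2, th3 = _theta(eigs, 1), _theta(eigs, 2), _theta(eigs, 3)
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    z = stats.norm.ppf(1 - alpha)
    inner = (
        z * np.sqrt(2.0 * th2 * h0**2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1**2
    )
    return float(th1 * inner ** (1.0 / h0))


def q_limit_box(residual_eigenvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Box's weighted chi-square limit: g·χ²_{1−α}(h), g = θ₂/θ₁, h = θ₁²/θ₂."""
    eigs = np.asarray(residual_eigenvalues, dtype=float)
    if np.any(eigs < 0):
        raise ValueError("residual eigenvalues must be nonnegative")
    eigs = eigs[eigs > 0]
    if eigs.size == 0:
        return 0.0
    th1, th2 = _theta(eigs, 1), _theta(eigs, 2)
    g = th2 / th1
    h = th1**2 / th2
    return float(g * stats.chi2.ppf(1 - alpha, h))


@dataclass
class MSPCModel:
    """Fitted monitoring model: PCA of NOC data plus chart limits."""

    pca: PCAModel
    preprocess_state: PreprocessState
    alpha: float
    t2_limit: float
    q_limit: float
    q_limit_method: str
    residual_eigenvalues: np.ndarray

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "t2_limit": float(self.t2_limit),
            "q_limit": float(self.q_limit),
            "q_limit_method": self.q_limit_method,
            "n_components": int(self.pca.n_components),
            "n_samples": int(self.pca.n_samples),
            "loadings": self.pca.loadings.tolist(),
            "eigenvalues": self.pca.eigenvalues.tolist(),
            "explained_variance_pct": self.pca.explained_variance_pct.tolist(),
            "residual_eigenvalues": self.residual_eigenvalues.tolist(),
            "preprocess_state": self.preprocess_state.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "MSPCModel":
        loadings = np.asarray(d["loadings"], dtype=float)
        eigs = np.asarray(d["eigenvalues"], dtype=float)
        pca = PCAModel(
            loadings=loadings,
            scores=np.zeros((0, loadings.shape[1])),
            eigenvalues=eigs,
            explained_variance_pct=np.asarray(
                d["explained_variance_pct"], dtype=float
            ),
            n_components=int(d["n_components"]),
            n_samples=int(d["n_samples"]),
        )
        return cls(
            pca=pca,
            preprocess_state=PreprocessState.from_dict(d["preprocess_state"]),
            alpha=float(d["alpha"]),
            t2_limit=float(d["t2_limit"]),
            q_limit=float(d["q_limit"]),
            q_limit_method=d["q_limit_method"],
            residual_eigenvalues=np.asarray(d["residual_eigenvalues"], dtype=float),
        )

    @classmethod
    def load(cls, path) -> "MSPCModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ChartPoint:
    """One monitored sample on the T²/Q charts."""

    timestamp: object
    t2: float
    q: float
    exceeds_t2: bool
    exceeds_q: bool


def fit_mspc(
    noc_block: SpectraBlock,
    n_components: int = 4,
    alpha: float = 0.05,
    q_method: str = "jackson_mudholkar",
    preprocess: PreprocessState | None = None,
) -> MSPCModel:
    """Fit the monitoring model on NOC-only calibration spectra.

    Default preprocessing is the Savitzky–Golay 2nd derivative followed by
    mean centering; pass a :class:`PreprocessState` to change it.  Residual
    eigenvalues for the Q limit are the positive eigenvalues of the
    calibration covariance beyond the retained components.
    """
    if noc_block.n_samples <= n_components:
        raise ValueError(
            f"{noc_block.n_samples} calibration samples cannot support "
            f"{n_components} components"
        )
    state = preprocess or PreprocessState(methods=["savitzky_golay", "mean_center"])
    Xp = state.fit_transform(noc_block)
    pca = fit_pca(Xp, n_components)
    resid_eigs = pca.all_eigenvalues[n_components:]
    resid_eigs = resid_eigs[resid_eigs > 0]
    if q_method == "jackson_mudholkar":
        q_lim = q_limit_jackson_mudholkar(resid_eigs, alpha)
    elif q_method == "box":
        q_lim = q_limit_box(resid_eigs, alpha)
    else:
        raise ValueError(f"unknown q_method {q_method!r}")
    return MSPCModel(
        pca=pca,
        preprocess_state=state,
        alpha=alpha,
        t2_limit=t2_limit(noc_block.n_samples, n_components, alpha),
        q_limit=q_lim,
        q_limit_method=q_method,
        residual_eigenvalues=resid_eigs,
    )


def monitor(block: SpectraBlock, model: MSPCModel) -> list[ChartPoint]:
    """Project new spectra on the fitted model and flag chart exceedances.

    Pure: the model's preprocessing state and PCA are applied, never refit,
    so monitoring the calibration block reproduces the calibration chart.
    """
    # every preprocessing step preserves the channel count, so the grid can
    # be checked before transforming
    if len(block.wavelengths) != model.pca.loadings.shape[0]:
        raise ValueError(
            f"block has {len(block.wavelengths)} wavelengths; model was fitted "
            f"on {model.pca.loadings.shape[0]}"
        )
    Xp = model.preprocess_state.transform(block)
    scores = model.pca.project(Xp)
    t2 = hotelling_t2(scores, model.pca.eigenvalues)
    q = q_statistic(Xp, model.pca)
    return [
        ChartPoint(
            timestamp=ts,
            t2=float(t2[i]),
            q=float(q[i]),
            exceeds_t2=bool(t2[i] > model.t2_limit),
            exceeds_q=bool(q[i] > model.q_limit),
        )
        for i, ts in enumerate(block.timestamps)
    ]


def chart_table(points: list[ChartPoint], model: MSPCModel) -> pd.DataFrame:
    """Chart points as a DataFrame with raw statistics and ratios to limits."""
    df = pd.DataFrame(
        {
            "timestamp": [p.timestamp for p in points],
            "T2": [p.t2 for p in points],
            "Q": [p.q for p in points],
            "T2_limit": model.t2_limit,
            "Q_limit": model.q_limit,
            "exceeds_T2": [p.exceeds_t2 for p in points],
            "exceeds_Q": [p.exceeds_q for p in points],
        }
    )
    df["T2_ratio"] = df["T2"] / df["T2_limit"]
    df["Q_ratio"] = df["Q"] / df["Q_limit"]
    return df


def flagged_episodes(flags: np.ndarray, min_length: int = 1) -> list[tuple[int, int]]:
    """Contiguous runs of flagged samples as (start, end) index pairs, end exclusive.

    ``min_length`` separates process episodes from nominal chart behaviour:
    at a 5% limit a calibrated chart flags a few isolated points, while a
    real departure from NOC flags a consecutive group; runs shorter than
    ``min_length`` are dropped.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    padded = np.diff(np.concatenate([[0], flags.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [
        (int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_length
    ]


def noc_calibration_split(
    timestamps,
    stop_intervals,
    cal_fraction: float = 0.65,
    non_noc_indices=None,
) -> SplitResult:
    """Temporally contiguous NOC split mimicking continuous monitoring.

    Within each stop-free period the first ``round(cal_fraction × length)``
    points go to calibration and the rest to the test set, so test samples
    always come later in time than the calibration samples of their period.
    Points inside stops, and any explicitly non-NOC points, go to the test
    set.
    """
    timestamps = pd.DatetimeIndex(timestamps)
    n = len(timestamps)
    if n == 0:
        raise ValueError("empty timeline")
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must lie in (0, 1)")
    in_stop = np.zeros(n, dtype=bool)
    for interval in stop_intervals:
        start, end = interval[0], interval[1]
        in_stop |= (timestamps >= start) & (timestamps <= end)
    non_noc = np.zeros(n, dtype=bool)
    if non_noc_indices is not None:
        non_noc[np.asarray(non_noc_indices, dtype=int)] = True
    eligible = ~in_stop & ~non_noc

    cal: list[int] = []
    test: list[int] = list(np.flatnonzero(~eligible))
    # maximal runs of eligible points = stop-free periods
    idx = np.flatnonzero(eligible)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        period_starts = np.concatenate([[0], breaks + 1])
        period_ends = np.concatenate([breaks + 1, [idx.size]])
        for s, e in zip(period_starts, period_ends):
            period = idx[s:e]
            n_cal = int(round(cal_fraction * period.size))
            n_cal = max(n_cal, 1) if period.size >= 1 else 0
            cal.extend(period[:n_cal].tolist())
            test.extend(period[n_cal:].tolist())
    if not cal:
        raise ValueError("no NOC periods found; cannot form a calibration set")
    return SplitResult(
        calibration_indices=np.array(sorted(cal)),
        test_indices=np.array(sorted(test)),
    )
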