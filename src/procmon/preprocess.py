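"""Spectral and tabular preprocessing.

Covers the standard chemometric steps applied before latent-variable
modelling of on-line NIR spectra:

* Savitzky-Golay derivative filtering along the wavelength axis,
* mean centering and autoscaling with stored state for new data,
* Dynamic Orthogonal Projection (DOP), a calibration-maintenance
  correction that removes spectral variability unrelated to the response.

DOP builds "virtual" target spectra as response-kernel-weighted averages of
source spectra (samples with the same, or very close, y should show the
same spectral profile), takes the SVD of the measured-minus-virtual
difference, and projects all spectra onto the orthogonal complement of the
leading difference directions::

    X*_tar = M @ X_source          # association-weighted virtual targets
    D      = X_tar - X*_tar        # response-unrelated variability
    V_A    = first A right singular vectors of D
    X_corr = X @ (I - V_A V_A^T)   # applied to calibration and new spectra

The projector is applied to the measured spectra being corrected —
calibration targets at fit time and any new spectra at prediction time —
so the correction is embedded in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .containers import SpectraBlock

__all__ = [
    "PreprocessState",
    "savitzky_golay",
    "mean_center",
    "apply_center",
    "undo_center",
    "autoscale",
    "apply_autoscale",
    "undo_autoscale",
    "DOPCorrection",
    "dop_association_matrix",
    "dop_virtual_targets",
    "dop_fit",
    "dop_apply",
    "fit_dop",
]


# ---------------------------------------------------------------------------
# Savitzky-Golay filtering
# ---------------------------------------------------------------------------


def savitzky_golay(
    block: SpectraBlock, window: int = 15, polyorder: int = 2, deriv: int = 2
) -> SpectraBlock:
    """Savitzky-Golay smoothing/derivative along the wavelength axis.

    Each spectrum (row) is replaced by the ``deriv``-th derivative of a local
    least-squares polynomial of degree ``polyorder`` fitted in a sliding
    window of ``window`` points.  The derivative is expressed per data-point
    step; on a uniform wavelength grid this is a fixed rescaling of the
    derivative per nm.  At the spectrum edges the polynomial fitted to the
    first/last full window is evaluated, so output shape equals input shape.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not (window > polyorder >= deriv):
        raise ValueError(
            f"need window > polyorder >= deriv, got {window}, {polyorder}, {deriv}"
        )
    if block.values.shape[1] < window:
        raise ValueError(
            f"spectrum has {block.values.shape[1]} points, fewer than window {window}"
        )
    filtered = savgol_filter(
        block.values, window_length=window, polyorder=polyorder, deriv=deriv, axis=1
    )
    return SpectraBlock(block.timestamps, block.wavelengths, filtered)


# ---------------------------------------------------------------------------
# Centering / scaling
# ---------------------------------------------------------------------------


def mean_center(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix; returns the centered matrix and the means."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0 or matrix.shape[0] < 1:
        raise ValueError("cannot center an empty matrix")
    means = matrix.mean(axis=0)
    return matrix - means, means


def apply_center(matrix: np.ndarray, means: np.ndarray) -> np.ndarray:
    return np.asarray(matrix, dtype=float) - means


def undo_center(matrix: np.ndarray, means: np.ndarray) -> np.ndarray:
    return np.asarray(matrix, dtype=float) + means


def autoscale(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale each column to unit standard deviation (ddof=1).

    Raises on zero-variance columns, naming the offenders — autoscaling a
    constant channel would divide by zero and such a channel carries no
    usable variance anyway.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0 or matrix.shape[0] < 2:
        raise ValueError("autoscaling needs at least two rows")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return (matrix - means) / sds, means, sds


def apply_autoscale(matrix, means, sds) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - means) / sds


def undo_autoscale(matrix, means, sds) -> np.ndarray:
    return np.asarray(matrix, dtype=float) * sds + means


# ---------------------------------------------------------------------------
# Preprocessing state (fit once, apply to streaming data)
# ---------------------------------------------------------------------------


@dataclass
class PreprocessState:
    """Fitted preprocessing parameters, applied identically to new spectra.

    ``methods`` lists the steps in application order; supported tags are
    ``"savitzky_golay"``, ``"mean_center"`` and ``"autoscale"``.
    """

    methods: list[str] = field(default_factory=list)
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    sg_window: int = 15
    sg_polyorder: int = 2
    sg_deriv: int = 2

    def fit_transform(self, block: SpectraBlock) -> np.ndarray:
        """Fit the centering/scaling statistics on ``block`` and transform it."""
        X = block
        out = block.values
        for step in self.methods:
            if step == "savitzky_golay":
                X = savitzky_golay(X, self.sg_window, self.sg_polyorder, self.sg_deriv)
                out = X.values
            elif step == "mean_center":
                out, self.column_means = mean_center(out)
            elif step == "autoscale":
                out, self.column_means, self.column_sds = autoscale(out)
            else:
                raise ValueError(f"unknown preprocessing step {step!r}")
        return out

    def transform(self, block: SpectraBlock) -> np.ndarray:
        """Apply the already-fitted steps to new data (never refits)."""
        X = block
        out = block.values
        for step in self.methods:
            if step == "savitzky_golay":
                X = savitzky_golay(X, self.sg_window, self.sg_polyorder, self.sg_deriv)
                out = X.values
            elif step == "mean_center":
                if self.column_means is None:
                    raise ValueError("mean_center state not fitted")
                out = apply_center(out, self.column_means)
            elif step == "autoscale":
                if self.column_means is None or self.column_sds is None:
                    raise ValueError("autoscale state not fitted")
                out = apply_autoscale(out, self.column_means, self.column_sds)
            else:
                raise ValueError(f"unknown preprocessing step {step!r}")
        return out

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "column_means": None
            if self.column_means is None
            else self.column_means.tolist(),
            "column_sds": None if self.column_sds is None else self.column_sds.tolist(),
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessState":
        return cls(
            methods=list(d["methods"]),
            column_means=None
            if d.get("column_means") is None
            else np.asarray(d["column_means"], dtype=float),
            column_sds=None
            if d.get("column_sds") is None
            else np.asarray(d["column_sds"], dtype=float),
            sg_window=int(d.get("sg_window", 15)),
            sg_polyorder=int(d.get("sg_polyorder", 2)),
            sg_deriv=int(d.get("sg_deriv", 2)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PreprocessState":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Dynamic Orthogonal Projection
# ---------------------------------------------------------------------------


@dataclass
class DOPCorrection:
    """Fitted orthogonalisation basis and the intermediates that built it.

    ``basis`` holds A orthonormal column vectors spanning the
    response-unrelated difference directions; applying the correction
    projects spectra onto the orthogonal complement of their span.  A
    degenerate fit (zero difference matrix) yields an empty basis and the
    correction is the identity.
    """

    basis: np.ndarray  # (n_wavelengths, A), orthonormal columns
    n_components: int
    bandwidth: float | None = None
    association_matrix: np.ndarray | None = None
    virtual_targets: np.ndarray | None = None
    difference: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.tolist(),
            "n_components": int(self.n_components),
            "bandwidth": None if self.bandwidth is None else float(self.bandwidth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DOPCorrection":
        return cls(
            basis=np.asarray(d["basis"], dtype=float),
            n_components=int(d["n_components"]),
            bandwidth=d.get("bandwidth"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "DOPCorrection":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def dop_association_matrix(
    y_target: np.ndarray, y_source: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian association kernel between target and source responses.

    ``M[i, j] = exp(-(y_t[i] - y_s[j])^2 / (2 bw^2))`` with each row
    normalised to sum to 1, so every virtual target is a convex combination
    of source spectra concentrated on sources with close y values.
    """
    y_target = np.asarray(y_target, dtype=float).ravel()
    y_source = np.asarray(y_source, dtype=float).ravel()
    if y_target.size == 0 or y_source.size == 0:
        raise ValueError("response vectors must be nonempty")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    d2 = (y_target[:, None] - y_source[None, :]) ** 2
    # subtract the row minimum before exponentiating: at tiny bandwidths the
    # raw kernel underflows to an all-zero row, while the normalized row is
    # a well-defined one-hot limit
    d2 = d2 - d2.min(axis=1, keepdims=True)
    M = np.exp(-d2 / (2.0 * bandwidth**2))
    return M / M.sum(axis=1, keepdims=True)


def dop_virtual_targets(M: np.ndarray, X_source: np.ndarray) -> np.ndarray:
    """Virtual target spectra: association-weighted mixes of source spectra."""
    M = np.asarray(M, dtype=float)
    X_source = np.asarray(X_source, dtype=float)
    if M.shape[1] != X_source.shape[0]:
        raise ValueError(
            f"association matrix has {M.shape[1]} columns but {X_source.shape[0]} "
            "source spectra were given"
        )
    return M @ X_source


def dop_fit(
    X_tar: np.ndarray,
    X_star_tar: np.ndarray,
    n_components: int = 4,
    *,
    bandwidth: float | None = None,
    association_matrix: np.ndarray | None = None,
    sv_tol: float = 1e-12,
) -> DOPCorrection:
    """SVD of the measured-minus-virtual difference; keep A right vectors.

    Singular directions with singular value below ``sv_tol`` (relative to the
    largest) are never extracted: when the difference matrix is numerically
    zero the correction degenerates to the identity instead of removing
    arbitrary directions.
    """
    X_tar = np.asarray(X_tar, dtype=float)
    X_star_tar = np.asarray(X_star_tar, dtype=float)
    if X_tar.shape != X_star_tar.shape:
        raise ValueError("measured and virtual target blocks must have equal shape")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(X_tar.shape):
        raise ValueError(
            f"n_components={n_components} exceeds difference-matrix dimensions {X_tar.shape}"
        )
    D = X_tar - X_star_tar
    _, s, Vt = np.linalg.svd(D, full_matrices=False)
    if s.size == 0 or s[0] <= sv_tol:
        keep = 0
    else:
        keep = min(n_components, int(np.sum(s > sv_tol * s[0])))
    basis = Vt[:keep].T
    return DOPCorrection(
        basis=basis,
        n_components=keep,
        virtual_targets=X_star_tar,
        difference=D,
    )


def dop_apply(X: np.ndarray, correction: DOPCorrection) -> np.ndarray:
    """Project spectra onto the orthogonal complement of the fitted basis.

    ``X (I - V V^T)`` computed as ``X - (X V) V^T``; idempotent, and the
    output is orthogonal to every basis vector.
    """
    X = np.asarray(X, dtype=float)
    V = correction.basis
    if V.shape[1] == 0:
        return X.copy()
    if X.shape[-1] != V.shape[0]:
        raise ValueError(
            f"spectra have {X.shape[-1]} channels but the basis was fitted on {V.shape[0]}"
        )
    return X - (X @ V) @ V.T


def fit_dop(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    n_components: int = 4,
    bandwidth: float | None = None,
    y_precision: float = 0.1,
) -> DOPCorrection:
    """Fit a DOP correction from calibration spectra and their responses.

    Source spectra are the per-unique-y averages of the calibration spectra
    (y grouped after rounding to the measurement precision, 0.1 cm for
    Bostwick consistency); targets are the raw calibration spectra.  The
    default kernel bandwidth is half the standard deviation of the
    calibration response.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if X_cal.shape[0] != y_cal.size:
        raise ValueError("X_cal rows and y_cal length differ")
    if bandwidth is None:
        sd = float(np.std(y_cal, ddof=1)) if y_cal.size > 1 else 0.0
        if sd == 0:
            raise ValueError("calibration response is constant; supply a bandwidth")
        bandwidth = 0.5 * sd
    y_rounded = np.round(y_cal / y_precision) * y_precision
    y_unique = np.unique(y_rounded)
    X_source = np.vstack(
        [X_cal[y_rounded == yv].mean(axis=0) for yv in y_unique]
    )
    M = dop_association_matrix(y_cal, y_unique, bandwidth)
    X_star = dop_virtual_targets(M, X_source)
    corr = dop_fit(X_cal, X_star, n_components)
    corr.bandwidth = bandwidth
    corr.association_matrix = M
    return corr
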