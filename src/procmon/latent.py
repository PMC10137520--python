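"""Latent-variable models: PCA, PLS1 regression, and their supporting tools.

PCA decomposes a centered data matrix as ``X = T P^T + E`` with orthonormal
loadings P and scores T; it drives both exploratory analysis and the
process-monitoring charts.  PLS1 relates a spectral block to one response
through latent variables oriented along directions of maximum covariance:

    X = T P^T + E      (outer relation, X side)
    y = U q^T + f      (outer relation, y side)
    U = b T            (inner relation)
    y_hat = X B        (regression form)

fitted by NIPALS with deflation of X only, which is the standard
single-response formulation.  Model selection uses venetian-blinds
cross-validation (sample i in fold i mod s); calibration/test partitioning
uses the deterministic duplex algorithm; interpretation uses VIP scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .preprocess import PreprocessState

__all__ = [
    "PCAModel",
    "PLSModel",
    "CVScheme",
    "SplitResult",
    "fit_pca",
    "venetian_blind_folds",
    "select_pca_components",
    "fit_pls",
    "predict_pls",
    "rmsecv",
    "rmsep",
    "vip_scores",
    "duplex_split",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Principal component model of a centered matrix.

    ``eigenvalues`` are the per-component score variances (ddof=1), i.e. the
    eigenvalues of the sample covariance matrix; ``all_eigenvalues`` keeps
    the full positive spectrum so monitoring limits can use the variance of
    the discarded components.
    """

    loadings: np.ndarray  # (n_variables, n_components)
    scores: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray  # (n_components,)
    explained_variance_pct: np.ndarray
    n_components: int
    n_samples: int
    all_eigenvalues: np.ndarray | None = None
    preprocess_state: PreprocessState | None = None

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scores of new (already preprocessed/centered) rows."""
        return np.asarray(X, dtype=float) @ self.loadings

    def residual(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X - self.project(X) @ self.loadings.T


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA by SVD of a centered matrix.

    The caller is responsible for centering (or supplies a preprocess state
    downstream); the decomposition itself never re-centers, so monitoring
    models can own their centering state explicitly.
    """
    X = np.asarray(X, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_variables)={min(n, m)}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    all_eigs = s**2 / (n - 1) if n > 1 else s**2
    total_var = all_eigs.sum()
    loadings = Vt[:n_components].T
    eigs = all_eigs[:n_components]
    explained = (
        100.0 * eigs / total_var if total_var > 0 else np.zeros(n_components)
    )
    return PCAModel(
        loadings=loadings,
        scores=scores[:, :n_components],
        eigenvalues=eigs,
        explained_variance_pct=explained,
        n_components=n_components,
        n_samples=n,
        all_eigenvalues=all_eigs,
    )


def venetian_blind_folds(n: int, n_splits: int = 10) -> np.ndarray:
    """Interleaved fold assignment: sample ``i`` goes to fold ``i mod n_splits``."""
    if n < n_splits:
        raise ValueError(f"cannot split {n} samples into {n_splits} venetian blinds")
    if n_splits < 2:
        raise ValueError("need at least two splits")
    return np.arange(n) % n_splits


def select_pca_components(
    X: np.ndarray, max_components: int, n_splits: int = 10
) -> tuple[int, np.ndarray]:
    """Choose the PCA dimensionality by cross-validated reconstruction PRESS.

    For each fold, loadings are fitted on the training rows; each held-out
    row is reconstructed through the pseudoinverse projection onto the first
    a loadings and its squared reconstruction error accumulated.  Projecting
    a held-out row onto any a-dimensional subspace removes an expected a/p
    share of pure noise, so the raw curve decreases even without structure;
    the PRESS is rescaled by p/(p − a) to remove that bias.  Returns the
    smallest component count whose PRESS is within one standard error (over
    folds) of the minimum, plus the PRESS curve.
    """
    X = np.asarray(X, dtype=float)
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    n, m = X.shape
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("X has no variance; component selection is undefined")
    folds = venetian_blind_folds(n, n_splits)
    max_components = min(max_components, m)
    press_per_fold = np.zeros((n_splits, max_components))
    for k in range(n_splits):
        train, test = folds != k, folds == k
        mu = X[train].mean(axis=0)
        Xtr, Xte = X[train] - mu, X[test] - mu
        kmax = min(max_components, min(Xtr.shape))
        P = fit_pca(Xtr, kmax).loadings
        for a in range(1, max_components + 1):
            Pa = P[:, : min(a, kmax)]
            # pseudoinverse projection; Pa has orthonormal columns so the
            # projector is Pa Pa^T
            recon = (Xte @ Pa) @ Pa.T
            dof = m / (m - Pa.shape[1]) if m > Pa.shape[1] else 1.0
            press_per_fold[k, a - 1] = np.sum((Xte - recon) ** 2) * dof
    press = press_per_fold.sum(axis=0)
    se = press_per_fold.std(axis=0, ddof=1) * np.sqrt(n_splits)
    best = int(np.argmin(press))
    threshold = press[best] + se[best]
    selected = int(np.argmax(press <= threshold)) + 1
    return selected, press


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Single-response PLS model in deflation (NIPALS) form.

    ``regression_vector`` collapses the sequential model into ``y_hat = X B``;
    the x/y means allow prediction from raw (uncentered) spectra.
    """

    x_weights: np.ndarray  # W, (m, A)
    x_loadings: np.ndarray  # P, (m, A)
    y_loadings: np.ndarray  # q, (A,)
    x_scores: np.ndarray  # T, (n, A)
    y_scores: np.ndarray  # U, (n, A)
    inner_coefficients: np.ndarray  # b per LV, (A,)
    regression_vector: np.ndarray  # B, (m,)
    n_lv: int
    x_mean: np.ndarray | None = None
    y_mean: float = 0.0
    preprocess_state: PreprocessState | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.x_mean is not None:
            X = X - self.x_mean
        return X @ self.regression_vector + self.y_mean

    def to_dict(self) -> dict:
        return {
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "inner_coefficients": self.inner_coefficients.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "n_lv": int(self.n_lv),
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "preprocess_state": None
            if self.preprocess_state is None
            else self.preprocess_state.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        W = np.asarray(d["x_weights"], dtype=float)
        n_lv = int(d["n_lv"])
        return cls(
            x_weights=W,
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_scores=np.zeros((0, n_lv)),
            y_scores=np.zeros((0, n_lv)),
            inner_coefficients=np.asarray(d["inner_coefficients"], dtype=float),
            regression_vector=np.asarray(d["regression_vector"], dtype=float),
            n_lv=n_lv,
            x_mean=None if d.get("x_mean") is None else np.asarray(d["x_mean"]),
            y_mean=float(d.get("y_mean", 0.0)),
            preprocess_state=None
            if d.get("preprocess_state") is None
            else PreprocessState.from_dict(d["preprocess_state"]),
        )

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    *,
    center: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> PLSModel:
    """Fit a PLS1 model by NIPALS with deflation of X only.

    For a single response the weight vector of each latent variable has the
    closed form ``w = X^T y / ||X^T y||``, so the NIPALS loop converges in
    one pass; ``tol``/``max_iter`` guard the general iteration.  The
    regression vector is assembled as ``B = W (P^T W)^{-1} q``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0) if center else X)
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds the rank {rank} of the predictor block")

    if center:
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xd = X - x_mean
        yd = y - y_mean
    else:
        x_mean, y_mean = None, 0.0
        Xd, yd = X.copy(), y.astype(float)

    n, m = Xd.shape
    W = np.zeros((m, n_lv))
    P = np.zeros((m, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    U = np.zeros((n, n_lv))
    b = np.zeros(n_lv)

    y_work = yd.copy()
    for a in range(n_lv):
        # NIPALS with a univariate response: u stays proportional to the
        # deflated y, so the w/t/u cycle is stationary after one pass; the
        # loop below is the general iteration and exits on its first check.
        u = y_work.copy()
        w = np.zeros(m)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ValueError(
                    f"response carries no covariance with X at latent variable {a + 1}"
                )
            w_new /= norm
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
            t = Xd @ w
            q_a = float(y_work @ t / (t @ t))
            u = y_work if q_a == 0 else y_work / q_a
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        q[a] = float(y_work @ t / tt)
        # inner relation U = b T; with u taken as the current deflated y the
        # inner coefficient coincides with the y loading for one response
        b[a] = float(y_work @ t / tt)
        W[:, a], P[:, a], T[:, a], U[:, a] = w, p, t, y_work
        Xd = Xd - np.outer(t, p)
        y_work = y_work - t * q[a]

    B = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        y_scores=U,
        inner_coefficients=b,
        regression_vector=B,
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def predict_pls(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def _pls_prediction_path(Xtr, ytr, Xte, max_lv):
    """Held-out predictions for 1..max_lv latent variables in one sweep."""
    x_mean = Xtr.mean(axis=0)
    y_mean = ytr.mean()
    Xd = Xtr - x_mean
    yd = ytr - y_mean
    Xt = Xte - x_mean
    preds = np.empty((Xte.shape[0], max_lv))
    yhat = np.zeros(Xte.shape[0])
    for a in range(max_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            # no covariance left: predictions stop improving
            preds[:, a:] = (yhat + y_mean)[:, None]
            return preds
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        q = float(yd @ t / tt)
        t_new = Xt @ w
        yhat = yhat + t_new * q
        preds[:, a] = yhat + y_mean
        Xd = Xd - np.outer(t, p)
        yd = yd - t * q
        Xt = Xt - np.outer(t_new, p)
    return preds


@dataclass
class CVScheme:
    """Cross-validation scheme; only interleaved venetian blinds is offered."""

    kind: str = "venetian_blinds"
    n_splits: int = 10

    def folds(self, n: int) -> np.ndarray:
        if self.kind != "venetian_blinds":
            raise ValueError(f"unknown CV scheme {self.kind!r}")
        return venetian_blind_folds(n, self.n_splits)


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    scheme: CVScheme | None = None,
) -> tuple[np.ndarray, int]:
    """Cross-validated RMSE per latent-variable count and the argmin count.

    Centering is refit inside each training fold (no leakage); the held-out
    squared errors are pooled over folds before the root is taken.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    scheme = scheme or CVScheme()
    folds = scheme.folds(X.shape[0])
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    for k in range(scheme.n_splits):
        if np.sum(folds != k) < 2:
            raise ValueError("each training fold needs at least 2 samples")
    sq = np.zeros(max_lv)
    for k in range(scheme.n_splits):
        train, test = folds != k, folds == k
        preds = _pls_prediction_path(X[train], y[train], X[test], max_lv)
        sq += np.sum((preds - y[test, None]) ** 2, axis=0)
    errors = np.sqrt(sq / X.shape[0])
    return errors, int(np.argmin(errors)) + 1


def rmsep(model: PLSModel, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Root mean square error of prediction on an external test set."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size == 0:
        raise ValueError("test set is empty")
    resid = y_test - model.predict(X_test)
    return float(np.sqrt(np.mean(resid**2)))


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable Influence in Projection for every predictor.

    VIP_j = sqrt( m * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a^T t_a the y-variance explained by latent variable a.
    The squared scores average to 1, so 1 is the conventional influence
    threshold.
    """
    W = model.x_weights
    T = model.x_scores
    q = model.y_loadings
    if T.shape[0] == 0:
        raise ValueError("VIP needs the fitted scores; reload from a full model")
    ssy = q**2 * np.einsum("ij,ij->j", T, T)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    m = W.shape[0]
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(m * (wnorm2 @ ssy) / total)


# ---------------------------------------------------------------------------
# Duplex calibration/test split
# ---------------------------------------------------------------------------


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    test_indices: np.ndarray


def duplex_split(X: np.ndarray, ratio: float = 0.7) -> SplitResult:
    """Deterministic duplex (Snee) partition into calibration and test sets.

    The two mutually farthest samples seed the calibration set and the two
    farthest remaining samples seed the test set; the sets then grow
    alternately, each taking the remaining sample farthest (max-min
    Euclidean distance) from its current members, until the test set reaches
    its quota ``n - round(ratio * n)``; all remaining samples then join
    calibration.  Distances are computed on the rows as given (preprocess
    first); ties break toward the lower sample index, so the split is fully
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    if n < 4:
        raise ValueError("duplex needs at least 4 samples")
    n_cal = int(round(ratio * n))
    n_test = n - n_cal
    if n_cal == 0 or n_test == 0:
        raise ValueError(f"ratio {ratio} leaves an empty set for n={n}")

    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    remaining = np.ones(n, dtype=bool)
    cal: list[int] = []
    test: list[int] = []
    # min distance from each sample to the current members of either set
    min_to = {"cal": np.full(n, np.inf), "test": np.full(n, np.inf)}

    def take(which: list[int], key: str, idx: int) -> None:
        which.append(idx)
        remaining[idx] = False
        np.minimum(min_to[key], d[idx], out=min_to[key])

    def farthest_pair() -> tuple[int, int]:
        sub = np.flatnonzero(remaining)
        dm = np.where(np.eye(sub.size, dtype=bool), -np.inf, d[np.ix_(sub, sub)])
        # argmax scans row-major, so on ties the lowest (i, j) pair wins
        i, j = np.unravel_index(np.argmax(dm), dm.shape)
        a, b = int(sub[i]), int(sub[j])
        return (a, b) if a < b else (b, a)

    for idx in farthest_pair():
        take(cal, "cal", idx)
    for idx in farthest_pair():
        if len(test) < n_test:
            take(test, "test", idx)

    while len(test) < n_test:
        if len(cal) < n_cal:
            sub = np.flatnonzero(remaining)
            take(cal, "cal", int(sub[np.argmax(min_to["cal"][sub])]))
        sub = np.flatnonzero(remaining)
        take(test, "test", int(sub[np.argmax(min_to["test"][sub])]))
    cal.extend(int(i) for i in np.flatnonzero(remaining))
    return SplitResult(
        calibration_indices=np.array(sorted(cal)),
        test_indices=np.array(sorted(test)),
    )
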