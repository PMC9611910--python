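"""PLS1 regression engine for descriptor-count → sensitivity models.

The model is ``y = X b + b0`` with ``X`` the molecule × fragment count
matrix and ``y`` the measured sensitivity (mV/decade). Fitting follows the
chemometric convention: constant columns are dropped, the remaining counts
are autoscaled (centered, unit variance), y is centered, and NIPALS PLS1
extracts A latent variables. Coefficients are kept in both spaces —
``b_weighted`` (autoscaled space, the scale on which descriptors are
compared and pruned) and ``b_raw`` (+ intercept, original count space).

The latent-variable count is selected by leave-one-out cross-validation:
every fold recomputes centering, scaling and the constant-column drop on
its own n−1 rows, so no information leaks from the held-out molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_TOL = 1e-12


class RankError(ValueError):
    """Requested more latent variables than the training data can support."""


@dataclass
class ModelMetrics:
    """Slope / RMSE / R² triplet for one evaluation context.

    ``slope`` is the least-squares slope of predicted on measured;
    ``rmse`` is in mV/decade; ``r2`` is the squared Pearson correlation of
    measured and predicted (``r2_residual`` — 1 − SS_res/SS_tot — is kept
    alongside for completeness).
    """

    slope: float
    rmse: float
    r2: float
    context: Literal["calibration", "loo_validation"]
    r2_residual: float = float("nan")

    def to_dict(self) -> Dict:
        return {
            "slope": float(self.slope),
            "rmse": float(self.rmse),
            "r2": float(self.r2),
            "context": self.context,
            "r2_residual": float(self.r2_residual),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelMetrics":
        return cls(**d)


@dataclass
class PLSModel:
    """Fitted PLS1 model on a fixed fragment vocabulary."""

    kept_columns: List[str]
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    weights: np.ndarray      # W, (p, A)
    loadings: np.ndarray     # P, (p, A)
    y_loadings: np.ndarray   # q, (A,)
    scores: np.ndarray       # T on training data, (n, A)
    b_weighted: np.ndarray   # coefficients in autoscaled space, (p,)
    b_raw: np.ndarray        # coefficients in count space, (p,)
    intercept: float
    n_lv: int

    def to_dict(self) -> Dict:
        return {
            "kept_columns": list(self.kept_columns),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": float(self.y_center),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "b_weighted": self.b_weighted.tolist(),
            "b_raw": self.b_raw.tolist(),
            "intercept": float(self.intercept),
            "n_lv": int(self.n_lv),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "PLSModel":
        return cls(
            kept_columns=list(d["kept_columns"]),
            x_center=np.asarray(d["x_center"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            y_center=float(d["y_center"]),
            weights=np.asarray(d["weights"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            b_weighted=np.asarray(d["b_weighted"], dtype=float),
            b_raw=np.asarray(d["b_raw"], dtype=float),
            intercept=float(d["intercept"]),
            n_lv=int(d["n_lv"]),
        )


@dataclass
class LOOResult:
    """Leave-one-out CV over a range of latent-variable counts."""

    rmsecv: np.ndarray          # (max_lv,), RMSECV for A = 1..max_lv
    selected_lv: int            # argmin RMSECV, ties → smallest A
    predictions: np.ndarray     # (max_lv, n) held-out predictions per A

    @property
    def selected_predictions(self) -> np.ndarray:
        return self.predictions[self.selected_lv - 1]


def _nipals_path(Xs: np.ndarray, yc: np.ndarray, max_lv: int
                 ) -> Tuple[List[np.ndarray], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS1, returning the cumulative coefficient vector after each
    component (scaled space) plus W, P, q and training scores T.

    Stops early if the residual covariance collapses (effective rank
    reached); deterministic, no randomness.
    """
    n, p = Xs.shape
    X = Xs.copy()
    y = yc.copy()
    b = np.zeros(p)
    b_path: List[np.ndarray] = []
    W: List[np.ndarray] = []
    P: List[np.ndarray] = []
    Q: List[float] = []
    R: List[np.ndarray] = []
    T: List[np.ndarray] = []
    for _ in range(max_lv):
        w = X.T @ y
        norm_w = np.linalg.norm(w)
        if norm_w < _TOL:
            break
        w /= norm_w
        t = X @ w
        tt = float(t @ t)
        if tt < _TOL:
            break
        p_vec = X.T @ t / tt
        q = float(y @ t) / tt
        X = X - np.outer(t, p_vec)
        y = y - q * t
        # r_a = w_a − Σ_{j<a} (p_jᵀ w_a) r_j gives B_A = Σ q_a r_a without
        # forming (PᵀW)⁻¹ explicitly
        r = w.copy()
        for p_j, r_j in zip(P, R):
            r -= float(p_j @ w) * r_j
        b = b + q * r
        W.append(w)
        P.append(p_vec)
        Q.append(q)
        R.append(r)
        T.append(t)
        b_path.append(b.copy())
    stack = lambda vs: np.column_stack(vs) if vs else np.zeros((p, 0))
    return b_path, stack(W), stack(P), np.asarray(Q, dtype=float), (
        np.column_stack(T) if T else np.zeros((n, 0)))


def _prepare(X: pd.DataFrame, scale: bool) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str], np.ndarray]:
    values = X.to_numpy(dtype=float)
    std = values.std(axis=0, ddof=1)
    keep = std > 0
    if not keep.any():
        raise RankError("all descriptor columns are constant across training rows")
    kept_cols = [c for c, k in zip(X.columns, keep) if k]
    Xk = values[:, keep]
    center = Xk.mean(axis=0)
    x_scale = Xk.std(axis=0, ddof=1) if scale else np.ones(Xk.shape[1])
    return (Xk - center) / x_scale, center, x_scale, kept_cols, keep


def fit_pls(X: pd.DataFrame, y: Sequence[float], n_lv: int, scale: bool = True) -> PLSModel:
    """Fit NIPALS PLS1 with ``n_lv`` components.

    Constant columns are dropped (recorded via ``kept_columns``), the rest
    autoscaled and y centered. Deterministic. Raises :class:`RankError` if
    ``n_lv`` exceeds the effective rank of the prepared matrix and
    ``ValueError`` for fewer than 3 training rows.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training rows")
    if not np.isfinite(y).all():
        raise ValueError("y contains missing/non-finite values")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv + 1 > X.shape[0]:
        raise ValueError(f"n_lv={n_lv} too large for {X.shape[0]} rows")
    Xs, center, x_scale, kept_cols, _ = _prepare(X, scale)
    y_center = float(y.mean())
    b_path, W, P, Q, T = _nipals_path(Xs, y - y_center, n_lv)
    if len(b_path) < n_lv:
        raise RankError(
            f"n_lv={n_lv} exceeds the effective rank {len(b_path)} of the training matrix"
        )
    b_weighted = b_path[n_lv - 1]
    b_raw = b_weighted / x_scale
    intercept = y_center - float(center @ b_raw)
    return PLSModel(
        kept_columns=kept_cols,
        x_center=center,
        x_scale=x_scale,
        y_center=y_center,
        weights=W[:, :n_lv],
        loadings=P[:, :n_lv],
        y_loadings=Q[:n_lv],
        scores=T[:, :n_lv],
        b_weighted=b_weighted,
        b_raw=b_raw,
        intercept=intercept,
        n_lv=n_lv,
    )


def _conform(model: PLSModel, X: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.kept_columns if c not in X.columns]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"descriptor matrix lacks {len(missing)} model column(s): {shown}"
            + ("…" if len(missing) > 10 else "")
        )
    return X[model.kept_columns].to_numpy(dtype=float)


def predict(model: PLSModel, X: pd.DataFrame) -> np.ndarray:
    """Predict sensitivities: ŷ = X·b_raw + intercept, row-wise."""
    return _conform(model, X) @ model.b_raw + model.intercept


def predict_via_latent(model: PLSModel, X: pd.DataFrame) -> np.ndarray:
    """Predict through the latent decomposition (score projection).

    Algebraically identical to :func:`predict`; kept as the structural
    cross-check of the coefficient collapse.
    """
    Xr = (_conform(model, X) - model.x_center) / model.x_scale
    y_hat = np.full(Xr.shape[0], model.y_center)
    for a in range(model.n_lv):
        t = Xr @ model.weights[:, a]
        Xr = Xr - np.outer(t, model.loadings[:, a])
        y_hat = y_hat + model.y_loadings[a] * t
    return y_hat


def loo_cv(X: pd.DataFrame, y: Sequence[float], max_lv: int, scale: bool = True) -> LOOResult:
    """Leave-one-out CV over A = 1..max_lv latent variables.

    Each of the n folds refits from scratch on its n−1 rows (constant-column
    drop, centering and scaling recomputed inside the fold). The selected A
    minimizes RMSECV; exact ties resolve to the smallest A. When a fold's
    effective rank is below A, its prediction at the largest attainable A is
    carried forward (the fold model cannot grow further).
    """
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if max_lv >= n:
        raise ValueError(f"max_lv={max_lv} must be smaller than n={n} for LOO")
    values = X.to_numpy(dtype=float)
    preds = np.zeros((max_lv, n))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xf = values[mask]
        yf = y[mask]
        std = Xf.std(axis=0, ddof=1)
        keep = std > 0
        if not keep.any():
            preds[:, i] = yf.mean()
            continue
        Xk = Xf[:, keep]
        center = Xk.mean(axis=0)
        x_scale = Xk.std(axis=0, ddof=1) if scale else np.ones(Xk.shape[1])
        y_center = yf.mean()
        b_path, *_ = _nipals_path((Xk - center) / x_scale, yf - y_center, max_lv)
        x_held = (values[i, keep] - center) / x_scale
        last = y_center  # 0-component fallback if the fold is degenerate
        for a in range(max_lv):
            if a < len(b_path):
                last = y_center + float(x_held @ b_path[a])
            preds[a, i] = last
    rmsecv = np.sqrt(((preds - y) ** 2).mean(axis=1))
    selected = int(np.argmin(rmsecv)) + 1
    return LOOResult(rmsecv=rmsecv, selected_lv=selected, predictions=preds)


def compute_metrics(y: Sequence[float], y_hat: Sequence[float],
                    context: Literal["calibration", "loo_validation"]) -> ModelMetrics:
    """Slope, RMSE and R² of predictions against measurements.

    RMSE = sqrt(mean((y−ŷ)²)); R² is the squared Pearson correlation
    between measured and predicted; slope is the least-squares slope of
    predicted regressed on measured (the measured-vs-predicted plot line).
    A constant prediction vector has undefined correlation — reported as
    R² = 0 (no statistical relationship).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be equal-length vectors")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    var_y = y.var()
    if var_y == 0:
        raise ValueError("zero variance in y: slope and R² are undefined")
    rmse = float(np.sqrt(((y - y_hat) ** 2).mean()))
    cov = float(((y - y.mean()) * (y_hat - y_hat.mean())).mean())
    slope = cov / float(var_y)
    var_hat = y_hat.var()
    r2 = (cov * cov) / (float(var_y) * float(var_hat)) if var_hat > 0 else 0.0
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return ModelMetrics(
        slope=float(slope),
        rmse=rmse,
        r2=float(r2),
        context=context,
        r2_residual=1.0 - ss_res / ss_tot,
    )
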