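"""Partial least squares regression (NIPALS) for univariate targets.

PLS projects the spectral matrix onto latent variables (LVs) that maximise
covariance with the target, which makes it the workhorse calibration for
high-dimensional, collinear NIR spectra.  This implementation uses the
deflation-based NIPALS algorithm with mean-centering only (no autoscaling
or derivative preprocessing), is fully deterministic, and exposes both the
latent decomposition and the equivalent affine form

    y_hat = intercept + x . coefficients

whose per-wavelength weights are the regression coefficients (RCs) used to
judge which wavelengths contribute to the calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from teahsi.errors import DegenerateTargetError, DimensionError, InvalidLVError

_Y_VAR_TOL = 1e-12


@dataclass
class CvPlan:
    """K-fold assignment for cross-validation.

    Folds are contiguous blocks after a seeded shuffle; sizes differ by at
    most one sample.
    """

    k: int = 5
    seed: int = 0
    fold_of_sample: np.ndarray | None = None

    def assign(self, n_samples: int) -> np.ndarray:
        if self.fold_of_sample is not None and self.fold_of_sample.size == n_samples:
            return self.fold_of_sample
        if self.k < 2 or self.k > n_samples:
            raise InvalidLVError(f"fold count k={self.k} invalid for n={n_samples}")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(n_samples)
        folds = np.empty(n_samples, dtype=int)
        for f, block in enumerate(np.array_split(order, self.k)):
            folds[block] = f
        self.fold_of_sample = folds
        return folds


@dataclass
class PLSModel:
    """Fitted PLS regression in both latent and coefficient form."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray           # p x A   (NIPALS weight vectors W)
    x_loadings: np.ndarray        # p x A   (P)
    y_loadings: np.ndarray        # A       (q)
    coefficients: np.ndarray      # p
    intercept: float
    n_lv: int
    training_wavelength_indices: np.ndarray | None = None
    wavelengths_nm: np.ndarray | None = None

    @property
    def n_variables(self) -> int:
        return self.coefficients.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Affine prediction ``intercept + X . coefficients``.

        ``X`` must already be subset to the model's variables (columns in
        ``training_wavelength_indices`` order when a subset was used).
        """
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_variables:
            raise DimensionError(
                f"X has {X.shape[1]} variables, model expects {self.n_variables}"
            )
        return self.intercept + X @ self.coefficients

    def to_json(self, path: str | Path) -> None:
        """Serialise to a self-describing JSON artifact (reloadable)."""
        payload = {
            "n_lv": int(self.n_lv),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "training_wavelength_indices": (
                None
                if self.training_wavelength_indices is None
                else [int(i) for i in self.training_wavelength_indices]
            ),
            "wavelengths_nm": (
                None if self.wavelengths_nm is None else self.wavelengths_nm.tolist()
            ),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            x_mean=np.array(d["x_mean"], float),
            y_mean=float(d["y_mean"]),
            weights=np.array(d["weights"], float),
            x_loadings=np.array(d["x_loadings"], float),
            y_loadings=np.array(d["y_loadings"], float),
            coefficients=np.array(d["coefficients"], float),
            intercept=float(d["intercept"]),
            n_lv=int(d["n_lv"]),
            training_wavelength_indices=(
                None
                if d["training_wavelength_indices"] is None
                else np.array(d["training_wavelength_indices"], int)
            ),
            wavelengths_nm=(
                None if d["wavelengths_nm"] is None else np.array(d["wavelengths_nm"], float)
            ),
        )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    wavelength_indices: np.ndarray | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> PLSModel:
    """Fit a univariate-y PLS model with ``n_lv`` latent variables.

    NIPALS with X- and y-deflation: at each step the weight vector is the
    covariance direction ``X' y`` (normalised), scores ``t = X w``,
    loadings ``p = X't / t't``, ``q = y't / t't``, then both matrices are
    deflated by the rank-one score contribution.  Deterministic: no random
    initialisation is involved.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DimensionError(f"X shape {X.shape} incompatible with y length {y.size}")
    n, p = X.shape
    if n < 2:
        raise DimensionError("need at least 2 samples to mean-center")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise InvalidLVError(f"n_lv={n_lv} outside [1, {max_lv}] for X of shape {X.shape}")
    if float(np.var(y)) < _Y_VAR_TOL:
        raise DegenerateTargetError("y has (near-)zero variance; nothing to calibrate")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # Residual X carries no covariance with y: remaining LVs are null.
            W, P, q = W[:, : a], P[:, : a], q[:a]
            n_lv = a
            break
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q = W[:, : a], P[:, : a], q[:a]
            n_lv = a
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc -= np.outer(t, pvec)
        yc -= qa * t
        W[:, a], P[:, a], q[a] = w, pvec, qa
    if n_lv == 0:
        raise DegenerateTargetError("X carries no covariance with y; cannot fit any LV")

    # Coefficient form: B = W (P'W)^{-1} q  (solve, not invert, for stability)
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        intercept=intercept,
        n_lv=n_lv,
        training_wavelength_indices=(
            None if wavelength_indices is None else np.asarray(wavelength_indices, int)
        ),
        wavelengths_nm=None if wavelengths_nm is None else np.asarray(wavelengths_nm, float),
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PLSModel.predict`."""
    return model.predict(X)


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 15,
    cv_plan: CvPlan | None = None,
) -> tuple[int, np.ndarray]:
    """Choose the LV count minimising k-fold RMSECV.

    RMSECV pools held-out residuals across folds.  ``max_lv`` is silently
    capped by the smallest training-fold size; ties in RMSECV go to the
    smallest LV count (parsimony).  Returns ``(best_n_lv, rmsecv)`` with
    one RMSECV entry per candidate 1..max_lv.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if cv_plan is None:
        cv_plan = CvPlan()
    folds = cv_plan.assign(n)
    smallest_train = min(n - int((folds == f).sum()) for f in range(cv_plan.k))
    max_lv = min(max_lv, smallest_train - 1, p)
    if max_lv < 1:
        raise InvalidLVError("no admissible LV count for this fold plan")

    residuals = np.zeros((max_lv, n))
    for f in range(cv_plan.k):
        test = folds == f
        train = ~test
        model = fit_pls(X[train], y[train], max_lv)
        # Reconstruct predictions at every intermediate LV count from one fit.
        Xc = X[test] - model.x_mean
        W, P, q = model.weights, model.x_loadings, model.y_loadings
        for a in range(1, max_lv + 1):
            if a <= model.n_lv:
                coef = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
            else:
                coef = model.coefficients
            pred = model.y_mean + Xc @ coef
            residuals[a - 1, test] = pred - y[test]
    rmsecv = np.sqrt((residuals**2).mean(axis=1))
    best = int(np.argmin(rmsecv)) + 1
    return best, rmsecv


def regression_coefficient_profile(model: PLSModel) -> pd.DataFrame:
    """Table of (wavelength_nm, regression_coefficient) for plotting.

    When the model was fitted on a wavelength subset, only those
    wavelengths appear.  Falls back to variable indices if the model
    carries no wavelength axis.
    """
    coef = model.coefficients
    if model.wavelengths_nm is not None:
        wl = model.wavelengths_nm
    else:
        wl = np.arange(coef.size, dtype=float)
    return pd.DataFrame({"wavelength_nm": wl, "regression_coefficient": coef})
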