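"""Model evaluation: splits, Rc/Rp/RMSE/RPD metrics, PCA, report tables.

The evaluation vocabulary is the standard chemometrics one: samples are
divided 2:1 into calibration and prediction sets; models are judged by the
Pearson correlation between measured and predicted values on each set
(Rc, Rp), the root-mean-square errors (RMSEC, RMSEP), and the residual
prediction deviation RPD = SD / RMSEP, where SD is the sample standard
deviation of the prediction-set reference values.  RPD above 2.0 is the
conventional threshold for a quantitatively accurate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from teahsi.errors import InvalidConfigurationError, TooFewSamplesError
from teahsi.pls_core import PLSModel

RPD_CAP = 1e6  # sentinel when RMSEP is exactly zero


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive calibration/prediction index sets."""

    calibration: np.ndarray
    prediction: np.ndarray
    ratio: tuple[int, int]
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration.tolist()), set(self.prediction.tolist())
        if cal & pred:
            raise InvalidConfigurationError("calibration and prediction sets overlap")


@dataclass
class ModelMetrics:
    """Performance record for one (target, model) pair."""

    rc: float
    rmsec: float
    rp: float
    rmsep: float
    sd: float
    rpd: float
    nv: int
    lv: int

    def as_dict(self) -> dict:
        return {
            "Rc": self.rc,
            "RMSEC": self.rmsec,
            "Rp": self.rp,
            "RMSEP": self.rmsep,
            "SD": self.sd,
            "RPD": self.rpd,
            "NV": self.nv,
            "LV": self.lv,
        }


def split_samples(
    y: np.ndarray,
    ratio: tuple[int, int] = (2, 1),
    method: str = "systematic",
    seed: int = 0,
) -> SplitPlan:
    """Divide samples into calibration and prediction sets.

    ``method='systematic'`` (default) is deterministic rank-based
    sampling: samples are sorted by the target value and, within each
    consecutive group of ``ratio[0] + ratio[1]`` samples, the middle
    ``ratio[1]`` go to prediction.  With the default 2:1 ratio this sends
    every third sample (by rank) to prediction while keeping the extreme
    values in calibration, so the prediction set spans the calibrated
    range.  ``method='random'`` shuffles with ``seed`` instead.
    The prediction-set size is ``floor(n * ratio[1] / sum(ratio))``.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    block = ratio[0] + ratio[1]
    if n < block:
        raise TooFewSamplesError(f"need at least {block} samples for a {ratio[0]}:{ratio[1]} split")
    n_pred = n * ratio[1] // block

    if method == "systematic":
        order = np.argsort(y, kind="stable")
        # middle element(s) of each rank-block go to prediction
        pred_pos: list[int] = []
        offset = ratio[0] // 2
        for b in range(n // block):
            start = b * block
            pred_pos.extend(range(start + offset, start + offset + ratio[1]))
        pred_idx = order[np.array(pred_pos[:n_pred], int)]
    elif method == "random":
        rng = np.random.default_rng(seed)
        pred_idx = rng.permutation(n)[:n_pred]
    else:
        raise InvalidConfigurationError(f"unknown split method '{method}'")

    pred_mask = np.zeros(n, bool)
    pred_mask[pred_idx] = True
    return SplitPlan(
        calibration=np.flatnonzero(~pred_mask),
        prediction=np.flatnonzero(pred_mask),
        ratio=ratio,
        method=method,
        seed=seed if method == "random" else None,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("Pearson correlation undefined (zero variance); reporting NaN")
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def _rmse(measured: np.ndarray, predicted: np.ndarray) -> float:
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def compute_metrics(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    subset_applied: bool = False,
) -> ModelMetrics:
    """Evaluate a fitted model on calibration and prediction sets.

    ``X_cal``/``X_pred`` are full-spectrum matrices; when the model was
    trained on a wavelength subset the columns are subset automatically
    (pass ``subset_applied=True`` if they already are).  SD uses the n-1
    denominator (sample standard deviation), the chemometrics convention
    for RPD; RPD = SD / RMSEP exactly.
    """
    def _subset(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if subset_applied or model.training_wavelength_indices is None:
            return X
        if X.shape[1] == model.n_variables:
            return X
        return X[:, model.training_wavelength_indices]

    y_cal = np.asarray(y_cal, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if np.std(y_pred, ddof=1) == 0:
        raise TooFewSamplesError("prediction-set y has zero variance; Rp/RPD undefined")
    yhat_cal = model.predict(_subset(X_cal))
    yhat_pred = model.predict(_subset(X_pred))

    rmsep = _rmse(y_pred, yhat_pred)
    sd = float(np.std(y_pred, ddof=1))
    if rmsep == 0.0:
        warnings.warn("RMSEP is exactly zero; RPD capped at sentinel value")
        rpd = RPD_CAP
    else:
        rpd = sd / rmsep
    return ModelMetrics(
        rc=_pearson(y_cal, yhat_cal),
        rmsec=_rmse(y_cal, yhat_cal),
        rp=_pearson(y_pred, yhat_pred),
        rmsep=rmsep,
        sd=sd,
        rpd=rpd,
        nv=model.n_variables,
        lv=model.n_lv,
    )


def run_pca(X: np.ndarray, n_pc: int = 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered PCA via SVD.

    Returns ``(scores, explained_pct, cumulative_pct)`` where the
    percentages are of total variance, in descending order.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if not 1 <= n_pc <= min(n - 1, p):
        raise InvalidConfigurationError(f"n_pc={n_pc} outside [1, {min(n - 1, p)}]")
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(X)
    explained = 100.0 * pca.explained_variance_ratio_
    return scores, explained, np.cumsum(explained)


def accuracy_verdict(metrics: ModelMetrics) -> str:
    """'accurate' iff RPD strictly exceeds 2.0, else 'not-accurate'."""
    return "accurate" if metrics.rpd > 2.0 else "not-accurate"


def variable_reduction_percent(n_full: int, n_selected: int) -> float:
    """Percentage of variables eliminated by selection, 100 (p - k) / p."""
    if n_full <= 0 or not 0 <= n_selected <= n_full:
        raise InvalidConfigurationError("require 0 <= n_selected <= n_full, n_full > 0")
    return 100.0 * (n_full - n_selected) / n_full


def build_report(results: dict[str, dict[str, ModelMetrics]]) -> pd.DataFrame:
    """Assemble the per-target model comparison table.

    ``results`` maps target name -> model name ('PLS', 'CARS-PLS') ->
    metrics.  Columns: Component, Model, NV, LV, Rc, RMSEC, Rp, RMSEP,
    RPD, Optimal; the optimal model per component is the one with the
    higher RPD.
    """
    rows = []
    for component, by_model in results.items():
        best = max(by_model, key=lambda m: by_model[m].rpd)
        for model_name, m in by_model.items():
            rows.append(
                {
                    "Component": component,
                    "Model": model_name,
                    "NV": m.nv,
                    "LV": m.lv,
                    "Rc": m.rc,
                    "RMSEC": m.rmsec,
                    "Rp": m.rp,
                    "RMSEP": m.rmsep,
                    "RPD": m.rpd,
                    "Optimal": model_name == best,
                }
            )
    return pd.DataFrame(rows)
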