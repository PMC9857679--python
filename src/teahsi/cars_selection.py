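"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

CARS treats wavelengths as competitors in a Monte-Carlo elimination
tournament.  At each of N runs a random subset of calibration samples is
drawn, a PLS model is fitted on the currently retained wavelengths, and
the absolute regression coefficients |b_j| decide survival twice over:

1. *Enforced elimination* — only the ceil(r_i * p) wavelengths with the
   largest |b_j| survive run i, where the retention ratio r_i follows an
   exponentially decreasing function (EDF) from r_1 = 1 down to r_N = 2/p.
2. *Adaptive reweighted sampling* (ARS) — a weighted bootstrap over the
   survivors with weights |b_j| / sum|b_j|; only distinctly sampled
   wavelengths are kept.

Each run's final subset is scored by k-fold RMSECV on the full calibration
set, and the subset with minimal RMSECV wins.  The procedure typically
reduces several hundred NIR wavelengths to a few dozen informative ones,
which both simplifies and sharpens the downstream PLS model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from teahsi.errors import InvalidConfigurationError
from teahsi.pls_core import CvPlan, PLSModel, fit_pls, select_n_lv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CarsConfig:
    """Hyperparameters of the CARS tournament.

    Defaults follow the method's canonical formulation: 50 Monte-Carlo
    runs, 80% of calibration samples drawn (without replacement) per run,
    5-fold RMSECV scoring.  ``max_lv`` bounds latent-variable counts both
    for the per-run working model and the final re-optimised model.
    """

    n_runs: int = 50
    mc_fraction: float = 0.8
    max_lv: int = 15
    cv_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise InvalidConfigurationError("n_runs must be >= 2")
        if not 0.0 < self.mc_fraction < 1.0:
            raise InvalidConfigurationError("mc_fraction must be in (0, 1)")
        if self.max_lv < 1:
            raise InvalidConfigurationError("max_lv must be >= 1")


@dataclass
class RunRecord:
    """One Monte-Carlo run's outcome."""

    run_index: int
    retained_indices: np.ndarray
    subset_size: int
    rmsecv: float


@dataclass
class CARSResult:
    """Full CARS trajectory and the winning wavelength subset."""

    runs: list[RunRecord]
    winning_run_index: int
    selected_wavelength_indices: np.ndarray
    selected_wavelengths_nm: np.ndarray | None
    n_variables_full: int

    @property
    def rmsecv_trajectory(self) -> np.ndarray:
        return np.array([r.rmsecv for r in self.runs])

    @property
    def subset_sizes(self) -> np.ndarray:
        return np.array([r.subset_size for r in self.runs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": [r.run_index for r in self.runs],
                "subset_size": [r.subset_size for r in self.runs],
                "rmsecv": [r.rmsecv for r in self.runs],
            }
        )


def edf_ratio(run_index: int, n_runs: int, n_variables: int) -> float:
    """Exponentially decreasing retention ratio r_i = a exp(-k i).

    Calibrated so r_1 = 1 (all variables kept at the first run) and
    r_N = 2/p (two variables at the last run):
    ``a = (p/2)^(1/(N-1))``, ``k = ln(p/2)/(N-1)``.
    """
    if n_variables < 2 or n_runs < 2:
        raise InvalidConfigurationError("EDF requires n_variables >= 2 and n_runs >= 2")
    if not 1 <= run_index <= n_runs:
        raise InvalidConfigurationError(f"run_index {run_index} outside [1, {n_runs}]")
    a = (n_variables / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(n_variables / 2.0) / (n_runs - 1)
    return float(a * np.exp(-k * run_index))


def _working_coefficients(
    X: np.ndarray, y: np.ndarray, retained: np.ndarray, n_lv: int, rng: np.random.Generator,
    mc_fraction: float,
) -> np.ndarray:
    """|b_j| from a PLS fit on a Monte-Carlo sample subset, retained vars only."""
    n = X.shape[0]
    n_draw = max(2, int(round(mc_fraction * n)))
    sample_idx = rng.choice(n, size=n_draw, replace=False)
    n_lv_eff = min(n_lv, retained.size, n_draw - 1)
    model = fit_pls(X[np.ix_(sample_idx, retained)], y[sample_idx], n_lv_eff)
    return np.abs(model.coefficients)


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    config: CarsConfig | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> CARSResult:
    """Run the CARS tournament on a calibration set.

    Deterministic for a fixed ``config.seed``: the Monte-Carlo sample
    draws, the ARS bootstrap and the RMSECV fold plan are all driven by it.
    Ties in RMSECV between runs are broken toward the smaller subset.
    """
    if config is None:
        config = CarsConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if p < 2:
        raise InvalidConfigurationError("CARS needs at least 2 variables to compete")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xCA25)))
    cv_plan = CvPlan(k=config.cv_k, seed=config.seed)
    cv_plan.assign(n)  # fold plan fixed across runs so RMSECVs are comparable

    # Working LV count: CV-selected on the full spectrum to start, then
    # re-optimised each run from the surviving subset's own RMSECV curve
    # (the curve is computed for scoring anyway, so this costs nothing and
    # keeps the elimination weights well-conditioned as the subset shrinks).
    current_lv, _ = select_n_lv(X, y, max_lv=config.max_lv, cv_plan=cv_plan)

    retained = np.arange(p)
    runs: list[RunRecord] = []
    for i in range(1, config.n_runs + 1):
        try:
            weights = _working_coefficients(
                X, y, retained, current_lv, rng, config.mc_fraction
            )
        except Exception:
            weights = np.ones(retained.size)
            logger.warning("run %d: working PLS fit failed; uniform weights", i)
        total = weights.sum()
        if total <= 0:
            weights = np.ones(retained.size)
            total = weights.sum()
            logger.warning("run %d: all-zero coefficients; uniform weights", i)
        w_norm = weights / total

        # (1) enforced elimination by the EDF schedule
        keep = min(retained.size, max(2, int(np.ceil(edf_ratio(i, config.n_runs, p) * p))))
        order = np.argsort(weights)[::-1]
        survivors = retained[np.sort(order[:keep])]
        surv_w = w_norm[np.sort(order[:keep])]

        # (2) adaptive reweighted sampling: weighted bootstrap with p draws,
        # keep distinct.  A fixed draw count (p, not the survivor count)
        # makes the bootstrap cover nearly all survivors once the subset is
        # below ~p/2, so subset sizes track the EDF schedule instead of
        # collapsing geometrically — the canonical two-phase trajectory
        # (fast decline first, then EDF-paced refinement).
        surv_w = surv_w / surv_w.sum()
        drawn = rng.choice(survivors.size, size=p, replace=True, p=surv_w)
        retained = survivors[np.unique(drawn)]

        lv_run, rmsecv_curve = select_n_lv(
            X[:, retained], y, max_lv=min(config.max_lv, retained.size), cv_plan=cv_plan
        )
        rmsecv = float(rmsecv_curve[lv_run - 1])
        current_lv = lv_run
        runs.append(
            RunRecord(
                run_index=i,
                retained_indices=retained.copy(),
                subset_size=retained.size,
                rmsecv=rmsecv,
            )
        )

    scores = [(r.rmsecv, r.subset_size, r.run_index) for r in runs]
    winner = runs[int(np.lexsort(([s[2] for s in scores], [s[1] for s in scores],
                                  [s[0] for s in scores]))[0])]
    selected = winner.retained_indices
    return CARSResult(
        runs=runs,
        winning_run_index=winner.run_index,
        selected_wavelength_indices=selected,
        selected_wavelengths_nm=(
            None if wavelengths_nm is None else np.asarray(wavelengths_nm, float)[selected]
        ),
        n_variables_full=p,
    )


def fit_cars_pls(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: CarsConfig | None = None,
    wavelengths_nm: np.ndarray | None = None,
) -> tuple[CARSResult, PLSModel]:
    """CARS selection followed by a final PLS on the winning wavelengths.

    The final model's LV count is re-optimised by k-fold cross-validation
    on the selected subset; the model records the subset so downstream
    prediction and pixel mapping can align cube bands to it.
    """
    if config is None:
        config = CarsConfig()
    result = cars_select(X_cal, y_cal, config, wavelengths_nm)
    sel = result.selected_wavelength_indices
    cv_plan = CvPlan(k=config.cv_k, seed=config.seed)
    n_lv, _ = select_n_lv(
        np.asarray(X_cal, float)[:, sel], y_cal, max_lv=min(config.max_lv, sel.size),
        cv_plan=cv_plan,
    )
    model = fit_pls(
        np.asarray(X_cal, float)[:, sel],
        y_cal,
        n_lv,
        wavelength_indices=sel,
        wavelengths_nm=result.selected_wavelengths_nm,
    )
    return result, model
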