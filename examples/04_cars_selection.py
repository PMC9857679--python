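"""CARS wavelength selection versus the full 508-band spectrum.

Runs the competitive adaptive reweighted sampling tournament for total
saturated fatty acids, prints the winning wavelength subset and compares
the simplified CARS-PLS model against full-spectrum PLS on the held-out
prediction set.
"""

import numpy as np

from teahsi.cars_selection import CarsConfig, fit_cars_pls
from teahsi.evaluation import compute_metrics, split_samples, variable_reduction_percent
from teahsi.pls_core import CvPlan, fit_pls, select_n_lv
from teahsi.synthetic_data import SimulationConfig, simulate_dataset

config = SimulationConfig(seed=0)
dataset = simulate_dataset(config)

target = "total_sfa"
X, y = dataset.spectra, dataset.target(target)
plan = split_samples(y)
X_cal, y_cal = X[plan.calibration], y[plan.calibration]
X_pred, y_pred = X[plan.prediction], y[plan.prediction]

n_lv, _ = select_n_lv(X_cal, y_cal, cv_plan=CvPlan(k=5, seed=0))
full = compute_metrics(fit_pls(X_cal, y_cal, n_lv), X_cal, y_cal, X_pred, y_pred)

result, model = fit_cars_pls(
    X_cal, y_cal, CarsConfig(n_runs=50, seed=0), wavelengths_nm=dataset.wavelengths
)
cars = compute_metrics(model, X_cal, y_cal, X_pred, y_pred)

kept = result.selected_wavelength_indices.size
print(f"winning run {result.winning_run_index} of {len(result.runs)}")
print(f"kept {kept} of 508 wavelengths "
      f"({variable_reduction_percent(508, kept):.2f}% eliminated)")
print("selected wavelengths (nm):",
      np.array2string(result.selected_wavelengths_nm.round(0), max_line_width=70))
print()
print(f"{'model':>10}  NV   LV    Rp     RMSEP    RPD")
print(f"{'PLS':>10}  508  {full.lv:3d}  {full.rp:.4f}  {full.rmsep:.4f}  {full.rpd:.2f}")
print(f"{'CARS-PLS':>10}  {cars.nv:3d}  {cars.lv:3d}  {cars.rp:.4f}  {cars.rmsep:.4f}  {cars.rpd:.2f}")
print()
print("Wavelength selection compresses the model ~8-fold while keeping the")
print("calibration quantitatively accurate (RPD > 2); many selected bands")
print("sit in the fatty-acid absorption block (1100-1400 nm).")
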