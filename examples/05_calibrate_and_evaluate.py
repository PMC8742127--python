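"""Predictor importance, analytic surfaces and the diameter-prediction CV.

Generates a surrogate calibration dataset (24 optical-property predictors,
betas from the two-exponential surfaces plus noise, K_norm per diameter),
ranks the predictors by out-of-bag permuted importance, refits the slope
surface, and compares surface-based calibration against fixed betas in the
repeated 80/20 evaluation.
"""

from spdri import (
    fit_analytic_surface,
    generate_calibration_dataset,
    rank_predictors,
    run_evaluation,
)
from spdri.properties import PREDICTOR_NAMES
from spdri.surrogate import SurrogateConfig

dataset = generate_calibration_dataset(SurrogateConfig(
    n_property_sets=120, seed=3))

imp = rank_predictors(dataset.predictors(),
                      dataset.frame["beta1_true"].to_numpy(),
                      names=PREDICTOR_NAMES, rng=0, n_trees=60)
print("top-4 predictors for the slope beta1:")
for name in imp.top(4):
    print(f"  {name}")

x1, x2 = dataset.surface_inputs()
surface = fit_analytic_surface(x1, x2,
                               dataset.frame["beta1_true"].to_numpy(),
                               response="beta1")
print(f"\nrefitted slope surface: "
      f"{surface.a1:.3f}*exp(-{surface.b1:.4f}*x1) + "
      f"{surface.a2:.3f}*exp(-{surface.b2:.4f}*x2) + {surface.c:.4f}"
      f"   (R^2 = {surface.r_squared:.4f})")

table = run_evaluation(dataset, n_repeats=10,
                       methods=("analytic", "fixed"), rng=1)
print("\ncoefficient of variation of the predicted diameter (%):")
print(f"{'diameter':>9s} {'analytic':>9s} {'fixed':>9s}")
for d in dataset.diameters_um:
    print(f"{d:9.0f} {table.cell('analytic', d)['cv_percent']:9.2f} "
          f"{table.cell('fixed', d)['cv_percent']:9.2f}")
print(f"{'overall':>9s} {table.overall_cv_percent['analytic']:9.2f} "
      f"{table.overall_cv_percent['fixed']:9.2f}")

# Estimating the betas from the two dominant reduced-scattering predictors
# roughly halves the dispersion compared with assuming fixed ideal-run
# betas -- calibration-free absolute diameter prediction becomes viable.
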