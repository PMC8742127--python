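"""Draw randomly perturbed optical-property sets.

Every scalar property of every medium is perturbed independently with a
Gaussian of 30% (mu_a, mu_s) or 3% (g, n) of its base value at 424 nm;
draws outside the physical bounds are redrawn.  The 24-predictor reduction
(mu_a, mu_s', n per medium) is what the calibration stage consumes.
"""

import numpy as np

from spdri import BasePropertySet, PREDICTOR_NAMES, sample_property_set

base = BasePropertySet.default()
draws = np.array([
    sample_property_set(base, rng=np.random.default_rng(i)).predictors
    for i in range(2000)
])

print(f"predictors per draw: {draws.shape[1]}")
print(f"{'predictor':34s} {'base':>8s} {'mean':>8s} {'sd/base':>8s}")
base_pred = sample_property_set(base, 0.0, 0.0, rng=0).predictors
for j in (0, 1, 2, 21, 22, 23):   # stratum corneum and blood rows
    name = PREDICTOR_NAMES[j]
    print(f"{name:34s} {base_pred[j]:8.3f} {draws[:, j].mean():8.3f} "
          f"{draws[:, j].std() / base_pred[j]:8.3f}")

# mu_a and the factors entering mu_s' fluctuate at the 30% level, the
# refractive index at 3%; means stay on the base values (unbiased draws).
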