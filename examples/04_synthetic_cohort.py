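"""Calibrate and generate a synthetic cohort with a planted dependency.

Finds the latent correlation that yields MI = 0.23 bits between two
symptoms with prevalences 47.4% and 29.7%, generates a 529-patient cohort,
and verifies the empirical MI.
"""

import numpy as np

from symptomnet import (
    CohortSpec,
    VariableSpec,
    calibrate_latent_rho,
    generate_cohort,
    mutual_information,
)

cal = calibrate_latent_rho(0.474, 0.297, target_mi_bits=0.23, tol=1e-4)
print(f"latent rho = {cal.latent_rho:.4f} gives population MI = "
      f"{cal.achieved_mi_bits:.4f} bits")

spec = CohortSpec(
    n_patients=529,
    variables=[
        VariableSpec("complex vocal tics", 0.474),
        VariableSpec("palilalia", 0.297),
    ],
    latent_corr=np.array([[1.0, cal.latent_rho], [cal.latent_rho, 1.0]]),
    seed=42,
)
cohort = generate_cohort(spec)
mi_hat = mutual_information(cohort.values[:, 0], cohort.values[:, 1]).mi_bits
print(f"empirical MI in one 529-patient draw: {mi_hat:.4f} bits")

# The single-draw estimate scatters around 0.23 with sampling noise of a few
# hundredths of a bit; at n=100,000 it converges to the calibrated value.
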