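"""Linear-quadratic dose calibration and estimation on simulated counts.

Per-cell dicentric counts follow Poisson(c0 + alpha D + beta D^2).  A
curve fit to six calibration doses is inverted to estimate a held-out
sample's dose; responses beyond the calibrated range are flagged instead
of extrapolated.
"""

import numpy as np

from dicecurator.dosimetry import estimate_dose, fit_calibration
from dicecurator.synthetic import generate_dose_sample

c0, alpha, beta = 0.001, 0.01, 0.05
doses = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0]
rng = np.random.default_rng(1)

responses = []
for d in doses:
    s = generate_dose_sample(d, (c0, alpha, beta), n_cells=500, seed=rng)
    responses.append(s.dc_counts.mean())
curve = fit_calibration(doses, responses)
print(f"fitted curve: c0={curve.c0:.4f}  alpha={curve.alpha:.4f}  "
      f"beta={curve.beta:.4f}  (true 0.0010 / 0.0100 / 0.0500)")
print("individual coefficients are noisy at 500 cells/dose; the curve as "
      "a whole still inverts doses accurately")

held_out = generate_dose_sample(2.0, (c0, alpha, beta), 500, seed=rng)
est, flag = estimate_dose(curve, held_out.dc_counts.mean())
print(f"held-out 2.0 Gy sample -> estimate {est:.2f} Gy ({flag})")
print("triage biodosimetry accepts estimates within 0.5 Gy of the "
      "physical dose")

est, flag = estimate_dose(curve, 1.5 * curve(4.0))
print(f"response beyond the calibrated range -> {est:.1f} Gy, flag={flag} "
      "(only a lower bound is reportable)")
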