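"""Poisson goodness-of-fit quality control of dicentric counts.

Whole-body low-LET exposure spreads dicentrics across cells as a Poisson
distribution; residual false positives (or missed true positives) distort
that distribution.  The test compares per-cell counts against
Poisson(lambda-hat) with an unmerged-bin Pearson chi-square, reporting
both the asymptotic p-value and a bootstrap-calibrated one.
"""

import numpy as np

from dicecurator.dosimetry import poisson_quality_test

rng = np.random.default_rng(0)

clean = rng.poisson(0.5, 500)
res = poisson_quality_test(clean, seed=1)
print(f"clean Poisson sample:    chi2={res.chi_square:.1f}  "
      f"p={res.p_value:.3f}  reject@0.005={res.rejects[0.005]}")

zeros = rng.random(500) < 0.6
contaminated = np.where(zeros, 0, rng.poisson(1.5, 500))
res = poisson_quality_test(contaminated, seed=1)
print(f"zero-inflated sample:    chi2={res.chi_square:.1f}  "
      f"p={res.p_value:.3f}  reject@0.005={res.rejects[0.005]}")
print("a rejected sample indicates curation problems: its dose estimate "
      "should not be trusted without review")

res = poisson_quality_test(np.zeros(100, int))
print(f"sample without dicentrics: {res.note!r} (no p-value)")
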