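"""End-to-end workflow on rendered synthetic metaphase images.

Simulates calibration samples and one blinded test sample, extracts
per-object morphometry, filters false-positive dicentrics, selects
images, fits the calibration curve and estimates the blinded dose.
Equivalent to the chained CLI:

    dicecurator simulate --out ws --seed 1 --doses 0,1.5,3 --test-doses 2 --n-cells 4
    dicecurator extract ws/manifest.csv --out ws
    dicecurator fp-filter ws/manifest.csv --out ws
    ...
"""

import tempfile
from pathlib import Path

import pandas as pd

from dicecurator import io, pipeline

workdir = Path(tempfile.mkdtemp(prefix="dicecurator_"))
cfg = io.PipelineConfig(seed=1)
cfg.selection.top_n = 4
spec = {
    "doses": [0, 1.5, 3.0],
    "test_doses": [2.0],
    "n_cells": 4,
    "curve": [0.005, 0.15, 0.15],     # exaggerated response so a 4-cell
    "cell_spec": {"canvas": (600, 800)},  # demo produces dicentrics
}
pipeline.run_pipeline(None, cfg,
                      ["simulate", "extract", "fp-filter", "select",
                       "calibrate", "estimate", "qc"],
                      workdir, simulate_spec=spec)

print("\ncalibration curve:", (workdir / "curve.json").read_text().strip())
print("estimates:\n", pd.read_csv(workdir / "estimates.csv").to_string(index=False))
print("\nthe estimate approximates the blinded 2 Gy within the noise of a "
      "4-cell demo; real samples use hundreds of cells per dose")
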