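"""Fit an encoding model and check it recovers the ground truth.

Runs the matched-core recovery scenario: simulate neurons from a known
Gabor-bank readout, fit the model with the same frozen core, and compare
fitted readout positions and weights with the generating ones.  Takes about
a minute on one CPU.
"""

import numpy as np

from pointreadout import run_recovery

report = run_recovery("matched_gabor", seed=1, verbose=True)

print(f"\nneurons passing the 0.15 EV filter: {report.reliable.size}")
print(f"median position error : {report.median_position_error:.4f} "
      "(relative coordinates; the map spans [-1, 1])")
print(f"median weight cosine  : {report.median_weight_cosine:.3f}")
print(f"mean FEVE, fitted     : {report.mean_feve_fit:.3f}")
print(f"mean FEVE, oracle     : {report.mean_feve_oracle:.3f}")

# Position errors well below the feature-map pixel spacing and weight
# cosines near 1 mean the Gaussian point readout identified where and what
# each simulated neuron reads from the feature space; the oracle FEVE ~ 1
# confirms the noise-corrected performance ceiling is estimated correctly.
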