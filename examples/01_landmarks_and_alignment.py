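"""Generalized Procrustes alignment of a landmark cohort.

Builds a small synthetic cohort of 72-point facial configurations (each
face digitized at a random position, orientation, and scale), writes and
re-reads them in the TPS dialect, and superimposes them with sliding
semilandmarks. The printed residual shows how much shape variation is
left once position, size, and orientation are removed.
"""

import tempfile
from pathlib import Path

import numpy as np

import facemetrics as fm
from facemetrics.synthetic_data import SyntheticConfig

scheme = fm.default_scheme()
configs, covariates, _ = fm.generate_cohort(
    SyntheticConfig(n_male=10, n_female=6, seed=1), scheme
)

with tempfile.TemporaryDirectory() as tmp:
    tps = Path(tmp) / "cohort.tps"
    fm.write_tps(configs, tps)
    configs = fm.read_tps(tps)

aligned = fm.gpa(configs, scheme=scheme, slide=True)
resid = np.sqrt(((aligned.aligned_coords - aligned.consensus) ** 2).sum(axis=(1, 2)))

print(f"aligned {len(aligned)} faces in {aligned.iterations_used} iterations "
      f"(converged={aligned.converged})")
print(f"centroid sizes (digitizing units): "
      f"{aligned.centroid_sizes.min():.0f} - {aligned.centroid_sizes.max():.0f}")
print(f"root-sum-square residual to consensus per face: "
      f"mean {resid.mean():.4f}, max {resid.max():.4f}")
# Residuals are in Procrustes units (unit centroid size): a value of 0.04
# means the face differs from the mean shape by ~4% of its overall scale.
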