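#!/usr/bin/env python
"""Blood cell-type deconvolution against the known mixing fractions.

Estimates the six blood cell-type proportions of every sample by robust
partial-correlation regression on the simulated reference panel and
compares them with the generator's true Dirichlet fractions.
"""

from pathlib import Path

import numpy as np

from entropyscape.deconvolution import estimate_fractions_matrix
from entropyscape.synthetic import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cfg = SimConfig(n_segments=50, seed=7)   # segments unused here; ref sites drive this
sim = simulate_cohort(cfg)
est = estimate_fractions_matrix(sim.ref_betas.beta, sim.reference,
                                sample_ids=sim.meta.sample_ids)
est.round(4).to_csv(OUT / "cell_fractions.tsv", sep="\t")

truth = sim.truth.fractions
rmse = np.sqrt(((est.to_numpy() - truth.to_numpy()) ** 2).mean(axis=1))
print(f"estimated fractions for {len(est)} samples -> "
      "results/cell_fractions.tsv")
print(f"per-sample RMSE vs truth: mean {rmse.mean():.4f}, "
      f"max {rmse.max():.4f} "
      f"(reference: {cfg.ref_sites_per_celltype} sites per cell type, "
      f"beta noise sd {cfg.ref_noise_sd})")
print("mean estimated composition:")
print(est.mean().round(3).to_string())
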