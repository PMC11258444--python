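#!/usr/bin/env python
"""Transcriptional noise of LER-associated genes in single-cell data.

Simulates PBMC-like scRNA counts for 7 LLI and 5 control donors in which a
planted gene set (standing in for genes with LERs in their promoters) has
half the excess expression variability in LLI cells.  After QC and
log-normalization, per-gene mean-adjusted variability (MAV) is computed per
donor group and the mean MAV_LLI/MAV_non-LLI ratio of the planted set is
tested against 1000 bootstrap sets of random genes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from entropyscape.scnoise import (
    log_normalize,
    mav,
    mav_ratio_bootstrap,
    qc_filter_cells,
)
from entropyscape.synthetic import simulate_scrna

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

expr, truth = simulate_scrna(seed=7)
n_before = len(expr.cells)
expr = qc_filter_cells(expr, min_genes=200, max_mito=0.25)
print(f"QC: kept {len(expr.cells)}/{n_before} cells")

X = log_normalize(expr)
grp = expr.cells["group"].to_numpy()
mav_lli = mav(X, expr.genes, grp == "LLI")
mav_ctl = mav(X, expr.genes, grp == "non-LLI")

merged = mav_lli.merge(mav_ctl, on="gene", suffixes=("_lli", "_ctl"))
merged.round(4).to_csv(OUT / "mav_per_gene.tsv", sep="\t", index=False)

planted = truth.loc[truth["planted"], "gene"]
obs, p, null = mav_ratio_bootstrap(mav_lli, mav_ctl, planted, n_boot=1000,
                                   seed=7)
pd.DataFrame({"null_mean_ratio": np.round(null, 4)}) \
    .to_csv(OUT / "mav_bootstrap_null.tsv", sep="\t", index=False)

print(f"planted gene set ({len(planted)} genes): mean MAV_LLI/MAV_non-LLI "
      f"= {obs:.3f}")
print(f"bootstrap null: mean {null.mean():.3f} "
      f"(range {null.min():.3f}-{null.max():.3f}, 1000 sets)")
print(f"one-sided empirical p = {p:.4f} "
      f"(floor 1/1001 = {1 / 1001:.4f}: observed below every null set)"
      if p <= 1.5 / 1001 else
      f"one-sided empirical p = {p:.4f}")
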