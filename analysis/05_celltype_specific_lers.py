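#!/usr/bin/env python
"""Which blood cell type carries the planted entropy suppression?

Runs the cell-type experiment: a cohort whose planted LERs are suppressed
only through the neutrophil component, then the CellDMC-style interaction
model (ME ~ cell fractions + fraction x phenotype) on LLI vs elder samples.
A segment is assigned to a cell type when its interaction term is the only
significant one (exclusive mode) — for planted segments that should be a
negative neutrophil coefficient.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from entropyscape.deconvolution import (
    celldmc_interactions,
    estimate_fractions_matrix,
)
from entropyscape.noise_metrics import methylation_entropy_matrix
from entropyscape.synthetic import CELL_TYPES, SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cfg = SimConfig(n_segments=4000, ler_celltype="Neutro", lli_suppression=60.0,
                kappa=160.0, fraction_conc=10.0, coverage_mean=60.0, seed=7)
sim = simulate_cohort(cfg)
me = methylation_entropy_matrix(sim.patterns.counts, cfg.b)
groups = sim.meta.table["group"].to_numpy()
sel = np.isin(groups, ["LLI", "elder"])
frac = estimate_fractions_matrix(sim.ref_betas.beta[:, sel], sim.reference,
                                 sample_ids=np.array(sim.meta.sample_ids)[sel])
res = celldmc_interactions(me[:, sel], frac,
                           (groups[sel] == "LLI").astype(float),
                           segment_ids=sim.patterns.segments["segment_id"])

planted = set(sim.truth.segments.loc[sim.truth.segments["ler_true"],
                                     "segment_id"])
rows = []
for ct in CELL_TYPES:
    sub = res[res["celltype"] == ct]
    hit = sub["specific"] & (sub["gamma"] < 0)
    hit_ids = set(sub.loc[hit, "segment_id"])
    rows.append({
        "celltype": ct,
        "n_specific_decrease": int(hit.sum()),
        "n_on_planted": len(hit_ids & planted),
    })
table = pd.DataFrame(rows)
table.to_csv(OUT / "celltype_specific_lers.tsv", sep="\t", index=False)
print(table.to_string(index=False))

neutro = table.set_index("celltype").loc["Neutro"]
detection = neutro["n_on_planted"] / len(planted)
share = neutro["n_specific_decrease"] / max(
    table["n_specific_decrease"].sum(), 1)
print(f"neutrophil detection rate on planted segments: {detection:.3f}")
print(f"neutrophils account for {100 * share:.1f}% of all cell-type-"
      "specific entropy decreases, mirroring their planted role")
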