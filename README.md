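# entropyscape

Read-level DNA methylation entropy analysis for aging and longevity
cohorts.

Aging blood methylomes drift from ordered to noisy: reads covering the same
CpGs increasingly disagree about their methylation state. This package
implements the analysis used to ask whether long-lived individuals (LLI,
>90 y) resist that drift in specific genomic regions — and whether those
regions of preserved epigenetic order also show reduced cell-to-cell
transcriptional noise. It is written for computational epigenomics work on
bisulfite sequencing cohorts with group structure (cases/controls by age),
and every statistical step is exposed as a library function exercised by
synthetic cohorts with planted ground truth.

## The statistic at the core

For a segment of b = 3 consecutive CpGs, reads covering all three positions
are binned into the 2^b = 8 binary methylation patterns and scored with the
normalized Shannon entropy

    ME = (1/b) * Σ_i −(n_i/N) log2(n_i/N)

(n_i reads of pattern i, N total). ME = 0 means every DNA molecule agrees;
ME = 1 means maximal disorder. The pipeline around it:

1. **IO / filtering** (`methylome_io`) — Bismark-style cytosine reports and
   per-read CpG call files; β = N_C/(N_C+N_T) per site; ≥10× coverage in
   >60% of samples; limma-style batch correction; segments covered by ≥5
   reads in at least half of every group.
2. **Noise metrics** (`noise_metrics`) — CV, k-bin quantization entropy,
   Martin–Plastino–Rosso permutation complexity, per-segment ME.
3. **Deconvolution** (`deconvolution`) — six blood cell-type fractions by
   robust partial correlation on a reference panel; CellDMC-style
   fraction × phenotype interactions to attribute entropy changes to a cell
   type.
4. **DER/LER inference** (`der`) — per-segment partial Kendall correlation
   of ME with group, adjusted for cell fractions; BH FDR; aging-related
   high-DERs that flip to significantly *lower* entropy in LLIs form the
   LLI-specific LER set; classical MDS for visualization coordinates.
5. **Annotation & enrichment** (`annotation`) — interval overlap labels,
   promoter CpG-O/E tertiles, 2×2 odds-ratio / Fisher enrichment of region
   sets.
6. **Transcriptional noise** (`scnoise`) — single-cell QC, log-
   normalization, mean-adjusted variability (MAV), and the
   MAV_LLI/MAV_non-LLI bootstrap test.
7. **Synthetic cohorts** (`synthetic`) — generators for all of the above
   with planted LERs, known cell fractions, batch offsets and ground-truth
   sidecars.

## Worked example

The numbered scripts under `analysis/` run the full story on synthetic
cohorts and write tables under `results/`. The central one:

```bash
python analysis/04_der_ler_analysis.py
```

prints (seed 7, 20,000 segments, 79/20/34 samples):

```
 n_segments  n_aging_der  n_high_der  pct_high_of_der  n_ler  pct_ler_of_high  n_planted  sensitivity  empirical_fdr
      20000        18752       18750            100.0   1853              9.9       2000        0.926            0.0
planted LERs recovered at sensitivity 0.93 with empirical FDR 0.0000 at q < 0.05
MDS centroid distances on LER entropies: LLI-younger 0.90, LLI-elder 6.23 (LLIs sit closer to the younger controls)
```

Reading this: essentially every segment drifts upward with age in the
generator, so almost all aging DERs are high-DERs; of those, the 1,853
called LERs recover 92.6% of the 2,000 planted ones with no false calls,
and on LER entropies the LLI samples sit with the *younger* controls in MDS
space — the signature of regionally preserved epigenetic order. The
companion scripts cover global noise metrics vs age (02), deconvolution
accuracy (03), neutrophil-specific LER attribution (05: detection rate 0.90,
neutrophils 100% of attributed decreases), promoter enrichment of called
LERs (06: OR 7.2 on the planted annotation; the genome-scale reconstruction
gives OR 6.95), and the single-cell noise bootstrap (07: planted gene set
mean MAV ratio 0.877, below all 1,000 null sets, p = 1/1001).

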