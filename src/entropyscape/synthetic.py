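"""Synthetic WGBS cohorts and scRNA counts with planted ground truth.

The generator emulates the statistical structure the entropy analysis
assumes, at desk scale:

* three groups of women — long-lived individuals (LLI, ages ~101 +/- 3.5),
  elder controls (~74.4 +/- 2.5) and younger controls (~58.6 +/- 5.7);
* per-segment read-level methylation patterns whose disorder grows with age
  (epigenetic drift) but is held low ("suppressed drift") in a planted subset
  of segments for the LLI group only — the ground-truth lower-entropy regions
  (LERs);
* six blood cell types mixed with known Dirichlet fractions, a reference
  beta matrix for deconvolution, and additive batch offsets on beta values;
* negative-binomial scRNA counts with group-specific overdispersion for the
  transcriptional-noise module.

Drift model
-----------
Each cell type in each segment has a base pattern distribution over the
2**b read patterns (product of per-CpG Bernoulli levels drawn from a bimodal
Beta mixture, so young methylomes are ordered).  A sample of age ``a`` keeps
the base with weight ``w = alpha/(alpha+1)`` where
``alpha = alpha0 * exp(-drift_slope * a)`` and drifts toward the uniform
pattern distribution with weight ``1-w``; in planted LER segments of LLI
samples, ``alpha`` is multiplied by ``lli_suppression`` (restoring order)
either in all cell types or only in the responsible cell type.  Read counts
are Dirichlet-multinomial around the sample's cell-fraction-weighted mixture
with replicate concentration ``kappa``.  Low concentration alpha therefore
means high methylation entropy, and entropy rises monotonically with age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .methylome_io import (
    CytosineRecord,
    ReadCall,
    SampleMetadata,
    SegmentPatternTable,
    SiteBetaMatrix,
    write_cpg_context,
    write_cytosine_report,
)
from .scnoise import ExpressionMatrix

CELL_TYPES = ("B", "CD4T", "CD8T", "Mono", "Neutro", "NK")

# blood-like mean fractions (neutrophil-dominant)
_FRACTION_MEANS = np.array([0.08, 0.15, 0.08, 0.08, 0.55, 0.06])


@dataclass
class SimConfig:
    """Study-like defaults for the synthetic cohort."""

    n_per_group: tuple[int, int, int] = (79, 20, 34)   # (LLI, elder, younger)
    age_mean: tuple[float, float, float] = (101.0, 74.4, 58.6)
    age_sd: tuple[float, float, float] = (3.5, 2.5, 5.7)
    n_segments: int = 20000
    b: int = 3
    frac_planted_ler: float = 0.10
    ler_celltype: str = "all"          # "all" or one of CELL_TYPES
    alpha0: float = 40.0               # concentration at age 0
    drift_slope: float = 0.045         # concentration decay per year
    lli_suppression: float = 8.0       # concentration multiplier in planted LERs
    kappa: float = 60.0                # replicate (biological) concentration
    coverage_mean: float = 30.0        # mean reads per segment
    min_reads: int = 5                 # shift of the Poisson read-count law
    n_celltypes: int = 6
    fraction_conc: float = 25.0        # Dirichlet concentration of cell fractions
    celltype_divergence: float = 0.15  # prob a cell type redraws a CpG level
    ref_sites_per_celltype: int = 200
    ref_noise_sd: float = 0.02
    n_batches: int = 2
    batch_offset: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_planted_ler <= 1.0):
            raise ValueError("frac_planted_ler must be in [0, 1]")
        if self.ler_celltype != "all" and self.ler_celltype not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.ler_celltype!r}")
        for rate in (self.alpha0, self.drift_slope, self.kappa,
                     self.coverage_mean, self.lli_suppression):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth emitted beside the simulated data."""

    segments: pd.DataFrame     # segment_id, ler_true, responsible_celltype
    fractions: pd.DataFrame    # samples x cell types (true mixing weights)


@dataclass
class CohortSim:
    """In-memory result of :func:`simulate_cohort`."""

    config: SimConfig
    meta: SampleMetadata
    patterns: SegmentPatternTable
    reference: pd.DataFrame          # ref sites x cell types (beta values)
    ref_betas: SiteBetaMatrix        # sample betas at reference sites
    truth: GroundTruth

    def segment_site_betas(self) -> SiteBetaMatrix:
        """Per-CpG beta values derived from the pattern marginals (batch
        offsets included), 3 sites per segment."""
        counts = self.patterns.counts
        b = self.patterns.b
        N = counts.sum(axis=2)
        bits = np.array(
            [[(i >> (b - 1 - j)) & 1 for i in range(2 ** b)] for j in range(b)],
            dtype=float,
        )  # (b, 2**b)
        meth = np.einsum("gsp,jp->gjs", counts.astype(float), bits)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = meth / N[:, None, :]
        offsets = _batch_offsets(self.meta.table["batch"].to_numpy(),
                                 self.config.batch_offset)
        beta = np.clip(beta + offsets[None, None, :], 0.0, 1.0)
        rows = []
        for seg in self.patterns.segments.itertuples(index=False):
            for pos in seg.cpg_positions:
                rows.append((seg.chrom, pos, "+"))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
        n_sites = len(sites)
        beta2 = beta.reshape(n_sites, -1)
        cov = np.repeat(N, b, axis=0).reshape(n_sites, -1)
        return SiteBetaMatrix(sites, list(self.patterns.samples),
                              np.where(cov > 0, beta2, np.nan), cov)

    def write(self, out_dir, write_reads: bool = True) -> None:
        """Emit the text formats the IO layer consumes, plus ground-truth
        sidecars.  Byte-identical across runs with the same seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.meta.write_tsv(out / "meta.tsv")
        seg = self.patterns.segments.copy()
        seg["cpg_positions"] = seg["cpg_positions"].map(
            lambda t: ",".join(str(p) for p in t))
        seg.to_csv(out / "segments.tsv", sep="\t", index=False)
        self.patterns.write_tsv(out / "patterns.tsv")
        self.truth.segments.to_csv(out / "truth_segments.tsv", sep="\t",
                                   index=False)
        self.truth.fractions.to_csv(out / "truth_fractions.tsv", sep="\t")
        self.reference.to_csv(out / "reference.tsv", sep="\t")
        ref_b = pd.DataFrame(self.ref_betas.beta,
                             index=self.ref_betas.sites["chrom"].astype(str)
                             + ":" + self.ref_betas.sites["pos"].astype(str),
                             columns=self.ref_betas.samples)
        ref_b.to_csv(out / "ref_betas.tsv", sep="\t")
        if write_reads:
            self._write_read_files(out)

    def _write_read_files(self, out: Path) -> None:
        calls_dir = out / "cpg_context"
        reports_dir = out / "cytosine_reports"
        calls_dir.mkdir(exist_ok=True)
        reports_dir.mkdir(exist_ok=True)
        b = self.patterns.b
        segs = list(self.patterns.segments.itertuples(index=False))
        for j, sample in enumerate(self.patterns.samples):
            calls: list[ReadCall] = []
            records: list[CytosineRecord] = []
            for i, seg in enumerate(segs):
                counts = self.patterns.counts[i, j]
                read_no = 0
                meth_per_site = np.zeros(b, dtype=int)
                for p in np.flatnonzero(counts):
                    pattern = SegmentPatternTable.index_to_pattern(int(p), b)
                    for _ in range(int(counts[p])):
                        rid = f"{seg.segment_id}_r{read_no}"
                        read_no += 1
                        for site, state in zip(seg.cpg_positions, pattern):
                            calls.append(ReadCall(rid, seg.chrom, site, state))
                    for k, state in enumerate(pattern):
                        if state == "M":
                            meth_per_site[k] += int(counts[p])
                N = int(counts.sum())
                for k, pos in enumerate(seg.cpg_positions):
                    records.append(CytosineRecord(
                        seg.chrom, pos, "+", int(meth_per_site[k]),
                        N - int(meth_per_site[k]), "CpG", "CGN"))
            write_cpg_context(calls, calls_dir / f"{sample}.txt")
            write_cytosine_report(records, reports_dir / f"{sample}.txt")


def _batch_offsets(batches: np.ndarray, magnitude: float) -> np.ndarray:
    """Additive per-sample offsets: sum-to-zero across batch levels."""
    levels = np.unique(batches)
    if len(levels) < 2 or magnitude == 0:
        return np.zeros(len(batches))
    centers = np.linspace(-magnitude, magnitude, len(levels))
    lut = dict(zip(levels, centers))
    return np.array([lut[b] for b in batches])


def _bimodal_beta(rng: np.random.Generator, size) -> np.ndarray:
    """Beta(0.3, 3) / Beta(3, 0.3) half-and-half mixture: values pile near 0
    and 1, so base pattern distributions are ordered and the deconvolution
    reference is well separated."""
    low = rng.beta(0.3, 3.0, size=size)
    high = rng.beta(3.0, 0.3, size=size)
    pick = rng.random(size) < 0.5
    return np.where(pick, high, low)


def _pattern_distribution_from_levels(levels: np.ndarray, b: int) -> np.ndarray:
    """Product-Bernoulli pattern distribution given per-CpG methylation
    probabilities; levels has shape (..., b), result (..., 2**b)."""
    out = np.ones(levels.shape[:-1] + (2 ** b,))
    for i in range(2 ** b):
        p = np.ones(levels.shape[:-1])
        for j in range(b):
            bit = (i >> (b - 1 - j)) & 1
            p = p * (levels[..., j] if bit else 1.0 - levels[..., j])
        out[..., i] = p
    return out


def _multinomial_rows(rng: np.random.Generator, n: np.ndarray,
                      p: np.ndarray) -> np.ndarray:
    """Vectorized multinomial sampling via the conditional-binomial chain.

    ``n`` broadcasts over the leading axes of ``p`` (shape (..., K)).
    """
    K = p.shape[-1]
    remaining = np.array(n, dtype=np.int64)
    remaining_p = np.ones(p.shape[:-1])
    counts = np.zeros(p.shape, dtype=np.int64)
    for i in range(K - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(remaining_p > 0, p[..., i] / remaining_p, 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        draw = rng.binomial(remaining, frac)
        counts[..., i] = draw
        remaining = remaining - draw
        remaining_p = np.maximum(remaining_p - p[..., i], 0.0)
    counts[..., K - 1] = remaining
    return counts


def simulate_cohort(config: SimConfig | None = None,
                    out_dir=None, write_reads: bool = True) -> CohortSim:
    """Generate a cohort under ``config``; optionally write the text formats.

    Returns a :class:`CohortSim` bundling metadata, the segment pattern
    table, the deconvolution reference with noisy sample betas at reference
    sites, and the planted ground truth.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    b = cfg.b
    n_patterns = 2 ** b

    # ---- samples -----------------------------------------------------------
    groups, ages, sample_ids = [], [], []
    for g, (label, n, mu, sd) in enumerate(
            zip(("LLI", "elder", "younger"), cfg.n_per_group,
                cfg.age_mean, cfg.age_sd)):
        a = rng.normal(mu, sd, size=n)
        a = np.clip(a, mu - 3 * sd, mu + 3 * sd)
        ages.extend(a)
        groups.extend([label] * n)
        sample_ids.extend(f"{label}_{i:03d}" for i in range(n))
    n_samples = len(sample_ids)
    batches = np.array([f"b{i % cfg.n_batches + 1}" for i in range(n_samples)])
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids, "group": groups,
        "age": np.round(ages, 1), "batch": batches,
    }))
    ages = meta.table["age"].to_numpy(dtype=float)
    is_lli = meta.table["group"].to_numpy() == "LLI"

    # ---- cell fractions ----------------------------------------------------
    fractions = rng.dirichlet(cfg.fraction_conc * _FRACTION_MEANS,
                              size=n_samples)          # samples x types
    truth_fractions = pd.DataFrame(fractions, index=sample_ids,
                                   columns=list(CELL_TYPES))

    # ---- segment base pattern distributions per cell type ------------------
    n_seg = cfg.n_segments
    seg_levels = _bimodal_beta(rng, (n_seg, b))
    type_levels = np.repeat(seg_levels[:, None, :], cfg.n_celltypes, axis=1)
    redraw = rng.random((n_seg, cfg.n_celltypes, b)) < cfg.celltype_divergence
    type_levels = np.where(redraw, _bimodal_beta(rng, redraw.shape), type_levels)
    base = _pattern_distribution_from_levels(type_levels, b)  # seg x type x 8

    # ---- planted LERs ------------------------------------------------------
    n_planted = int(round(cfg.frac_planted_ler * n_seg))
    planted_idx = rng.choice(n_seg, size=n_planted, replace=False)
    planted = np.zeros(n_seg, dtype=bool)
    planted[planted_idx] = True

    # ---- drift weights -----------------------------------------------------
    alpha = cfg.alpha0 * np.exp(-cfg.drift_slope * ages)       # per sample
    w = alpha / (alpha + 1.0)
    alpha_sup = alpha * cfg.lli_suppression
    w_sup = alpha_sup / (alpha_sup + 1.0)

    # mixture mean over cell types, without suppression:
    # m = w * (f @ base) + (1 - w)/8
    base_mix = np.einsum("sc,gcp->gsp", fractions, base)       # seg x samp x 8
    m = w[None, :, None] * base_mix + (1.0 - w)[None, :, None] / n_patterns

    lli_cols = np.flatnonzero(is_lli)
    if n_planted and len(lli_cols):
        if cfg.ler_celltype == "all":
            sub = (w_sup[lli_cols, None] * base_mix[np.ix_(planted_idx, lli_cols)]
                   + (1.0 - w_sup[lli_cols])[None, :, None] / n_patterns)
            m[np.ix_(planted_idx, lli_cols)] = sub
        else:
            c = CELL_TYPES.index(cfg.ler_celltype)
            dw = (w_sup - w)[lli_cols]                         # per LLI sample
            f_c = fractions[lli_cols, c]
            corr = (f_c * dw)[None, :, None] * (
                base[planted_idx][:, None, c, :] - 1.0 / n_patterns)
            m[np.ix_(planted_idx, lli_cols)] += corr

    # ---- reads: Dirichlet-multinomial around m -----------------------------
    N = cfg.min_reads + rng.poisson(
        max(cfg.coverage_mean - cfg.min_reads, 0.0), size=(n_seg, n_samples))
    gam = rng.gamma(np.maximum(cfg.kappa * m, 1e-12))
    p = gam / gam.sum(axis=2, keepdims=True)
    counts = _multinomial_rows(rng, N, p)

    # ---- segment coordinates ----------------------------------------------
    starts = 1000 + 1000 * np.arange(n_seg)
    seg_rows = [(f"chr1:{s}", "chr1", int(s), (int(s), int(s) + 50, int(s) + 100))
                for s in starts]
    segments = pd.DataFrame(
        seg_rows, columns=["segment_id", "chrom", "start_pos", "cpg_positions"])
    patterns = SegmentPatternTable(segments, sample_ids, b, counts)

    truth_segments = pd.DataFrame({
        "segment_id": segments["segment_id"],
        "ler_true": planted,
        "responsible_celltype": np.where(
            planted, cfg.ler_celltype if cfg.ler_celltype != "all" else "all",
            "none"),
    })

    # ---- deconvolution reference and sample betas at reference sites -------
    n_ref = cfg.ref_sites_per_celltype * cfg.n_celltypes
    ref = _bimodal_beta(rng, (n_ref, cfg.n_celltypes))
    ref_df = pd.DataFrame(ref, columns=list(CELL_TYPES),
                          index=[f"ref_{i}" for i in range(n_ref)])
    mix_betas = ref @ fractions.T                              # sites x samples
    mix_betas = mix_betas + rng.normal(0.0, cfg.ref_noise_sd, mix_betas.shape)
    mix_betas = mix_betas + _batch_offsets(batches, cfg.batch_offset)[None, :]
    mix_betas = np.clip(mix_betas, 0.0, 1.0)
    ref_sites = pd.DataFrame({
        "chrom": "chrR",
        "pos": np.arange(1, n_ref + 1) * 100,
        "strand": "+",
    })
    ref_betas = SiteBetaMatrix(
        ref_sites, sample_ids, mix_betas,
        np.full(mix_betas.shape, int(cfg.coverage_mean), dtype=np.int64))

    sim = CohortSim(cfg, meta, patterns, ref_df, ref_betas,
                    GroundTruth(truth_segments, truth_fractions))
    if out_dir is not None:
        sim.write(out_dir, write_reads=write_reads)
    return sim


# --------------------------------------------------------------------------
# single-cell RNA counts
# --------------------------------------------------------------------------

def simulate_scrna(
    n_genes: int = 2000,
    cells_per_donor: int = 300,
    donors: pd.DataFrame | None = None,
    n_planted: int = 100,
    planted_multiplier: float = 0.5,
    planted_group: str = "LLI",
    frac_mito: float = 0.025,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial scRNA counts with a planted variability gene set.

    Counts are gamma-Poisson: variance = mu + disp * mu**2, with the
    overdispersion coefficient ``disp`` multiplied by ``planted_multiplier``
    for the planted genes in cells of ``planted_group`` (a multiplier of 0.5
    halves the excess variability; 1.0 is the null).  The donor table defaults
    to 7 LLI and 5 non-LLI donors, mirroring a longevity PBMC cohort.
    Library sizes are lognormal; a subset of genes is flagged mitochondrial
    for QC exercises.

    Returns the expression matrix and a per-gene truth table
    (gene, planted, multiplier).
    """
    if planted_multiplier <= 0:
        raise ValueError("multipliers must be > 0")
    rng = np.random.default_rng(seed)
    if donors is None:
        donors = pd.DataFrame({
            "donor": [f"LLI_{i}" for i in range(7)]
                     + [f"CTL_{i}" for i in range(5)],
            "group": ["LLI"] * 7 + ["non-LLI"] * 5,
        })
    cells_per = np.full(len(donors), cells_per_donor, dtype=int) \
        if np.isscalar(cells_per_donor) else np.asarray(cells_per_donor)
    keep = cells_per > 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.sum(~keep)} donor(s) with zero cells", stacklevel=2)
        donors = donors.loc[keep].reset_index(drop=True)
        cells_per = cells_per[keep]

    genes = np.array([f"gene_{i:04d}" for i in range(n_genes)], dtype=object)
    n_mito = int(round(frac_mito * n_genes))
    mito_flag = np.zeros(n_genes, dtype=bool)
    mito_idx = rng.choice(n_genes, size=n_mito, replace=False)
    mito_flag[mito_idx] = True
    genes[mito_idx] = [f"MT-{i:03d}" for i in range(n_mito)]

    non_mito = np.flatnonzero(~mito_flag)
    planted_idx = rng.choice(non_mito, size=n_planted, replace=False)
    planted = np.zeros(n_genes, dtype=bool)
    planted[planted_idx] = True

    mu = rng.lognormal(mean=np.log(1.0), sigma=1.0, size=n_genes)
    mu = np.clip(mu, 0.05, 50.0)
    disp = rng.lognormal(mean=np.log(0.8), sigma=0.4, size=n_genes)

    cell_donor = np.repeat(donors["donor"].to_numpy(), cells_per)
    cell_group = np.repeat(donors["group"].to_numpy(), cells_per)
    n_cells = len(cell_donor)
    size_factor = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)

    disp_matrix = np.repeat(disp[:, None], n_cells, axis=1)
    in_group = cell_group == planted_group
    disp_matrix[np.ix_(planted, in_group)] *= planted_multiplier

    mean_matrix = mu[:, None] * size_factor[None, :]
    shape = 1.0 / disp_matrix
    lam = rng.gamma(shape, mean_matrix * disp_matrix)
    counts = rng.poisson(lam)

    expr = ExpressionMatrix(
        counts=counts,
        genes=pd.DataFrame({"gene": genes, "mito": mito_flag}),
        cells=pd.DataFrame({"cell": [f"c{i}" for i in range(n_cells)],
                            "donor": cell_donor, "group": cell_group}),
    )
    truth = pd.DataFrame({
        "gene": genes,
        "planted": planted,
        "multiplier": np.where(planted & True, planted_multiplier, 1.0),
    })
    return expr, truth
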