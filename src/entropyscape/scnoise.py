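"""Single-cell transcriptional noise: MAV and its bootstrap comparison.

Mean-adjusted variability (MAV) scores a gene's cell-to-cell expression
variability relative to genes of similar mean expression: the squared
coefficient of variation of log-normalized expression, divided by the median
squared CV of the gene's mean-expression bin.  A MAV of 1 is typical for the
gene's expression level; the MAV_LLI / MAV_non-LLI ratio of a gene set
measures relative transcriptional noise between donor groups, and its
significance is assessed against bootstrap sets of random genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "qc_filter_cells",
    "log_normalize",
    "mav",
    "mav_ratio_bootstrap",
]


@dataclass
class ExpressionMatrix:
    """Gene x cell counts with cell metadata and a mitochondrial gene flag."""

    counts: np.ndarray | sparse.spmatrix   # genes x cells
    genes: pd.DataFrame                    # columns: gene, mito
    cells: pd.DataFrame                    # columns: cell, donor, group

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes or len(self.cells) != n_cells:
            raise ValueError("metadata does not match count matrix shape")
        if "mito" not in self.genes.columns:
            raise ValueError("genes table needs a 'mito' flag column")
        if "donor" not in self.cells.columns:
            raise ValueError("every cell needs a donor")
        self.genes = self.genes.reset_index(drop=True)
        self.cells = self.cells.reset_index(drop=True)

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        counts = self.counts[:, mask] if not sparse.issparse(self.counts) \
            else self.counts.tocsc()[:, mask]
        return ExpressionMatrix(counts, self.genes,
                                self.cells.loc[mask].reset_index(drop=True))


def qc_filter_cells(
    expr: ExpressionMatrix,
    min_genes: int = 500,
    max_mito: float = 0.05,
) -> ExpressionMatrix:
    """Retain cells with >= ``min_genes`` expressed genes (non-zero counts)
    and <= ``max_mito`` mitochondrial count fraction (both inclusive)."""
    counts = expr.dense()
    n_expressed = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    mito = counts[expr.genes["mito"].to_numpy()].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 1.0)
    keep = (n_expressed >= min_genes) & (mito_frac <= max_mito)
    if not keep.any():
        raise ValueError("no cells pass QC")
    return expr.subset_cells(keep)


def log_normalize(expr: ExpressionMatrix, scale: float = 1e4) -> np.ndarray:
    """ln(1 + count / cell_total * scale) per gene and cell (natural log)."""
    counts = expr.dense().astype(float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total cell encountered (run QC first)")
    return np.log1p(counts / totals[None, :] * scale)


def _merge_small_bins(bin_ids: np.ndarray, n_bins: int,
                      min_per_bin: int = 5) -> np.ndarray:
    """Merge mean-expression bins holding fewer than ``min_per_bin`` genes
    into their lower neighbor (warn)."""
    merged = bin_ids.copy()
    changed = False
    for bid in range(n_bins):
        size = int((merged == bid).sum())
        if 0 < size < min_per_bin:
            target = bid - 1 if bid > 0 else bid + 1
            merged[merged == bid] = target
            changed = True
    if changed:
        warnings.warn("merged mean-expression bins with < 5 genes",
                      stacklevel=2)
    return merged


def mav(
    norm_expr: np.ndarray,
    genes: pd.DataFrame,
    cell_mask: np.ndarray | None = None,
    n_bins: int = 20,
    min_expr_frac: float = 0.05,
) -> pd.DataFrame:
    """Mean-adjusted variability per gene over one group of cells.

    Genes expressed in fewer than ``min_expr_frac`` of the group's cells get
    NaN.  Expressed genes are ranked into ``n_bins`` equal-count bins by mean
    normalized expression; MAV = squared CV / median squared CV of the bin.

    Returns a DataFrame (gene, mean_expr, cv2, mav).
    """
    X = norm_expr if cell_mask is None else norm_expr[:, cell_mask]
    if X.shape[1] < 50:
        warnings.warn(f"only {X.shape[1]} cells in group; MAV is noisy",
                      stacklevel=2)
    expressed_frac = (X > 0).mean(axis=1)
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2 = np.where(mean > 0, var / mean ** 2, np.nan)
    ok = (expressed_frac >= min_expr_frac) & (mean > 0)

    mav_values = np.full(X.shape[0], np.nan)
    idx = np.flatnonzero(ok)
    if idx.size:
        order = idx[np.argsort(mean[idx], kind="stable")]
        n_bins_eff = min(n_bins, idx.size)
        bin_of = np.zeros(X.shape[0], dtype=int)
        bin_of[order] = np.minimum(
            (np.arange(idx.size) * n_bins_eff) // idx.size, n_bins_eff - 1)
        bin_of[~ok] = -1
        bin_of[ok] = _merge_small_bins(bin_of[ok], n_bins_eff)
        for bid in np.unique(bin_of[ok]):
            members = ok & (bin_of == bid)
            med = np.nanmedian(cv2[members])
            if med > 0:
                mav_values[members] = cv2[members] / med
    return pd.DataFrame({
        "gene": genes["gene"].to_numpy(),
        "mean_expr": mean,
        "cv2": cv2,
        "mav": mav_values,
    })


def mav_ratio_bootstrap(
    mav_a: pd.DataFrame,
    mav_b: pd.DataFrame,
    gene_set,
    n_boot: int = 1000,
    seed: int = 0,
    from_complement: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Observed mean MAV_a/MAV_b over ``gene_set`` versus bootstrap sets.

    The null distribution is ``n_boot`` means over random gene sets of equal
    size drawn without replacement from genes NOT in the set (or from all
    genes with ``from_complement=False``).  The one-sided (lower) empirical
    p-value is (1 + #{null <= observed}) / (n_boot + 1), so the attainable
    floor is 1/(n_boot+1).

    Returns (observed_mean_ratio, p_empirical, null_means).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    merged = pd.merge(mav_a[["gene", "mav"]], mav_b[["gene", "mav"]],
                      on="gene", suffixes=("_a", "_b")).dropna()
    merged = merged[merged["mav_b"] > 0]
    ratio = (merged["mav_a"] / merged["mav_b"]).to_numpy()
    gene_names = merged["gene"].to_numpy()
    in_set = np.isin(gene_names, list(gene_set))
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene_set has no genes with MAV in both tables")
    if k < 10:
        warnings.warn(f"gene set has only {k} usable genes", stacklevel=2)
    pool = ratio[~in_set] if from_complement else ratio
    if pool.size < k:
        raise ValueError("complement too small to draw bootstrap sets")
    observed = float(ratio[in_set].mean())
    rng = np.random.default_rng(seed)
    # without-replacement draws via per-row random keys
    keys = rng.random((n_boot, pool.size))
    take = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null_means = pool[take].mean(axis=1)
    p = (1.0 + np.sum(null_means <= observed)) / (n_boot + 1.0)
    return observed, float(p), null_means
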