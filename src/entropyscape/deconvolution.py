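"""Blood cell-type deconvolution and cell-type-specific entropy effects.

Two pieces:

* :func:`estimate_fractions_rpc` — reference-based estimation of the six
  blood cell-type proportions (B, CD4T, CD8T, Mono, Neutro, NK) from a bulk
  methylome by robust partial correlation: Huber-loss iteratively reweighted
  regression of the sample's beta values on the reference columns, negative
  coefficients truncated and the rest renormalized to sum to one.
* :func:`celldmc_interactions` — per-segment interaction model between cell
  fractions and a phenotype indicator to locate which cell type carries an
  entropy change: ME = sum_c f_c*beta_c + sum_c (f_c*pheno)*gamma_c + eps,
  with no global intercept (the fractions sum to one, so the f_c columns
  absorb it).  A segment is called specific to cell type c when gamma_c is
  significant (BH within cell type) and, in "exclusive" mode, no other cell
  type is.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .der import bh_fdr

__all__ = ["estimate_fractions_rpc", "estimate_fractions_matrix",
           "celldmc_interactions"]


def estimate_fractions_rpc(
    sample_betas: np.ndarray,
    reference: pd.DataFrame | np.ndarray,
    intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-6,
    huber_t: float = 1.345,
) -> np.ndarray:
    """Estimate cell-type fractions for ONE sample.

    Robust (Huber) linear regression of beta values at reference sites on the
    reference matrix columns, with an intercept that is discarded afterwards;
    negative coefficients are truncated to zero and the remainder renormalized
    to sum to one.
    """
    R = np.asarray(reference, dtype=float)
    y = np.asarray(sample_betas, dtype=float)
    if R.ndim != 2 or len(y) != R.shape[0]:
        raise ValueError("sample_betas length must match reference rows")
    if R.shape[0] < 2 * R.shape[1]:
        raise ValueError("need at least 2x more sites than cell types")
    if np.isnan(R).any():
        raise ValueError("reference contains missing values")
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        corr = np.corrcoef(R.T)
        pairs = [
            (i, j) for i in range(R.shape[1]) for j in range(i + 1, R.shape[1])
            if abs(corr[i, j]) > 0.999
        ]
        names = (list(reference.columns) if isinstance(reference, pd.DataFrame)
                 else list(range(R.shape[1])))
        named = [(names[i], names[j]) for i, j in pairs]
        raise ValueError(f"reference is rank-deficient; collinear columns: "
                         f"{named or 'undetermined'}")
    ok = ~np.isnan(y)
    X = sm.add_constant(R[ok]) if intercept else R[ok]
    model = sm.RLM(y[ok], X, M=sm.robust.norms.HuberT(t=huber_t))
    fit = model.fit(maxiter=max_iter, tol=tol)
    coefs = fit.params[1:] if intercept else fit.params
    coefs = np.clip(coefs, 0.0, None)
    total = coefs.sum()
    if total == 0:
        raise ValueError("all coefficients truncated to zero")
    return coefs / total


def estimate_fractions_matrix(
    betas: np.ndarray,
    reference: pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`estimate_fractions_rpc` column-wise to a sites x samples
    beta matrix; returns samples x cell types (rows sum to 1)."""
    betas = np.asarray(betas, dtype=float)
    rows = [estimate_fractions_rpc(betas[:, j], reference, **kwargs)
            for j in range(betas.shape[1])]
    index = (list(sample_ids) if sample_ids is not None
             else list(range(betas.shape[1])))
    return pd.DataFrame(rows, index=index, columns=list(reference.columns))


def celldmc_interactions(
    me: np.ndarray,
    fractions: pd.DataFrame,
    phenotype: np.ndarray,
    segment_ids: Sequence | None = None,
    q_threshold: float = 0.05,
    mode: str = "exclusive",
) -> pd.DataFrame:
    """Interaction analysis of ME against cell fractions and a phenotype.

    Parameters
    ----------
    me : (n_segments, n_samples) entropy matrix.
    fractions : samples x cell types, rows summing to ~1.
    phenotype : binary per-sample indicator (0/1); needs both levels with at
        least 3 samples each.
    mode : "exclusive" flags a segment for cell type c only when no other
        type is significant there; "any" flags every significant type.

    Returns a long DataFrame (segment_id, celltype, gamma, se, p, q,
    significant, specific) with one row per (segment, cell type);
    coefficients inestimable due to a near-singular design are NA.
    """
    me = np.asarray(me, dtype=float)
    F = fractions.to_numpy(dtype=float)
    pheno = np.asarray(phenotype, dtype=float)
    n_seg, n_samples = me.shape
    if F.shape[0] != n_samples or len(pheno) != n_samples:
        raise ValueError("fractions/phenotype must align with ME columns")
    levels = np.unique(pheno)
    if len(levels) < 2:
        raise ValueError("phenotype is constant")
    if min((pheno == l).sum() for l in levels) < 3:
        raise ValueError("each phenotype level needs >= 3 samples")
    celltypes = list(fractions.columns)
    k = len(celltypes)

    X = np.column_stack([F, F * pheno[:, None]])       # n x 2k
    # guard against a cell type with (near) zero fraction variance making the
    # interaction block singular
    XtX = X.T @ X
    sv = np.linalg.svd(XtX, compute_uv=False)
    bad_design = sv[-1] < sv[0] * 1e-10
    if bad_design:
        warnings.warn("near-singular CellDMC design; coefficients reported "
                      "as NA where inestimable", stacklevel=2)
    pinv = np.linalg.pinv(X)
    coefs = pinv @ me.T                                # 2k x n_seg
    resid = me.T - X @ coefs
    dof = n_samples - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    cov_diag = np.diag(pinv @ pinv.T)                  # == diag((X'X)^-1) if full rank
    se = np.sqrt(np.outer(cov_diag, sigma2))           # 2k x n_seg
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = coefs / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    gamma = coefs[k:, :]                               # k x n_seg
    gamma_se = se[k:, :]
    gamma_p = pvals[k:, :]
    if bad_design:
        # columns dropped by the pseudo-inverse (cov ~ 0) or wildly inflated
        unstable = (cov_diag[k:] < 1e-12) | (cov_diag[k:] > 1e8)
        gamma[unstable, :] = np.nan
        gamma_se[unstable, :] = np.nan
        gamma_p[unstable, :] = np.nan

    seg_ids = (np.asarray(segment_ids) if segment_ids is not None
               else np.arange(n_seg))
    rows = []
    qmat = np.vstack([bh_fdr(gamma_p[c]) for c in range(k)])   # k x n_seg
    sig = qmat < q_threshold
    if mode == "exclusive":
        n_sig = sig.sum(axis=0)
        specific = sig & (n_sig[None, :] == 1)
    elif mode == "any":
        specific = sig
    else:
        raise ValueError("mode must be 'exclusive' or 'any'")
    for c, ct in enumerate(celltypes):
        rows.append(pd.DataFrame({
            "segment_id": seg_ids,
            "celltype": ct,
            "gamma": gamma[c],
            "se": gamma_se[c],
            "p": gamma_p[c],
            "q": qmat[c],
            "significant": sig[c],
            "specific": specific[c],
        }))
    return pd.concat(rows, ignore_index=True)
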