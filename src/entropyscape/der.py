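"""Differential entropy regions: partial Kendall tests, FDR, LER calling, MDS.

The central inference of the pipeline: for each 3-CpG segment, the
association between group membership and read-level methylation entropy (ME)
is scored by a partial Kendall correlation that adjusts for estimated blood
cell-type composition, p-values come from the ppcor-style normal
approximation, and Benjamini-Hochberg FDR control is applied across
segments.  Aging-related DERs (elder vs younger) with higher entropy in the
elder group that show significantly LOWER entropy in long-lived individuals
(LLI vs elder) form the LLI-specific lower-entropy-region (LER) set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kendall_tau_b",
    "partial_kendall",
    "bh_fdr",
    "identify_ders",
    "classify_lli_lers",
    "classical_mds",
    "LERSet",
]


def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b with tie correction; NaN when x or y has no variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _tau_matrix(columns: np.ndarray) -> np.ndarray:
    """Pairwise tau-b matrix of the columns of an (n, m) array."""
    m = columns.shape[1]
    T = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            T[i, j] = T[j, i] = kendall_tau_b(columns[:, i], columns[:, j])
    return T


def batch_tau_b(Y: np.ndarray, Z: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Tau-b of every row of ``Y`` (S x n) against every column of ``Z``
    (n x m), via the O(n^2) sign-pair sum.  Returns (S, m); NaN where either
    variable is constant."""
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    S_rows, n = Y.shape
    sgnZ = np.sign(Z[:, None, :] - Z[None, :, :])          # n x n x m
    n0 = n * (n - 1)
    tz = (sgnZ == 0).sum(axis=(0, 1)) - n                   # ordered tied pairs
    out = np.empty((S_rows, Z.shape[1]))
    for start in range(0, S_rows, chunk):
        yb = Y[start:start + chunk]
        sgnY = np.sign(yb[:, :, None] - yb[:, None, :])     # c x n x n
        num = np.einsum("cij,ijm->cm", sgnY, sgnZ)
        ty = (sgnY == 0).sum(axis=(1, 2)) - n
        denom = np.sqrt((n0 - ty)[:, None] * (n0 - tz)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            out[start:start + chunk] = np.where(denom > 0, num / denom, np.nan)
    return out


def _pcor_from_tau(T: np.ndarray) -> tuple[float, bool]:
    """Partial correlation of variables 0 and 1 given the rest, from their
    correlation matrix; returns (pcor, used_pseudoinverse)."""
    used_pinv = False
    try:
        S = np.linalg.inv(T)
        if not np.isfinite(S).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        S = np.linalg.pinv(T)
        used_pinv = True
    denom = np.sqrt(S[0, 0] * S[1, 1])
    pcor = float(np.clip(-S[0, 1] / denom, -1.0, 1.0))
    return pcor, used_pinv


def _kendall_pcor_p(pcor: np.ndarray, n: int, g: int) -> np.ndarray:
    """Two-sided p for a partial Kendall correlation with g covariates via
    the normal approximation z = pcor * sqrt(9 n (n-1-g) / (2 (2(n-g)+5)))."""
    z = pcor * np.sqrt(9.0 * n * (n - 1 - g) / (2.0 * (2.0 * (n - g) + 5.0)))
    return 2.0 * stats.norm.sf(np.abs(z))


def partial_kendall(x, y, covars=None) -> tuple[float, float]:
    """Partial Kendall correlation of x and y given covariate columns.

    Builds the pairwise tau-b matrix of [x, y, covariates], inverts it
    (pseudo-inverse with a warning when near-singular) and reads off the
    partial correlation; with no covariates this is plain tau-b.  Returns
    (pcor, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = (np.empty((len(x), 0)) if covars is None
         else np.atleast_2d(np.asarray(covars, dtype=float)))
    if C.shape[0] != len(x) and C.shape[1] == len(x):
        C = C.T
    g = C.shape[1]
    n = len(x)
    if n <= g + 2:
        raise ValueError(f"need n > g + 2 (n={n}, g={g})")
    V = np.column_stack([x, y, C])
    T = _tau_matrix(V)
    if np.isnan(T).any():
        return float("nan"), float("nan")
    pcor, used_pinv = _pcor_from_tau(T)
    if used_pinv:
        warnings.warn("tau matrix near-singular; used pseudo-inverse",
                      stacklevel=2)
    p = float(_kendall_pcor_p(np.array(pcor), n, g))
    return pcor, p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN inputs propagate and are
    excluded from the number of tests m."""
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


CONTRASTS = {
    "elder_vs_younger": ("younger", "elder"),   # (reference=0, comparison=1)
    "lli_vs_elder": ("elder", "LLI"),
}


def identify_ders(
    me: np.ndarray,
    meta,
    fractions: pd.DataFrame,
    contrast: str = "elder_vs_younger",
    q_threshold: float = 0.05,
    segment_ids=None,
    drop_covariate: str | None = "Neutro",
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Per-segment partial Kendall DER test for one group contrast.

    ``me`` is segments x samples (aligned with ``meta.sample_ids``); the
    comparison group is coded 1 and the reference group 0, so
    direction="higher" means higher entropy in the elder (aging contrast) or
    LLI group.  Cell-fraction covariates enter after dropping one column
    (they sum to one; pass ``drop_covariate=None`` to keep all six, with a
    pseudo-inverse).  Segments with too few complete observations per group
    are skipped (NaN p).

    Returns a DataFrame (segment_id, contrast, pcor, p, q, direction,
    significant).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    ref_group, cmp_group = CONTRASTS[contrast]
    groups = meta.table["group"].to_numpy()
    sel = np.isin(groups, [ref_group, cmp_group])
    if sel.sum() == 0:
        raise ValueError("contrast groups absent from metadata")
    me = np.asarray(me, dtype=float)[:, sel]
    x = (groups[sel] == cmp_group).astype(float)
    F = fractions.to_numpy(dtype=float)[sel]
    cols = list(fractions.columns)
    if drop_covariate is not None:
        if drop_covariate not in cols:
            raise ValueError(f"covariate {drop_covariate!r} not in fractions")
        keep = [c for c in cols if c != drop_covariate]
        F = F[:, [cols.index(c) for c in keep]]
    g = F.shape[1]
    n = int(sel.sum())
    if n <= g + 2:
        raise ValueError("too few samples for the covariate count")

    Z = np.column_stack([x, F])                      # n x (1+g)
    TZ = _tau_matrix(Z)                              # constant block
    n_seg = me.shape[0]
    pcor = np.full(n_seg, np.nan)
    pval = np.full(n_seg, np.nan)

    complete = ~np.isnan(me).any(axis=1)
    # enough samples per group among complete columns is guaranteed when the
    # row is complete; incomplete rows are handled one by one below
    if complete.any():
        tau_y = batch_tau_b(me[complete], Z)         # S x (1+g)
        T = np.empty((int(complete.sum()), g + 2, g + 2))
        T[:, 0, 0] = 1.0
        T[:, 1, 1] = 1.0
        T[:, 0, 2:] = TZ[0, 1:]
        T[:, 2:, 0] = TZ[0, 1:]
        T[:, 2:, 2:] = TZ[1:, 1:]
        T[:, 1, 0] = T[:, 0, 1] = tau_y[:, 0]
        T[:, 1, 2:] = tau_y[:, 1:]
        T[:, 2:, 1] = tau_y[:, 1:]
        good = ~np.isnan(T).any(axis=(1, 2))
        Sinv = np.full_like(T, np.nan)
        if good.any():
            try:
                Sinv[good] = np.linalg.inv(T[good])
            except np.linalg.LinAlgError:
                for i in np.flatnonzero(good):
                    Sinv[i], _ = np.linalg.pinv(T[i]), True
        with np.errstate(invalid="ignore", divide="ignore"):
            pc = np.clip(-Sinv[:, 0, 1]
                         / np.sqrt(Sinv[:, 0, 0] * Sinv[:, 1, 1]), -1.0, 1.0)
        pcor[complete] = pc
        pval[complete] = _kendall_pcor_p(pc, n, g)
    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(me[i])
        counts = [np.sum(x[obs] == v) for v in (0.0, 1.0)]
        if min(counts) < min_per_group or obs.sum() <= g + 2:
            continue  # skipped, p stays NaN
        try:
            pcor[i], pval[i] = partial_kendall(x[obs], me[i, obs], F[obs])
        except ValueError:
            continue

    q = bh_fdr(pval)
    seg_ids = (np.asarray(segment_ids) if segment_ids is not None
               else np.arange(n_seg))
    direction = np.where(pcor > 0, "higher", "lower")
    return pd.DataFrame({
        "segment_id": seg_ids,
        "contrast": contrast,
        "pcor": pcor,
        "p": pval,
        "q": q,
        "direction": direction,
        "significant": (q < q_threshold) & ~np.isnan(q),
    })


@dataclass
class LERSet:
    """LLI-specific lower-entropy regions with the parent counts."""

    segment_ids: np.ndarray
    n_aging_der: int
    n_high_der: int
    n_ler: int

    @property
    def pct_high_of_der(self) -> float:
        """Percentage of aging DERs that are high-DERs."""
        return 100.0 * self.n_high_der / self.n_aging_der

    @property
    def pct_ler_of_high(self) -> float:
        """Percentage of high-DERs that are LLI-specific LERs."""
        return 100.0 * self.n_ler / self.n_high_der


def classify_lli_lers(
    aging: pd.DataFrame,
    lli_contrast: pd.DataFrame,
    q_threshold: float = 0.05,
) -> LERSet:
    """Intersect the two contrasts into the LER set.

    LER = aging-significant with direction "higher" (high-DER) AND
    LLI-vs-elder-significant with direction "lower".  The two record tables
    must share a segment universe.
    """
    a = aging.set_index("segment_id")
    l = lli_contrast.set_index("segment_id")
    if not a.index.equals(l.index):
        common = a.index.intersection(l.index)
        if len(common) == 0:
            raise ValueError("DER tables have disjoint segment universes")
        if len(common) != len(a.index) or len(common) != len(l.index):
            raise ValueError("DER tables cover different segment universes")
        l = l.loc[a.index]
    a_sig = (a["q"] < q_threshold) & a["q"].notna()
    l_sig = (l["q"] < q_threshold) & l["q"].notna()
    aging_der = a_sig
    high_der = a_sig & (a["direction"] == "higher")
    ler = high_der & l_sig & (l["direction"] == "lower")
    return LERSet(
        segment_ids=a.index[ler].to_numpy(),
        n_aging_der=int(aging_der.sum()),
        n_high_der=int(high_der.sum()),
        n_ler=int(ler.sum()),
    )


def classical_mds(
    points: np.ndarray,
    k: int = 3,
    top_variable: int | None = 20000,
) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of samples x features data.

    The ``top_variable`` highest-variance features are kept (all, with a
    warning, if fewer exist), Euclidean distances are double-centered and the
    top-k eigenpairs scaled by sqrt(eigenvalue) give the coordinates.  Sign
    convention: in each coordinate the entry of largest magnitude is
    positive.  Negative eigenvalues yield zero coordinates.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    if top_variable is not None:
        if X.shape[1] > top_variable:
            var = X.var(axis=0)
            idx = np.argsort(var, kind="stable")[::-1][:top_variable]
            X = X[:, np.sort(idx)]
        elif X.shape[1] < top_variable:
            warnings.warn(
                f"only {X.shape[1]} features available (< {top_variable}); "
                "using all", stacklevel=2)
    sq = (X ** 2).sum(axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    for j in range(coords.shape[1]):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords
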