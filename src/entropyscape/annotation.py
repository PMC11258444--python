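"""Genomic annotation of segments and region-set enrichment statistics.

Annotation sets are named interval collections (BED-style, 0-based
half-open).  A segment — the span from its first to last CpG — carries every
label it overlaps by >= 1 bp; a stated precedence order collapses multiple
labels to one for genic summaries.  Enrichment of a query segment set
against a universe is the classic 2x2 association: odds ratio plus Fisher's
exact p (hypergeometric), falling back to a chi-square approximation for
very large tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "read_bed",
    "annotate_segments",
    "enrichment_test",
    "cpg_oe",
    "classify_promoters",
    "GENIC_PRECEDENCE",
]

GENIC_PRECEDENCE = ("promoter", "5UTR", "exon", "intron", "3UTR", "intergenic")


@dataclass
class AnnotationSet:
    """Named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: pd.DataFrame    # columns: chrom, start, end [, metadata...]

    def __post_init__(self) -> None:
        iv = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in iv.columns:
                raise ValueError(f"intervals missing column {col!r}")
        if (iv["start"] >= iv["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.intervals = iv.sort_values(["chrom", "start"]).reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            self._trees[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"]))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False


def read_bed(path, name: str | None = None) -> AnnotationSet:
    """Read a BED3+ file into an :class:`AnnotationSet`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df = df.rename(columns={3: "feature"})
    return AnnotationSet(name or str(path), df)


def _segment_spans(segments: pd.DataFrame) -> pd.DataFrame:
    """Half-open span of each segment (first to last CpG, inclusive 1-based
    CpG coordinates converted to 0-based half-open)."""
    if "cpg_positions" in segments.columns:
        first = segments["cpg_positions"].map(lambda t: min(t))
        last = segments["cpg_positions"].map(lambda t: max(t))
    else:
        first = segments["start_pos"]
        last = segments["end_pos"] if "end_pos" in segments.columns \
            else segments["start_pos"]
    return pd.DataFrame({
        "segment_id": segments["segment_id"],
        "chrom": segments["chrom"],
        "start": first - 1,     # 1-based inclusive -> 0-based half-open
        "end": last,
    })


def annotate_segments(
    segments: pd.DataFrame,
    annotation_sets: list[AnnotationSet],
    precedence: tuple[str, ...] = GENIC_PRECEDENCE,
) -> pd.DataFrame:
    """Label segments by >= 1 bp overlap against each annotation set.

    Returns a DataFrame with one boolean column per annotation set plus a
    ``label`` column giving the single highest-precedence label
    ("intergenic" when nothing overlaps, "unplaced" for segments on
    chromosomes absent from every annotation set).
    """
    spans = _segment_spans(segments)
    known_chroms = {c for a in annotation_sets for c in a._trees}
    out = pd.DataFrame({"segment_id": spans["segment_id"]})
    hits = {}
    for annot in annotation_sets:
        hits[annot.name] = np.array([
            annot.overlaps(c, s, e)
            for c, s, e in zip(spans["chrom"], spans["start"], spans["end"])
        ])
        out[annot.name] = hits[annot.name]
    labels = []
    n_unplaced = 0
    for i, chrom in enumerate(spans["chrom"]):
        if chrom not in known_chroms:
            labels.append("unplaced")
            n_unplaced += 1
            continue
        label = "intergenic"
        for name in precedence:
            if name in hits and hits[name][i]:
                label = name
                break
        labels.append(label)
    if n_unplaced:
        warnings.warn(f"{n_unplaced} segment(s) on chromosomes absent from "
                      "all annotation sets; labeled 'unplaced'", stacklevel=2)
    out["label"] = labels
    return out


@dataclass
class EnrichmentResult:
    """2x2 association of a query segment set with an annotation."""

    annotation: str
    a: int      # query & annotated
    b: int      # query & not annotated
    c: int      # background (universe minus query) & annotated
    d: int      # background & not annotated
    odds_ratio: float
    p: float
    method: str
    haldane: bool = False


def enrichment_test(
    query: pd.DataFrame,
    universe: pd.DataFrame,
    annot: AnnotationSet,
    one_sided: bool = False,
    exact_margin: int = 10_000,
    method: str = "auto",
) -> EnrichmentResult:
    """Enrichment of ``query`` segments (subset of ``universe``) in
    ``annot``.

    The 2x2 table compares query vs universe-minus-query by annotation
    overlap.  The sample odds ratio uses the Haldane 0.5 correction only when
    a zero cell occurs (flagged).  The p-value is Fisher's exact test when
    the smallest table margin is <= ``exact_margin`` (or ``method="fisher"``),
    else a chi-square approximation (flagged via ``method``); two-sided by
    default, one-sided (greater) with ``one_sided``.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    uni_ids = set(universe["segment_id"])
    missing = set(query["segment_id"]) - uni_ids
    if missing:
        raise ValueError("query is not a subset of the universe")
    labels = annotate_segments(universe, [annot])
    annotated = dict(zip(labels["segment_id"], labels[annot.name]))
    q_ids = set(query["segment_id"])
    a = sum(1 for s in q_ids if annotated[s])
    b = len(q_ids) - a
    bg = uni_ids - q_ids
    if not bg:
        return EnrichmentResult(annot.name, a, b, 0, 0, math.nan, math.nan,
                                "degenerate")
    c = sum(1 for s in bg if annotated[s])
    d = len(bg) - c
    return enrichment_from_table(a, b, c, d, annotation=annot.name,
                                 one_sided=one_sided,
                                 exact_margin=exact_margin, method=method)


def enrichment_from_table(
    a: int, b: int, c: int, d: int,
    annotation: str = "",
    one_sided: bool = False,
    exact_margin: int = 10_000,
    method: str = "auto",
) -> EnrichmentResult:
    """Odds ratio and p for an explicit 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    table = np.array([[a, b], [c, d]])
    margins = [a + b, c + d, a + c, b + d]
    alternative = "greater" if one_sided else "two-sided"
    if method == "fisher" or (method == "auto" and min(margins) <= exact_margin):
        p = float(stats.fisher_exact(table, alternative=alternative).pvalue)
        used = "fisher"
    else:
        chi2 = stats.chi2_contingency(table, correction=True)
        p = float(chi2.pvalue)
        if one_sided:
            # signed one-sided approximation from the chi-square
            p = p / 2 if odds_ratio >= 1 else 1 - p / 2
        used = "chi2_approx"
    return EnrichmentResult(annotation, a, b, c, d, float(odds_ratio), p,
                            used, haldane)


def cpg_oe(sequence: str) -> float:
    """Observed/expected CpG ratio of a DNA sequence.

    (CG dinucleotide count * L) / (C count * G count) with N bases excluded
    from the counts and from L; CG pairs involving an N are not counted.
    NaN when the sequence has no C or no G.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence too short")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters: {sorted(bad)}")
    L = sum(1 for ch in seq if ch != "N")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    if n_c == 0 or n_g == 0:
        return math.nan
    return (n_cg * L) / (n_c * n_g)


def classify_promoters(ratios) -> np.ndarray:
    """Tertile classes of promoter CpG O/E ratios.

    Classes are "low" (<= 1/3 quantile), "medium" (<= 2/3 quantile) and
    "high"; quantiles use linear interpolation and boundary ties fall to the
    lower class.  NaN ratios are excluded (warned) and classified as "NA".
    """
    r = np.asarray(ratios, dtype=float)
    ok = ~np.isnan(r)
    if ok.sum() < 3:
        raise ValueError("need at least 3 promoters with defined ratios")
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} undefined ratio(s) excluded",
                      stacklevel=2)
    q1, q2 = np.quantile(r[ok], [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn("degenerate quantiles; ties all fall to the lower "
                      "class", stacklevel=2)
    classes = np.full(r.shape, "NA", dtype=object)
    classes[ok & (r <= q1)] = "low"
    classes[ok & (r > q1) & (r <= q2)] = "medium"
    classes[ok & (r > q2)] = "high"
    return classes
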