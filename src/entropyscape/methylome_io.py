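"""Bisulfite-derived formats, site filters, batch correction, segment tables.

Input dialects
--------------
* Bismark-style cytosine report: 7 tab-separated columns
  ``chrom  pos(1-based)  strand  count_methylated  count_unmethylated
  context  trinucleotide``.
* Bismark-style CpG-context per-read call file (minimal dialect): 5 columns
  ``read_id  flag  chrom  pos(1-based)  call_symbol`` where the call symbol is
  ``Z`` (methylated CpG) or ``z`` (unmethylated CpG).
* Pattern tables: long TSV ``segment_id  sample_id  pattern  count`` where
  ``pattern`` is a 5'->3' string over {M, U}.

Coordinates are 1-based in cytosine-report and call files (as emitted by the
upstream extractor); BED-style interfaces elsewhere are 0-based half-open.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed line in an input file; message names the line number."""


# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine from a per-CpG coverage report.

    ``n_meth``/``n_unmeth`` are the read counts supporting the methylated and
    unmethylated state (N_C and N_T).
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str = "CpG"
    trinucleotide: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative read counts")

    @property
    def is_cpg(self) -> bool:
        return self.context.upper() in ("CPG", "CG")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class ReadCall:
    """A single CpG methylation call on one sequencing read."""

    read_id: str
    chrom: str
    pos: int
    state: str  # "M" or "U"

    def __post_init__(self) -> None:
        if self.state not in ("M", "U"):
            raise ValueError(f"state must be M or U, got {self.state!r}")


@dataclass
class SampleMetadata:
    """Cohort description: group label, age and batch per sample."""

    table: pd.DataFrame  # columns: sample_id, group, age, batch

    REQUIRED = ("sample_id", "group", "age", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if (self.table["age"] <= 0).any():
            raise ValueError("ages must be positive")
        if self.table["group"].isna().any():
            raise ValueError("every sample needs a group label")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SiteBetaMatrix:
    """Per-sample per-CpG methylation fractions with read depths.

    ``beta`` holds raw fractions in [0, 1] wherever ``coverage`` > 0 (NaN at
    zero coverage); values may exit [0, 1] after batch correction.
    """

    sites: pd.DataFrame          # columns: chrom, pos, strand
    samples: list[str]
    beta: np.ndarray             # (n_sites, n_samples) float
    coverage: np.ndarray         # (n_sites, n_samples) int

    def __post_init__(self) -> None:
        n_sites, n_samples = self.beta.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError("inconsistent dimensions")
        if self.coverage.shape != self.beta.shape:
            raise ValueError("beta/coverage shape mismatch")

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @classmethod
    def from_reports(
        cls,
        paths: Sequence,
        sample_ids: Sequence[str],
        cpg_only: bool = True,
        merge_strands: bool = False,
    ) -> "SiteBetaMatrix":
        """Assemble a beta matrix from per-sample cytosine reports.

        The site universe is the union of sites over samples; missing sites get
        coverage 0 and beta NaN.  With ``merge_strands`` the - strand cytosine
        of a CpG dinucleotide (position p+1) is pooled onto the + strand
        cytosine at p.
        """
        if len(paths) != len(sample_ids):
            raise ValueError("one sample id per report path")
        per_sample: list[dict[tuple, tuple[int, int]]] = []
        for path in paths:
            records = read_cytosine_report(path)
            d: dict[tuple, tuple[int, int]] = {}
            for r in records:
                if cpg_only and not r.is_cpg:
                    continue
                if merge_strands and r.strand == "-":
                    key = (r.chrom, r.pos - 1, "+")
                else:
                    key = (r.chrom, r.pos, "+" if merge_strands else r.strand)
                nm, nu = d.get(key, (0, 0))
                d[key] = (nm + r.n_meth, nu + r.n_unmeth)
            per_sample.append(d)
        keys = sorted({k for d in per_sample for k in d})
        beta = np.full((len(keys), len(paths)), np.nan)
        cov = np.zeros((len(keys), len(paths)), dtype=np.int64)
        index = {k: i for i, k in enumerate(keys)}
        for j, d in enumerate(per_sample):
            for k, (nm, nu) in d.items():
                i = index[k]
                cov[i, j] = nm + nu
                if nm + nu > 0:
                    beta[i, j] = nm / (nm + nu)
        sites = pd.DataFrame(keys, columns=["chrom", "pos", "strand"])
        return cls(sites, list(sample_ids), beta, cov)


@dataclass
class SegmentPatternTable:
    """Per-(segment, sample) counts of read-level methylation patterns.

    A segment is a run of ``b`` consecutive catalog CpGs.  Pattern index i is
    the binary encoding of the 5'->3' methylation string with M=1 and the
    first CpG as the most significant bit, so for b=3 index 0 is UUU and
    index 5 (0b101) is MUM.
    """

    segments: pd.DataFrame       # columns: segment_id, chrom, start_pos, cpg_positions
    samples: list[str]
    b: int
    counts: np.ndarray           # (n_segments, n_samples, 2**b) int

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.segments), len(self.samples), 2 ** self.b):
            raise ValueError("counts shape mismatch")

    @property
    def N(self) -> np.ndarray:
        """Total reads fully covering each (segment, sample)."""
        return self.counts.sum(axis=2)

    # ---- pattern string helpers ----

    @staticmethod
    def pattern_to_index(pattern: str) -> int:
        idx = 0
        for ch in pattern:
            if ch not in "MU":
                raise ValueError(f"bad pattern symbol {ch!r}")
            idx = (idx << 1) | (ch == "M")
        return idx

    @staticmethod
    def index_to_pattern(idx: int, b: int) -> str:
        return "".join("M" if (idx >> (b - 1 - j)) & 1 else "U" for j in range(b))

    # ---- long-format TSV round trip ----

    def write_tsv(self, path) -> None:
        rows = []
        seg_ids = self.segments["segment_id"].to_numpy()
        for i in range(len(self.segments)):
            for j, sample in enumerate(self.samples):
                for p in np.flatnonzero(self.counts[i, j]):
                    rows.append(
                        (seg_ids[i], sample,
                         self.index_to_pattern(int(p), self.b),
                         int(self.counts[i, j, p]))
                    )
        pd.DataFrame(rows, columns=["segment_id", "sample_id", "pattern", "count"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, segments: pd.DataFrame, samples: Sequence[str],
                 b: int = 3) -> "SegmentPatternTable":
        long = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        counts = np.zeros((len(segments), len(samples), 2 ** b), dtype=np.int64)
        seg_index = {s: i for i, s in enumerate(segments["segment_id"])}
        samp_index = {s: j for j, s in enumerate(samples)}
        for row in long.itertuples(index=False):
            counts[seg_index[row.segment_id], samp_index[row.sample_id],
                   cls.pattern_to_index(row.pattern)] += row.count
        return cls(segments.reset_index(drop=True), list(samples), b, counts)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def read_cytosine_report(path) -> list[CytosineRecord]:
    """Parse a cytosine report; non-CpG contexts are retained (flagged via
    :attr:`CytosineRecord.is_cpg`)."""
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, strand, nm, nu, context, tri = fields
            try:
                rec = CytosineRecord(chrom, int(pos), strand, int(nm), int(nu),
                                     context, tri)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cytosine_report(records: Iterable[CytosineRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.n_meth}\t{r.n_unmeth}"
                     f"\t{r.context}\t{r.trinucleotide}\n")


def site_methylation(record: CytosineRecord) -> float:
    """Methylation level N_C / (N_C + N_T); NaN at zero coverage."""
    total = record.n_meth + record.n_unmeth
    if total == 0:
        return math.nan
    return record.n_meth / total


def filter_sites_by_coverage(
    matrix: SiteBetaMatrix,
    min_cov: int = 10,
    min_sample_frac: float = 0.6,
    strict: bool = True,
) -> SiteBetaMatrix:
    """Keep sites covered >= ``min_cov`` in more than ``min_sample_frac`` of
    samples (strict >; set ``strict=False`` for >=)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not (0 < min_sample_frac <= 1):
        raise ValueError("min_sample_frac must be in (0, 1]")
    n_ok = (matrix.coverage >= min_cov).sum(axis=1)
    threshold = min_sample_frac * matrix.n_samples
    keep = n_ok > threshold if strict else n_ok >= threshold
    return SiteBetaMatrix(
        matrix.sites.loc[keep].reset_index(drop=True),
        list(matrix.samples),
        matrix.beta[keep],
        matrix.coverage[keep],
    )


def remove_batch_effect(values: np.ndarray, batch: Sequence) -> np.ndarray:
    """Subtract the least-squares batch component per feature.

    ``values`` is features x samples.  Batches are coded with sum-to-zero
    contrasts and fitted jointly with an intercept; the fitted batch component
    (re-centered to zero mean) is subtracted, so the per-feature grand mean is
    preserved exactly.  With fewer than two batches the input is returned
    unchanged.  NaNs pass through untouched per feature-sample cell only when
    absent; features containing NaN are corrected on observed entries.
    """
    values = np.asarray(values, dtype=float)
    batch = np.asarray(batch)
    if values.ndim != 2 or values.shape[1] != len(batch):
        raise ValueError("values must be features x samples matching batch length")
    levels, codes = np.unique(batch, return_inverse=True)
    counts = np.bincount(codes)
    if counts.min() == 0:
        raise ValueError("a batch level has no samples")
    if len(levels) < 2:
        return values.copy()
    # sum-to-zero contrast matrix: k-1 columns; last level = -1 on all
    n = len(batch)
    k = len(levels)
    C = np.zeros((n, k - 1))
    for j in range(k - 1):
        C[codes == j, j] = 1.0
    C[codes == k - 1, :] = -1.0
    X = np.column_stack([np.ones(n), C])
    if np.isnan(values).any():
        corrected = values.copy()
        for i in range(values.shape[0]):
            row = values[i]
            obs = ~np.isnan(row)
            if obs.sum() < X.shape[1]:
                continue
            coef, *_ = np.linalg.lstsq(X[obs], row[obs], rcond=None)
            comp = C[obs] @ coef[1:]
            corrected[i, obs] = row[obs] - (comp - comp.mean())
        return corrected
    coef, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    comp = C @ coef[1:]                      # samples x features
    comp = comp - comp.mean(axis=0, keepdims=True)
    return values - comp.T


def group_coverage_thresholds(
    group_sizes: Sequence[int], min_group_frac: float = 0.5
) -> list[int]:
    """Per-group minimum number of samples implied by an "at least half of the
    group" rule: ceil(frac * size) for each group."""
    return [math.ceil(min_group_frac * s) for s in group_sizes]


def build_segments(
    calls: Iterable[ReadCall],
    cpg_catalog: pd.DataFrame,
    b: int = 3,
    sliding: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Count read-level methylation patterns over windows of ``b`` consecutive
    catalog CpGs for ONE sample.

    ``cpg_catalog`` has columns chrom, pos (1-based CpG cytosine positions),
    sorted within chromosome.  A read contributes to a window only if it calls
    all ``b`` positions; a read with conflicting duplicate calls at a position
    is excluded from windows containing that position (counted in the returned
    warning).  With ``sliding`` the window start steps by 1 CpG, else windows
    tile disjointly.

    Returns ``(segments, counts)`` where segments has columns
    (segment_id, chrom, start_pos, cpg_positions) and counts is
    (n_segments, 2**b).
    """
    catalog = cpg_catalog.sort_values(["chrom", "pos"]).reset_index(drop=True)
    pos_index: dict[tuple[str, int], int] = {}
    chrom_positions: dict[str, np.ndarray] = {}
    for chrom, sub in catalog.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        if not np.all(np.diff(p) > 0):
            raise ValueError(f"catalog positions not strictly increasing on {chrom}")
        chrom_positions[chrom] = p
        for i, pos in enumerate(p):
            pos_index[(chrom, int(pos))] = i

    # per read: catalog-local calls {(chrom, idx): state}
    by_read: dict[tuple[str, str], dict[int, str]] = {}
    conflicted: dict[tuple[str, str], set[int]] = {}
    for call in calls:
        key = (call.chrom, call.read_id)
        idx = pos_index.get((call.chrom, call.pos))
        if idx is None:
            continue  # call at a CpG not in the catalog
        states = by_read.setdefault(key, {})
        if idx in states and states[idx] != call.state:
            conflicted.setdefault(key, set()).add(idx)
        else:
            states[idx] = call.state

    segments_rows = []
    counts_rows = []
    n_conflict_exclusions = 0
    for chrom in chrom_positions:
        positions = chrom_positions[chrom]
        n = len(positions)
        starts = range(0, n - b + 1, 1 if sliding else b)
        window_counts: dict[int, np.ndarray] = {
            s: np.zeros(2 ** b, dtype=np.int64) for s in starts
        }
        for (c, read_id), states in by_read.items():
            if c != chrom:
                continue
            bad = conflicted.get((c, read_id), set())
            idxs = sorted(states)
            for s in window_counts:
                window = range(s, s + b)
                if all(i in states for i in window):
                    if any(i in bad for i in window):
                        n_conflict_exclusions += 1
                        continue
                    pattern = 0
                    for i in window:
                        pattern = (pattern << 1) | (states[i] == "M")
                    window_counts[s][pattern] += 1
        for s in window_counts:
            cpgs = tuple(int(p) for p in positions[s:s + b])
            segments_rows.append(
                (f"{chrom}:{cpgs[0]}", chrom, cpgs[0], cpgs)
            )
            counts_rows.append(window_counts[s])
    if n_conflict_exclusions:
        warnings.warn(
            f"{n_conflict_exclusions} read-window contributions dropped due to "
            "conflicting duplicate calls",
            stacklevel=2,
        )
    segments = pd.DataFrame(
        segments_rows, columns=["segment_id", "chrom", "start_pos", "cpg_positions"]
    )
    counts = (np.vstack(counts_rows) if counts_rows
              else np.zeros((0, 2 ** b), dtype=np.int64))
    return segments, counts


def build_segment_table(
    call_files: Sequence,
    sample_ids: Sequence[str],
    cpg_catalog: pd.DataFrame,
    b: int = 3,
    sliding: bool = True,
) -> SegmentPatternTable:
    """Run :func:`build_segments` per sample call file and stack the counts."""
    if len(call_files) != len(sample_ids):
        raise ValueError("one sample id per call file")
    all_counts = []
    segments = None
    for path in call_files:
        seg, counts = build_segments(read_cpg_context(path), cpg_catalog, b=b,
                                     sliding=sliding)
        if segments is None:
            segments = seg
        all_counts.append(counts)
    assert segments is not None
    counts3 = np.stack(all_counts, axis=1)
    return SegmentPatternTable(segments, list(sample_ids), b, counts3)


def read_cpg_context(path) -> list[ReadCall]:
    """Parse a CpG-context call file (minimal 5-column dialect)."""
    calls: list[ReadCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("Bismark"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            read_id, _flag, chrom, pos, symbol = fields
            if symbol not in ("Z", "z"):
                continue  # non-CpG-context symbols ignored
            calls.append(ReadCall(read_id, chrom, int(pos),
                                  "M" if symbol == "Z" else "U"))
    return calls


def write_cpg_context(calls: Iterable[ReadCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            symbol = "Z" if c.state == "M" else "z"
            flag = "+" if c.state == "M" else "-"
            fh.write(f"{c.read_id}\t{flag}\t{c.chrom}\t{c.pos}\t{symbol}\n")


def segment_group_coverage_filter(
    table: SegmentPatternTable,
    meta: SampleMetadata,
    min_reads: int = 5,
    min_group_frac: float = 0.5,
) -> SegmentPatternTable:
    """Keep segments with >= ``min_reads`` reads in at least
    ceil(``min_group_frac`` * group size) samples of EVERY group."""
    groups = meta.groups.reindex(table.samples)
    if groups.isna().any():
        raise ValueError("every sample in the table needs a group assignment")
    N = table.N  # segments x samples
    keep = np.ones(len(table.segments), dtype=bool)
    for g, sub in groups.groupby(groups):
        size = len(sub)
        if size == 0:
            raise ValueError(f"group {g!r} is empty")
        threshold = math.ceil(min_group_frac * size)
        cols = [table.samples.index(s) for s in sub.index]
        keep &= (N[:, cols] >= min_reads).sum(axis=1) >= threshold
    return SegmentPatternTable(
        table.segments.loc[keep].reset_index(drop=True),
        list(table.samples),
        table.b,
        table.counts[keep],
    )
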