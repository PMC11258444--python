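import math

import numpy as np
import pandas as pd
import pytest

from entropyscape.methylome_io import (
    CytosineRecord,
    ParseError,
    ReadCall,
    SampleMetadata,
    SegmentPatternTable,
    SiteBetaMatrix,
    build_segment_table,
    build_segments,
    filter_sites_by_coverage,
    group_coverage_thresholds,
    read_cpg_context,
    read_cytosine_report,
    remove_batch_effect,
    segment_group_coverage_filter,
    site_methylation,
    write_cytosine_report,
)


# ---------------------------------------------------------------- parsing

class TestCytosineReport:
    def test_parses_fields(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text("chr1\t100\t+\t3\t1\tCpG\tCGG\n")
        (rec,) = read_cytosine_report(p)
        assert (rec.chrom, rec.pos, rec.strand) == ("chr1", 100, "+")
        assert (rec.n_meth, rec.n_unmeth) == (3, 1)
        assert rec.is_cpg

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text("")
        assert read_cytosine_report(p) == []

    @pytest.mark.parametrize("line", [
        "chr1\t100\t+\t3\t1",                      # 5 columns
        "chr1\t100\t+\t-3\t1\tCpG\tCGG",           # negative count
        "chr1\t0\t+\t3\t1\tCpG\tCGG",              # pos < 1
    ])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "r.txt"
        p.write_text("chr1\t1\t+\t0\t1\tCpG\tCGG\n" + line + "\n")
        with pytest.raises(ParseError, match=":2"):
            read_cytosine_report(p)

    def test_non_cpg_context_retained_and_flagged(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text("chr1\t5\t+\t1\t1\tCHH\tCAT\n")
        (rec,) = read_cytosine_report(p)
        assert not rec.is_cpg

    def test_round_trip(self, tmp_path):
        records = [CytosineRecord("chr2", 7, "-", 4, 9, "CpG", "CGA"),
                   CytosineRecord("chr2", 9, "+", 0, 2, "CHG", "CAG")]
        p = tmp_path / "w.txt"
        write_cytosine_report(records, p)
        assert read_cytosine_report(p) == records


@pytest.mark.parametrize("nm,nu,expected", [
    (3, 1, 0.75),
    (0, 5, 0.0),
    (7, 0, 1.0),
])
def test_site_methylation(nm, nu, expected):
    assert site_methylation(CytosineRecord("c", 1, "+", nm, nu)) == expected


def test_site_methylation_zero_coverage_is_nan_not_zero():
    assert math.isnan(site_methylation(CytosineRecord("c", 1, "+", 0, 0)))


# ---------------------------------------------------------------- filters

def _beta_matrix(coverage: np.ndarray) -> SiteBetaMatrix:
    n_sites, n_samples = coverage.shape
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.arange(1, n_sites + 1),
                          "strand": "+"})
    beta = np.where(coverage > 0, 0.5, np.nan)
    return SiteBetaMatrix(sites, [f"s{j}" for j in range(n_samples)],
                          beta, coverage)


class TestSiteFilter:
    def test_cohort_rule_133_samples(self):
        # with 133 samples and frac 0.6, a site needs >= 80 covered samples
        # (133 * 0.6 = 79.8, strict >)
        cov = np.zeros((3, 133), dtype=int)
        cov[0, :80] = 10
        cov[1, :79] = 10
        cov[2, :80] = 9   # deep enough in count but below min_cov
        kept = filter_sites_by_coverage(_beta_matrix(cov), 10, 0.6)
        assert list(kept.sites["pos"]) == [1]

    def test_strict_vs_inclusive_boundary(self):
        cov = np.full((1, 10), 10)
        cov[0, 4:] = 0     # exactly 40% covered
        m = _beta_matrix(cov)
        assert filter_sites_by_coverage(m, 10, 0.4).n_sites == 0
        assert filter_sites_by_coverage(m, 10, 0.4, strict=False).n_sites == 1

    def test_full_fraction_with_strict_keeps_nothing(self):
        cov = np.full((2, 5), 99)
        assert filter_sites_by_coverage(_beta_matrix(cov), 1, 1.0).n_sites == 0
        assert filter_sites_by_coverage(
            _beta_matrix(cov), 1, 1.0, strict=False).n_sites == 2

    def test_all_zero_coverage_empty(self):
        cov = np.zeros((4, 6), dtype=int)
        assert filter_sites_by_coverage(_beta_matrix(cov), 10, 0.6).n_sites == 0


class TestBatchCorrection:
    def test_single_batch_identity(self, rng):
        X = rng.random((5, 8))
        out = remove_batch_effect(X, ["a"] * 8)
        np.testing.assert_allclose(out, X)

    def test_balanced_shift_removed_mean_preserved(self, rng):
        X = rng.random((20, 10))
        shifted = X.copy()
        shifted[:, 5:] += 0.1
        batch = ["b1"] * 5 + ["b2"] * 5
        out = remove_batch_effect(shifted, batch)
        np.testing.assert_allclose(out.mean(axis=1), shifted.mean(axis=1),
                                   atol=1e-10)
        # the +0.1 offset is gone: group means agree per feature
        np.testing.assert_allclose(out[:, :5].mean(axis=1),
                                   out[:, 5:].mean(axis=1), atol=1e-10)

    def test_no_batch_effect_is_noop(self, rng):
        X = rng.random((3, 12))
        X[:, 1::2] = X[:, ::2]   # batch b mirrors batch a exactly
        out = remove_batch_effect(X, ["a", "b"] * 6)
        np.testing.assert_allclose(out, X, atol=1e-10)

    def test_idempotent_and_mean_preserving_unbalanced(self, rng):
        X = rng.random((15, 9))
        batch = ["a"] * 2 + ["b"] * 3 + ["c"] * 4
        once = remove_batch_effect(X, batch)
        twice = remove_batch_effect(once, batch)
        np.testing.assert_allclose(once, twice, atol=1e-8)
        np.testing.assert_allclose(once.mean(axis=1), X.mean(axis=1),
                                   atol=1e-10)


# ---------------------------------------------------------------- segments

def _catalog(*pos, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": list(pos)})


def _reads(read_specs):
    """read_specs: list of (read_id, {pos: state})."""
    return [ReadCall(rid, "chr1", pos, st)
            for rid, calls in read_specs for pos, st in calls.items()]


class TestBuildSegments:
    def test_uniform_unmethylated_reads(self):
        calls = _reads([(f"r{i}", {100: "U", 110: "U", 120: "U"})
                        for i in range(5)])
        seg, counts = build_segments(calls, _catalog(100, 110, 120))
        assert len(seg) == 1
        assert counts[0, SegmentPatternTable.pattern_to_index("UUU")] == 5
        assert counts.sum() == 5

    def test_partial_read_contributes_nothing(self):
        calls = _reads([("r1", {100: "M", 110: "M"})])
        _, counts = build_segments(calls, _catalog(100, 110, 120))
        assert counts.sum() == 0

    def test_mixed_patterns_counted(self):
        calls = _reads([("a", {100: "M", 110: "U", 120: "M"}),
                        ("b", {100: "M", 110: "U", 120: "M"}),
                        ("c", {100: "U", 110: "U", 120: "U"})])
        _, counts = build_segments(calls, _catalog(100, 110, 120))
        assert counts[0, SegmentPatternTable.pattern_to_index("MUM")] == 2
        assert counts[0, SegmentPatternTable.pattern_to_index("UUU")] == 1
        assert counts.sum() == 3

    def test_conflicting_duplicate_call_excludes_read(self):
        calls = _reads([("ok", {100: "U", 110: "U", 120: "U"})])
        calls += [ReadCall("dup", "chr1", 100, "M"),
                  ReadCall("dup", "chr1", 100, "U"),
                  ReadCall("dup", "chr1", 110, "M"),
                  ReadCall("dup", "chr1", 120, "M")]
        with pytest.warns(UserWarning, match="conflicting"):
            _, counts = build_segments(calls, _catalog(100, 110, 120))
        assert counts.sum() == 1

    def test_sliding_windows_step_one_cpg(self):
        calls = _reads([("r", {10: "M", 20: "M", 30: "M", 40: "M"})])
        seg, counts = build_segments(calls, _catalog(10, 20, 30, 40))
        assert list(seg["start_pos"]) == [10, 20]
        assert counts.sum() == 2  # the read covers both windows

    def test_disjoint_tiling_option(self):
        seg, _ = build_segments([], _catalog(10, 20, 30, 40, 50, 60),
                                sliding=False)
        assert list(seg["start_pos"]) == [10, 40]

    def test_segment_cpgs_are_consecutive_catalog_entries(self):
        seg, _ = build_segments([], _catalog(5, 9, 14, 20))
        for row in seg.itertuples():
            assert list(row.cpg_positions) == [5, 9, 14, 20][
                list([5, 9, 14, 20]).index(row.cpg_positions[0]):][:3]
            assert np.all(np.diff(row.cpg_positions) > 0)


class TestGroupCoverageFilter:
    def test_printed_thresholds_from_group_sizes(self):
        assert group_coverage_thresholds((79, 34, 20)) == [40, 17, 10]

    def _table(self, N, samples, b=3):
        n_seg = N.shape[0]
        counts = np.zeros((n_seg, len(samples), 2 ** b), dtype=np.int64)
        counts[:, :, 0] = N
        seg = pd.DataFrame({
            "segment_id": [f"s{i}" for i in range(n_seg)],
            "chrom": "chr1",
            "start_pos": np.arange(n_seg),
            "cpg_positions": [(i, i + 1, i + 2) for i in range(n_seg)],
        })
        return SegmentPatternTable(seg, samples, b, counts)

    def test_segment_needs_half_of_every_group(self, tiny_meta):
        # groups of 2 need ceil(0.5*2) = 1 covered sample each
        N = np.array([[5, 0, 5, 0, 5, 0],     # 1/1/1 -> kept
                      [5, 5, 0, 0, 5, 5]])    # 2/0/2 -> dropped (elder 0)
        table = self._table(N, tiny_meta.sample_ids)
        kept = segment_group_coverage_filter(table, tiny_meta)
        assert list(kept.segments["segment_id"]) == ["s0"]

    def test_min_reads_one_keeps_all_covered(self, tiny_meta):
        N = np.ones((3, 6), dtype=int)
        table = self._table(N, tiny_meta.sample_ids)
        kept = segment_group_coverage_filter(table, tiny_meta, min_reads=1)
        assert len(kept.segments) == 3

    def test_larger_groups_use_ceil(self):
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"x{i}" for i in range(12)],
            "group": ["LLI"] * 4 + ["elder"] * 4 + ["younger"] * 4,
            "age": [100.0] * 4 + [75.0] * 4 + [60.0] * 4,
            "batch": ["b1"] * 12,
        }))
        # 2/1/2 samples covered: needs 2/2/2 -> dropped
        N = np.zeros((1, 12), dtype=int)
        N[0, [0, 1, 4, 8, 9]] = 5
        table = self._table(N, meta.sample_ids)
        assert len(segment_group_coverage_filter(table, meta).segments) == 0


# ---------------------------------------------------------------- invariants

class TestPatternTableInvariants:
    def test_counts_sum_to_N_and_k_bounded(self, small_cohort):
        t = small_cohort.patterns
        assert np.array_equal(t.counts.sum(axis=2), t.N)
        k = (t.counts > 0).sum(axis=2)
        assert k.max() <= 2 ** t.b

    def test_tsv_round_trip_lossless(self, small_cohort, tmp_path):
        t = small_cohort.patterns
        t.write_tsv(tmp_path / "p.tsv")
        back = SegmentPatternTable.read_tsv(tmp_path / "p.tsv", t.segments,
                                            t.samples, t.b)
        assert np.array_equal(back.counts, t.counts)

    def test_pattern_string_encoding(self):
        assert SegmentPatternTable.pattern_to_index("MUM") == 0b101
        assert SegmentPatternTable.index_to_pattern(0b101, 3) == "MUM"
        for i in range(8):
            s = SegmentPatternTable.index_to_pattern(i, 3)
            assert SegmentPatternTable.pattern_to_index(s) == i


def test_read_files_reproduce_in_memory_counts(tmp_path):
    """Writing per-read call files and re-building the pattern table gives
    back the simulated counts (IO path == in-memory path)."""
    from entropyscape.synthetic import SimConfig, simulate_cohort

    cfg = SimConfig(n_per_group=(3, 2, 2), n_segments=6, seed=7)
    sim = simulate_cohort(cfg, out_dir=tmp_path)
    catalog = pd.DataFrame(
        [(seg.chrom, pos) for seg in sim.patterns.segments.itertuples()
         for pos in seg.cpg_positions], columns=["chrom", "pos"])
    rebuilt = build_segment_table(
        [tmp_path / "cpg_context" / f"{s}.txt" for s in sim.meta.sample_ids],
        sim.meta.sample_ids, catalog)
    mask = rebuilt.segments["segment_id"].isin(
        sim.patterns.segments["segment_id"]).to_numpy()
    assert np.array_equal(rebuilt.counts[mask], sim.patterns.counts)
    # and the cytosine reports carry the matching marginals
    calls = read_cpg_context(tmp_path / "cpg_context"
                             / f"{sim.meta.sample_ids[0]}.txt")
    assert all(c.state in "MU" for c in calls)
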