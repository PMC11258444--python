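import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from entropyscape.der import (
    LERSet,
    batch_tau_b,
    bh_fdr,
    classical_mds,
    classify_lli_lers,
    identify_ders,
    kendall_tau_b,
    partial_kendall,
)


def _pair_counting_tau_b(x, y):
    """O(n^2) oracle: explicit concordant/discordant pair counts with the
    tau-b tie correction."""
    n = len(x)
    S = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            S += np.sign(dx) * np.sign(dy)
            tx += dx == 0
            ty += dy == 0
    n0 = n * (n - 1) / 2
    return S / math.sqrt((n0 - tx) * (n0 - ty))


class TestKendall:
    def test_perfect_concordance(self):
        assert kendall_tau_b([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_one_discordant_pair(self):
        assert kendall_tau_b([1, 2, 3], [1, 3, 2]) == pytest.approx(1 / 3)

    def test_constant_variable_undefined(self):
        assert math.isnan(kendall_tau_b([1, 2, 3], [5, 5, 5]))

    @pytest.mark.parametrize("n", [10, 57, 200])
    def test_matches_pair_counting_oracle(self, rng, n):
        x = rng.integers(0, 12, n).astype(float)   # plenty of ties
        y = x * 0.3 + rng.normal(size=n)
        y[rng.integers(0, n, n // 10)] = y[0]
        assert kendall_tau_b(x, y) == pytest.approx(
            _pair_counting_tau_b(x, y), abs=1e-12)

    def test_batch_tau_matches_scalar(self, rng):
        Y = rng.integers(0, 8, size=(7, 40)).astype(float)
        Z = np.column_stack([rng.integers(0, 2, 40),
                             rng.normal(size=40)]).astype(float)
        out = batch_tau_b(Y, Z, chunk=3)
        for i in range(7):
            for j in range(2):
                assert out[i, j] == pytest.approx(
                    kendall_tau_b(Y[i], Z[:, j]), abs=1e-12)

    def test_batch_tau_nan_for_constant_row(self):
        Y = np.vstack([np.ones(10), np.arange(10.0)])
        Z = np.arange(10.0).reshape(-1, 1)
        out = batch_tau_b(Y, Z)
        assert math.isnan(out[0, 0]) and out[1, 0] == pytest.approx(1.0)


class TestPartialKendall:
    def test_reduces_to_tau_without_covariates(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        pcor, _ = partial_kendall(x, y)
        assert pcor == pytest.approx(kendall_tau_b(x, y), abs=1e-12)

    def test_single_covariate_recursive_formula(self, rng):
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.5 * x + 0.8 * z + rng.normal(size=40)
        pcor, p = partial_kendall(x, y, z[:, None])
        txy = kendall_tau_b(x, y)
        txz = kendall_tau_b(x, z)
        tyz = kendall_tau_b(y, z)
        expected = (txy - txz * tyz) / math.sqrt((1 - txz ** 2) * (1 - tyz ** 2))
        assert pcor == pytest.approx(expected, abs=1e-10)
        assert 0 <= p <= 1

    def test_covariate_explains_y(self, rng):
        z = rng.normal(size=60)
        x = rng.normal(size=60)
        pcor, _ = partial_kendall(x, z, z[:, None] + 0.0)
        # y == z: partialling z out of the (x, y) association leaves nothing
        assert abs(pcor) < 0.15

    def test_sample_size_guard(self, rng):
        with pytest.raises(ValueError, match="n > g"):
            partial_kendall([1, 2, 3], [3, 1, 2], np.ones((3, 1)))


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self, rng):
        p = rng.random(200) ** 2
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_permutation_invariance_and_monotone(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_nan_excluded_from_m(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert math.isnan(q[1])
        # m = 2, so q = [0.02, 0.04]
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestIdentifyDers:
    def test_recovers_planted_directions(self, small_cohort):
        from entropyscape.noise_metrics import methylation_entropy_matrix

        sim = small_cohort
        me = methylation_entropy_matrix(sim.patterns.counts, 3)
        frac = sim.truth.fractions  # true fractions as covariates
        aging = identify_ders(me, sim.meta, frac, "elder_vs_younger",
                              q_threshold=0.05,
                              segment_ids=sim.patterns.segments["segment_id"])
        sig = aging[aging["significant"]]
        assert len(sig) > 0
        assert (sig["direction"] == "higher").mean() > 0.95

    def test_label_permutation_kills_detections(self, small_cohort, rng):
        from entropyscape.noise_metrics import methylation_entropy_matrix
        from entropyscape.methylome_io import SampleMetadata

        sim = small_cohort
        me = methylation_entropy_matrix(sim.patterns.counts, 3)
        table = sim.meta.table.copy()
        table["group"] = rng.permutation(table["group"].to_numpy())
        permuted = SampleMetadata(table)
        res = identify_ders(me, permuted, sim.truth.fractions,
                            "elder_vs_younger", 0.05)
        assert res["significant"].mean() <= 0.02

    def test_direction_sign_consistency(self, small_cohort):
        from entropyscape.noise_metrics import methylation_entropy_matrix

        sim = small_cohort
        me = methylation_entropy_matrix(sim.patterns.counts, 3)
        res = identify_ders(me, sim.meta, sim.truth.fractions, "lli_vs_elder",
                            0.05)
        ok = res.dropna(subset=["pcor"])
        assert ((ok["pcor"] > 0) == (ok["direction"] == "higher")).all()

    def test_unknown_contrast(self, small_cohort):
        with pytest.raises(ValueError, match="contrast"):
            identify_ders(np.ones((2, 30)), small_cohort.meta,
                          small_cohort.truth.fractions, "old_vs_new")

    def test_segments_with_missing_data_are_skipped(self, rng):
        from entropyscape.methylome_io import SampleMetadata

        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(18)],
            "group": ["LLI"] * 6 + ["elder"] * 6 + ["younger"] * 6,
            "age": [100.0] * 6 + [75.0] * 6 + [60.0] * 6,
            "batch": ["b1"] * 18,
        }))
        frac = pd.DataFrame(
            rng.dirichlet(np.full(6, 10.0), size=18),
            columns=["B", "CD4T", "CD8T", "Mono", "Neutro", "NK"])
        me = rng.random((3, 18))
        me[1, 6:10] = np.nan    # elder group down to 2 complete samples
        res = identify_ders(me, meta, frac, "elder_vs_younger", 0.05)
        assert math.isnan(res.loc[1, "p"])          # skipped, not an error
        assert res.loc[[0, 2], "p"].notna().all()   # others still tested


class TestClassifyLers:
    def _records(self, ids, sig, direction, contrast):
        return pd.DataFrame({
            "segment_id": ids, "contrast": contrast,
            "pcor": [0.5 if d == "higher" else -0.5 for d in direction],
            "p": [0.001 if s else 0.5 for s in sig],
            "q": [0.01 if s else 0.9 for s in sig],
            "direction": direction, "significant": sig,
        })

    def test_set_inclusions_and_counts(self):
        ids = list("abcdef")
        aging = self._records(ids,
                              [True, True, True, True, False, False],
                              ["higher", "higher", "higher", "lower",
                               "higher", "lower"], "elder_vs_younger")
        lli = self._records(ids,
                            [True, True, False, True, True, False],
                            ["lower", "higher", "lower", "lower", "lower",
                             "higher"], "lli_vs_elder")
        lers = classify_lli_lers(aging, lli, 0.05)
        assert lers.n_aging_der == 4
        assert lers.n_high_der == 3
        assert set(lers.segment_ids) == {"a"}
        assert lers.n_ler <= lers.n_high_der <= lers.n_aging_der

    def test_no_lli_signal_gives_empty_set(self):
        ids = list("abc")
        aging = self._records(ids, [True] * 3, ["higher"] * 3,
                              "elder_vs_younger")
        lli = self._records(ids, [False] * 3, ["lower"] * 3, "lli_vs_elder")
        assert classify_lli_lers(aging, lli, 0.05).n_ler == 0

    def test_disjoint_universes_error(self):
        a = self._records(["a"], [True], ["higher"], "elder_vs_younger")
        b = self._records(["b"], [True], ["lower"], "lli_vs_elder")
        with pytest.raises(ValueError, match="universe"):
            classify_lli_lers(a, b, 0.05)

    def test_percentages_of_parent_counts(self):
        s = LERSet(np.array([]), n_aging_der=172419, n_high_der=121113,
                   n_ler=38923)
        assert s.pct_high_of_der == pytest.approx(70.2, abs=0.05)
        assert s.pct_ler_of_high == pytest.approx(32.1, abs=0.05)


class TestClassicalMDS:
    def test_recovers_line_geometry(self, rng):
        # samples at 1-D positions (0, 3, 4) embedded in 6 dimensions
        direction = rng.normal(size=6)
        direction /= np.linalg.norm(direction)
        X = np.outer([0.0, 3.0, 4.0], direction) + rng.normal(size=6) * 0.0
        coords = classical_mds(X, k=2, top_variable=None)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(
            [d[0, 1], d[0, 2], d[1, 2]], [3.0, 4.0, 1.0], atol=1e-8)

    def test_duplicate_samples_coincide(self, rng):
        X = rng.random((5, 8))
        X[3] = X[1]
        coords = classical_mds(X, k=3, top_variable=None)
        np.testing.assert_allclose(coords[3], coords[1], atol=1e-8)

    def test_full_rank_reproduces_distances(self, rng):
        X = rng.random((6, 10))
        coords = classical_mds(X, k=5, top_variable=None)
        d_in = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_out = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d_out, d_in, atol=1e-8)

    def test_top_variable_selection_and_warning(self, rng):
        X = rng.random((5, 7))
        with pytest.warns(UserWarning, match="features"):
            classical_mds(X, k=2, top_variable=100)
        # adding dead features does not change the embedding
        X2 = np.hstack([X, np.zeros((5, 50))])
        c1 = classical_mds(X, k=2, top_variable=7)
        c2 = classical_mds(X2, k=2, top_variable=7)
        np.testing.assert_allclose(np.abs(c1), np.abs(c2), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        X = rng.random((8, 12))
        c1 = classical_mds(X, k=3, top_variable=None)
        c2 = classical_mds(X.copy(), k=3, top_variable=None)
        np.testing.assert_allclose(c1, c2)
        for j in range(3):
            assert c1[np.argmax(np.abs(c1[:, j])), j] >= 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            classical_mds(np.ones((3, 4)), k=3)
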