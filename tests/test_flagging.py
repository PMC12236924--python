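import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkqc.flagging import (FlagConfig, cluster_flag_matrix, estimate_metric_cutoffs,
                             flag_dataset, flag_gbc, flag_value, ks_curve_statistic)


class TestBootstrapCutoffs:
    def test_matches_analytic_normal_quantiles(self):
        rng = np.random.default_rng(42)
        ref = rng.normal(100, 10, 1000)
        cfg = FlagConfig(seed=1)
        warn, fail = estimate_metric_cutoffs(ref, "low_is_bad", cfg)
        # Monte-Carlo tolerance: reference-sampling + bootstrap-center noise
        assert warn == pytest.approx(100 + stats.norm.ppf(0.10) * 10, abs=1.5)
        assert fail == pytest.approx(100 + stats.norm.ppf(0.05) * 10, abs=1.5)
        assert fail < warn
        whi, fhi = estimate_metric_cutoffs(ref, "high_is_bad", cfg)
        assert whi == pytest.approx(100 + stats.norm.ppf(0.90) * 10, abs=1.5)
        assert fhi > whi

    def test_constant_reference_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            warn, fail = estimate_metric_cutoffs([5, 5, 5, 5, 5], "low_is_bad",
                                                 FlagConfig(seed=0))
        assert warn == fail == 5.0

    def test_deterministic_given_seed(self):
        ref = np.random.default_rng(3).lognormal(3, 1, 50)
        a = estimate_metric_cutoffs(ref, "low_is_bad", FlagConfig(seed=9))
        b = estimate_metric_cutoffs(ref, "low_is_bad", FlagConfig(seed=9))
        assert a == b

    def test_too_few_reference_values(self):
        with pytest.raises(ValueError, match="5"):
            estimate_metric_cutoffs([1, 2, 3], "low_is_bad", FlagConfig())

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FlagConfig(warn_quantile=0.05, fail_quantile=0.1)
        with pytest.raises(ValueError):
            FlagConfig(n_bootstrap=10)


class TestFlagValue:
    def test_boundary_is_pass(self):
        assert flag_value(10.0, (10.0, 5.0), "low_is_bad") == "pass"
        assert flag_value(5.0, (10.0, 5.0), "low_is_bad") == "warn"

    def test_below_fail_cutoff_fails(self):
        assert flag_value(4.9, (10.0, 5.0), "low_is_bad") == "fail"

    def test_absent_value_gives_no_flag(self):
        assert flag_value(np.nan, (10.0, 5.0), "low_is_bad") is None

    def test_matches_brute_force_classifier(self, rng):
        vals = rng.uniform(-3, 3, 10_000)
        for direction, (w, f) in [("low_is_bad", (-1.0, -2.0)),
                                  ("high_is_bad", (1.0, 2.0))]:
            got = [flag_value(v, (w, f), direction) for v in vals]
            for v, g in zip(vals, got):
                worse = (v < f) if direction == "low_is_bad" else (v > f)
                warned = (v < w) if direction == "low_is_bad" else (v > w)
                expect = "fail" if worse else ("warn" if warned else "pass")
                assert g == expect

    def test_monotone_and_fail_implies_warn(self, rng):
        """Worsening a value never moves its flag toward pass."""
        order = {"pass": 0, "warn": 1, "fail": 2}
        w, f = -1.0, -2.0
        vals = np.sort(rng.uniform(-4, 2, 500))[::-1]  # decreasing = worsening
        flags = [order[flag_value(v, (w, f), "low_is_bad")] for v in vals]
        assert all(b >= a for a, b in zip(flags, flags[1:]))
        # every fail satisfies the warn condition too
        for v in vals:
            if flag_value(v, (w, f), "low_is_bad") == "fail":
                assert v < w


class TestKSFlag:
    def _flat(self):
        return np.linspace(0.5, 1.0, 100)

    def test_identical_to_median_passes_with_zero_statistic(self):
        ref = np.tile(self._flat(), (5, 1))
        res = flag_gbc("s", self._flat(), ref, FlagConfig())
        assert res.ks_statistic == 0.0 and res.flag == "pass"

    def test_three_prime_mass_fails_with_near_maximal_gap(self):
        ref = np.tile(np.ones(100), (5, 1))
        sample = np.zeros(100)
        sample[90:] = 1.0
        res = flag_gbc("s", sample, ref, FlagConfig())
        # brute-force CDF gap: flat CDF at bin 89 = 0.90, sample CDF = 0
        flat_cdf = np.cumsum(np.ones(100) / 100)
        samp_cdf = np.cumsum(sample / sample.sum())
        expected = np.abs(flat_cdf - samp_cdf).max()
        assert res.ks_statistic == pytest.approx(expected)
        assert expected == pytest.approx(0.90)
        assert res.flag == "fail"

    def test_statistic_symmetric_in_roles(self, rng):
        a = rng.uniform(0.1, 1, 100)
        b = rng.uniform(0.1, 1, 100)
        assert ks_curve_statistic(a, b) == pytest.approx(ks_curve_statistic(b, a))

    def test_degenerate_curve_unscoreable(self):
        ref = np.tile(self._flat(), (5, 1))
        res = flag_gbc("s", np.zeros(100), ref, FlagConfig())
        assert res.flag == "unscoreable"


class TestFlagDataset:
    def test_identical_samples_all_pass(self):
        qc = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(8)],
            "batch_id": "all",
            "n_sequenced_reads": 1_000_000,
            "n_post_trim_reads": 990_000,
            "n_uniquely_aligned_reads": 800_000,
            "n_rrna_reads": 20_000,
            "n_mapped_to_exons": 600_000,
        })
        with pytest.warns(UserWarning, match="zero-variance"):
            flags, _ = flag_dataset(qc, config=FlagConfig(seed=0))
        assert (flags.fillna(0.0) == 0.0).all().all()

    def test_custom_cutoffs_pass_through_verbatim(self, cohort):
        custom = pd.DataFrame(
            {"direction": ["low_is_bad"], "warn_cutoff": [1e6], "fail_cutoff": [5e5]},
            index=pd.Index(["n_sequenced_reads"], name="metric"))
        flags, cuts = flag_dataset(cohort.qc, config=FlagConfig(seed=0),
                                   custom_cutoffs=custom)
        assert cuts.loc["n_sequenced_reads", "warn_cutoff"] == 1e6
        assert cuts.loc["n_sequenced_reads", "fail_cutoff"] == 5e5

    def test_rerun_with_same_seed_reproduces_flags(self, cohort):
        cfg = FlagConfig(seed=11)
        f1, c1 = flag_dataset(cohort.qc, counts=cohort.counts, gbc=cohort.gbc, config=cfg)
        f2, c2 = flag_dataset(cohort.qc, counts=cohort.counts, gbc=cohort.gbc, config=cfg)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_defect_samples_receive_fail_flags(self, cohort):
        flags, _ = flag_dataset(cohort.qc, counts=cohort.counts, gbc=cohort.gbc,
                                config=FlagConfig(seed=0))
        fail_any = (flags == 1.0).any(axis=1)
        defect = cohort.truth["is_defect"]
        assert fail_any[defect].mean() >= 0.9
        # fail count never exceeds warn-or-fail count, per metric
        n_fail = (flags == 1.0).sum()
        n_warn_or_fail = ((flags == 1.0) | (flags == 0.5)).sum()
        assert (n_fail <= n_warn_or_fail).all()

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            flag_dataset(pd.DataFrame(columns=["sample_id", "batch_id"]))


class TestClusterFlagMatrix:
    def test_identical_vectors_merge_at_zero(self):
        flags = pd.DataFrame([[0.0, 1.0], [0.0, 1.0]], index=["a", "b"])
        order, link = cluster_flag_matrix(flags)
        assert set(order) == {"a", "b"} and link[0, 2] == 0.0

    def test_opposite_unit_vectors_merge_at_sqrt2(self):
        flags = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["a", "b"])
        _, link = cluster_flag_matrix(flags)
        assert link[0, 2] == pytest.approx(np.sqrt(2))

    def test_single_sample_identity_ordering(self):
        flags = pd.DataFrame([[1.0]], index=["only"])
        order, link = cluster_flag_matrix(flags)
        assert order == ["only"] and link is None

    def test_linkage_heights_match_brute_force(self, random_flag_table):
        """Complete-linkage merge heights agree with an O(n^3) recomputation."""
        flags = random_flag_table.iloc[:10]
        _, link = cluster_flag_matrix(flags)
        # brute-force complete linkage
        pts = [flags.iloc[[i]].to_numpy() for i in range(len(flags))]
        clusters = {i: [i] for i in range(len(flags))}
        mat = flags.to_numpy()
        heights = []
        active = list(clusters)
        while len(active) > 1:
            best = None
            for ai in range(len(active)):
                for bi in range(ai + 1, len(active)):
                    a, b = active[ai], active[bi]
                    d = max(np.linalg.norm(mat[i] - mat[j])
                            for i in clusters[a] for j in clusters[b])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            d, a, b = best
            heights.append(d)
            new = max(clusters) + 1
            clusters[new] = clusters.pop(a) + clusters.pop(b)
            active = [c for c in active if c not in (a, b)] + [new]
        np.testing.assert_allclose(sorted(link[:, 2]), sorted(heights), atol=1e-12)
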