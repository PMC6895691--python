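import numpy as np
import pandas as pd
import pytest

from absasfit.filtering import (
    classify_clusters, classify_table, determine_cutoff, filter_disulphide,
    filter_report, filter_rfactor, joint_filter, make_table,
)
from absasfit.structures import DistanceSummary


def example_table(n=20, seed=0):
    rng = np.random.default_rng(seed)
    dists = [DistanceSummary(d1=float(rng.uniform(4, 12)),
                             d2=float(rng.uniform(5, 10)),
                             d3=float(rng.uniform(5, 10)))
             for _ in range(n)]
    return make_table(
        [f"m{i}" for i in range(n)],
        {"xray": rng.uniform(1, 8, n), "neutron": rng.uniform(1, 8, n)},
        distances=dists,
        ss_distances=rng.uniform(0.3, 1.2, size=(n, 2)))


class TestDetermineCutoff:
    def test_identical_duplicates_no_cutoff(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(1, 10, 200)
        res = determine_cutoff(r, r.copy())
        assert res.cutoff is None
        assert len(res.trace) > 0

    def test_independent_noise_cutoff_at_top(self):
        rng = np.random.default_rng(2)
        ra = rng.uniform(1, 10, 400)
        rb = rng.uniform(1, 10, 400)
        res = determine_cutoff(ra, rb)
        pooled = np.concatenate([ra, rb])
        # decorrelated from the start: the largest scanned candidate wins
        assert res.cutoff == pytest.approx(np.percentile(pooled, 99), rel=1e-9)

    def test_shared_signal_recovers_noise_floor(self):
        # r = s + eps with a dense tail of good fits; the crossing should
        # bracket the scale where the shared signal drops below the noise
        rng = np.random.default_rng(3)
        s = 2.0 + rng.exponential(2.0, 800)
        ra = s + rng.normal(0, 0.35, 800)
        rb = s + rng.normal(0, 0.35, 800)
        res = determine_cutoff(ra, rb)
        assert res.cutoff is not None

        # brute-force oracle at 10x grid resolution
        combined = np.maximum(ra, rb)
        pooled = np.concatenate([ra, rb])
        lo, hi = np.percentile(pooled, [1, 99])
        from scipy.stats import pearsonr, spearmanr
        crossing = None
        for c in np.linspace(hi, lo, 2000):
            keep = combined <= c
            if keep.sum() < 5:
                break
            pr = pearsonr(ra[keep], rb[keep])[0]
            sr = spearmanr(ra[keep], rb[keep])[0]
            if pr < 0.5 and sr < 0.5:
                crossing = c
                break
        assert crossing is not None
        decile = np.ptp(pooled) / 10
        assert abs(res.cutoff - crossing) <= decile

    def test_population_precondition(self):
        with pytest.raises(ValueError, match="min_n"):
            determine_cutoff(np.ones(10), np.ones(10), min_n=50)


class TestFilters:
    def test_rfactor_extremes(self):
        t = example_table()
        assert len(filter_rfactor(t, "xray", t["R_xray"].min() - 1)) == 0
        assert len(filter_rfactor(t, "xray", t["R_xray"].max() + 1)) == len(t)

    def test_rfactor_matches_comprehension(self):
        t = example_table(seed=5)
        out = filter_rfactor(t, "neutron", 4.0)
        expected = {m for m, r in zip(t.model_id, t.R_neutron) if r <= 4.0}
        assert set(out.model_id) == expected

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            filter_rfactor(example_table(), "muon", 3.0)

    @pytest.mark.parametrize("d,kept", [(0.74, True), (0.76, False)])
    def test_disulphide_boundary(self, d, kept):
        t = make_table(["m0"], {"xray": [1.0]},
                       ss_distances=np.array([[d, 0.5]]))
        assert (len(filter_disulphide(t)) == 1) is kept

    def test_disulphide_nesting(self):
        t = example_table(seed=7)
        wide = set(filter_disulphide(t, 1.0).model_id)
        narrow = set(filter_disulphide(t, 0.6).model_id)
        assert narrow <= wide

    def test_joint_filter_order_independent(self):
        t = example_table(seed=9)
        joint = joint_filter(t, "xray", 5.0, "neutron", 5.0, 0.75)
        alt = filter_rfactor(
            filter_disulphide(filter_rfactor(t, "neutron", 5.0), 0.75),
            "xray", 5.0)
        assert set(joint.model_id) == set(alt.model_id)
        brute = {m for i, m in enumerate(t.model_id)
                 if t.R_xray[i] <= 5.0 and t.R_neutron[i] <= 5.0
                 and t.ss_dist_1[i] <= 0.75 and t.ss_dist_2[i] <= 0.75}
        assert set(joint.model_id) == brute

    def test_empty_component_empty_joint(self):
        t = example_table()
        assert len(joint_filter(t, "xray", 0.0, "neutron", 10.0, 2.0)) == 0


class TestClassify:
    @pytest.mark.parametrize("d1,d2,d3,expected", [
        (6.0, 8.0, 8.5, "alpha"),          # compact, symmetric
        (9.5, 8.4, 5.9, "beta1"),          # extended, asymmetric
        (9.5, 8.0, 7.5, "beta2"),          # extended, symmetric
        (7.0, 8.0, 7.5, "beta2"),          # boundary goes to beta
    ])
    def test_assignments(self, d1, d2, d3, expected):
        lab = classify_clusters(DistanceSummary(d1=d1, d2=d2, d3=d3))
        assert lab.cluster == expected

    def test_table_classification_matches_scalar(self):
        t = example_table(seed=11)
        out = classify_table(t)
        for _, row in out.iterrows():
            lab = classify_clusters(DistanceSummary(
                d1=row.d1, d2=row.d2, d3=row.d3))
            assert row.cluster == lab.cluster


class TestReport:
    def test_single_row_stats(self):
        t = make_table(["a"], {"xray": [2.5]},
                       distances=[DistanceSummary(9.0, 8.0, 6.0)],
                       ss_distances=np.array([[0.5, 0.6]]))
        rep = filter_report([t])
        assert rep.loc[0, "n_models"] == 1
        assert rep.loc[0, "R_xray_mean"] == 2.5
        assert rep.loc[0, "R_xray_sd"] == 0.0
        assert rep.loc[0, "max_d23_mean"] == 8.0

    def test_three_row_manual_means(self):
        t = make_table(["a", "b", "c"], {"xray": [2.0, 3.0, 4.0]},
                       distances=[DistanceSummary(6, 8, 9),
                                  DistanceSummary(9, 8, 6),
                                  DistanceSummary(12, 10, 8)])
        rep = filter_report([t])
        assert rep.loc[0, "R_xray_mean"] == pytest.approx(3.0)
        assert rep.loc[0, "d1_mean"] == pytest.approx((6 + 9 + 12) / 3)
        assert rep.loc[0, "max_d23_mean"] == pytest.approx((9 + 8 + 10) / 3)
        assert rep.loc[0, "min_d23_mean"] == pytest.approx((8 + 6 + 8) / 3)

    def test_counts_non_increasing_along_cascade(self):
        t = example_table(n=50, seed=13)
        s1 = filter_rfactor(t, "xray", 5.0)
        s2 = filter_disulphide(s1, 0.9)
        rep = filter_report([t, s1, s2])
        counts = rep["n_models"].to_list()
        assert counts == sorted(counts, reverse=True)

    def test_empty_stage_list(self):
        with pytest.raises(ValueError):
            filter_report([])
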