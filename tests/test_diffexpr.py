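import numpy as np
import pytest

from cncpipe.datasets import example_validation
from cncpipe.diffexpr import (
    DERecord,
    QpcrOutcome,
    call_de,
    cluster_order,
    concordance_rate,
    de_table,
    fold_change_linear,
    select_validation_candidates,
    t_test_two_sample,
)
from cncpipe.io_formats import GroupDesign
from .conftest import make_bundle

AGES_CASE = (84.0, 83.0, 93.0, 93.0)
AGES_CTRL = (81.0, 81.0, 87.0, 86.0)
DUR_CASE = (140.0, 155.0, 190.0, 80.0)
DUR_CTRL = (100.0, 170.0, 70.0, 120.0)


class TestTTest:
    def test_reference_age_p(self):
        _, p, df = t_test_two_sample(AGES_CASE, AGES_CTRL, equal_variance=True)
        assert round(p, 3) == 0.207
        assert df == 6

    def test_reference_duration_p(self):
        _, p, _ = t_test_two_sample(DUR_CASE, DUR_CTRL, equal_variance=True)
        assert round(p, 3) == 0.431

    def test_identical_groups(self):
        t, p, _ = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_zero_variance_equal_means(self):
        t, p, _ = t_test_two_sample([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_flagged(self):
        with pytest.warns(RuntimeWarning):
            t, p, _ = t_test_two_sample([5.0, 5.0], [3.0, 3.0])
        assert p == 0.0
        assert t == np.inf

    def test_group_swap_flips_sign_only(self):
        t1, p1, _ = t_test_two_sample(AGES_CASE, AGES_CTRL)
        t2, p2, _ = t_test_two_sample(AGES_CTRL, AGES_CASE)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_affine_rescale_invariance(self):
        t1, p1, _ = t_test_two_sample(AGES_CASE, AGES_CTRL)
        xs = [3.0 * v + 7.0 for v in AGES_CASE]
        ys = [3.0 * v + 7.0 for v in AGES_CTRL]
        t2, p2, _ = t_test_two_sample(xs, ys)
        assert t1 == pytest.approx(t2)
        assert p1 == pytest.approx(p2)

    def test_welch_differs_from_pooled(self):
        xs, ys = (1.0, 2.0, 3.0, 4.0), (10.0, 30.0, 50.0, 90.0)
        _, _, df_pooled = t_test_two_sample(xs, ys, equal_variance=True)
        _, _, df_welch = t_test_two_sample(xs, ys, equal_variance=False)
        assert df_welch < df_pooled

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([1.0], [2.0, 3.0])


class TestFoldChange:
    def test_up(self):
        assert fold_change_linear(20, 10) == (2.0, "up")

    def test_down(self):
        assert fold_change_linear(10, 20) == (2.0, "down")

    def test_tie_is_down(self):
        fc, direction = fold_change_linear(10, 10)
        assert fc == 1.0
        assert direction == "down"

    def test_symmetry(self):
        fc1, d1 = fold_change_linear(7.0, 3.0)
        fc2, d2 = fold_change_linear(3.0, 7.0)
        assert fc1 == pytest.approx(fc2)
        assert {d1, d2} == {"up", "down"}

    def test_non_positive_mean(self):
        with pytest.raises(ValueError):
            fold_change_linear(0.0, 1.0)


class TestCallDe:
    def _bundle(self, rng, n_feat=50, shift_first=None):
        log2 = rng.normal(8.0, 0.05, size=(n_feat, 8))
        if shift_first is not None:
            log2[0, :4] += shift_first
        cols = [f"case_{i}" for i in range(1, 5)] + [f"ctrl_{i}" for i in range(1, 5)]
        return make_bundle(np.power(2.0, log2), sample_ids=cols)

    def test_planted_four_fold_called(self, four_v_four_design):
        rng = np.random.default_rng(1)
        b = self._bundle(rng, shift_first=np.log2(4.0))
        recs = call_de(b, four_v_four_design)
        assert recs[0].is_de
        assert recs[0].direction == "up"
        assert recs[0].fold_change > 3.0

    def test_identical_groups_not_de(self, four_v_four_design):
        vals = np.tile([[4.0]], (1, 8))
        cols = [f"case_{i}" for i in range(1, 5)] + [f"ctrl_{i}" for i in range(1, 5)]
        recs = call_de(make_bundle(vals, sample_ids=cols), four_v_four_design)
        assert not recs[0].is_de
        assert recs[0].p_value == 1.0

    def test_null_matrix_size_control(self, four_v_four_design):
        # Monte-Carlo size check on 2000 null features at a fixed seed
        rng = np.random.default_rng(99)
        b = self._bundle(rng, n_feat=2000)
        recs = call_de(b, four_v_four_design)
        frac_p = np.mean([r.p_value < 0.05 for r in recs])
        from scipy.stats import binom

        lo = binom.ppf(0.005, 2000, 0.05) / 2000
        hi = binom.ppf(0.995, 2000, 0.05) / 2000
        assert lo <= frac_p <= hi
        frac_de = np.mean([r.is_de for r in recs])
        assert frac_de <= frac_p  # the FC gate only removes calls

    def test_small_group_error(self, four_v_four_design):
        b = self._bundle(np.random.default_rng(0))
        from cncpipe.io_formats import SchemaError

        with pytest.raises(SchemaError):
            GroupDesign({"case_1": "case", "ctrl_1": "control", "ctrl_2": "control"})

    def test_de_table_bh_column(self, four_v_four_design):
        b = self._bundle(np.random.default_rng(3))
        df = de_table(call_de(b, four_v_four_design))
        assert "q_bh" in df.columns
        assert (df["q_bh"] >= df["p"] - 1e-12).all()


def _record(fid, fc, p, intensity, direction="up", biotype="lncRNA"):
    mc, mctl = (intensity, intensity / fc) if direction == "up" else (intensity / fc, intensity)
    return DERecord(fid, biotype, mc, mctl, fc, direction, 2.0, p, intensity, True)


class TestValidationCandidates:
    def test_top_ten_of_thirty(self):
        recs = [_record(f"f{i:02d}", 2.5 + i * 0.1, 0.01, 1000) for i in range(30)]
        out = select_validation_candidates(recs)
        chosen = out["lncRNA:up"]
        assert len(chosen) == 10
        assert chosen[0].feature_id == "f29"  # max fold change first
        assert all(r.fold_change >= 2.5 + 2.0 for r in chosen)

    def test_intensity_gate(self):
        recs = [_record("hi", 3.0, 0.01, 1000), _record("lo", 3.0, 0.01, 400)]
        with pytest.warns(RuntimeWarning):
            out = select_validation_candidates(recs)
        assert [r.feature_id for r in out["lncRNA:up"]] == ["hi"]

    def test_strict_fc_gate(self):
        recs = [_record("edge", 2.0, 0.01, 1000)]  # FC exactly 2 is excluded
        out = select_validation_candidates(recs)
        assert out == {}

    def test_tie_break_lexicographic(self):
        recs = [_record("b", 3.0, 0.01, 1000), _record("a", 3.0, 0.01, 1000)]
        with pytest.warns(RuntimeWarning):
            out = select_validation_candidates(recs)
        assert [r.feature_id for r in out["lncRNA:up"]] == ["a", "b"]

    def test_fewer_than_n_each_warns(self):
        recs = [_record("only", 3.0, 0.01, 1000)]
        with pytest.warns(RuntimeWarning, match="only 1"):
            out = select_validation_candidates(recs)
        assert len(out["lncRNA:up"]) == 1


class TestConcordance:
    def test_reference_seventy_percent(self):
        candidates, outcomes = example_validation("lncRNA")
        assert concordance_rate(candidates, outcomes) == 70.0

    def test_all_confirmed(self):
        candidates, _ = example_validation("lncRNA")
        outcomes = [QpcrOutcome(r.feature_id, r.direction) for r in candidates]
        assert concordance_rate(candidates, outcomes) == 100.0

    def test_none_confirmed(self):
        candidates, _ = example_validation("lncRNA")
        outcomes = [QpcrOutcome(r.feature_id, "unchanged") for r in candidates]
        assert concordance_rate(candidates, outcomes) == 0.0

    def test_missing_outcome_names_feature(self):
        candidates, outcomes = example_validation("lncRNA")
        with pytest.raises(ValueError, match=candidates[0].feature_id):
            concordance_rate(candidates, outcomes[1:])


class TestClusterOrder:
    def test_identical_features_adjacent(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        vals = np.vstack([base, rng.normal(size=8), base + 0.0, rng.normal(size=8)])
        b = make_bundle(vals, scale="log2")
        order = cluster_order(b, b.feature_ids)
        i1, i3 = order.index("f1"), order.index("f3")
        assert abs(i1 - i3) == 1

    def test_anticorrelated_pair_split_by_uncorrelated(self):
        # d(f1,f2) = 2 (perfect anticorrelation); f3 closer to one of them
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        f3 = np.array([2.0, 1.0, 4.0, 3.0, 5.0])  # positively but imperfectly correlated
        b = make_bundle(np.vstack([x, -x, f3]), scale="log2")
        order = cluster_order(b, b.feature_ids)
        # f1 and f3 merge first (distance < 1), f2 at distance 2 joins last
        assert abs(order.index("f1") - order.index("f3")) == 1
        assert order[0] == "f2" or order[-1] == "f2"

    def test_average_linkage_heights_match_brute_force(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(4, 10))
        corr = np.corrcoef(vals)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        # brute-force agglomeration with unweighted-average cluster distance
        clusters = [[i] for i in range(4)]
        heights = []
        while len(clusters) > 1:
            best = None
            for a in range(len(clusters)):
                for b_ in range(a + 1, len(clusters)):
                    d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b_]])
                    if best is None or d < best[0]:
                        best = (d, a, b_)
            d, a, b_ = best
            heights.append(d)
            clusters = [c for k, c in enumerate(clusters) if k not in (a, b_)] + [
                clusters[a] + clusters[b_]
            ]
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        link = average(squareform(dist, checks=False))
        assert np.allclose(sorted(link[:, 2]), sorted(heights), atol=1e-12)

    def test_constant_feature_flagged(self):
        vals = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0)[::-1]])
        b = make_bundle(vals)
        with pytest.warns(RuntimeWarning, match="constant"):
            order = cluster_order(b, b.feature_ids)
        assert set(order) == {"f1", "f2", "f3"}

    def test_two_features_minimum(self, small_bundle):
        with pytest.raises(ValueError):
            cluster_order(small_bundle, ["f1"])
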