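import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylocontrasts as pc
from phylocontrasts.ie import (
    TriangleSides,
    UndefinedValueError,
    adaptive_peak,
    ancestral_state,
    farris_T,
    ie_distance,
    ie_reconstruct,
    log_distance,
    r_values,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestIEDistance:
    @pytest.mark.parametrize(
        "x,y,expected", [(5, 5, 0.0), (1, 3, 1.0), (3, 1, 1.0), (2, 8, 1.2)]
    )
    def test_values(self, x, y, expected):
        assert ie_distance(x, y) == pytest.approx(expected)

    def test_asymptote(self):
        assert 2 - 1e-6 < ie_distance(1, 1e9) < 2

    def test_undefined_at_zero_sum(self):
        with pytest.raises(UndefinedValueError, match="x\\+y"):
            ie_distance(-1.0, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(positive, positive)
    def test_bounded_symmetric_nonnegative(self, x, y):
        s = ie_distance(x, y)
        assert 0 <= s < 2
        assert s == pytest.approx(ie_distance(y, x))


class TestLogDistance:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(math.e, 1, 1.0), (5, 5, 0.0), (1, 3, 1.0986122886681098)],
    )
    def test_values(self, x, y, expected):
        assert log_distance(x, y) == pytest.approx(expected, abs=1e-10)

    def test_unbounded(self):
        assert log_distance(1, 1e9) > 2  # unlike the IE metric

    @pytest.mark.parametrize("x,y", [(0, 1), (-2, 3), (1, -1)])
    def test_nonpositive_rejected(self, x, y):
        with pytest.raises(UndefinedValueError):
            log_distance(x, y)


class TestAdaptivePeak:
    def test_equal_distances_give_mean(self):
        t = pc.read_tree("(A:1,B:1);")
        assert adaptive_peak(t, {"A": 2, "B": 8}, t.root) == pytest.approx(5.0)

    def test_inverse_distance_weighting(self):
        t = pc.read_tree("(A:1,B:3);")
        # (2/1 + 8/3) / (1 + 1/3)
        assert adaptive_peak(t, {"A": 2, "B": 8}, t.root) == pytest.approx(3.5)

    def test_constant_tips(self):
        t = pc.read_tree("((A:1,B:2):1,C:3);")
        for v in t.internal_nodes:
            assert adaptive_peak(t, {"A": 4, "B": 4, "C": 4}, int(v)) == pytest.approx(4.0)

    def test_within_tip_range(self, yule100):
        truth = pc.simulate_bm_trait(yule100, seed=3)
        tips = truth.tip_values("arithmetic")
        v = int(yule100.internal_nodes[0])
        ap = adaptive_peak(yule100, tips, v)
        assert min(tips.values()) <= ap <= max(tips.values())

    def test_missing_tip(self):
        t = pc.read_tree("(A:1,B:1);")
        with pytest.raises(KeyError):
            adaptive_peak(t, {"A": 1.0}, t.root)


class TestFarrisT:
    def test_printed_worked_example(self):
        t1, t2, t3 = farris_T(TriangleSides(1.2, 0.24, 1.04))
        assert t1 == pytest.approx(1.0)
        assert t2 == pytest.approx(0.2)
        assert t3 == pytest.approx(0.04)

    def test_collinear_gives_zero_peak_distance(self):
        t1, t2, t3 = farris_T(TriangleSides(s1=1.0, s2=0.4, s3=0.6))
        assert t3 == pytest.approx(0.0, abs=1e-15)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=1e-6, max_value=1e3))
    def test_equilateral(self, s):
        assert farris_T(TriangleSides(s, s, s)) == pytest.approx((s / 2,) * 3)


class TestRValues:
    def test_equal_branches_identity(self):
        assert r_values(0.5, 0.3, 2.0, 2.0) == pytest.approx((0.5, 0.3))

    def test_branch_length_scaling(self):
        assert r_values(1.0, 1.0, 3.0, 1.0) == pytest.approx((1.5, 0.5))

    def test_zero_T_gives_zero_R(self):
        assert r_values(0.0, 0.7, 1.0, 4.0)[0] == 0.0

    def test_nonpositive_branch_rejected(self):
        with pytest.raises(ValueError):
            r_values(1.0, 1.0, 0.0, 1.0)


class TestAncestralState:
    def test_equal_weights_give_mean(self):
        assert ancestral_state(2, 8, 0.5, 0.5) == pytest.approx(5.0)

    def test_inverse_r_weighting(self):
        assert ancestral_state(2, 8, 1.0, 3.0) == pytest.approx(3.5)

    def test_zero_r_undefined(self):
        with pytest.raises(UndefinedValueError):
            ancestral_state(5, 5, 0.0, 0.3)


class TestIEReconstruct:
    def test_modified_cherry_recovers_adaptive_peak(self):
        t = pc.read_tree("(A:2,B:2);")
        res = ie_reconstruct(t, {"A": 3.0, "B": 7.0}, metric="log")
        row = res.nodes.iloc[0]
        assert row["ancestral_state"] == pytest.approx(row["adaptive_peak"], rel=1e-10)

    def test_constant_tips_undefined(self):
        t = pc.read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(UndefinedValueError, match="node"):
            ie_reconstruct(t, {"A": 3.0, "B": 3.0, "C": 3.0}, metric="ie")

    def test_permissive_mode_records_nan_and_continues(self):
        t = pc.read_tree("(((A:1,B:1):1,C:2):1,D:3);")
        res = ie_reconstruct(
            t, {"A": 3.0, "B": 3.0, "C": 5.0, "D": 9.0}, metric="ie", on_undefined="nan"
        )
        assert res.n_undefined >= 1
        assert res.nodes["ancestral_state"].isna().any()
        assert len(res.nodes) == 3 and len(res.branches) == 6

    def test_output_counts(self, yule100):
        truth = pc.simulate_bm_trait(yule100, seed=5)
        res = ie_reconstruct(yule100, truth.tip_values("arithmetic"), metric="ie")
        assert len(res.nodes) == 99
        assert len(res.branches) == 198
        assert res.branches["R"].notna().all()
        assert (res.branches["R"] >= 0).all()

    def test_sides_below_two_for_ie_metric(self, yule100):
        truth = pc.simulate_bm_trait(yule100, seed=5)
        res = ie_reconstruct(yule100, truth.tip_values("arithmetic"), metric="ie")
        assert (res.nodes[["s1", "s2", "s3"]].to_numpy() < 2).all()
        assert (res.nodes[["s1", "s2", "s3"]].to_numpy() >= 0).all()

    def test_signed_r_follows_direction_of_change(self):
        t = pc.read_tree("(A:1,B:1);")
        res = ie_reconstruct(t, {"A": 2.0, "B": 8.0}, metric="ie")
        b = res.branches.set_index("branch")
        anc = res.nodes["ancestral_state"].iloc[0]
        a_id = t.node_of_label("A")
        assert 2.0 < anc < 8.0
        assert b.loc[a_id, "signed_R"] < 0  # A is below the ancestor
        assert b.loc[t.node_of_label("B"), "signed_R"] > 0

    def test_contrasts_are_log_space_standardized(self):
        t = pc.read_tree("(A:4,B:1);")
        res = ie_reconstruct(t, {"A": 2.0, "B": 8.0}, metric="ie")
        anc = res.nodes["ancestral_state"].iloc[0]
        b = res.branches.set_index("branch")
        a_id = t.node_of_label("A")
        expected = (math.log(2.0) - math.log(anc)) / math.sqrt(4.0)
        assert b.loc[a_id, "contrast"] == pytest.approx(expected)

    def test_deterministic(self, yule100):
        truth = pc.simulate_bm_trait(yule100, seed=5)
        tips = truth.tip_values("arithmetic")
        r1 = ie_reconstruct(yule100, tips, metric="ie")
        r2 = ie_reconstruct(yule100, tips, metric="ie")
        assert r1.nodes.equals(r2.nodes)
        assert r1.branches.equals(r2.branches)

    def test_unknown_options_rejected(self, yule100):
        truth = pc.simulate_bm_trait(yule100, seed=5)
        with pytest.raises(ValueError):
            ie_reconstruct(yule100, truth.tip_values("arithmetic"), metric="bogus")
        with pytest.raises(ValueError):
            ie_reconstruct(
                yule100, truth.tip_values("arithmetic"), on_undefined="ignore"
            )

    def test_nonpositive_trait_rejected(self):
        t = pc.read_tree("(A:1,B:1);")
        with pytest.raises(ValueError, match="positive"):
            ie_reconstruct(t, {"A": -1.0, "B": 2.0}, metric="ie")


class TestEquivalenceProperty:
    def test_thousand_random_equal_branch_cherries(self):
        """Modified IE (logged data, log-difference sides) on an equal-branch
        cherry always returns the adaptive peak as the ancestral state."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            b = rng.uniform(0.1, 10.0)
            x1, x2 = np.exp(rng.normal(1.0, 1.0, size=2))
            if x1 == x2:
                continue
            t = pc.read_tree(f"(A:{b},B:{b});")
            res = ie_reconstruct(t, {"A": float(x1), "B": float(x2)}, metric="log")
            row = res.nodes.iloc[0]
            assert np.isclose(
                row["ancestral_state"], row["adaptive_peak"], rtol=1e-10, atol=1e-12
            )


class TestBiasProperties:
    """Directional biases of IE under geometric BM (root log value 0)."""

    @staticmethod
    def _one_sided_t(mean, sd, n, direction):
        from scipy import stats

        t = mean / (sd / math.sqrt(n))
        p = stats.t.sf(t, df=n - 1) if direction == "greater" else stats.t.cdf(t, df=n - 1)
        return p

    def test_root_estimate_inflated(self, single200):
        tab = single200.node_bias["IE"].table
        root_row = tab.iloc[0]  # depth-ordered: first row is the root
        assert root_row["depth"] == 0.0
        p = self._one_sided_t(root_row["mean"], root_row["sd"], root_row["n"], "greater")
        assert root_row["mean"] > 0
        assert p < 0.01

    def test_root_branch_contrasts_skewed_negative(self, single200):
        tab = single200.branch_bias["IE"].table
        two = tab.iloc[:2]  # the two branches incident to the root
        n = int(two["n"].sum())
        grand = float(np.average(two["mean_value"], weights=two["n"]))
        ss = float(
            sum(
                (row["n"] - 1) * row["sd_value"] ** 2
                + row["n"] * (row["mean_value"] - grand) ** 2
                for _, row in two.iterrows()
            )
        )
        sd = math.sqrt(ss / (n - 1))
        p = self._one_sided_t(grand, sd, n, "less")
        assert grand < 0
        assert p < 0.01
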