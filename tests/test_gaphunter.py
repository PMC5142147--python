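import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaphunt.datatypes import BetaMatrix, ValidationError
from gaphunt.gaphunter import (
    GapHunter,
    GapHuntParams,
    assign_groups,
    beta_to_mvalues,
    find_gaps,
    gaphunter_matrix,
    is_outlier_driven,
    mvalues_to_beta,
)
from oracles import single_linkage_groups

betas = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestFindGaps:
    def test_worked_example(self, six_values):
        idx, cuts = find_gaps(six_values, 0.05)
        assert idx.tolist() == [2, 4]
        assert cuts == pytest.approx([0.34, 0.76])

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_constant_vector_has_no_gaps(self, n):
        idx, cuts = find_gaps(np.full(n, 0.37), 0.05)
        assert len(idx) == 0 and len(cuts) == 0

    def test_single_pair(self):
        idx, cuts = find_gaps(np.array([0.0, 1.0]), 0.05)
        assert idx.tolist() == [0]
        assert cuts == pytest.approx([0.5])

    def test_difference_equal_to_threshold_is_not_a_gap(self):
        idx, _ = find_gaps(np.array([0.2, 0.25]), 0.05)
        assert len(idx) == 0
        idx, _ = find_gaps(np.array([0.2, 0.2500001]), 0.05)
        assert idx.tolist() == [0]

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            find_gaps(np.array([0.5]), 0.05)


class TestAssignGroups:
    def test_worked_example(self, six_values):
        labels, sizes, cuts = assign_groups(six_values, 0.05, min_samples=2)
        assert labels.tolist() == [1, 1, 1, 2, 2, 3]
        assert sizes == (3, 2, 1)
        assert cuts == pytest.approx((0.34, 0.76))

    def test_permutation_invariance(self, six_values):
        rng = np.random.default_rng(0)
        perm = rng.permutation(6)
        labels, sizes, _ = assign_groups(six_values[perm], 0.05, min_samples=2)
        expect = np.array([1, 1, 1, 2, 2, 3])[perm]
        assert labels.tolist() == expect.tolist()
        assert sizes == (3, 2, 1)

    def test_missing_values_propagate(self, six_values):
        v = six_values.copy()
        v[1] = np.nan
        labels, sizes, _ = assign_groups(v, 0.05, min_samples=2)
        assert np.isnan(labels[1])
        assert sizes == (2, 2, 1)

    def test_min_samples_guard(self):
        with pytest.raises(ValidationError):
            assign_groups(np.array([0.1, 0.9, np.nan]), 0.05, min_samples=3)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(betas, min_size=2, max_size=50),
           st.floats(min_value=0.01, max_value=0.5))
    def test_matches_single_linkage_oracle(self, values, threshold):
        """Gap groups are the single-linkage components cut at the threshold."""
        v = np.array(values)
        labels, _, _ = assign_groups(v, threshold, min_samples=2)
        assert labels.tolist() == single_linkage_groups(v, threshold).tolist()

    @settings(deadline=None, max_examples=100)
    @given(st.lists(betas, min_size=2, max_size=30), st.floats(0.01, 0.4),
           st.floats(-0.2, 0.2))
    def test_affine_shift_preserves_structure(self, values, threshold, shift):
        v = np.array(values)
        w = v + shift
        if w.min() < 0 or w.max() > 1:
            return
        l1, s1, _ = assign_groups(v, threshold, min_samples=2)
        l2, s2, _ = assign_groups(w, threshold, min_samples=2)
        assert l1.tolist() == l2.tolist() and s1 == s2


class TestOutlierRule:
    @pytest.mark.parametrize(
        "sizes,cutoff,n,expected",
        [
            ((99, 1), 0.01, 100, True),  # 1 <= 1: "does not exceed"
            ((584, 6), 0.01, 590, False),  # 6 > 5.9
            ((50, 50), 0.01, 100, False),
            ((98, 1, 1), 0.02, 100, True),
            ((50, 50), 0.5, 100, True),  # ties: largest subtracted once
        ],
    )
    def test_rule(self, sizes, cutoff, n, expected):
        assert is_outlier_driven(sizes, cutoff, n) is expected

    def test_raising_cutoff_never_unflags(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sizes = tuple(rng.integers(1, 50, size=rng.integers(2, 5)))
            n = sum(sizes)
            flagged = [is_outlier_driven(sizes, c, n) for c in (0.01, 0.05, 0.2, 0.5)]
            # once flagged at a lower cutoff, stays flagged at higher ones
            assert flagged == sorted(flagged)


class TestGaphunterMatrix:
    def test_composition(self, small_beta):
        calls = gaphunter_matrix(small_beta, GapHuntParams(min_samples=2))
        assert [c.probe_id for c in calls] == ["probe_gap"]
        assert calls[0].n_groups == 3

    def test_large_threshold_yields_nothing(self, small_beta):
        calls = gaphunter_matrix(small_beta, GapHuntParams(threshold=0.5, min_samples=2))
        assert calls == []

    def test_outlier_probe_excluded_then_retained(self):
        v = np.concatenate([np.linspace(0.30, 0.32, 99), [0.9]])
        beta = BetaMatrix(pd.DataFrame([v], index=["p"], columns=[f"S{i}" for i in range(100)]))
        assert gaphunter_matrix(beta, GapHuntParams()) == []
        calls = gaphunter_matrix(beta, GapHuntParams(keep_outlier_driven=True))
        assert len(calls) == 1 and calls[0].outlier_driven
        assert calls[0].group_sizes == (99, 1)

    def test_empty_matrix(self):
        beta = BetaMatrix(pd.DataFrame(np.empty((0, 3)), columns=list("abc")))
        assert gaphunter_matrix(beta) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.uniform(size=(200, 40)),
                            index=[f"p{i}" for i in range(200)],
                            columns=[f"S{i}" for i in range(40)])
        beta = BetaMatrix(data)
        prev = None
        for t in (0.025, 0.05, 0.10, 0.2):
            ids = {c.probe_id
                   for c in gaphunter_matrix(beta, GapHuntParams(threshold=t, out_cutoff=0.5))}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_n_groups_equals_gaps_plus_one(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.uniform(size=(50, 30)))
        data.columns = data.columns.astype(str)
        data.index = data.index.astype(str)
        for c in gaphunter_matrix(BetaMatrix(data), GapHuntParams(out_cutoff=0.9,
                                                                  keep_outlier_driven=True)):
            assert c.n_groups == len(c.cutpoints) + 1
            assert sum(c.group_sizes) == 30


class TestMValues:
    def test_known_points(self):
        assert mvalues_to_beta(np.array([0.0]))[0] == pytest.approx(0.5)
        assert mvalues_to_beta(np.array([np.log2(3)]))[0] == pytest.approx(0.75)

    def test_round_trip(self):
        b = np.linspace(0.01, 0.99, 25)
        back = mvalues_to_beta(beta_to_mvalues(b, eps=1e-12))
        assert np.allclose(back, b, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            mvalues_to_beta(np.array([np.inf]))


class TestModelInterface:
    def test_fit_and_summary(self, small_beta):
        res = GapHunter(small_beta).fit(min_samples=2)
        assert res.gap_ids == ["probe_gap"]
        assert res.group_counts().to_dict() == {3: 1}
        s = res.summary()
        assert "gap probes:          1" in s
        assert res.call_for("probe_gap").group_sizes == (3, 2, 1)
        with pytest.raises(KeyError):
            res.call_for("nope")

    def test_params_conflict(self, small_beta):
        with pytest.raises(ValidationError):
            GapHunter(small_beta).fit(GapHuntParams(), threshold=0.1)

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            GapHuntParams(threshold=1.5)
        with pytest.raises(ValidationError):
            GapHuntParams(out_cutoff=0.0)
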