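"""Invariant-set normalization and MBEI summarization."""

import numpy as np
import pandas as pd
import pytest

from zgaprof import (
    ExpressionMatrix,
    StageDesign,
    invariant_set_normalize,
    mbei_summarize,
    rescale_to_common_median,
    select_invariant_set,
)
from zgaprof.arraynorm import choose_reference, summarize_probesets


def _em(values, design):
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                     columns=design.sample_names()),
        design,
    )


class TestInvariantSet:
    def test_identical_arrays_retain_all(self):
        ref = np.linspace(1, 100, 50)
        assert len(select_invariant_set(ref, ref.copy())) == 50

    def test_global_scaling_retains_all(self):
        ref = np.linspace(1, 100, 50)
        assert len(select_invariant_set(ref, 2 * ref)) == 50

    def test_rank_swapped_probe_is_excluded(self):
        # probe 0 moved between ranks 3 and 4: rank diff 2/10 = 0.2 for it,
        # 1/10 for the two displaced probes, 0 elsewhere
        ref = np.arange(1.0, 11.0)          # ranks 1..10
        target = ref.copy()
        target[0] = 3.5                      # now rank 3 in target
        inv = select_invariant_set(ref, target, rank_threshold=0.15, min_probes=5)
        assert 0 not in inv
        assert set(inv) == set(range(1, 10))

    def test_too_few_survivors_errors(self):
        ref = np.arange(1.0, 11.0)
        target = ref[::-1]  # fully rank-reversed
        with pytest.raises(ValueError, match="loosen"):
            select_invariant_set(ref, target, rank_threshold=0.01)


class TestNormalize:
    def test_identity(self):
        ref = np.linspace(1, 50, 20)
        inv = np.arange(20)
        out = invariant_set_normalize(ref, ref.copy(), inv)
        assert np.allclose(out, ref, atol=1e-12)

    def test_scaled_target_maps_onto_reference(self):
        rng = np.random.default_rng(1)
        ref = np.sort(rng.uniform(1, 100, 40))
        target = 2.0 * ref
        out = invariant_set_normalize(ref, target, np.arange(40))
        assert np.allclose(out, ref, atol=1e-9)

    def test_map_is_non_decreasing(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(1, 100, 30)
        target = rng.uniform(1, 100, 30)
        inv = select_invariant_set(ref, target, rank_threshold=0.3, min_probes=5)
        mapped = invariant_set_normalize(ref, target, inv)
        order = np.argsort(target)
        assert np.all(np.diff(mapped[order]) >= -1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(1, 100, 50)
        target = rng.uniform(1, 100, 50)
        inv = select_invariant_set(ref, target, rank_threshold=0.3, min_probes=5)
        once = invariant_set_normalize(ref, target, inv)
        twice = invariant_set_normalize(ref, once, inv)
        assert np.allclose(twice, once, atol=1e-9)


class TestRescale:
    design = StageDesign(["a", "b", "c"], 1)

    def test_single_matrix_unchanged(self):
        m = _em([[1.0, 2.0, 3.0]], self.design)
        (out,) = rescale_to_common_median([m])
        assert np.allclose(out.values, m.values)

    def test_two_arrays_meet_at_grand_median(self):
        m1 = _em([[5.0, 10.0, 20.0]], self.design)   # median 10
        m2 = _em([[10.0, 20.0, 40.0]], self.design)  # median 20
        o1, o2 = rescale_to_common_median([m1, m2])
        assert np.isclose(np.median(o1.values), 15.0)
        assert np.isclose(np.median(o2.values), 15.0)
        assert np.allclose(o1.values, m1.values * 1.5)
        assert np.allclose(o2.values, m2.values * 0.75)

    def test_rank_order_untouched(self):
        rng = np.random.default_rng(4)
        m1 = _em(rng.uniform(1, 100, (5, 3)), self.design)
        m2 = _em(rng.uniform(1, 50, (5, 3)), self.design)
        o1, _ = rescale_to_common_median([m1, m2])
        assert np.array_equal(np.argsort(o1.values.to_numpy(), axis=None),
                              np.argsort(m1.values.to_numpy(), axis=None))

    def test_non_positive_median_errors(self):
        m = _em([[-1.0, 0.0, 1.0]], self.design)
        with pytest.raises(ValueError, match="median"):
            rescale_to_common_median([m])

    def test_reference_choice_prefers_grand_median(self):
        mats = [_em([[v, v, v]], self.design) for v in (10.0, 15.0, 20.0)]
        assert choose_reference(mats) == 1


class TestMbei:
    def test_noiseless_rank_one_recovery(self):
        theta = np.array([1.0, 2.0, 3.0, 4.0])
        phi = np.array([1.0, 1.0, 1.0])
        fit = mbei_summarize(np.outer(phi, theta))
        assert fit.residual_ss < 1e-18
        # theta recovered up to the phi-norm scale convention
        ratio = fit.theta / theta
        assert np.allclose(ratio, ratio[0])
        assert np.isclose((fit.phi**2).sum(), 3.0)  # identifiability constraint

    def test_single_probe_theta_proportional_to_row(self):
        row = np.array([[2.0, 4.0, 8.0]])
        fit = mbei_summarize(row)
        assert np.allclose(fit.theta / row[0], fit.theta[0] / row[0, 0])

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(1, 10, (4, 5))
        perm = [3, 1, 4, 0, 2]
        fit = mbei_summarize(v)
        fit_p = mbei_summarize(v[:, perm])
        assert np.allclose(fit_p.theta, fit.theta[perm], atol=1e-6)

    def test_residual_history_non_increasing(self):
        rng = np.random.default_rng(6)
        v = np.outer(rng.uniform(0.5, 2, 6), rng.uniform(1, 5, 4)) + rng.normal(0, 0.3, (6, 4))
        fit = mbei_summarize(np.abs(v))
        assert all(b <= a + 1e-12 for a, b in zip(fit.residual_history, fit.residual_history[1:]))

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            mbei_summarize(np.zeros((3, 3)))

    def test_probeset_summarization(self):
        frame = pd.DataFrame(
            np.outer([1.0, 1.2, 0.8, 2.0], [1.0, 2.0, 3.0]),
            index=["a_p1", "a_p2", "a_p3", "b_p1"], columns=["s1", "s2", "s3"],
        )
        out = summarize_probesets(frame, {"a_p1": "a", "a_p2": "a", "a_p3": "a", "b_p1": "b"})
        assert set(out.index) == {"a", "b"}
        assert np.allclose(out.loc["a"] / out.loc["a"].iloc[0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="missing"):
            summarize_probesets(frame, {"a_p1": "a"})
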