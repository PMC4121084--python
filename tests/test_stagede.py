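"""Stage-transition tests, variance moderation, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zgaprof import (
    ExpressionMatrix,
    StageDesign,
    bh_fdr,
    comparative_expression,
    fit_moderated,
    moderated_two_sample_t,
    pooled_two_sample_t,
    transition_tests,
)
from zgaprof.stagede import ModeratedFit, trigamma_inverse


def bh_brute_force(p):
    """Independent step-up oracle: q(i) = min_{j>=i} p(j)*m/j on sorted p."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


# --- comparative expression -------------------------------------------------

def _linear_matrix(values, design):
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                     columns=design.sample_names()),
        design, scale="linear",
    )


def test_comparative_expression_formula():
    design = StageDesign(["MII"], 1)
    m = _linear_matrix([[400.0], [100.0], [300.0]], design)
    out = comparative_expression(m, ["g1", "g2"])  # controls average 200
    assert np.isclose(out.values.loc["g0", "MII_1"], 1.0)  # log2(400)-log2(200)
    # a gene equal to the control average maps to 0
    m2 = _linear_matrix([[200.0], [100.0], [300.0]], design)
    assert np.isclose(comparative_expression(m2, ["g1", "g2"]).values.loc["g0", "MII_1"], 0.0)


def test_comparative_expression_scale_invariance():
    design = StageDesign(["MII", "4-cell"], 2)
    rng = np.random.default_rng(0)
    vals = rng.uniform(10, 1000, (5, 4))
    m = _linear_matrix(vals, design)
    doubled = _linear_matrix(vals * np.array([2.0, 1.0, 1.0, 1.0]), design)  # double one sample
    a = comparative_expression(m, ["g3", "g4"]).values
    b = comparative_expression(doubled, ["g3", "g4"]).values
    assert np.allclose(a, b)


def test_comparative_expression_errors():
    design = StageDesign(["MII"], 1)
    m = _linear_matrix([[400.0]], design)
    with pytest.raises(ValueError, match="control"):
        comparative_expression(m, ["nope"])
    with pytest.raises(ValueError, match="positive"):
        comparative_expression(_linear_matrix([[0.0]], design), ["g0"])


# --- t statistics -----------------------------------------------------------

def test_identical_groups_give_t0_p1():
    a = np.array([[1.0, 2.0, 3.0]])
    _, t, _, p = pooled_two_sample_t(a, a.copy())
    assert t[0] == 0.0 and p[0] == 1.0


def test_separated_groups_give_tiny_p():
    rng = np.random.default_rng(1)
    a = 10.0 + rng.normal(0, 0.01, (1, 3))
    b = rng.normal(0, 0.01, (1, 3))
    lfc, _, _, p = pooled_two_sample_t(a, b)
    assert p[0] < 1e-6
    assert np.isclose(lfc[0], 10.0, atol=0.05)


def test_constant_but_separated_groups():
    lfc, t, _, p = pooled_two_sample_t(np.array([[5.0, 5.0]]), np.array([[1.0, 1.0]]))
    assert np.isinf(t[0]) and p[0] == 0.0 and lfc[0] == 4.0


def test_transition_skipped_with_single_replicate():
    design = StageDesign(["MII", "4-cell"], {"MII": 1, "4-cell": 3})
    m = ExpressionMatrix(
        pd.DataFrame([[1.0, 2.0, 2.1, 1.9]], index=["g"], columns=design.sample_names()),
        design, scale="log2",
    )
    (res,) = transition_tests(m)
    assert res.status == "skipped"
    assert np.isnan(res.p_value)


def test_unknown_method_rejected(small_study):
    with pytest.raises(ValueError, match="method"):
        transition_tests(small_study.human_array_a, method="bayes")


# --- moderation -------------------------------------------------------------

def test_moderated_equals_student_when_d0_zero():
    rng = np.random.default_rng(2)
    later = rng.normal(1, 0.5, (50, 3))
    earlier = rng.normal(0, 0.5, (50, 3))
    _, t_ord, _, p_ord = pooled_two_sample_t(later, earlier)
    pin = ModeratedFit(d0=0.0, s0_sq=1.0, s_tilde_sq=np.empty(0))
    _, t_mod, df_mod, p_mod, _ = moderated_two_sample_t(later, earlier, fit=pin)
    assert np.max(np.abs(t_mod - t_ord)) <= 1e-9
    assert np.max(np.abs(p_mod - p_ord)) <= 1e-9
    assert np.all(df_mod == 4.0)


def test_equal_variances_drive_d0_to_cap():
    fit = fit_moderated(np.full(20, 0.7), np.full(20, 4.0))
    assert fit.d0 == 1e6
    assert np.isclose(fit.s0_sq, 0.7, rtol=1e-3)
    assert np.allclose(fit.s_tilde_sq, 0.7, rtol=1e-3)


def test_posterior_variance_plug_in():
    # pinned prior (d0=4, s0^2=2) applied to s^2=[1,4] at df=2 each:
    # s~^2 = (4*2 + 2*s^2)/6
    later = np.array([[1.0 - np.sqrt(0.5), 1.0 + np.sqrt(0.5)],   # group var 1
                      [1.0 - np.sqrt(2.0), 1.0 + np.sqrt(2.0)]])  # group var 4
    earlier = np.zeros((2, 2)) + later - later.mean(axis=1, keepdims=True)  # same spread, mean 0
    pin = ModeratedFit(d0=4.0, s0_sq=2.0, s_tilde_sq=np.empty(0))
    _, t, df, _, fit = moderated_two_sample_t(later, earlier, fit=pin)
    assert np.allclose(fit.s_tilde_sq, [10.0 / 6.0, 16.0 / 6.0])
    assert np.allclose(df, 6.0)
    assert np.allclose(t, 1.0 / np.sqrt(fit.s_tilde_sq * (0.5 + 0.5)))


def test_moderation_matches_limma_reference_fit():
    # frozen from limma::squeezeVar on this variance vector with df=4
    s2 = np.array([
        0.560916912472, 0.980814087035, 0.266163970167, 11.8891712021, 0.13768647591,
        6.39051984557, 0.136017931813, 11.8159043984, 0.472096599635, 5.31867643215,
        0.0605042081502, 7.53964126536, 0.265355057264, 3.4259153873, 0.248824056459,
        8.81464889258, 0.0281692126536, 11.4549683922, 0.229911632266, 4.81434178193,
    ])
    fit = fit_moderated(s2, np.full(20, 4.0))
    assert np.isclose(fit.d0, 1.28279187878, rtol=1e-6)
    assert np.isclose(fit.s0_sq, 0.522687109501, rtol=1e-6)
    expected_post = np.array([
        0.551633775467, 0.869569582288, 0.328454101486, 9.12910913286, 0.231174104693,
        4.96566564866, 0.229910724165, 9.07363331224, 0.484381220474, 4.15409219431,
        0.172733591016, 5.8357521076, 0.327841612543, 2.7209401124, 0.315324745564,
        6.80115650473, 0.148250328197, 8.80034145099, 0.301004723405, 3.77222240894,
    ])
    assert np.allclose(fit.s_tilde_sq, expected_post, rtol=1e-6)


def test_variance_shrinks_toward_prior_as_d0_grows():
    s2 = np.array([0.2, 5.0])
    df = np.array([4.0, 4.0])
    s0 = 1.0
    gaps = []
    for d0 in (0.5, 2.0, 10.0, 100.0):
        post = (d0 * s0 + df * s2) / (d0 + df)
        gaps.append(np.abs(post - s0).max())
        assert np.all((post >= np.minimum(s2, s0)) & (post <= np.maximum(s2, s0)))
    assert all(b < a for a, b in zip(gaps, gaps[1:]))


def test_too_few_positive_variances_falls_back():
    with pytest.warns(UserWarning, match="ordinary"):
        fit = fit_moderated([0.0, 0.0, 0.5], [2, 2, 2])
    assert fit.d0 == 0.0


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma

    for x in (0.1, 1.0, 7.3, 120.0):
        assert np.isclose(trigamma_inverse(float(polygamma(1, x))), x, rtol=1e-6)


# --- FDR --------------------------------------------------------------------

def test_bh_examples():
    assert np.isclose(bh_fdr([0.03])[0], 0.03)
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_bh_monotone_on_sorted_input():
    rng = np.random.default_rng(3)
    p = np.sort(rng.uniform(size=200))
    q = bh_fdr(p)
    assert np.all(np.diff(q) >= -1e-15)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
def test_bh_matches_brute_force(p):
    assert np.allclose(bh_fdr(p), bh_brute_force(p), atol=1e-12)


def test_transition_q_values_are_per_family(human_design):
    rng = np.random.default_rng(4)
    vals = rng.normal(0, 1, (30, human_design.n_samples))
    m = ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(30)],
                     columns=human_design.sample_names()),
        human_design, scale="log2",
    )
    results = transition_tests(m, method="student")
    for pair in human_design.consecutive_pairs():
        fam = [r for r in results if r.stage_pair == pair]
        qs = bh_fdr([r.p_value for r in fam])
        assert np.allclose([r.q_value for r in fam], qs)
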