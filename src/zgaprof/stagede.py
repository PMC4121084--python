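"""Stage-transition differential expression.

For every pair of consecutive developmental stages, every feature is
tested with a two-sided two-sample t-test on its replicate values —
either the ordinary Student test (pooled variance; Welch available
behind a flag) or an empirical-Bayes moderated test in which per-feature
variances are shrunk toward a common prior before forming the statistic.
P-values are corrected per stage-pair family with the Benjamini-Hochberg
step-up procedure.

The moderated test follows the standard hierarchical model for gene-wise
variances: sample variances s_g^2 with d_g residual degrees of freedom
are assumed scaled-chi-squared around true variances drawn from a
scaled-inverse-chi-squared prior with d0 degrees of freedom and scale
s0^2. The prior parameters are estimated by method of moments on
log s_g^2 (digamma/trigamma matching), the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t is referred to a t distribution on d_g + d0 degrees
of freedom.

Array expression is put on the comparative scale of the study design
before testing: log2(comparative expression) = log2[gene] -
log2[average of the endogenous-control probes] per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import ExpressionMatrix, get_logger

__all__ = [
    "ComparativeExpression",
    "TransitionResult",
    "ModeratedFit",
    "comparative_expression",
    "bh_fdr",
    "fit_moderated",
    "trigamma_inverse",
    "pooled_two_sample_t",
    "moderated_two_sample_t",
    "transition_tests",
    "transitions_to_frame",
    "transitions_by_feature",
]

_log = get_logger("stagede")

#: cap above which the prior degrees of freedom are treated as infinite
D0_CAP = 1e6


@dataclass
class ComparativeExpression:
    """Log2 expression referenced to the mean of endogenous-control features."""

    values: pd.DataFrame
    control_ids: tuple[str, ...]
    design: object = None


@dataclass
class TransitionResult:
    """Test outcome for one feature across one consecutive stage pair.

    ``log_fc`` is the later-stage minus earlier-stage mean on the input
    (log) scale. ``status`` is ``"tested"`` or ``"skipped"`` (fewer than
    two usable replicates in either stage); skipped rows carry no
    statistics. ``q_value`` is None when no FDR correction was applied
    (the raw-p policies of the qPCR and RPKM stages).
    """

    feature_id: str
    stage_pair: tuple[str, str]
    log_fc: float = np.nan
    t_stat: float = np.nan
    df: float = np.nan
    p_value: float = np.nan
    q_value: float | None = None

    status: str = "tested"

    def significant(self, alpha: float, use_q: bool = True) -> bool:
        if self.status != "tested":
            return False
        stat = self.q_value if (use_q and self.q_value is not None) else self.p_value
        return bool(stat <= alpha)


@dataclass
class ModeratedFit:
    """Empirical-Bayes variance prior and per-feature posterior variances."""

    d0: float
    s0_sq: float
    s_tilde_sq: np.ndarray


def comparative_expression(
    matrix: ExpressionMatrix, control_ids: Sequence[str]
) -> ComparativeExpression:
    """log2(comparative expression) = log2[gene] - log2[mean of controls], per sample.

    Requires linear-scale positive values and all control features present.
    """
    missing = [c for c in control_ids if c not in matrix.values.index]
    if missing:
        raise ValueError(f"control feature(s) not in matrix: {missing}")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("comparative expression needs strictly positive linear values")
    ctrl_mean = matrix.values.loc[list(control_ids)].mean(axis=0)
    out = np.log2(matrix.values) - np.log2(ctrl_mean)
    return ComparativeExpression(out, tuple(control_ids), design=matrix.design)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def fit_moderated(s_sq: Sequence[float], df: Sequence[float]) -> ModeratedFit:
    """Estimate the variance prior (d0, s0^2) and posterior variances.

    Method of moments on z = log(s^2): E[z] and Var[z] are matched to the
    digamma/trigamma expressions implied by the hierarchical model.
    ``d0`` is capped at ``D0_CAP`` (treated as infinite). With fewer than
    two features of positive variance no moderation is possible and the
    fit degenerates to the ordinary test (d0 = 0) with a warning.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    if (df < 1).any():
        raise ValueError("residual degrees of freedom must be >= 1")
    if (s_sq < 0).any():
        raise ValueError("variances must be non-negative")
    ok = s_sq > 0
    if ok.sum() < 2:
        warnings.warn("fewer than 2 positive variances; falling back to ordinary t", stacklevel=2)
        return ModeratedFit(d0=0.0, s0_sq=float(s_sq[ok].mean()) if ok.any() else 1.0,
                            s_tilde_sq=s_sq.copy())
    x, d = s_sq[ok], df[ok]
    e = np.log(x) - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(e.mean())
    n = len(e)
    rhs = float(np.mean((e - ebar) ** 2 * n / (n - 1) - special.polygamma(1, d / 2.0)))
    if rhs > 0:
        d0 = 2.0 * trigamma_inverse(rhs)
        if d0 > D0_CAP:
            d0 = D0_CAP
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread in log s^2 beyond sampling noise: infinite prior df
        d0 = D0_CAP
        s0_sq = float(x.mean())
    s_tilde = (d0 * s0_sq + df * s_sq) / (d0 + df)
    return ModeratedFit(d0=d0, s0_sq=s0_sq, s_tilde_sq=s_tilde)


def _t_pieces(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-row difference of means, variance of the difference scale, df, se factor.

    ``a``/``b`` are features x replicates (later and earlier stage).
    Returns (diff, pooled_s_sq, df, inv_n_sum) for the pooled case.
    """
    n1, n2 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # n=1 rows are skipped later
        v1 = a.var(axis=1, ddof=1)
        v2 = b.var(axis=1, ddof=1)
    if equal_var:
        s_sq = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = np.full(len(diff), float(n1 + n2 - 2))
        inv_n = 1.0 / n1 + 1.0 / n2
        return diff, s_sq, df, np.full(len(diff), inv_n)
    # Welch: fold the unequal-variance SE into an effective s^2 with inv_n = 1
    se_sq = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se_sq**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    return diff, se_sq, df, np.ones(len(diff))


def _t_p_from(diff: np.ndarray, var: np.ndarray, inv_n: np.ndarray, df: np.ndarray):
    se = np.sqrt(var * inv_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero-variance conventions: identical groups -> t=0, p=1; separated
    # constant groups -> infinite t, p=0
    t_degenerate = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    t = np.where(se == 0, t_degenerate, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, np.minimum(p, 1.0)


def pooled_two_sample_t(later: np.ndarray, earlier: np.ndarray, equal_var: bool = True):
    """Vectorized two-sided two-sample t over feature rows.

    Returns (log_fc, t, df, p).
    """
    diff, var, df, inv_n = _t_pieces(np.asarray(later, float), np.asarray(earlier, float), equal_var)
    t, p = _t_p_from(diff, var, inv_n, df)
    return diff, t, df, p


def moderated_two_sample_t(
    later: np.ndarray, earlier: np.ndarray, fit: ModeratedFit | None = None
):
    """Moderated two-sided t: pooled variances shrunk toward the prior.

    With ``fit=None`` the prior is estimated from the data; pass an
    explicit :class:`ModeratedFit` to pin the prior (d0 = 0 reproduces
    the ordinary Student test exactly).
    """
    later = np.asarray(later, float)
    earlier = np.asarray(earlier, float)
    diff, s_sq, df, inv_n = _t_pieces(later, earlier, equal_var=True)
    if fit is None:
        fit = fit_moderated(s_sq, df)
    else:
        fit = ModeratedFit(fit.d0, fit.s0_sq,
                           (fit.d0 * fit.s0_sq + df * s_sq) / (fit.d0 + df) if fit.d0 > 0 else s_sq)
    total_df = np.minimum(df + fit.d0, D0_CAP)
    t, p = _t_p_from(diff, fit.s_tilde_sq, inv_n, total_df)
    return diff, t, total_df, p, fit


def transition_tests(
    matrix: ExpressionMatrix,
    method: str = "student",
    alpha: float = 0.05,
    equal_var: bool = True,
    usable: pd.DataFrame | None = None,
    min_replicates: int = 2,
    apply_fdr: bool = True,
) -> list[TransitionResult]:
    """Test every feature across every consecutive stage pair.

    ``matrix`` must already be on a log (or -dCt) scale. ``usable``
    optionally masks replicate cells (False = unusable, e.g. undetected
    qPCR wells); a feature is skipped for a pair when either stage has
    fewer than ``min_replicates`` usable replicates. BH q-values are
    computed per stage-pair family when ``apply_fdr`` (the microarray
    policy); the qPCR/RPKM stages use raw p-values instead.
    """
    if method not in ("student", "moderated"):
        raise ValueError(f"unknown method {method!r} (student | moderated)")
    design = matrix.design
    if len(design.stages) < 2:
        raise ValueError("need at least two stages")
    features = matrix.feature_ids
    results: list[TransitionResult] = []
    for earlier, later in design.consecutive_pairs():
        a = matrix.stage_values(later).to_numpy(float)
        b = matrix.stage_values(earlier).to_numpy(float)
        if usable is not None:
            ua = usable[design.stage_columns(later)].to_numpy(bool)
            ub = usable[design.stage_columns(earlier)].to_numpy(bool)
            ok = (ua.sum(axis=1) >= min_replicates) & (ub.sum(axis=1) >= min_replicates)
        else:
            ok = np.ones(len(features), dtype=bool)
            if a.shape[1] < min_replicates or b.shape[1] < min_replicates:
                ok[:] = False
        if method == "student":
            lfc, t, df, p = pooled_two_sample_t(a, b, equal_var=equal_var)
        else:
            lfc, t, df, p, _fit = moderated_two_sample_t(a[ok], b[ok])
            full = np.full(len(features), np.nan)
            lfc_f, t_f, df_f, p_f = full.copy(), full.copy(), full.copy(), full.copy()
            lfc_f[ok], t_f[ok], df_f[ok], p_f[ok] = lfc, t, df, p
            lfc, t, df, p = lfc_f, t_f, df_f, p_f
        q = np.full(len(features), np.nan)
        if apply_fdr and ok.any():
            q[ok] = bh_fdr(p[ok])
        for i, fid in enumerate(features):
            if ok[i]:
                results.append(
                    TransitionResult(
                        fid, (earlier, later), log_fc=float(lfc[i]), t_stat=float(t[i]),
                        df=float(df[i]), p_value=float(p[i]),
                        q_value=float(q[i]) if apply_fdr else None, status="tested",
                    )
                )
            else:
                results.append(TransitionResult(fid, (earlier, later), status="skipped"))
    n_sig = sum(r.significant(alpha) for r in results)
    _log.info("%s: %d tests over %d transitions, %d significant at %.3g",
              method, len(results), len(design.stages) - 1, n_sig, alpha)
    return results


def transitions_to_frame(results: Sequence[TransitionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "earlier": [r.stage_pair[0] for r in results],
            "later": [r.stage_pair[1] for r in results],
            "log_fc": [r.log_fc for r in results],
            "t_stat": [r.t_stat for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [np.nan if r.q_value is None else r.q_value for r in results],
            "status": [r.status for r in results],
        }
    )


def transitions_by_feature(results: Sequence[TransitionResult]) -> dict[str, list[TransitionResult]]:
    out: dict[str, list[TransitionResult]] = {}
    for r in results:
        out.setdefault(r.feature_id, []).append(r)
    return out
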