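"""Array preprocessing: invariant-set normalization and MBEI summarization.

Between-array normalization uses the rank-invariant probe set: probes
whose proportional rank is stable between a target array and the
reference are assumed non-differential, and a monotone piecewise-linear
map fitted on them brings the target onto the reference scale. Arrays
are then rescaled to a common median and probe sets are summarized with
the model-based expression index (MBEI): ``value[i, j] ~ phi[i] * theta[j]``
with per-probe affinities ``phi`` and per-array expression indices
``theta``, fitted by alternating least squares under the identifiability
constraint ``sum(phi^2) = n_probes``.

Probe/array outlier pruning of the original MBEI procedure is omitted;
the fit is plain alternating least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ExpressionMatrix, get_logger

__all__ = [
    "MbeiFit",
    "select_invariant_set",
    "invariant_set_normalize",
    "rescale_to_common_median",
    "choose_reference",
    "mbei_summarize",
    "summarize_probesets",
]

_log = get_logger("arraynorm")


@dataclass
class MbeiFit:
    """Result of an MBEI alternating-least-squares fit.

    ``theta`` are the per-array expression indices (the summary values),
    ``phi`` the per-probe affinities with ``sum(phi^2) == n_probes``.
    """

    theta: np.ndarray
    phi: np.ndarray
    residual_ss: float
    iterations: int
    residual_history: list[float] = field(default_factory=list)


def select_invariant_set(
    reference: np.ndarray,
    target: np.ndarray,
    rank_threshold: float = 0.05,
    max_iter: int = 10,
    min_probes: int = 5,
) -> np.ndarray:
    """Iteratively select probes with rank-stable intensity across two arrays.

    Probes whose proportional rank difference
    ``|rank_ref - rank_target| / n_retained`` is at or below
    ``rank_threshold`` are retained; ranks are recomputed within the
    retained set each iteration until a fixed point (or ``max_iter``).
    Returns the sorted indices of the invariant probes.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.shape != target.shape or reference.ndim != 1:
        raise ValueError("reference and target must be equal-length 1-D arrays")
    if len(reference) < 10:
        raise ValueError("invariant-set selection needs at least 10 probes")
    retained = np.arange(len(reference))
    for _ in range(max_iter):
        n = len(retained)
        prd = np.abs(rankdata(reference[retained]) - rankdata(target[retained])) / n
        keep = prd <= rank_threshold
        new = retained[keep]
        if len(new) < min_probes:
            raise ValueError(
                f"only {len(new)} probes survive invariant-set selection "
                f"(minimum {min_probes}); loosen rank_threshold"
            )
        if len(new) == len(retained):
            break
        retained = new
    return retained


def invariant_set_normalize(
    reference: np.ndarray, target: np.ndarray, invariant: np.ndarray
) -> np.ndarray:
    """Map all target probes onto the reference scale.

    The normalization curve pairs the order statistics of the invariant
    probes (invariant target values sorted against invariant reference
    values sorted), which makes the piecewise-linear map non-decreasing
    by construction, and interpolates between the pairs with linear
    extrapolation beyond the extremes.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.isfinite(reference).all() and np.isfinite(target).all()):
        raise ValueError("non-finite values in normalization input")
    x = np.sort(target[invariant])
    y = np.sort(reference[invariant])
    # collapse duplicated knot positions so interpolation is well defined
    x, first = np.unique(x, return_index=True)
    y = np.array([y[i] for i in first])
    if len(x) == 1:
        return target + (y[0] - x[0])
    out = np.interp(target, x, y)
    below = target < x[0]
    above = target > x[-1]
    slope_lo = (y[1] - y[0]) / (x[1] - x[0])
    slope_hi = (y[-1] - y[-2]) / (x[-1] - x[-2])
    out[below] = y[0] + slope_lo * (target[below] - x[0])
    out[above] = y[-1] + slope_hi * (target[above] - x[-1])
    return out


def _medians(matrices: Sequence[ExpressionMatrix]) -> np.ndarray:
    return np.array([float(np.median(m.values.to_numpy())) for m in matrices])


def choose_reference(matrices: Sequence[ExpressionMatrix]) -> int:
    """Index of the array whose median is closest to the grand median (ties: first)."""
    med = _medians(matrices)
    grand = float(np.median(med))
    return int(np.argmin(np.abs(med - grand)))


def rescale_to_common_median(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Multiply each matrix by a scalar so all medians equal the grand median.

    The grand median is the median of the per-matrix medians (midpoint
    convention for an even count). Relative values within a matrix are
    unchanged; a zero or negative median raises.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    med = _medians(matrices)
    if (med <= 0).any():
        raise ValueError(f"non-positive matrix median(s): {med[med <= 0]}")
    grand = float(np.median(med))
    out = []
    for m, mm in zip(matrices, med):
        out.append(
            ExpressionMatrix(m.values * (grand / mm), m.design, scale=m.scale, platform=m.platform)
        )
    return out


def mbei_summarize(
    probe_matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> MbeiFit:
    """Fit ``value[i, j] ~ phi[i] * theta[j]`` by alternating least squares.

    ``phi`` is rescaled every iteration to satisfy ``sum(phi^2) = n_probes``;
    convergence when the largest parameter change drops below ``tol``.
    ``theta`` is the per-array expression summary.
    """
    v = np.asarray(probe_matrix, dtype=float)
    if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 2:
        raise ValueError("probe matrix must be probes x arrays with >= 2 arrays")
    n_probes = v.shape[0]
    if not v.any():
        raise ValueError("all-zero probe matrix: MBEI fit is degenerate")
    phi = np.ones(n_probes)
    theta = phi @ v / n_probes
    history: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        theta_new = phi @ v / (phi @ phi)
        phi_new = v @ theta_new / (theta_new @ theta_new)
        scale = np.sqrt(n_probes / (phi_new @ phi_new))
        phi_new *= scale
        theta_new /= scale
        resid = float(((v - np.outer(phi_new, theta_new)) ** 2).sum())
        if history and resid > history[-1] + 1e-12:
            raise AssertionError("MBEI residual increased between iterations")
        history.append(resid)
        delta = max(np.max(np.abs(theta_new - theta)), np.max(np.abs(phi_new - phi)))
        phi, theta = phi_new, theta_new
        if delta < tol:
            break
    if phi.sum() < 0:  # sign convention: affinities mostly positive
        phi, theta = -phi, -theta
    return MbeiFit(theta=theta, phi=phi, residual_ss=history[-1], iterations=iterations,
                   residual_history=history)


def summarize_probesets(
    probe_values: pd.DataFrame, probe_to_set: Mapping[str, str], **mbei_kwargs
) -> pd.DataFrame:
    """MBEI-summarize a probe-level matrix into probeset x array indices."""
    missing = [p for p in probe_values.index if p not in probe_to_set]
    if missing:
        raise ValueError(f"probes missing from probe map: {missing[:10]}")
    groups: dict[str, list[str]] = {}
    for p in probe_values.index:
        groups.setdefault(probe_to_set[p], []).append(p)
    rows = {}
    for pset, probes in groups.items():
        fit = mbei_summarize(probe_values.loc[probes].to_numpy(), **mbei_kwargs)
        rows[pset] = fit.theta
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(probe_values.columns))
    _log.info("summarized %d probes into %d probesets", len(probe_values), len(out))
    return out
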