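"""RNA-seq RPKM stage analysis: fold-change filter and ln(RPKM+1) transform.

Two distinct pseudocounts are used and never conflated: 0.1 is added to
every RPKM value before the fold-change/significance filter, and 1.0 is
added before the natural-log transform used for plotting/averaging.
A gene passes the filter when its late/early mean ratio exceeds the
threshold (strictly) *and* the two-sided pooled t-test on the
pseudocounted replicate values reaches the alpha level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, get_logger
from .stagede import pooled_two_sample_t

__all__ = ["FoldChangeResult", "fold_change_filter", "ln_rpkm_transform"]

_log = get_logger("rpkmflow")


@dataclass
class FoldChangeResult:
    gene_id: str
    ratio: float
    p_value: float
    passed: bool


def fold_change_filter(
    rpkm: ExpressionMatrix,
    early_stage: str,
    late_stage: str,
    pseudocount: float = 0.1,
    fc_threshold: float = 5.0,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[FoldChangeResult]:
    """Flag genes upregulated more than ``fc_threshold``-fold with p <= alpha.

    ``ratio = mean(late + pseudocount) / mean(early + pseudocount)``;
    the p-value is from a two-sided pooled-variance t-test on the same
    pseudocounted values. "More than" is strict: ratio must exceed the
    threshold. Both stages need at least two replicates.
    """
    values = rpkm.values.to_numpy(float)
    if (values < 0).any():
        raise ValueError("RPKM values must be non-negative")
    early = rpkm.stage_values(early_stage).to_numpy(float) + pseudocount
    late = rpkm.stage_values(late_stage).to_numpy(float) + pseudocount
    if early.shape[1] < 2 or late.shape[1] < 2:
        raise ValueError("both stages need at least two replicates")
    ratio = late.mean(axis=1) / early.mean(axis=1)
    _, _, _, p = pooled_two_sample_t(late, early, equal_var=equal_var)
    passed = (ratio > fc_threshold) & (p <= alpha)
    results = [
        FoldChangeResult(g, float(ratio[i]), float(p[i]), bool(passed[i]))
        for i, g in enumerate(rpkm.feature_ids)
    ]
    _log.info("%s -> %s: %d / %d genes pass (> %g-fold, p <= %g)",
              early_stage, late_stage, int(passed.sum()), len(results), fc_threshold, alpha)
    return results


def ln_rpkm_transform(rpkm: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """``value -> ln(value + 1)`` plus per-stage averages on the transformed scale."""
    if (rpkm.values.to_numpy(float) < 0).any():
        raise ValueError("RPKM values must be non-negative")
    transformed = ExpressionMatrix(
        np.log1p(rpkm.values), rpkm.design, scale="ln_rpkm_plus1", platform=rpkm.platform
    )
    return transformed, transformed.stage_averages()
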