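"""TaqMan Ct processing: -dCt, detection-floor imputation, stage tests.

Expression is quantified as -dCt = -(Ct_gene - mean Ct of the endogenous
controls in the same sample), so higher means more transcript and sample
offsets cancel. Undetected wells enter the calculation with Ct = 40.0
(the cycle ceiling) and are then floored: every undetected cell is set
to the lowest -dCt calculated among detected cells of the same protocol
run. Two deliberately different downstream policies follow:

* t-tests between stages *include* the floored values;
* plotting averages *exclude* undetected replicates, unless every
  replicate of a (assay, stage) cell is undetected, in which case the
  average is the floor itself.

Stage-pair comparisons use the two-sided Student t-test (pooled
variance) on -dCt replicate values, skipped when fewer than two
replicates were detected in either stage; significance is judged on the
raw p-value (no FDR), the qPCR-side policy of the study design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CtTable, StageDesign, get_logger
from .stagede import TransitionResult, pooled_two_sample_t

__all__ = [
    "NegDeltaCtTable",
    "neg_delta_ct",
    "impute_undetected",
    "stage_averages",
    "stage_pair_tests",
]

_log = get_logger("qpcr")

#: Ct assigned to wells where no amplification was called
UNDETECTED_CT = 40.0


@dataclass
class NegDeltaCtTable:
    """Assay x sample -dCt values with an imputation mask.

    ``imputed`` marks cells that were undetected; after
    :func:`impute_undetected` they all hold ``floor_value``, the lowest
    -dCt calculated from a detected well in this protocol run
    (``floor_value`` is None before imputation). Control assays are kept
    in the table but excluded from the floor computation — their -dCt is
    definitionally near zero.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame
    design: StageDesign
    protocol: str = "default"
    control_assays: tuple[str, ...] = ()
    floor_value: float | None = None

    def detected_mask(self) -> pd.DataFrame:
        return ~self.imputed


def neg_delta_ct(
    ct: CtTable,
    control_assays: Sequence[str],
    undetected_ct: float = UNDETECTED_CT,
) -> NegDeltaCtTable:
    """-dCt against the per-sample mean of the endogenous controls.

    Undetected wells are computed with Ct = ``undetected_ct`` and flagged
    for imputation. A control undetected in any sample is an error naming
    the sample.
    """
    missing = [c for c in control_assays if c not in ct.ct.index]
    if missing:
        raise ValueError(f"control assay(s) not in table: {missing}")
    ctrl_det = ct.detected.loc[list(control_assays)]
    if not ctrl_det.all().all():
        bad = [col for col in ctrl_det.columns if not ctrl_det[col].all()]
        raise ValueError(f"endogenous control undetected in sample(s): {bad}")
    filled = ct.ct.where(ct.detected, undetected_ct)
    ctrl_mean = filled.loc[list(control_assays)].mean(axis=0)
    values = -(filled - ctrl_mean)
    imputed = ~ct.detected
    return NegDeltaCtTable(
        values, imputed, ct.design, protocol=ct.protocol,
        control_assays=tuple(control_assays),
    )


def impute_undetected(table: NegDeltaCtTable) -> NegDeltaCtTable:
    """Set every undetected cell to the protocol's detected minimum -dCt."""
    non_control = table.values.index.difference(table.control_assays)
    detected_vals = table.values.loc[non_control].where(table.detected_mask().loc[non_control])
    if detected_vals.notna().sum().sum() == 0:
        raise ValueError("no detected cells: cannot derive an imputation floor")
    floor = float(detected_vals.min().min())
    values = table.values.where(table.detected_mask(), floor)
    _log.info("protocol %s: imputation floor -dCt = %.4g (%d cells imputed)",
              table.protocol, floor, int(table.imputed.to_numpy().sum()))
    return NegDeltaCtTable(
        values, table.imputed.copy(), table.design, protocol=table.protocol,
        control_assays=table.control_assays, floor_value=floor,
    )


def stage_averages(table: NegDeltaCtTable) -> pd.DataFrame:
    """Per-(assay, stage) plotting averages over *detected* replicates.

    A cell whose replicates were all undetected gets the floor value.
    Requires an imputed table (floor known).
    """
    if table.floor_value is None:
        raise ValueError("stage_averages needs an imputed table (run impute_undetected)")
    out = {}
    for stage in table.design.stages:
        cols = table.design.stage_columns(stage)
        detected = table.values[cols].where(table.detected_mask()[cols])
        out[stage] = detected.mean(axis=1).fillna(table.floor_value)
    return pd.DataFrame(out)


def stage_pair_tests(
    table: NegDeltaCtTable,
    pairs: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    min_detected: int = 2,
) -> list[TransitionResult]:
    """Student t-tests on -dCt between stage pairs (default: consecutive pairs).

    Floored (imputed) values are included in the test; an assay is
    skipped for a pair when either stage has fewer than ``min_detected``
    detected replicates. q_value is None — significance here is on the
    raw p-value.
    """
    if table.floor_value is None:
        raise ValueError("stage_pair_tests needs an imputed table (run impute_undetected)")
    if pairs is None:
        pairs = table.design.consecutive_pairs()
    for earlier, later in pairs:
        for s in (earlier, later):
            if s not in table.design.stages:
                raise ValueError(f"unknown stage {s!r}")
    assays = list(table.values.index)
    results: list[TransitionResult] = []
    for earlier, later in pairs:
        ce = table.design.stage_columns(earlier)
        cl = table.design.stage_columns(later)
        det_e = table.detected_mask()[ce].sum(axis=1).to_numpy()
        det_l = table.detected_mask()[cl].sum(axis=1).to_numpy()
        ok = (det_e >= min_detected) & (det_l >= min_detected)
        lfc, t, df, p = pooled_two_sample_t(
            table.values[cl].to_numpy(float), table.values[ce].to_numpy(float),
            equal_var=equal_var,
        )
        for i, assay in enumerate(assays):
            if ok[i]:
                results.append(
                    TransitionResult(assay, (earlier, later), log_fc=float(lfc[i]),
                                     t_stat=float(t[i]), df=float(df[i]),
                                     p_value=float(p[i]), q_value=None, status="tested")
                )
            else:
                results.append(TransitionResult(assay, (earlier, later), status="skipped"))
    n_sig = sum(r.significant(alpha) for r in results)
    _log.info("qPCR: %d stage-pair tests, %d significant at p<=%.3g", len(results), n_sig, alpha)
    return results
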