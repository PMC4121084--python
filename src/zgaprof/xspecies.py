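"""Cross-species ortholog concordance, stage correlations, clustering.

Given a human gene's expression class (UP / UP_DOWN / DOWN) and the
stage-transition evidence of its mouse ortholog over (MII, 1-cell,
2-cell, 8-cell), the ortholog is judged:

* **SIMILAR** — the mouse gene reproduces the human behaviour at the
  mouse ZGA: a significant 1-cell -> 2-cell increase (UP); the increase
  plus a significant 2-cell -> 8-cell decrease (UP_DOWN); or, for DOWN,
  at least one significant decreasing transition and no significant
  increase over the course of preimplantation development.
* **DIFFERENT_MATERNAL** — the human pattern is not reproduced but the
  mouse ortholog decays like a maternal transcript (a significant
  decrease by the 8-cell stage).
* **UNCLASSIFIED** — no evidence either way.

An optional relaxation accepts up-without-down as SIMILAR for UP_DOWN
orthologs (some transiently activated genes reach significance only on
the rising flank); it is off by default and divergences are logged.

Stage-matched Pearson correlations and complete-linkage hierarchical
clustering (Euclidean distance) support the heatmap-style comparison of
per-stage average profiles between platforms and species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr

from .core_io import OrthologMap, get_logger
from .profclass import DOWN, UNCLASSIFIED, UP, UP_DOWN
from .stagede import TransitionResult

__all__ = [
    "SIMILAR",
    "DIFFERENT_MATERNAL",
    "ConcordanceCall",
    "map_orthologs",
    "classify_concordance",
    "pearson_stage_correlation",
    "hierarchical_cluster",
]

SIMILAR = "SIMILAR"
DIFFERENT_MATERNAL = "DIFFERENT_MATERNAL"

_log = get_logger("xspecies")


@dataclass
class ConcordanceCall:
    human_gene: str
    mouse_gene: str
    human_class: str
    verdict: str
    evidence: list[tuple[tuple[str, str], str, float]] = field(default_factory=list)


def map_orthologs(
    gene_calls: Mapping[str, str], omap: OrthologMap
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Inner-join gene classes with the ortholog map.

    Returns ``(records, dropped)`` where each record is
    ``(human_gene, mouse_gene, human_class)`` — one per ortholog pair, so
    1:many human genes yield several records — and ``dropped`` lists
    human genes without any ortholog.
    """
    by_human: dict[str, list[str]] = {}
    for h, m in omap.pairs:
        by_human.setdefault(h, []).append(m)
    records: list[tuple[str, str, str]] = []
    dropped: list[str] = []
    for gene, call in gene_calls.items():
        partners = by_human.get(gene)
        if not partners:
            dropped.append(gene)
            continue
        records.extend((gene, m, call) for m in partners)
    if dropped:
        _log.info("%d human gene(s) without mouse ortholog dropped", len(dropped))
    return records, dropped


def _sig_transitions(
    transitions: Sequence[TransitionResult], alpha: float
) -> tuple[list[TransitionResult], list[TransitionResult]]:
    ups = [t for t in transitions if t.significant(alpha, use_q=False) and t.log_fc > 0]
    downs = [t for t in transitions if t.significant(alpha, use_q=False) and t.log_fc < 0]
    return ups, downs


def classify_concordance(
    human_class: str,
    mouse_transitions: Sequence[TransitionResult],
    alpha: float = 0.05,
    zga_pair: tuple[str, str] = ("1-cell", "2-cell"),
    decline_pair: tuple[str, str] = ("2-cell", "8-cell"),
    relax_up_down: bool = False,
    human_gene: str = "",
    mouse_gene: str = "",
) -> ConcordanceCall:
    """Judge one ortholog pair from the mouse transition evidence.

    ``mouse_transitions`` must cover ``zga_pair`` and ``decline_pair``
    (skipped results are allowed and count as non-significant).
    Significance is on the raw p-value, the qPCR-side policy.
    """
    present = {t.stage_pair for t in mouse_transitions}
    for pair in (zga_pair, decline_pair):
        if pair not in present:
            raise ValueError(f"missing mouse transition {pair}")
    if human_class not in (UP, UP_DOWN, DOWN):
        raise ValueError(f"human class must be UP/UP_DOWN/DOWN, got {human_class!r}")
    ups, downs = _sig_transitions(mouse_transitions, alpha)
    up_zga = any(t.stage_pair == zga_pair for t in ups)
    down_late = any(t.stage_pair == decline_pair for t in downs)

    similar = False
    if human_class == UP:
        similar = up_zga
    elif human_class == UP_DOWN:
        similar = up_zga and down_late
        if not similar and relax_up_down and up_zga:
            similar = True
            _log.info("UP_DOWN relaxation applied: %s/%s up without down", human_gene, mouse_gene)
    elif human_class == DOWN:
        similar = bool(downs) and not ups

    evidence = [
        (t.stage_pair, "up" if t.log_fc > 0 else "down", t.p_value) for t in ups + downs
    ]
    if similar:
        verdict = SIMILAR
    elif downs:  # maternal decay: a significant decrease by the 8-cell stage
        verdict = DIFFERENT_MATERNAL
    else:
        verdict = UNCLASSIFIED
    return ConcordanceCall(human_gene, mouse_gene, human_class, verdict, evidence)


def pearson_stage_correlation(
    averages_a: pd.DataFrame,
    averages_b: pd.DataFrame,
    matched_features: Sequence[tuple[str, str]],
    stage_pairs: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], float]:
    """Pearson r between matched per-stage average vectors.

    ``averages_*`` are features x stages frames; ``matched_features``
    pairs a row of A with a row of B (e.g. human gene with its mouse
    ortholog). A zero-variance vector makes r undefined: reported as NaN
    with a warning.
    """
    if len(matched_features) < 3:
        raise ValueError("need at least 3 matched features per correlation")
    rows_a = [a for a, _ in matched_features]
    rows_b = [b for _, b in matched_features]
    out: dict[tuple[str, str], float] = {}
    for sa, sb in stage_pairs:
        x = averages_a.loc[rows_a, sa].to_numpy(float)
        y = averages_b.loc[rows_b, sb].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero variance in stage pair ({sa}, {sb}); correlation undefined",
                          stacklevel=2)
            out[(sa, sb)] = float("nan")
            continue
        out[(sa, sb)] = float(pearsonr(x, y).statistic)
    return out


def hierarchical_cluster(
    matrix: pd.DataFrame, k: int, method: str = "complete", metric: str = "euclidean"
) -> tuple[list[str], dict[str, int]]:
    """Agglomerative clustering of per-stage average profiles.

    Complete linkage on Euclidean distances by default (the convention
    of standard heatmap-drawing routines). Returns the deterministic
    dendrogram leaf order (ties resolved by input index) and the k-cut
    cluster label per feature.
    """
    values = matrix.to_numpy(float)
    if len(matrix) < 2:
        raise ValueError("need at least 2 features to cluster")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in clustering input")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds feature count {len(matrix)}")
    link = hierarchy.linkage(values, method=method, metric=metric)
    order = [matrix.index[i] for i in hierarchy.leaves_list(link)]
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return order, {f: int(l) for f, l in zip(matrix.index, labels)}
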