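"""Expression-profile classification: "Up", "Up-down", "Down".

A feature's significant stage transitions are turned into one of three
developmental profiles:

* **UP** — a significant increase into the ZGA window (the stages at
  which the embryonic genome switches on) with no later significant
  decrease: an embryonically activated gene.
* **UP_DOWN** — a significant increase into the ZGA window followed by a
  significant decrease into the late window: transiently activated.
* **DOWN** — a significant decrease into the late window with no earlier
  significant increase: a degrading maternal transcript.
* **UNCLASSIFIED** otherwise.

Because a feature that rises and then falls satisfies both the Up and
Down sub-rules, precedence is UP_DOWN > UP > DOWN (Up-down is the only
class that requires both signals).

Calls from two independent datasets are intersected — a feature is kept
only when both datasets assign the same non-UNCLASSIFIED class — and
probe-level calls are collapsed to genes, with conflicting-probe genes
flagged ambiguous and excluded from class counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import StageDesign, get_logger
from .stagede import TransitionResult

__all__ = [
    "UP",
    "UP_DOWN",
    "DOWN",
    "UNCLASSIFIED",
    "ProfileCall",
    "GeneCollapse",
    "classify_profile",
    "classify_all",
    "intersect_datasets",
    "collapse_probes_to_genes",
]

UP = "UP"
UP_DOWN = "UP_DOWN"
DOWN = "DOWN"
UNCLASSIFIED = "UNCLASSIFIED"

_log = get_logger("profclass")


@dataclass
class ProfileCall:
    feature_id: str
    call: str
    evidence: list[tuple[tuple[str, str], str, float]] = field(default_factory=list)


def _ordered(transitions: Sequence[TransitionResult], design: StageDesign) -> list[TransitionResult]:
    pairs = design.consecutive_pairs()
    order = {p: i for i, p in enumerate(pairs)}
    unknown = [t for t in transitions if t.stage_pair not in order]
    if unknown:
        raise ValueError(f"transitions {sorted({t.stage_pair for t in unknown})} "
                         f"are not consecutive pairs of the design")
    return sorted(transitions, key=lambda t: order[t.stage_pair])


def classify_profile(
    transitions: Sequence[TransitionResult],
    design: StageDesign,
    zga_window: Sequence[str],
    late_window: Sequence[str],
    alpha: float = 0.05,
    use_q: bool = True,
) -> ProfileCall:
    """Classify one feature from its consecutive-stage transitions.

    ``zga_window`` are the stages a significant increase into which counts
    as embryonic activation; ``late_window`` the stages a significant
    decrease into which counts as degradation. Significance is on the BH
    q-value when present (``use_q``), otherwise the raw p-value.
    The result is a pure function of the evidence: input order of
    ``transitions`` does not matter.
    """
    for w, name in ((zga_window, "zga_window"), (late_window, "late_window")):
        bad = set(w) - set(design.stages)
        if bad:
            raise ValueError(f"{name} stages {sorted(bad)} not in design")
    ts = _ordered(transitions, design)
    sig = [t.significant(alpha, use_q=use_q) for t in ts]
    ups_zga = [i for i, t in enumerate(ts) if sig[i] and t.log_fc > 0 and t.stage_pair[1] in zga_window]
    downs = [i for i, t in enumerate(ts) if sig[i] and t.log_fc < 0]
    downs_late = [i for i in downs if ts[i].stage_pair[1] in late_window]
    ups = [i for i, t in enumerate(ts) if sig[i] and t.log_fc > 0]

    evidence = [
        (ts[i].stage_pair, "up" if ts[i].log_fc > 0 else "down",
         ts[i].q_value if (use_q and ts[i].q_value is not None) else ts[i].p_value)
        for i in range(len(ts)) if sig[i]
    ]
    feature = ts[0].feature_id if ts else ""

    if ups_zga and any(j > i for i in ups_zga for j in downs_late):
        return ProfileCall(feature, UP_DOWN, evidence)
    if ups_zga and not any(j > min(ups_zga) for j in downs):
        return ProfileCall(feature, UP, evidence)
    if any(all(i > j for i in ups) for j in downs_late):
        return ProfileCall(feature, DOWN, evidence)
    return ProfileCall(feature, UNCLASSIFIED, evidence)


def classify_all(
    transitions: Sequence[TransitionResult],
    design: StageDesign,
    zga_window: Sequence[str],
    late_window: Sequence[str],
    alpha: float = 0.05,
    use_q: bool = True,
) -> list[ProfileCall]:
    """Classify every feature appearing in a flat transition list."""
    by_feature: dict[str, list[TransitionResult]] = {}
    for t in transitions:
        by_feature.setdefault(t.feature_id, []).append(t)
    return [
        classify_profile(ts, design, zga_window, late_window, alpha=alpha, use_q=use_q)
        for ts in by_feature.values()
    ]


def intersect_datasets(
    calls_a: Sequence[ProfileCall], calls_b: Sequence[ProfileCall]
) -> list[ProfileCall]:
    """Consensus calls: features with the same non-UNCLASSIFIED class in both datasets."""
    b_by_id = {c.feature_id: c for c in calls_b}
    consensus: list[ProfileCall] = []
    for a in calls_a:
        b = b_by_id.get(a.feature_id)
        if b is None or a.call == UNCLASSIFIED or a.call != b.call:
            continue
        consensus.append(ProfileCall(a.feature_id, a.call, a.evidence + b.evidence))
    counts = {c: sum(1 for x in consensus if x.call == c) for c in (UP, UP_DOWN, DOWN)}
    _log.info("consensus features per class: %s", counts)
    return consensus


@dataclass
class GeneCollapse:
    """Gene-level calls plus the probes-per-class / genes-per-class tallies."""

    gene_calls: dict[str, str]
    ambiguous_genes: list[str]
    probe_counts: dict[str, int]
    gene_counts: dict[str, int]


def collapse_probes_to_genes(
    calls: Sequence[ProfileCall], probe_to_gene: Mapping[str, str]
) -> GeneCollapse:
    """Collapse consensus probe calls to gene calls.

    A gene takes class C when at least one of its probes is called C; a
    gene whose probes disagree is flagged ambiguous and excluded from the
    per-class gene counts. Probes absent from the map raise.
    """
    missing = [c.feature_id for c in calls if c.feature_id not in probe_to_gene]
    if missing:
        raise ValueError(f"probes missing from probe->gene map: {missing}")
    by_gene: dict[str, set[str]] = {}
    for c in calls:
        if c.call == UNCLASSIFIED:
            continue
        by_gene.setdefault(probe_to_gene[c.feature_id], set()).add(c.call)
    gene_calls: dict[str, str] = {}
    ambiguous: list[str] = []
    for gene, classes in by_gene.items():
        if len(classes) == 1:
            gene_calls[gene] = next(iter(classes))
        else:
            ambiguous.append(gene)
    probe_counts = {c: sum(1 for x in calls if x.call == c) for c in (UP, UP_DOWN, DOWN)}
    gene_counts = {c: sum(1 for v in gene_calls.values() if v == c) for c in (UP, UP_DOWN, DOWN)}
    _log.info("collapse: probes %s -> genes %s (%d ambiguous)",
              probe_counts, gene_counts, len(ambiguous))
    return GeneCollapse(gene_calls, sorted(ambiguous), probe_counts, gene_counts)
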