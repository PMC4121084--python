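"""Synthetic two-species preimplantation studies with planted ground truth.

Every downstream stage of the pipeline (normalization, stage-transition
differential expression, profile classification, qPCR processing, RPKM
filtering, cross-species concordance) can be exercised on the output of
:func:`simulate_study` without any external download.

Genes are planted in one of four archetypes on the log2 scale:

``up``
    step increase at the zygotic-genome-activation (ZGA) stage that
    persists to the last profiled stage;
``up_down``
    step up at ZGA, back to baseline by the final stage;
``down``
    maternal profile — high in the oocyte, stepping down once maternal
    transcripts are degraded;
``flat``
    constant (the null archetype).

The ZGA stage defaults to 4-cell in human and 2-cell in mouse. Replicate
values are template + per-gene baseline + Gaussian noise; arrays add a
per-probe affinity offset, qPCR inverts expression into Ct cycles with a
detection limit, and RPKM matrices are non-negative linear values.
Discordant mouse orthologs receive the maternal (down) template
regardless of their human archetype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CtTable,
    ExpressionMatrix,
    OrthologMap,
    StageDesign,
    write_ct_table,
    write_expression_matrix,
    write_ortholog_map,
)

__all__ = [
    "ARCHETYPES",
    "SimConfig",
    "SimulatedStudy",
    "profile_template",
    "expression_to_ct",
    "simulate_study",
    "write_study",
]

ARCHETYPES = ("up", "up_down", "down", "flat")

#: default ZGA stage per naming convention: human 4-cell, mouse 2-cell
_ZGA_CANDIDATES = ("4-cell", "2-cell")

HUMAN_ARRAY_A_DESIGN = StageDesign(["MII", "4-cell", "8-cell", "blastocyst"], 3, species="human")
HUMAN_ARRAY_B_DESIGN = StageDesign(["1-cell", "4-cell", "8-cell", "blastocyst"], 3, species="human")
MOUSE_CT_DESIGN = StageDesign(["MII", "1-cell", "2-cell", "8-cell"], 3, species="mouse")
HUMAN_RPKM_DESIGN = StageDesign(["oocyte", "4-cell", "8-cell", "morula"], 3, species="human")
MOUSE_RPKM_DESIGN = StageDesign(["oocyte", "1-cell", "2-cell", "8-cell"], 3, species="mouse")

#: control assays planted in the simulated Ct tables (stably expressed)
CONTROL_ASSAYS = ("Hprt1", "Psmb6")
_CONTROL_LOG2 = 8.0


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated study.

    Defaults mirror the profiled designs: two independent human array
    datasets (MII/1-cell, 4-cell, 8-cell, blastocyst; 3 replicates),
    a mouse TaqMan run (MII, 1-cell, 2-cell, 8-cell) and RPKM matrices
    for both species. ``effect_log2`` is the archetype step size (2.0,
    a 4-fold change), ``noise_sd_log2`` the replicate noise (0.25).
    ``ct_intercept`` is the cycle number corresponding to log2-expression
    zero and ``ct_limit`` the detection limit (40 cycles).
    """

    seed: int = 0
    n_per_archetype: int = 100
    archetypes: tuple[str, ...] = ARCHETYPES
    human_design_a: StageDesign = HUMAN_ARRAY_A_DESIGN
    human_design_b: StageDesign = HUMAN_ARRAY_B_DESIGN
    mouse_design: StageDesign = MOUSE_CT_DESIGN
    human_rpkm_design: StageDesign = HUMAN_RPKM_DESIGN
    mouse_rpkm_design: StageDesign = MOUSE_RPKM_DESIGN
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.25
    probe_affinity_sd: float = 0.3
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    ct_intercept: float = 40.0
    ct_limit: float = 40.0
    rpkm_floor: float = 1.0
    concordant_fraction: float = 0.6
    human_zga_stage: str = "4-cell"
    mouse_zga_stage: str = "2-cell"
    #: stage at which the human maternal (down) template drops; human
    #: maternal transcripts persist through ZGA onset and are degraded
    #: by the 8-cell stage, unlike the mouse where the drop coincides
    #: with ZGA at 2-cell.
    human_down_stage: str = "8-cell"
    max_probes_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd_log2 < 0 or self.probe_affinity_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0.0 <= self.concordant_fraction <= 1.0:
            raise ValueError("concordant_fraction must lie in [0, 1]")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")


@dataclass
class SimulatedStudy:
    """All matrices of one simulated study plus the planted truth table.

    ``truth`` has one row per gene: human/mouse gene IDs, the planted
    human archetype, the mouse archetype actually planted, and the
    concordance label (``similar`` / ``different_maternal``; empty for
    flat genes, where concordance is not defined).
    """

    config: SimConfig
    human_array_a: ExpressionMatrix
    human_array_b: ExpressionMatrix
    mouse_ct: CtTable
    human_rpkm: ExpressionMatrix
    mouse_rpkm: ExpressionMatrix
    ortholog_map: OrthologMap
    truth: pd.DataFrame
    probe_to_gene: dict[str, str] = field(default_factory=dict)


def _zga_index(stages: Sequence[str], zga_stage: str | None) -> int:
    if zga_stage is None:
        for cand in _ZGA_CANDIDATES:
            if cand in stages:
                zga_stage = cand
                break
        else:
            zga_stage = stages[1]
    if zga_stage not in stages:
        raise ValueError(f"ZGA stage {zga_stage!r} not among stages {list(stages)}")
    return list(stages).index(zga_stage)


def profile_template(
    archetype: str,
    stages: Sequence[str],
    effect_log2: float,
    zga_stage: str | None = None,
    down_stage: str | None = None,
) -> np.ndarray:
    """Per-stage mean log2 offsets for one archetype.

    ``zga_stage`` defaults to 4-cell if present, else 2-cell, else the
    second stage. ``down_stage`` — the stage at which the maternal
    template drops — defaults to the ZGA stage.
    """
    stages = list(stages)
    if len(stages) < 3:
        raise ValueError("profile templates need at least 3 stages")
    z = _zga_index(stages, zga_stage)
    idx = np.arange(len(stages))
    if archetype == "up":
        return np.where(idx >= z, effect_log2, 0.0)
    if archetype == "up_down":
        return np.where((idx >= z) & (idx < len(stages) - 1), effect_log2, 0.0)
    if archetype == "down":
        d = z if down_stage is None else _zga_index(stages, down_stage)
        return np.where(idx < d, effect_log2, 0.0)
    if archetype == "flat":
        return np.zeros(len(stages))
    raise ValueError(f"unknown archetype {archetype!r}")


def expression_to_ct(
    log2_expr: np.ndarray | float, ct_intercept: float, ct_limit: float
) -> tuple[np.ndarray, np.ndarray]:
    """Invert log2 expression into qPCR cycle numbers.

    One cycle corresponds to one doubling: ``ct = ct_intercept - log2_expr``.
    Cells reaching the detection limit (``ct >= ct_limit``) are undetected
    and carry no Ct value (NaN).
    """
    log2_expr = np.asarray(log2_expr, dtype=float)
    ct = ct_intercept - log2_expr
    detected = ct < ct_limit
    return np.where(detected, ct, np.nan), detected


def _stage_matrix(
    rng: np.random.Generator,
    design: StageDesign,
    templates: np.ndarray,  # genes x stages
    baselines: np.ndarray,
    noise_sd: float,
) -> np.ndarray:
    """Replicate-level log2 values: template + baseline + N(0, noise_sd)."""
    cols = []
    for j, stage in enumerate(design.stages):
        n = design.replicate_count[stage]
        means = templates[:, j] + baselines
        cols.append(means[:, None] + rng.normal(0.0, noise_sd, size=(len(baselines), n)))
    return np.concatenate(cols, axis=1)


def _templates_for(
    archetypes: Sequence[str],
    design: StageDesign,
    effect: float,
    zga_stage: str,
    down_stage: str | None = None,
) -> np.ndarray:
    cache = {
        a: profile_template(a, design.stages, effect, zga_stage=zga_stage, down_stage=down_stage)
        for a in set(archetypes)
    }
    return np.vstack([cache[a] for a in archetypes])


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate one reproducible study under ``config``.

    One root seed; each matrix draws from its own deterministically
    derived substream, so adding a matrix type does not perturb the
    others. Gene-level properties (baseline, probe multiplicity,
    concordance flags) come from substream 0.
    """
    streams = {k: np.random.default_rng([config.seed, i]) for i, k in enumerate(
        ["genes", "array_a", "array_b", "mouse_ct", "human_rpkm", "mouse_rpkm"]
    )}
    g = streams["genes"]

    n_genes = config.n_per_archetype * len(config.archetypes)
    width = len(str(n_genes))
    human_genes = [f"HG{i:0{width}d}" for i in range(1, n_genes + 1)]
    mouse_genes = [f"mg{i:0{width}d}" for i in range(1, n_genes + 1)]
    archetypes = [a for a in config.archetypes for _ in range(config.n_per_archetype)]

    baselines = g.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    concordant = g.random(n_genes) < config.concordant_fraction
    # discordance is only observable for genes the human embryo activates;
    # maternal (down) genes keep the same profile either way and flat genes
    # have no concordance notion.
    mouse_archetypes: list[str] = []
    labels: list[str] = []
    for i, a in enumerate(archetypes):
        if a in ("up", "up_down"):
            if concordant[i]:
                mouse_archetypes.append(a)
                labels.append("similar")
            else:
                mouse_archetypes.append("down")
                labels.append("different_maternal")
        elif a == "down":
            concordant[i] = True
            mouse_archetypes.append("down")
            labels.append("similar")
        else:
            concordant[i] = True
            mouse_archetypes.append("flat")
            labels.append("")

    # probe layer shared by both array datasets (same platform)
    probes_per_gene = g.integers(1, config.max_probes_per_gene + 1, n_genes)
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    for i, k in enumerate(probes_per_gene):
        for p in range(1, k + 1):
            probe_ids.append(f"{human_genes[i]}_p{p}")
            probe_gene_idx.append(i)
    probe_gene_idx = np.asarray(probe_gene_idx)
    affinities = g.normal(0.0, config.probe_affinity_sd, len(probe_ids))

    def array_matrix(design: StageDesign, stream: np.random.Generator) -> ExpressionMatrix:
        tmpl = _templates_for(
            archetypes, design, config.effect_log2, config.human_zga_stage,
            down_stage=config.human_down_stage,
        )
        vals = _stage_matrix(
            stream, design, tmpl[probe_gene_idx], baselines[probe_gene_idx] + affinities,
            config.noise_sd_log2,
        )
        frame = pd.DataFrame(vals, index=probe_ids, columns=design.sample_names())
        return ExpressionMatrix(frame, design, scale="log2", platform="array")

    human_array_a = array_matrix(config.human_design_a, streams["array_a"])
    human_array_b = array_matrix(config.human_design_b, streams["array_b"])

    # mouse TaqMan: per-gene assays plus stable endogenous controls
    mt = _templates_for(mouse_archetypes, config.mouse_design, config.effect_log2, config.mouse_zga_stage)
    mexpr = _stage_matrix(streams["mouse_ct"], config.mouse_design, mt, baselines, config.noise_sd_log2)
    ctrl = _stage_matrix(
        streams["mouse_ct"], config.mouse_design,
        np.zeros((len(CONTROL_ASSAYS), len(config.mouse_design.stages))),
        np.full(len(CONTROL_ASSAYS), _CONTROL_LOG2), config.noise_sd_log2,
    )
    ct_vals, detected = expression_to_ct(
        np.vstack([mexpr, ctrl]), config.ct_intercept, config.ct_limit
    )
    ct_frame = pd.DataFrame(
        ct_vals, index=mouse_genes + list(CONTROL_ASSAYS), columns=config.mouse_design.sample_names()
    )
    det_frame = pd.DataFrame(detected, index=ct_frame.index, columns=ct_frame.columns)
    mouse_ct = CtTable(ct_frame, det_frame, config.mouse_design, protocol="simulated-12ng-random-hexamer")

    def rpkm_matrix(
        design: StageDesign, stream: np.random.Generator, archs: Sequence[str],
        ids: Sequence[str], zga: str, down_stage: str | None,
    ) -> ExpressionMatrix:
        tmpl = _templates_for(archs, design, config.effect_log2, zga, down_stage=down_stage)
        log2v = _stage_matrix(stream, design, tmpl, baselines, config.noise_sd_log2)
        linear = np.clip(np.exp2(log2v) - config.rpkm_floor, 0.0, None)
        frame = pd.DataFrame(linear, index=list(ids), columns=design.sample_names())
        return ExpressionMatrix(frame, design, scale="linear", platform="rpkm")

    human_rpkm = rpkm_matrix(
        config.human_rpkm_design, streams["human_rpkm"], archetypes, human_genes,
        config.human_zga_stage, config.human_down_stage,
    )
    mouse_rpkm = rpkm_matrix(
        config.mouse_rpkm_design, streams["mouse_rpkm"], mouse_archetypes, mouse_genes,
        config.mouse_zga_stage, None,
    )

    truth = pd.DataFrame(
        {
            "human_gene": human_genes,
            "mouse_gene": mouse_genes,
            "archetype": archetypes,
            "mouse_archetype": mouse_archetypes,
            "concordant": concordant,
            "concordance": labels,
        }
    ).set_index("human_gene", drop=False)

    return SimulatedStudy(
        config=config,
        human_array_a=human_array_a,
        human_array_b=human_array_b,
        mouse_ct=mouse_ct,
        human_rpkm=human_rpkm,
        mouse_rpkm=mouse_rpkm,
        ortholog_map=OrthologMap(list(zip(human_genes, mouse_genes))),
        truth=truth,
        probe_to_gene={p: human_genes[i] for p, i in zip(probe_ids, probe_gene_idx)},
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write every matrix of a study as TSV plus ``truth.tsv`` and the probe map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(study.human_array_a, outdir / "human_array_A.tsv")
    write_expression_matrix(study.human_array_b, outdir / "human_array_B.tsv")
    write_ct_table(study.mouse_ct, outdir / "mouse_ct.tsv")
    write_expression_matrix(study.human_rpkm, outdir / "human_rpkm.tsv")
    write_expression_matrix(study.mouse_rpkm, outdir / "mouse_rpkm.tsv")
    write_ortholog_map(study.ortholog_map, outdir / "orthologs.tsv")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.Series(study.probe_to_gene, name="gene").rename_axis("probe").to_csv(
        outdir / "probe_map.tsv", sep="\t"
    )
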