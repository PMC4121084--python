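# Methods

## The analysis in one paragraph

Early embryos live off maternally deposited mRNA until the zygotic
genome activates (ZGA) — around the 4–8-cell stage in human and the
1–2-cell stage in mouse. Given stage × replicate expression tables, the
pipeline tests every feature between consecutive stages, condenses the
significant transitions into three profiles (Up = embryonically
activated, Up-down = transiently activated, Down = degrading maternal
transcript), requires agreement between two independent human datasets,
and then asks whether each gene's mouse ortholog reproduces the human
behaviour at the mouse ZGA or instead follows a maternal profile. A
synthetic-data generator plants these archetypes with known labels so
the whole chain is checkable end to end.

## Statistical model

**Transition tests.** Two-sided two-sample *t*-tests on replicate
values per consecutive stage pair. The default is the pooled-variance
Student test; Welch is available behind `equal_var=False`. A feature is
skipped for a pair when either stage has fewer than two usable
replicates; skipped rows carry no statistics. Degenerate inputs follow
the conventions t = 0, p = 1 for identical zero-variance groups and
|t| = inf, p = 0 for separated zero-variance groups.

**Variance moderation.** The moderated test assumes gene-wise sample
variances s²_g | σ²_g ~ σ²_g·χ²_{d_g}/d_g with a scaled-inverse-χ²
prior σ²_g ~ s₀²·d₀/χ²_{d₀}. (d₀, s₀²) are estimated by method of
moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of
Var(e) over the sampling term mean ψ′(d_g/2) is inverted through the
trigamma function (Newton iteration) to give d₀, and s₀² follows from
the mean of e. When the excess is non-positive the prior degrees of
freedom are infinite — capped at 10⁶ to keep arithmetic finite — and
s₀² is the arithmetic mean of the sample variances, matching the
reference R implementation of this estimator, against which the fit is
cross-checked in the test suite on a frozen fixture. Posterior variances
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) give a *t* on d_g + d₀ degrees of
freedom. With fewer than two positive variances the fit falls back to
the ordinary test with a warning.

**Multiple testing.** Benjamini–Hochberg step-up per stage-pair family
(all features of one transition form one family; a global family across
transitions is possible by correcting the pooled p-vector, but
per-transition families mirror per-comparison linear-model contrasts
and are the default). The microarray arm calls significance at
q ≤ 0.05; the qPCR and RPKM arms deliberately use raw p ≤ 0.05 — two
different policies, kept distinct throughout.

**Profile rules.** With a ZGA window (default 4-cell, 8-cell) and a
late window (default 8-cell, blastocyst): Up-down requires a
significant increase into the ZGA window followed (strictly later) by a
significant decrease into the late window; Up requires the increase
with no subsequent significant decrease; Down requires a significant
decrease into the late window with no significant increase before it.
Precedence Up-down > Up > Down, because a rise-then-fall satisfies both
single-signal sub-rules and Up-down is the only class requiring both.
Dataset intersection requires the same class in both datasets (not the
same significant transition — the looser reading; transitions may
differ, e.g. MII → 4-cell in one design and 1-cell → 4-cell in the
other, which is why the windows are parameters rather than constants).
A gene whose consensus probes disagree is reported ambiguous and
excluded from class counts rather than resolved by majority — conflicts
are surfaced, not hidden.

**qPCR policies.** −ΔCt = −(Ct_gene − mean Ct of controls) per sample;
undetected wells enter at Ct 40.0 and are floored to the minimum −ΔCt
calculated from detected, non-control wells of the same protocol run
(protocol is an attribute of the table because different cDNA-synthesis
runs have different floors). Floored values are *included* in the
stage-pair tests but *excluded* from plotting averages unless a cell's
replicates are all undetected, in which case the average is the floor.
Control rows stay in the table but never define the floor — their −ΔCt
is near zero by construction.

**Concordance rules.** For a human Up gene the mouse ortholog is
SIMILAR iff its 1-cell → 2-cell increase is significant; Up-down
additionally requires a significant 2-cell → 8-cell decrease (a
configurable relaxation accepts up-without-down, off by default, for
genes that reach significance only on the rising flank); Down requires
at least one significant decreasing transition and no significant
increase — the alternative single test of MII vs 8-cell is deliberately
not the default because it conflates early and late decay. Failing
these, any significant decrease (all mouse stages are at or before
8-cell) marks the maternal profile DIFFERENT_MATERNAL; otherwise
UNCLASSIFIED. Because UNCLASSIFIED pairs are neither similar nor
demonstrably maternal, summary tallies report all three counts rather
than folding the unclassified into either side. Verdicts for 1:many
ortholog maps are per pair, never aggregated to the human gene.

**Array preprocessing.** Between-array normalization selects the
rank-invariant probe set (proportional rank difference at or below the
threshold, default 0.05, re-ranked within the retained set until a
fixed point) and maps the target onto the reference through the paired
order statistics of the invariant probes — a non-decreasing
piecewise-linear curve with linear extrapolation at the ends. The
reference array is the one whose median is closest to the grand median
(ties: first in input order; the choice is logged). Arrays are then
rescaled to the common grand median and probe sets summarized by the
model-based expression index value[i,j] ≈ φ_i·θ_j, fitted by
alternating least squares under Σφ² = n_probes, residual checked to be
non-increasing every iteration. The original procedure's probe/array
outlier rejection is omitted: it adds unverifiable complexity at this
scale and the fit is already exact on rank-1 structure.

**RPKM arm.** Ratios and p-values are computed after adding 0.1 to
every value; the test behind the published filter was never named, so
the pooled Student *t* — the test used everywhere else in the design —
is the default with Welch optional. "More than 5 times" is strict
(> 5). The plotting transform adds 1 before the natural log; the two
pseudocounts are distinct constants and never conflated. Same-stage
columns (cells or embryos) are treated as replicates.

## The synthetic-data generator

`simdata` plants four archetypes on the log2 scale — step size
`effect_log2` (default 2.0, i.e. 4-fold), replicate noise
`noise_sd_log2` (default 0.25), per-gene baselines N(4, 2) — across
five matrices sharing the same genes: two human array datasets
(MII/1-cell, 4-cell, 8-cell, blastocyst; shared probes, 1–3 per gene,
with N(0, 0.3) affinity offsets constant across samples), a mouse
TaqMan table (MII, 1-cell, 2-cell, 8-cell) produced by inverting
expression into cycles (ct = 40 − log2 expr, detection limit 40 — about
2 % of low-baseline wells drop out, exercising the floor policies), and
RPKM matrices for both species (2^log2expr minus a floor of 1, clipped
at 0, so weakly expressed genes hit exact zeros). Three replicates per
stage throughout. One root seed; every matrix draws from its own
deterministically derived substream, so adding a matrix type cannot
shift the others.

Template timing: the human maternal (down) template drops into the
8-cell stage — human maternal transcripts persist through ZGA onset and
are cleared by 8-cell, which is also what the late classification
window expects — whereas the mouse drop coincides with ZGA at 2-cell.
`profile_template` exposes this as `down_stage` (default: the ZGA
stage). Discordant mouse orthologs receive the maternal template
regardless of the human archetype; since that makes discordance
unobservable for human Down genes, concordance labels are planted only
for Up/Up-down genes (default concordant fraction 0.6) and the
planted-fraction recovery is measured over those pairs.

What the generator does **not** emulate: count-based sequencing noise
(no negative-binomial/library-size model — RPKM noise is log-normal),
qPCR amplification-efficiency variation, probe cross-hybridization,
batch effects, and the heavy-tailed variance heterogeneity of real
arrays. Passing tests therefore demonstrate that the statistical
machinery and the rule sets behave as specified under clean,
well-powered conditions — not that the pipeline is robust to every
pathology of real embryo data.

## Problem sizes and numerics

The recovery checks run 400 genes per archetype (the acceptance
script's default), null calibration 10,000 flat genes, concordance
recovery 300 pairs; the whole acceptance script completes in seconds.
MBEI converges when the largest parameter change drops below 1e-10
(max 200 iterations); the trigamma inverse iterates Newton to relative
1e-10; BH is delegated to scipy and verified exactly against a
brute-force step-up oracle; expression TSVs round-trip losslessly
(`%.17g`, numpy's correctly-rounded parser — notably,
`pandas.to_numeric` is not correctly rounded and is avoided).
Duplicate knot positions in the normalization curve are collapsed to
their first reference value; a single-knot invariant set degrades to a
pure shift.

## Known limitations

- Under the raw-p qPCR policy, ~1 − 0.95³ ≈ 14 % of truly flat genes
  show at least one spurious significant transition across three
  tested pairs; that is the stated policy's property, quantified by the
  null-calibration check, not an implementation artifact.
- The moderated fit assumes a single variance prior for all features;
  no mean-variance trend (covariate) is modelled.
- The invariant-set map is piecewise linear, not a smoothing spline;
  with very few invariant probes the extrapolation tails are crude.
- Ortholog maps are file inputs; no live database lookup, and probe →
  gene annotation is likewise a user-supplied mapping.
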