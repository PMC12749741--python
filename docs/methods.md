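# Methods

`crcmeth` analyses DNA methylation dynamics along the colorectal
adenoma–carcinoma sequence: non-tumor colon (NONTUMOR) → low-grade adenoma
(LGA) → high-grade adenoma (HGA) → adenocarcinoma (ADK). This note records
the models, the defaults and why, the numerical choices, and what the
synthetic data do and do not establish.

## Methylation scales

A beta value is the methylated fraction of signal at a CpG, in [0, 1]. All
modelling is done on M values, `M = log2(beta / (1 − beta))`, which are
approximately variance-stabilised and unbounded. Boundary betas are clamped
to `[ε, 1 − ε]` with ε = 0.001 before the logit, keeping M finite
(|M| ≤ ~9.97) with negligible interior distortion. Probes on chrX/chrY are
removed before analysis (sex confounds methylation), as are probes missing
in more than 20% of samples; remaining missing values propagate as NaN and
are excluded pairwise with degrees of freedom adjusted.

## Tumor cellularity (purity)

A bulk specimen mixes dysplastic cells (fraction *p*, the purity) with
stromal/normal tissue. At a CpG whose methylation differs between the
dysplastic lineage and reference tissue, the observed beta deviates from the
reference level by `p × (pure-cell level − reference level)`. The estimator:

1. **Informative CpGs** — probes ranked by two-sample pooled t statistic on
   betas (reference vs target group), kept only if the group-mean gap is at
   least `min_delta` (default 0.2), top `k` (default 1000) retained with the
   direction of change per probe.
2. **Per-probe rescaling** — signed deviations from the reference median are
   divided by a per-probe gap estimate: the 95th percentile of absolute
   deviations over the target group, floored at 0.5. With near-pure samples
   present this percentile approaches the pure-cell gap, so rescaled
   deviations sit on the purity scale. Without rescaling the estimate would
   be biased low by the factor of the pure-cell gap (0.8 for levels
   0.1/0.9). The floor stops noise amplification when the observed gap is
   small. Note the degenerate case: if every sample has the same purity, gap
   and purity are unidentifiable and the estimator returns ~1; purity
   estimation needs a cohort spanning a range of cellularity.
3. **Mode** — a Gaussian KDE (Silverman bandwidth, floored at 1.5 grid
   steps so a near-degenerate sample cannot slip between evaluation points)
   over the clamped deviations, evaluated on a fixed 512-point grid on
   [0, 1]; the purity is the density mode. The mode, unlike the mean, is
   robust to the minority of informative CpGs that are wrong-direction or
   saturated in a given sample.

Adenomas and adenocarcinomas get separate informative sets (their pure-cell
profiles differ). Group purity comparisons use the two-sided Wilcoxon
rank-sum test, exact when both groups have n ≤ 10 without ties, otherwise
the tie-corrected normal approximation; all-tied input returns p = 1 with a
warning. Samples whose mean beta over user-supplied MLH1 promoter probes is
≥ 0.3 are flagged as likely MSI and excluded from downstream stages by
default.

## Differential methylation

Each probe gets a one-way fixed-effects fit across the four groups: group
means, pooled within-group variance s² on d = n − g degrees of freedom.
Per-probe variances at these sample sizes (12–22 per group) are noisy, so
they are shrunk toward a prior: s² is modelled as s0²·F(d, d0) and the
moderated variance

    s̃² = (d0·s0² + d·s²) / (d0 + d)

replaces s² in the t statistic, which gains d0 degrees of freedom. The prior
is estimated by moment matching on log s²:

    trigamma(d0/2) = var(log s²) − trigamma(d/2)
    log s0² = mean(log s²) − digamma(d/2) + log(d/2) + digamma(d0/2) − log(d0/2)

with d0 solved by monotone bisection to 1e-8. A non-positive variance excess
(or exactly constant s²) means no detectable heterogeneity: d0 = ∞, the t
becomes a z with variance s0² (for constant s², s0² is that constant).
d0 = 0 disables moderation and recovers the ordinary pooled t. Probes with
s² = 0 and finite d0 are rescued by the prior (s̃² = d0·s0²/(d0+d)).

Contrasts default to the three successive transitions plus the end-to-end
one (N→LGA, LGA→HGA, HGA→ADK, N→ADK). P-values are two-sided from the t
distribution with d + d0 df; Benjamini–Hochberg is applied within each
contrast across probes (per-comparison convention). A DMC requires
**q < 1e-4 and |ΔM| ≥ 2**; the q threshold is deliberately extreme because
adenoma cellularity attenuates effect sizes, which also rules out an
absolute beta-difference filter. Effects are not purity-corrected (an
optional corrected-beta mode exists in the trajectory stage but is off by
default). A probe counts as "modified during oncogenesis" if any contrast
calls it; per-contrast calls are logged so alternative schemes are
recomputable.

## Trajectory taxonomy

Binary methylation status per group = sign of the group-mean M (exact zero →
unmethylated, a declared tie-break). The ordered quadruple over
(NONTUMOR, LGA, HGA, ADK) maps to exactly one of five classes: stable (2
patterns), definitive methylation/unmethylation (status differs between the
end points; 4 + 4 patterns), transitory methylation/unmethylation (end
points agree, an adenoma differs; 3 + 3). Definitive timing is the earliest
stage from which the status equals the ADK status through all later stages;
this also covers non-monotone patterns such as 0101 (→ to_ADK). Status is
taken at tissue-type level (group mean) rather than per-sample majority
vote — the mean-M reading is the primary definition, majority vote is
available for sensitivity analysis. Summaries (class counts, early
fraction, transitory share) are restricted to the DMC union by default.

## Context, gene sets, biomarkers

Context enrichment: per CpG-density context (island, N/S shore, N/S shelf,
open sea; shores/shelves mergeable) a 2×2 Fisher exact test of DMCs of one
direction against all tested probes, odds ratio with Haldane 0.5 correction
on zero cells, BH across contexts within a direction. Promoter mapping uses
the array convention TSS200/TSS1500/1stExon; gene-set enrichment is the
upper-tail hypergeometric test against the universe of genes with at least
one promoter probe, for user-supplied GMT sets (no ontology retrieval, and
no per-gene probe-number bias correction — a known difference from
enrichment tools that model selection bias).

The packaged biomarker panel (35 entries) lists published CRC methylation
biomarkers. A sample is methylated at a panel probe when beta ≥ 0.3; a group
is methylated when at least half its samples are. Stage labels: *early*
(LGA, HGA and ADK methylated), *high_grade_onset* (HGA and ADK, not LGA),
*carcinoma_onset* (ADK only), *non_informative* (not ADK). The ≥ 0.5
majority rule is this package's explicit operationalisation of a visual
"majority methylated" judgment.

## Global structure

PCA runs on M values, mean-centering each probe but not scaling (M values
are bimodal; unit-variance scaling would inflate uninformative probes);
k = 17 components by default, k truncated to rank with a warning. The
non-tumor group can be randomly downsampled (default n = 20) with a seeded
draw to match the tumor-group scale. Cross-dataset concordance restricts to
shared probes and reports per-group Spearman correlations of group-mean
betas plus a direction-aware DMC concordance, |shared same-direction
DMCs| / |DMCs in either dataset| — a union (Jaccard-with-direction)
definition, declared because published "concordance" figures rarely define
the denominator; intersection-over-smaller is recomputable from the logged
counts.

## Synthetic data: what it emulates, what it does not

The generator plants, per probe, one of six classes — stable
unmethylated/methylated, definitive gain/loss (with a timing of change),
transitory gain/loss — as pure dysplastic-cell beta patterns over the four
groups using two levels (defaults 0.1/0.9). Defaults encode the emulated
study: group sizes 20/12/19/22; 11.9% of probes changed, split across the
four change classes as 32051 : 822 : 27735 : 4227; 67.4% of definitive
changes timed to_LGA. Observed betas are purity mixtures
(`p·dysplastic + (1−p)·stromal`) with the stromal profile equal to the
probe's non-tumor level jittered per individual on the logit scale
(sd 0.2), followed by Beta(μκ, (1−μ)κ) measurement noise with κ = 80
(chosen to mimic array-replicate dispersion; κ = None disables noise).
Purity defaults: adenomas Beta(4,4), adenocarcinomas Beta(8,3) — adenomas
have lower cellularity; non-tumor samples are pure stroma (p = 0).
Island-context annotation is drawn with a direction bias (gains enrich
islands/shores, losses shelves/open sea) so context enrichment has a planted
signal.

An identifiability caveat drives the recovery-test conditions: with adenoma
purity centred at 0.5 and symmetric levels, the mixture group-mean beta of a
probe changing at the adenoma stage sits exactly at 0.5 (M ≈ 0), so its
binary status is a coin flip. Recovery tests therefore use purity laws with
support [0.6, 1] and levels 0.2/0.8 (planted pure-signal |ΔM| = 4); the
defaults stay at the emulated study conditions. Problem sizes used by the
test suite and the acceptance script — 50,000 probes for planted-truth
recovery, 20 × 10,000 probes for the null calibration, 200,000 variances
for prior recovery, 50 samples for the purity grid — are the package's
declared verification scales.

What passing these tests does **not** show about real data: the simulator
has no probe-type chemistry differences, no batch or normalization
artifacts, no copy-number effects, only two pure-cell levels per probe, a
single shared stromal profile, and beta noise with common concentration.
Recovery rates on it are upper bounds on real-data performance, not
estimates of it.

## Determinism and numerical conventions

One seed governs all stochastic steps via named SHA-256-derived substreams
(simulation, PCA downsampling), so identical config + seed gives an
identical report hash (wall-clock fields excluded). Ties and degenerate
inputs are resolved explicitly: status at M = 0 is unmethylated; all-tied
rank-sum input returns p = 1; a KDE over a near-constant deviation sample
falls back to the point mass; empty DMC sets yield empty summaries with a
warning rather than errors.
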