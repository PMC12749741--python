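# crcmeth

Analysis of DNA methylation dynamics along the colorectal
adenoma–carcinoma sequence: non-tumor colon → low-grade adenoma →
high-grade adenoma → adenocarcinoma. The package is written for
epigenomics analysts working with methylation-array beta matrices who want
to ask *when* each CpG changes during oncogenesis, whether the change is
permanent, and what that implies for early-detection biomarkers — with
every stage verifiable against synthetic data carrying planted truth.

## What it computes

Given a beta matrix (probes × samples), sample sheet and probe manifest:

- **Cellularity QC** — the dysplastic-cell fraction of each specimen,
  estimated from the kernel-density mode of rescaled deviations at
  informative CpGs, plus MLH1-promoter flagging of likely-MSI samples.
- **Differential methylation** — per-CpG one-way models on
  M = log2(β/(1−β)) with empirical-Bayes variance moderation: s² is shrunk
  toward a prior via s̃² = (d₀s₀² + d s²)/(d₀ + d), the prior (d₀, s₀²)
  estimated by trigamma moment matching. A DMC requires BH q < 10⁻⁴ and
  |ΔM| ≥ 2 in at least one transition contrast.
- **Trajectory classification** — the binary methylation status per tissue
  group (sign of the group-mean M) maps each CpG to stable, definitive
  (gain/loss with timing to_LGA / to_HGA / to_ADK) or transitory
  (adenoma-specific) change; summaries report the early-change fraction and
  the transitory share.
- **Context & gene sets** — Fisher enrichment of gains/losses across CpG
  island/shore/shelf/open-sea contexts; promoter (TSS200/TSS1500/1stExon)
  gene mapping and hypergeometric gene-set enrichment from GMT files.
- **Biomarker staging** — a packaged 35-entry panel of published CRC
  methylation biomarkers, staged by the β ≥ 0.3 majority rule into
  early / high-grade-onset / carcinoma-onset / non-informative.
- **Global structure** — unscaled PCA on M values with seeded group
  downsampling, and cross-dataset Spearman + direction-aware DMC
  concordance.
- **Synthetic data** — a generator planting trajectory classes, purity
  mixtures and beta noise, with full ground truth for recovery testing.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on a seeded
synthetic dataset (generated on first use under `results/data/`):

```sh
cd analysis
python 01_simulate.py
python 03_differential_methylation.py
python 04_trajectories.py
```

which prints, among other lines:

```
variance prior: d0 = 507.6, s0^2 = 0.1957
  NONTUMOR->LGA: 1689 DMCs
union of DMCs: 2420 (12.1% of the methylome)
recall of planted changes: 100.0%; false discoveries: 0
early changes (acquired at non-tumor -> low-grade): 67.2% of definitive changes
transitory share: 7.8% of changes
class agreement with planted truth on DMC probes: 100.0%
```

Read: the moderated test finds 12.1% of the methylome changed (12.1% was
planted in this draw), every planted change is recovered with no false
calls at q < 10⁻⁴, about two-thirds of definitive changes are already
present in low-grade adenomas, and ~8% of changes are adenoma-specific
(transitory). Scripts `02`, `05`, `06`, `07` cover purity QC, context and
gene-set enrichment, biomarker staging and PCA/concordance.

The same stages are available as a CLI
(`crcmeth simulate|qc|dmc|trajectory|annotate|biomarkers|pca|concord|run|validate`)
and as library functions (`crcmeth.diffmeth`, `crcmeth.trajectory`, …).

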