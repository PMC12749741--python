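"""Reference-based tumor-cellularity estimation and sample QC.

A bulk adenoma or adenocarcinoma specimen is a mixture of dysplastic cells
with stromal/normal tissue.  At a CpG whose methylation differs between the
dysplastic lineage and the reference tissue, the observed beta deviates from
the reference level in proportion to the dysplastic-cell fraction (purity).
The estimator therefore:

1. selects informative CpGs — the strongest reference-vs-target differences
   by two-sample t statistic, requiring a minimum group-mean beta gap;
2. for one sample, computes the signed deviation of each informative CpG from
   the reference median, rescales it to the purity scale by a per-probe gap
   estimate, and clamps to [0, 1];
3. reports the mode of a Gaussian kernel density over those deviations,
   evaluated on a fixed 512-point grid on [0, 1].

The per-probe rescaling gap is estimated as the 95th percentile of the
absolute deviations observed in the target group (floored at 0.5): with any
near-pure samples present, that percentile approaches the pure-cell beta gap,
so deviations divided by it sit on the purity scale.  Without rescaling the
mode would estimate purity x gap and be biased low whenever the pure-cell gap
is below 1.

The module also flags samples with a methylated MLH1 promoter (a surrogate
for MSI status, excluded from downstream analysis by default) and compares
purity between groups with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationError, BetaMatrix


class InsufficientEvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class InformativeCpGSet:
    """Informative CpGs for purity estimation.

    ``table`` is indexed by probe id with columns ``direction`` (+1 hyper in
    target, -1 hypo), ``ref_median``, ``gap`` (per-probe rescaling factor) and
    ``t_stat``.
    """

    table: pd.DataFrame
    reference_group: str
    target_group: str

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class PurityEstimate:
    sample_id: str
    purity: float
    n_cpgs: int
    bandwidth: float


def select_informative_cpgs(
    bm: BetaMatrix,
    reference_group: str,
    target_group: str,
    k: int = 1000,
    min_delta: float = 0.2,
    gap_floor: float = 0.5,
) -> InformativeCpGSet:
    """Rank probes by two-sample t statistic (reference vs target betas),
    keep the top ``k`` with absolute group-mean difference >= ``min_delta``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref_samples = bm.samples_in_group(reference_group)
    tgt_samples = bm.samples_in_group(target_group)
    if len(ref_samples) < 2 or len(tgt_samples) < 2:
        raise ValueError("both groups need at least 2 samples")

    ref = bm.values[ref_samples].to_numpy(dtype=float)
    tgt = bm.values[tgt_samples].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref_mean = np.nanmean(ref, axis=1)
        tgt_mean = np.nanmean(tgt, axis=1)
        n1 = np.sum(~np.isnan(ref), axis=1)
        n2 = np.sum(~np.isnan(tgt), axis=1)
        v1 = np.nanvar(ref, axis=1, ddof=1)
        v2 = np.nanvar(tgt, axis=1, ddof=1)
    delta = tgt_mean - ref_mean
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t[~np.isfinite(t)] = 0.0

    passing = np.abs(delta) >= min_delta
    if not passing.any():
        raise InsufficientEvidenceError(
            f"no probe reaches |group-mean difference| >= {min_delta}; "
            "relax min_delta"
        )
    order = np.argsort(-np.abs(np.where(passing, t, 0.0)), kind="stable")
    chosen = [i for i in order if passing[i]][:k]
    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} probes pass min_delta={min_delta}; requested {k}",
            stacklevel=2,
        )

    chosen = np.asarray(chosen)
    ref_median = np.nanmedian(bm.values[ref_samples].to_numpy(dtype=float), axis=1)
    dev = np.abs(tgt[chosen] - ref_median[chosen, None])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gap = np.nanquantile(dev, 0.95, axis=1)
    gap = np.maximum(gap, gap_floor)

    table = pd.DataFrame(
        {
            "direction": np.sign(delta[chosen]).astype(int),
            "ref_median": ref_median[chosen],
            "gap": gap,
            "t_stat": t[chosen],
        },
        index=bm.probe_ids[chosen],
    )
    return InformativeCpGSet(
        table=table, reference_group=reference_group, target_group=target_group
    )


def estimate_purity(
    bm: BetaMatrix,
    cpgs: InformativeCpGSet,
    sample_id: str,
    grid_points: int = 512,
    min_cpgs: int = 20,
) -> PurityEstimate:
    """Kernel-density-mode purity of one sample from its informative-CpG
    deviations (Silverman bandwidth, fixed grid on [0, 1])."""
    if sample_id not in bm.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    probes = cpgs.table.index.intersection(bm.probe_ids)
    if len(probes) < min_cpgs:
        raise InsufficientEvidenceError(
            f"only {len(probes)} informative CpGs available; need >= {min_cpgs}"
        )
    tab = cpgs.table.loc[probes]
    beta = bm.values.loc[probes, sample_id].to_numpy(dtype=float)
    r = tab["direction"].to_numpy() * (beta - tab["ref_median"].to_numpy())
    r = r / tab["gap"].to_numpy()
    r = np.clip(r, 0.0, 1.0)
    r = r[~np.isnan(r)]
    if len(r) < min_cpgs:
        raise InsufficientEvidenceError(
            f"only {len(r)} non-missing deviations; need >= {min_cpgs}"
        )

    grid = np.linspace(0.0, 1.0, grid_points)
    if np.ptp(r) < 1e-12:  # degenerate: KDE undefined, mode is the point mass
        mode = float(np.clip(r[0], 0.0, 1.0))
        return PurityEstimate(sample_id, mode, len(r), 0.0)
    kde = stats.gaussian_kde(r, bw_method="silverman")
    # keep the kernel at least as wide as the evaluation grid step, or a
    # near-degenerate deviation sample can slip between grid points
    grid_step = grid[1] - grid[0]
    min_factor = 1.5 * grid_step / r.std(ddof=1)
    if kde.factor < min_factor:
        kde = stats.gaussian_kde(r, bw_method=min_factor)
    density = kde(grid)
    mode = float(grid[np.argmax(density)])
    bandwidth = float(kde.factor * r.std(ddof=1))
    return PurityEstimate(sample_id, mode, len(r), bandwidth)


def estimate_purity_all(
    bm: BetaMatrix,
    reference_group: str,
    target_group: str,
    k: int = 1000,
    min_delta: float = 0.2,
) -> pd.DataFrame:
    """Purity for every sample of ``target_group`` (one informative set)."""
    cpgs = select_informative_cpgs(bm, reference_group, target_group, k, min_delta)
    rows = []
    for s in bm.samples_in_group(target_group):
        est = estimate_purity(bm, cpgs, s)
        rows.append((est.sample_id, target_group, est.purity, est.n_cpgs))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "purity", "n_cpgs"]
    ).set_index("sample_id")


def flag_mlh1_methylation(
    bm: BetaMatrix, mlh1_probes: list[str], cutoff: float = 0.3
) -> pd.DataFrame:
    """Flag samples whose mean beta over the MLH1 promoter probes is >= cutoff.

    Flagged samples suggest MSI status and are excluded downstream by default.
    """
    present = [p for p in mlh1_probes if p in bm.probe_ids]
    if not present:
        raise AnnotationError(
            f"none of the MLH1 promoter probes {mlh1_probes} present in matrix"
        )
    mean_beta = bm.values.loc[present].mean(axis=0, skipna=True)
    return pd.DataFrame(
        {
            "mlh1_mean_beta": mean_beta,
            "flagged": mean_beta >= cutoff,
        }
    ).rename_axis("sample_id")


def compare_purity_groups(
    estimates: pd.DataFrame, group_a: str, group_b: str
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of purity between two groups.

    Exact enumeration when both groups have n <= 10 and no ties; otherwise the
    tie-corrected normal approximation.
    """
    a = estimates.loc[estimates["group"] == group_a, "purity"].to_numpy()
    b = estimates.loc[estimates["group"] == group_b, "purity"].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 samples per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) < 1e-15:
        warnings.warn("all purity values tied; p = 1", stacklevel=2)
        return {"statistic": float(len(a) * len(b) / 2), "p_value": 1.0, "method": "degenerate"}
    ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 10 and len(b) <= 10 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "method": method}
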