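"""Global sample structure: unscaled PCA and cross-dataset concordance.

PCA is run on M values, mean-centering each probe but not scaling to unit
variance — M values are bimodal and scaling would inflate uninformative
probes.  A group may be randomly downsampled first (the large non-tumor
reference is reduced to the scale of the tumor groups) with a seeded draw.

Cross-dataset concordance restricts both datasets to their shared probes and
reports (a) the Spearman correlation of group-mean betas for each matched
group and (b) the fraction of DMCs replicated with the same direction:
|shared same-direction DMCs| / |DMCs in either dataset|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, MValueMatrix


@dataclass(frozen=True)
class EmbeddingResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    retained_samples: list[str]
    downsample_seed: int | None


@dataclass(frozen=True)
class ConcordanceReport:
    n_shared_probes: int
    spearman_by_group: dict[str, float]
    dmc_concordance: float
    n_dmc_a: int
    n_dmc_b: int
    n_shared_same_direction: int


def run_pca(
    mv: MValueMatrix,
    k: int = 17,
    downsample: tuple[str, int, int] | None = None,
) -> EmbeddingResult:
    """Principal components of the samples (centered, unscaled).

    ``downsample`` is an optional (group, n, seed) triple: that group is
    reduced to n randomly chosen samples before the decomposition.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = mv.values
    seed = None
    if downsample is not None:
        group, n, seed = downsample
        labels = mv.sample_groups()
        members = list(labels.index[labels == group])
        if len(members) < n:
            raise ValueError(f"group {group!r} has {len(members)} samples, need {n}")
        rng = np.random.default_rng(seed)
        keep_members = set(rng.choice(members, size=n, replace=False))
        keep = [s for s in values.columns if labels[s] != group or s in keep_members]
        values = values[keep]

    X = values.to_numpy(dtype=float).T  # samples x probes
    X = X - X.mean(axis=0, keepdims=True)
    rank = int(np.linalg.matrix_rank(X))
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * s[:k]
    total_var = float(np.sum(s**2))
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    coordinates = pd.DataFrame(
        coords, index=values.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return EmbeddingResult(
        coordinates=coordinates,
        explained_variance_ratio=evr,
        retained_samples=list(values.columns),
        downsample_seed=seed,
    )


def _group_mean_betas(bm: BetaMatrix) -> pd.DataFrame:
    labels = bm.sample_groups()
    return pd.DataFrame(
        {
            g: bm.values[labels.index[labels == g]].mean(axis=1)
            for g in pd.unique(labels)
        }
    )


def cross_platform_concordance(
    dmcs_a: pd.DataFrame,
    dmcs_b: pd.DataFrame,
    betas_a: BetaMatrix,
    betas_b: BetaMatrix,
    min_shared: int = 100,
) -> ConcordanceReport:
    """Concordance between two datasets on their shared probes.

    ``dmcs_a``/``dmcs_b`` are DMC record frames (columns ``probe_id``,
    ``is_dmc``, ``direction``); a probe counts as a DMC of a dataset when any
    of its contrasts is called, with the direction of the largest effect.
    """
    shared = betas_a.probe_ids.intersection(betas_b.probe_ids)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared probes; need >= {min_shared}"
        )

    means_a = _group_mean_betas(betas_a.subset_probes(shared))
    means_b = _group_mean_betas(betas_b.subset_probes(shared))
    spearman = {}
    for g in means_a.columns.intersection(means_b.columns):
        rho = stats.spearmanr(means_a[g], means_b[g], nan_policy="omit").statistic
        spearman[g] = float(rho)

    def _directions(records: pd.DataFrame) -> pd.Series:
        hits = records.loc[records["is_dmc"]].copy()
        hits = hits.loc[hits["probe_id"].isin(shared)]
        if hits.empty:
            return pd.Series(dtype=object)
        hits["abs_delta"] = hits["delta_m"].abs()
        top = hits.sort_values("abs_delta", ascending=False).drop_duplicates(
            "probe_id"
        )
        return top.set_index("probe_id")["direction"]

    dir_a = _directions(dmcs_a)
    dir_b = _directions(dmcs_b)
    union = dir_a.index.union(dir_b.index)
    both = dir_a.index.intersection(dir_b.index)
    same = int((dir_a.loc[both] == dir_b.loc[both]).sum())
    concordance = same / len(union) if len(union) else 0.0

    return ConcordanceReport(
        n_shared_probes=int(len(shared)),
        spearman_by_group=spearman,
        dmc_concordance=float(concordance),
        n_dmc_a=int(len(dir_a)),
        n_dmc_b=int(len(dir_b)),
        n_shared_same_direction=same,
    )


def pool_adenomas(bm: BetaMatrix) -> BetaMatrix:
    """Relabel LGA and HGA samples as a pooled ADENOMA group.

    Used when comparing against datasets that do not grade dysplasia.
    Note the pooled label falls outside the four-level factor, so the result
    is only suitable for concordance computations, not the staged pipeline.
    """
    groups = bm.groups.replace({"LGA": "ADENOMA", "HGA": "ADENOMA"})
    return BetaMatrix(values=bm.values, groups=groups)
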