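"""Per-CpG group linear models on M values with empirical-Bayes moderation.

Each probe is fitted with a one-way fixed-effects model across the four
tissue groups: the group means are the effect estimates, the pooled
within-group variance s^2 is the residual variance on d = n - g degrees of
freedom.  Because per-probe variances at these sample sizes are noisy, they
are shrunk toward a common prior: s^2 is modelled as s0^2 * F(d, d0), the
prior parameters (d0, s0^2) are estimated by moment matching on log s^2, and
the posterior (moderated) variance

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces s^2 in the t statistic, which gains d0 extra degrees of freedom.
The limits are the familiar ones: d0 -> 0 recovers the ordinary pooled
two-sample t, d0 -> infinity a z-like statistic with fixed variance s0^2.

A differentially methylated CpG (DMC) is called when the Benjamini-Hochberg
q-value is below 1e-4 AND the absolute group-mean difference is at least
2 M values; the q threshold is deliberately stringent because effect sizes
are attenuated by the limited cellularity of adenoma specimens, which rules
out an absolute beta-difference filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import GROUPS, MValueMatrix, SampleSheet

logger = logging.getLogger(__name__)

#: Default contrasts: the three successive transitions plus the end-to-end one.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("NONTUMOR", "LGA"),
    ("LGA", "HGA"),
    ("HGA", "ADK"),
    ("NONTUMOR", "ADK"),
)

Q_THRESHOLD = 1e-4
DELTA_M_THRESHOLD = 2.0


@dataclass(frozen=True)
class EBayesParams:
    """Prior of the variance model s^2 ~ s0^2 * F(d, d0)."""

    d0: float  # prior degrees of freedom; may be inf
    s02: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("d0 must be >= 0")
        if not self.s02 > 0:
            raise ValueError("s0^2 must be > 0")


@dataclass(frozen=True)
class GroupFit:
    """Per-probe one-way fit: group means, pooled variance, residual df,
    and per-group observation counts (NaN-aware)."""

    means: pd.DataFrame  # probes x groups
    s2: pd.Series
    df: pd.Series
    n_obs: pd.DataFrame  # probes x groups


def fit_group_model(mv: MValueMatrix, sheet: SampleSheet | None = None) -> GroupFit:
    """One-way fixed-effects fit per probe.

    Missing values are excluded per probe with degrees of freedom adjusted;
    probes observed in fewer than two groups are dropped with a log entry.
    """
    labels = mv.sample_groups() if sheet is None else sheet.groups.reindex(mv.sample_ids)
    present_groups = [g for g in GROUPS if (labels == g).sum() > 0]
    if sum((labels == g).sum() >= 2 for g in present_groups) < 2:
        raise ValueError("need at least 2 groups with at least 2 samples")

    X = mv.values.to_numpy(dtype=float)
    means = {}
    counts = {}
    ss_within = np.zeros(X.shape[0])
    for g in present_groups:
        cols = np.asarray(labels == g)
        sub = X[:, cols]
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            m = np.nansum(sub, axis=1) / np.where(n > 0, n, np.nan)
            ss = np.nansum((sub - m[:, None]) ** 2, axis=1)
        means[g] = m
        counts[g] = n
        ss_within += np.where(n > 1, ss, 0.0)

    n_obs = pd.DataFrame(counts, index=mv.probe_ids)
    groups_observed = (n_obs >= 1).sum(axis=1)
    n_total = n_obs.sum(axis=1)
    df = n_total - groups_observed
    s2 = pd.Series(
        np.where(df > 0, ss_within / np.where(df > 0, df, 1), np.nan),
        index=mv.probe_ids,
        name="s2",
    )

    usable = groups_observed >= 2
    dropped = int((~usable).sum())
    if dropped:
        logger.info("dropping %d probes observed in < 2 groups", dropped)
    means_df = pd.DataFrame(means, index=mv.probe_ids)
    return GroupFit(
        means=means_df.loc[usable],
        s2=s2.loc[usable],
        df=df.loc[usable].astype(float),
        n_obs=n_obs.loc[usable],
    )


def _trigamma(x):
    return special.polygamma(1, x)


def _solve_trigamma(target: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = target for x > 0 by monotone bisection."""
    lo, hi = 1e-12, 1.0
    while _trigamma(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            return np.inf
    while _trigamma(lo) < target:
        lo /= 2.0
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if _trigamma(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_ebayes_params(s2, df, min_probes: int = 100) -> EBayesParams:
    """Moment-matching estimate of the variance prior on the log scale.

    With s^2 ~ s0^2 F(d, d0), log s^2 has variance trigamma(d/2) +
    trigamma(d0/2) and mean log s0^2 + digamma(d/2) - log(d/2) -
    digamma(d0/2) + log(d0/2); solving the variance equation for d0 by
    bisection and back-substituting gives (d0, s0^2).  A non-positive
    variance excess means no detectable variance heterogeneity: d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < min_probes:
        raise ValueError(
            f"need >= {min_probes} probes with finite positive variance, "
            f"got {int(ok.sum())}"
        )
    z = np.log(s2[ok])
    d = df[ok]
    evar = float(np.var(z, ddof=1))
    if evar < 1e-15:  # all variances identical: no sampling spread to model
        return EBayesParams(d0=np.inf, s02=float(np.exp(np.mean(z))))
    target = evar - float(np.mean(_trigamma(d / 2.0)))
    emean_adj = float(np.mean(z) - np.mean(special.digamma(d / 2.0) - np.log(d / 2.0)))
    if target <= 0:
        return EBayesParams(d0=np.inf, s02=float(np.exp(emean_adj)))
    half_d0 = _solve_trigamma(target)
    if not np.isfinite(half_d0):
        return EBayesParams(d0=np.inf, s02=float(np.exp(emean_adj)))
    d0 = 2.0 * half_d0
    log_s02 = emean_adj + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    return EBayesParams(d0=float(d0), s02=float(np.exp(log_s02)))


def posterior_variance(s2, df, params: EBayesParams):
    """Moderated variance s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if params.d0 == 0:
        return s2
    if np.isinf(params.d0):
        return np.full_like(s2, params.s02)
    return (params.d0 * params.s02 + df * s2) / (params.d0 + df)


def moderate_and_test(
    fit: GroupFit, params: EBayesParams, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Moderated t-test of one group contrast; no thresholds applied.

    Returns one row per probe with ``delta_m`` (mean of the second group
    minus the first), the moderated ``t``, total df, and two-sided ``p``.
    """
    a, b = contrast
    for g in (a, b):
        if g not in fit.means.columns:
            raise ValueError(f"group {g!r} not fitted")
    n_a = fit.n_obs[a].to_numpy(dtype=float)
    n_b = fit.n_obs[b].to_numpy(dtype=float)
    ok = (n_a >= 2) & (n_b >= 2)
    if not ok.any():
        raise ValueError(f"contrast {a}->{b} has no probe with >= 2 samples per group")

    delta = (fit.means[b] - fit.means[a]).to_numpy(dtype=float)
    s2_post = posterior_variance(fit.s2.to_numpy(), fit.df.to_numpy(), params)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
        t = delta / se
    df_total = fit.df.to_numpy(dtype=float) + (
        0.0 if np.isinf(params.d0) else params.d0
    )
    if np.isinf(params.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "contrast": f"{a}->{b}",
            "delta_m": delta,
            "t": t,
            "df_total": np.inf if np.isinf(params.d0) else df_total,
            "p": p,
        },
        index=fit.means.index,
    )
    return out.loc[ok].rename_axis("probe_id")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmcs(
    records: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
    delta_threshold: float = DELTA_M_THRESHOLD,
) -> pd.DataFrame:
    """Flag DMCs under the dual threshold; BH is applied within each contrast."""
    out = records.copy()
    out["q"] = np.nan
    for _, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["is_dmc"] = (out["q"] < q_threshold) & (out["delta_m"].abs() >= delta_threshold)
    out["direction"] = np.where(out["delta_m"] >= 0, "gain", "loss")
    return out


def run_dmc_analysis(
    mv: MValueMatrix,
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
    q_threshold: float = Q_THRESHOLD,
    delta_threshold: float = DELTA_M_THRESHOLD,
    params: EBayesParams | None = None,
) -> tuple[pd.DataFrame, GroupFit, EBayesParams, dict]:
    """Fit, moderate, test every contrast and call DMCs.

    Returns (records, fit, params, summary); ``records`` has one row per
    probe x contrast.  A probe counts as modified during oncogenesis when any
    contrast calls it.
    """
    fit = fit_group_model(mv)
    if params is None:
        params = estimate_ebayes_params(fit.s2, fit.df)
    pieces = [moderate_and_test(fit, params, c) for c in contrasts]
    records = call_dmcs(
        pd.concat(pieces).reset_index(), q_threshold, delta_threshold
    )
    union = records.loc[records["is_dmc"], "probe_id"].unique()
    summary = {
        "n_probes": int(len(fit.means)),
        "d0": float(params.d0),
        "s02": float(params.s02),
        "q_threshold": q_threshold,
        "delta_m_threshold": delta_threshold,
        "dmc_per_contrast": {
            c: int(n)
            for c, n in records.groupby("contrast")["is_dmc"].sum().items()
        },
        "dmc_union": int(len(union)),
        "modified_fraction": float(len(union) / max(len(fit.means), 1)),
    }
    return records, fit, params, summary


def dmc_union(records: pd.DataFrame) -> pd.Index:
    """Probe ids called DMC in at least one contrast."""
    return pd.Index(records.loc[records["is_dmc"], "probe_id"].unique())
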