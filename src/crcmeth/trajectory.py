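"""Methylation-trajectory taxonomy along the adenoma-carcinoma sequence.

Each CpG gets a binary methylation status per tissue group from the sign of
the group-mean M value (positive = methylated, i.e. group-mean beta above
0.5; exact zero counts as unmethylated by declared tie-break).  The ordered
status quadruple (NONTUMOR, LGA, HGA, ADK) is then classified:

* **stable** — status identical in all four groups;
* **definitive** (methylation/unmethylation) — status differs between
  non-tumor tissue and adenocarcinoma; the change can be acquired at the
  transition to low-grade adenoma, to high-grade adenoma, or to
  adenocarcinoma.  Timing is the earliest stage from which the status equals
  the adenocarcinoma status through all later stages, which also covers
  non-monotone patterns;
* **transitory** (methylation/unmethylation) — status equal in non-tumor and
  adenocarcinoma but different in low- and/or high-grade adenomas; the
  direction is the adenoma status (methylated in adenomas = transitory
  methylation).

All 16 possible patterns map to exactly one class: 2 stable, 8 definitive,
6 transitory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core import GROUPS, MValueMatrix

TRAJECTORY_CLASSES: tuple[str, ...] = (
    "stable",
    "definitive_methylation",
    "definitive_unmethylation",
    "transitory_methylation",
    "transitory_unmethylation",
)

_TIMING_BY_STAGE = {1: "to_LGA", 2: "to_HGA", 3: "to_ADK"}


def call_status(group_mean_m: float) -> int:
    """Binary methylation status from a group-mean M value (> 0 = methylated)."""
    return int(group_mean_m > 0)


@dataclass(frozen=True)
class TrajectoryCall:
    pattern: tuple[int, int, int, int]
    class_: str
    timing: str  # to_LGA / to_HGA / to_ADK / not_applicable


def classify_trajectory(pattern) -> TrajectoryCall:
    """Classify one status quadruple (NONTUMOR, LGA, HGA, ADK)."""
    p = tuple(int(bool(x)) for x in pattern)
    if len(p) != 4:
        raise ValueError("pattern must have exactly 4 entries")
    n, lga, hga, adk = p
    if n != adk:
        cls = "definitive_methylation" if adk == 1 else "definitive_unmethylation"
        # earliest stage from which status equals the ADK status throughout
        timing_stage = 3
        for stage in (1, 2):
            if all(s == adk for s in p[stage:]):
                timing_stage = stage
                break
        return TrajectoryCall(p, cls, _TIMING_BY_STAGE[timing_stage])
    if lga != n or hga != n:
        # adenoma status opposes the shared end-points, fixing the direction
        cls = "transitory_methylation" if n == 0 else "transitory_unmethylation"
        return TrajectoryCall(p, cls, "not_applicable")
    return TrajectoryCall(p, "stable", "not_applicable")


def classify_all(group_mean_m: pd.DataFrame) -> pd.DataFrame:
    """Classify every probe from its per-group mean M values.

    ``group_mean_m`` must contain one column per group in GROUPS order.
    Returns a frame with the status pattern, class and timing per probe.
    """
    missing = [g for g in GROUPS if g not in group_mean_m.columns]
    if missing:
        raise ValueError(f"missing group means for {missing}")
    status = (group_mean_m[list(GROUPS)] > 0).astype(int)
    # only 16 patterns exist: classify each once and map
    lut = {}
    for key in range(16):
        pat = tuple((key >> (3 - i)) & 1 for i in range(4))
        lut[pat] = classify_trajectory(pat)
    keys = [tuple(row) for row in status.to_numpy()]
    calls = [lut[k] for k in keys]
    return pd.DataFrame(
        {
            "pattern": ["".join(map(str, k)) for k in keys],
            "class": [c.class_ for c in calls],
            "timing": [c.timing for c in calls],
        },
        index=group_mean_m.index,
    )


def classify_matrix(mv: MValueMatrix) -> pd.DataFrame:
    return classify_all(mv.group_means())


def summarize_trajectories(calls: pd.DataFrame, dmc_union) -> dict:
    """Summary statistics over the DMC probes.

    * class counts restricted to the DMC union;
    * ``early_fraction`` — share of definitive changes acquired at the
      non-tumor -> low-grade transition;
    * ``transitory_share`` — transitory probes among all changed probes;
    * ``modified_fraction`` — changed DMC probes over all classified probes.
    """
    dmc_union = pd.Index(dmc_union)
    if len(dmc_union) == 0:
        warnings.warn("empty DMC set; summary is empty", stacklevel=2)
        return {
            "class_counts": {},
            "early_fraction": float("nan"),
            "transitory_share": float("nan"),
            "modified_fraction": 0.0,
            "n_changed": 0,
            "n_total": int(len(calls)),
        }
    sub = calls.loc[calls.index.intersection(dmc_union)]
    changed = sub.loc[sub["class"] != "stable"]
    counts = changed["class"].value_counts().to_dict()
    definitive = changed.loc[changed["class"].str.startswith("definitive")]
    transitory = changed.loc[changed["class"].str.startswith("transitory")]
    early = (
        float((definitive["timing"] == "to_LGA").mean()) if len(definitive) else float("nan")
    )
    share = float(len(transitory) / len(changed)) if len(changed) else float("nan")
    return {
        "class_counts": {k: int(v) for k, v in counts.items()},
        "early_fraction": early,
        "transitory_share": share,
        "modified_fraction": float(len(changed) / max(len(calls), 1)),
        "n_changed": int(len(changed)),
        "n_total": int(len(calls)),
    }
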