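"""Synthetic four-group methylome generator with planted ground truth.

The generator emulates the study design of a colorectal oncogenesis methylome:
four ordered tissue groups (non-tumor colon, low-grade adenoma, high-grade
adenoma, adenocarcinoma), each bulk specimen a purity-confounded mixture of a
dysplastic-cell signal with a shared stromal signal, measured with
beta-distributed array noise.

Each CpG is assigned one of six trajectory classes.  Writing L for the low
methylation level and H for the high level, the pure dysplastic-cell beta
across (NONTUMOR, LGA, HGA, ADK) is:

    stable_unmeth        (L, L, L, L)
    stable_meth          (H, H, H, H)
    definitive_meth      (L, H, H, H) / (L, L, H, H) / (L, L, L, H)
                         depending on the timing of change
    definitive_unmeth    the mirrored loss patterns
    transitory_meth      (L, H, H, L)   gained in adenomas only
    transitory_unmeth    (H, L, L, H)   lost in adenomas only

The observed beta of a tumor-lineage sample with purity ``p`` is
``p * dysplastic + (1 - p) * stromal`` followed by Beta(mu*kappa, (1-mu)*kappa)
measurement noise; non-tumor samples have purity fixed at 0 (pure stromal
signal).  The stromal profile of a probe equals its non-tumor level, jittered
per individual on the logit scale.

Island-context annotation is drawn with a methylation-direction bias (gains
enrich islands/shores, losses enrich shelves/open sea) so that context
enrichment has a planted signal to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GROUPS,
    ISLAND_CONTEXTS,
    REGION_GROUPS,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
)

CLASSES: tuple[str, ...] = (
    "stable_unmeth",
    "stable_meth",
    "definitive_meth",
    "definitive_unmeth",
    "transitory_meth",
    "transitory_unmeth",
)

TIMINGS: tuple[str, ...] = ("to_LGA", "to_HGA", "to_ADK")

#: Biomarker stage labels and the pure-cell level pattern they plant.
STAGE_PATTERNS: dict[str, tuple[int, int, int, int]] = {
    "early": (0, 1, 1, 1),
    "high_grade_onset": (0, 0, 1, 1),
    "carcinoma_onset": (0, 0, 0, 1),
    "never": (0, 0, 0, 0),
}

# Study-condition class mix: 11.9% of probes carry a change, split across the
# four change classes in the proportions of the observed class counts
# (definitive gain 32051, transitory gain 822, definitive loss 27735,
# transitory loss 4227); the remainder is stable, split evenly.
_CHANGED = 0.119
_CLASS_COUNTS = {
    "definitive_meth": 32051,
    "transitory_meth": 822,
    "definitive_unmeth": 27735,
    "transitory_unmeth": 4227,
}
_TOTAL = sum(_CLASS_COUNTS.values())
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "stable_unmeth": (1.0 - _CHANGED) / 2,
    "stable_meth": (1.0 - _CHANGED) / 2,
    **{k: _CHANGED * v / _TOTAL for k, v in _CLASS_COUNTS.items()},
}

#: Share of definitive changes completed at each transition; about two-thirds
#: of changes are already in place in low-grade adenomas.
DEFAULT_TIMING_PROBS: dict[str, float] = {
    "to_LGA": 0.674,
    "to_HGA": 0.2,
    "to_ADK": 0.126,
}

#: Purity Beta-law parameters (a, b, loc, scale) per group; adenomas centre
#: near 0.5 and adenocarcinomas higher, encoding the lower cellularity of
#: adenoma specimens.  NONTUMOR purity is fixed at 0.
DEFAULT_PURITY_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "LGA": (4.0, 4.0, 0.0, 1.0),
    "HGA": (4.0, 4.0, 0.0, 1.0),
    "ADK": (8.0, 3.0, 0.0, 1.0),
}

# Island-context sampling weights by methylation direction of the planted
# change (order matches ISLAND_CONTEXTS).
_CONTEXT_WEIGHTS = {
    "gain": (0.45, 0.175, 0.175, 0.04, 0.04, 0.12),
    "loss": (0.08, 0.06, 0.06, 0.16, 0.16, 0.48),
    "none": (0.30, 0.12, 0.12, 0.08, 0.08, 0.30),
}


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults encode the emulated study design."""

    n_probes: int = 20000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NONTUMOR": 20, "LGA": 12, "HGA": 19, "ADK": 22}
    )
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    timing_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIMING_PROBS)
    )
    purity_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PURITY_PARAMS)
    )
    noise_concentration: float | None = 80.0  # None disables measurement noise
    low_level: float = 0.1
    high_level: float = 0.9
    stromal_logit_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_proportions) != set(CLASSES):
            raise SimulationConfigError(
                f"class_proportions must cover exactly {CLASSES}"
            )
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(
                f"class proportions sum to {total!r}, expected 1"
            )
        if abs(sum(self.timing_probs.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("timing probabilities must sum to 1")
        if any(n < 2 for n in self.group_sizes.values()):
            raise SimulationConfigError("every group needs at least 2 samples")
        if not 0 < self.low_level < 0.5 < self.high_level < 1:
            raise SimulationConfigError(
                "levels must satisfy 0 < low < 0.5 < high < 1"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a generated dataset.

    ``probes``: per-probe class, timing, direction and pure-cell beta level per
    group.  ``samples``: per-sample group and true purity.  ``biomarkers``
    maps designated biomarker probe ids to their planted stage label.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    biomarkers: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probes": self.probes.reset_index().to_dict(orient="list"),
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "biomarkers": self.biomarkers,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        probes = pd.DataFrame(payload["probes"]).set_index("probe_id")
        samples = pd.DataFrame(payload["samples"]).set_index("sample_id")
        return cls(probes=probes, samples=samples, biomarkers=payload["biomarkers"])


def _level_pattern(cls: str, timing: str | None, low: float, high: float):
    """Pure dysplastic-cell beta across the four groups for one probe."""
    L, H = low, high
    if cls == "stable_unmeth":
        return (L, L, L, L)
    if cls == "stable_meth":
        return (H, H, H, H)
    if cls == "definitive_meth":
        k = TIMINGS.index(timing)
        return tuple(L if i <= k else H for i in range(4))  # change after stage k
    if cls == "definitive_unmeth":
        k = TIMINGS.index(timing)
        return tuple(H if i <= k else L for i in range(4))
    if cls == "transitory_meth":
        return (L, H, H, L)
    if cls == "transitory_unmeth":
        return (H, L, L, H)
    raise ValueError(cls)


def _direction(cls: str) -> str:
    if cls.endswith("_meth") and not cls.startswith("stable"):
        return "gain"
    if cls.endswith("_unmeth") and not cls.startswith("stable"):
        return "loss"
    return "none"


def build_truth(cfg: SimulationConfig, rng: np.random.Generator) -> SyntheticTruth:
    """Draw the planted per-probe classes/levels and per-sample purities."""
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    classes = rng.choice(
        CLASSES, size=cfg.n_probes, p=[cfg.class_proportions[c] for c in CLASSES]
    )
    timings = np.full(cfg.n_probes, "not_applicable", dtype=object)
    definitive = np.isin(classes, ("definitive_meth", "definitive_unmeth"))
    timings[definitive] = rng.choice(
        TIMINGS, size=int(definitive.sum()), p=[cfg.timing_probs[t] for t in TIMINGS]
    )

    levels = np.empty((cfg.n_probes, 4))
    for i, (cls, t) in enumerate(zip(classes, timings)):
        levels[i] = _level_pattern(
            cls, None if t == "not_applicable" else t, cfg.low_level, cfg.high_level
        )

    probes = pd.DataFrame(
        {
            "class": classes,
            "timing": timings,
            "direction": [_direction(c) for c in classes],
            **{f"level_{g}": levels[:, j] for j, g in enumerate(GROUPS)},
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    sample_rows = []
    for g in GROUPS:
        n = cfg.group_sizes[g]
        if g == "NONTUMOR":
            purity = np.zeros(n)
        else:
            a, b, loc, scale = cfg.purity_params[g]
            purity = loc + scale * rng.beta(a, b, size=n)
        for j in range(n):
            sample_rows.append((f"{g}_{j:03d}", g, purity[j]))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "group", "purity"]
    ).set_index("sample_id")

    return SyntheticTruth(probes=probes, samples=samples)


def plant_biomarkers(
    truth: SyntheticTruth,
    panel: pd.DataFrame,
    stage_map: dict[str, str],
) -> SyntheticTruth:
    """Overwrite designated probes so each biomarker follows its stage pattern.

    ``panel`` needs columns ``gene`` and ``probe_id``; ``stage_map`` maps gene
    symbol to a stage label in :data:`STAGE_PATTERNS`.  Panel probes absent
    from the truth table are appended.
    """
    bad = set(stage_map.values()) - set(STAGE_PATTERNS)
    if bad:
        raise SimulationConfigError(f"unknown stage labels: {sorted(bad)}")

    probes = truth.probes.copy()
    low = probes[[f"level_{g}" for g in GROUPS]].to_numpy().min()
    high = probes[[f"level_{g}" for g in GROUPS]].to_numpy().max()
    if high <= 0.5:  # degenerate truth with no methylated probes
        high = 0.9
    if low >= 0.5:
        low = 0.1

    biomarkers = dict(truth.biomarkers)
    for _, row in panel.iterrows():
        gene, probe = row["gene"], row["probe_id"]
        if gene not in stage_map:
            continue
        stage = stage_map[gene]
        pattern = STAGE_PATTERNS[stage]
        levels = {
            f"level_{g}": (high if bit else low) for g, bit in zip(GROUPS, pattern)
        }
        if stage == "early":
            cls, timing = "definitive_meth", "to_LGA"
        elif stage == "high_grade_onset":
            cls, timing = "definitive_meth", "to_HGA"
        elif stage == "carcinoma_onset":
            cls, timing = "definitive_meth", "to_ADK"
        else:
            cls, timing = "stable_unmeth", "not_applicable"
        probes.loc[probe, ["class", "timing", "direction"]] = [
            cls,
            timing,
            _direction(cls),
        ]
        probes.loc[probe, list(levels)] = list(levels.values())
        biomarkers[probe] = stage
    # appended probes may have NaN direction fields if brand new; fill
    probes["direction"] = probes["direction"].fillna("none")
    return replace(truth, probes=probes, biomarkers=biomarkers)


def synthesize_annotation(
    truth: SyntheticTruth, rng: np.random.Generator, genes_per_block: int = 8
) -> ProbeAnnotation:
    """Draw island contexts (direction-biased) and gene/region annotations."""
    n = len(truth.probes)
    contexts = np.empty(n, dtype=object)
    for direction, weights in _CONTEXT_WEIGHTS.items():
        mask = (truth.probes["direction"] == direction).to_numpy()
        contexts[mask] = rng.choice(ISLAND_CONTEXTS, size=int(mask.sum()), p=weights)

    chroms = [f"chr{1 + i % 22}" for i in range(n)]
    gene_ids = [f"GENE{i // genes_per_block:05d}" for i in range(n)]
    regions = rng.choice(REGION_GROUPS, size=n)
    frame = pd.DataFrame(
        {
            "chr": chroms,
            "pos": np.arange(1, n + 1) * 1000,
            "island_context": contexts,
            "gene_symbols": [[g] for g in gene_ids],
            "region_groups": [[r] for r in regions],
        },
        index=truth.probes.index,
    )
    return ProbeAnnotation(frame)


def synthesize_matrix(
    truth: SyntheticTruth, cfg: SimulationConfig, rng: np.random.Generator
) -> BetaMatrix:
    """Realise an observed beta matrix from planted truth.

    Mixture mean per (probe, sample): ``p * level_group + (1 - p) * stromal``
    where the stromal profile is the probe's non-tumor level with per-sample
    logit jitter; then Beta noise at the configured concentration.
    """
    levels = truth.probes[[f"level_{g}" for g in GROUPS]].to_numpy()
    level_by_group = {g: levels[:, j] for j, g in enumerate(GROUPS)}
    stromal_base = level_by_group["NONTUMOR"]

    n_probes = len(truth.probes)
    cols = {}
    for sample_id, row in truth.samples.iterrows():
        p = float(row["purity"])
        jitter = rng.normal(0.0, cfg.stromal_logit_sd, size=n_probes)
        base = np.clip(stromal_base, 1e-6, 1 - 1e-6)
        stromal = 1.0 / (1.0 + np.exp(-(np.log(base / (1 - base)) + jitter)))
        mu = p * level_by_group[row["group"]] + (1.0 - p) * stromal
        mu = np.clip(mu, 1e-6, 1.0 - 1e-6)
        if cfg.noise_concentration is None or not np.isfinite(cfg.noise_concentration):
            beta = mu
        else:
            kappa = cfg.noise_concentration
            beta = rng.beta(mu * kappa, (1.0 - mu) * kappa)
        cols[sample_id] = beta

    values = pd.DataFrame(cols, index=truth.probes.index)
    groups = truth.samples["group"]
    return BetaMatrix(values=values, groups=groups)


def generate_dataset(
    cfg: SimulationConfig,
    biomarker_panel: pd.DataFrame | None = None,
    stage_map: dict[str, str] | None = None,
) -> tuple[BetaMatrix, ProbeAnnotation, SampleSheet, SyntheticTruth]:
    """Generate a full synthetic dataset; identical seed, identical output."""
    rng = np.random.default_rng(cfg.seed)
    truth = build_truth(cfg, rng)
    if biomarker_panel is not None and stage_map is not None:
        truth = plant_biomarkers(truth, biomarker_panel, stage_map)
    ann = synthesize_annotation(truth, rng)
    bm = synthesize_matrix(truth, cfg, rng)
    sheet = SampleSheet(
        truth.samples.reset_index()[["sample_id", "group", "purity"]]
    )
    return bm, ann, sheet, truth
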