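"""End-to-end orchestration: load -> filter -> MLH1 exclusion -> purity ->
M conversion -> DMC calling -> trajectory -> context/gene enrichment ->
biomarkers -> PCA, with a machine-readable run report.

One seed governs every stochastic step (PCA downsampling; simulation when a
synthetic run is requested) via named substreams, so stages remain
individually reproducible.  Identical config + seed produces an identical
report hash (the timestamp field is excluded from hashing).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import diffmeth, purity, structure, trajectory
from .core import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    filter_probes,
    read_beta_matrix,
    read_manifest,
    read_sample_sheet,
    to_m_values,
)
from .simulate import SyntheticTruth

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: Truth-table class names -> trajectory-call class names.
TRUTH_TO_CALL = {
    "stable_unmeth": "stable",
    "stable_meth": "stable",
    "definitive_meth": "definitive_methylation",
    "definitive_unmeth": "definitive_unmethylation",
    "transitory_meth": "transitory_methylation",
    "transitory_unmeth": "transitory_unmethylation",
}


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one analysis run."""

    beta_matrix: str | None = None
    sample_sheet: str | None = None
    manifest: str | None = None
    gene_sets: str | None = None
    biomarker_panel: str | None = None  # None -> packaged panel
    output_dir: str = "crcmeth_run"
    q_threshold: float = 1e-4
    delta_m_threshold: float = 2.0
    beta_cutoff: float = 0.3
    mlh1_cutoff: float = 0.3
    mlh1_probes: list[str] = field(default_factory=list)
    exclude_mlh1_flagged: bool = True
    drop_sex_chromosomes: bool = True
    max_missing_fraction: float = 0.2
    purity_k: int = 1000
    purity_min_delta: float = 0.2
    pca_components: int = 17
    pca_downsample_group: str | None = "NONTUMOR"
    pca_downsample_n: int = 20
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        if not 0 < self.q_threshold < 1:
            raise PipelineConfigError(
                f"q_threshold must lie in (0, 1), got {self.q_threshold}"
            )
        if self.delta_m_threshold < 0:
            raise PipelineConfigError("delta_m_threshold must be >= 0")
        for name in ("beta_cutoff", "mlh1_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PipelineConfigError(f"{name} must lie in [0, 1], got {v}")
        if check_paths:
            for name in ("beta_matrix", "sample_sheet", "manifest"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineConfigError(f"config missing required path {name}")
                if not Path(p).exists():
                    raise PipelineConfigError(f"{name} path does not exist: {p}")
            for name in ("gene_sets", "biomarker_panel"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise PipelineConfigError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the run seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


#: Report fields that vary between identical runs and are excluded from hashing.
_VOLATILE_FIELDS = frozenset({"timestamp", "elapsed_s", "report_hash"})


def report_hash(report: dict) -> str:
    """Hash of the report with wall-clock fields excluded."""
    clean = {k: v for k, v in report.items() if k not in _VOLATILE_FIELDS}
    return hashlib.sha256(
        json.dumps(clean, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(
    cfg: PipelineConfig,
    bm: BetaMatrix | None = None,
    ann: ProbeAnnotation | None = None,
    sheet: SampleSheet | None = None,
    write_artifacts: bool = True,
) -> dict:
    """Execute all stages; returns the run report (and writes artifacts).

    In-memory inputs may be passed directly (synthetic runs); otherwise they
    are loaded from the configured paths.
    """
    cfg.validate(check_paths=bm is None)
    out = Path(cfg.output_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)

    t_start = time.time()
    if bm is None:
        sheet = read_sample_sheet(cfg.sample_sheet)
        bm = read_beta_matrix(cfg.beta_matrix, sheet)
        ann = read_manifest(cfg.manifest)
    assert ann is not None
    n_samples_before = {
        g: int(n) for g, n in bm.sample_groups().value_counts().items()
    }
    logger.info("loaded %d probes x %d samples", *bm.shape)

    # --- probe filtering
    bm, filter_log = filter_probes(
        bm,
        ann,
        drop_sex_chromosomes=cfg.drop_sex_chromosomes,
        max_missing_fraction=cfg.max_missing_fraction,
    )
    logger.info("probe filter: %s", filter_log.counts)

    # --- MLH1 exclusion
    mlh1_flags = None
    if cfg.mlh1_probes:
        mlh1_flags = purity.flag_mlh1_methylation(
            bm, cfg.mlh1_probes, cutoff=cfg.mlh1_cutoff
        )
        if cfg.exclude_mlh1_flagged:
            keep = mlh1_flags.index[~mlh1_flags["flagged"]]
            bm = bm.subset_samples([s for s in bm.sample_ids if s in set(keep)])
        if write_artifacts:
            mlh1_flags.to_csv(out / "flags.tsv", sep="\t")
    n_samples_after = {
        g: int(n) for g, n in bm.sample_groups().value_counts().items()
    }

    # --- purity (adenomas and adenocarcinomas estimated separately)
    purity_frames = []
    for target in ("LGA", "HGA", "ADK"):
        if len(bm.samples_in_group(target)) >= 2:
            purity_frames.append(
                purity.estimate_purity_all(
                    bm,
                    "NONTUMOR",
                    target,
                    k=cfg.purity_k,
                    min_delta=cfg.purity_min_delta,
                )
            )
    purity_table = pd.concat(purity_frames) if purity_frames else pd.DataFrame()
    purity_summary = {}
    if len(purity_table):
        purity_summary = {
            g: float(v)
            for g, v in purity_table.groupby("group")["purity"].median().items()
        }
        est_lga_hga = purity_table[purity_table["group"].isin(["LGA", "HGA"])]
        if (
            len(est_lga_hga[est_lga_hga["group"] == "LGA"]) >= 3
            and len(est_lga_hga[est_lga_hga["group"] == "HGA"]) >= 3
        ):
            purity_summary["lga_vs_hga_p"] = purity.compare_purity_groups(
                est_lga_hga, "LGA", "HGA"
            )["p_value"]
        if write_artifacts:
            purity_table.to_csv(out / "purity.tsv", sep="\t")

    # --- M conversion + DMC calling
    mv = to_m_values(bm)
    records, fit, eb_params, dmc_summary = diffmeth.run_dmc_analysis(
        mv,
        q_threshold=cfg.q_threshold,
        delta_threshold=cfg.delta_m_threshold,
    )
    union = diffmeth.dmc_union(records)
    if write_artifacts:
        records.to_csv(out / "dmc_records.tsv", sep="\t", index=False)
        (out / "dmc_summary.json").write_text(json.dumps(dmc_summary, indent=2))

    # --- trajectory classification (DMC probes)
    calls = trajectory.classify_all(mv.group_means())
    traj_summary = trajectory.summarize_trajectories(calls, union)
    if write_artifacts:
        calls.to_csv(out / "trajectory_calls.tsv", sep="\t")
        (out / "trajectory_summary.json").write_text(json.dumps(traj_summary, indent=2))

    # --- context enrichment per direction
    dmc_hits = records.loc[records["is_dmc"]]
    context_tables = []
    for direction in ("gain", "loss"):
        probes = dmc_hits.loc[dmc_hits["direction"] == direction, "probe_id"].unique()
        context_tables.append(
            ann_mod.context_enrichment(probes, bm.probe_ids, ann, direction)
        )
    context_table = pd.concat(context_tables, ignore_index=True)
    if write_artifacts:
        context_table.to_csv(out / "context_enrichment.tsv", sep="\t", index=False)

    # --- promoter genes + optional gene-set enrichment
    hit_genes, _ = ann_mod.map_promoter_genes(union, ann)
    universe = ann_mod.promoter_universe(ann)
    geneset_table = None
    if cfg.gene_sets:
        sets = ann_mod.read_gmt(cfg.gene_sets)
        geneset_table = ann_mod.geneset_enrichment(hit_genes & universe, universe, sets)
        if write_artifacts:
            geneset_table.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)

    # --- biomarker staging
    panel = (
        pd.read_csv(cfg.biomarker_panel)
        if cfg.biomarker_panel
        else ann_mod.load_biomarker_panel()
    )
    panel_present = panel[panel["probe_id"].isin(bm.probe_ids)]
    biomarker_table = None
    if len(panel_present):
        biomarker_table = ann_mod.evaluate_biomarkers(
            bm, panel_present, cutoff=cfg.beta_cutoff
        )
        if write_artifacts:
            biomarker_table.to_csv(out / "biomarkers.tsv", sep="\t", index=False)

    # --- PCA
    downsample = None
    if cfg.pca_downsample_group is not None:
        n_avail = len(bm.samples_in_group(cfg.pca_downsample_group))
        if n_avail >= cfg.pca_downsample_n:
            pca_seed = int(substream(cfg.seed, "pca").integers(0, 2**31 - 1))
            downsample = (cfg.pca_downsample_group, cfg.pca_downsample_n, pca_seed)
    embedding = structure.run_pca(mv, k=cfg.pca_components, downsample=downsample)
    if write_artifacts:
        embedding.coordinates.to_csv(out / "embedding.tsv", sep="\t")

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "timestamp": time.time(),
        "samples_before_exclusion": n_samples_before,
        "samples_after_exclusion": n_samples_after,
        "mlh1_flagged": (
            [] if mlh1_flags is None else list(mlh1_flags.index[mlh1_flags["flagged"]])
        ),
        "probes_tested": int(bm.shape[0]),
        "probes_removed": filter_log.counts,
        "ebayes": {"d0": float(eb_params.d0), "s02": float(eb_params.s02)},
        "dmc": dmc_summary,
        "trajectory": traj_summary,
        "context_enrichment": context_table.to_dict(orient="records"),
        "n_promoter_hit_genes": len(hit_genes),
        "biomarkers": (
            [] if biomarker_table is None else biomarker_table.to_dict(orient="records")
        ),
        "purity_summary": purity_summary,
        "pca_explained_variance": [float(v) for v in embedding.explained_variance_ratio],
        "elapsed_s": round(time.time() - t_start, 3),
    }
    report["report_hash"] = report_hash(report)
    if write_artifacts:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def validate_report(
    report: dict,
    truth: SyntheticTruth,
    calls: pd.DataFrame,
    purity_table: pd.DataFrame | None = None,
) -> dict:
    """Recovery metrics of a synthetic run against its planted truth.

    ``calls`` is the per-probe trajectory table of the run.  Reports per-class
    precision/recall on DMC probes, purity MAE/rank correlation when purity
    estimates are supplied, and the early-fraction error.
    """
    probes = calls.index.intersection(truth.probes.index)
    if len(probes) == 0:
        raise ValueError("truth and report share no probes")
    truth_cls = truth.probes.loc[probes, "class"].map(TRUTH_TO_CALL)
    pred_cls = calls.loc[probes, "class"]

    per_class = {}
    for cls in set(truth_cls):
        tp = int(((truth_cls == cls) & (pred_cls == cls)).sum())
        fn = int(((truth_cls == cls) & (pred_cls != cls)).sum())
        fp = int(((truth_cls != cls) & (pred_cls == cls)).sum())
        per_class[cls] = {
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "n_true": tp + fn,
        }

    truth_def = truth.probes.loc[probes]
    truth_def = truth_def[truth_def["class"].isin(["definitive_meth", "definitive_unmeth"])]
    planted_early = (
        float((truth_def["timing"] == "to_LGA").mean()) if len(truth_def) else float("nan")
    )
    early_err = report["trajectory"]["early_fraction"] - planted_early

    metrics = {
        "per_class": per_class,
        "planted_early_fraction": planted_early,
        "early_fraction_error": float(early_err),
    }
    if purity_table is not None and len(purity_table):
        shared = purity_table.index.intersection(truth.samples.index)
        if len(shared) == 0:
            raise ValueError("purity estimates and truth share no samples")
        est = purity_table.loc[shared, "purity"].astype(float)
        true = truth.samples.loc[shared, "purity"].astype(float)
        from scipy import stats as _stats

        metrics["purity_mae"] = float((est - true).abs().mean())
        metrics["purity_spearman"] = float(_stats.spearmanr(est, true).statistic)
    return metrics
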