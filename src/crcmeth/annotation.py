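"""Genomic-context enrichment, promoter gene mapping, gene-set enrichment and
the clinical biomarker staging panel.

Context enrichment asks whether DMCs of a given direction (gain/loss) are
over-represented in each CpG-density context (island, shores, shelves, open
sea) relative to all tested probes, via a 2x2 Fisher exact test per context
with BH correction across contexts.  In colorectal oncogenesis methylation
gains concentrate in islands and shores while losses concentrate in shelves
and open sea; the synthetic generator plants exactly that signal.

Promoter mapping follows the array convention: a probe is promoter-associated
for a gene when its region group is TSS200, TSS1500 or 1stExon.  Gene-set
enrichment is the upper-tail hypergeometric test of the overlap between hit
genes and each supplied set (GMT format), against the universe of genes with
at least one promoter probe on the array.

The packaged biomarker panel lists published colorectal-cancer methylation
biomarkers (gene, CpG probe, region, specimen).  A gene's stage label comes
from the per-group fraction of samples methylated (beta >= 0.3): methylated
in a group means that fraction >= 0.5.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ISLAND_CONTEXTS,
    PROMOTER_REGIONS,
    BetaMatrix,
    ProbeAnnotation,
)
from .diffmeth import bh_adjust

BETA_CUTOFF = 0.3  # beta at or above this counts a sample as methylated
MAJORITY = 0.5  # fraction of samples needed for a group to count as methylated

STAGE_LABELS: tuple[str, ...] = (
    "early",
    "high_grade_onset",
    "carcinoma_onset",
    "non_informative",
)


# ---------------------------------------------------------------------------
# Context enrichment


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Odds ratio with Haldane 0.5 correction applied when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def context_enrichment(
    dmc_probes,
    tested_probes,
    ann: ProbeAnnotation,
    direction: str,
    merge_shores_shelves: bool = False,
) -> pd.DataFrame:
    """Per-context 2x2 Fisher enrichment of DMCs among tested probes.

    ``dmc_probes`` are the DMCs of one direction; ``tested_probes`` the full
    analysis universe.  Shores and shelves may be merged (N_+S_) on request.
    """
    tested = pd.Index(tested_probes)
    dmcs = pd.Index(dmc_probes).intersection(tested)
    ctx = ann.frame.loc[tested, "island_context"].copy()
    if merge_shores_shelves:
        ctx = ctx.str.replace(r"^[NS]_", "", regex=True)
        contexts = ("Island", "Shore", "Shelf", "OpenSea")
    else:
        contexts = ISLAND_CONTEXTS
    is_dmc = ctx.index.isin(dmcs)

    rows = []
    for context in contexts:
        in_ctx = (ctx == context).to_numpy()
        a = int(np.sum(is_dmc & in_ctx))
        b = int(np.sum(is_dmc & ~in_ctx))
        c = int(np.sum(~is_dmc & in_ctx))
        d = int(np.sum(~is_dmc & ~in_ctx))
        if a + c == 0:  # context absent from the data
            rows.append((context, direction, a, b, c, d, np.nan, 1.0))
            continue
        p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        rows.append((context, direction, a, b, c, d, _odds_ratio(a, b, c, d), p))
    out = pd.DataFrame(
        rows,
        columns=["island_context", "direction", "a", "b", "c", "d", "odds_ratio", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Promoter mapping and gene-set enrichment


def map_promoter_genes(
    probes, ann: ProbeAnnotation
) -> tuple[set[str], pd.DataFrame]:
    """Genes with a promoter-region probe among ``probes``.

    Returns the gene set and the probe->gene mapping table (promoter rows
    only).  A probe mapping to several genes contributes each gene whose
    paired region group is a promoter category.
    """
    probes = [p for p in probes if p in ann.probe_ids]
    records = []
    for probe in probes:
        row = ann.frame.loc[probe]
        for gene, region in zip(row["gene_symbols"], row["region_groups"]):
            if region in PROMOTER_REGIONS:
                records.append((probe, gene, region))
    table = pd.DataFrame(records, columns=["probe_id", "gene", "region_group"])
    return set(table["gene"]), table


def promoter_universe(ann: ProbeAnnotation) -> set[str]:
    """All genes with at least one promoter probe on the array."""
    genes, _ = map_promoter_genes(ann.probe_ids, ann)
    return genes


def geneset_enrichment(
    hit_genes, universe_genes, gene_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each gene set.

    Sets are intersected with the universe; rows sorted by q then overlap.
    """
    universe = set(universe_genes)
    hits = set(hit_genes)
    outside = hits - universe
    if outside:
        raise ValueError(f"hit genes outside universe: {sorted(outside)[:10]}")
    N, n = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & hits)
        # P(overlap >= k) drawing n genes from N with K marked
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "overlap"], ascending=[True, False]).reset_index(
        drop=True
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line — name, description, member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# Biomarker panel


def load_biomarker_panel() -> pd.DataFrame:
    """The packaged panel of published CRC methylation biomarkers."""
    with resources.files("crcmeth.data").joinpath("biomarker_panel.csv").open() as fh:
        return pd.read_csv(fh)


def stage_from_fractions(fractions: dict[str, float], majority: float = MAJORITY) -> str:
    """Stage label from per-group methylated-sample fractions.

    early: majority-methylated in LGA, HGA and ADK; high_grade_onset: in HGA
    and ADK but not LGA; carcinoma_onset: ADK only; non_informative: not
    methylated in ADK.
    """
    lga = fractions.get("LGA", 0.0) >= majority
    hga = fractions.get("HGA", 0.0) >= majority
    adk = fractions.get("ADK", 0.0) >= majority
    if not adk:
        return "non_informative"
    if lga and hga:
        return "early"
    if hga:
        return "high_grade_onset"
    return "carcinoma_onset"


def evaluate_biomarkers(
    bm: BetaMatrix,
    panel: pd.DataFrame | None = None,
    cutoff: float = BETA_CUTOFF,
    majority: float = MAJORITY,
) -> pd.DataFrame:
    """Per-biomarker methylated-sample fractions by group and stage label."""
    if panel is None:
        panel = load_biomarker_panel()
    labels = bm.sample_groups()
    groups = [g for g in ("NONTUMOR", "LGA", "HGA", "ADK") if (labels == g).any()]
    if not any(p in bm.probe_ids for p in panel["probe_id"]):
        raise ValueError("no panel probe present in the matrix")

    rows = []
    for _, entry in panel.iterrows():
        probe = entry["probe_id"]
        if probe not in bm.probe_ids:
            warnings.warn(f"panel probe {probe} absent from matrix", stacklevel=2)
            rows.append(
                {
                    "gene": entry["gene"],
                    "probe_id": probe,
                    "region_group": entry.get("region_group", ""),
                    **{f"frac_{g}": np.nan for g in groups},
                    "stage": "missing",
                }
            )
            continue
        fracs = {}
        for g in groups:
            vals = bm.values.loc[probe, labels.index[labels == g]].astype(float)
            fracs[g] = float((vals >= cutoff).mean())
        rows.append(
            {
                "gene": entry["gene"],
                "probe_id": probe,
                "region_group": entry.get("region_group", ""),
                **{f"frac_{g}": fracs[g] for g in groups},
                "stage": stage_from_fractions(fracs, majority),
            }
        )
    return pd.DataFrame(rows)
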