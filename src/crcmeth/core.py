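"""Core data model for methylation-array analysis.

Beta values are per-CpG methylation fractions in [0, 1]; M values are their
logit-2 transform ``M = log2(beta / (1 - beta))``, the variance-stabilised
scale used for linear modelling.  Samples belong to one of four ordered
histology groups along the adenoma-carcinoma sequence:

    NONTUMOR < LGA (low-grade adenoma) < HGA (high-grade adenoma)
             < ADK (adenocarcinoma)

Matrices are oriented probes-in-rows, samples-in-columns, the dominant
array-data convention.  Missing beta values are carried as NaN and excluded
pairwise downstream; probes exceeding a missingness threshold are dropped by
:func:`filter_probes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Ordered tissue groups of the adenoma-carcinoma sequence.
GROUPS: tuple[str, ...] = ("NONTUMOR", "LGA", "HGA", "ADK")

ISLAND_CONTEXTS: tuple[str, ...] = (
    "Island",
    "N_Shore",
    "S_Shore",
    "N_Shelf",
    "S_Shelf",
    "OpenSea",
)

REGION_GROUPS: tuple[str, ...] = (
    "TSS200",
    "TSS1500",
    "1stExon",
    "5UTR",
    "Body",
    "3UTR",
)

#: Probe-to-gene region categories counted as promoter.
PROMOTER_REGIONS: frozenset[str] = frozenset({"TSS200", "TSS1500", "1stExon"})

SEX_CHROMOSOMES: frozenset[str] = frozenset({"chrX", "chrY"})


class ConfigurationError(ValueError):
    """Sample sheet / configuration inconsistent with the data."""


class BetaParseError(ValueError):
    """A beta-matrix cell could not be parsed or violates [0, 1]."""


class AnnotationError(ValueError):
    """Probes required by an operation are missing from the annotation."""


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: group label, optional known purity and platform."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ConfigurationError(f"duplicate sample ids: {sorted(set(dups))}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise ConfigurationError(
                f"unknown group labels {sorted(bad)}; expected one of {GROUPS}"
            )
        if "purity" in self.frame.columns:
            pur = self.frame["purity"].dropna()
            if ((pur < 0) | (pur > 1)).any():
                raise ConfigurationError("purity values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            self.frame["group"].values, index=self.frame["sample_id"].values, name="group"
        )

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV with columns ``sample_id,group[,purity,platform]``."""
    frame = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    return SampleSheet(frame)


# ---------------------------------------------------------------------------
# Beta / M matrices


@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples matrix of methylation fractions with group labels.

    ``values`` is a DataFrame indexed by probe id with one column per sample;
    NaN marks missing measurements.  ``groups`` maps sample id -> group label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise BetaParseError("duplicate probe ids")
        if self.values.columns.duplicated().any():
            raise BetaParseError("duplicate sample ids")
        unlabelled = set(self.values.columns) - set(self.groups.index)
        if unlabelled:
            raise ConfigurationError(f"samples without group label: {sorted(unlabelled)}")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise BetaParseError(
                f"beta value {arr[i, j]} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_groups(self) -> pd.Series:
        """Group label per sample, aligned to the matrix column order."""
        return self.groups.reindex(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        labels = self.sample_groups()
        return list(labels.index[labels == group])

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return replace(self, values=self.values.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return replace(self, values=self.values[list(sample_ids)])


@dataclass(frozen=True)
class MValueMatrix:
    """Probes x samples matrix of M values (unbounded logit-2 scores)."""

    values: pd.DataFrame
    groups: pd.Series

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def sample_groups(self) -> pd.Series:
        return self.groups.reindex(self.values.columns)

    def group_means(self, groups: tuple[str, ...] = GROUPS) -> pd.DataFrame:
        """Per-probe mean M value for each group (NaN-aware)."""
        labels = self.sample_groups()
        cols = {}
        for g in groups:
            members = labels.index[labels == g]
            if len(members):
                cols[g] = self.values[members].mean(axis=1)
        return pd.DataFrame(cols)


def beta_to_m(beta, epsilon: float = 0.001):
    """Convert beta fractions to M values, ``M = log2(b / (1 - b))``.

    Betas are clamped to ``[epsilon, 1 - epsilon]`` so boundary values map to
    finite scores; NaN propagates.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` away from the clamp bounds."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)


def to_m_values(bm: BetaMatrix, epsilon: float = 0.001) -> MValueMatrix:
    """Transform a whole BetaMatrix to the M scale."""
    vals = pd.DataFrame(
        beta_to_m(bm.values.to_numpy(dtype=float), epsilon=epsilon),
        index=bm.values.index,
        columns=bm.values.columns,
    )
    return MValueMatrix(values=vals, groups=bm.groups)


def read_beta_matrix(path: str | Path, sample_sheet: SampleSheet) -> BetaMatrix:
    """Read a delimited beta matrix (first column ``probe_id``, one column per
    sample) and validate it against the sample sheet.

    The delimiter is inferred from the extension (.tsv -> tab, else comma).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    first = raw.columns[0]
    if first != "probe_id":
        raise BetaParseError(
            f"first column must be named 'probe_id', found {first!r}"
        )
    raw = raw.set_index("probe_id")
    absent = [s for s in sample_sheet.sample_ids if s not in raw.columns]
    if absent:
        raise ConfigurationError(
            f"sample sheet lists samples absent from matrix header: {absent}"
        )
    raw = raw[sample_sheet.sample_ids]
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        newly_bad = coerced.isna() & raw[col].notna()
        if newly_bad.any():
            probe = raw.index[newly_bad][0]
            raise BetaParseError(
                f"non-numeric value {raw.loc[probe, col]!r} at probe {probe!r}, "
                f"sample {col!r}"
            )
        raw[col] = coerced
    return BetaMatrix(values=raw.astype(float), groups=sample_sheet.groups)


def write_beta_matrix(bm: BetaMatrix, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    bm.values.to_csv(path, sep=sep, index_label="probe_id")


# ---------------------------------------------------------------------------
# Probe annotation


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe genomic metadata.

    ``frame`` is indexed by probe id with columns ``chr`` (chr1..chr22, chrX,
    chrY), ``pos`` (1-based), ``island_context`` (one of the six CpG-density
    annuli), ``gene_symbols`` and ``region_groups`` (index-paired lists; a
    probe may map to several genes, each with its own region category).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chr", "pos", "island_context", "gene_symbols", "region_groups"}
        missing = required - set(self.frame.columns)
        if missing:
            raise AnnotationError(f"annotation missing columns: {sorted(missing)}")
        bad = set(self.frame["island_context"]) - set(ISLAND_CONTEXTS)
        if bad:
            raise AnnotationError(f"unknown island_context values: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    def chromosomes(self) -> pd.Series:
        return self.frame["chr"]

    def subset(self, probe_ids) -> "ProbeAnnotation":
        return ProbeAnnotation(self.frame.loc[list(probe_ids)])

    def gene_region_pairs(self) -> pd.DataFrame:
        """Long table of (probe_id, gene, region_group), one row per mapping."""
        records = []
        for probe, row in self.frame.iterrows():
            for gene, region in zip(row["gene_symbols"], row["region_groups"]):
                records.append((probe, gene, region))
        return pd.DataFrame(records, columns=["probe_id", "gene", "region_group"])


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return str(value).split(";")


def read_manifest(path: str | Path) -> ProbeAnnotation:
    """Read a manifest CSV: ``probe_id,chr,pos,island_context,gene_symbols,
    region_groups`` with semicolon-joined multi-values."""
    frame = pd.read_csv(path, dtype={"probe_id": str, "chr": str})
    frame = frame.set_index("probe_id")
    frame["gene_symbols"] = frame["gene_symbols"].map(_split_multi)
    frame["region_groups"] = frame["region_groups"].map(_split_multi)
    return ProbeAnnotation(frame)


def write_manifest(ann: ProbeAnnotation, path: str | Path) -> None:
    out = ann.frame.copy()
    out["gene_symbols"] = out["gene_symbols"].map(";".join)
    out["region_groups"] = out["region_groups"].map(";".join)
    out.to_csv(path, index_label="probe_id")


# ---------------------------------------------------------------------------
# Probe filtering


@dataclass(frozen=True)
class FilterLog:
    """Removal counts and probe lists, keyed by reason."""

    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {reason: len(probes) for reason, probes in self.removed.items()}

    def all_removed(self) -> set[str]:
        out: set[str] = set()
        for probes in self.removed.values():
            out |= set(probes)
        return out


def filter_probes(
    bm: BetaMatrix,
    ann: ProbeAnnotation | None = None,
    drop_sex_chromosomes: bool = True,
    max_missing_fraction: float = 0.2,
) -> tuple[BetaMatrix, FilterLog]:
    """Drop sex-chromosome probes and probes with excessive missingness.

    Removal reasons partition the removed set: a probe on chrX that is also
    mostly missing is counted once, under ``sex_chromosome``.
    """
    removed: dict[str, list[str]] = {}
    keep = pd.Series(True, index=bm.probe_ids)

    if drop_sex_chromosomes:
        if ann is None:
            raise AnnotationError("sex-chromosome filtering requires an annotation")
        unannotated = bm.probe_ids.difference(ann.probe_ids)
        if len(unannotated):
            raise AnnotationError(
                f"{len(unannotated)} probes absent from annotation: "
                f"{sorted(unannotated)[:10]}"
            )
        chrom = ann.frame.loc[bm.probe_ids, "chr"]
        on_sex = chrom.isin(SEX_CHROMOSOMES)
        removed["sex_chromosome"] = list(bm.probe_ids[on_sex])
        keep &= ~on_sex

    miss_frac = bm.values.isna().mean(axis=1)
    too_missing = (miss_frac > max_missing_fraction) & keep
    removed["missingness"] = list(bm.probe_ids[too_missing])
    keep &= ~too_missing

    filtered = bm.subset_probes(bm.probe_ids[keep])
    return filtered, FilterLog(removed=removed)
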