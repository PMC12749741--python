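"""Shared plumbing for the numbered analysis scripts: one seeded synthetic
study dataset under results/data/, generated on first use."""

from __future__ import annotations

from pathlib import Path

from crcmeth.core import read_beta_matrix, read_manifest, read_sample_sheet, write_beta_matrix, write_manifest
from crcmeth.simulate import SimulationConfig, SyntheticTruth, generate_dataset

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

#: Study conditions of the emulated design: four groups at the cohort sizes
#: (20/12/19/22), 20,000 probes, purity at least 0.6 so tissue-level status
#: is identifiable, pure-signal levels 0.2/0.8.
STUDY_CONFIG = dict(
    n_probes=20_000,
    low_level=0.2,
    high_level=0.8,
    purity_params={
        "LGA": (2.0, 2.0, 0.6, 0.4),
        "HGA": (2.0, 2.0, 0.6, 0.4),
        "ADK": (8.0, 3.0, 0.6, 0.4),
    },
)


def load_or_simulate(seed: int = 2026):
    """Return (beta matrix, annotation, sheet, truth), simulating on demand."""
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    beta_path = DATA_DIR / "beta_matrix.tsv"
    if not beta_path.exists():
        cfg = SimulationConfig(seed=seed, **STUDY_CONFIG)
        bm, ann, sheet, truth = generate_dataset(cfg)
        write_beta_matrix(bm, beta_path)
        sheet.frame.to_csv(DATA_DIR / "sample_sheet.csv", index=False)
        write_manifest(ann, DATA_DIR / "manifest.csv")
        truth.to_json(DATA_DIR / "truth.json")
        return bm, ann, sheet, truth
    sheet = read_sample_sheet(DATA_DIR / "sample_sheet.csv")
    bm = read_beta_matrix(beta_path, sheet)
    ann = read_manifest(DATA_DIR / "manifest.csv")
    truth = SyntheticTruth.from_json(DATA_DIR / "truth.json")
    return bm, ann, sheet, truth
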