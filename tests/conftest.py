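import numpy as np
import pandas as pd
import pytest

from crcmeth.core import BetaMatrix, ProbeAnnotation, SampleSheet
from crcmeth.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sheet() -> SampleSheet:
    frame = pd.DataFrame(
        {
            "sample_id": ["N1", "N2", "N3", "L1", "L2", "H1", "H2", "A1", "A2"],
            "group": ["NONTUMOR"] * 3 + ["LGA"] * 2 + ["HGA"] * 2 + ["ADK"] * 2,
        }
    )
    return SampleSheet(frame)


@pytest.fixture
def small_matrix(small_sheet) -> BetaMatrix:
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(20, 9)),
        index=[f"cg{i:08d}" for i in range(20)],
        columns=small_sheet.sample_ids,
    )
    return BetaMatrix(values=values, groups=small_sheet.groups)


@pytest.fixture
def small_annotation(small_matrix) -> ProbeAnnotation:
    probes = small_matrix.probe_ids
    n = len(probes)
    frame = pd.DataFrame(
        {
            "chr": ["chrX", "chrY"] + [f"chr{1 + i % 22}" for i in range(n - 2)],
            "pos": np.arange(1, n + 1) * 100,
            "island_context": ["Island", "OpenSea"] * (n // 2),
            "gene_symbols": [[f"G{i}"] for i in range(n)],
            "region_groups": [["TSS200" if i % 2 == 0 else "Body"] for i in range(n)],
        },
        index=probes,
    )
    return ProbeAnnotation(frame)


@pytest.fixture(scope="session")
def default_synthetic():
    """One modest synthetic dataset shared by read-only tests."""
    cfg = SimulationConfig(n_probes=4000, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_synthetic():
    """Synthetic dataset under identifiable conditions: purity at least 0.6
    in every tumor sample, so group-mean statuses reflect the planted
    dysplastic-cell levels."""
    cfg = SimulationConfig(
        n_probes=6000,
        seed=19,
        low_level=0.2,
        high_level=0.8,
        purity_params={
            "LGA": (2.0, 2.0, 0.6, 0.4),
            "HGA": (2.0, 2.0, 0.6, 0.4),
            "ADK": (8.0, 3.0, 0.6, 0.4),
        },
    )
    return generate_dataset(cfg)
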