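import numpy as np
import pytest

from gcgrloc import generate, two_class_benchmark_spec
from gcgrloc.io import LabeledDataset, ProteinRecord, STANDARD_AMINO_ACIDS
from gcgrloc.svm import FusionConfig, fusion_matrix

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark_dataset() -> LabeledDataset:
    """Two compositionally separated classes, 30 sequences each."""
    return generate(two_class_benchmark_spec(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def benchmark_fusion(benchmark_dataset):
    """Precomputed 445-dim fusion matrix for the benchmark dataset."""
    return fusion_matrix(benchmark_dataset, FusionConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))


@pytest.fixture()
def toy_records() -> list[ProteinRecord]:
    return [
        ProteinRecord(id="p1", sequence="YAMQESHFTCI", label="a"),
        ProteinRecord(id="p2", sequence="MKVLAAGICK", label="b"),
        ProteinRecord(id="p3", sequence="GGSSTTPPWW", label="a"),
    ]
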