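import numpy as np
import pytest

from plantdbp.sequences import CANONICAL_RESIDUES, ProteinRecord


def random_protein(rng: np.random.Generator, length: int, prefix: str = "p",
                   index: int = 0) -> ProteinRecord:
    seq = "".join(
        CANONICAL_RESIDUES[i]
        for i in rng.integers(len(CANONICAL_RESIDUES), size=length)
    )
    return ProteinRecord(id=f"{prefix}{index}", sequence=seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def separable_dataset():
    """Small synthetic dataset with a strong compositional class shift."""
    from plantdbp.simulate import SyntheticSpec, generate

    spec = SyntheticSpec(n_pos=100, n_neg=100, effect_delta=0.12, seed=3)
    dataset, truth = generate(spec)
    return dataset, truth
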