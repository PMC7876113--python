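import numpy as np
import pytest

from pairaudit.core import InteractionDataset, PairExample, Protein


@pytest.fixture
def toy_registry():
    """Five short proteins with distinct sequences."""
    seqs = {
        "P1": "ACDEFGHIKL",
        "P2": "KLMNPQRSTV",
        "P3": "WYACDEFGHI",
        "P4": "MNPQRSTVWY",
        "P5": "GGGGAAAACC",
    }
    return {pid: Protein(pid, s) for pid, s in seqs.items()}


@pytest.fixture
def toy_dataset(toy_registry):
    pairs = [
        PairExample.make("P1", "P2", 1),
        PairExample.make("P1", "P3", 1),
        PairExample.make("P2", "P3", 0),
        PairExample.make("P4", "P5", 0),
    ]
    return InteractionDataset(toy_registry, pairs, "toy")


def random_registry(n: int, length: int = 30, seed: int = 0):
    """Programmatic registry of random sequences for property tests."""
    from pairaudit.core import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    return {
        f"R{i:03d}": Protein(
            f"R{i:03d}",
            "".join(AMINO_ACIDS[j] for j in rng.integers(20, size=length)))
        for i in range(n)
    }
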