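from __future__ import annotations

import numpy as np
import pytest

from ringcensus import ProteomeConfig, RingMatch, generate_proteome

ENRICHED_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_weights = np.ones(20)
_weights[ENRICHED_ALPHABET == "C"] = 5.0
_weights[ENRICHED_ALPHABET == "H"] = 3.0
ENRICHED_PROBS = _weights / _weights.sum()


def random_enriched_sequence(rng: np.random.Generator, length: int = 150) -> str:
    """Random sequence with elevated Cys/His frequency."""
    return "".join(rng.choice(ENRICHED_ALPHABET, size=length, p=ENRICHED_PROBS))


def make_match(
    gaps: tuple[int, ...],
    protein_id: str = "p",
    type_name: str = "RING-H2",
    start: int = 0,
) -> RingMatch:
    """Build a structurally consistent RingMatch from a gap vector."""
    positions = [start]
    for g in gaps:
        positions.append(positions[-1] + g + 1)
    return RingMatch(
        protein_id,
        tuple(positions),
        ("C",) * 8,
        tuple(gaps),
        type_name,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_proteome():
    """A small synthetic proteome shared across tests (read-only)."""
    config = ProteomeConfig(
        n_proteins=40,
        n_domains=30,
        n_decoys=5,
        tandem_clusters=(3,),
        intronless_fraction=0.3,
    )
    records, gene_models, truth = generate_proteome(config, seed=11)
    return records, gene_models, truth
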