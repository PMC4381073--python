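"""Shared fixtures: code table, fixture scale, toy pairs, synthetic sweeps.

All sequence fixtures are generated programmatically; nothing is read from
disk.  The 50-pair steered sweep is session-scoped because several test
modules interrogate the same distributions.
"""

import numpy as np
import pytest

from pyrmatch import (
    GeneratorConfig,
    RecodingConfig,
    SequencePair,
    standard_table,
    transcriptome_sweep,
)
from pyrmatch.synthetic import FIXTURE_SCALE, generate_pairs


@pytest.fixture(scope="session")
def table():
    return standard_table()


@pytest.fixture(scope="session")
def scale():
    return FIXTURE_SCALE


def make_toy_pair(seed: int = 3, n_codons: int = 45, pair_id: str = "toy") -> SequencePair:
    """A small pair with ~10 eligible positions: fixed-composition body of
    non-degenerate residues plus a shuffled tail of the variable ones."""
    rng = np.random.default_rng(seed)
    fixed = "".join(rng.choice(list("DEFHKMNQWY"), n_codons - 11))
    variable = "".join(rng.permutation(list("LIVSTARGSP")))
    protein = ("M" + fixed + variable)[:n_codons]
    cds = standard_table().back_translate(protein, rng)
    return SequencePair.from_sequences(pair_id, protein, cds + "UAA")


@pytest.fixture(scope="session")
def toy_pair():
    return make_toy_pair()


@pytest.fixture(scope="session")
def synthetic_pairs():
    """50 random pairs, 120-300 residues, uniform composition."""
    return generate_pairs(GeneratorConfig(n_pairs=50, seed=11))


@pytest.fixture(scope="session")
def sweep50(synthetic_pairs, scale):
    """Steered sweep (both directions, 1e4 steps) over the 50-pair set."""
    return transcriptome_sweep(
        synthetic_pairs, scale, RecodingConfig(n_steps=10_000, seed=101)
    )
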