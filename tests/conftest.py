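import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

_BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_genome(tmp_path):
    """A 200-kb genome with one true family and one decoy, written to disk."""
    from mitescout import FamilySpec, simulate
    from mitescout.sequence_model import write_fasta

    specs = [
        FamilySpec("m1", 220, 14, 3, 15, 0.02, "true_mite"),
        FamilySpec("d1", 240, 12, 4, 12, 0.0, "false_retro_like"),
    ]
    sim = simulate(200_000, 2, specs, seed=11, n_simple=2)
    path = tmp_path / "genome.fasta"
    write_fasta([(e.id, e.residues) for e in sim.db], path)
    return sim, path
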