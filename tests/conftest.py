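import numpy as np
import pytest

from probecap.mock_community import synth_reference_set
from probecap.read_classify import ProteinDB
from probecap.target_registry import Registry, SequenceRecord

_BASES = np.array(list("ACGT"))


@pytest.fixture(scope="session")
def registry():
    return Registry.default()


@pytest.fixture(scope="session")
def refset(registry):
    return synth_reference_set(registry, seed=7)


@pytest.fixture(scope="session")
def protein_db(refset):
    return ProteinDB(refset.protein_db()).calibrate(seed=7)


@pytest.fixture(scope="session")
def protein_db_no_decoys(refset):
    return ProteinDB(refset.protein_db(include_decoys=False)).calibrate(seed=7)


def random_seq(length, rng):
    return "".join(rng.choice(_BASES, size=length))


def mutate(seq, divergence, rng):
    """Substitution-only mutation used by test fixtures (indel-free)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    for i in np.nonzero(rng.random(arr.size) < divergence)[0]:
        arr[i] = _BASES[_BASES != arr[i]][rng.integers(3)]
    return "".join(arr)


def records(seqs, prefix="s"):
    return [SequenceRecord(id=f"{prefix}{i}", residues=s) for i, s in enumerate(seqs)]
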