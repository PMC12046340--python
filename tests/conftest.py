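import numpy as np
import pytest

from barcodepop.seqio import AlignedSet, SequenceRecord


def make_set(rows):
    """rows: (seq_id, species, sequence[, population]) tuples."""
    return AlignedSet([SequenceRecord(*r) for r in rows])


@pytest.fixture
def two_species_set():
    # two species, 100 nt, inter-species distance ~0.10 (p-distance 10/100)
    base = "ACGT" * 25
    other = list(base)
    for i in range(0, 40, 4):  # 10 transversion-free changes (A->G transitions)
        other[i] = "G"
    other = "".join(other)
    return make_set(
        [
            ("a1", "A", base),
            ("a2", "A", base),
            ("b1", "B", other),
            ("b2", "B", other),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seqs(rng, n, length, alphabet="ACGT"):
    return ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]


def related_seqs(rng, n, length, divergence=0.1):
    """Sequences derived from one ancestor; keeps K2P well away from
    saturation (unrelated uniform-random pairs saturate the correction)."""
    base = rng.choice(list("ACGT"), size=length)
    out = []
    for _ in range(n):
        s = base.copy()
        k = int(divergence * length)
        sites = rng.choice(length, size=k, replace=False)
        for i in sites:
            s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
        out.append("".join(s))
    return out
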