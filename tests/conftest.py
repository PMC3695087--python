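import random

import pytest
from Bio.Align import substitution_matrices
from hypothesis import settings

from antigenscreen.pepalign import ProteinRecord, ScoringScheme

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

AA20 = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def blosum62():
    return substitution_matrices.load("BLOSUM62")


def brute_force_best_gapless(peptide, protein, matrix):
    """Exhaustive maximum over all ungapped (offset, window) alignments.

    Independent oracle for the diagonal-scan aligner: enumerates every
    peptide window against every protein position and sums matrix entries.
    Returns 0 when nothing scores positive.
    """
    best = 0
    m, n = len(peptide), len(protein)
    for a in range(m):
        for length in range(1, m - a + 1):
            window = peptide[a : a + length]
            for b in range(n - length + 1):
                s = sum(int(matrix[window[i], protein[b + i]]) for i in range(length))
                if s > best:
                    best = s
    return best


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


@pytest.fixture
def toy_protein():
    return ProteinRecord("TOY_1", "toy protein", "MMMMNFTLPSWAMMMM")
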