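"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from memhomology import synthetic as syn
from memhomology.core_io import AnnotatedSequence, Segment, SequenceRecord, Topology


# ---------------------------------------------------------------------------
# Independent Smith–Waterman oracle: naive exhaustive DP, no vectorisation.
# Gap convention: a gap of length k costs open + (k-1)*extend.
# ---------------------------------------------------------------------------

_BLOSUM62_ROWS = """\
A  4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0
R -1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3
N -2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3
D -2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3
C  0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1
Q -1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2
E -1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2
G  0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3
H -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3
I -1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3
L -1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1
K -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2
M -1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1
F -2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1
P -1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2
S  1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2
T  0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0
W -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3
Y -2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1
V  0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4
"""


def _parse_blosum62() -> dict[tuple[str, str], int]:
    order = "ARNDCQEGHILKMFPSTWYV"
    table = {}
    for line in _BLOSUM62_ROWS.strip().splitlines():
        parts = line.split()
        a = parts[0]
        for b, v in zip(order, parts[1:]):
            table[(a, b)] = int(v)
    return table


BLOSUM62_ORACLE = _parse_blosum62()


def sw_oracle_score(a: str, b: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Naive affine-gap local alignment DP over all cells (Gotoh)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = BLOSUM62_ORACLE[(a[i - 1], b[j - 1])]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


@pytest.fixture(scope="session")
def sw_oracle():
    return sw_oracle_score


# ---------------------------------------------------------------------------
# Small shared synthetic objects (session-scoped: generation is pure)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def spec31() -> syn.TopologySpec:
    return syn.three_plus_one_spec()


@pytest.fixture(scope="session")
def ancestor(spec31) -> AnnotatedSequence:
    return syn.sample_ancestor(spec31, 11, "anc")


@pytest.fixture(scope="session")
def family(ancestor):
    members, truth = syn.evolve_family(ancestor, 8, 0.4, 12, "fam")
    return members, truth


@pytest.fixture(scope="session")
def family_msa_fixture(ancestor, family):
    members, _ = family
    rows, cols = syn.family_msa(members, len(ancestor))
    topo = syn.msa_consensus_topology(ancestor, cols)
    return rows, cols, topo


def make_annotated(residues: str, segments, seq_id: str = "s") -> AnnotatedSequence:
    """Helper: annotated sequence from residue string + (start, end, kind)."""
    topo = Topology(tuple(Segment(s, e, k) for s, e, k in segments))
    return AnnotatedSequence(SequenceRecord(seq_id, residues), topo)
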