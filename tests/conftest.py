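import numpy as np
import pytest

from postmod.core import AMINO_ACIDS, NEGATIVE, POSITIVE, Peptide, Profile, SubstitutionMatrix
from postmod.similarity import AlignmentParams


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionMatrix.blosum62()


@pytest.fixture
def align_params():
    return AlignmentParams()


def make_peptide(window41: str, pid: str = "P", label: str = POSITIVE) -> Peptide:
    assert len(window41) == 41
    return Peptide(
        protein_id=pid,
        center_pos=21,
        center_residue=window41[20],
        window7=window41[17:24],
        window41=window41,
        label=label,
    )


def random_window41(rng: np.random.Generator, center: str = "S") -> str:
    chars = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=41)]
    chars[20] = center
    return "".join(chars)


def random_profile(rng: np.random.Generator, length: int, score_scale: float = 2.0) -> Profile:
    freq = rng.dirichlet(np.ones(20), size=length)
    score = rng.normal(0.0, score_scale, size=(length, 20))
    return Profile(freq=freq, score=score, source="synthetic")


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def window_oracle(sequence: str, pos: int, half_width: int) -> str:
    """Slice-and-pad reference for window extraction (0-based slicing)."""
    padded = "X" * half_width + sequence + "X" * half_width
    start = pos - 1  # pos-1 (0-based) + half_width (left pad) - half_width
    return padded[start : start + 2 * half_width + 1]


def enumerate_global_alignments(P: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by exhaustive path enumeration.

    Every monotone path from (0,0) to (n,m) is generated; each maximal run
    of L gapped columns in one sequence costs gap_open + (L-1)*gap_extend.
    Exponential: only for tiny matrices.
    """
    n, m = P.shape
    best = [-np.inf]

    def path_score(moves):
        total, i, j = 0.0, 0, 0
        run = None
        for mv in moves:
            if mv == "D":
                total += P[i, j]
                i, j = i + 1, j + 1
                run = None
            else:
                total -= gap_extend if mv == run else gap_open
                run = mv
                if mv == "U":
                    i += 1
                else:
                    j += 1
        return total

    def rec(i, j, moves):
        if i == n and j == m:
            best[0] = max(best[0], path_score(moves))
            return
        if i < n and j < m:
            rec(i + 1, j + 1, moves + ["D"])
        if i < n:
            rec(i + 1, j, moves + ["U"])
        if j < m:
            rec(i, j + 1, moves + ["L"])

    rec(0, 0, [])
    return best[0]


def auc_pair_count(scores, labels, tiebreak=None) -> float:
    """Mann-Whitney pair-counting AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    tb = np.zeros_like(scores) if tiebreak is None else np.asarray(tiebreak, dtype=float)
    pos = [i for i, l in enumerate(labels) if l == POSITIVE]
    neg = [i for i, l in enumerate(labels) if l == NEGATIVE]
    total = 0.0
    for p in pos:
        for q in neg:
            kp, kq = (scores[p], tb[p]), (scores[q], tb[q])
            total += 1.0 if kp > kq else (0.5 if kp == kq else 0.0)
    return total / (len(pos) * len(neg))
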