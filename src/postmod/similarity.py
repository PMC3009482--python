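"""Peptide similarity scores.

Three levels of similarity between two candidate phosphosites:

* ``s_blosum62`` — sum of BLOSUM62 substitution scores over the fixed
  7-residue windows (gapless, position-by-position).
* ``s_profile`` — optimal global profile-profile alignment score over the
  41-residue windows, with affine gap costs (a gap of length L costs
  ``gap_open + (L-1) * gap_extend``).  Column pairs are scored by the
  symmetric cross-product of one profile's frequencies with the other's
  log-odds scores.
* ``s_combined`` — the product of the two, clamped to 0 when either
  component is non-positive (two negative components would otherwise
  multiply into a spuriously high similarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import Peptide, Profile, SubstitutionMatrix


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap alignment settings for the profile-profile score."""

    gap_open: float = 3.0
    gap_extend: float = 0.75
    mode: str = "global"
    window: int = 41

    def __post_init__(self):
        if not self.gap_open >= self.gap_extend > 0:
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class CombinedScore:
    s_blosum: float
    s_profile: float
    s_combined: float

    @property
    def raw_product(self) -> float:
        """Unclamped product, kept for diagnostics."""
        return self.s_blosum * self.s_profile


def s_blosum62(pepA: Peptide, pepB: Peptide, matrix: SubstitutionMatrix) -> float:
    """Gapless substitution-matrix similarity of two 7-residue windows."""
    a, b = pepA.window7, pepB.window7
    if len(a) != 7 or len(b) != 7:
        raise ValueError("s_blosum62 requires 7-residue windows")
    return float(sum(matrix.score(x, y) for x, y in zip(a, b)))


def ppa_score(profA: Profile, i: int, profB: Profile, j: int) -> float:
    """Profile-profile column score for 1-based positions ``i`` of A, ``j`` of B.

    Defined as the symmetric cross-product
    ``0.5 * sum_k (f_ik * S_jk + f_jk * S_ik)`` over the 20 amino acids,
    where ``f`` are frequencies (PSFM) and ``S`` log-odds scores (PSSM).
    """
    if not 1 <= i <= profA.length:
        raise ValueError(f"position {i} out of range for profile A")
    if not 1 <= j <= profB.length:
        raise ValueError(f"position {j} out of range for profile B")
    fa, sa = profA.freq[i - 1], profA.score[i - 1]
    fb, sb = profB.freq[j - 1], profB.score[j - 1]
    return 0.5 * float(fa @ sb + fb @ sa)


def ppa_matrix(profA: Profile, profB: Profile) -> np.ndarray:
    """All column-pair profile-profile scores as an (LA, LB) array."""
    return 0.5 * (profA.freq @ profB.score.T + profA.score @ profB.freq.T)


@njit(cache=True)
def _gotoh_global(P, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = P.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = P[i - 1, j - 1] + best
            Ix[i, j] = max(M[i - 1, j] - gap_open,
                           Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open,
                           Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - gap_open)
    return max(M[n, m], Ix[n, m], Iy[n, m])


@njit(cache=True)
def _gotoh_local(P, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = P.shape
    NEG = -1e30
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = max(0.0, P[i - 1, j - 1] + prev)
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            if M[i, j] > best:
                best = M[i, j]
    return best


@njit(cache=True)
def _cross_profile_scores(FQ, SQ, FRT, SRT, gap_open, gap_extend):  # pragma: no cover - numba
    # FRT/SRT are the reference arrays pre-transposed to (n, 20, L)
    nq, nr = FQ.shape[0], FRT.shape[0]
    out = np.zeros((nq, nr))
    for a in range(nq):
        for b in range(nr):
            P = 0.5 * (FQ[a] @ SRT[b] + SQ[a] @ FRT[b])
            out[a, b] = _gotoh_global(P, gap_open, gap_extend)
    return out


@njit(cache=True)
def _batch_profile_scores(F, S, FT, ST, gap_open, gap_extend):  # pragma: no cover - numba
    # FT/ST are F/S pre-transposed to (n, 20, L)
    n = F.shape[0]
    out = np.zeros((n, n))
    for a in range(n):
        Fa = F[a]
        Sa = S[a]
        for b in range(a, n):
            P = 0.5 * (Fa @ ST[b] + Sa @ FT[b])
            sc = _gotoh_global(P, gap_open, gap_extend)
            out[a, b] = sc
            out[b, a] = sc
    return out


def s_profile(profA: Profile, profB: Profile, params: AlignmentParams | None = None) -> float:
    """Optimal affine-gap profile-profile alignment score of two windows."""
    params = params or AlignmentParams()
    if profA.length != params.window or profB.length != params.window:
        raise ValueError(
            f"profile lengths ({profA.length}, {profB.length}) do not match "
            f"alignment window {params.window}"
        )
    P = ppa_matrix(profA, profB)
    if params.mode == "local":
        return float(_gotoh_local(P, params.gap_open, params.gap_extend))
    return float(_gotoh_global(P, params.gap_open, params.gap_extend))


def s_combined(
    pepA: Peptide,
    pepB: Peptide,
    profA: Profile,
    profB: Profile,
    matrix: SubstitutionMatrix,
    params: AlignmentParams | None = None,
) -> CombinedScore:
    """Combined similarity: product of the window and profile scores.

    The combined value is ``s_blosum * s_profile`` when both components are
    strictly positive and 0 otherwise.
    """
    sb = s_blosum62(pepA, pepB, matrix)
    sp = s_profile(profA, profB, params)
    sc = sb * sp if (sb > 0 and sp > 0) else 0.0
    return CombinedScore(s_blosum=sb, s_profile=sp, s_combined=sc)


@dataclass
class ScoreMatrix:
    """All-pairs similarity scores for a list of peptides.

    Arrays are (n, n), symmetric, indexed like ``keys``; the diagonal holds
    each peptide's self-similarity and is ignored by consumers that must
    exclude self-matches.
    """

    keys: list
    s_blosum: np.ndarray
    s_profile: np.ndarray
    s_combined: np.ndarray

    def __len__(self) -> int:
        return len(self.keys)

    def entry(self, i: int, j: int) -> CombinedScore:
        return CombinedScore(
            s_blosum=float(self.s_blosum[i, j]),
            s_profile=float(self.s_profile[i, j]),
            s_combined=float(self.s_combined[i, j]),
        )

    def to_frame(self):
        import pandas as pd

        n = len(self.keys)
        ii, jj = np.triu_indices(n)
        return pd.DataFrame(
            {
                "id_i": [self.keys[i] for i in ii],
                "id_j": [self.keys[j] for j in jj],
                "s_blosum": self.s_blosum[ii, jj],
                "s_profile": self.s_profile[ii, jj],
                "s_combined": self.s_combined[ii, jj],
            }
        )


def score_matrix(
    peptides: list[Peptide],
    profiles: dict[str, Profile],
    matrix: SubstitutionMatrix,
    params: AlignmentParams | None = None,
) -> ScoreMatrix:
    """Compute all-pairs component and combined scores for ``peptides``.

    Profiles are looked up by peptide key.  Runs the window score with a
    vectorized matrix lookup and the profile alignments in a compiled batch
    kernel; results match element-wise pairwise calls.
    """
    params = params or AlignmentParams()
    n = len(peptides)
    keys = [p.key for p in peptides]
    if n == 0:
        empty = np.zeros((0, 0))
        return ScoreMatrix(keys, empty.copy(), empty.copy(), empty.copy())

    enc7 = np.stack([matrix.encode(p.window7) for p in peptides])
    pairwise = matrix.entries[enc7[:, None, :], enc7[None, :, :]]
    sb = pairwise.sum(axis=2)

    F = np.stack([profiles[k].freq for k in keys])
    S = np.stack([profiles[k].score for k in keys])
    if F.shape[1] != params.window:
        raise ValueError(
            f"profiles have length {F.shape[1]}, alignment window is {params.window}"
        )
    if params.mode == "global":
        FT = np.ascontiguousarray(F.transpose(0, 2, 1))
        ST = np.ascontiguousarray(S.transpose(0, 2, 1))
        sp = _batch_profile_scores(F, S, FT, ST, params.gap_open, params.gap_extend)
    else:
        sp = np.zeros((n, n))
        for a in range(n):
            for b in range(a, n):
                P = 0.5 * (F[a] @ S[b].T + S[a] @ F[b].T)
                sp[a, b] = sp[b, a] = float(_gotoh_local(P, params.gap_open, params.gap_extend))

    sc = np.where((sb > 0) & (sp > 0), sb * sp, 0.0)
    return ScoreMatrix(keys=keys, s_blosum=sb, s_profile=sp, s_combined=sc)


@dataclass
class CrossScores:
    """Query-vs-reference component and combined scores, shape (nq, nr)."""

    query_keys: list
    ref_keys: list
    s_blosum: np.ndarray
    s_profile: np.ndarray
    s_combined: np.ndarray


def cross_scores(
    query_peptides: list[Peptide],
    query_profiles: dict[str, Profile],
    ref_peptides: list[Peptide],
    ref_profiles: dict[str, Profile],
    matrix: SubstitutionMatrix,
    params: AlignmentParams | None = None,
) -> CrossScores:
    """Scores of every query peptide against every reference peptide."""
    params = params or AlignmentParams()
    if params.mode != "global":
        raise ValueError("cross_scores supports global alignment only")
    qkeys = [p.key for p in query_peptides]
    rkeys = [p.key for p in ref_peptides]
    encq = np.stack([matrix.encode(p.window7) for p in query_peptides])
    encr = np.stack([matrix.encode(p.window7) for p in ref_peptides])
    sb = matrix.entries[encq[:, None, :], encr[None, :, :]].sum(axis=2)
    FQ = np.stack([query_profiles[k].freq for k in qkeys])
    SQ = np.stack([query_profiles[k].score for k in qkeys])
    FR = np.stack([ref_profiles[k].freq for k in rkeys])
    SR = np.stack([ref_profiles[k].score for k in rkeys])
    FRT = np.ascontiguousarray(FR.transpose(0, 2, 1))
    SRT = np.ascontiguousarray(SR.transpose(0, 2, 1))
    sp = _cross_profile_scores(FQ, SQ, FRT, SRT, params.gap_open, params.gap_extend)
    sc = np.where((sb > 0) & (sp > 0), sb * sp, 0.0)
    return CrossScores(query_keys=qkeys, ref_keys=rkeys, s_blosum=sb,
                       s_profile=sp, s_combined=sc)
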