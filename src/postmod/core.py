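"""Core domain types: residue alphabet, peptide windows, profiles, noise parameters.

Conventions used throughout the package:

* Positions in proteins are 1-based (Phospho.ELM convention).
* Peptide windows are closed intervals ``[pos - w, pos + w]``; positions
  falling outside the parent sequence are padded with ``'X'``.
* Frequency/score vectors are ordered by :data:`AMINO_ACIDS`
  (alphabetical one-letter codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Padding / unknown residue.
UNKNOWN = "X"

#: Full residue alphabet accepted in peptide windows.
ALPHABET = AMINO_ACIDS + UNKNOWN

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Phospho-acceptor residues (serine, threonine, tyrosine).
ACCEPTORS = "STY"

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unknown"

# BLOSUM62 marginal amino-acid frequencies (Henikoff & Henikoff counts),
# reordered to AMINO_ACIDS and renormalized to sum exactly to 1.
_BG = {
    "A": 0.0742, "R": 0.0516, "N": 0.0446, "D": 0.0536, "C": 0.0246,
    "Q": 0.0342, "E": 0.0543, "G": 0.0741, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0250, "F": 0.0474, "P": 0.0389,
    "S": 0.0572, "T": 0.0509, "W": 0.0131, "Y": 0.0321, "V": 0.0729,
}
BACKGROUND = np.array([_BG[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()


class SubstitutionMatrix:
    """Symmetric residue substitution matrix over :data:`ALPHABET` (21 symbols).

    Wraps a dense 21x21 float array indexed by :data:`AA_INDEX`.  The default
    instance carries NCBI BLOSUM62 including its ``X`` row.
    """

    def __init__(self, entries: np.ndarray, name: str = "BLOSUM62"):
        entries = np.asarray(entries, dtype=float)
        if entries.shape != (21, 21):
            raise ValueError(f"expected a 21x21 matrix, got {entries.shape}")
        if not np.allclose(entries, entries.T):
            raise ValueError("substitution matrix must be symmetric")
        self.entries = entries
        self.name = name

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        raw = substitution_matrices.load("BLOSUM62")
        ent = np.zeros((21, 21))
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                ent[i, j] = raw[a, b]
        return cls(ent, "BLOSUM62")

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.entries[AA_INDEX[a], AA_INDEX[b]])
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} not in alphabet") from None

    def row(self, a: str) -> np.ndarray:
        """Score of residue ``a`` against each of the 20 standard residues."""
        return self.entries[AA_INDEX[a], :20].copy()

    def encode(self, peptide: str) -> np.ndarray:
        """Integer-encode a residue string for vectorized lookups."""
        try:
            return np.array([AA_INDEX[c] for c in peptide], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} not in alphabet") from None


def extract_window(sequence: str, pos: int, half_width: int) -> str:
    """Extract the window of ``2*half_width + 1`` residues centered at ``pos``.

    ``pos`` is 1-based.  Positions before the N terminus or past the
    C terminus are represented as ``'X'``.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if not 1 <= pos <= len(sequence):
        raise ValueError(
            f"position {pos} out of range for sequence of length {len(sequence)}"
        )
    chars = []
    for p in range(pos - half_width, pos + half_width + 1):
        chars.append(sequence[p - 1] if 1 <= p <= len(sequence) else UNKNOWN)
    return "".join(chars)


@dataclass(frozen=True)
class Peptide:
    """A candidate phosphosite: fixed 7- and 41-residue windows around an S/T/Y.

    ``window7`` is the central 7 residues of ``window41``; both are centered
    on ``center_residue`` at 1-based position ``center_pos`` of the parent
    protein.
    """

    protein_id: str
    center_pos: int
    center_residue: str
    window7: str
    window41: str
    label: str = UNLABELED
    kinase: str = ""

    def __post_init__(self):
        if self.center_residue not in ACCEPTORS:
            raise ValueError(
                f"{self.protein_id}:{self.center_pos}: center residue "
                f"{self.center_residue!r} is not one of S/T/Y"
            )
        if len(self.window7) != 7 or len(self.window41) != 41:
            raise ValueError(
                f"{self.protein_id}:{self.center_pos}: window lengths must be 7 and 41"
            )
        if self.window41[17:24] != self.window7:
            raise ValueError(
                f"{self.protein_id}:{self.center_pos}: window7 is not the "
                "central 7 residues of window41"
            )
        if self.window7[3] != self.center_residue:
            raise ValueError(
                f"{self.protein_id}:{self.center_pos}: window center "
                f"{self.window7[3]!r} != {self.center_residue!r}"
            )
        if self.label not in (POSITIVE, NEGATIVE, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")
        for c in self.window41:
            if c not in AA_INDEX:
                raise ValueError(f"invalid residue {c!r} in window")

    @property
    def key(self) -> str:
        """Stable identity used for profile lookup and deterministic tie-breaks."""
        return f"{self.protein_id}:{self.center_pos}"

    @classmethod
    def from_site(
        cls,
        sequence: str,
        protein_id: str,
        pos: int,
        label: str = UNLABELED,
        kinase: str = "",
    ) -> "Peptide":
        residue = sequence[pos - 1]
        return cls(
            protein_id=protein_id,
            center_pos=pos,
            center_residue=residue,
            window7=extract_window(sequence, pos, 3),
            window41=extract_window(sequence, pos, 20),
            label=label,
            kinase=kinase,
        )


@dataclass
class Profile:
    """Per-position frequency (PSFM) and log-odds (PSSM) vectors.

    ``freq`` and ``score`` are ``(length, 20)`` arrays over
    :data:`AMINO_ACIDS`.  Every frequency row sums to 1; padding positions
    carry the background distribution and zero scores.
    """

    freq: np.ndarray
    score: np.ndarray
    source: str = "pseudo"

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 20:
            raise ValueError("freq must be (length, 20)")
        if self.score.shape != self.freq.shape:
            raise ValueError("score shape must match freq shape")
        sums = self.freq.sum(axis=1)
        if not np.all(np.abs(sums - 1.0) <= 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"frequency row {bad} sums to {sums[bad]:.8f}, not 1")
        if self.source not in ("psiblast", "pseudo", "synthetic"):
            raise ValueError(f"unknown profile source {self.source!r}")

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    def window(self, pos: int, half_width: int) -> "Profile":
        """Slice the window centered at 1-based ``pos``, padding out-of-range
        positions with the background distribution and zero scores."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} out of profile range 1..{self.length}")
        n = 2 * half_width + 1
        freq = np.tile(BACKGROUND, (n, 1))
        score = np.zeros((n, 20))
        for k, p in enumerate(range(pos - half_width, pos + half_width + 1)):
            if 1 <= p <= self.length:
                freq[k] = self.freq[p - 1]
                score[k] = self.score[p - 1]
        return Profile(freq=freq, score=score, source=self.source)


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the indirect-relationship noise reducer.

    alpha: number of top direct hits retrieved for the query.
    beta: number of top indirect hits inspected for the decision.
    gamma: the query is called positive when the top-beta hits contain
        strictly more than ``gamma`` positive peptides.
    weight: multiplier applied to relationships whose partner peptide is
        positive, compensating the negative:positive imbalance.
    """

    alpha: int
    beta: int
    gamma: int
    weight: float

    def __post_init__(self):
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("alpha and beta must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.gamma >= self.beta:
            raise ValueError("gamma must be < beta")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


def default_noise_params(
    n_positive: int, n_negative: int, force_weight: float | None = None
) -> NoiseParams:
    """Derive alpha/beta/gamma from the positive count of a reference set.

    alpha, beta and gamma are one-half, one-third and one-fourth of the
    number of positive peptides (floored; alpha and beta at least 1).  The
    weight defaults to the realized negative:positive ratio; pass
    ``force_weight`` to pin it (e.g. to the nominal 10).
    """
    if n_positive < 1 or n_negative < 1:
        raise ValueError("reference set must contain positives and negatives")
    alpha = max(1, n_positive // 2)
    beta = max(1, n_positive // 3)
    gamma = n_positive // 4
    if gamma >= beta:
        gamma = beta - 1
    weight = float(force_weight) if force_weight is not None else n_negative / n_positive
    return NoiseParams(alpha=alpha, beta=beta, gamma=gamma, weight=weight)
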