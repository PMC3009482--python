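"""Seeded synthetic data: planted-motif reference sets and the miniature
worked-example fixture.

The generator emulates the training data of a kinase-specific predictor:
positive peptides carry a position-weight-matrix motif in the central
7 residues of a 41-residue window, negatives are drawn from background
composition with the same center residue, at 10 negatives per positive.

Synthetic profiles are derived from the generating distributions: motif
columns are "conserved" (concentrated frequencies, positive log-odds),
flank columns are background-like (log-odds near zero), which is how an
iterative profile search annotates conserved versus variable positions.
Frequencies are perturbed by seeded Dirichlet sampling noise.  A
sequence-derived pseudo-profile mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ACCEPTORS,
    AMINO_ACIDS,
    BACKGROUND,
    NEGATIVE,
    POSITIVE,
    NoiseParams,
    Peptide,
    Profile,
)
from .io_formats import ReferenceSet, pseudo_profile

_AA = np.array(list(AMINO_ACIDS))


@dataclass
class MotifModel:
    """A 7-column position-weight matrix with a forced S/T/Y center.

    ``strength`` mixes each non-center column with the background:
    the effective column is ``strength * pwm + (1 - strength) * flank``.
    ``flank_model`` is the residue distribution outside the motif.
    """

    pwm: np.ndarray
    strength: float = 1.0
    flank_model: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (7, 20):
            raise ValueError("pwm must be (7, 20)")
        if np.any(self.pwm < 0) or not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("pwm columns must be probability distributions")
        center = self.pwm[3]
        if not (center.max() == 1.0 and _AA[int(center.argmax())] in ACCEPTORS):
            raise ValueError("center column must be a point mass on S, T or Y")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        self.flank_model = np.asarray(self.flank_model, dtype=float)
        if self.flank_model.shape != (20,) or not np.isclose(self.flank_model.sum(), 1.0):
            raise ValueError("flank_model must be a 20-residue distribution")

    @property
    def center_residue(self) -> str:
        return str(_AA[int(self.pwm[3].argmax())])

    def column(self, offset: int) -> np.ndarray:
        """Effective sampling distribution for motif offset -3..+3."""
        col = self.pwm[offset + 3]
        if offset == 0:
            return col
        return self.strength * col + (1.0 - self.strength) * self.flank_model


def _column(preferred: dict[str, float]) -> np.ndarray:
    """A PWM column: the stated preferences plus background for the rest."""
    col = np.zeros(20)
    for aa, p in preferred.items():
        col[AMINO_ACIDS.index(aa)] = p
    rest = 1.0 - col.sum()
    if rest < 0:
        raise ValueError("preferences exceed 1")
    bg = BACKGROUND * (col == 0)
    col += rest * bg / bg.sum()
    return col


def default_motif(center: str = "S", strength: float = 1.0) -> MotifModel:
    """A basophilic kinase-like recognition motif: R-R-x-S/T-hydrophobic-x-acidic."""
    if center not in ACCEPTORS:
        raise ValueError("center must be S, T or Y")
    pwm = np.stack(
        [
            _column({"R": 0.70, "K": 0.20}),
            _column({"R": 0.80, "K": 0.12}),
            _column({"S": 0.25, "A": 0.25, "T": 0.15}),
            _column({center: 1.0}),
            _column({"L": 0.40, "I": 0.18, "V": 0.18, "F": 0.09}),
            _column({"S": 0.20, "P": 0.20}),
            _column({"D": 0.30, "E": 0.30}),
        ]
    )
    return MotifModel(pwm=pwm, strength=strength)


def _sample(rng: np.random.Generator, dist: np.ndarray, n: int) -> list[str]:
    return list(_AA[rng.choice(20, size=n, p=dist / dist.sum())])


def _log_odds(freq: np.ndarray, pseudocount: float = 0.3, clip: float = 10.0) -> np.ndarray:
    """PSSM-style scores from column frequencies: 2 * log2(f / background).

    Frequencies are shrunk toward the background before taking log-odds,
    mirroring the pseudocount regularization of iterative profile searches;
    without it, sampling noise alone would push every unconserved column's
    expected score below zero.
    """
    f = (1.0 - pseudocount) * freq + pseudocount * BACKGROUND
    return np.clip(2.0 * np.log2(f / BACKGROUND), -clip, clip)


def _sampled_profile(
    column_dists: np.ndarray, rng: np.random.Generator, conc: float
) -> Profile:
    """A synthetic 41-window profile drawn around per-position distributions.

    Frequencies are Dirichlet samples centered on the generating
    distribution (concentration ``conc``); scores are the log-odds of the
    sampled frequencies.  ``conc=inf`` disables the jitter.
    """
    freq = np.empty_like(column_dists)
    for i, col in enumerate(column_dists):
        if np.isinf(conc):
            freq[i] = col
        else:
            freq[i] = rng.dirichlet(conc * col + 0.5)
    freq /= freq.sum(axis=1, keepdims=True)
    return Profile(freq=freq, score=_log_odds(freq), source="synthetic")


def _window_dists(motif: MotifModel, positive: bool) -> np.ndarray:
    """Per-position generating distributions for a 41-residue window."""
    dists = np.tile(motif.flank_model, (41, 1))
    if positive:
        for off in range(-3, 4):
            dists[20 + off] = motif.column(off)
    else:
        center = np.zeros(20)
        center[AMINO_ACIDS.index(motif.center_residue)] = 1.0
        dists[20] = center
    return dists


def generate_refset(
    motif: MotifModel,
    n_pos: int,
    neg_ratio: int = 10,
    seed: int = 0,
    kinase: str = "SYN1",
    profile_mode: str = "sampled",
    profile_conc: float = 50.0,
) -> ReferenceSet:
    """Generate a labeled reference set with planted-motif positives.

    Positives sample the motif's central 7 columns (center residue forced);
    negatives sample pure background with the same center residue,
    ``neg_ratio`` per positive.  Parent "proteins" are the 41-residue windows
    themselves, so the set round-trips through the FASTA/TSV readers.

    ``profile_mode``: ``"sampled"`` (default) draws profiles around the
    generating distributions with Dirichlet noise; ``"pseudo"`` derives them
    from the sequences alone.
    """
    if n_pos < 2:
        raise ValueError("need at least 2 positive peptides")
    if profile_mode not in ("sampled", "pseudo"):
        raise ValueError(f"unknown profile_mode {profile_mode!r}")
    rng = np.random.default_rng(seed)
    center = motif.center_residue

    def make_peptide(pid: str, label: str, positive: bool) -> Peptide:
        chars = _sample(rng, motif.flank_model, 41)
        if positive:
            for off in range(-3, 4):
                if off == 0:
                    continue
                chars[20 + off] = _sample(rng, motif.column(off), 1)[0]
        chars[20] = center
        window41 = "".join(chars)
        return Peptide(
            protein_id=pid,
            center_pos=21,
            center_residue=center,
            window7=window41[17:24],
            window41=window41,
            label=label,
            kinase=kinase,
        )

    positives = [make_peptide(f"SP{i:04d}", POSITIVE, True) for i in range(n_pos)]
    negatives = [
        make_peptide(f"SN{j:04d}", NEGATIVE, False) for j in range(n_pos * neg_ratio)
    ]

    profiles = {}
    for pep, positive in [(p, True) for p in positives] + [(p, False) for p in negatives]:
        if profile_mode == "pseudo":
            profiles[pep.key] = pseudo_profile(pep.window41)
        else:
            profiles[pep.key] = _sampled_profile(
                _window_dists(motif, positive), rng, profile_conc
            )

    return ReferenceSet(
        kinase=kinase,
        positives=positives,
        negatives=negatives,
        profiles=profiles,
        sampling_seed=seed,
        neg_ratio=neg_ratio,
    )


def write_dataset(refset: ReferenceSet, outdir) -> None:
    """Emit FASTA + sites TSV + ground-truth TSV for a generated set.

    Each peptide's parent protein is its own 41-residue window; the sites
    table annotates the positive centers, and ``truth.tsv`` records every
    generated peptide with its label.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for pep in refset.peptides:
            fh.write(f">{pep.protein_id}\n{pep.window41}\n")
    with open(outdir / "sites.tsv", "w") as fh:
        fh.write("protein_id\tposition\tresidue\tkinase\n")
        for pep in refset.positives:
            fh.write(f"{pep.protein_id}\t{pep.center_pos}\t{pep.center_residue}\t{pep.kinase}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("protein_id\tposition\tresidue\tkinase\tlabel\n")
        for pep in refset.peptides:
            fh.write(
                f"{pep.protein_id}\t{pep.center_pos}\t{pep.center_residue}\t"
                f"{pep.kinase}\t{pep.label}\n"
            )


@dataclass
class WorkedExample:
    """Miniature reference set with an injected combined-score table.

    Reproduces the published illustration of the noise reducer: 10 reference
    peptides (5 positive, 5 negative), a query whose top-5 direct hits are
    2 positives and 3 negatives, and relationship scores arranged so that
    positive peptide P2's indirect relationships are P1 (0.61), P4 (0.01)
    and N3 (0.50), giving the indirect score 10*(0.61+0.01) - 0.50 = 5.70,
    and so that the final top-4 contains 3 positives (confidence 0.75).
    """

    reference: list
    query: Peptide
    query_scores: np.ndarray
    ref_scores: np.ndarray
    params: NoiseParams

    def index(self, protein_id: str) -> int:
        return [p.protein_id for p in self.reference].index(protein_id)


def figure1_fixture() -> WorkedExample:
    window41 = "A" * 20 + "S" + "A" * 20

    def pep(pid: str, label: str) -> Peptide:
        return Peptide(
            protein_id=pid,
            center_pos=21,
            center_residue="S",
            window7=window41[17:24],
            window41=window41,
            label=label,
            kinase="FIG1",
        )

    names = ["P1", "P2", "P3", "P4", "P5", "N1", "N2", "N3", "N4", "N5"]
    reference = [pep(n, POSITIVE if n.startswith("P") else NEGATIVE) for n in names]
    query = pep("QRY", POSITIVE)

    idx = {n: i for i, n in enumerate(names)}
    ref_scores = np.zeros((10, 10))

    def put(a: str, b: str, v: float) -> None:
        ref_scores[idx[a], idx[b]] = ref_scores[idx[b], idx[a]] = v

    # P2's only nonzero relationships are the three published values; the
    # remaining pairs steer its partners' rows away from P2 and shape the
    # final top-4 as {P2, P3, P4, N2}.
    put("P2", "P1", 0.61)
    put("P2", "P4", 0.01)
    put("P2", "N3", 0.50)
    put("P1", "P3", 0.70)
    put("P1", "P4", 0.65)
    put("P1", "N1", 5.00)
    put("P1", "N4", 4.50)
    put("P1", "N5", 4.00)
    put("N3", "N1", 0.60)
    put("N3", "N4", 0.58)
    put("N3", "N5", 0.55)
    put("N3", "N2", 0.52)
    put("N3", "P5", 0.51)
    put("N1", "N4", 0.90)
    put("N1", "N5", 0.80)
    put("N2", "N4", 0.80)
    put("N2", "N5", 0.70)

    direct = {
        "P1": 0.95, "P2": 0.90, "N1": 0.85, "N2": 0.80, "N3": 0.75,
        "P3": 0.10, "P4": 0.09, "P5": 0.08, "N4": 0.07, "N5": 0.06,
    }
    query_scores = np.array([direct[n] for n in names])
    return WorkedExample(
        reference=reference,
        query=query,
        query_scores=query_scores,
        ref_scores=ref_scores,
        params=NoiseParams(alpha=5, beta=4, gamma=2, weight=10.0),
    )
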