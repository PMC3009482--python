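"""Readers/writers for FASTA, phosphosite tables, PSI-BLAST ASCII PSSMs and
the on-disk reference-set layout, plus reference-set construction with
10:1 negative sampling.

All coordinates are 1-based.  Malformed rows are rejected, never silently
coerced; rejection reasons are returned to the caller and logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ACCEPTORS,
    ALPHABET,
    AMINO_ACIDS,
    BACKGROUND,
    NEGATIVE,
    POSITIVE,
    Peptide,
    Profile,
    SubstitutionMatrix,
    extract_window,
)

logger = logging.getLogger("postmod")

#: Column order of NCBI PSI-BLAST PSSM files (blastpgp ``-Q`` output).
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PSSM_TO_ALPHA = [PSSM_COLUMN_ORDER.index(a) for a in AMINO_ACIDS]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class SiteRecord:
    """One annotated phosphosite: protein, 1-based position, residue, kinase."""

    protein_id: str
    position: int
    residue: str
    kinase: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.protein_id}: position must be >= 1")
        if self.residue not in ACCEPTORS:
            raise ValueError(
                f"{self.protein_id}:{self.position}: residue {self.residue!r} "
                "is not one of S/T/Y"
            )


@dataclass
class ReferenceSet:
    """Labeled positive and negative peptides (with 41-window profiles) for
    one kinase group."""

    kinase: str
    positives: list
    negatives: list
    profiles: dict
    sampling_seed: int = 0
    neg_ratio: int = 10

    def __post_init__(self):
        pos_keys = {p.key for p in self.positives}
        neg_keys = {p.key for p in self.negatives}
        if pos_keys & neg_keys:
            raise ValueError(
                f"peptides appear in both lists: {sorted(pos_keys & neg_keys)[:3]}"
            )
        for p in self.peptides:
            prof = self.profiles.get(p.key)
            if prof is None:
                raise ValueError(f"missing profile for peptide {p.key}")
            if prof.length != 41:
                raise ValueError(f"profile for {p.key} has length {prof.length}, not 41")
        want = self.neg_ratio * len(self.positives)
        if len(self.negatives) != want:
            logger.warning(
                "reference set %s has %d negatives, expected %d (candidate pool "
                "exhausted)", self.kinase, len(self.negatives), want,
            )

    @property
    def peptides(self) -> list:
        return list(self.positives) + list(self.negatives)

    @property
    def labels(self) -> list:
        return [p.label for p in self.peptides]


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by the first token of each header.

    Sequences are upper-cased; characters outside the 20-letter alphabet are
    mapped to ``'X'`` (count logged).
    """
    from Bio import SeqIO

    path = Path(path)
    sequences: dict[str, str] = {}
    n_replaced = 0
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        seq = str(rec.seq).upper()
        cleaned = []
        for c in seq:
            if c in AMINO_ACIDS:
                cleaned.append(c)
            else:
                cleaned.append("X")
                n_replaced += 1
        if not cleaned:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        sequences[rec.id] = "".join(cleaned)
    if n_replaced:
        logger.warning("%s: %d non-standard residues mapped to 'X'", path, n_replaced)
    return sequences


def read_sites(path, sequences: dict[str, str] | None = None):
    """Read a phosphosite TSV (protein_id, position, residue, kinase).

    Returns ``(records, rejections)`` where ``rejections`` is a list of
    human-readable reasons, one per rejected row.  When ``sequences`` is
    given, rows whose residue disagrees with the FASTA are rejected.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    required = ["protein_id", "position", "residue", "kinase"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")

    records: list[SiteRecord] = []
    rejections: list[str] = []
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        pid = row.protein_id.strip()
        try:
            pos = int(row.position)
        except ValueError:
            raise FormatError(
                f"{path}: row {row_no}: non-integer position {row.position!r}"
            ) from None
        residue = row.residue.strip().upper()
        kinase = row.kinase.strip()
        if residue not in ACCEPTORS:
            rejections.append(f"row {row_no}: residue {residue!r} is not S/T/Y")
            continue
        if pos < 1:
            rejections.append(f"row {row_no}: position {pos} < 1")
            continue
        if sequences is not None:
            seq = sequences.get(pid)
            if seq is None:
                rejections.append(f"row {row_no}: protein {pid!r} not in FASTA")
                continue
            if pos > len(seq):
                rejections.append(
                    f"row {row_no}: position {pos} beyond {pid} length {len(seq)}"
                )
                continue
            if seq[pos - 1] != residue:
                rejections.append(
                    f"row {row_no}: residue {residue} disagrees with {pid} "
                    f"sequence ({seq[pos - 1]}) at position {pos}"
                )
                continue
        records.append(SiteRecord(pid, pos, residue, kinase))
    for reason in rejections:
        logger.warning("%s: rejected %s", path, reason)
    return records, rejections


def parse_psiblast_pssm(path, sequence: str | None = None) -> Profile:
    """Parse a blastpgp ``-Q`` ASCII PSSM into a whole-protein Profile.

    Each data row carries 20 integer log-odds scores followed by 20
    percentage frequencies (NCBI column order).  Percentages are divided by
    100 and renormalized per row; all-zero rows are replaced by the
    background distribution.
    """
    path = Path(path)
    freq_rows, score_rows, residues = [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 42:
                continue
            try:
                idx = int(tokens[0])
            except ValueError:
                continue
            if len(tokens[1]) != 1 or tokens[1] not in ALPHABET:
                continue
            try:
                scores = [float(t) for t in tokens[2:22]]
                pcts = [float(t) for t in tokens[22:42]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {line_no}: non-numeric cell ({exc})"
                ) from None
            if idx != len(residues) + 1:
                raise FormatError(
                    f"{path}: line {line_no}: position {idx} out of order "
                    f"(expected {len(residues) + 1})"
                )
            residues.append(tokens[1])
            score_rows.append(scores)
            freq_rows.append(pcts)
    if not residues:
        raise FormatError(f"{path}: no PSSM data rows found")
    if sequence is not None and len(residues) != len(sequence):
        raise FormatError(
            f"{path}: {len(residues)} PSSM rows for a sequence of length "
            f"{len(sequence)}"
        )

    score = np.array(score_rows)[:, _PSSM_TO_ALPHA]
    freq = np.array(freq_rows)[:, _PSSM_TO_ALPHA] / 100.0
    sums = freq.sum(axis=1)
    zero = sums <= 0
    freq[zero] = BACKGROUND
    freq[~zero] /= sums[~zero, None]
    return Profile(freq=freq, score=score, source="psiblast")


def pseudo_profile(
    sequence: str, lam: float = 0.3, matrix: SubstitutionMatrix | None = None
) -> Profile:
    """Sequence-derived stand-in profile used when no PSI-BLAST output exists.

    Position with residue ``a`` gets frequencies ``(1-lam)*delta_a +
    lam*background`` and the substitution-matrix row of ``a`` as scores;
    ``'X'`` positions get the pure background and zero scores.  Deterministic.
    """
    if not sequence:
        raise ValueError("cannot build a profile for an empty sequence")
    matrix = matrix or SubstitutionMatrix.blosum62()
    n = len(sequence)
    freq = np.tile(BACKGROUND * lam, (n, 1))
    score = np.zeros((n, 20))
    for i, a in enumerate(sequence):
        if a == "X":
            freq[i] = BACKGROUND
        elif a in AMINO_ACIDS:
            freq[i, AMINO_ACIDS.index(a)] += 1.0 - lam
            score[i] = matrix.row(a)
        else:
            raise ValueError(f"invalid residue {a!r} at position {i + 1}")
    return Profile(freq=freq, score=score, source="pseudo")


def build_reference_set(
    sites: list[SiteRecord],
    fasta: dict[str, str],
    kinase: str,
    neg_ratio: int = 10,
    min_sites: int = 21,
    seed: int = 0,
    profiles: dict[str, Profile] | None = None,
    pool_all_proteins: bool = False,
) -> ReferenceSet:
    """Assemble the labeled reference set for one kinase group.

    Positives are every annotated site of ``kinase`` (at least ``min_sites``
    required).  Candidate negatives are all S/T/Y occurrences in the positive
    set's protein collection (or in every FASTA protein when
    ``pool_all_proteins``) that no kinase in ``sites`` annotates; they are
    sampled without replacement, ``neg_ratio`` per positive, matching the
    positives' center-residue composition per type.

    ``profiles`` optionally maps protein ids to whole-protein profiles
    (e.g. from :func:`parse_psiblast_pssm`); proteins without one get a
    :func:`pseudo_profile`.
    """
    pos_sites = [s for s in sites if s.kinase == kinase]
    if len(pos_sites) < min_sites:
        raise ValueError(
            f"kinase {kinase!r} has {len(pos_sites)} sites, below the minimum "
            f"of {min_sites}"
        )
    missing = sorted({s.protein_id for s in pos_sites} - set(fasta))
    if missing:
        raise ValueError(f"proteins missing from FASTA: {missing[:5]}")

    protein_profiles: dict[str, Profile] = {}

    def protein_profile(pid: str) -> Profile:
        if pid not in protein_profiles:
            prof = (profiles or {}).get(pid)
            protein_profiles[pid] = prof if prof is not None else pseudo_profile(fasta[pid])
        return protein_profiles[pid]

    positives, peptide_profiles = [], {}
    for s in sorted(pos_sites, key=lambda s: (s.protein_id, s.position)):
        pep = Peptide.from_site(fasta[s.protein_id], s.protein_id, s.position,
                                label=POSITIVE, kinase=kinase)
        positives.append(pep)
        peptide_profiles[pep.key] = protein_profile(s.protein_id).window(s.position, 20)

    annotated = {(s.protein_id, s.position) for s in sites}
    universe = sorted(fasta) if pool_all_proteins else sorted({s.protein_id for s in pos_sites})
    candidates: dict[str, list[tuple[str, int]]] = {r: [] for r in ACCEPTORS}
    for pid in universe:
        seq = fasta[pid]
        for p, c in enumerate(seq, start=1):
            if c in ACCEPTORS and (pid, p) not in annotated:
                candidates[c].append((pid, p))

    rng = np.random.default_rng(seed)
    pos_counts = {r: sum(1 for p in positives if p.center_residue == r) for r in ACCEPTORS}
    negatives = []
    for r in ACCEPTORS:
        want = neg_ratio * pos_counts[r]
        pool = candidates[r]
        if want == 0:
            continue
        if len(pool) < want:
            logger.warning(
                "kinase %s: only %d candidate %s negatives for a target of %d; "
                "taking all", kinase, len(pool), r, want,
            )
            chosen = list(range(len(pool)))
        else:
            chosen = rng.choice(len(pool), size=want, replace=False)
        for i in sorted(int(i) for i in chosen):
            pid, p = pool[i]
            pep = Peptide.from_site(fasta[pid], pid, p, label=NEGATIVE, kinase=kinase)
            negatives.append(pep)
            peptide_profiles[pep.key] = protein_profile(pid).window(p, 20)

    return ReferenceSet(
        kinase=kinase,
        positives=positives,
        negatives=negatives,
        profiles=peptide_profiles,
        sampling_seed=seed,
        neg_ratio=neg_ratio,
    )


# ---------------------------------------------------------------------------
# On-disk reference-set layout: ref.d/{meta.json, positives.tsv,
# negatives.tsv, profiles/{index.json, *.tsv}}
# ---------------------------------------------------------------------------

_PEPTIDE_COLUMNS = ["protein_id", "position", "residue", "kinase", "window7", "window41"]


def write_profile(path, window: str, profile: Profile) -> None:
    """Write one peptide profile as TSV: residue, 20 freqs, 20 scores per row."""
    if len(window) != profile.length:
        raise ValueError("window length does not match profile length")
    with open(path, "w") as fh:
        header = ["residue"] + [f"f_{a}" for a in AMINO_ACIDS] + [f"s_{a}" for a in AMINO_ACIDS]
        fh.write("\t".join(header) + "\n")
        for i, c in enumerate(window):
            cells = [c] + [f"{v:.12g}" for v in profile.freq[i]] + [
                f"{v:.12g}" for v in profile.score[i]
            ]
            fh.write("\t".join(cells) + "\n")


def read_profile(path, source: str = "pseudo"):
    """Read a peptide profile TSV back; returns ``(window, Profile)``."""
    table = pd.read_csv(path, sep="\t")
    expected = 1 + 40
    if table.shape[1] != expected:
        raise FormatError(f"{path}: expected {expected} columns, found {table.shape[1]}")
    window = "".join(table["residue"])
    freq = table[[f"f_{a}" for a in AMINO_ACIDS]].to_numpy(dtype=float)
    score = table[[f"s_{a}" for a in AMINO_ACIDS]].to_numpy(dtype=float)
    return window, Profile(freq=freq, score=score, source=source)


def _peptide_frame(peptides) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in peptides],
            "position": [p.center_pos for p in peptides],
            "residue": [p.center_residue for p in peptides],
            "kinase": [p.kinase for p in peptides],
            "window7": [p.window7 for p in peptides],
            "window41": [p.window41 for p in peptides],
        }
    )


def save_refset(refset: ReferenceSet, outdir) -> None:
    outdir = Path(outdir)
    (outdir / "profiles").mkdir(parents=True, exist_ok=True)
    _peptide_frame(refset.positives).to_csv(outdir / "positives.tsv", sep="\t", index=False)
    _peptide_frame(refset.negatives).to_csv(outdir / "negatives.tsv", sep="\t", index=False)

    index = {}
    for i, pep in enumerate(refset.peptides):
        fname = f"pep{i:05d}.tsv"
        index[pep.key] = {"file": fname, "source": refset.profiles[pep.key].source}
        write_profile(outdir / "profiles" / fname, pep.window41, refset.profiles[pep.key])
    with open(outdir / "profiles" / "index.json", "w") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)

    meta = {
        "format": "postmod-refset-1",
        "kinase": refset.kinase,
        "n_positive": len(refset.positives),
        "n_negative": len(refset.negatives),
        "neg_ratio": refset.neg_ratio,
        "sampling_seed": refset.sampling_seed,
    }
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_refset(indir) -> ReferenceSet:
    indir = Path(indir)
    try:
        with open(indir / "meta.json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"{indir}: not a reference-set directory (no meta.json)") from None

    def load_peptides(fname, label):
        table = pd.read_csv(indir / fname, sep="\t", dtype={"position": int})
        peps = []
        for row in table.itertuples(index=False):
            peps.append(
                Peptide(
                    protein_id=str(row.protein_id),
                    center_pos=int(row.position),
                    center_residue=str(row.residue),
                    window7=str(row.window7),
                    window41=str(row.window41),
                    label=label,
                    kinase=str(row.kinase),
                )
            )
        return peps

    positives = load_peptides("positives.tsv", POSITIVE)
    negatives = load_peptides("negatives.tsv", NEGATIVE)
    with open(indir / "profiles" / "index.json") as fh:
        index = json.load(fh)
    profiles = {}
    for key, entry in index.items():
        _, prof = read_profile(indir / "profiles" / entry["file"], source=entry["source"])
        profiles[key] = prof
    return ReferenceSet(
        kinase=meta["kinase"],
        positives=positives,
        negatives=negatives,
        profiles=profiles,
        sampling_seed=meta.get("sampling_seed", 0),
        neg_ratio=meta.get("neg_ratio", 10),
    )
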