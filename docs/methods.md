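# Methods

## Model

`postmod` treats kinase-specific phosphosite prediction as labeled
instance-based classification: a query peptide is compared against a
reference set of known substrate sites (positives) and sampled non-sites
(negatives) of one kinase group, and the evidence of its nearest neighbors
— direct and indirect — decides the call. No parametric model is fitted;
everything is determined by the similarity function, the reference set and
four integer/real parameters.

### Peptide representation

A candidate site is the S/T/Y residue at a 1-based position of a protein.
Two windows are extracted around it: 7 residues (center ± 3) for the
substitution-matrix score and 41 residues (center ± 20) for the profile
score. Positions beyond the termini are padded with `X`; `X` scores by the
NCBI BLOSUM62 `X` row (0 against most residues, −1 against itself) and
carries the background distribution in profiles. The window sizes reflect
the two relevant length scales: immediate physicochemical context of the
acceptor, and the longer region that can carry structural or evolutionary
signatures of the kinase-docking surface.

### Similarity levels

1. `S_BLOSUM62` — gapless sum of BLOSUM62 substitutions over the 7-window.
2. `S_profile` — global affine-gap alignment of the two 41-column
   profiles. The column score is the symmetric profile-profile
   cross-product `PPA_ij = ½ Σ_k (f_ik S_jk + f_jk S_ik)` (frequencies of
   one profile against log-odds of the other, both directions averaged).
   A gap of length L costs `gap_open + (L−1)·gap_extend` with defaults
   3.0 / 0.75; end gaps are penalized (the windows are fixed-length and
   site-centered, so unaligned overhangs are genuine mismatch). A local
   (Smith-Waterman-style) mode exists behind `AlignmentParams(mode="local")`
   for sensitivity analysis.
3. `S_combined = S_BLOSUM62 · S_profile` if both are > 0, else 0. Clamping
   prevents two negative components from multiplying into spuriously high
   similarity; the unclamped product is kept as a diagnostic
   (`CombinedScore.raw_product`).

The affine-gap DP is a standard three-state (match / gap-in-A / gap-in-B)
recursion compiled with numba; correctness is pinned by an exhaustive
alignment-enumeration oracle for windows ≤ 4 columns, and cross-checked
against `S_BLOSUM62` in the point-mass-profile, gapless limit.

### Noise reduction by indirect relationships

Direct similarity ranking is noisy: an unrelated peptide can score high by
chance. The noise reducer re-ranks the reference using one round of
relationship propagation:

1. Retrieve the top α reference peptides by `S_combined` to the query.
2. Build the indirect-relationship matrix: each hit keeps only its own top
   α reference neighbors (self and the query excluded); other entries are
   zero.
3. Score every reference peptide by summing, over all relationships it
   participates in (as a hit's row or as a selected partner), the value
   `sign · w(partner) · S_combined`, where sign = +1 for same-label pairs
   (signal) and −1 for cross-label pairs (noise), and `w` = the
   positive-relationship weight when the partner is positive, 1 otherwise.
   Both endpoints receive each relationship's contribution — this is what
   lets reference peptides outside the initial hit list acquire indirect
   support and enter the final ranking.
4. Rank by indirect score (ties: higher direct similarity to the query,
   then lexicographic peptide key), take the top β, and call the query
   positive iff strictly more than γ of them are positive. The confidence
   is the positive fraction of the top β; the prediction CLI thresholds it
   at ≥ 0.5.

A baseline classifier (`classify_direct`) applies the same top-β/γ decision
to the direct ranking, enabling the four-level ablation
(window / profile / combined / noise-reducing).

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| window sizes | 7 and 41 | residues | substitution vs profile context |
| gap_open | 3.0 | score | first gapped column of a gap |
| gap_extend | 0.75 | score | each further gapped column |
| neg_ratio | 10 | — | negatives sampled per positive |
| min_sites | 21 | sites | smallest usable kinase group (strictly more than 20) |
| α | ⌊n⁺/2⌋ (≥1) | peptides | direct hits retrieved |
| β | ⌊n⁺/3⌋ (≥1) | peptides | indirect hits inspected |
| γ | ⌊n⁺/4⌋, capped at β−1 | peptides | positive-count threshold (strict >) |
| weight | n⁻/n⁺ | — | positive-partner up-weighting |
| confidence threshold | 0.5 | — | prediction cut-off (≥) |

n⁺/n⁻ are the positive/negative counts of the reference in use; during
cross-validation they are recomputed per fold after removing the held-out
queries. The weight defaults to the *realized* class ratio because its
purpose is to offset the sampling imbalance; `force_weight=10` pins the
nominal value. The fraction-based parameters floor with a minimum of 1
(γ may be 0); the γ < β invariant is enforced by lowering γ, which only
triggers for very small positive counts.

## Input formats

* FASTA (biopython); record ids are the first header token; non-standard
  residues map to `X` with a logged count.
* Phosphosite TSV with header `protein_id  position  residue  kinase`,
  1-based positions; rows disagreeing with the FASTA are rejected and the
  reasons returned, never silently dropped.
* PSI-BLAST ASCII PSSMs (`blastpgp -Q` dialect): 20 integer log-odds
  columns then 20 percentage columns per residue, NCBI column order;
  percentages are renormalized to frequencies, all-zero rows replaced by
  the background distribution.
* When no PSSM is supplied, a deterministic pseudo-profile is derived from
  the sequence: frequencies `0.7·δ_residue + 0.3·background` (background =
  BLOSUM62 marginal amino-acid frequencies) and the BLOSUM62 row of the
  observed residue as scores; `X` positions get pure background and zero
  scores.

Reference sets are stored as a diffable directory
(`meta.json`, `positives.tsv`, `negatives.tsv`, `profiles/*.tsv` with a
JSON index); profile round-trips preserve values to better than 1e−9.

### Negative sampling

Candidate negatives are every S/T/Y occurrence in the proteins of the
positive set (optionally the whole FASTA) that no kinase in the site table
annotates — an "unknown is not negative" stance, since sites annotated for
other kinases are excluded rather than used. Sampling is seeded, without
replacement, and matches the positives' center-residue composition exactly
per residue type (10 negatives per positive of each type). If the pool is
short the full pool is taken and a warning logged.

## Synthetic data

The generator emulates the structure of a kinase reference set with fully
known ground truth. Positives draw their central 7 residues from a
position-weight matrix (default: a basophilic R-R-x-S/T-hydrophobic-x-acidic
motif) mixed with background at a `strength` in [0,1]; the center residue is
forced. Flanks and negatives are background draws; negatives share the
positives' center residue exactly, so center composition is matched by
construction. Everything derives from one seeded generator: identical
parameters and seed give byte-identical files.

Synthetic profiles (default mode `"sampled"`) are drawn around the
*generating* per-position distributions: Dirichlet samples (concentration
50) of each column, with log-odds scores `2·log2(f/bg)` after shrinking the
frequencies 30% toward the background. This mirrors how an iterative
profile search annotates data: conserved (motif) columns get concentrated
frequencies and positive scores, variable columns get background-like
frequencies and near-zero scores, and the pseudocount shrinkage keeps
sampling noise from biasing unconserved scores negative. The alternative
mode `"pseudo"` uses the sequence-derived pseudo-profile; it models every
position as a confident single observation, which makes unrelated 41-window
pairs score systematically negative and is therefore the harsher, less
profile-realistic benchmark.

What passing the synthetic benchmarks shows: the pipeline recovers a
planted, profile-consistent motif (strength 0.9 gives near-perfect LOOCV
at the profile-aware levels), stays at chance AUC when there is no signal
(strength 0), and the noise reducer does not lose recall relative to the
combined score. What it does not show: performance on real kinase data,
where motifs are degenerate, substrates are phylogenetically related
(profile flanks correlate), negatives can be unannotated true sites, and
the four levels are far from saturation.

A second fixture reproduces the published miniature illustration of the
noise reducer exactly (10 reference peptides, α=5, β=4, γ=2, weight 10):
the three printed relationship values (0.61, 0.01, 0.50) are injected into
an otherwise hand-constructed symmetric score table arranged so that the
illustrated peptide participates in exactly those three relationships and
the final top-4 contains three positives. Scores, not sequences, define
this fixture; the classifier accepts precomputed score tables for exactly
this purpose.

## Numerical and design choices

* Ties are always broken deterministically: score descending, then (where
  applicable) direct query similarity descending, then peptide key
  ascending. Re-running any pipeline stage with the same inputs and seed
  is byte-identical.
* ROC curves step all tied queries at once; the normalized area equals the
  Mann-Whitney statistic with ties counted one half. Classifier outputs
  are ranked by confidence with the mean combined similarity of the top-α
  hits as a deterministic tie-break (β quantizes confidence to β+1 levels,
  so ties are common).
* Precision with zero predicted positives is reported as 0 and flagged
  (`precision_defined=False`) rather than NaN.
* k-fold CV shuffles each class with the seed and deals them round-robin
  with a continuing cursor: fold sizes differ by ≤1 per class and k = n
  reduces exactly to leave-one-out. Stratification is by label only;
  peptides from one protein may land in different folds (homology leakage
  is the user's concern at dataset construction time).
* Cross-validation problem sizes in the test suite use 30 positives + 300
  negatives (the scale of a mid-sized kinase group), where a full LOOCV
  including the all-pairs 41-column alignments runs in a few seconds.
* Degenerate inputs fail loudly: empty reference sets, single-class ROC
  input, k outside [2, n], γ ≥ β, non-acceptor centers, malformed files.

## Known limitations

* One round of indirect propagation only; no iterated or learned weights.
* The profile alignment assumes both windows are exactly 41 columns;
  variable-length or asymmetric windows are not supported.
* The pseudo-profile is a stated approximation, not a replacement for real
  iterative-search profiles; predictions without PSSMs lean mostly on the
  window score's information.
* Negative sampling trusts the site table: unannotated true sites become
  label noise in the negatives, as in any database-derived benchmark.
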