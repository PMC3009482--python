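# postmod

Kinase-specific phosphorylation-site prediction from peptide similarity,
with an indirect-relationship noise reducer.

Protein kinases recognize their substrate serines, threonines and tyrosines
partly through the sequence surrounding the acceptor residue. `postmod`
predicts whether a candidate site is a substrate of a given kinase group by
comparing it against a *reference set* of known phosphosites (positives) and
sampled non-sites (negatives, 10 per positive), using three nested
similarity levels and a re-ranking step that exploits similarity
relationships *among* the reference peptides. It is aimed at computational
biologists who want a transparent, training-free alternative to kernel- or
network-based site predictors, and at method developers who need a fully
seeded synthetic benchmark for this class of algorithm.

## Method

For two candidate sites A and B:

* **Window score** — over the fixed 7-residue windows centered on the site,

  `S_BLOSUM62(A,B) = Σ_{i=1..7} blosum62(A_i, B_i)`,

  with `X` padding at protein termini.

* **Profile score** — each site carries a 41-position profile (PSFM
  frequencies `f` and PSSM log-odds `S`, from PSI-BLAST `-Q` output or a
  documented sequence-derived pseudo-profile). Column pairs are scored by
  the symmetric cross-product

  `PPA_ij = ½ Σ_{k=1..20} (f_ik S_jk + f_jk S_ik)`,

  and `S_profile(A,B)` is the optimal global alignment of the two
  41-column windows under affine gap costs (gap open 3.0, extension 0.75).

* **Combined score** — `S_combined = S_BLOSUM62 · S_profile` when both
  components are positive, else 0.

* **Noise reduction** — for a query, the top α reference peptides by
  `S_combined` are retrieved; an indirect-relationship matrix keeps each
  hit's own top-α reference neighbors; every relationship contributes its
  score to both endpoints, signed +1 between same-label peptides (signal)
  and −1 across labels (noise), weighted ×w when the partner is a positive
  peptide (w = the negative:positive ratio, nominally 10). Reference
  peptides are re-ranked by these indirect scores; the query is called
  positive when the top β contain strictly more than γ positives, with
  confidence = (positives in top β)/β. Defaults follow the positive count
  n⁺ of the reference set: α = ⌊n⁺/2⌋, β = ⌊n⁺/3⌋, γ = ⌊n⁺/4⌋.

Evaluation is leave-one-out (or stratified k-fold) cross-validation with
accuracy, precision and recall, plus ROC machinery (normalized AUC and
cumulative true-matches-per-false-matches counts).

## Worked example

A fully seeded synthetic benchmark: 30 positive peptides carrying a
basophilic R-R-x-S-Φ motif (strength 0.9) in the central 7 of a 41-residue
window, 300 background negatives, and matching synthetic profiles.

```python
from postmod import default_motif, generate_refset, ablation_report

motif = default_motif("S", strength=0.9)
refset = generate_refset(motif, n_pos=30, seed=1)
for feature, rep in ablation_report(refset).items():
    print(f"{feature:>10}  ACC {rep.acc:.3f}  P {rep.precision:.3f}  R {rep.recall:.3f}")
```

prints

```
    blosum  ACC 0.945  P 0.929  R 0.433
   profile  ACC 1.000  P 1.000  R 1.000
  combined  ACC 1.000  P 1.000  R 1.000
     noise  ACC 0.997  P 0.968  R 1.000
```

Each row is a leave-one-out cross-validation at one similarity level: the
7-residue window score alone recovers under half of the planted sites at
this operating point, while the profile-aware levels separate this (easy,
profile-consistent) synthetic signal essentially perfectly. An all-negative
baseline would score ACC = 10/11 ≈ 0.909 with zero recall. On real
phosphosite data the levels are far from saturation and the noise reducer
chiefly buys recall at held precision; see `docs/methods.md` for what this
synthetic benchmark does and does not demonstrate.

The same pipeline is scriptable from the shell:

```
postmod simulate --out sim/ --n-pos 30 --strength 0.9 --seed 1
postmod build-ref --fasta sim/proteins.fasta --sites sim/sites.tsv \
    --kinase SYN1 --out ref.d --min-sites 21 --seed 1
postmod predict --ref sim/ref.d --query my_protein.fasta --out pred.tsv
postmod evaluate --ref sim/ref.d --mode loocv --feature all --out metrics.json
```

`predict` scores every candidate acceptor residue of the query (S/T and/or
Y, matching the reference kinase's site types) and marks sites with
confidence ≥ 0.5 as predicted phosphosites.

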