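# Methods

## Problem and model

`plantdbp` frames DNA-binding-protein (DNA-BP) annotation as binary
classification of whole protein sequences. The feature space is the
amino-acid composition simplex: a protein maps to the 20-vector of
canonical-residue fractions, computed over canonical residues only so the
vector always sums to one. Composition discards residue order and all
evolutionary information by design — the intended deployment is
proteome-wide prediction in lineages where position-specific scoring
matrices cannot be built — and its discriminative signal rests on the
compositional biases of DNA-binding domains (notably enrichment of
positively charged residues that contact the phosphate backbone).

The classifier is a soft-margin SVM with RBF kernel. Hyperparameters are
chosen by exhaustive grid search: for every (C, γ) pair, stratified
k-fold cross-validation *within the training set* scores plain (uncalibrated)
SVMs by accuracy; the winning pair is refit on the full training set with
sigmoid (Platt-style) probability calibration on internal cross-validated
decision values. Ties in the grid go to smaller C, then smaller γ —
preferring the smoother model. Composition fractions are used raw: they
are already commensurate and bounded in [0, 1], and the model file records
this along with the fixed residue ordering so feature columns cannot
silently permute between training and prediction.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| min sequence length | 40 | residues | excludes fragments that cannot be full-length proteins |
| identity threshold | 35 | % of alignment columns | redundancy edge; standard benchmark practice |
| coverage threshold | 0.9 | fraction of each sequence | required on **both** sequences (conservative; see below) |
| alignment scoring | BLOSUM62, gap open 11 / extend 1 | — | standard protein local-alignment parameters |
| evidence policy | IDA | GO evidence codes | direct-assay-only positives; `manual` preset widens to curated codes |
| cost grid | 2⁻⁵…2¹⁵ step ×4 | — | standard practitioner grid |
| γ grid | 2⁻¹⁵…2³ step ×4 | — | standard practitioner grid |
| small grid | C 2⁻¹…2⁷, γ 2⁻⁷…2¹ | — | default for datasets of a few hundred sequences, where the outer grid plateaus and the full grid only adds runtime |
| CV folds | 5 | — | field convention for these dataset sizes |
| realistic class ratio | 10:1 | non-DNA-BP : DNA-BP | expected in-proteome ratio |
| expected DNA-BP fraction | 0.06 | of proteome | literature estimate of 6–7%; used for threshold selection |
| probability threshold | selected, typically 0.85 | [0.5, 1.0] | smallest threshold whose predicted set fits under the expected count |
| FDR level | 0.05 | q-value | enrichment significance |

## Dataset assembly

Redundancy removal re-implements single-linkage identity clustering:
pairs are linked when the best local alignment reaches the identity
threshold over the coverage threshold of *both* sequences, clusters are
connected components, and one representative per cluster is drawn
uniformly under the run seed. Requiring coverage on both sequences is the
conservative reading of "over 90% of sequence length" — it can only link
fewer pairs, hence remove at least as much redundancy, and it avoids a
long protein surviving alongside its contained domain. Cluster
*membership* is seed-independent; only representative choice is
randomised, and input order fixes iteration order so runs reproduce.

The realistic split halves the negative pool (larger half to training;
1767 negatives become 884/883) and caps positives per side at
⌊negatives/ratio⌋, further capped by half the positive pool so train and
test stay disjoint. The combined lineage pool takes every positive from
all sources and samples negatives per source at stated counts, which must
balance the positives.

Proteins carrying both a DNA-binding and a non-DNA-binding
molecular-function annotation are excluded from the negative class: an
annotation-complete negative set is impossible, but at least known
positives must not leak into it.

## Numerical and degenerate-case choices

* Metrics are computed at full precision; rounding to 2 d.p. happens only
  in report tables. A metric with a zero denominator is reported as
  undefined (`None`) rather than 0.
* Cross-validation is summarised on the pooled confusion matrix rather
  than the mean of per-fold metrics: with 100-protein folds, per-fold MCC
  is noisy and pooling weights every test prediction equally. Per-fold
  reports are returned alongside.
* Threshold-sweep counting is inclusive (score ≥ threshold), matching
  "probability ≥ 0.85" usage; sweep totals are asserted non-increasing.
* The expected DNA-BP count rounds half-up (0.06 × 34725 = 2083.5 →
  2084). If no threshold fits under the expected count, the largest is
  returned with a warning instead of failing the run.
* Noncanonical residues (X, B, Z, J, U, O — ambiguity codes,
  selenocysteine, pyrrolysine) are tolerated at read time and excluded
  from composition numerator and denominator. One noncanonical residue is
  always tolerated; beyond that, records over 10% noncanonical are
  rejected as junk. Sequences that are entirely noncanonical are errors.
* Residues without a BLOSUM62 row (J, U, O) are scored as X during
  alignment only; the stored sequence is unchanged.
* GO term closure uses `is_a` edges only by default; `part_of` is a flag.
  Within the molecular-function hierarchy `part_of` is essentially absent,
  so the default matches how DNA-binding descendants are enumerated in
  practice.
* Term enrichment compares the query set against the reference *minus*
  the set (disjoint 2×2 margins), one-sided for over-representation, with
  Benjamini–Hochberg adjustment — the behaviour of standard singular
  enrichment analysis tools.

## Synthetic data: what it does and does not show

The generator draws sequences i.i.d. per residue from class-specific
compositions: a shared base composition (default uniform 0.05) with extra
probability mass δ added to a residue subset (default {K, R}) for the
positive class, taken proportionally from the remaining residues. Lengths
are uniform on [40, 600]. Optional homolog families — a parent plus point
mutants at <10% of positions — give the redundancy stage true clusters whose
recovery is guaranteed by construction. Default study conditions are
δ = 0.08 at n = 200/200 for signal recovery and δ = 0 at n = 250/250 for
null calibration; δ = 0.08 mirrors the magnitude of the K+R enrichment
separating real DNA-binding from non-binding sets, and a few hundred
sequences per class matches the size of curated single-species pools.

Because the classifier uses only composition, this generator spans the
entire feature space the model can see, and passing tests demonstrate
correct recovery of compositional class structure, correct null behaviour
(|MCC| near zero when classes are exchangeable), and end-to-end pipeline
integrity. They do **not** demonstrate real-world accuracy: real
DNA-binding and non-binding proteins overlap heavily in composition
space (real balanced benchmarks sit near 80% accuracy, not the ≥95% seen
on synthetic classes), real negatives are annotation-incomplete, and real
homology is not i.i.d. mutation. Claims about biological performance
require curated GO-derived datasets supplied by the user.

## Known limitations

* All-pairs alignment makes redundancy removal O(n²) alignments — fine
  for curated pools of a few thousand sequences, not for whole proteomes
  (no k-mer prefiltering is implemented).
* The GOA-DB domain-keyword list is a configurable heuristic over domain
  *labels*; it does not reproduce any specific curator's Interpro/Pfam
  judgement.
* Negative-set construction trusts the annotation corpus; unannotated
  DNA-BPs in the negative pool depress measured sensitivity.
* Model files are Python pickles: self-describing and verified on load,
  but not portable across major scikit-learn versions.
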