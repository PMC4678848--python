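# plantdbp

Lineage-specific prediction of DNA-binding proteins (DNA-BPs) from protein
sequence, built for plant genome annotation.

Most plant proteomes are poorly annotated: on the order of half of all
predicted proteins lack a molecular-function GO term, and DNA-binding
proteins — transcription factors, histones, chromatin remodellers — are a
large, multi-domain class that generic predictors trained on mixed-species
structural data handle badly. `plantdbp` takes the opposite approach: train
a species- or lineage-specific support vector machine on GO-curated
sequences from that lineage, using the single cheapest feature that scales
to whole proteomes.

## The model

Each protein is reduced to its **amino-acid composition**: the 20-vector
*x* with *x_r* = count(*r*) / (canonical residues), *r* ∈
{A,C,D,E,…,Y}. A soft-margin SVM with radial-basis kernel

  K(x, x′) = exp(−γ‖x − x′‖²)

is trained on a curated binary dataset (DNA-BP vs non-DNA-BP), with the
cost *C* and kernel width γ selected by grid search under stratified inner
cross-validation. Platt-style sigmoid calibration turns decision values
into posteriors, so every prediction carries a **probability score**
max(p, 1−p) ∈ [0.5, 1.0] for its predicted class.

Training sets are built the way curated benchmarks in this field are
built:

1. select positives by the GO terms GO:0003677 (DNA binding) and
   GO:0003700 (DNA-binding transcription factor activity) plus all their
   `is_a` descendants, restricted to an evidence-code policy (default:
   IDA only); negatives are proteins whose allowed molecular-function
   annotations all fall outside that closure;
2. drop fragments shorter than 40 residues;
3. remove redundancy by single-linkage clustering at ≥35% local-alignment
   identity over ≥90% of both sequence lengths (BLOSUM62, affine gaps),
   keeping one random representative per cluster;
4. assemble balanced (equal) splits, realistic ~10:1 splits matching the
   expected in-proteome class ratio, or a combined multi-source lineage
   pool.

Evaluation reports accuracy, sensitivity, specificity and the Matthews
correlation coefficient from the pooled 5-fold cross-validation confusion
matrix. For proteome-wide annotation, a threshold sweep tabulates the
predicted-set size per probability cutoff and the selection rule picks the
smallest threshold whose predicted set does not exceed the expected
DNA-BP content of the proteome (~6%). Predicted sets are then compared
with existing annotation (GOA-DB / GOA-Other / GOA-Unknown classes),
scored for nuclear-localisation fold enrichment, and tested for GO-term
over-representation (one-sided Fisher exact tests with
Benjamini–Hochberg FDR).

## Worked example

A fully synthetic run: two compositional classes, the positive class
shifted by +0.08 total probability mass on K+R (the charge bias of real
DNA-binding surfaces), 80 proteins per class.

```sh
plantdbp simulate --out-dir sim --n-pos 80 --n-neg 80 --delta 0.12 --seed 5
plantdbp build-dataset --fasta sim/proteins.fasta \
    --annotations sim/annotations.tsv --obo sim/ontology.obo \
    --out-dir ds --seed 5 --skip-homology-reduction
plantdbp train --fasta sim/proteins.fasta --dataset-table ds/dataset.tsv \
    --model-out model.pkl --seed 5
plantdbp evaluate --fasta sim/proteins.fasta --dataset-table ds/dataset.tsv \
    --model-file model.pkl --out metrics.tsv --seed 5
plantdbp predict --model-file model.pkl --fasta sim/proteins.fasta --out preds.tsv
```

which prints

```
train: 64+64, test: 16+16
selected cost=8.0 gamma=2.0
5-fold_cv: {'accuracy': 0.98, 'sensitivity': 0.97, 'specificity': 0.98, 'mcc': 0.95}
test: {'accuracy': 0.97, 'sensitivity': 0.94, 'specificity': 1.0, 'mcc': 0.94}
78 of 160 predicted DNA-binding
```

`train` reports the grid-search winner; the `evaluate` lines are the
pooled 5-fold CV metrics on the training split and the held-out test-split
metrics (values near 1 because the synthetic class shift is strong). The
prediction table lists one line per protein with its label, p(DNA-BP) and
probability score; `plantdbp sweep` and `plantdbp annotate` then drive
threshold selection and annotation-class / enrichment reports from it.

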