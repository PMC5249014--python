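# mirnacle

Completely ab initio pre-miRNA prediction from genomic sequence: a sliding
window is folded through a triangular base-pairing matrix, hairpins are
assembled incrementally in three stages (exact stems → non-exact stems →
complete hairpins), and each stage is gated by its own SMOTE-balanced
random-forest model so that only candidates whose positive-class probability
clears the stage threshold move on.

## Layout

| module | role |
| --- | --- |
| `mirnacle.pairing_matrix` | run-length base-pairing matrix of one window (Watson-Crick + G·U wobble) |
| `mirnacle.hairpin_search` | exact-stem extraction, symmetric-loop extension, best-first hairpin construction with bulges/asymmetric loops |
| `mirnacle.features` | stage-1/2/3 feature vectors (29/35/80 features, incl. 16 dinucleotides and 32 structure triplets) and the pluggable energy backend |
| `mirnacle.cascade` | stage training sets (ARFF in/out), SMOTE oversampling, per-stage random forests, thresholds, cross-validation |
| `mirnacle.scanner` | window scanning, duplicate merging, center-distance evaluation (SN/SL/GM) |
| `mirnacle.synthetic_data` | seeded stem-loop/background/implanted-genome generators so everything runs offline |
| `mirnacle.io` | FASTA (gzip-transparent, T→U), GFF3/BED6, structure FASTA, minimal ARFF |

## CLI

```bash
# train the three-stage cascade from FASTA corpora
mirnacle train --positives pos.fa --negatives neg.fa --model-dir model/ \
    --trees 100 --smote-k 5 --seed 1 [--arff-dir arff/]

# scan a genome (GFF3 out; optional BED6 and dot-bracket structure FASTA)
mirnacle scan --input genome.fa --model-dir model/ --out pred.gff3 \
    --thresholds 0.3,0.3,0.7 --window 150 --step 10 --min-stem 4 \
    --min-size 50 --max-size 150 [--bed pred.bed --structures pred.fa]

# evaluate against known hairpins (center within 10% of the known size)
mirnacle evaluate --pred pred.gff3 --truth known.bed

# 10-fold cross-validation of one stage training set (SMOTE in train folds only)
mirnacle cv --trainset stage1.arff --folds 10

# synthetic genome with implanted hairpins + truth BED
mirnacle synth --genome-length 5000 --hairpins 3 --seed 1 \
    --fasta genome.fa --truth-bed truth.bed
```

Defaults: minimum exact-stem size 4 bp, window 150 nt, step 10 nt,
prediction size 50–150 nt, stage thresholds (0.3, 0.3, 0.7), terminal loop
≥ 3 nt. All coordinates are 0-based half-open internally; GFF3 output is
1-based.

The default energy backend is a dependency-free stacking-count
approximation (−2/−1/−0.5 kcal·mol⁻¹ for GC/AU/GU pairs, nested-structure
DP for the fold MFE); any object with `duplex_energy(arm5, arm3)` and
`fold_mfe(sequence)` can be passed in its place (e.g. an adapter around an
external thermodynamic folder).

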