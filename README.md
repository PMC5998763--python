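# metmatch

Match natural products to similar human metabolites and transfer the
metabolites' known phenotype annotations to the matched products as
predicted therapeutic effects.

Each candidate (partner, metabolite) pair is scored on three similarity
features:

* **structure** — Tanimoto coefficient over hashed path fingerprints
  (RDKit, 1024 bits by default);
* **target** — normalized Smith-Waterman similarity (BLOSUM-62,
  gap open 10 / extend 0.5, score divided by the geometric mean of the
  self-alignment scores) between the pair's target proteins, averaged over
  the scores above a global top-5% threshold;
* **phenotype** — absolute Pearson correlation between random-walk-with-
  restart profiles (restart 0.7, convergence 1e-5) of the pair's targets on
  a directed gene/phenotype association network, restricted to phenotype
  nodes.

A positive-unlabeled SVM ensemble (100 balanced resamples of known
drug-metabolite positives vs. sampled unlabeled pairs, 10-fold CV recorded
per member) fuses the three features; pairs whose mean member probability
passes the decision threshold are called similar, and the metabolite's
phenotype terms are transferred to the partner.

The package also ships the full evaluation battery (feature-ablation AUROC
with random or structure-filtered negatives at a configurable Tanimoto
floor, indication precision/recall against a random-pairing baseline, and
literature co-occurrence statistics: Jaccard index, Fisher's exact test,
Mann-Whitney U) and a synthetic fixture generator with controllable planted
signal so everything is testable offline.

## CLI

All inputs are plain text: SMILES lists, FASTA, and TSV tables
(tab-separated, header row, `.` for missing).

```sh
# generate a synthetic dataset (presets: tiny, default, stress)
metmatch fixture --preset tiny --seed 7 --out data/

# score matrix for drug x metabolite pairs
metmatch features \
    --metabolites data/metabolites.smi --metabolite-targets data/metabolite_targets.tsv \
    --partners data/drugs.smi --partner-targets data/drug_targets.tsv --partner-role drug \
    --proteome data/proteome.fasta --network data/network.tsv \
    --out drug_features.tsv

# train the ensemble on positive drug-metabolite pairs
metmatch train --features drug_features.tsv --positives data/positives.tsv \
    --n-resamples 100 --seed 7 --out model.joblib

# score natural-product x metabolite pairs (build np_features.tsv the same
# way with --partners data/natural_products.smi) and transfer annotations
metmatch predict --model model.joblib --features np_features.tsv --out predictions.tsv
metmatch transfer --predictions predictions.tsv --annotations data/annotations.tsv \
    --out transfers.tsv

# evaluation designs
metmatch evaluate --mode ablation --features drug_features.tsv \
    --positives data/positives.tsv --test-mode structure_filtered --out ablation.tsv
metmatch evaluate --mode indications --transfers transfers.tsv \
    --indications data/indications.tsv --annotations data/annotations.tsv --out ind.tsv
metmatch evaluate --mode literature --cooccurrence data/cooccurrence.tsv \
    --cooccurrence-random data/cooccurrence_random.tsv --out lit.tsv
```

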