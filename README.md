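# domsign

Top-down enzyme EC-number annotation from Pfam-A domain signatures.

`domsign` is for computational biologists who need to assign Enzyme
Commission (EC) digits to large protein sets — database releases, genomes,
metagenome gene catalogs — where close homologs of most queries are not
available and BLAST-style best-hit transfer over-predicts or fails. Instead
of sequence similarity, it transfers function through the **domain signature
(DS)**: the deduplicated set of Pfam-A families detected in a protein.

## Method

Training proteins (single-EC enzymes with Pfam-A domains) are grouped by
shared DS. For level *k* of the EC hierarchy, each group of size
*N*<sub>DS<sub>i</sub></sub> splits into subgroups by the first *k* EC digits,
and the abundance of subgroup *j*,

&nbsp;&nbsp;&nbsp;&nbsp;*A*<sub>DS<sub>i</sub>–EC<sub>j</sub></sub> = *N*<sub>DS<sub>i</sub>–EC<sub>j</sub></sub> / *N*<sub>DS<sub>i</sub></sub>,

is the **specificity** of that DS–EC pair. The dominant (largest) subgroup
defines the pair stored in the level-*k* model. Four such models, one per EC
level, form the predictor.

Annotation is two-stage and top-down:

1. **Candidate selection.** A query's DS must belong to the
   *specific-enzyme-DS set* — enzyme-derived DSs minus every DS also observed
   in reliably non-enzymatic proteins (EC-less entries whose description,
   keyword and cross-reference text contains none of nine catalytic/
   uncertainty terms such as `ase`, `enzyme`, `putative`). Queries without a
   DS are `NO_DOMAIN`; those failing the filter are `NON_ENZYME`.
2. **Level-by-level digit assignment.** Descend levels 1→4, at each level
   taking the best subgroup extending the digits already emitted. Stop the
   first time the specificity falls below the user threshold (default
   **0.80**); the digits assigned so far are the output and their
   specificities become per-digit **confidence scores**. A candidate stopped
   before the first digit is `UNRESOLVED_ENZYME` (`EC = -.-.-.-`).

The threshold trades recall for precision: strict thresholds (0.99) emit
fewer, shallower, safer digits; permissive ones annotate deeper.

Predictions are scored with a four-category hierarchical scheme — **E**quality,
**OP** (overprediction: ≥1 wrong digit, or an enzyme call on a non-enzyme),
**IA** (insufficient annotation: correct but shallower than truth, or a missed
enzyme — adds no error), **IM** (improvement: deeper than the recorded truth)
— plus example-based precision/recall over the four-level EC decomposition and
per-level exact accuracy. A k-fold cross-validation harness retrains
everything, including the specific-DS set, per fold.

## Worked example

One hundred proteins share a DS; their four-digit ECs are 1.1.1.1 ×43,
1.1.1.2 ×42, 1.1.2.1 ×3, 1.2.1.1 ×2 and 2.1.1.1 ×10. The dominant-subgroup
abundances are therefore 90/100, 88/100, 85/100 and 43/100 at levels 1–4.

```python
from fractions import Fraction
from domsign import synthetic, training, predict

enzymes, nonenzymes = synthetic.generate(synthetic.WORKED_EXAMPLE_SPEC)
trained = training.train(enzymes, nonenzymes)
result = predict.predict_one(
    "query", enzymes[0].signature, trained.models, trained.specific_ds,
    predict.EngineConfig(threshold=Fraction(4, 5)),
)
print(result.status.value, result.ec.render())
print([float(c) for c in result.confidences])
```

prints

```
ANNOTATED 1.1.1.-
[0.9, 0.88, 0.85]
```

At the 0.80 threshold the descent keeps the first three digits (specificities
0.90 ≥ 0.88 ≥ 0.85, all above threshold) and stops at level 4 (0.43 < 0.80),
so the query is annotated `1.1.1.-` with one confidence score per digit.

The same pipeline runs from the shell:

```sh
domsign simulate --spec corpus.yaml --out corpus.tsv
domsign train   --proteins corpus.tsv --out model.tsv
domsign predict --model model.tsv --proteins corpus.tsv --threshold 0.8 --out annotations.tsv
domsign cv      --proteins corpus.tsv --k 10 --seed 17 --threshold 0.8 --report report.tsv
```

Real data enters either as a protein table (`id  pfam;accessions  EC`), as
`hmmsearch --domtblout` output (`--domtblout hits.tbl`), or as a FASTA plus a
Pfam-A HMM library (`--fasta q.faa --pfam PfamA.hmm`), in which case the
search is run in process with each family's trusted cutoff.

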