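# scibet

Supervised cell-type annotation for single-cell RNA-seq, built around three
closed-form ideas:

1. **E-test marker selection.** For gene *i* with per-type mean normalized
   expression *X*<sub>ij</sub> over *n* cell types, the total entropy
   difference

   ΔS<sub>i</sub> = n · ln( AM<sub>i</sub> / GM<sub>i</sub> )

   compares the arithmetic and geometric means of the (pseudocounted)
   *X*<sub>ij</sub> across types. By the AM–GM inequality ΔS ≥ 0, with
   equality exactly when the means are identical — so ranking genes by ΔS
   surfaces type-specific markers with nothing but linear passes over the
   matrix. A label-permutation test supplies p-values.

2. **Multinomial models per type.** Each type *j* becomes a probability
   vector over the selected genes via Laplace smoothing,
   p̂<sub>ij</sub> = (1 + X<sub>ij</sub>) / Σ<sub>i</sub>(1 + X<sub>ij</sub>),
   and a query cell **y** is assigned
   argmax<sub>j</sub> Σ<sub>i</sub> y<sub>i</sub> ln p̂<sub>ij</sub> —
   equivalently the type whose profile has minimal Kullback–Leibler
   divergence to the cell. Training and scoring are a group-mean and a
   matrix product, which is why prediction runs at ~10⁵ cells/s.

3. **Null-background rejection.** Cells whose type is absent from the
   reference are caught by the likelihood ratio
   C = ∏<sub>i</sub> p<sub>ir</sub><sup>y_i</sup> / ∏<sub>i</sub> p<sub>in</sub><sup>y_i</sup>
   between the pooled reference and a broad null background, computed on the
   genes that best separate the two; low-C cells are left "unassigned"
   instead of being forced onto a wrong label.

The package is aimed at anyone with a labeled reference matrix who wants
fast, reproducible annotation of new datasets, including cross-species
queries via one-to-one ortholog tables. A Poisson-Gamma (negative-binomial)
simulator with planted markers is included, so everything can be exercised
without external data.

## Worked example

```bash
python examples/01_select_markers.py
```

```
  gene  delta_S  rank
g00010 0.332119     1
g00062 0.324017     2
g00066 0.323500     3
...
planted markers recovered in the top 100 genes: 100/100
```

The simulator plants 20 marker genes in each of 5 types (8-fold elevated
mean); every one lands in the top 100 by ΔS. The other examples walk the
remaining capabilities — `02_train_and_predict.py` (hold-out annotation,
accuracy 1.000 on the simulation), `03_reject_unknown_types.py` (mean
log C of +1.19 for reference-type cells vs −8.72 for an unseen type, false
positive rate 0.000 at C < 0.05), and `04_cross_validation.py` (repeated
stratified 7:3 benchmarking).

The same pipeline is available from the shell:

```bash
scibet simulate --out-dir data/
scibet select  --matrix data/matrix.tsv --labels data/labels.tsv --out markers.tsv
scibet train   --matrix data/matrix.tsv --labels data/labels.tsv --out model.tsv
scibet predict --model model.tsv --query data/matrix.tsv --out pred.tsv
scibet benchmark --matrix data/matrix.tsv --labels data/labels.tsv --repeats 10 --out cv.tsv
```

Every command writes a `*.run.json` summary with the parameters and seed
that produced its output. See `docs/methods.md` for the statistical model,
parameter defaults and numerical conventions.

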