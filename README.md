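# itcwalk

Network-based prioritization of **inter-tissue communicators** (ITCs) —
protein ligands and receptors that carry signals between tissues — for
diseases with known disease genes, plus two validation harnesses that test
the selected communicators as diagnostic plasma biomarkers and as inferred
perturbation drivers of the disease genes.

The package is aimed at computational biologists who have a heterogeneous
molecular network (protein–protein, TF–target, miRNA–target edges), a
ligand/receptor catalog, and per-disease gene sets, and who want a ranked,
disease-specific shortlist of communicators without any disease expression
data.

## Method

For a column-stochastic transition matrix *W* of the network, a random
walk with restart (RWR) is seeded at each communicator *s*:

```
p_{t+1} = (1 − r) W p_t + r p_0,      p_0 = e_s,  r = 0.15
```

whose fixed point `p = r (I − (1−r)W)⁻¹ e_s` measures the topological
relevance of every node to the seed. The pipeline then:

1. **Calibrates a significance threshold θ**: within-set pairwise RWR
   values are collected for curated pathway gene sets and for size-matched
   uniform random node sets; θ is the maximum of the random-set medians.
   Walk values ≤ θ are treated as no influence.
2. **Scores influence**: for communicator *i* and disease *d* with genes
   *G_d*, the raw score is `Σ_{g∈G_d} p_i[g]·1[p_i[g] > θ]`, normalized by
   the mean of the same quantity over random seed genes (correcting for
   hub-like disease genes that attract walk mass from anywhere).
3. **Selects disease-specific communicators**: per communicator, a
   modified Z-score `modZ = 0.6745 (x − median) / MAD` is computed across
   diseases (with a documented mean-absolute-deviation fallback when
   MAD = 0); pairs with modZ > 5 are reported.

Validation harness A cleans a donors × proteins plasma matrix
(missingness filters, median imputation) and compares three feature sets —
the disease's specific communicators, size-matched random plasma proteins,
and raw disease genes — by repeated stratified CV (7:3 hold-out, 10-fold ×
5 repeats) of a gradient-boosted tree classifier, reporting AUROC and
AUPRC against the prevalence baseline. Validation harness B infers each
communicator's perturbation effect from the signatures of its downstream
transcription factors, selects cell lines whose signatures correlate at
the disease genes (average-linkage clustering, mean pairwise r > 0.4,
≥ 3 lines), and compares the disease set against 100 random communicator
sets by fold increase with a one-sample t-test against 1.

A first-class synthetic-fixture module generates all inputs with planted
ground truth (modules, communicators, informative proteins, correlated
cell-line blocks) so every stage is testable without external data.

## Worked example

```bash
python examples/02_prioritize_communicators.py
```

prints (seed 7):

```
calibrated significance threshold: 1.2357e-03
planted communicators: G0107, G0124, G0313, G0430, G0448

top 5 normalized influence scores:
  G0107      5.19  (planted)
  G0430      5.13  (planted)
  G0448      4.81  (planted)
  G0313      4.64  (planted)
  G0124      4.50  (planted)

top-5 precision: 1.00
```

The five communicators planted with extra wiring into the disease-gene
module occupy the top five normalized scores; scores around 5 mean those
nodes deliver about five times the walk mass to the disease genes that a
random network node would. The other examples (`01` walk basics, `03`
diagnostic CV, `04` perturbation folds) follow the same pattern: build or
generate a small input, run one capability, print what the numbers mean.

The same pipeline is scriptable from the shell:

```bash
itcwalk simulate --out fixture --seed 3 --kind network
itcwalk all --edges fixture/edges.tsv --pathways fixture/pathways.gmt \
    --itc-catalog fixture/itc_catalog.tsv \
    --disease-genes fixture/disease_genes.gmt --seed 3 --out run
```

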