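# Methods

## Model and assumptions

The method treats disease relevance of a ligand or receptor (an
inter-tissue communicator, ITC) as the amount of random-walk-with-restart
(RWR) probability mass it delivers to a disease's known genes through a
molecular interaction network. The walk

p_{t+1} = (1 − r) W p_t + r p_0

is iterated from the single-seed indicator p_0 = e_s on a
column-stochastic W built from the network adjacency. Because the
spectral radius of (1 − r)W is at most 1 − r, the iteration contracts in
L1 with factor 1 − r and the fixed point p = r(I − (1 − r)W)⁻¹e_s is
unique for any r > 0; the dense solve of that linear system doubles as an
independent oracle for the iterative solver (guarded to ≤ 2000 nodes).
Two consequences are asserted throughout: probability conservation
(Σp = 1) and the restart floor p[seed] ≥ r.

The model assumes unit edge weights (no reliability weighting) and, by
default, undirected propagation: regulatory (TF–target, miRNA–target)
edges are symmetrized, which is the common convention for RWR gene
prioritization and maximizes reachability from ITC seeds. An
`as_declared` policy that keeps regulatory edges directed is available,
since either convention is defensible. Multi-layer duplicates of the same
node pair count once; self-loops are dropped with a logged count.
Columns with no out-edges are handled by an explicit dangling policy:
`uniform_jump` (default; spreads the mass uniformly, keeping W
column-stochastic without trapping it) or `self_loop`. Protein complexes
are single nodes whose id is the `::`-joined sorted member list —
deterministic and collision-free.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| restart probability r | 0.15 | community-standard restart mass per step |
| convergence tolerance | 1e-10 (L1) | natural norm for probability vectors; implies ≤ log(tol)/log(1−r)+1 iterations |
| significance threshold θ | calibrated | max of random-set medians (below) |
| modified-Z cutoff | 5 | cross-disease outlier cutoff for specificity |
| min disease genes | 10 | disease admitted only with ≥ 10 genes in the network |
| missingness thresholds | 150 / 740 | max missing proteins per donor, then max missing donors per protein |
| CV settings | 7:3, 10-fold × 5 | stratified hold-out; models scored on the fixed test set |
| min cases per disease | 100 | label admission floor for the diagnostic harness |
| cell-line cluster | ≥ 3 lines, mean r > 0.4 | correlation at disease genes only |
| random ITC sets | 100 | size-matched, excluding the disease set |

The calibration interprets "median RWR value per gene set" as the median
over all ordered seed→target pair values pooled within the set (the
per-seed-first alternative is not offered); one size-matched random set
is drawn per pathway set per draw, uniformly from all network nodes.
Random draws are seeded per pathway set from (seed, crc32(set name),
draw index), which makes the threshold invariant to the order in which
pathway sets are supplied — an invariant worth having because the
threshold is defined as an exact maximum.

The modified Z-score is the Iglewicz–Hoaglin form 0.6745(x − med)/MAD.
Score rows are frequently zero-heavy, so MAD = 0 is common; the fallback
scale is 1.2533 × mean absolute deviation with the 0.6745 factor
retained, and an all-constant row scores 0 everywhere. A consequence
worth knowing: for a row with a single outlier and all other values tied,
modZ of the outlier is ≈ 0.538 × (number of diseases) regardless of the
outlier's size, so the cutoff of 5 needs roughly ten diseases to be
reachable at all. The selection is meant for many-disease panels.

Normalization by random genes: the per-disease baseline is the mean
censored sum over n random seeds (default: catalog size; repeatable via
`n_baseline_repeats`). Random seeds may include catalog ITCs (no
exclusion by default; a flag exists). A zero baseline falls back to the
smallest positive random sum; a disease with no positive random sum at
all is dropped as unusable — division by zero must be defined somehow,
and this choice preserves ranking while flagging the degenerate case.

## Diagnostic harness

Donors are filtered before proteins, and the order matters (a donor
dropped for overall missingness no longer counts against any protein);
imputation uses the per-protein median over surviving donors only. The
classifier is a gradient-boosted tree ensemble (xgboost) with
`scale_pos_weight` set to n_negative/n_positive of each CV fold's
training portion and otherwise library defaults — no tuning is performed,
and every model is evaluated on the one held-out 30% test split rather
than on fold-out samples. AUPRC is computed as average precision; its
baseline is exactly the test-set prevalence. A feature condition with no
measured proteins is reported at that baseline ("baseline-only") rather
than from a model. Condition comparisons across diseases use a paired
one-sided Wilcoxon signed-rank test on per-disease medians (deltas over
the baseline for AUPRC); with fewer than five complete diseases only the
deltas are reported. Random proteins are fixed per disease (not resampled
per repeat).

## Perturbation harness

Signature columns pass, in order: exemplar flag, max-TAS among
(perturbagen, cell line, ptype) duplicates, allowed perturbation types
(over-expression OX, knock-down KD — analyzed separately end-to-end),
required time point (96 h), excluded cell lines. The order is part of
the contract: a higher-TAS off-time duplicate displaces its 96 h sibling
at the dedup stage and is then itself dropped by the time rule.
Signature values are taken as already standardized effect scores; no
further normalization is applied.

A receptor maps to every TF reachable by a directed pathway path
(transitive closure restricted to TFs); a ligand inherits the union over
its paired receptors. Cell-line correlations are computed at the disease
genes on matched (perturbagen, ptype) columns only — correlations on
unaligned perturbations are meaningless. Lines are clustered by average
linkage on 1 − r and the dendrogram is cut at 1 − 0.4; among resulting
clusters of ≥ 3 lines the largest with mean pairwise r > 0.4 wins (ties:
higher mean r). Cutting at the threshold rather than scanning all merge
heights keeps weakly-correlated intruders out of a strongly-correlated
block. The per-ITC signature is the TF-sum per selected cell line, the
absolute values averaged across lines, restricted to disease genes;
set scores are additive over ITCs (the implementation precomputes per-ITC
contributions for the 100-set comparison — numerically identical, ~30×
faster). The fold test is a one-sample t-test of the 100 fold values
against 1, two-sided by default with a one-sided option; a random set
scoring exactly 0 is redrawn up to 10 times, then excluded with a log.

## Synthetic study conditions

The generators' defaults are the conditions every distributional test
runs under:

* **Network**: 500 nodes, preferential-attachment backbone (m = 2),
  5 planted modules of 20 nodes (within-module edge probability 0.3,
  between 0.01); module 0 is the disease-gene set; 5 planted
  communicators with 10 extra edges each into the disease module and 45
  decoys with 10 uniformly random extra edges, so planted and decoy
  nodes are degree-matched and only the wiring direction distinguishes
  them. `wiring_strength=0` and `p_within=p_between` are the negative
  controls.
* **Proteome**: 300 donors × 40 proteins, 60 cases, 5 informative
  proteins shifted by `effect_size` standard deviations (0 = null,
  3 = separable), i.i.d. missingness at 1% plus one planted
  high-missingness donor and protein; filter thresholds default to 5% of
  proteins per donor and 2% of donors per protein, mirroring the usual
  proteome-cleaning proportions. Expected filter survivors are counted
  directly on the realized mask and stored in the manifest.
* **Signatures**: 80 genes (20 disease genes) × 8 cell lines × 24 TF
  perturbagens × {OX, KD}, plus duplicate, non-exemplar, off-time and
  excluded-cell-line columns for the filter rules. Four cell lines share
  a latent factor at the disease-gene rows (pairwise r ≈ 0.6); TFs
  downstream of the three disease receptors have disease-gene effects
  multiplied by `dg_inflation` (1 = null, 3 = planted effect), and the
  disease receptors draw from a TF pool disjoint from the other
  receptors so the planted inflation cannot leak into random ITC sets
  through shared TFs. The TF pool is kept large enough that the single
  disease-score realization is not dominated by a handful of latent
  draws.

What these fixtures do *not* emulate: realistic degree distributions of
curated interactomes, correlated missingness and batch structure of real
plasma panels, or the heavy-tailed, dose- and time-dependent structure of
real perturbation libraries. Passing tests therefore demonstrate
correctness and statistical behavior of the machinery, not biological
performance on real data.

## Numerical choices and degenerate inputs

All randomness flows through explicit `numpy` Generator seeds; no global
RNG state is touched, and fixtures regenerate bit-identically from their
manifest seed. Score and selection files are written with `%.12g`
formatting and sorted indices so repeated runs are byte-identical.
Column sums of the transition matrix are verified to 1e-12 after
normalization; normalization is idempotent at that tolerance. Ties in
the specific-ITC lists are broken by id after descending modZ. Gene sets
with fewer than two mapped members are skipped (calibration) or raised
(direct calls); an empty disease∩network intersection scores 0 with a
warning rather than failing a whole run.

## Problem sizes

Distributional assertions use 20 seeded replicates (calibration
separation, planted recovery, null perturbation folds), 10 replicates for
the null diagnosis AUROC, 1000 random vectors for the outlier-score
oracle, and 50-node networks for the solver/oracle comparison; these
sizes give stable pass/fail behavior for the stated tolerances while
keeping a full run of the suite and the acceptance script in the
low minutes on one CPU.

## Known limitations

* The modified-Z selection is uninformative for panels with few diseases
  (see above); `select_specific` refuses fewer than three.
* The diagnostic harness fixes hyperparameters at library defaults; it
  measures feature-set informativeness, not best-achievable accuracy.
* Ligand→TF inheritance assumes the ligand acts entirely through its
  cataloged receptors.
* `uniform_jump` makes dangling-column mass jump anywhere, which slightly
  favors well-connected components; `self_loop` is provided where that is
  unwanted.
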