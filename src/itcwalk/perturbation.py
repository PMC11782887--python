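"""Perturbation-signature validation of disease-specific communicators.

Direct perturbation data for ligands/receptors is rarely available, so an
ITC's effect is inferred from the perturbation signatures of its
downstream transcription factors (TFs): a receptor maps to every TF it can
reach through a directed pathway graph, and a ligand inherits the TF sets
of its paired receptors.  Signatures are quality-filtered (exemplar flag,
max transcriptional activity score among duplicates, perturbation type,
time point, excluded cell lines), cell lines are selected by clustering
their pairwise correlations at the disease genes, and the aggregate
perturbation of the disease-specific ITC set on the disease genes is
compared to 100 random size-matched ITC sets by fold increase with a
one-sample t-test against 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genesets import GeneSet

logger = logging.getLogger(__name__)

PTYPES = ("OX", "KD")
META_COLUMNS = ("cell_line", "perturbagen", "ptype", "time", "exemplar", "tas")


@dataclass
class SignatureMatrix:
    """Genes x signatures effect values plus per-signature metadata."""

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("metadata rows must match matrix columns, in order")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"signature metadata missing columns: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.meta["cell_line"].unique())

    def subset(self, signature_ids: list[str]) -> "SignatureMatrix":
        return SignatureMatrix(self.values[signature_ids],
                               self.meta.loc[signature_ids])

    def write_tsv(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene",
                           float_format="%.12g")
        self.meta.to_csv(meta_path, sep="\t", index_label="signature_id")

    @classmethod
    def read_tsv(cls, values_path: str | Path, meta_path: str | Path) -> "SignatureMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene")
        meta = pd.read_csv(meta_path, sep="\t", index_col="signature_id",
                           dtype={"exemplar": bool})
        return cls(values, meta)


@dataclass
class ITCtoTFMap:
    """ITC id -> downstream TF set, with the unmapped ITCs listed."""

    mapping: dict[str, frozenset[str]]
    unmapped: list[str]
    mode: str = "receptor_path"

    def __getitem__(self, itc: str) -> frozenset[str]:
        return self.mapping[itc]

    def __contains__(self, itc: str) -> bool:
        return itc in self.mapping


@dataclass
class PerturbationResult:
    """Disease-vs-random fold comparison for one disease and ptype."""

    disease_id: str
    ptype: str
    disease_score: float
    random_scores: list[float]
    fold_values: list[float]
    mean_fold: float
    t_stat: float
    p_value: float
    cell_lines_used: list[str]
    n_sets_excluded: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "disease_id": self.disease_id,
            "ptype": self.ptype,
            "disease_score": self.disease_score,
            "mean_fold": self.mean_fold,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "cell_lines_used": self.cell_lines_used,
            "n_sets_excluded": self.n_sets_excluded,
            "random_scores": self.random_scores,
            "fold_values": self.fold_values,
        }, indent=2, sort_keys=True) + "\n")


def filter_signatures(
    sig: SignatureMatrix,
    require_exemplar: bool = True,
    allowed_ptypes: tuple[str, ...] = PTYPES,
    required_time: str = "96 h",
    excluded_cell_lines: tuple[str, ...] = (),
) -> SignatureMatrix:
    """Quality and condition filtering of signature columns.

    Rules apply in order: keep exemplar-flagged columns; among duplicates
    of (perturbagen, cell line, ptype) keep the highest transcriptional
    activity score; keep only allowed perturbation types; keep the required
    time point; drop excluded cell lines.  Per-rule drop counts are logged;
    an empty result is an error reporting them.
    """
    meta = sig.meta
    drops: dict[str, int] = {}

    keep = meta.index
    if require_exemplar:
        kept = meta.index[meta["exemplar"].astype(bool)]
        drops["not_exemplar"] = len(keep) - len(kept)
        keep = kept
    m = meta.loc[keep]
    best = m.sort_values("tas", ascending=False, kind="stable").drop_duplicates(
        subset=["perturbagen", "cell_line", "ptype"], keep="first"
    )
    drops["duplicate_lower_tas"] = len(keep) - len(best)
    keep = meta.index[meta.index.isin(best.index)]  # preserve column order

    m = meta.loc[keep]
    kept = keep[m["ptype"].isin(allowed_ptypes)]
    drops["ptype"] = len(keep) - len(kept)
    keep = kept

    m = meta.loc[keep]
    kept = keep[m["time"] == required_time]
    drops["time"] = len(keep) - len(kept)
    keep = kept

    m = meta.loc[keep]
    kept = keep[~m["cell_line"].isin(excluded_cell_lines)]
    drops["excluded_cell_line"] = len(keep) - len(kept)
    keep = kept

    logger.info("filter_signatures drops: %s", drops)
    if len(keep) == 0:
        raise ValueError(f"filter_signatures removed every column; drops: {drops}")
    return sig.subset(list(keep))


def map_itcs_to_tfs(
    pathway_graph: nx.DiGraph,
    receptors: list[str],
    ligand_receptor_pairs: list[tuple[str, str]],
    tfs: list[str],
) -> ITCtoTFMap:
    """Receptor -> reachable TFs; ligand -> union over its receptors.

    A receptor maps to every TF reachable by a directed path in the
    pathway graph.  Receptors absent from the graph, or with no reachable
    TF, are listed as unmapped (as are ligands with no mapped receptor).
    """
    if not isinstance(pathway_graph, nx.DiGraph):
        raise ValueError("pathway graph must be a directed graph")
    if not tfs:
        raise ValueError("TF list must be nonempty")
    tf_set = set(tfs)
    mapping: dict[str, frozenset[str]] = {}
    unmapped: list[str] = []
    for rec in receptors:
        if rec not in pathway_graph:
            logger.info("map_itcs_to_tfs: receptor %r absent from pathway graph", rec)
            unmapped.append(rec)
            continue
        downstream = frozenset(nx.descendants(pathway_graph, rec) & tf_set)
        if downstream:
            mapping[rec] = downstream
        else:
            unmapped.append(rec)
    for ligand, receptor in ligand_receptor_pairs:
        tf_union = mapping.get(receptor, frozenset())
        if ligand in mapping:
            tf_union = tf_union | mapping[ligand]
        if tf_union:
            mapping[ligand] = frozenset(tf_union)
        elif ligand not in unmapped:
            unmapped.append(ligand)
    return ITCtoTFMap(mapping=mapping, unmapped=sorted(set(unmapped) - set(mapping)))


def itc_signature(
    sig: SignatureMatrix,
    tf_set: frozenset[str] | set[str],
    cell_line: str,
    ptype: str,
) -> pd.Series:
    """Elementwise sum of the TF-perturbagen signatures in one cell line.

    TFs without a signature in that cell line and ptype are skipped with a
    log count; no usable TF at all is an error (the caller treats the ITC
    as unusable for that cell line).
    """
    meta = sig.meta
    cols = meta.index[
        (meta["cell_line"] == cell_line)
        & (meta["ptype"] == ptype)
        & meta["perturbagen"].isin(tf_set)
    ]
    if len(cols) == 0:
        raise ValueError(
            f"no signatures for TFs {sorted(tf_set)} in {cell_line}/{ptype}"
        )
    n_skipped = len(set(tf_set)) - meta.loc[cols, "perturbagen"].nunique()
    if n_skipped:
        logger.debug("itc_signature: %d TFs without signatures in %s/%s",
                     n_skipped, cell_line, ptype)
    return sig.values[list(cols)].sum(axis=1)


def _pairwise_cell_line_corr(
    sig: SignatureMatrix, disease_genes: GeneSet
) -> tuple[list[str], np.ndarray]:
    lines = sig.cell_lines
    genes = [g for g in disease_genes.members if g in set(sig.genes)]
    if not genes:
        raise ValueError("no disease genes present in the signature matrix")
    corr = np.eye(len(lines))
    meta = sig.meta
    # signature id per (perturbagen, ptype) key, per cell line; post-filter
    # each key appears at most once per line
    per_line: dict[str, dict[tuple[str, str], str]] = {}
    for cl in lines:
        sub = meta[meta["cell_line"] == cl]
        per_line[cl] = {
            (row.perturbagen, row.ptype): sig_id
            for sig_id, row in sub.iterrows()
        }
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            a, b = per_line[lines[i]], per_line[lines[j]]
            matched = sorted(set(a) & set(b))
            if not matched:
                continue
            xa = sig.values.loc[genes, [a[m] for m in matched]].to_numpy().ravel()
            xb = sig.values.loc[genes, [b[m] for m in matched]].to_numpy().ravel()
            if xa.size < 2 or xa.std() == 0 or xb.std() == 0:
                continue
            corr[i, j] = corr[j, i] = float(np.corrcoef(xa, xb)[0, 1])
    return lines, corr


def select_cell_lines(
    sig: SignatureMatrix,
    disease_genes: GeneSet,
    min_cluster: int = 3,
    min_avg_corr: float = 0.4,
) -> list[str]:
    """Largest cluster of cell lines correlated at the disease genes.

    Pearson correlations between cell lines are computed on disease-gene
    rows of matched (perturbagen, ptype) columns; cell lines are clustered
    by average linkage on 1 - correlation and the dendrogram is cut at
    distance 1 - ``min_avg_corr``.  Among the resulting clusters of at
    least ``min_cluster`` lines whose mean pairwise correlation exceeds
    ``min_avg_corr``, the largest (ties: highest mean correlation) is
    returned.  An empty list means the disease is discarded for this
    analysis.
    """
    lines, corr = _pairwise_cell_line_corr(sig, disease_genes)
    if len(lines) < min_cluster:
        return []
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - min_avg_corr, criterion="distance")

    best: tuple[int, float, list[str]] | None = None
    for lab in np.unique(labels):
        members = [k for k in range(len(lines)) if labels[k] == lab]
        if len(members) < min_cluster:
            continue
        sub = corr[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        mean_corr = float(sub[iu].mean())
        if mean_corr > min_avg_corr:
            cand = (len(members), mean_corr, sorted(lines[k] for k in members))
            if best is None or cand[:2] > best[:2]:
                best = cand
    return best[2] if best else []


def disease_perturbation_score(
    sig: SignatureMatrix,
    itc_set: list[str],
    tf_map: ITCtoTFMap,
    cell_lines: list[str],
    disease_genes: GeneSet,
    ptype: str,
) -> float:
    """Mean aggregated perturbation of an ITC set at the disease genes.

    Per ITC: its TF-sum signature is computed in each selected cell line,
    the absolute values are averaged elementwise across cell lines, and the
    result is restricted to disease genes.  The per-gene contributions are
    summed across ITCs into a disease profile whose mean over disease genes
    is returned.  Positively homogeneous of degree 1 in the signature
    values.
    """
    genes = [g for g in disease_genes.members if g in set(sig.genes)]
    if not genes:
        raise ValueError("no disease genes present in the signature matrix")
    profile = pd.Series(0.0, index=genes)
    n_usable = 0
    for itc in itc_set:
        if itc not in tf_map:
            continue
        per_line = []
        for cl in cell_lines:
            try:
                per_line.append(itc_signature(sig, tf_map[itc], cl, ptype))
            except ValueError:
                logger.debug("ITC %r unusable in cell line %r", itc, cl)
        if not per_line:
            continue
        avg_abs = pd.concat(per_line, axis=1).abs().mean(axis=1)
        profile = profile + avg_abs.reindex(genes).fillna(0.0)
        n_usable += 1
    if n_usable == 0:
        raise ValueError("no usable ITC in the set (no mapped TFs with signatures)")
    return float(profile.mean())


def _itc_contributions(
    sig: SignatureMatrix,
    itcs: list[str],
    tf_map: ITCtoTFMap,
    cell_lines: list[str],
    disease_genes: GeneSet,
    ptype: str,
) -> dict[str, float]:
    """Per-ITC mean disease-gene perturbation contribution.

    :func:`disease_perturbation_score` is additive over the ITC set, so a
    set's score is the sum of these per-ITC scalars; precomputing them
    makes the 100-random-set comparison cheap without changing the value.
    """
    genes = [g for g in disease_genes.members if g in set(sig.genes)]
    out: dict[str, float] = {}
    for itc in itcs:
        if itc not in tf_map:
            continue
        per_line = []
        for cl in cell_lines:
            try:
                per_line.append(itc_signature(sig, tf_map[itc], cl, ptype))
            except ValueError:
                continue
        if not per_line:
            continue
        avg_abs = pd.concat(per_line, axis=1).abs().mean(axis=1)
        out[itc] = float(avg_abs.reindex(genes).fillna(0.0).mean())
    return out


def fold_vs_random(
    sig: SignatureMatrix,
    disease_itcs: list[str],
    itc_pool: list[str],
    tf_map: ITCtoTFMap,
    cell_lines: list[str],
    disease_genes: GeneSet,
    ptype: str,
    disease_id: str = "",
    n_sets: int = 100,
    rng_seed: int = 0,
    alternative: str = "two-sided",
) -> PerturbationResult:
    """Fold increase of the disease-ITC perturbation over random ITC sets.

    ``n_sets`` size-matched random sets are drawn (seeded, without
    replacement within a set) from the pool excluding the disease-specific
    ITCs; fold values disease_score / random_score are tested against 1 by
    a one-sample t-test.  A random set scoring exactly zero is redrawn up
    to 10 times, then excluded with a log entry.
    """
    pool = sorted(set(itc_pool) - set(disease_itcs))
    size = len(disease_itcs)
    if len(pool) < size:
        raise ValueError("ITC pool too small for size-matched random sets")
    disease_score = disease_perturbation_score(
        sig, disease_itcs, tf_map, cell_lines, disease_genes, ptype
    )
    contributions = _itc_contributions(sig, pool, tf_map, cell_lines,
                                       disease_genes, ptype)
    rng = np.random.default_rng(rng_seed)
    random_scores: list[float] = []
    n_excluded = 0
    for _ in range(n_sets):
        score = 0.0
        for _attempt in range(10):
            picks = rng.choice(len(pool), size=size, replace=False)
            score = sum(contributions.get(pool[i], 0.0) for i in picks)
            if score > 0:
                break
        if score > 0:
            random_scores.append(score)
        else:
            n_excluded += 1
            logger.info("fold_vs_random: a random set scored 0 after retries; excluded")
    if not random_scores:
        raise ValueError("every random ITC set scored zero")
    folds = [disease_score / s for s in random_scores]
    if np.ptp(folds) == 0:
        t_stat = 0.0 if folds[0] == 1.0 else float("inf")
        p_value = 1.0 if folds[0] == 1.0 else 0.0
    else:
        t_stat, p_value = stats.ttest_1samp(folds, 1.0, alternative=alternative)
    return PerturbationResult(
        disease_id=disease_id,
        ptype=ptype,
        disease_score=disease_score,
        random_scores=random_scores,
        fold_values=folds,
        mean_fold=float(np.mean(folds)),
        t_stat=float(t_stat),
        p_value=float(p_value),
        cell_lines_used=list(cell_lines),
        n_sets_excluded=n_excluded,
    )
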