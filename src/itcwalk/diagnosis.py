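"""Diagnostic-prediction validation on a plasma-proteome matrix.

Disease-specific communicators are tested as diagnostic features: a
donors x proteins measurement table is cleaned by missingness filtering
and median imputation, features are assembled under three conditions
(disease-specific ITCs, size-matched random plasma proteins, raw disease
genes), and a gradient-boosted tree classifier is evaluated by repeated
stratified cross-validation with AUROC and AUPRC reported against the
hold-out test set.  The AUPRC baseline is the test-set case prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

FEATURE_CONDITIONS = ("specific_itcs", "random_proteins", "raw_disease_genes")


@dataclass
class ProteomeTable:
    """Donors x proteins measurements; NaN marks a missing value."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("donor and protein ids must be unique")

    @property
    def donors(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "ProteomeTable":
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.values.to_csv(path, sep=sep)


@dataclass
class DiseaseLabelSet:
    """Disease id -> set of case donor ids."""

    cases: dict[str, set[str]]

    def admitted(self, donors: list[str], min_cases: int = 100) -> dict[str, set[str]]:
        """Diseases whose case count among ``donors`` meets ``min_cases``."""
        pool = set(donors)
        out = {}
        for disease, ids in self.cases.items():
            present = ids & pool
            if len(present) >= min_cases:
                out[disease] = present
            else:
                logger.info("disease %r dropped (%d cases < %d)", disease,
                            len(present), min_cases)
        return out

    def label_vector(self, disease: str, donors: list[str]) -> np.ndarray:
        ids = self.cases[disease]
        return np.array([d in ids for d in donors], dtype=int)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseLabelSet":
        df = pd.read_csv(path, sep="\t")
        need = {"disease_id", "donor_id"}
        if not need <= set(df.columns):
            raise ValueError(f"label table needs columns {sorted(need)}")
        cases: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            cases.setdefault(str(row.disease_id), set()).add(str(row.donor_id))
        return cls(cases)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("disease_id\tdonor_id\n")
            for disease in sorted(self.cases):
                for donor in sorted(self.cases[disease]):
                    fh.write(f"{disease}\t{donor}\n")


@dataclass
class DiagnosisResult:
    """Metric distributions over CV models, scored on the hold-out test set."""

    aurocs: list[float]
    auprcs: list[float]
    auprc_baseline: float
    n_features_used: int
    condition: str = ""
    disease_id: str = ""
    baseline_only: bool = False

    @property
    def median_auroc(self) -> float:
        return float(np.median(self.aurocs)) if self.aurocs else float("nan")

    @property
    def median_auprc(self) -> float:
        return float(np.median(self.auprcs)) if self.auprcs else self.auprc_baseline


def filter_missing(
    table: ProteomeTable,
    max_missing_per_donor: int = 150,
    max_missing_per_protein: int = 740,
) -> ProteomeTable:
    """Missingness filtering and median imputation, in a fixed order.

    Donors missing more than ``max_missing_per_donor`` proteins are dropped
    first; then proteins missing in more than ``max_missing_per_protein``
    of the remaining donors are dropped; remaining gaps are filled with the
    per-protein median over the surviving donors.  The order matters and is
    part of the contract.
    """
    if max_missing_per_donor < 0 or max_missing_per_protein < 0:
        raise ValueError("missingness thresholds must be >= 0")
    df = table.values
    donor_missing = df.isna().sum(axis=1)
    kept_donors = donor_missing <= max_missing_per_donor
    if not kept_donors.any():
        raise ValueError("filter_missing dropped every donor")
    df = df.loc[kept_donors]
    protein_missing = df.isna().sum(axis=0)
    kept_proteins = protein_missing <= max_missing_per_protein
    if not kept_proteins.any():
        raise ValueError("filter_missing dropped every protein")
    df = df.loc[:, kept_proteins]
    logger.info("filter_missing: %d/%d donors, %d/%d proteins survive",
                df.shape[0], table.values.shape[0],
                df.shape[1], table.values.shape[1])
    return ProteomeTable(df.fillna(df.median(axis=0)))


def assemble_features(
    table: ProteomeTable,
    feature_ids: list[str],
    condition: str,
    rng_seed: int = 0,
    n_random: int | None = None,
    exclude_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, list[str], bool]:
    """Feature matrix for one condition; returns (X, used ids, baseline_only).

    Requested ids are intersected with the measured proteins.  The
    ``random_proteins`` condition samples ``n_random`` proteins uniformly,
    excluding ``exclude_ids`` (the disease's specific ITCs).  A condition
    with zero measured features is flagged baseline-only: its score is
    reported at the prevalence baseline rather than from a model.
    """
    if condition not in FEATURE_CONDITIONS:
        raise ValueError(f"unknown feature condition {condition!r}")
    measured = set(table.proteins)
    if condition == "random_proteins":
        if n_random is None:
            raise ValueError("random_proteins needs n_random (the ITC count to match)")
        pool = sorted(measured - (exclude_ids or set()))
        if n_random > len(pool):
            raise ValueError("not enough measured proteins to sample from")
        rng = np.random.default_rng(rng_seed)
        used = sorted(rng.choice(pool, size=n_random, replace=False).tolist())
    else:
        used = [f for f in feature_ids if f in measured]
    if not used:
        logger.info("assemble_features: condition %r has no measured features; "
                    "baseline-only", condition)
        return pd.DataFrame(index=table.values.index), [], True
    return table.values[used], used, False


def run_diagnosis(
    features: pd.DataFrame,
    labels: np.ndarray,
    split_ratio: float = 0.7,
    folds: int = 10,
    repeats: int = 5,
    rng_seed: int = 0,
) -> DiagnosisResult:
    """Repeated stratified CV of a gradient-boosted tree classifier.

    Donors are split 7:3 into train/test by stratified sampling; each of
    the folds x repeats CV models is trained on its fold-train portion with
    positive-class weight n_negative/n_positive and scored by AUROC and
    AUPRC on the fixed hold-out test set.  Folds whose training portion
    contains a single class are skipped with a warning.
    """
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("run_diagnosis needs both classes present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_ratio, stratify=y, random_state=rng_seed % (2**31)
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("both classes required on each side of the split")
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=(rng_seed + 1) % (2**31))
    aurocs: list[float] = []
    auprcs: list[float] = []
    for k, (fold_idx, _) in enumerate(cv.split(X_tr, y_tr)):
        y_fold = y_tr[fold_idx]
        n_pos = int(y_fold.sum())
        n_neg = len(y_fold) - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"CV fold {k} has a single class; skipped")
            continue
        model = XGBClassifier(
            scale_pos_weight=n_neg / n_pos,
            random_state=(rng_seed + 2 + k) % (2**31),
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
        model.fit(X_tr[fold_idx], y_fold)
        prob = model.predict_proba(X_te)[:, 1]
        aurocs.append(float(roc_auc_score(y_te, prob)))
        auprcs.append(float(average_precision_score(y_te, prob)))
    return DiagnosisResult(
        aurocs=aurocs,
        auprcs=auprcs,
        auprc_baseline=float(y_te.mean()),
        n_features_used=features.shape[1],
    )


def baseline_only_result(labels: np.ndarray, split_ratio: float = 0.7,
                         rng_seed: int = 0) -> DiagnosisResult:
    """Prevalence-level result for a condition with no measured features."""
    y = np.asarray(labels, dtype=int)
    _, y_te = train_test_split(y, train_size=split_ratio, stratify=y,
                               random_state=rng_seed % (2**31))
    prevalence = float(np.asarray(y_te).mean())
    return DiagnosisResult(aurocs=[0.5], auprcs=[prevalence],
                           auprc_baseline=prevalence, n_features_used=0,
                           baseline_only=True)


def compare_conditions(
    results: dict[str, dict[str, DiagnosisResult]],
    metric: str = "auroc",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Paired comparison of feature conditions across diseases.

    Uses per-disease median metrics (AUPRC reported as delta over its
    baseline) and a paired one-sided Wilcoxon signed-rank test per
    condition pair.  With fewer than five complete diseases only the
    deltas are reported (p-value NaN).
    """
    if metric not in ("auroc", "auprc"):
        raise ValueError("metric must be 'auroc' or 'auprc'")

    def value(res: DiagnosisResult) -> float:
        if metric == "auroc":
            return res.median_auroc
        return res.median_auprc - res.auprc_baseline

    complete = {
        d: conds for d, conds in results.items()
        if set(FEATURE_CONDITIONS) <= set(conds)
    }
    rows = []
    for a, b in [("specific_itcs", "random_proteins"),
                 ("specific_itcs", "raw_disease_genes"),
                 ("random_proteins", "raw_disease_genes")]:
        xs = np.array([value(complete[d][a]) for d in sorted(complete)])
        ys = np.array([value(complete[d][b]) for d in sorted(complete)])
        deltas = xs - ys
        if len(deltas) >= 5 and np.any(deltas != 0):
            stat, p = stats.wilcoxon(xs, ys, alternative=alternative)
        else:
            stat, p = float("nan"), float("nan")
        rows.append({
            "condition_a": a,
            "condition_b": b,
            "metric": metric,
            "n_diseases": len(deltas),
            "mean_delta": float(deltas.mean()) if len(deltas) else float("nan"),
            "statistic": float(stat),
            "p_value": float(p),
        })
    return pd.DataFrame(rows)
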