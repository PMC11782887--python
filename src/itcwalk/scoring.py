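"""Disease-specific communicator scoring.

For each inter-tissue communicator (ITC; a ligand or receptor catalog
entry) a walk is seeded and its probabilities at a disease's genes are
summed after censoring values below the calibrated significance threshold.
The sum is normalized by the mean obtained from an equal number of random
seed genes, which corrects for hub-like disease genes that attract walk
mass from anywhere.  Normalized scores are compared across diseases with a
modified Z-score; scores above the cutoff (default 5) mark an ITC as
specific to that disease.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import GeneSet
from .network import TransitionMatrix
from .rwr import RWRConfig, RWRProfile, rwr

logger = logging.getLogger(__name__)

ITC_ROLES = ("ligand", "receptor", "both")


@dataclass
class ITCCatalog:
    """Ligand/receptor catalog: (node id, role) entries with unique ids."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("ITC catalog ids must be unique")
        for _, role in self.entries:
            if role not in ITC_ROLES:
                raise ValueError(f"unknown ITC role {role!r}")

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ITCCatalog":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if not reader.fieldnames or "id" not in reader.fieldnames:
                raise ValueError(f"ITC catalog {path} needs an 'id' column")
            for row in reader:
                entries.append((row["id"].strip(), (row.get("role") or "both").strip()))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\trole\n")
            for node_id, role in self.entries:
                fh.write(f"{node_id}\t{role}\n")


@dataclass
class InfluenceScore:
    """One ITC's influence on one disease's genes."""

    itc_id: str
    disease_id: str
    raw_sum: float
    normalized: float
    n_dg_hit: int


@dataclass
class ScoreMatrix:
    """Normalized influence scores, ITCs as rows and diseases as columns."""

    scores: pd.DataFrame
    threshold: float
    rng_seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def itcs(self) -> list[str]:
        return list(self.scores.index)

    @property
    def diseases(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.sort_index(axis=0).sort_index(axis=1)
        out.to_csv(path, sep="\t", index_label="itc", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = float("nan"),
                 rng_seed: int = -1) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col="itc")
        return cls(df, threshold, rng_seed)


@dataclass
class SpecificITCResult:
    """Disease -> [(itc, modZ)] lists, sorted by descending modZ."""

    per_disease: dict[str, list[tuple[str, float]]]
    modz_cutoff: float = 5.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("disease\titc\tmodz\n")
            for disease in sorted(self.per_disease):
                for itc, z in self.per_disease[disease]:
                    fh.write(f"{disease}\t{itc}\t{z:.12g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, modz_cutoff: float = 5.0) -> "SpecificITCResult":
        per: dict[str, list[tuple[str, float]]] = {}
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            per.setdefault(row.disease, []).append((row.itc, float(row.modz)))
        return cls(per, modz_cutoff)


def thresholded_influence(
    profile: RWRProfile,
    disease_genes: GeneSet,
    threshold: float,
    disease_id: str = "",
) -> InfluenceScore:
    """Sum the profile at disease genes, censoring values <= threshold.

    Walk values not exceeding the significance threshold are replaced with
    zero (no influence).  ``normalized`` is left as NaN here; it is filled
    by :func:`score_all` after the random-gene baseline is known.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    index = {n: i for i, n in enumerate(profile.node_ids)}
    mapped = [index[g] for g in disease_genes.members if g in index]
    if not mapped:
        logger.warning("thresholded_influence: no disease genes of %r in network",
                       disease_genes.name)
        return InfluenceScore(profile.seed_id, disease_id, 0.0, float("nan"), 0)
    values = profile.p[mapped]
    hits = values > threshold
    return InfluenceScore(
        itc_id=profile.seed_id,
        disease_id=disease_id,
        raw_sum=float(values[hits].sum()),
        normalized=float("nan"),
        n_dg_hit=int(hits.sum()),
    )


def _random_raw_sums(
    W: TransitionMatrix,
    disease_genes: GeneSet,
    n_random: int,
    threshold: float,
    rng: np.random.Generator,
    config: RWRConfig,
    exclude: set[str] | None = None,
) -> np.ndarray:
    pool = [n for n in W.node_ids if not exclude or n not in exclude]
    if n_random > len(pool):
        raise ValueError(f"n_random={n_random} exceeds available nodes ({len(pool)})")
    picks = rng.choice(len(pool), size=n_random, replace=False)
    sums = np.empty(n_random)
    for k, i in enumerate(picks):
        profile = rwr(W, pool[i], config)
        sums[k] = thresholded_influence(profile, disease_genes, threshold).raw_sum
    return sums


def random_gene_baseline(
    W: TransitionMatrix,
    disease_genes: GeneSet,
    n_random: int,
    threshold: float,
    rng_seed: int = 0,
    config: RWRConfig = RWRConfig(),
    exclude: set[str] | None = None,
) -> float:
    """Mean censored influence sum over uniformly drawn random seed genes."""
    rng = np.random.default_rng(rng_seed)
    return float(
        _random_raw_sums(W, disease_genes, n_random, threshold, rng, config,
                         exclude).mean()
    )


def score_all(
    W: TransitionMatrix,
    itc_catalog: ITCCatalog,
    disease_gene_sets: list[GeneSet],
    threshold: float,
    rng_seed: int = 0,
    config: RWRConfig = RWRConfig(),
    n_random: int | None = None,
    n_baseline_repeats: int = 1,
    exclude_itcs_from_baseline: bool = False,
    min_disease_genes: int = 10,
) -> ScoreMatrix:
    """Normalized ITC x disease influence matrix.

    Walk profiles are computed once per mapped ITC and reused across
    diseases.  Diseases with fewer than ``min_disease_genes`` genes in the
    network are excluded with a log entry.  The per-disease baseline is the
    mean censored sum from ``n_random`` random seeds (default: catalog
    size); a zero baseline falls back to the smallest positive random sum,
    and a disease with no positive random sums at all is dropped as
    unusable.
    """
    if not len(itc_catalog):
        raise ValueError("empty ITC catalog")
    mapped_itcs = [i for i in itc_catalog.ids if i in W.node_index]
    unmapped = sorted(set(itc_catalog.ids) - set(mapped_itcs))
    if unmapped:
        logger.info("score_all: %d unmapped ITCs (scored 0): %s",
                    len(unmapped), ", ".join(unmapped[:5]))
    if n_random is None:
        n_random = len(itc_catalog)
    exclude = set(itc_catalog.ids) if exclude_itcs_from_baseline else None

    diseases: list[GeneSet] = []
    for gs in disease_gene_sets:
        mapped = gs.intersect(W.node_index)
        if len(mapped) < min_disease_genes:
            logger.info("score_all: disease %r excluded (%d mapped genes < %d)",
                        gs.name, len(mapped), min_disease_genes)
            continue
        diseases.append(mapped)
    if not diseases:
        raise ValueError(
            f"no disease with >= {min_disease_genes} genes in the network"
        )

    profiles = {itc: rwr(W, itc, config) for itc in mapped_itcs}
    rng = np.random.default_rng(rng_seed)
    matrix = pd.DataFrame(0.0, index=itc_catalog.ids,
                          columns=[d.name for d in diseases])
    dropped: list[str] = []
    for disease in diseases:
        sums = np.concatenate([
            _random_raw_sums(W, disease, n_random, threshold, rng, config, exclude)
            for _ in range(n_baseline_repeats)
        ])
        baseline = float(sums.mean())
        if baseline == 0:
            positive = sums[sums > 0]
            if positive.size == 0:
                logger.warning("score_all: disease %r unusable (all-zero baseline)",
                               disease.name)
                dropped.append(disease.name)
                continue
            baseline = float(positive.min())
        for itc in mapped_itcs:
            raw = thresholded_influence(profiles[itc], disease, threshold,
                                        disease.name).raw_sum
            matrix.loc[itc, disease.name] = raw / baseline
    if dropped:
        matrix = matrix.drop(columns=dropped)
    if matrix.shape[1] == 0:
        raise ValueError("score_all: no usable disease columns")
    return ScoreMatrix(
        scores=matrix,
        threshold=threshold,
        rng_seed=rng_seed,
        provenance={
            "n_random": n_random,
            "n_baseline_repeats": n_baseline_repeats,
            "exclude_itcs_from_baseline": exclude_itcs_from_baseline,
            "min_disease_genes": min_disease_genes,
            "unmapped_itcs": unmapped,
            "restart_prob": config.restart_prob,
        },
    )


def modified_z(values: np.ndarray | list[float]) -> np.ndarray:
    """Robust outlier score: 0.6745 * (x - median) / MAD.

    When the median absolute deviation is zero (common for zero-heavy score
    rows) the scale falls back to 1.2533 * mean absolute deviation; if that
    is also zero every score is 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("modified_z needs a 1-d vector of >= 3 values")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        return 0.6745 * dev / mad
    mean_ad = np.abs(dev).mean()
    if mean_ad > 0:
        return 0.6745 * dev / (1.2533 * mean_ad)
    return np.zeros_like(x)


def select_specific(
    scores: ScoreMatrix, modz_cutoff: float = 5.0
) -> SpecificITCResult:
    """Mark (ITC, disease) pairs whose cross-disease modZ exceeds the cutoff.

    The modified Z-score is computed per ITC across all diseases, so an ITC
    is specific to a disease exactly when that disease is a high outlier in
    the ITC's own score distribution.
    """
    if scores.scores.shape[1] < 3:
        raise ValueError(
            f"select_specific needs >= 3 diseases, got {scores.scores.shape[1]}"
        )
    per_disease: dict[str, list[tuple[str, float]]] = {
        d: [] for d in scores.diseases
    }
    for itc, row in scores.scores.iterrows():
        z = modified_z(row.to_numpy())
        for disease, zi in zip(scores.diseases, z):
            if zi > modz_cutoff:
                per_disease[disease].append((itc, float(zi)))
    for disease in per_disease:
        per_disease[disease].sort(key=lambda t: (-t[1], t[0]))
    return SpecificITCResult(
        per_disease={d: lst for d, lst in per_disease.items() if lst},
        modz_cutoff=modz_cutoff,
    )
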