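"""Significance-threshold calibration for walk probabilities.

Raw RWR values reflect topology only, so a minimum value with biological
meaning is derived empirically: pairwise within-set walk probabilities are
collected for curated pathway gene sets and for size-matched sets of
uniformly random network nodes, and the threshold is the maximum of the
random-set medians.  Values below it are treated as no influence.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genesets import GeneSet
from .network import TransitionMatrix
from .rwr import RWRConfig, rwr

logger = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    """Per-pathway medians, random-set medians, and their max as threshold."""

    pathway_medians: dict[str, float]
    random_medians: list[float]
    threshold: float
    rng_seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "rng_seed": self.rng_seed,
            "pathway_medians": self.pathway_medians,
            "random_medians": self.random_medians,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        d = json.loads(Path(path).read_text())
        return cls(d["pathway_medians"], d["random_medians"], d["threshold"],
                   d["rng_seed"])

    def medians_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("set\tmedian\tgroup\n")
            for name in sorted(self.pathway_medians):
                fh.write(f"{name}\t{self.pathway_medians[name]:.12g}\tpathway\n")
            for i, m in enumerate(self.random_medians):
                fh.write(f"random_{i}\t{m:.12g}\trandom\n")


def within_set_rwr_values(
    W: TransitionMatrix,
    gene_set: GeneSet,
    config: RWRConfig = RWRConfig(),
) -> list[float]:
    """Walk probabilities for every ordered in-set pair (seed s, target t).

    Members absent from the network are excluded; fewer than two mapped
    members is an error (callers that batch over sets skip and log it).
    """
    mapped = [m for m in gene_set.members if m in W.node_index]
    if len(mapped) < 2:
        raise ValueError(
            f"gene set {gene_set.name!r} has {len(mapped)} mapped members; need >= 2"
        )
    values: list[float] = []
    for s in mapped:
        profile = rwr(W, s, config)
        for t in mapped:
            if t != s:
                values.append(float(profile.p[W.node_index[t]]))
    return values


def _draw_random_set(
    node_ids: list[str], size: int, rng_seed: int, set_name: str, draw: int
) -> GeneSet:
    # per-set, per-draw RNG stream keyed by the set name so the calibration
    # threshold does not depend on the order pathway sets are supplied
    stream = np.random.default_rng([rng_seed, zlib.crc32(set_name.encode()), draw])
    members = stream.choice(len(node_ids), size=size, replace=False)
    return GeneSet(f"random::{set_name}::{draw}",
                   tuple(node_ids[i] for i in members))


def calibrate_threshold(
    W: TransitionMatrix,
    pathway_sets: list[GeneSet],
    n_random_draws: int = 1,
    rng_seed: int = 0,
    config: RWRConfig = RWRConfig(),
) -> CalibrationResult:
    """Compare within-pathway walk values to random gene sets.

    For each usable pathway set the median over all ordered pair values is
    recorded; for each pathway set and each of ``n_random_draws`` draws, a
    size-matched set of uniformly random network nodes yields a random
    median.  The threshold is the exact maximum of the random medians.
    """
    if n_random_draws < 1:
        raise ValueError("n_random_draws must be >= 1")
    node_ids = list(W.node_ids)
    usable: list[tuple[GeneSet, int]] = []
    for gs in pathway_sets:
        mapped = sum(1 for m in gs.members if m in W.node_index)
        if mapped < 2:
            logger.info("calibrate_threshold: skipping %r (%d mapped members)",
                        gs.name, mapped)
            continue
        if mapped > W.n_nodes:
            raise ValueError(f"set {gs.name!r} larger than the network")
        usable.append((gs, mapped))
    if not usable:
        raise ValueError("no usable pathway sets (need >= 2 mapped members each)")

    pathway_medians: dict[str, float] = {}
    for gs, _ in usable:
        pathway_medians[gs.name] = float(
            np.median(within_set_rwr_values(W, gs, config))
        )

    random_medians: list[float] = []
    for gs, size in sorted(usable, key=lambda u: u[0].name):
        for draw in range(n_random_draws):
            rand_set = _draw_random_set(node_ids, size, rng_seed, gs.name, draw)
            random_medians.append(
                float(np.median(within_set_rwr_values(W, rand_set, config)))
            )
    return CalibrationResult(
        pathway_medians=pathway_medians,
        random_medians=random_medians,
        threshold=float(max(random_medians)),
        rng_seed=rng_seed,
    )
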