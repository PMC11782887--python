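"""High-level in-memory pipelines over the synthetic study conditions.

These helpers chain the stages the way the file-based CLI does, but on
in-memory objects, and are what the recovery and separation experiments
(and the acceptance checks) run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationResult, calibrate_threshold
from .fixtures import make_network_fixture, network_fixture_genesets
from .network import column_normalize
from .rwr import RWRConfig
from .scoring import ScoreMatrix, score_all


@dataclass
class RecoveryRun:
    """One seeded planted-communicator recovery experiment."""

    calibration: CalibrationResult
    scores: ScoreMatrix
    planted: list[str]
    top5: list[str]
    precision: float


def recovery_run(
    rng_seed: int,
    wiring_strength: int = 10,
    config: RWRConfig = RWRConfig(),
    **fixture_kwargs,
) -> RecoveryRun:
    """Fixture -> calibrate -> score; report top-|planted| precision.

    The significance threshold is calibrated on the fixture's own planted
    modules versus size-matched random node sets, then each catalog entry
    (planted communicators plus decoys) is scored against the planted
    disease-gene set; precision is the fraction of planted communicators
    among the top-k normalized scores (k = number planted).
    """
    network, catalog, manifest = make_network_fixture(
        wiring_strength=wiring_strength, rng_seed=rng_seed, **fixture_kwargs
    )
    W = column_normalize(network)
    pathways, disease = network_fixture_genesets(manifest)
    calibration = calibrate_threshold(W, pathways, rng_seed=rng_seed, config=config)
    scores = score_all(
        W, catalog, [disease], calibration.threshold,
        rng_seed=rng_seed, config=config,
    )
    planted = manifest.ground_truth["planted_itcs"]
    col = scores.scores[disease.name]
    top = col.sort_values(ascending=False, kind="stable").index[:len(planted)]
    precision = len(set(top) & set(planted)) / len(planted)
    return RecoveryRun(calibration, scores, planted, list(top), precision)


def calibration_separation(
    rng_seed: int, config: RWRConfig = RWRConfig(), **fixture_kwargs
) -> tuple[float, float]:
    """(median of planted-module medians, random-set threshold) for one seed."""
    network, _, manifest = make_network_fixture(rng_seed=rng_seed, **fixture_kwargs)
    W = column_normalize(network)
    pathways, _ = network_fixture_genesets(manifest)
    result = calibrate_threshold(W, pathways, rng_seed=rng_seed, config=config)
    return float(np.median(list(result.pathway_medians.values()))), result.threshold
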