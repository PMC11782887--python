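import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import itcwalk as k
from itcwalk.genesets import GeneSet
from itcwalk.rwr import RWRConfig
from itcwalk.scoring import ITCCatalog, ScoreMatrix

from conftest import make_transition


def modified_z_oracle(x):
    """Direct evaluation of the robust outlier score, written independently."""
    x = np.asarray(x, dtype=float)
    med = float(np.median(x))
    abs_dev = [abs(v - med) for v in x]
    mad = float(np.median(abs_dev))
    if mad > 0:
        return np.array([0.6745 * (v - med) / mad for v in x])
    mean_ad = sum(abs_dev) / len(x)
    if mean_ad > 0:
        return np.array([0.6745 * (v - med) / (1.2533 * mean_ad) for v in x])
    return np.zeros(len(x))


class TestThresholdedInfluence:
    def make_profile(self, values, nodes):
        from itcwalk.rwr import RWRProfile
        return RWRProfile("seed", np.asarray(values, float), 1, True,
                          RWRConfig(), list(nodes))

    def test_full_censoring(self):
        p = self.make_profile([0.01, 0.02, 0.03], "ABC")
        score = k.thresholded_influence(p, GeneSet("d", ("A", "B", "C")), 0.5)
        assert score.raw_sum == 0 and score.n_dg_hit == 0

    def test_zero_threshold_plain_sum(self):
        p = self.make_profile([0.1, 0.2, 0.3], "ABC")
        score = k.thresholded_influence(p, GeneSet("d", ("A", "C")), 0.0)
        assert score.raw_sum == pytest.approx(0.4)

    def test_hand_example(self):
        theta = 0.05
        p = self.make_profile([2 * theta, theta / 2, 3 * theta], "ABC")
        score = k.thresholded_influence(p, GeneSet("d", ("A", "B", "C")), theta)
        assert score.raw_sum == pytest.approx(5 * theta)
        assert score.n_dg_hit == 2

    def test_empty_intersection_warns_zero(self, caplog):
        p = self.make_profile([0.5, 0.5], "AB")
        score = k.thresholded_influence(p, GeneSet("d", ("X",)), 0.0)
        assert score.raw_sum == 0 and score.n_dg_hit == 0


class TestRandomBaseline:
    def test_deterministic(self, path3):
        dg = GeneSet("d", ("A", "B"))
        b1 = k.random_gene_baseline(path3, dg, 2, 0.0, rng_seed=5)
        b2 = k.random_gene_baseline(path3, dg, 2, 0.0, rng_seed=5)
        assert b1 == b2

    def test_too_many_random_fails(self, path3):
        with pytest.raises(ValueError):
            k.random_gene_baseline(path3, GeneSet("d", ("A",)), 99, 0.0)

    def test_hub_attached_dgs_have_higher_baseline(self):
        # hub H with many leaves plus a long tail: the hub-adjacent disease
        # set soaks up more walk mass from random seeds than the tail end
        pairs = [("H", f"L{i}") for i in range(12)]
        tail = ["H"] + [f"T{i}" for i in range(8)]
        pairs += list(zip(tail, tail[1:]))
        tm = make_transition(pairs)
        hub_dg = GeneSet("hub", ("H", "L0", "L1"))
        tail_dg = GeneSet("tail", ("T5", "T6", "T7"))
        n = tm.n_nodes
        hub_b = k.random_gene_baseline(tm, hub_dg, n, 0.0, rng_seed=0)
        tail_b = k.random_gene_baseline(tm, tail_dg, n, 0.0, rng_seed=0)
        assert hub_b > tail_b


class TestScoreAll:
    def test_disconnected_itc_scores_zero(self):
        pairs = [("A", "B"), ("B", "C"), ("X", "Y"), ("Y", "Z")]
        tm = make_transition(pairs)
        catalog = ITCCatalog([("X", "ligand"), ("A", "receptor")])
        dg = GeneSet("d", ("B", "C"))
        scores = k.score_all(tm, catalog, [dg], threshold=0.0, rng_seed=0,
                             n_random=tm.n_nodes, min_disease_genes=2)
        assert scores.scores.loc["X", "d"] == 0
        assert scores.scores.loc["A", "d"] > 0

    def test_normalization_preserves_ranking(self):
        net, catalog, manifest = k.make_network_fixture(
            n_nodes=120, n_modules=2, module_size=12, n_itcs=3, n_decoys=6,
            rng_seed=2)
        W = k.column_normalize(net)
        dg = GeneSet("d", tuple(manifest.ground_truth["disease_genes"]))
        scores = k.score_all(W, catalog, [dg], threshold=0.0, rng_seed=4)
        raw = {}
        for itc in catalog.ids:
            profile = k.rwr(W, itc)
            raw[itc] = k.thresholded_influence(profile, dg, 0.0).raw_sum
        ranked_raw = sorted(raw, key=lambda i: -raw[i])
        ranked_norm = scores.scores["d"].sort_values(ascending=False).index.tolist()
        assert ranked_raw == ranked_norm

    def test_empty_catalog_fails(self, path3):
        with pytest.raises(ValueError, match="catalog"):
            k.score_all(path3, ITCCatalog([]), [GeneSet("d", ("A", "B"))], 0.0,
                        min_disease_genes=2)

    def test_disease_below_gene_floor_excluded(self, path3):
        catalog = ITCCatalog([("A", "ligand")])
        with pytest.raises(ValueError, match="no disease"):
            k.score_all(path3, catalog, [GeneSet("d", ("B",))], 0.0,
                        min_disease_genes=2)


class TestModifiedZ:
    def test_constant_vector_zero(self):
        assert np.array_equal(k.modified_z([3.0] * 7), np.zeros(7))

    def test_mad_zero_fallback_example(self):
        x = [1, 1, 1, 1, 1, 1, 1, 1, 1, 10]
        z = k.modified_z(x)
        expected = 0.6745 * 9 / (1.2533 * 0.9)
        assert z[-1] == pytest.approx(expected)
        assert z[-1] > 5

    def test_antisymmetry(self):
        z = k.modified_z([-2.0, 0.0, 2.0])
        assert z[0] == -z[2] and z[1] == 0

    def test_too_short_fails(self):
        with pytest.raises(ValueError):
            k.modified_z([1.0, 2.0])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=3,
                    max_size=40))
    def test_matches_independent_oracle(self, values):
        assert np.allclose(k.modified_z(values), modified_z_oracle(values),
                           atol=1e-12, rtol=1e-12)


class TestSelectSpecific:
    def make_scores(self, data, diseases):
        df = pd.DataFrame(data, columns=diseases)
        df.index = [f"itc{i}" for i in range(len(df))]
        return ScoreMatrix(df, threshold=0.0, rng_seed=0)

    def test_outlier_disease_only(self):
        row = [1.0] * 9 + [10.0]
        diseases = [f"d{i}" for i in range(10)]
        scores = self.make_scores([row], diseases)
        result = k.select_specific(scores, 5.0)
        assert list(result.per_disease) == ["d9"]
        z = modified_z_oracle(row)
        assert result.per_disease["d9"][0][1] == pytest.approx(z[-1])

    def test_zero_itc_nowhere(self):
        scores = self.make_scores([[0.0, 0.0, 0.0], [1, 1, 9]],
                                  ["a", "b", "c"])
        result = k.select_specific(scores, 5.0)
        assert all("itc0" not in [i for i, _ in lst]
                   for lst in result.per_disease.values())

    def test_infinite_cutoff_empty(self):
        scores = self.make_scores([[1, 1, 9]], ["a", "b", "c"])
        assert k.select_specific(scores, float("inf")).per_disease == {}

    def test_needs_three_diseases(self):
        scores = self.make_scores([[1, 2]], ["a", "b"])
        with pytest.raises(ValueError, match="3 diseases"):
            k.select_specific(scores)

    def test_lists_sorted_descending(self):
        base = list(range(9))
        rows = [base + [100], base + [50], base + [1]]
        scores = self.make_scores(rows, [f"d{i}" for i in range(10)])
        result = k.select_specific(scores, 5.0)
        zs = [z for _, z in result.per_disease["d9"]]
        assert len(zs) == 2
        assert zs == sorted(zs, reverse=True)


def test_select_then_invert_commutes():
    """Keeping pairs by modZ then grouping equals grouping then filtering."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.exponential(1.0, size=(12, 6)),
                      index=[f"itc{i}" for i in range(12)],
                      columns=[f"d{j}" for j in range(6)])
    df.iloc[0, 0] = 60.0
    df.iloc[3, 4] = 90.0
    scores = ScoreMatrix(df, 0.0, 0)
    result = k.select_specific(scores, 5.0)
    # independent route: flat pair list filtered, then grouped
    pairs = []
    for itc, row in df.iterrows():
        z = modified_z_oracle(row.to_numpy())
        pairs += [(d, itc, zi) for d, zi in zip(df.columns, z) if zi > 5.0]
    grouped = {}
    for d, itc, z in pairs:
        grouped.setdefault(d, set()).add(itc)
    assert {d: {i for i, _ in lst} for d, lst in result.per_disease.items()} \
        == grouped


def test_full_scoring_pipeline_reproducible():
    from itcwalk.pipeline import recovery_run
    a = recovery_run(13)
    b = recovery_run(13)
    pd.testing.assert_frame_equal(a.scores.scores, b.scores.scores)
    assert a.calibration.threshold == b.calibration.threshold
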