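import networkx as nx
import numpy as np
import pandas as pd
import pytest

import itcwalk as k
from itcwalk.fixtures import signature_fixture_genesets
from itcwalk.genesets import GeneSet
from itcwalk.perturbation import SignatureMatrix


def toy_signature(columns, genes=("g0", "g1", "g2"), meta_overrides=None):
    """SignatureMatrix from {sig_id: values}; metadata defaults to clean."""
    values = pd.DataFrame(columns, index=list(genes))
    meta = pd.DataFrame({
        "cell_line": ["CL1"] * len(columns),
        "perturbagen": [f"TF{i}" for i in range(len(columns))],
        "ptype": ["KD"] * len(columns),
        "time": ["96 h"] * len(columns),
        "exemplar": [True] * len(columns),
        "tas": [0.5] * len(columns),
    }, index=list(columns))
    if meta_overrides:
        for col, over in meta_overrides.items():
            for key, val in over.items():
                meta.loc[col, key] = val
    return SignatureMatrix(values, meta)


class TestFilterSignatures:
    def test_max_tas_among_duplicates(self):
        sig = toy_signature(
            {"a": [1, 1, 1], "b": [2, 2, 2]},
            meta_overrides={"a": {"perturbagen": "TFX", "tas": 0.2},
                            "b": {"perturbagen": "TFX", "tas": 0.7}},
        )
        out = k.filter_signatures(sig)
        assert list(out.values.columns) == ["b"]

    def test_identity_when_everything_passes(self):
        sig = toy_signature({"a": [1, 0, 0], "b": [0, 1, 0]})
        out = k.filter_signatures(sig, excluded_cell_lines=())
        assert list(out.values.columns) == ["a", "b"]

    def test_empty_result_reports_drop_counts(self):
        sig = toy_signature({"a": [1, 0, 0]},
                            meta_overrides={"a": {"exemplar": False}})
        with pytest.raises(ValueError, match="not_exemplar"):
            k.filter_signatures(sig)

    def test_generator_manifest_bookkeeping(self):
        sig, _, _, manifest = k.make_signature_fixture(rng_seed=8)
        out = k.filter_signatures(
            sig,
            excluded_cell_lines=(manifest.parameters["excluded_cell_line"],),
        )
        assert set(out.values.columns) == \
            set(manifest.ground_truth["surviving_signatures"])


class TestMapItcsToTfs:
    def test_chain_and_ligand_inheritance(self):
        g = nx.DiGraph([("R", "X"), ("X", "TF1")])
        tf_map = k.map_itcs_to_tfs(g, ["R"], [("L", "R")], ["TF1"])
        assert tf_map["R"] == {"TF1"}
        assert tf_map["L"] == {"TF1"}

    def test_absent_receptor_unmapped(self):
        g = nx.DiGraph([("R", "TF1")])
        tf_map = k.map_itcs_to_tfs(g, ["R", "GHOST"], [], ["TF1"])
        assert "GHOST" in tf_map.unmapped and "GHOST" not in tf_map

    def test_undirected_graph_rejected(self):
        with pytest.raises(ValueError):
            k.map_itcs_to_tfs(nx.Graph([("a", "b")]), ["a"], [], ["b"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        g = nx.gnp_random_graph(n, 0.05, seed=seed, directed=True)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
        nodes = list(g)
        receptors = nodes[:10]
        tfs = nodes[-15:]
        tf_map = k.map_itcs_to_tfs(g, receptors, [], tfs)

        def reachable(start):
            seen, stack = set(), [start]
            while stack:
                u = stack.pop()
                for v in g.successors(u):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            return seen

        for rec in receptors:
            expected = reachable(rec) & set(tfs)
            got = set(tf_map[rec]) if rec in tf_map else set()
            assert got == expected


class TestItcSignature:
    def test_single_tf_equals_column(self):
        sig = toy_signature({"a": [1, 2, 3], "b": [9, 9, 9]})
        out = k.itc_signature(sig, {"TF0"}, "CL1", "KD")
        assert list(out) == [1, 2, 3]

    def test_cancellation(self):
        sig = toy_signature({"a": [1, -2, 3], "b": [-1, 2, -3]})
        out = k.itc_signature(sig, {"TF0", "TF1"}, "CL1", "KD")
        assert np.allclose(out, 0)

    def test_three_tf_column_sum_oracle(self):
        rng = np.random.default_rng(0)
        cols = {f"s{i}": rng.normal(size=3) for i in range(3)}
        sig = toy_signature(cols)
        out = k.itc_signature(sig, {"TF0", "TF1", "TF2"}, "CL1", "KD")
        expected = sum(cols.values())
        assert np.allclose(out, expected)

    def test_no_signature_for_tf_set(self):
        sig = toy_signature({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            k.itc_signature(sig, {"TF9"}, "CL1", "KD")


class TestSelectCellLines:
    def test_identical_blocks_all_selected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 3))
        columns, meta_over = {}, {}
        for cl in ("CL1", "CL2", "CL3"):
            for t in range(3):
                cid = f"{cl}_{t}"
                columns[cid] = base[:, t]
                meta_over[cid] = {"cell_line": cl, "perturbagen": f"TF{t}"}
        sig = toy_signature(columns, genes=[f"g{i}" for i in range(4)],
                            meta_overrides=meta_over)
        out = k.select_cell_lines(sig, GeneSet("d", ("g0", "g1", "g2", "g3")))
        assert out == ["CL1", "CL2", "CL3"]

    def test_independent_noise_gives_empty(self):
        rng = np.random.default_rng(1)
        columns, meta_over = {}, {}
        for cl in ("CL1", "CL2", "CL3"):
            for t in range(6):
                cid = f"{cl}_{t}"
                columns[cid] = rng.normal(size=12)
                meta_over[cid] = {"cell_line": cl, "perturbagen": f"TF{t}"}
        sig = toy_signature(columns, genes=[f"g{i}" for i in range(12)],
                            meta_overrides=meta_over)
        out = k.select_cell_lines(sig, GeneSet("d", tuple(f"g{i}" for i in range(12))))
        assert out == []

    def test_too_few_cell_lines_empty(self):
        sig = toy_signature({"a": [1, 2, 3]})
        assert k.select_cell_lines(sig, GeneSet("d", ("g0", "g1"))) == []

    def test_planted_block_recovered_exactly(self):
        sig, _, _, manifest = k.make_signature_fixture(rng_seed=4)
        filt = k.filter_signatures(
            sig, excluded_cell_lines=(manifest.parameters["excluded_cell_line"],))
        out = k.select_cell_lines(filt, signature_fixture_genesets(manifest))
        assert out == manifest.parameters["corr_block"]


class FoldFixture:
    def __init__(self, seed=0, dg_inflation=3.0):
        sig, graph, lr_pairs, manifest = k.make_signature_fixture(
            rng_seed=seed, dg_inflation=dg_inflation)
        self.manifest = manifest
        self.sig = k.filter_signatures(
            sig, excluded_cell_lines=(manifest.parameters["excluded_cell_line"],))
        gt = manifest.ground_truth
        self.dg = signature_fixture_genesets(manifest)
        self.tf_map = k.map_itcs_to_tfs(graph, gt["receptors"],
                                        [tuple(p) for p in gt["lr_pairs"]],
                                        gt["tfs"])
        self.disease_itcs = gt["disease_receptors"] + gt["disease_ligands"]
        self.pool = gt["receptors"] + gt["ligands"]
        self.lines = k.select_cell_lines(self.sig, self.dg)


class TestDiseasePerturbationScore:
    def test_unit_field(self):
        sig = toy_signature({"a": [1.0, 1.0, 1.0]})
        tf_map = k.map_itcs_to_tfs(nx.DiGraph([("R", "TF0")]), ["R"], [],
                                   ["TF0"])
        score = k.disease_perturbation_score(
            sig, ["R"], tf_map, ["CL1"], GeneSet("d", ("g0", "g1", "g2")), "KD")
        assert score == pytest.approx(1.0)

    def test_homogeneity(self):
        fx = FoldFixture(seed=2)
        s1 = k.disease_perturbation_score(fx.sig, fx.disease_itcs, fx.tf_map,
                                          fx.lines, fx.dg, "KD")
        doubled = SignatureMatrix(fx.sig.values * 2, fx.sig.meta)
        s2 = k.disease_perturbation_score(doubled, fx.disease_itcs, fx.tf_map,
                                          fx.lines, fx.dg, "KD")
        assert s2 == pytest.approx(2 * s1)

    def test_brute_force_oracle(self):
        fx = FoldFixture(seed=3)
        got = k.disease_perturbation_score(fx.sig, fx.disease_itcs, fx.tf_map,
                                           fx.lines, fx.dg, "KD")
        # independent recomputation with plain numpy indexing
        meta = fx.sig.meta
        genes = [g for g in fx.dg.members if g in set(fx.sig.genes)]
        total = np.zeros(len(genes))
        for itc in fx.disease_itcs:
            per_line = []
            for cl in fx.lines:
                cols = [sid for sid in meta.index
                        if meta.loc[sid, "cell_line"] == cl
                        and meta.loc[sid, "ptype"] == "KD"
                        and meta.loc[sid, "perturbagen"] in fx.tf_map[itc]]
                if cols:
                    per_line.append(
                        fx.sig.values.loc[genes, cols].to_numpy().sum(axis=1))
            if per_line:
                total += np.abs(np.stack(per_line)).mean(axis=0)
        assert got == pytest.approx(total.mean())

    def test_no_usable_itc_fails(self):
        sig = toy_signature({"a": [1, 1, 1]})
        tf_map = k.map_itcs_to_tfs(nx.DiGraph([("R", "TF9")]), ["R"], [],
                                   ["TF9"])
        with pytest.raises(ValueError):
            k.disease_perturbation_score(sig, ["R"], tf_map, ["CL1"],
                                         GeneSet("d", ("g0",)), "KD")


class TestFoldVsRandom:
    def test_deterministic(self):
        fx = FoldFixture(seed=5)
        r1 = k.fold_vs_random(fx.sig, fx.disease_itcs, fx.pool, fx.tf_map,
                              fx.lines, fx.dg, "KD", rng_seed=5, n_sets=20)
        r2 = k.fold_vs_random(fx.sig, fx.disease_itcs, fx.pool, fx.tf_map,
                              fx.lines, fx.dg, "KD", rng_seed=5, n_sets=20)
        assert r1.fold_values == r2.fold_values
        assert r1.mean_fold == r2.mean_fold

    def test_null_identity_when_all_sets_equivalent(self):
        # every ITC maps to the same single TF, so every random set has
        # exactly the disease set's score: folds are all 1, t-stat 0
        sig = toy_signature({"a": [1.0, 2.0, 3.0]})
        g = nx.DiGraph([(f"R{i}", "TF0") for i in range(5)])
        tf_map = k.map_itcs_to_tfs(g, [f"R{i}" for i in range(5)], [], ["TF0"])
        res = k.fold_vs_random(sig, ["R0"], [f"R{i}" for i in range(5)],
                               tf_map, ["CL1"], GeneSet("d", ("g0", "g1")),
                               "KD", n_sets=10, rng_seed=0)
        assert res.fold_values == [1.0] * 10
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_planted_effect_detected(self):
        fx = FoldFixture(seed=6, dg_inflation=3.0)
        res = k.fold_vs_random(fx.sig, fx.disease_itcs, fx.pool, fx.tf_map,
                               fx.lines, fx.dg, "KD", rng_seed=6)
        assert res.mean_fold > 1.5
        assert res.p_value < 0.01
        assert len(res.random_scores) + res.n_sets_excluded == 100

    def test_pool_too_small_fails(self):
        fx = FoldFixture(seed=7)
        with pytest.raises(ValueError, match="pool"):
            k.fold_vs_random(fx.sig, fx.pool, fx.pool, fx.tf_map,
                             fx.lines, fx.dg, "KD")
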