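"""Synthetic fixtures with ground-truth manifests.

Three generators emulate the method's real inputs at desk scale:

* a modular scale-free network with planted pathway modules, a designated
  disease-gene module, and planted "communicator" nodes preferentially
  wired into it (plus degree-matched decoys);
* a donors x proteins measurement table with case/control signal on a few
  informative proteins and a planted missingness pattern with analytically
  known filter survivors;
* a genes x signatures perturbation matrix with a correlated cell-line
  block at the disease genes, inflated effects downstream of the disease
  communicators, and metadata exercising every signature filter rule.

Each generator is fully determined by its seed, and every planted truth is
recorded in a :class:`FixtureManifest` so recovery tests can assert
against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diagnosis import DiseaseLabelSet, ProteomeTable
from .genesets import GeneSet
from .network import EdgeRecord, HeteroNetwork, assemble_network
from .perturbation import SignatureMatrix
from .scoring import ITCCatalog


@dataclass
class FixtureManifest:
    """Seed, parameters and planted ground truth of one synthetic fixture."""

    rng_seed: int
    generator: str
    parameters: dict
    ground_truth: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "rng_seed": self.rng_seed,
            "generator": self.generator,
            "parameters": self.parameters,
            "ground_truth": self.ground_truth,
        }, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["rng_seed"], d["generator"], d["parameters"],
                   d["ground_truth"])


# ---------------------------------------------------------------------------
# network fixture


def make_network_fixture(
    n_nodes: int = 500,
    n_modules: int = 5,
    module_size: int = 20,
    p_within: float = 0.3,
    p_between: float = 0.01,
    n_itcs: int = 5,
    n_decoys: int = 45,
    n_dg: int | None = None,
    wiring_strength: int = 10,
    rng_seed: int = 0,
) -> tuple[HeteroNetwork, ITCCatalog, FixtureManifest]:
    """Planted-module, planted-communicator network.

    A preferential-attachment backbone is overlaid with ``n_modules``
    stochastic-block modules (within-module edge probability ``p_within``,
    between-module ``p_between``).  Module 0 is the disease-gene module;
    its first ``n_dg`` members are the disease-gene set.  ``n_itcs``
    planted communicators each get ``wiring_strength`` extra edges into
    the disease module; ``n_decoys`` decoys get the same number of extra
    edges to uniformly random nodes, so planted and decoy communicators
    are degree-matched.
    """
    if module_size * n_modules > n_nodes:
        raise ValueError("modules do not fit into the node count")
    if not (0 < p_within < 1 and 0 < p_between < 1):
        raise ValueError("edge probabilities must be in (0, 1)")
    if n_dg is None:
        n_dg = module_size
    if n_dg > module_size:
        raise ValueError("n_dg cannot exceed module_size")
    rng = np.random.default_rng(rng_seed)
    ids = [f"G{i:04d}" for i in range(n_nodes)]

    backbone = nx.barabasi_albert_graph(n_nodes, 2, seed=int(rng.integers(2**31)))
    edges: set[tuple[str, str]] = set()

    def add_edge(u: int, v: int) -> None:
        if u != v:
            a, b = sorted((ids[u], ids[v]))
            edges.add((a, b))

    for u, v in backbone.edges():
        add_edge(u, v)

    module_nodes = rng.choice(n_nodes, size=n_modules * module_size, replace=False)
    modules = [
        sorted(int(x) for x in module_nodes[m * module_size:(m + 1) * module_size])
        for m in range(n_modules)
    ]
    for m, members in enumerate(modules):
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                if rng.random() < p_within:
                    add_edge(members[a_idx], members[b_idx])
        for other in modules[m + 1:]:
            for u in members:
                for v in other:
                    if rng.random() < p_between:
                        add_edge(u, v)

    dg_nodes = modules[0][:n_dg]
    non_module = sorted(set(range(n_nodes)) - set(int(x) for x in module_nodes))
    if len(non_module) < n_itcs + n_decoys:
        raise ValueError("not enough non-module nodes for communicators and decoys")
    picks = rng.choice(len(non_module), size=n_itcs + n_decoys, replace=False)
    planted = sorted(non_module[i] for i in picks[:n_itcs])
    decoys = sorted(non_module[i] for i in picks[n_itcs:])
    for itc in planted:
        targets = rng.choice(len(modules[0]), size=min(wiring_strength, len(modules[0])),
                             replace=False)
        for t in targets:
            add_edge(itc, modules[0][t])
    for dec in decoys:
        n_extra = min(wiring_strength, len(modules[0]))
        targets = rng.choice(n_nodes, size=n_extra, replace=False)
        for t in targets:
            add_edge(dec, int(t))

    records = [EdgeRecord(a, b, "ppi", directed=False, provenance="fixture")
               for a, b in sorted(edges)]
    network = assemble_network([records], direction_policy="undirected_all")
    roles = ["receptor", "ligand"]
    catalog = ITCCatalog([
        (ids[i], roles[k % 2]) for k, i in enumerate(planted + decoys)
    ])
    manifest = FixtureManifest(
        rng_seed=rng_seed,
        generator="make_network_fixture",
        parameters={
            "n_nodes": n_nodes, "n_modules": n_modules,
            "module_size": module_size, "p_within": p_within,
            "p_between": p_between, "n_itcs": n_itcs, "n_decoys": n_decoys,
            "n_dg": n_dg, "wiring_strength": wiring_strength,
        },
        ground_truth={
            "planted_itcs": [ids[i] for i in planted],
            "decoy_itcs": [ids[i] for i in decoys],
            "modules": {f"module_{m}": [ids[i] for i in members]
                        for m, members in enumerate(modules)},
            "disease_genes": [ids[i] for i in dg_nodes],
            "n_edges": len(records),
        },
    )
    return network, catalog, manifest


def network_fixture_genesets(manifest: FixtureManifest) -> tuple[list[GeneSet], GeneSet]:
    """(pathway sets from the planted modules, disease-gene set)."""
    pathways = [
        GeneSet(name, tuple(members))
        for name, members in sorted(manifest.ground_truth["modules"].items())
    ]
    disease = GeneSet("planted_disease",
                      tuple(manifest.ground_truth["disease_genes"]))
    return pathways, disease


# ---------------------------------------------------------------------------
# proteome fixture


def make_proteome_fixture(
    n_donors: int = 300,
    n_proteins: int = 40,
    n_cases: int = 60,
    n_informative: int = 5,
    effect_size: float = 1.0,
    missing_rate: float = 0.01,
    rng_seed: int = 0,
    max_missing_per_donor: int | None = None,
    max_missing_per_protein: int | None = None,
    disease_id: str = "D1",
) -> tuple[ProteomeTable, DiseaseLabelSet, FixtureManifest]:
    """Case/control proteome with signal and a planted missingness pattern.

    Each protein has a Gaussian baseline; cases are shifted by
    ``effect_size`` standard deviations on the informative proteins
    (``effect_size=0`` gives a null fixture).  Cells go missing i.i.d. at
    ``missing_rate``; additionally one donor and one protein are planted
    with missingness exceeding the filter thresholds (which default to 5%
    of proteins per donor and 2% of donors per protein, mirroring the
    usual proteome cleaning proportions).  The manifest stores the exact
    surviving donor/protein counts, computed by direct counting on the
    realized missingness mask.
    """
    if n_cases >= n_donors:
        raise ValueError("n_cases must be below n_donors")
    if n_informative > n_proteins:
        raise ValueError("more informative proteins than proteins")
    if max_missing_per_donor is None:
        max_missing_per_donor = max(2, int(round(0.05 * n_proteins)))
    if max_missing_per_protein is None:
        max_missing_per_protein = max(2, int(round(0.02 * n_donors)))
    rng = np.random.default_rng(rng_seed)

    donors = [f"donor{i:04d}" for i in range(n_donors)]
    proteins = [f"P{j:03d}" for j in range(n_proteins)]
    informative = proteins[:n_informative]
    cases = sorted(rng.choice(n_donors, size=n_cases, replace=False).tolist())
    case_mask = np.zeros(n_donors, dtype=bool)
    case_mask[cases] = True

    mu = rng.normal(0, 2, size=n_proteins)
    sd = rng.uniform(0.5, 1.5, size=n_proteins)
    values = rng.normal(mu, sd, size=(n_donors, n_proteins))
    values[np.ix_(case_mask, np.arange(n_informative))] += effect_size * sd[:n_informative]

    missing = rng.random((n_donors, n_proteins)) < missing_rate
    # planted high-missingness donor and protein; neither informative nor
    # used for the planted protein so the signal survives filtering
    bad_donor = n_donors - 1
    bad_protein = n_proteins - 1
    n_bad = min(n_proteins, max_missing_per_donor + 3)
    missing[bad_donor, rng.choice(n_proteins, size=n_bad, replace=False)] = True
    surviving_donor_mask = missing.sum(axis=1) <= max_missing_per_donor
    # make the planted protein exceed its threshold among surviving donors
    donors_left = np.flatnonzero(surviving_donor_mask)
    n_bad_p = min(len(donors_left), max_missing_per_protein + 3)
    missing[rng.choice(donors_left, size=n_bad_p, replace=False), bad_protein] = True

    values = values.astype(float)
    values[missing] = np.nan
    table = ProteomeTable(pd.DataFrame(values, index=donors, columns=proteins))
    labels = DiseaseLabelSet({disease_id: {donors[i] for i in cases}})

    # analytic filter survivors from the realized mask (donors first,
    # then proteins on the remaining donors)
    donor_keep = missing.sum(axis=1) <= max_missing_per_donor
    protein_keep = missing[donor_keep].sum(axis=0) <= max_missing_per_protein
    manifest = FixtureManifest(
        rng_seed=rng_seed,
        generator="make_proteome_fixture",
        parameters={
            "n_donors": n_donors, "n_proteins": n_proteins, "n_cases": n_cases,
            "n_informative": n_informative, "effect_size": effect_size,
            "missing_rate": missing_rate,
            "max_missing_per_donor": max_missing_per_donor,
            "max_missing_per_protein": max_missing_per_protein,
        },
        ground_truth={
            "disease_id": disease_id,
            "informative_proteins": informative,
            "case_donors": [donors[i] for i in cases],
            "planted_bad_donor": donors[bad_donor],
            "planted_bad_protein": proteins[bad_protein],
            "expected_surviving_donors": int(donor_keep.sum()),
            "expected_surviving_proteins": int(protein_keep.sum()),
        },
    )
    return table, labels, manifest


# ---------------------------------------------------------------------------
# signature fixture


def make_signature_fixture(
    n_genes: int = 80,
    n_dg: int = 20,
    cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3", "CL4",
                                   "CL5", "CL6", "CL7", "CL8"),
    corr_block: tuple[str, ...] = ("CL1", "CL2", "CL3", "CL4"),
    n_tf_perturbagens: int = 24,
    n_receptors: int = 12,
    n_disease_receptors: int = 3,
    n_ligands: int = 6,
    tfs_per_receptor: int = 3,
    dg_inflation: float = 3.0,
    block_corr: float = 0.6,
    rng_seed: int = 0,
) -> tuple[SignatureMatrix, nx.DiGraph, list[tuple[str, str]], FixtureManifest]:
    """Perturbation-signature fixture with pathway graph and LR pairs.

    Signatures are i.i.d. standard normal except that cell lines in
    ``corr_block`` share a latent factor at the disease-gene rows (pairwise
    correlation ``block_corr``) and TFs downstream of the disease
    receptors have their disease-gene effects multiplied by
    ``dg_inflation`` (1.0 gives the null fixture).  Metadata includes
    lower-TAS duplicates, non-exemplar columns, an off-time column and an
    excluded cell line, so every filter rule has something to drop; the
    manifest records which signature ids survive the canonical filter.
    """
    if not set(corr_block) <= set(cell_lines):
        raise ValueError("corr_block must be a subset of cell_lines")
    if n_dg > n_genes:
        raise ValueError("n_dg cannot exceed n_genes")
    if n_disease_receptors > n_receptors:
        raise ValueError("more disease receptors than receptors")
    rng = np.random.default_rng(rng_seed)

    genes = [f"g{i:03d}" for i in range(n_genes)]
    dg = genes[:n_dg]
    tfs = [f"TF{i:02d}" for i in range(n_tf_perturbagens)]
    receptors = [f"R{i:02d}" for i in range(n_receptors)]
    ligands = [f"L{i:02d}" for i in range(n_ligands)]
    disease_receptors = receptors[:n_disease_receptors]

    # directed pathway graph: receptor -> intermediate -> TFs; disease
    # receptors draw from a disjoint TF pool so the planted inflation does
    # not leak into random ITC sets through shared TFs
    n_disease_tf_pool = min(2 * tfs_per_receptor, n_tf_perturbagens // 2)
    disease_tf_pool = tfs[:n_disease_tf_pool]
    other_tf_pool = tfs[n_disease_tf_pool:]
    graph = nx.DiGraph()
    receptor_tfs: dict[str, list[str]] = {}
    for k, rec in enumerate(receptors):
        pool = disease_tf_pool if rec in disease_receptors else other_tf_pool
        chosen = sorted(
            pool[i] for i in rng.choice(len(pool), size=tfs_per_receptor,
                                        replace=False)
        )
        receptor_tfs[rec] = chosen
        mid = f"X{k:02d}"
        graph.add_edge(rec, mid)
        for tf in chosen:
            graph.add_edge(mid, tf)
    lr_pairs = [(lig, receptors[k % n_receptors]) for k, lig in enumerate(ligands)]
    disease_tfs = sorted({tf for rec in disease_receptors for tf in receptor_tfs[rec]})
    disease_ligands = [lig for lig, rec in lr_pairs if rec in disease_receptors]

    dg_idx = np.arange(n_dg)
    block = set(corr_block)
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    surviving: list[str] = []

    def add_column(sig_id: str, cell_line: str, tf: str, ptype: str, time: str,
                   exemplar: bool, tas: float, keep: bool,
                   latent: np.ndarray | None) -> None:
        col = rng.normal(0, 1, size=n_genes)
        if latent is not None and cell_line in block:
            col[dg_idx] = (np.sqrt(block_corr) * latent
                           + np.sqrt(1 - block_corr) * col[dg_idx])
        if tf in disease_tfs:
            col[dg_idx] *= dg_inflation
        columns[sig_id] = col
        meta_rows.append({
            "signature_id": sig_id, "cell_line": cell_line, "perturbagen": tf,
            "ptype": ptype, "time": time, "exemplar": exemplar, "tas": tas,
        })
        if keep:
            surviving.append(sig_id)

    excluded_line = "XLINE"
    for ptype in ("OX", "KD"):
        for t_idx, tf in enumerate(tfs):
            latent = rng.normal(0, 1, size=n_dg)  # shared across block lines
            for cl in cell_lines:
                tas = float(rng.uniform(0.4, 0.9))
                sig_id = f"{cl}_{tf}_{ptype}"
                # the off-time duplicate below outranks this column at the
                # max-TAS dedup stage and is then dropped by the time rule,
                # taking this (cell line, tf, ptype) out of the filtered set
                displaced = t_idx % 4 == 2 and cl == cell_lines[2]
                add_column(sig_id, cl, tf, ptype, "96 h", True, tas,
                           not displaced, latent)
            # filter-exercising extras, deterministic pattern per (tf, ptype)
            if t_idx % 4 == 0:
                add_column(f"{cell_lines[0]}_{tf}_{ptype}_dup", cell_lines[0], tf,
                           ptype, "96 h", True, 0.1, False, latent)
            if t_idx % 4 == 1:
                add_column(f"{cell_lines[1]}_{tf}_{ptype}_nonex", cell_lines[1], tf,
                           ptype, "96 h", False, 0.95, False, latent)
            if t_idx % 4 == 2:
                add_column(f"{cell_lines[2]}_{tf}_{ptype}_24h", cell_lines[2], tf,
                           ptype, "24 h", True, 0.95, False, None)
            if t_idx % 4 == 3:
                add_column(f"{excluded_line}_{tf}_{ptype}", excluded_line, tf,
                           ptype, "96 h", True, float(rng.uniform(0.4, 0.9)),
                           False, latent)

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("signature_id")
    sig = SignatureMatrix(values, meta)
    manifest = FixtureManifest(
        rng_seed=rng_seed,
        generator="make_signature_fixture",
        parameters={
            "n_genes": n_genes, "n_dg": n_dg, "cell_lines": list(cell_lines),
            "corr_block": list(corr_block),
            "n_tf_perturbagens": n_tf_perturbagens,
            "n_receptors": n_receptors,
            "n_disease_receptors": n_disease_receptors,
            "n_ligands": n_ligands, "tfs_per_receptor": tfs_per_receptor,
            "dg_inflation": dg_inflation, "block_corr": block_corr,
            "excluded_cell_line": excluded_line,
        },
        ground_truth={
            "disease_genes": dg,
            "tfs": tfs,
            "receptors": receptors,
            "ligands": ligands,
            "lr_pairs": [list(p) for p in lr_pairs],
            "receptor_tfs": receptor_tfs,
            "disease_receptors": disease_receptors,
            "disease_ligands": disease_ligands,
            "disease_tfs": disease_tfs,
            "surviving_signatures": surviving,
        },
    )
    return sig, graph, lr_pairs, manifest


def signature_fixture_genesets(manifest: FixtureManifest) -> GeneSet:
    """Disease-gene set of a signature fixture."""
    return GeneSet("planted_disease", tuple(manifest.ground_truth["disease_genes"]))
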