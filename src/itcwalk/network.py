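"""Heterogeneous biological network assembly and column normalization.

The walkable network is built from typed edge tables covering three layers
of molecular interactions: protein-protein interactions (``ppi``),
transcription-factor/target regulation (``tf_target``) and miRNA/target
regulation (``mirna_target``).  Protein complexes are represented as a
single node whose identifier is the sorted, ``::``-joined list of member
identifiers.  The end product is a column-stochastic transition matrix
suitable for random walk with restart.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

LAYERS = ("ppi", "tf_target", "mirna_target")
DIRECTION_POLICIES = ("undirected_all", "as_declared")
DANGLING_POLICIES = ("uniform_jump", "self_loop")
COMPLEX_DELIMITER = "::"


def complex_id(members: Iterable[str]) -> str:
    """Deterministic identifier for a protein complex node."""
    return COMPLEX_DELIMITER.join(sorted(members))


def _infer_kind(node_id: str) -> str:
    if COMPLEX_DELIMITER in node_id:
        return "complex"
    low = node_id.lower()
    if low.startswith(("hsa-mir", "hsa-let", "mir")):
        return "mirna"
    return "protein"


@dataclass(frozen=True)
class GeneNode:
    """A node of the heterogeneous network: protein, miRNA or complex."""

    id: str
    kind: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GeneNode id must be nonempty")


@dataclass(frozen=True)
class EdgeRecord:
    """One typed interaction edge between two nodes."""

    source: str
    target: str
    layer: str
    directed: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")


def load_edge_table(
    path: str | Path,
    layer: str | None = None,
    directed: bool | None = None,
) -> list[EdgeRecord]:
    """Read a TSV edge table into deduplicated :class:`EdgeRecord` rows.

    The file must have a header with at least ``source`` and ``target``
    columns.  ``layer``, ``directed`` and ``provenance`` columns are used
    when present; the ``layer``/``directed`` arguments override them for
    the whole file.  Malformed rows (empty endpoint) are skipped and
    counted; duplicate (source, target, layer) triples collapse to the
    first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge table not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in ("source", "target") if c not in header]
        if missing:
            raise ValueError(
                f"edge table {path} is missing mandatory columns: {', '.join(missing)}"
            )
        records: dict[tuple[str, str, str], EdgeRecord] = {}
        n_skipped = 0
        for row in reader:
            src = (row.get("source") or "").strip()
            tgt = (row.get("target") or "").strip()
            if not src or not tgt:
                n_skipped += 1
                continue
            row_layer = layer if layer is not None else (row.get("layer") or "ppi").strip()
            if directed is not None:
                row_directed = directed
            else:
                raw = (row.get("directed") or "").strip().lower()
                row_directed = raw in ("1", "true", "yes")
            key = (src, tgt, row_layer)
            if key in records:
                continue
            records[key] = EdgeRecord(
                source=src,
                target=tgt,
                layer=row_layer,
                directed=row_directed,
                provenance=(row.get("provenance") or "").strip(),
            )
    if n_skipped:
        logger.info("load_edge_table(%s): skipped %d malformed rows", path.name, n_skipped)
    return list(records.values())


@dataclass
class HeteroNetwork:
    """Assembled multi-layer network with a sparse adjacency matrix.

    ``adjacency[i, j] > 0`` iff an edge j -> i exists under the chosen
    direction policy (columns are walk sources).
    """

    nodes: list[GeneNode]
    node_index: dict[str, int]
    edges: list[EdgeRecord]
    adjacency: sp.csr_matrix
    direction_policy: str = "undirected_all"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def to_edge_tsv(self, path: str | Path) -> None:
        """Write the input edge list back out as a TSV edge table."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["source", "target", "layer", "directed", "provenance"])
            for e in self.edges:
                writer.writerow(
                    [e.source, e.target, e.layer, str(e.directed).lower(), e.provenance]
                )

    def manifest(self) -> dict:
        coo = self.adjacency.tocoo()
        digest = hashlib.sha256()
        digest.update(np.asarray(sorted(zip(coo.row.tolist(), coo.col.tolist()))).tobytes())
        return {
            "n_nodes": self.n_nodes,
            "n_edges": len(self.edges),
            "n_adjacency_entries": int(self.adjacency.nnz),
            "direction_policy": self.direction_policy,
            "checksum": digest.hexdigest(),
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n")


def assemble_network(
    edge_lists: Sequence[Sequence[EdgeRecord]] | Sequence[EdgeRecord],
    direction_policy: str = "undirected_all",
) -> HeteroNetwork:
    """Merge edge lists into a :class:`HeteroNetwork`.

    Under ``undirected_all`` every layer is symmetrized (the common
    convention for walk-based gene prioritization); ``as_declared`` keeps
    regulatory edges directed as annotated.  Self-loops are removed with a
    logged count, all edges carry unit weight and duplicate node pairs
    across layers count once.
    """
    if direction_policy not in DIRECTION_POLICIES:
        raise ValueError(f"unknown direction policy {direction_policy!r}")
    if edge_lists and isinstance(edge_lists[0], EdgeRecord):
        edge_lists = [edge_lists]  # type: ignore[list-item]
    edges: list[EdgeRecord] = []
    seen: set[tuple[str, str, str]] = set()
    n_self = 0
    for lst in edge_lists:
        for e in lst:
            if e.source == e.target:
                n_self += 1
                continue
            key = (e.source, e.target, e.layer)
            if key in seen:
                continue
            seen.add(key)
            edges.append(e)
    if n_self:
        logger.info("assemble_network: dropped %d self-loops", n_self)
    if not edges:
        raise ValueError("assemble_network: empty edge union")

    ids = sorted({e.source for e in edges} | {e.target for e in edges})
    nodes = [GeneNode(i, _infer_kind(i)) for i in ids]
    index = {i: k for k, i in enumerate(ids)}

    pairs: set[tuple[int, int]] = set()
    for e in edges:
        s, t = index[e.source], index[e.target]
        symmetric = direction_policy == "undirected_all" or not e.directed
        pairs.add((t, s))  # column s -> row t
        if symmetric:
            pairs.add((s, t))
    rows, cols = zip(*sorted(pairs))
    adj = sp.csr_matrix(
        (np.ones(len(pairs)), (np.array(rows), np.array(cols))),
        shape=(len(ids), len(ids)),
    )
    return HeteroNetwork(nodes=nodes, node_index=index, edges=edges, adjacency=adj,
                         direction_policy=direction_policy)


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix with an explicit dangling-column policy.

    ``W`` holds the normalized columns with nonzero out-mass.  Columns with
    no outgoing edges are handled per ``dangling_policy``: ``uniform_jump``
    spreads their mass uniformly over all nodes (kept implicit so the
    matrix stays sparse), ``self_loop`` pins it on the diagonal.
    """

    W: sp.csr_matrix
    dangling: np.ndarray  # boolean mask over columns
    dangling_policy: str
    node_ids: list[str]
    node_index: dict[str, int]
    source_network_hash: str = ""

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def matvec(self, p: np.ndarray) -> np.ndarray:
        """Effective stochastic product W_eff @ p including dangling mass."""
        out = self.W @ p
        if self.dangling_policy == "uniform_jump":
            mass = float(p[self.dangling].sum())
            if mass:
                out = out + mass / self.n_nodes
        # self_loop dangling columns already carry their diagonal entry in W
        return out

    def dense(self) -> np.ndarray:
        """Materialize the effective matrix (small networks only)."""
        dense = self.W.toarray()
        if self.dangling_policy == "uniform_jump" and self.dangling.any():
            dense[:, self.dangling] = 1.0 / self.n_nodes
        return dense

    def column_sums(self) -> np.ndarray:
        sums = np.asarray(self.W.sum(axis=0)).ravel()
        if self.dangling_policy == "uniform_jump":
            sums = sums + self.dangling.astype(float)
        return sums


def column_normalize(
    network: HeteroNetwork | sp.spmatrix | np.ndarray,
    dangling_policy: str = "uniform_jump",
) -> TransitionMatrix:
    """Normalize adjacency columns to sum to one.

    Accepts an assembled network or a raw nonnegative matrix.  Fails on
    negative entries; verifies every effective column sum is 1 within
    1e-12.
    """
    if dangling_policy not in DANGLING_POLICIES:
        raise ValueError(f"unknown dangling policy {dangling_policy!r}")
    if isinstance(network, HeteroNetwork):
        adj = network.adjacency.tocsc(copy=True).astype(float)
        node_ids = network.node_ids
        source_hash = network.manifest()["checksum"]
    else:
        adj = sp.csc_matrix(network, dtype=float)
        node_ids = [str(i) for i in range(adj.shape[0])]
        source_hash = ""
    if adj.nnz and adj.data.min() < 0:
        raise ValueError("column_normalize: adjacency has negative entries")

    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    dangling = col_sums == 0
    inv = np.ones_like(col_sums)
    inv[~dangling] = 1.0 / col_sums[~dangling]
    W = (adj @ sp.diags(inv)).tocsc()
    if dangling_policy == "self_loop" and dangling.any():
        W = W.tolil()
        for j in np.flatnonzero(dangling):
            W[j, j] = 1.0
        W = W.tocsc()
        dangling = np.zeros_like(dangling)

    tm = TransitionMatrix(
        W=W.tocsr(),
        dangling=dangling,
        dangling_policy=dangling_policy,
        node_ids=list(node_ids),
        node_index={i: k for k, i in enumerate(node_ids)},
        source_network_hash=source_hash,
    )
    sums = tm.column_sums()
    if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
        raise AssertionError("column sums deviate from 1 beyond 1e-12")
    return tm
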