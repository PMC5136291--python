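"""Protein-interaction subnetwork dissection of a pathway signal.

To localize a pathway-level association, the most highly connected genes
(hubs) of the pathway's interaction subgraph are identified, a subnetwork
is formed around each hub from its directly connected pathway neighbours,
and each subnetwork's variants are tested with the same kernel test as the
parent pathway.  Connectivity is counted on the subgraph induced by the
pathway's genes, so cross-pathway neighbours contribute neither to hub
ranking nor to subnetwork membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import SchemaError
from .geno_io import GenotypeMatrix
from .genesets import MIN_SET_SIZE, VariantSet
from .kernel_test import (
    DEFAULT_RHO_GRID,
    KernelTestResult,
    NullModel,
    WeightSpec,
    beta_weights,
    skat_o,
)
from .permtest import _set_mafs

logger = logging.getLogger("pathkat.netdissect")

__all__ = [
    "Subnetwork",
    "read_edge_list",
    "pathway_hubs",
    "hub_subnetwork",
    "test_subnetworks",
]


@dataclass(frozen=True)
class Subnetwork:
    """A hub gene plus its directly connected pathway neighbours."""

    hub: str
    members: frozenset[str]

    def __post_init__(self):
        if self.hub not in self.members:
            raise ValueError("hub must be a member of its own subnetwork")


def read_edge_list(path, min_score: float = 0.0) -> nx.Graph:
    """Read an undirected interaction graph from a 3-column TSV.

    Columns: ``gene_a, gene_b, experimental_score`` (evidence-channel score
    in [0, 1000]).  Edges below ``min_score`` are dropped; duplicate pairs
    keep the maximum score; self-loops are discarded with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    for col in ("gene_a", "gene_b", "experimental_score"):
        if col not in df.columns:
            raise SchemaError(f"edge list {path} is missing column {col!r}")
    scores = pd.to_numeric(df["experimental_score"], errors="coerce")
    bad = scores.isna() | df["gene_a"].isna() | df["gene_b"].isna()
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        raise SchemaError(f"edge list {path}: malformed row(s) at line(s) {lines}")

    graph = nx.Graph()
    n_self = 0
    for a, b, s in zip(df["gene_a"], df["gene_b"], scores):
        if a == b:
            n_self += 1
            continue
        s = float(s)
        if s < min_score:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], s)
        else:
            graph.add_edge(a, b, score=s)
    if n_self:
        logger.warning("stage=read_edge_list self_loops_dropped=%d", n_self)
    logger.info(
        "stage=read_edge_list n_nodes=%d n_edges=%d",
        graph.number_of_nodes(), graph.number_of_edges(),
    )
    return graph


def pathway_hubs(graph: nx.Graph, pathway_genes, k: int = 3) -> list[str]:
    """Top-k pathway genes by degree on the pathway-induced subgraph.

    Ties break by higher summed edge score, then lexicographic symbol.
    Returns fewer than k genes (with a warning) when fewer have degree >= 1.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    genes = set(pathway_genes)
    sub = graph.subgraph(genes & set(graph.nodes))
    candidates = [g for g in sub.nodes if sub.degree(g) >= 1]
    if len(candidates) < k:
        logger.warning(
            "stage=pathway_hubs requested=%d connected_genes=%d", k, len(candidates)
        )

    def sort_key(g):
        score_sum = sum(d["score"] for _, _, d in sub.edges(g, data=True))
        return (-sub.degree(g), -score_sum, g)

    return sorted(candidates, key=sort_key)[:k]


def hub_subnetwork(graph: nx.Graph, hub: str, pathway_genes) -> Subnetwork:
    """The hub plus its direct neighbours, intersected with the pathway."""
    genes = set(pathway_genes)
    if hub not in genes:
        raise ValueError(f"hub {hub!r} is not a member of the pathway")
    if hub not in graph:
        logger.warning("stage=hub_subnetwork hub=%s absent_from_graph", hub)
        return Subnetwork(hub=hub, members=frozenset({hub}))
    members = {hub} | (set(graph.neighbors(hub)) & genes)
    return Subnetwork(hub=hub, members=frozenset(members))


def test_subnetworks(
    subnetworks: list[Subnetwork],
    gene_map: dict[str, list[int]],
    gm: GenotypeMatrix,
    null: NullModel,
    weights: WeightSpec = WeightSpec(),
    rho_grid=DEFAULT_RHO_GRID,
) -> list[tuple[Subnetwork, VariantSet, KernelTestResult | None]]:
    """Kernel-test each subnetwork's variant union; ineligible ones untested.

    Each subnetwork's variant set is the deduplicated union over member
    genes of their assigned variant indices (from the active filter
    regime's gene map); sets with fewer than two variants are reported with
    a ``None`` result.
    """
    out = []
    for sn in subnetworks:
        indices: set[int] = set()
        for g in sn.members:
            indices.update(gene_map.get(g, []))
        vset = VariantSet(
            label=f"subnetwork:{sn.hub}", level="subnetwork",
            indices=tuple(indices),
        )
        if vset.n_variants < MIN_SET_SIZE:
            logger.info(
                "stage=test_subnetworks hub=%s n_variants=%d ineligible",
                sn.hub, vset.n_variants,
            )
            out.append((sn, vset, None))
            continue
        G = gm.dosage[:, list(vset.indices)]
        w = beta_weights(_set_mafs(gm, vset.indices), weights)
        res = skat_o(null, G, w, rho_grid=rho_grid, label=vset.label)
        out.append((sn, vset, res))
    return out
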