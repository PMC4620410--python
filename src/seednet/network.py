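"""Reference-graph construction, seed mapping, and subnetwork extraction.

The reference interactome and every derived subnetwork are undirected
simple graphs (``networkx.Graph``) over protein accessions: self-loops
are dropped and duplicate / reciprocal-duplicate pairs collapse to one
edge. Seed proteins enter the graph through best-ortholog-hit mapping,
and the expanded seed subnetwork is the induced subgraph on the mapped
seeds plus their direct interactors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .exceptions import ConfigurationError, ValidationError
from .io import DapRecord, OrthologHit

logger = logging.getLogger(__name__)

EXPANSION_MODES = ("induced", "star")


@dataclass
class SeedMapping:
    """Outcome of mapping seed proteins onto the reference network.

    ``mapped`` and ``unmapped`` partition the seed set; several seeds may
    map to the same network node (the graph collapses them, the mapping
    keeps the many-to-one record).
    """

    mapped: dict[str, str]            # seed query_id -> network node
    unmapped: list[str]               # seed query_ids with no usable hit
    hit_used: dict[str, OrthologHit]  # seed query_id -> winning hit

    @property
    def mapped_nodes(self) -> frozenset[str]:
        return frozenset(self.mapped.values())

    def check_invariants(self, seed_ids: Iterable[str]) -> None:
        seeds = set(seed_ids)
        if set(self.mapped) | set(self.unmapped) != seeds or \
                set(self.mapped) & set(self.unmapped):
            raise ValidationError("mapped/unmapped do not partition the seed set")


def build_network(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    """Build a simple undirected graph from raw id pairs.

    Self-loops are dropped and duplicates (in either orientation)
    collapsed; counts of dropped rows are logged.
    """
    g = nx.Graph()
    loops = dups = 0
    for a, b in pairs:
        if a == b:
            loops += 1
            g.add_node(a)
            continue
        if g.has_edge(a, b):
            dups += 1
            continue
        g.add_edge(a, b)
    if loops or dups:
        logger.info("build_network: dropped %d self-loops, %d duplicate pairs",
                    loops, dups)
    return g


def map_seeds(daps: Sequence[DapRecord], hits: Sequence[OrthologHit],
              network: nx.Graph, e_cutoff: float = 0.5) -> SeedMapping:
    """Assign each seed its best ortholog hit on the network.

    A hit is a candidate when its e-value is strictly below ``e_cutoff``
    and its subject is a network node. The best candidate maximizes bit
    score, with ties broken by smaller e-value, then by lexicographically
    smallest subject id. Seeds without a candidate are unmapped.
    """
    if e_cutoff <= 0:
        raise ConfigurationError(f"e_cutoff must be > 0, got {e_cutoff}")
    by_query: dict[str, list[OrthologHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)

    nodes = set(network.nodes)
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    hit_used: dict[str, OrthologHit] = {}
    for dap in daps:
        candidates = [h for h in by_query.get(dap.query_id, ())
                      if h.e_value < e_cutoff and h.subject_id in nodes]
        if not candidates:
            unmapped.append(dap.query_id)
            continue
        best = min(candidates,
                   key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
        mapped[dap.query_id] = best.subject_id
        hit_used[dap.query_id] = best
    mapping = SeedMapping(mapped=mapped, unmapped=unmapped, hit_used=hit_used)
    mapping.check_invariants(d.query_id for d in daps)
    logger.info("map_seeds: %d/%d seeds mapped (%d distinct nodes)",
                len(mapped), len(daps), len(mapping.mapped_nodes))
    return mapping


def _require_subset(network: nx.Graph, nodes: Iterable[str]) -> set[str]:
    nodes = set(nodes)
    missing = nodes - set(network.nodes)
    if missing:
        raise ValidationError(
            f"nodes not in network: {sorted(missing)[:5]}"
            f"{'...' if len(missing) > 5 else ''}")
    return nodes


def core_subnetwork(network: nx.Graph, mapped_nodes: Iterable[str]) -> nx.Graph:
    """Induced subgraph on the mapped seed nodes only (the core network)."""
    nodes = _require_subset(network, mapped_nodes)
    return nx.Graph(network.subgraph(nodes))


def expand_first_neighbors(network: nx.Graph, mapped_nodes: Iterable[str],
                           mode: str = "induced") -> nx.Graph:
    """Expand seeds to their closed first neighborhood.

    ``induced`` (default) keeps every reference-network edge among the
    selected nodes, including neighbor–neighbor edges. ``star`` keeps
    only edges incident to a seed, for sensitivity analysis.
    """
    if mode not in EXPANSION_MODES:
        raise ConfigurationError(
            f"expansion mode must be one of {EXPANSION_MODES}, got {mode!r}")
    seeds = _require_subset(network, mapped_nodes)
    closed = set(seeds)
    for v in seeds:
        closed.update(network.neighbors(v))
    if mode == "induced":
        return nx.Graph(network.subgraph(closed))
    g = nx.Graph()
    g.add_nodes_from(closed)
    for v in seeds:
        for w in network.neighbors(v):
            g.add_edge(v, w)
    return g


def giant_component(network: nx.Graph) -> tuple[nx.Graph, list[set[str]]]:
    """Split a graph into its giant component and the remaining small clusters.

    The giant component is the largest by node count (ties broken by
    lexicographically smallest member id); the rest are returned sorted
    by descending size with the same tie-break. Path-based centralities
    are computed on the giant component only.
    """
    if network.number_of_nodes() == 0:
        return nx.Graph(), []
    comps = sorted(nx.connected_components(network),
                   key=lambda c: (-len(c), min(c)))
    giant = nx.Graph(network.subgraph(comps[0]))
    return giant, [set(c) for c in comps[1:]]
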