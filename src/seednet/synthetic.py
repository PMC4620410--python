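"""Synthetic study generator: interactome, seed table, ortholog map, GO terms.

The generator emulates the statistical setting the analysis assumes, so
every downstream stage is testable without any database download:

* a **scale-free background interactome** grown by preferential
  attachment (Barabási–Albert), mirroring the heavy-tailed degree
  distributions reported for curated plant interactomes;
* a **seed study**: a table of differentially accumulated proteins of
  which only a configurable fraction has an ortholog hit on the
  background network (partial ortholog mapping is the norm when the
  study organism has no sequenced genome);
* a **planted seed module**: the mapped ortholog targets are densified
  with extra edges so the seed neighborhood is a genuine community the
  pipeline can rediscover by degree/betweenness ranking;
* **planted GO terms** whose gene sets are biased toward the module, so
  hypergeometric enrichment has a true signal to find, plus background
  terms drawn uniformly as the null.

All randomness flows from ``SyntheticConfig.rng_seed`` through
stage-labelled substreams; identical configs produce byte-identical
serialized bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml

from . import io as sio
from ._utils import derive_seed
from .exceptions import ConfigurationError
from .io import AnnotationTable, DapRecord, OrthologHit

#: functional-category labels attached to planted terms so that the default
#: relevance-keyword filter (see ``seednet.keys``) can find the planted signal.
PLANTED_TERM_LABELS = (
    "cell cycle regulation",
    "cell wall modification and endosperm weakening",
    "hormone signaling",
    "metabolism and mobilization of storage reserves",
    "protein modification and ubiquitination",
    "signaling and transport",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults encode the desk-scale study conditions: an 88-protein seed
    table of which 68 map onto a 2000-node preferential-attachment
    interactome, a module densified at 0.3, and five GO terms planted at
    odds 20 with 50–100 genes each (small enough to clear a 100-gene
    generic-term filter).
    """

    n_background: int = 2000
    attach_m: int = 3
    n_seeds: int = 88
    map_fraction: float = 68 / 88
    module_density: float = 0.3
    n_terms: int = 120
    term_size_range: tuple[int, int] = (50, 100)
    n_planted_terms: int = 5
    planted_odds: float = 20.0
    up_fraction: float = 0.5
    rng_seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_background < 2:
            raise ConfigurationError(f"n_background must be >= 2, got {self.n_background}")
        if self.attach_m < 1:
            raise ConfigurationError(f"attach_m must be >= 1, got {self.attach_m}")
        if self.attach_m >= self.n_background:
            raise ConfigurationError(
                f"attach_m must be < n_background, got {self.attach_m}")
        if not (0 < self.map_fraction <= 1):
            raise ConfigurationError(
                f"map_fraction must be in (0, 1], got {self.map_fraction}")
        if not (0 <= self.module_density <= 1):
            raise ConfigurationError(
                f"module_density must be in [0, 1], got {self.module_density}")
        if self.n_seeds < 1 or self.n_seeds > self.n_background:
            raise ConfigurationError(
                f"n_seeds must be in [1, n_background], got {self.n_seeds}")
        lo, hi = self.term_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"term_size_range must satisfy 1 <= min <= max, got {self.term_size_range}")
        if hi > self.n_background:
            raise ConfigurationError(
                f"term_size_range max {hi} exceeds n_background {self.n_background}")
        if self.n_terms < 0 or self.n_planted_terms < 0 or self.n_planted_terms > self.n_terms:
            raise ConfigurationError(
                f"need 0 <= n_planted_terms <= n_terms, got "
                f"{self.n_planted_terms}/{self.n_terms}")
        if self.planted_odds < 1:
            raise ConfigurationError(
                f"planted_odds must be >= 1, got {self.planted_odds}")
        if not (0 <= self.up_fraction <= 1):
            raise ConfigurationError(
                f"up_fraction must be in [0, 1], got {self.up_fraction}")
        return self

    def as_dict(self) -> dict:
        d = asdict(self)
        d["term_size_range"] = list(self.term_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "term_size_range" in d:
            d["term_size_range"] = tuple(d["term_size_range"])
        return cls(**d).validate()


@dataclass
class SyntheticBundle:
    """Everything one synthetic study produces, ready for the pipeline."""

    config: SyntheticConfig
    network: nx.Graph
    daps: list[DapRecord]
    ortholog_hits: list[OrthologHit]
    annotations: AnnotationTable | None
    planted_terms: list[str]
    planted_module: list[str]

    def check_invariants(self) -> None:
        nodes = set(self.network.nodes)
        for h in self.ortholog_hits:
            if h.subject_id not in nodes:
                raise ConfigurationError(
                    f"ortholog hit subject {h.subject_id} not a network node")
        if any(m not in nodes for m in self.planted_module):
            raise ConfigurationError("planted module contains non-network node")
        if self.annotations is not None:
            missing = set(self.planted_terms) - self.annotations.terms
            if missing:
                raise ConfigurationError(
                    f"planted terms missing from annotations: {sorted(missing)}")


def _node_name(i: int) -> str:
    return f"N{i:05d}"


def generate_interactome(config: SyntheticConfig) -> nx.Graph:
    """Grow a scale-free background interactome by preferential attachment.

    Each new protein attaches to ``attach_m`` existing proteins with
    probability proportional to their current degree, which yields the
    heavy-tailed (power-law-like) degree distribution observed in real
    protein-interaction networks. The graph is simple, undirected and
    connected, with nodes named ``N00000 ...``.
    """
    config.validate()
    seed = derive_seed(config.rng_seed, "interactome")
    g = nx.barabasi_albert_graph(config.n_background, config.attach_m, seed=seed)
    return nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes})


def generate_seed_study(config: SyntheticConfig,
                        network: nx.Graph) -> SyntheticBundle:
    """Generate the seed-protein table, ortholog hits and planted module.

    ``round(map_fraction * n_seeds)`` seeds receive exactly one ortholog
    hit each, to distinct network nodes sampled uniformly without
    replacement; those targets form the planted module, densified by
    adding each missing within-module edge with probability
    ``module_density``. The remaining seeds have no hit at all. Up/down
    accumulation labels are assigned so that ``round(up_fraction *
    n_seeds)`` seeds are up-accumulated.

    Returns a bundle whose ``annotations`` is still ``None``; see
    :func:`generate_annotations` / :func:`generate_bundle`.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.rng_seed, "seed_study"))
    n = config.n_seeds
    n_mapped = int(round(config.map_fraction * n))

    n_up = int(round(config.up_fraction * n))
    labels = np.array(["up"] * n_up + ["down"] * (n - n_up))
    rng.shuffle(labels)
    daps = [
        DapRecord(
            spot_id=f"{i + 1:03d}",
            protein_name=f"seed protein {i + 1}",
            regulation=str(labels[i]),
            query_id=f"PGP{i + 1:03d}",
        )
        for i in range(n)
    ]

    mapped_idx = sorted(rng.choice(n, size=n_mapped, replace=False).tolist())
    nodes = sorted(network.nodes)
    module = sorted(
        rng.choice(len(nodes), size=n_mapped, replace=False).tolist())
    module_nodes = [nodes[i] for i in module]

    hits = []
    for rank, i in enumerate(mapped_idx):
        # store the formatted values so a TSV round trip is lossless
        e_value = float(f"{10.0 ** (-rng.uniform(4.0, 60.0)):.3e}")
        bit_score = float(f"{rng.uniform(80.0, 400.0):.1f}")
        hits.append(OrthologHit(daps[i].query_id, module_nodes[rank],
                                e_value, bit_score))

    g = network.copy()
    for a_i in range(len(module_nodes)):
        for b_i in range(a_i + 1, len(module_nodes)):
            a, b = module_nodes[a_i], module_nodes[b_i]
            if not g.has_edge(a, b) and rng.random() < config.module_density:
                g.add_edge(a, b)

    bundle = SyntheticBundle(
        config=config,
        network=g,
        daps=daps,
        ortholog_hits=hits,
        annotations=None,
        planted_terms=[],
        planted_module=module_nodes,
    )
    bundle.check_invariants()
    return bundle


def generate_annotations(config: SyntheticConfig, network: nx.Graph,
                         module: Sequence[str]) -> tuple[AnnotationTable, list[str]]:
    """Assign genes to GO terms, with some terms planted as module-enriched.

    Every term draws its size uniformly from ``term_size_range`` and
    samples genes without replacement. For the first ``n_planted_terms``
    terms, module genes carry ``planted_odds`` times the sampling weight
    of background genes, realizing the assumption that functionally
    related genes accumulate in shared GO categories; at odds 1 planted
    terms are statistically indistinguishable from background terms.
    Planted terms are labelled with germination-relevant functional
    categories, background terms with generic labels.
    """
    config.validate()
    nodes = sorted(network.nodes)
    module_set = set(module)
    if not module_set <= set(nodes):
        raise ConfigurationError("module contains nodes outside the network")
    lo, hi = config.term_size_range
    if hi > len(nodes):
        raise ConfigurationError(
            f"term_size_range max {hi} exceeds node count {len(nodes)}")

    rng = np.random.default_rng(derive_seed(config.rng_seed, "annotations"))
    is_module = np.array([v in module_set for v in nodes], dtype=float)
    planted_w = is_module * (config.planted_odds - 1.0) + 1.0
    planted_p = planted_w / planted_w.sum()
    uniform_p = np.full(len(nodes), 1.0 / len(nodes))

    rows: list[tuple[str, str, str]] = []
    labels: dict[str, str] = {}
    planted: list[str] = []
    for t in range(config.n_terms):
        term = f"GO:SYN{t:04d}"
        size = int(rng.integers(lo, hi + 1))
        is_planted = t < config.n_planted_terms
        p = planted_p if is_planted else uniform_p
        idx = rng.choice(len(nodes), size=size, replace=False, p=p)
        ns = "MF" if rng.random() < 0.5 else "BP"
        for i in sorted(idx.tolist()):
            rows.append((nodes[i], term, ns))
        if is_planted:
            planted.append(term)
            labels[term] = PLANTED_TERM_LABELS[t % len(PLANTED_TERM_LABELS)]
        else:
            labels[term] = f"generic annotation {t}"
    return AnnotationTable(rows, term_labels=labels), planted


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Run all three generator stages and return a complete bundle."""
    config.validate()
    network = generate_interactome(config)
    bundle = generate_seed_study(config, network)
    annotations, planted = generate_annotations(
        config, bundle.network, bundle.planted_module)
    bundle.annotations = annotations
    bundle.planted_terms = planted
    bundle.check_invariants()
    return bundle


# ---------------------------------------------------------------------------
# bundle (de)serialization — one directory per bundle, all plain text


def write_bundle(bundle: SyntheticBundle, out_dir) -> Path:
    out = sio.ensure_dir(out_dir)
    with open(out / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(bundle.config.as_dict(), fh, sort_keys=True)
    sio.write_edge_list(bundle.network.edges, out / "network.sif")
    sio.write_dap_table(bundle.daps, out / "daps.tsv")
    sio.write_blast_tabular(bundle.ortholog_hits, out / "hits.tsv")
    if bundle.annotations is not None:
        sio.write_annotations(bundle.annotations, out / "annotations.tsv")
        sio.write_term_labels(bundle.annotations.term_labels, out / "term_labels.tsv")
    with open(out / "planted.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {"planted_terms": sorted(bundle.planted_terms),
             "planted_module": sorted(bundle.planted_module)},
            fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def read_bundle(bundle_dir) -> SyntheticBundle:
    d = Path(bundle_dir)
    with open(d / "config.yaml", encoding="utf-8") as fh:
        config = SyntheticConfig.from_dict(yaml.safe_load(fh))
    pairs = sio.read_edge_list(d / "network.sif", dialect="sif")
    network = nx.Graph()
    network.add_nodes_from(_node_name(i) for i in range(config.n_background))
    network.add_edges_from(pairs)
    daps = sio.read_dap_table(d / "daps.tsv")
    hits = sio.read_blast_tabular(d / "hits.tsv")
    annotations = None
    if (d / "annotations.tsv").exists():
        labels = (sio.read_term_labels(d / "term_labels.tsv")
                  if (d / "term_labels.tsv").exists() else None)
        annotations = sio.read_annotations(d / "annotations.tsv", term_labels=labels)
    with open(d / "planted.json", encoding="utf-8") as fh:
        planted = json.load(fh)
    bundle = SyntheticBundle(
        config=config, network=network, daps=daps, ortholog_hits=hits,
        annotations=annotations,
        planted_terms=list(planted["planted_terms"]),
        planted_module=list(planted["planted_module"]),
    )
    bundle.check_invariants()
    return bundle
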