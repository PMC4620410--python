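"""Key-protein selection from centrality rankings.

The selection procedure mirrors a hub/bottleneck analysis: per-metric
Top-k sets (tie-aware: boundary ties are included, so a "Top 50" can
legitimately hold 57 nodes), unions over two correlated metric pairs
(hubs: degree + betweenness; dynamically central nodes: closeness +
radiality), pooling into a candidate list, a functional-relevance
keyword filter standing in for manual annotation curation, Venn
accounting of the two pruned pair sets, and the overlap of the surviving
key proteins with the originally assayed seed proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import AnnotationTable, DapRecord
from .network import SeedMapping

logger = logging.getLogger(__name__)

DEFAULT_METRIC_PAIRS = (("degree", "betweenness"), ("closeness", "radiality"))

#: functional categories used as the default relevance filter; derived from
#: the germination-biology processes a curator would screen for.
DEFAULT_KEYWORDS = (
    "cell cycle",
    "cell wall",
    "endosperm",
    "hormone",
    "signaling",
    "transport",
    "metabolism",
    "protein modification",
    "ubiquitination",
    "storage reserve",
)


class DapOverlap(NamedTuple):
    node: str
    query_id: str
    regulation: str


@dataclass
class KeyProteinReport:
    """All sets produced by one key-protein selection run."""

    k: int
    topk: dict[str, frozenset[str]]
    pair_sets: dict[str, frozenset[str]]
    candidates: frozenset[str]
    key_proteins: frozenset[str]
    matched_keywords: dict[str, str]
    venn: tuple[int, int, int]           # (only A, only B, both)
    dap_overlap: tuple[DapOverlap, ...]

    def check_invariants(self) -> None:
        if not self.key_proteins <= self.candidates:
            raise ValidationError("key proteins must be a subset of candidates")
        if not {o.node for o in self.dap_overlap} <= self.key_proteins:
            raise ValidationError("DAP overlap must be a subset of key proteins")


def metric_correlations(table: pd.DataFrame,
                        metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of metrics over nodes.

    Raises when fewer than 3 nodes are available or a metric has zero
    variance (its correlations would be undefined).
    """
    metrics = list(metrics) if metrics is not None else list(table.columns)
    missing = [m for m in metrics if m not in table.columns]
    if missing:
        raise ValidationError(f"unknown metrics: {missing}")
    if len(table) < 3:
        raise ValidationError("correlations need at least 3 nodes")
    sub = table[metrics].astype(float)
    for m in metrics:
        if np.isclose(sub[m].std(ddof=0), 0.0):
            raise ValidationError(f"metric {m!r} has zero variance")
    mat = np.corrcoef(sub.to_numpy(), rowvar=False)
    return pd.DataFrame(mat, index=metrics, columns=metrics)


def top_k(values: Mapping[str, float], k: int) -> frozenset[str]:
    """All nodes with value >= the k-th largest value (boundary ties kept)."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if not values:
        return frozenset()
    ordered = sorted(values.values(), reverse=True)
    threshold = ordered[min(k, len(ordered)) - 1]
    return frozenset(v for v, x in values.items() if x >= threshold)


def top_k_sets(table: pd.DataFrame, metrics: Iterable[str],
               k: int) -> dict[str, frozenset[str]]:
    return {m: top_k(table[m].to_dict(), k) for m in metrics}


def pair_union(topk: Mapping[str, frozenset[str]],
               pair: tuple[str, str]) -> frozenset[str]:
    """Unique proteins of a metric pair: the union of its two Top-k sets."""
    for m in pair:
        if m not in topk:
            raise ValidationError(f"metric {m!r} has no Top-k set")
    return frozenset(topk[pair[0]] | topk[pair[1]])


def pool_candidates(pair_sets: Mapping[str, frozenset[str]]) -> frozenset[str]:
    out: set[str] = set()
    for label, s in pair_sets.items():
        out |= s
    logger.info("pooled %d candidate proteins from %d pair sets",
                len(out), len(pair_sets))
    return frozenset(out)


def prune_by_relevance(candidates: Iterable[str],
                       annotations: AnnotationTable | None,
                       keywords: Sequence[str],
                       protein_labels: Mapping[str, str] | None = None,
                       ) -> tuple[frozenset[str], dict[str, str]]:
    """Keep candidates whose annotations look germination-relevant.

    A candidate survives when any of its GO term ids, term labels, or its
    own free-text label contains any keyword (case-insensitive
    substring). The wildcard keyword ``"*"`` retains everything. Returns
    the pruned set plus the first keyword matched per retained protein.
    """
    if not keywords:
        raise ValidationError("keyword list must be non-empty")
    candidates = set(candidates)
    if "*" in keywords:
        return frozenset(candidates), {c: "*" for c in candidates}

    term_labels = annotations.term_labels if annotations is not None else {}
    kept: dict[str, str] = {}
    for node in sorted(candidates):
        texts: list[str] = []
        if annotations is not None:
            for term in sorted(annotations.gene_to_terms.get(node, ())):
                texts.append(term)
                if term in term_labels:
                    texts.append(term_labels[term])
        if protein_labels and node in protein_labels:
            texts.append(protein_labels[node])
        joined = [t.lower() for t in texts]
        for kw in keywords:
            if any(kw.lower() in t for t in joined):
                kept[node] = kw
                break
    if not kept:
        logger.warning("relevance pruning removed every candidate")
    return frozenset(kept), kept


def venn_counts(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, int, int]:
    """Disjoint Venn regions (only A, only B, both); sums to |A ∪ B|."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(b - a), len(a & b)


def overlap_with_daps(key_proteins: Iterable[str], mapping: SeedMapping,
                      daps: Sequence[DapRecord]) -> tuple[DapOverlap, ...]:
    """Key proteins that are mapped seed targets, with their up/down labels."""
    keys = set(key_proteins)
    by_query = {d.query_id: d for d in daps}
    out = []
    for query, node in sorted(mapping.mapped.items()):
        if node in keys and query in by_query:
            out.append(DapOverlap(node=node, query_id=query,
                                  regulation=by_query[query].regulation))
    return tuple(out)


def regulation_counts(overlap: Sequence[DapOverlap]) -> dict[str, int]:
    return {
        "up": sum(1 for o in overlap if o.regulation == "up"),
        "down": sum(1 for o in overlap if o.regulation == "down"),
    }


def build_key_report(table: pd.DataFrame, *,
                     k: int = 50,
                     pairs: Sequence[tuple[str, str]] = DEFAULT_METRIC_PAIRS,
                     annotations: AnnotationTable | None = None,
                     keywords: Sequence[str] = DEFAULT_KEYWORDS,
                     protein_labels: Mapping[str, str] | None = None,
                     mapping: SeedMapping | None = None,
                     daps: Sequence[DapRecord] | None = None,
                     ) -> KeyProteinReport:
    """Run the whole selection procedure on one centrality table.

    The Venn triple compares the two (pruned) pair sets; when more or
    fewer than two pairs are configured it is computed over the first two
    and zero-padded/ignored accordingly.
    """
    metrics = sorted({m for p in pairs for m in p})
    topk = top_k_sets(table, metrics, k)
    pair_sets = {f"{a}+{b}": pair_union(topk, (a, b)) for a, b in pairs}
    candidates = pool_candidates(pair_sets)
    key_proteins, matched = prune_by_relevance(
        candidates, annotations, keywords, protein_labels)

    labels = list(pair_sets)
    if len(labels) >= 2:
        venn = venn_counts(pair_sets[labels[0]] & key_proteins,
                           pair_sets[labels[1]] & key_proteins)
    else:
        only = len(pair_sets[labels[0]] & key_proteins) if labels else 0
        venn = (only, 0, 0)

    overlap: tuple[DapOverlap, ...] = ()
    if mapping is not None and daps is not None:
        overlap = overlap_with_daps(key_proteins, mapping, daps)

    report = KeyProteinReport(
        k=k, topk=topk, pair_sets=pair_sets, candidates=candidates,
        key_proteins=key_proteins, matched_keywords=matched,
        venn=venn, dap_overlap=overlap)
    report.check_invariants()
    return report
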