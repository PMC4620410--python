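"""Hypergeometric GO-term enrichment of a target gene set against a source set.

For a term annotating ``B`` of the ``N`` source (background) genes, of
which ``b`` fall in the ``n``-gene target set, the enrichment p-value is
the hypergeometric upper tail

    p = P(X >= b) = sum_{i=b}^{min(n,B)} C(B,i) C(N-B, n-i) / C(N,n)

("two unranked gene lists" mode). Terms are reported when ``p`` is below
the significance threshold AND the term annotates at most
``max_term_size`` source genes — the latter weeds out generic,
uninformative categories. No multiple-testing correction enters the
filter; a Benjamini–Hochberg q-value column is emitted for reference
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

from scipy import stats

from .exceptions import ValidationError
from .io import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's enrichment outcome against the source background."""

    term_id: str
    namespace: str        # MF | BP
    N: int                # source-set size
    B: int                # source genes annotated to the term
    n: int                # target-set size
    b: int                # target genes annotated to the term
    p_value: float
    enrichment_ratio: float  # (b/n) / (B/N)
    q_value: float | None = None  # BH-adjusted, reference only


class EnrichmentSummary(NamedTuple):
    total: int
    mf: int
    bp: int


def _validate_counts(N: int, B: int, n: int, b: int) -> None:
    for name, v in (("N", N), ("B", B), ("n", n), ("b", b)):
        if not isinstance(v, (int,)) or v < 0:
            raise ValidationError(f"count {name} must be a non-negative integer, got {v!r}")
    if B > N or n > N:
        raise ValidationError(f"need B <= N and n <= N, got N={N}, B={B}, n={n}")
    if b > min(n, B):
        raise ValidationError(f"need b <= min(n, B), got b={b}, n={n}, B={B}")


def hypergeometric_upper_tail(N: int, B: int, n: int, b: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= b).

    Delegates to the survival function of ``scipy.stats.hypergeom``,
    which is evaluated stably for the count ranges of annotation data.
    ``b = 0`` returns exactly 1.
    """
    _validate_counts(N, B, n, b)
    if b == 0:
        return 1.0
    p = float(stats.hypergeom.sf(b - 1, N, B, n))
    return min(max(p, 0.0), 1.0)


def enrich(target: Iterable[str], source: Iterable[str],
           annotations: AnnotationTable,
           p_threshold: float = 1e-3,
           max_term_size: int = 100) -> list[EnrichmentResult]:
    """Enrich a target gene set against a source (background) gene set.

    Target genes outside the source are dropped with a warning. Terms
    with no annotated source gene are skipped. Surviving terms (``p <
    p_threshold`` and ``B <= max_term_size``) are returned sorted by
    ascending p-value, term id breaking ties; MF and BP terms travel in
    the same list and are split by :func:`summarize_enrichment`.
    """
    if p_threshold <= 0 or max_term_size <= 0:
        raise ValidationError("p_threshold and max_term_size must be positive")
    source_set = frozenset(source)
    if not source_set:
        raise ValidationError("source gene set is empty")
    target_set = frozenset(target)
    stray = target_set - source_set
    if stray:
        logger.warning("dropping %d target genes absent from the source set",
                       len(stray))
        target_set = target_set & source_set

    N, n = len(source_set), len(target_set)
    candidates: list[EnrichmentResult] = []
    for term in sorted(annotations.term_to_genes):
        genes = annotations.term_to_genes[term]
        B = len(genes & source_set)
        if B == 0:
            continue
        b = len(genes & target_set)
        p = hypergeometric_upper_tail(N, B, n, b)
        ratio = (b / n) / (B / N) if n > 0 else 0.0
        candidates.append(EnrichmentResult(
            term_id=term, namespace=annotations.term_namespace[term],
            N=N, B=B, n=n, b=b, p_value=p, enrichment_ratio=ratio))

    if candidates:
        qs = stats.false_discovery_control([c.p_value for c in candidates])
        candidates = [replace(c, q_value=float(q))
                      for c, q in zip(candidates, qs)]

    kept = [c for c in candidates
            if c.p_value < p_threshold and c.B <= max_term_size]
    kept.sort(key=lambda r: (r.p_value, r.term_id))
    return kept


def summarize_enrichment(results: Sequence[EnrichmentResult]) -> EnrichmentSummary:
    """Count enriched terms in total and per namespace (total = MF + BP)."""
    mf = sum(1 for r in results if r.namespace == "MF")
    bp = sum(1 for r in results if r.namespace == "BP")
    return EnrichmentSummary(total=mf + bp, mf=mf, bp=bp)
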