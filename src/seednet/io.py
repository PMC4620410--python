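"""Readers and writers for the on-disk formats the pipeline touches.

Supported formats: SIF and two-column TSV edge lists, BLAST tabular
(outfmt 6), TSV tables for seed proteins / GO annotations / term labels,
and the derived report tables. Identifiers are opaque case-sensitive
strings; the only token ever case-folded is the up/down regulation label
(and, optionally, accession ids when ``uppercase_ids`` is requested to
reconcile mixed locus-id case styles).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

VALID_NAMESPACES = frozenset({"MF", "BP"})
VALID_REGULATION = frozenset({"up", "down"})


@dataclass(frozen=True)
class OrthologHit:
    """One BLAST tabular row: a candidate ortholog for a seed protein."""

    query_id: str
    subject_id: str
    e_value: float
    bit_score: float

    def __post_init__(self):
        if not self.query_id or not self.subject_id:
            raise ValidationError("ortholog hit ids must be non-empty")
        if self.e_value < 0:
            raise ValidationError(f"e_value must be >= 0, got {self.e_value}")


@dataclass(frozen=True)
class DapRecord:
    """A differentially accumulated seed protein from the proteomics table."""

    spot_id: str
    protein_name: str
    regulation: str  # "up" | "down"
    query_id: str

    def __post_init__(self):
        if self.regulation not in VALID_REGULATION:
            raise ValidationError(
                f"regulation must be one of {sorted(VALID_REGULATION)}, "
                f"got {self.regulation!r}"
            )


class AnnotationTable:
    """Flat gene -> GO-term annotation table with MF/BP namespaces.

    Duplicate (gene, term) rows collapse to one with a logged warning.
    No term-graph propagation is performed: a gene carries exactly the
    terms listed for it.
    """

    def __init__(self, rows: Iterable[tuple[str, str, str]],
                 term_labels: Mapping[str, str] | None = None):
        seen: dict[tuple[str, str], str] = {}
        namespaces: dict[str, str] = {}
        dup = 0
        for gene, term, ns in rows:
            if ns not in VALID_NAMESPACES:
                raise ValidationError(
                    f"namespace must be MF or BP, got {ns!r} for ({gene}, {term})"
                )
            if (gene, term) in seen:
                dup += 1
                continue
            if term in namespaces and namespaces[term] != ns:
                logger.warning(
                    "term %s seen with conflicting namespaces %s/%s; keeping %s",
                    term, namespaces[term], ns, namespaces[term],
                )
                ns = namespaces[term]
            seen[(gene, term)] = ns
            namespaces[term] = ns
        if dup:
            logger.warning("dropped %d duplicate (gene, term) annotation rows", dup)

        self._rows: tuple[tuple[str, str, str], ...] = tuple(
            sorted((g, t, ns) for (g, t), ns in seen.items())
        )
        self.term_namespace: dict[str, str] = dict(sorted(namespaces.items()))
        t2g: dict[str, set[str]] = {}
        g2t: dict[str, set[str]] = {}
        for g, t, _ in self._rows:
            t2g.setdefault(t, set()).add(g)
            g2t.setdefault(g, set()).add(t)
        self.term_to_genes: dict[str, frozenset[str]] = {
            t: frozenset(s) for t, s in t2g.items()
        }
        self.gene_to_terms: dict[str, frozenset[str]] = {
            g: frozenset(s) for g, s in g2t.items()
        }
        self.term_labels: dict[str, str] = dict(term_labels or {})

    @property
    def rows(self) -> tuple[tuple[str, str, str], ...]:
        return self._rows

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.term_to_genes)

    def __len__(self) -> int:
        return len(self._rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._rows == other._rows and self.term_labels == other.term_labels

    def __repr__(self) -> str:
        return (f"AnnotationTable({len(self._rows)} rows, "
                f"{len(self.term_to_genes)} terms, {len(self.genes)} genes)")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path, dialect: str = "sif",
                   uppercase_ids: bool = False) -> list[tuple[str, str]]:
    """Read raw interaction pairs from a SIF or 2-column TSV edge list.

    SIF rows are ``source relation target [target ...]`` and fan out to one
    pair per target; relation tokens are ignored. No dedup or self-loop
    handling happens here — graph semantics belong to network construction.
    """
    if dialect not in {"sif", "tsv2"}:
        raise ValidationError(f"unknown edge-list dialect {dialect!r}")
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "sif":
                tokens = line.split()
                if len(tokens) < 3:
                    raise ParseError(
                        f"SIF row needs 'source relation target...', got {line!r}",
                        path=path, line=lineno,
                    )
                src, targets = tokens[0], tokens[2:]
                for tgt in targets:
                    pairs.append((src, tgt))
            else:
                fields = line.split("\t")
                if len(fields) != 2 or not fields[0] or not fields[1]:
                    raise ParseError(
                        f"TSV edge row needs exactly two fields, got {line!r}",
                        path=path, line=lineno,
                    )
                pairs.append((fields[0], fields[1]))
    if uppercase_ids:
        pairs = [(a.upper(), b.upper()) for a, b in pairs]
    return pairs


def write_edge_list(edges: Iterable[tuple[str, str]], path,
                    dialect: str = "sif", relation: str = "pp") -> None:
    """Write edges deterministically (each pair sorted, rows sorted)."""
    if dialect not in {"sif", "tsv2"}:
        raise ValidationError(f"unknown edge-list dialect {dialect!r}")
    rows = sorted(tuple(sorted(e)) for e in edges)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in rows:
            if dialect == "sif":
                fh.write(f"{a}\t{relation}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tabular(path, uppercase_ids: bool = False) -> list[OrthologHit]:
    """Read 12-column BLAST outfmt-6 rows into OrthologHit records."""
    hits: list[OrthologHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, got {len(fields)}",
                    path=path, line=lineno,
                )
            try:
                e_value = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric e-value/bit score: {exc}", path=path, line=lineno
                ) from None
            query, subject = fields[0], fields[1]
            if uppercase_ids:
                query, subject = query.upper(), subject.upper()
            hits.append(OrthologHit(query, subject, e_value, bit_score))
    return hits


def write_blast_tabular(hits: Sequence[OrthologHit], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            filler = ["100.000", "100", "0", "0", "1", "100", "1", "100"]
            fh.write("\t".join(
                [h.query_id, h.subject_id, *filler,
                 f"{h.e_value:.3e}", f"{h.bit_score:.1f}"]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_dap_table(path) -> list[DapRecord]:
    """Read the seed-protein table (spot_id, protein_name, regulation, query_id)."""
    records: list[DapRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"spot_id", "protein_name", "regulation", "query_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"seed table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}", path=path, line=1,
            )
        for i, row in enumerate(reader, start=2):
            reg = (row["regulation"] or "").strip().lower()
            if reg not in VALID_REGULATION:
                raise ValidationError(
                    f"row {i} of {path}: regulation must be up/down, "
                    f"got {row['regulation']!r}"
                )
            records.append(DapRecord(row["spot_id"], row["protein_name"],
                                     reg, row["query_id"]))
    return records


def write_dap_table(records: Sequence[DapRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("spot_id\tprotein_name\tregulation\tquery_id\n")
        for r in records:
            fh.write(f"{r.spot_id}\t{r.protein_name}\t{r.regulation}\t{r.query_id}\n")


def read_annotations(path, term_labels: Mapping[str, str] | None = None) -> AnnotationTable:
    """Read a flat (gene_id, term_id, namespace) annotation TSV."""
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "term_id", "namespace"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"annotation table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}", path=path, line=1,
            )
        for i, row in enumerate(reader, start=2):
            ns = (row["namespace"] or "").strip().upper()
            if ns not in VALID_NAMESPACES:
                raise ValidationError(
                    f"row {i} of {path}: namespace must be MF or BP, "
                    f"got {row['namespace']!r}"
                )
            rows.append((row["gene_id"], row["term_id"], ns))
    return AnnotationTable(rows, term_labels=term_labels)


def write_annotations(table: AnnotationTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tterm_id\tnamespace\n")
        for g, t, ns in table.rows:
            fh.write(f"{g}\t{t}\t{ns}\n")


def read_term_labels(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"term_id", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"term-label table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}", path=path, line=1,
            )
        for row in reader:
            labels[row["term_id"]] = row["label"]
    return labels


def write_term_labels(labels: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tlabel\n")
        for term, label in sorted(labels.items()):
            fh.write(f"{term}\t{label}\n")


def read_gene_list(path) -> list[str]:
    """One gene id per line; blanks and # comments skipped."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
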