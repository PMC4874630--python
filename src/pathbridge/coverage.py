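"""Coverage of annotation terms by pathway collections, by set arithmetic.

A term (e.g. a GO term or a metabolome entry) is *covered* by a pathway
collection iff at least one of its annotated entities appears in that
collection.  Comparing two collections A and B over an annotation map yields
the classic partition: only-A, only-B, overlap, combined (their union) and
uncovered, with the identities ``only_a + only_b + overlap = combined`` and
``combined + uncovered = total``.  Coverage is by direct annotation — no
ontology-graph ancestor propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from pathbridge.errors import ValidationError
from pathbridge.gpml import GpmlPathway

GENE_NODE_TYPES = ("GeneProduct", "Protein", "Rna")
METABOLITE_NODE_TYPES = ("Metabolite",)


@dataclass
class AnnotationMap:
    """One category of term → entity-identifier annotations."""

    category: str
    terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, ids in self.terms.items():
            self.terms[term] = set(ids)


def read_annotation_map(path, category: str | None = None) -> AnnotationMap:
    """Read a GAF-like two-column TSV (term, entity) or a GMT file.

    GMT lines are ``term<TAB>description<TAB>entity...``; two-column lines
    are accumulated term-wise.  Lines starting with '#' are skipped.
    """
    terms: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"annotation line needs >= 2 columns: {line!r}")
            term = fields[0]
            ids = fields[1:2] if len(fields) == 2 else fields[2:]
            terms.setdefault(term, set()).update(i for i in ids if i)
    name = category or str(path)
    return AnnotationMap(category=name, terms=terms)


def collect_identifiers(
    pathways: Iterable[GpmlPathway],
    wanted_node_types: Iterable[str] = GENE_NODE_TYPES,
    id_mapping: Mapping[str, str] | None = None,
) -> set[str]:
    """Distinct xref identifiers of the wanted node types across pathways.

    ``id_mapping`` (source id → canonical id) unifies identifier schemes
    from a static two-column mapping file; identifiers without an entry are
    kept as-is.
    """
    wanted = set(wanted_node_types)
    mapping = id_mapping or {}
    out: set[str] = set()
    for p in pathways:
        for n in p.data_nodes:
            if n.node_type in wanted and n.xref is not None:
                ident = n.xref[1]
                out.add(mapping.get(ident, ident))
    return out


def read_id_mapping(path) -> dict[str, str]:
    """Two-column TSV: source identifier → canonical identifier."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"mapping line needs exactly 2 columns: {line!r}")
            out[fields[0]] = fields[1]
    return out


@dataclass
class CategoryCoverage:
    category: str
    label_a: str
    label_b: str
    total_terms: int
    only_a: int
    only_b: int
    overlap: int
    combined: int
    uncovered: int


@dataclass
class CoverageReport:
    categories: list[CategoryCoverage] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": c.category,
                    "total_terms": c.total_terms,
                    f"only_{c.label_a}": c.only_a,
                    f"only_{c.label_b}": c.only_b,
                    "combined": c.combined,
                    "overlap": c.overlap,
                    "uncovered": c.uncovered,
                }
                for c in self.categories
            ]
        )


def compute_coverage(
    a: set[str],
    b: set[str],
    ann: AnnotationMap,
    label_a: str = "A",
    label_b: str = "B",
) -> CategoryCoverage:
    """Partition the map's terms by which collection(s) cover them."""
    only_a = only_b = overlap = 0
    for ids in ann.terms.values():
        in_a = not ids.isdisjoint(a)
        in_b = not ids.isdisjoint(b)
        if in_a and in_b:
            overlap += 1
        elif in_a:
            only_a += 1
        elif in_b:
            only_b += 1
    total = len(ann.terms)
    combined = only_a + only_b + overlap
    return CategoryCoverage(
        category=ann.category,
        label_a=label_a,
        label_b=label_b,
        total_terms=total,
        only_a=only_a,
        only_b=only_b,
        overlap=overlap,
        combined=combined,
        uncovered=total - combined,
    )


def coverage_report(
    a: set[str],
    b: set[str],
    maps: Iterable[AnnotationMap],
    label_a: str = "A",
    label_b: str = "B",
) -> CoverageReport:
    return CoverageReport(
        categories=[compute_coverage(a, b, m, label_a, label_b) for m in maps]
    )
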