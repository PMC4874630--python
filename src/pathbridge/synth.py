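"""Seeded generators for source pathways, expression tables and annotations.

Everything downstream is exercised on fixtures from this module: random
reaction-centric pathways (with nested complexes up to depth 2, role-typed
reaction branches, compartments and notes), expression tables with a planted
enrichment signal, and annotation maps for coverage arithmetic.  Each
generator also returns a ground-truth record sufficient to recompute the
oracles in the other modules without re-parsing any output.

All randomness flows through ``numpy.random.default_rng`` on an explicit
seed, so outputs are reproducible byte-for-byte from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pathbridge.convert import annotate
from pathbridge.coverage import AnnotationMap
from pathbridge.enrichment import DataTable
from pathbridge.errors import DomainError
from pathbridge.source_model import (
    ReactionBranch,
    SourceCompartment,
    SourceEntity,
    SourceNote,
    SourcePathway,
    SourceReaction,
    Xref,
    iter_leaf_components,
)

import pandas as pd


@dataclass
class ExpressionSpec:
    """Mixture model for the planted-signal expression table.

    Signal genes (members of the planted pathway) qualify under
    ``abs([logFC]) > 1 AND [P.value] < 0.05`` with probability
    ``fraction_signal``; background genes with probability
    ``background_rate``.  Qualifying rows draw |logFC| around ``effect``
    (sd 0.25, random sign) and P.value uniform below 0.05; non-qualifying
    rows draw logFC around 0 and a P.value safely above the cutoff.
    """

    n_extra_genes: int = 200
    fraction_signal: float = 0.8
    background_rate: float = 0.1
    effect: float = 2.0

    def validate(self) -> None:
        for name in ("fraction_signal", "background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        if self.n_extra_genes < 0:
            raise DomainError("n_extra_genes must be >= 0")


@dataclass
class AnnotationSpec:
    n_terms: int = 50
    mean_genes_per_term: float = 4.0

    def validate(self) -> None:
        if self.n_terms < 0:
            raise DomainError("n_terms must be >= 0")
        if self.mean_genes_per_term <= 0:
            raise DomainError("mean_genes_per_term must be positive")


@dataclass
class FixtureSpec:
    n_entities: int = 30
    n_reactions: int = 10
    p_complex: float = 0.2
    mean_components: float = 3.0
    n_compartments: int = 2
    p_nested: float = 0.3  # chance a container includes another container
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)

    def validate(self) -> None:
        if not 0.0 <= self.p_complex <= 1.0:
            raise DomainError(f"p_complex must be in [0, 1], got {self.p_complex}")
        if not 0.0 <= self.p_nested <= 1.0:
            raise DomainError(f"p_nested must be in [0, 1], got {self.p_nested}")
        for name in ("n_entities", "n_reactions", "n_compartments"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.mean_components < 1:
            raise DomainError("mean_components must be >= 1")
        n_containers = int(round(self.p_complex * self.n_entities))
        if n_containers > 0 and self.n_entities - n_containers < 1:
            raise DomainError("spec leaves no non-container entities for components")
        if self.n_reactions > 0 and self.n_entities - n_containers < 2:
            raise DomainError("reactions need at least two participant entities")
        self.expression.validate()
        self.annotation.validate()


@dataclass
class PathwayTruth:
    """Generator bookkeeping consumed by the test oracles."""

    entity_classes: dict[str, str] = field(default_factory=dict)
    container_leaves: dict[str, list[str]] = field(default_factory=dict)
    branch_triples: list[tuple[str, str, str]] = field(default_factory=list)
    # identifier the annotation step will select, per leaf entity
    leaf_identifiers: dict[str, str] = field(default_factory=dict)

    def gene_identifiers(self) -> set[str]:
        return set(self.leaf_identifiers.values())


_LEAF_CLASSES = ("protein", "small_molecule", "rna", "gene", "process_node")
_LEAF_WEIGHTS = (0.55, 0.2, 0.1, 0.1, 0.05)

_XREF_SOURCE = {
    "protein": "UniProt",
    "small_molecule": "ChEBI",
    "rna": "Ensembl",
    "gene": "Ensembl",
    "process_node": "Reactome",
}


def gen_source_pathway(
    spec: FixtureSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    name: str = "Synthetic pathway",
    id_offset: int = 0,
) -> tuple[SourcePathway, PathwayTruth]:
    """Generate a valid random source pathway plus its ground truth.

    ``id_offset`` shifts the identifier space so pathways generated in a
    collection carry disjoint database identifiers.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = PathwayTruth()

    n_containers = int(round(spec.p_complex * spec.n_entities))
    n_leaves = spec.n_entities - n_containers

    entities: list[SourceEntity] = []
    ident = id_offset

    # compartments first: two side-by-side rectangles (or more)
    compartments = [
        SourceCompartment(
            compartment_id=f"C{i + 1}",
            name=f"compartment {i + 1}",
            geometry=(40.0 + 440.0 * i, 40.0, 400.0, 500.0),
            membrane=bool(rng.random() < 0.5),
        )
        for i in range(spec.n_compartments)
    ]

    def inside(cx: float, cy: float) -> str | None:
        for c in compartments:
            x, y, w, h = c.geometry
            if x <= cx <= x + w and y <= cy <= y + h:
                return c.compartment_id
        return None

    leaves: list[SourceEntity] = []
    for i in range(n_leaves):
        cls = str(rng.choice(_LEAF_CLASSES, p=_LEAF_WEIGHTS))
        if i < 2 and cls == "process_node":
            # reactions and containers need at least two molecular leaves
            cls = "protein"
        ident += 1
        source = _XREF_SOURCE[cls]
        primary = {
            "UniProt": f"P{ident:05d}",
            "ChEBI": f"CHEBI:{ident}",
            "Ensembl": f"ENSG{ident:011d}",
            "Reactome": f"R-HSA-{ident}",
        }[source]
        xrefs = [Xref(source, primary)]
        if source != "Reactome":
            if rng.random() < 0.1:
                # exercise the Reactome-identifier fallback
                xrefs = [Xref("Reactome", f"R-HSA-{ident}")]
            else:
                xrefs.append(Xref("Reactome", f"R-HSA-{ident}"))
        cx = float(np.round(rng.uniform(80.0, 860.0), 1))
        cy = float(np.round(rng.uniform(80.0, 500.0), 1))
        e = SourceEntity(
            entity_id=f"E{i + 1}",
            display_name=f"{cls[:3].upper()}{ident}",
            entity_class=cls,
            geometry=(cx, cy, 80.0, 25.0),
            compartment_id=inside(cx, cy),
            xrefs=xrefs,
            literature=[str(20000000 + ident)] if rng.random() < 0.3 else [],
        )
        leaves.append(e)
        entities.append(e)
        truth.entity_classes[e.entity_id] = cls
        chosen, _ = annotate(e)
        if chosen is not None and cls != "process_node":
            truth.leaf_identifiers[e.entity_id] = chosen[1]

    member_pool = [e for e in leaves if e.entity_class != "process_node"]
    containers: list[SourceEntity] = []
    for i in range(n_containers):
        ident += 1
        cls = "complex" if rng.random() < 0.6 else "entity_set"
        k = 1 + int(rng.poisson(max(spec.mean_components - 1, 0)))
        k = min(k, len(member_pool))
        k = max(k, 1)
        chosen_members = list(rng.choice(len(member_pool), size=k, replace=False))
        components = [
            (member_pool[j].entity_id, int(1 + (rng.random() < 0.2)))
            for j in chosen_members
        ]
        # depth-2 nesting: only containers made purely of leaves may be
        # absorbed, which bounds the nesting depth at 2
        flat_inners = [
            c for c in containers
            if all(truth.entity_classes[m] not in ("complex", "entity_set")
                   for m, _ in c.components)
        ]
        if flat_inners and rng.random() < spec.p_nested:
            inner = flat_inners[int(rng.integers(len(flat_inners)))]
            if not any(m == inner.entity_id for m, _ in components):
                components.append((inner.entity_id, 1))
        cx = float(np.round(rng.uniform(80.0, 860.0), 1))
        cy = float(np.round(rng.uniform(80.0, 500.0), 1))
        e = SourceEntity(
            entity_id=f"X{i + 1}",
            display_name=f"{'CPX' if cls == 'complex' else 'SET'}{ident}",
            entity_class=cls,
            geometry=(cx, cy, 100.0, 40.0),
            compartment_id=inside(cx, cy),
            xrefs=[Xref("Reactome", f"R-HSA-{ident}")],
            components=components,
        )
        # nesting may not create depth > 2: only first-wave containers are
        # eligible inners, and they hold only leaves, so this is depth <= 2
        containers.append(e)
        entities.append(e)
        truth.entity_classes[e.entity_id] = cls

    pathway = SourcePathway(
        name=name,
        organism="Homo sapiens",
        source_version="54",
        authors=["Synthetic Author"],
        maintainers=[("Synthetic Maintainer", "maintainer@example.org")],
        entities=entities,
        compartments=compartments,
        notes=(
            [SourceNote(text="synthetic note", position=(60.0, 560.0))]
            if rng.random() < 0.5
            else []
        ),
        xref=Xref("Reactome", f"R-HSA-{id_offset + 999999}"),
    )

    for c in containers:
        seen: list[str] = []
        for member_id, _ in iter_leaf_components(pathway, c):
            if member_id not in seen:
                seen.append(member_id)
        truth.container_leaves[c.entity_id] = seen

    participants = [e for e in entities if e.entity_class != "process_node"]
    reactions: list[SourceReaction] = []
    rxn_types = ("transition", "binding", "dissociation", "omitted", "uncertain")
    rxn_weights = (0.7, 0.15, 0.05, 0.05, 0.05)
    for i in range(spec.n_reactions):
        rid = f"R{i + 1}"
        n_in = 1 + int(rng.random() < 0.3)
        n_out = 1 + int(rng.random() < 0.2)
        n_cat = int(rng.random() < 0.5)
        n_act = int(rng.random() < 0.2)
        n_inh = int(rng.random() < 0.2)
        total = n_in + n_out + n_cat + n_act + n_inh
        total = min(total, len(participants))
        picks = rng.choice(len(participants), size=total, replace=False)
        chosen = [participants[j].entity_id for j in picks]
        roles = (
            ["input"] * n_in + ["output"] * n_out + ["catalyst"] * n_cat
            + ["activator"] * n_act + ["inhibitor"] * n_inh
        )[:total]
        if "input" not in roles and "output" not in roles:  # pragma: no cover
            roles[0] = "input"
        branches = [
            ReactionBranch(role=role, entity_id=eid, stoichiometry=int(1 + (rng.random() < 0.15)))
            for role, eid in zip(roles, chosen)
        ]
        pts = [
            (float(np.round(rng.uniform(100.0, 800.0), 1)), float(np.round(rng.uniform(100.0, 480.0), 1)))
            for _ in range(2 + int(rng.random() < 0.2))
        ]
        ident += 1
        reactions.append(
            SourceReaction(
                reaction_id=rid,
                reaction_type=str(rng.choice(rxn_types, p=rxn_weights)),
                branches=branches,
                backbone_points=pts,
                xrefs=[Xref("Reactome", f"R-HSA-{ident}")],
                literature=[str(21000000 + ident)] if rng.random() < 0.3 else [],
            )
        )
        truth.branch_triples.extend((rid, b.role, b.entity_id) for b in branches)
    pathway.reactions = reactions
    return pathway, truth


def gen_pathway_collection(
    spec: FixtureSpec,
    n_pathways: int,
    seed: int,
    name_prefix: str = "Synthetic pathway",
) -> list[tuple[SourcePathway, PathwayTruth]]:
    """Generate a collection with disjoint identifier spaces per pathway."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_pathways):
        out.append(
            gen_source_pathway(
                spec,
                rng=rng,
                name=f"{name_prefix} {i + 1:03d}",
                id_offset=10000 * (i + 1),
            )
        )
    return out


def gen_expression_table(
    spec: ExpressionSpec,
    gene_sets: dict[str, set[str]],
    planted: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DataTable, dict[str, bool]]:
    """Expression statistics (logFC, P.value) with a planted pathway signal.

    Returns the table and the ground-truth qualification of every gene under
    ``abs([logFC]) > 1 AND [P.value] < 0.05``.
    """
    spec.validate()
    if planted not in gene_sets:
        raise DomainError(f"planted pathway {planted!r} not in the collection")
    if rng is None:
        rng = np.random.default_rng(seed)
    all_genes: list[str] = sorted(set().union(*gene_sets.values()) if gene_sets else set())
    extra = [f"BG{j + 1:05d}" for j in range(spec.n_extra_genes)]
    planted_set = gene_sets[planted]

    records = []
    truth: dict[str, bool] = {}
    for gene in all_genes + extra:
        p_qual = spec.fraction_signal if gene in planted_set else spec.background_rate
        qualifies = bool(rng.random() < p_qual)
        if qualifies:
            logfc = 0.0
            while abs(logfc) <= 1.0:
                logfc = rng.normal(spec.effect, 0.25) * (1 if rng.random() < 0.5 else -1)
            pval = float(rng.uniform(0.0005, 0.0495))
        else:
            # P.value safely above the cutoff guarantees non-qualification
            logfc = rng.normal(0.0, 0.25)
            pval = float(rng.uniform(0.055, 1.0))
        truth[gene] = qualifies
        records.append(
            {"id": gene, "logFC": round(float(logfc), 4), "P.value": round(pval, 5)}
        )
    frame = pd.DataFrame.from_records(records)
    return DataTable(frame=frame, id_column="id"), truth


def gen_annotation_map(
    spec: AnnotationSpec,
    id_pool: list[str],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    category: str = "synthetic",
) -> AnnotationMap:
    """Random term → identifier map over a given identifier pool."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = sorted(id_pool)
    if not pool and spec.n_terms > 0:
        raise DomainError("cannot annotate terms from an empty identifier pool")
    terms: dict[str, set[str]] = {}
    for t in range(spec.n_terms):
        k = 1 + int(rng.poisson(max(spec.mean_genes_per_term - 1, 0)))
        k = min(k, len(pool))
        chosen = rng.choice(len(pool), size=k, replace=False)
        terms[f"T:{t + 1:07d}"] = {pool[j] for j in chosen}
    return AnnotationMap(category=category, terms=terms)
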