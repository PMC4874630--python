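"""Reaction-centric source pathway model and its JSON fixture format.

This module defines an in-memory model of a Reactome-style pathway: entities
(proteins, small molecules, RNAs, genes, process nodes, complexes, entity
sets), reactions modelled as hyperedges with role-typed branches (input,
output, catalyst, activator, inhibitor), compartments, free-text notes and
cross-references.  Production Reactome content lives in a relational database
behind a Java API; this package instead reads the same structure from a JSON
document (schema shipped in ``pathbridge/schemas/source_pathway.schema.json``)
so that conversion and analysis are testable at desk scale, and a real export
can be adapted to the documented format.

Coordinates are diagram units with the origin at the top-left and y
increasing downward, matching GPML's convention, so no axis flip is needed
during conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

from pathbridge.errors import (
    ParseError,
    ReferentialIntegrityError,
    ValidationError,
)

DATA_SOURCES = ("UniProt", "ChEBI", "Reactome", "Ensembl", "HMDB", "PubMed", "Other")

ENTITY_CLASSES = (
    "protein",
    "small_molecule",
    "rna",
    "gene",
    "process_node",
    "complex",
    "entity_set",
    "other",
)

CONTAINER_CLASSES = ("complex", "entity_set")

BRANCH_ROLES = ("input", "output", "catalyst", "activator", "inhibitor")

REACTION_TYPES = ("transition", "binding", "dissociation", "omitted", "uncertain")


@dataclass(frozen=True)
class Xref:
    """A cross-reference: data source name plus identifier."""

    data_source: str
    identifier: str

    def __post_init__(self) -> None:
        if self.data_source not in DATA_SOURCES:
            raise ValidationError(
                f"xref data_source {self.data_source!r} not in {DATA_SOURCES}"
            )
        if not self.identifier or self.identifier != self.identifier.strip():
            raise ValidationError(
                f"xref identifier {self.identifier!r} must be nonempty with no "
                "surrounding whitespace"
            )


@dataclass
class SourceEntity:
    """A pathway participant, including complex / entity-set containers.

    ``components`` is nonempty only for containers (entity_class ``complex``
    or ``entity_set``) and holds ``(member_entity_id, stoichiometry)`` pairs.
    For entity sets the members are alternatives playing the same role, so
    their stoichiometry is carried but ignored downstream.
    """

    entity_id: str
    display_name: str
    entity_class: str
    geometry: tuple[float, float, float, float]  # center_x, center_y, w, h
    compartment_id: str | None = None
    xrefs: list[Xref] = field(default_factory=list)
    components: list[tuple[str, int]] = field(default_factory=list)
    literature: list[str] = field(default_factory=list)

    @property
    def is_container(self) -> bool:
        return self.entity_class in CONTAINER_CLASSES

    def primary_xref(self) -> Xref | None:
        return self.xrefs[0] if self.xrefs else None


@dataclass
class ReactionBranch:
    role: str
    entity_id: str
    stoichiometry: int = 1


@dataclass
class SourceReaction:
    """A hyperedge: one backbone polyline with role-typed branches."""

    reaction_id: str
    reaction_type: str
    branches: list[ReactionBranch]
    backbone_points: list[tuple[float, float]]
    xrefs: list[Xref] = field(default_factory=list)
    literature: list[str] = field(default_factory=list)

    def branches_with_role(self, role: str) -> list[ReactionBranch]:
        return [b for b in self.branches if b.role == role]


@dataclass
class SourceCompartment:
    compartment_id: str
    name: str
    geometry: tuple[float, float, float, float]  # x, y, w, h (top-left anchored)
    membrane: bool = False


@dataclass
class SourceNote:
    text: str
    position: tuple[float, float]


@dataclass
class SourcePathway:
    name: str
    organism: str
    source_version: str = ""
    authors: list[str] = field(default_factory=list)
    maintainers: list[tuple[str, str]] = field(default_factory=list)  # (name, email)
    entities: list[SourceEntity] = field(default_factory=list)
    reactions: list[SourceReaction] = field(default_factory=list)
    compartments: list[SourceCompartment] = field(default_factory=list)
    notes: list[SourceNote] = field(default_factory=list)
    xref: Xref | None = None

    def entity_index(self) -> dict[str, SourceEntity]:
        return {e.entity_id: e for e in self.entities}

    def containers(self) -> list[SourceEntity]:
        return [e for e in self.entities if e.is_container]


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the offending element id and the rule name."""

    element_id: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.element_id}] {self.rule}: {self.message}"


def validate_source_pathway(p: SourcePathway) -> list[Violation]:
    """Check every model invariant; return violations instead of raising.

    An empty list means the pathway is valid.  Each violation names the
    element id and the rule it breaks, so callers can report precisely.
    """
    out: list[Violation] = []
    index: dict[str, SourceEntity] = {}
    for e in p.entities:
        if e.entity_id in index:
            out.append(Violation(e.entity_id, "unique-entity-id", "duplicate entity_id"))
        index[e.entity_id] = e

    for e in p.entities:
        if e.entity_class not in ENTITY_CLASSES:
            out.append(
                Violation(e.entity_id, "entity-class", f"unknown class {e.entity_class!r}")
            )
        _, _, w, h = e.geometry
        if w <= 0 or h <= 0:
            out.append(
                Violation(e.entity_id, "positive-geometry", f"width/height ({w}, {h})")
            )
        if e.components and not e.is_container:
            out.append(
                Violation(
                    e.entity_id,
                    "components-on-non-container",
                    f"class {e.entity_class!r} must not list components",
                )
            )
        if e.is_container and not e.components:
            out.append(
                Violation(e.entity_id, "empty-container", "complex/entity_set needs components")
            )
        for member_id, stoich in e.components:
            if member_id not in index:
                out.append(
                    Violation(
                        e.entity_id,
                        "dangling-component",
                        f"component {member_id!r} not in pathway",
                    )
                )
            if stoich < 1:
                out.append(
                    Violation(
                        e.entity_id,
                        "non-positive-stoichiometry",
                        f"component {member_id!r} stoichiometry {stoich}",
                    )
                )
        if e.compartment_id is not None and e.compartment_id not in {
            c.compartment_id for c in p.compartments
        }:
            out.append(
                Violation(
                    e.entity_id,
                    "dangling-compartment",
                    f"compartment {e.compartment_id!r} not in pathway",
                )
            )

    seen_rxn: set[str] = set()
    for r in p.reactions:
        if r.reaction_id in seen_rxn:
            out.append(Violation(r.reaction_id, "unique-reaction-id", "duplicate reaction_id"))
        seen_rxn.add(r.reaction_id)
        if r.reaction_type not in REACTION_TYPES:
            out.append(
                Violation(r.reaction_id, "reaction-type", f"unknown type {r.reaction_type!r}")
            )
        if len(r.backbone_points) < 2:
            out.append(
                Violation(r.reaction_id, "backbone-length", "needs at least two points")
            )
        if not any(b.role in ("input", "output") for b in r.branches):
            out.append(
                Violation(r.reaction_id, "no-substrate", "needs an input or output branch")
            )
        for b in r.branches:
            if b.role not in BRANCH_ROLES:
                out.append(
                    Violation(r.reaction_id, "branch-role", f"unknown role {b.role!r}")
                )
            if b.stoichiometry < 1:
                out.append(
                    Violation(
                        r.reaction_id,
                        "non-positive-stoichiometry",
                        f"branch {b.entity_id!r} stoichiometry {b.stoichiometry}",
                    )
                )
            target = index.get(b.entity_id)
            if target is None:
                out.append(
                    Violation(
                        r.reaction_id,
                        "dangling-branch",
                        f"branch entity {b.entity_id!r} not in pathway",
                    )
                )
            elif target.entity_class == "process_node":
                out.append(
                    Violation(
                        r.reaction_id,
                        "process-node-participant",
                        f"branch entity {b.entity_id!r} is a process node",
                    )
                )

    for c in p.compartments:
        _, _, w, h = c.geometry
        if w <= 0 or h <= 0:
            out.append(
                Violation(c.compartment_id, "positive-geometry", f"width/height ({w}, {h})")
            )
    for i, n in enumerate(p.notes):
        if not n.text:
            out.append(Violation(f"note[{i}]", "empty-note", "note text must be nonempty"))
    return out


# ---------------------------------------------------------------------------
# JSON reading / writing


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ValidationError(f"{where}: missing required field {key!r}")
    return d[key]


def _xref_from_json(d: dict, where: str) -> Xref:
    return Xref(_require(d, "dataSource", where), _require(d, "identifier", where))


def _entity_from_json(d: dict) -> SourceEntity:
    eid = _require(d, "id", "entity")
    where = f"entity {eid!r}"
    geom = _require(d, "geometry", where)
    try:
        geometry = (
            float(geom["centerX"]),
            float(geom["centerY"]),
            float(geom["width"]),
            float(geom["height"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: bad geometry object: {exc}") from exc
    components = [
        (str(c["member"]), int(c.get("stoichiometry", 1)))
        for c in d.get("components", [])
    ]
    return SourceEntity(
        entity_id=str(eid),
        display_name=str(_require(d, "displayName", where)),
        entity_class=str(_require(d, "class", where)),
        geometry=geometry,
        compartment_id=d.get("compartment"),
        xrefs=[_xref_from_json(x, where) for x in d.get("xrefs", [])],
        components=components,
        literature=[str(x) for x in d.get("literature", [])],
    )


def _reaction_from_json(d: dict) -> SourceReaction:
    rid = _require(d, "id", "reaction")
    where = f"reaction {rid!r}"
    branches = [
        ReactionBranch(
            role=str(_require(b, "role", where)),
            entity_id=str(_require(b, "entity", where)),
            stoichiometry=int(b.get("stoichiometry", 1)),
        )
        for b in _require(d, "branches", where)
    ]
    points = [(float(x), float(y)) for x, y in _require(d, "backbonePoints", where)]
    return SourceReaction(
        reaction_id=str(rid),
        reaction_type=str(d.get("type", "transition")),
        branches=branches,
        backbone_points=points,
        xrefs=[_xref_from_json(x, where) for x in d.get("xrefs", [])],
        literature=[str(x) for x in d.get("literature", [])],
    )


def source_pathway_from_dict(doc: dict) -> SourcePathway:
    """Build and validate a SourcePathway from a parsed JSON document."""
    if not isinstance(doc, dict):
        raise ValidationError("top level of pathway document must be a JSON object")
    pathway = SourcePathway(
        name=str(_require(doc, "name", "pathway")),
        organism=str(_require(doc, "organism", "pathway")),
        source_version=str(doc.get("sourceVersion", "")),
        authors=[str(a) for a in doc.get("authors", [])],
        maintainers=[(str(m["name"]), str(m.get("email", ""))) for m in doc.get("maintainers", [])],
        entities=[_entity_from_json(e) for e in doc.get("entities", [])],
        reactions=[_reaction_from_json(r) for r in doc.get("reactions", [])],
        compartments=[
            SourceCompartment(
                compartment_id=str(_require(c, "id", "compartment")),
                name=str(_require(c, "name", "compartment")),
                geometry=(
                    float(c["geometry"]["x"]),
                    float(c["geometry"]["y"]),
                    float(c["geometry"]["width"]),
                    float(c["geometry"]["height"]),
                ),
                membrane=bool(c.get("membrane", False)),
            )
            for c in doc.get("compartments", [])
        ],
        notes=[
            SourceNote(text=str(_require(n, "text", "note")), position=(float(n["position"][0]), float(n["position"][1])))
            for n in doc.get("notes", [])
        ],
        xref=_xref_from_json(doc["xref"], "pathway") if doc.get("xref") else None,
    )
    violations = validate_source_pathway(pathway)
    if violations:
        first = violations[0]
        exc_type = (
            ReferentialIntegrityError
            if first.rule.startswith("dangling")
            else ValidationError
        )
        raise exc_type(
            f"{len(violations)} invariant violation(s); first: {first}"
        )
    return pathway


def read_source_pathway(path) -> SourcePathway:
    """Read a pathway JSON document, enforcing every model invariant.

    Raises ParseError (with the byte offset) on malformed JSON,
    ValidationError naming the failing field on schema problems, and
    ReferentialIntegrityError naming the id on dangling references.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"malformed JSON at byte offset {exc.pos} (line {exc.lineno}, "
            f"column {exc.colno}): {exc.msg}"
        ) from exc
    return source_pathway_from_dict(doc)


def source_pathway_to_dict(p: SourcePathway) -> dict:
    def xref(x: Xref) -> dict:
        return {"dataSource": x.data_source, "identifier": x.identifier}

    doc: dict = {
        "name": p.name,
        "organism": p.organism,
        "sourceVersion": p.source_version,
        "authors": list(p.authors),
        "maintainers": [{"name": n, "email": e} for n, e in p.maintainers],
        "entities": [
            {
                "id": e.entity_id,
                "displayName": e.display_name,
                "class": e.entity_class,
                "geometry": {
                    "centerX": e.geometry[0],
                    "centerY": e.geometry[1],
                    "width": e.geometry[2],
                    "height": e.geometry[3],
                },
                **({"compartment": e.compartment_id} if e.compartment_id else {}),
                "xrefs": [xref(x) for x in e.xrefs],
                "components": [
                    {"member": m, "stoichiometry": s} for m, s in e.components
                ],
                "literature": list(e.literature),
            }
            for e in p.entities
        ],
        "reactions": [
            {
                "id": r.reaction_id,
                "type": r.reaction_type,
                "branches": [
                    {"role": b.role, "entity": b.entity_id, "stoichiometry": b.stoichiometry}
                    for b in r.branches
                ],
                "backbonePoints": [[x, y] for x, y in r.backbone_points],
                "xrefs": [xref(x) for x in r.xrefs],
                "literature": list(r.literature),
            }
            for r in p.reactions
        ],
        "compartments": [
            {
                "id": c.compartment_id,
                "name": c.name,
                "geometry": {
                    "x": c.geometry[0],
                    "y": c.geometry[1],
                    "width": c.geometry[2],
                    "height": c.geometry[3],
                },
                "membrane": c.membrane,
            }
            for c in p.compartments
        ],
        "notes": [{"text": n.text, "position": [n.position[0], n.position[1]]} for n in p.notes],
    }
    if p.xref is not None:
        doc["xref"] = xref(p.xref)
    return doc


def write_source_pathway(p: SourcePathway, path) -> None:
    """Serialize a pathway to the JSON fixture format (read_source_pathway inverse)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(source_pathway_to_dict(p), fh, indent=2, sort_keys=False)
        fh.write("\n")


def iter_leaf_components(
    p: SourcePathway, container: SourceEntity, _depth: int = 0
) -> Iterator[tuple[str, int]]:
    """Recursively expand a container to its non-container (leaf) members.

    Nested complexes contribute their own members; entity-set member
    stoichiometry is reported as given but ignored by the converter.
    Depth is bounded by the pathway size to guard against cyclic membership.
    """
    if _depth > len(p.entities):
        raise ValidationError(f"cyclic container membership at {container.entity_id!r}")
    index = p.entity_index()
    for member_id, stoich in container.components:
        member = index[member_id]
        if member.is_container:
            yield from iter_leaf_components(p, member, _depth + 1)
        else:
            yield member_id, stoich
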