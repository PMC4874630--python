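"""Reaction-centric pathway → GPML conversion.

The conversion follows three steps: (i) create a GPML pathway carrying the
source metadata (data source, source version, organism, authors, maintainers);
(ii) convert the elements — entities to typed DataNodes, complexes and entity
sets to Groups with an in-diagram placeholder node, hyperedge reactions to a
backbone interaction plus per-branch interactions attached via anchors,
compartments to Groups with a labelled rectangle, notes to Labels, and the
flattened complex/entity-set components to a deduplicated grid at the bottom
of the diagram; (iii) annotate everything — proteins UniProt-first,
metabolites ChEBI-first, falling back to Reactome identifiers, while
interactions, complexes and pathway links carry Reactome identifiers only,
and every PubMed literature reference is carried over.

Conversion is deterministic: graph ids come from per-kind counters
(``dn_0001``, ``in_0001``, ...), so converting the same pathway twice yields
byte-identical GPML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pathbridge.errors import ContractError, ReferentialIntegrityError, ValidationError
from pathbridge.gpml import (
    GpmlAnchor,
    GpmlDataNode,
    GpmlGroup,
    GpmlInteraction,
    GpmlLabel,
    GpmlPathway,
    GpmlPoint,
    GpmlShape,
)
from pathbridge.source_model import (
    SourceEntity,
    SourcePathway,
    SourceReaction,
    Xref,
    iter_leaf_components,
    validate_source_pathway,
)

log = logging.getLogger(__name__)

ENTITY_CLASS_TO_NODE_TYPE = {
    "protein": "Protein",
    "small_molecule": "Metabolite",
    "rna": "Rna",
    "gene": "GeneProduct",
    "process_node": "Pathway",
    "other": "Unknown",
}

# Annotation preference per entity class; first matching source wins.
DEFAULT_PREFERRED_SOURCES = {
    "protein": ("UniProt", "Reactome"),
    "small_molecule": ("ChEBI", "Reactome"),
    "rna": ("Ensembl", "UniProt", "Reactome"),
    "gene": ("Ensembl", "Reactome"),
    "process_node": ("Reactome",),
    "complex": ("Reactome",),
    "entity_set": ("Reactome",),
    "other": ("Reactome",),
    "reaction": ("Reactome",),
}

BACKBONE_ARROWS = {
    "transition": "mim_conversion",
    "binding": "mim_binding",
    "dissociation": "arrow",
    "omitted": "arrow",
    "uncertain": "arrow",
}

MODIFIER_ARROWS = {
    "catalyst": "mim_catalysis",
    "activator": "mim_stimulation",
    "inhibitor": "t_bar",
}

COMPONENT_MAP_COMMENT = "ComplexComponents"
REACTION_ID_COMMENT = "ReactionId"


@dataclass
class ComponentGrid:
    columns: int = 10
    cell_width: float = 100.0
    cell_height: float = 40.0
    top_margin: float = 60.0

    def __post_init__(self) -> None:
        if self.columns < 1:
            raise ValidationError("component grid needs at least one column")


@dataclass
class ConversionOptions:
    draw_components: bool = True
    component_grid: ComponentGrid = field(default_factory=ComponentGrid)
    preferred_sources: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PREFERRED_SOURCES)
    )


@dataclass
class ComplexComponentMap:
    """Links container graph ids to their flattened component node ids."""

    mapping: dict[str, list[str]] = field(default_factory=dict)

    def containers_of(self, component_id: str) -> list[str]:
        return [c for c, members in self.mapping.items() if component_id in members]

    @classmethod
    def from_gpml(cls, p: GpmlPathway) -> "ComplexComponentMap":
        """Recover the map from the comments the converter records."""
        mapping: dict[str, list[str]] = {}
        for n in p.data_nodes:
            for source, text in n.comments:
                if source == COMPONENT_MAP_COMMENT:
                    mapping[n.graph_id] = [t for t in text.split(",") if t]
        return cls(mapping)


@dataclass
class ConversionReport:
    """Bookkeeping produced alongside the GPML document."""

    node_ids: dict[str, str] = field(default_factory=dict)  # entity_id -> graph_id
    group_ids: dict[str, str] = field(default_factory=dict)  # container entity_id -> group_id
    component_map: ComplexComponentMap = field(default_factory=ComplexComponentMap)
    component_entities: dict[str, str] = field(default_factory=dict)  # comp node id -> entity_id


class _IdGen:
    def __init__(self) -> None:
        self._counters: dict[str, int] = {}

    def next(self, prefix: str) -> str:
        n = self._counters.get(prefix, 0) + 1
        self._counters[prefix] = n
        return f"{prefix}_{n:04d}"


def map_entity_class(entity_class: str) -> str:
    """Map a source entity class to the GPML data-node type.

    Containers (complex / entity_set) become Groups, not typed nodes, so
    passing one here is a caller error pointing at ``convert_container``.
    """
    if entity_class in ("complex", "entity_set"):
        raise ContractError(
            f"{entity_class!r} maps to a Group; use convert_container instead"
        )
    try:
        return ENTITY_CLASS_TO_NODE_TYPE[entity_class]
    except KeyError:
        raise ContractError(f"unknown entity class {entity_class!r}") from None


def annotate(
    element: SourceEntity | SourceReaction,
    preferred_sources: dict[str, tuple[str, ...]] | None = None,
) -> tuple[tuple[str, str] | None, list[str]]:
    """Pick the element's database annotation and carry its literature.

    Proteins prefer UniProt, metabolites ChEBI, with Reactome as fallback;
    reactions, containers and pathway links take Reactome identifiers only.
    Returns ``(xref, pubmed_ids)``; the xref is None (with a logged note)
    when nothing acceptable is present.
    """
    prefs = preferred_sources or DEFAULT_PREFERRED_SOURCES
    if isinstance(element, SourceReaction):
        kind, xrefs, label = "reaction", element.xrefs, element.reaction_id
    else:
        kind, xrefs, label = element.entity_class, element.xrefs, element.entity_id
    order = prefs.get(kind, ("Reactome",))
    chosen: Xref | None = None
    for source in order:
        for x in xrefs:
            if x.data_source == source:
                chosen = x
                break
        if chosen:
            break
    if chosen is None:
        log.info("no acceptable xref for %s %r (sources tried: %s)", kind, label, order)
        return None, list(element.literature)
    return (chosen.data_source, chosen.identifier), list(element.literature)


def convert_container(
    e: SourceEntity,
    p: SourcePathway,
    idgen: _IdGen | None = None,
    preferred_sources: dict[str, tuple[str, ...]] | None = None,
) -> tuple[GpmlGroup, GpmlDataNode, list[str]]:
    """Convert a complex or entity set to a Group plus placeholder node.

    Complexes take group style ``Complex``, entity sets ``Group``.  The
    placeholder is a Complex-typed data node carrying the container's label
    and Reactome annotation; component nodes are emitted separately by
    ``flatten_components``.  Also returns the recursively expanded leaf
    member entity ids (the future ComplexComponentMap entry).
    """
    if not e.is_container:
        raise ContractError(f"{e.entity_id!r} is not a complex or entity set")
    if not e.components:
        raise ValidationError(f"container {e.entity_id!r} has no components")
    idgen = idgen or _IdGen()
    group = GpmlGroup(
        group_id=idgen.next("grp"),
        style="Complex" if e.entity_class == "complex" else "Group",
    )
    xref, literature = annotate(e, preferred_sources)
    placeholder = GpmlDataNode(
        graph_id=idgen.next("dn"),
        text_label=e.display_name,
        node_type="Complex",
        center=(e.geometry[0], e.geometry[1]),
        size=(e.geometry[2], e.geometry[3]),
        group_ref=group.group_id,
        xref=xref,
        literature=literature,
    )
    leaves: list[str] = []
    seen: set[str] = set()
    for member_id, _stoich in iter_leaf_components(p, e):
        if member_id not in seen:
            seen.add(member_id)
            leaves.append(member_id)
    return group, placeholder, leaves


def _polyline_point(points: list[tuple[float, float]], t: float) -> tuple[float, float]:
    """Point at fraction t of the arc length along a polyline."""
    import math

    seg_lengths = [
        math.dist(points[i], points[i + 1]) for i in range(len(points) - 1)
    ]
    total = sum(seg_lengths)
    if total == 0:
        return points[0]
    target = t * total
    acc = 0.0
    for (a, b), L in zip(zip(points, points[1:]), seg_lengths):
        if acc + L >= target or L == seg_lengths[-1] and (a, b) == (points[-2], points[-1]):
            frac = 0.0 if L == 0 else (target - acc) / L
            frac = min(max(frac, 0.0), 1.0)
            return (a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1]))
        acc += L
    return points[-1]


def convert_hyperedge(
    r: SourceReaction,
    node_ids: dict[str, str],
    node_centers: dict[str, tuple[float, float]] | None = None,
    idgen: _IdGen | None = None,
    preferred_sources: dict[str, tuple[str, ...]] | None = None,
) -> tuple[GpmlInteraction, list[GpmlInteraction]]:
    """Decompose a hyperedge reaction into backbone + branch interactions.

    The backbone follows the reaction's polyline and ends in an arrowhead
    keyed to the reaction type (mim-conversion for transitions, mim-binding
    for binding, plain arrow otherwise).  The first input and first output
    (document order) attach directly to the backbone endpoints; every other
    branch becomes its own interaction bound to a fresh anchor, with
    arrowheads input→none, output→arrow, catalyst→mim-catalysis,
    activator→mim-stimulation, inhibitor→t-bar.  Anchors sit at evenly
    spaced fractions k/(m+1), branches ordered inputs, outputs, catalysts,
    activators, inhibitors.

    Emitted interaction count is therefore
    ``1 + max(0, #in - 1) + max(0, #out - 1) + #cat + #act + #inh``
    with ``anchors = interactions - 1``.
    """
    idgen = idgen or _IdGen()
    node_centers = node_centers or {}
    for b in r.branches:
        if b.entity_id not in node_ids:
            raise ReferentialIntegrityError(
                f"reaction {r.reaction_id!r}: branch entity {b.entity_id!r} "
                "has no converted data node"
            )

    inputs = r.branches_with_role("input")
    outputs = r.branches_with_role("output")
    extras = (
        inputs[1:]
        + outputs[1:]
        + r.branches_with_role("catalyst")
        + r.branches_with_role("activator")
        + r.branches_with_role("inhibitor")
    )

    pts = [tuple(map(float, xy)) for xy in r.backbone_points]
    first = GpmlPoint(coords=pts[0])
    if inputs:
        first.graph_ref = node_ids[inputs[0].entity_id]
    last = GpmlPoint(coords=pts[-1], arrow_head=BACKBONE_ARROWS[r.reaction_type])
    if outputs:
        last.graph_ref = node_ids[outputs[0].entity_id]
    mid = [GpmlPoint(coords=xy) for xy in pts[1:-1]]

    xref, literature = annotate(r, preferred_sources)
    backbone = GpmlInteraction(
        graph_id=idgen.next("in"),
        points=[first, *mid, last],
        xref=xref,
        comments=[(REACTION_ID_COMMENT, r.reaction_id)],
        literature=literature,
    )
    for b in inputs[:1] + outputs[:1]:
        if b.stoichiometry != 1:
            backbone.comments.append(
                ("Stoichiometry", f"{b.role}:{b.entity_id}:{b.stoichiometry}")
            )

    branch_edges: list[GpmlInteraction] = []
    m = len(extras)
    for k, b in enumerate(extras, start=1):
        position = k / (m + 1)
        anchor = GpmlAnchor(anchor_id=idgen.next("an"), position=position)
        backbone.anchors.append(anchor)
        node_id = node_ids[b.entity_id]
        node_pt = GpmlPoint(
            coords=node_centers.get(b.entity_id, pts[0]), graph_ref=node_id
        )
        anchor_pt = GpmlPoint(
            coords=_polyline_point(pts, position), graph_ref=anchor.anchor_id
        )
        if b.role == "output":
            node_pt.arrow_head = "arrow"
            points = [anchor_pt, node_pt]
        elif b.role == "input":
            points = [node_pt, anchor_pt]
        else:
            anchor_pt.arrow_head = MODIFIER_ARROWS[b.role]
            points = [node_pt, anchor_pt]
        edge = GpmlInteraction(graph_id=idgen.next("in"), points=points)
        if b.stoichiometry != 1:
            edge.comments.append(
                ("Stoichiometry", f"{b.role}:{b.entity_id}:{b.stoichiometry}")
            )
        branch_edges.append(edge)
    return backbone, branch_edges


def flatten_components(
    p: SourcePathway,
    opts: ConversionOptions | None = None,
    container_node_ids: dict[str, str] | None = None,
    idgen: _IdGen | None = None,
    grid_top: float | None = None,
) -> tuple[list[GpmlDataNode], ComplexComponentMap, dict[str, str]]:
    """Draw the unique complex/entity-set components in a bottom grid.

    Components are deduplicated by primary xref (falling back to display
    name); duplicates are not drawn again but are recorded as comments on
    the drawn node so nothing is lost from the document.  The returned map
    links every container (by its placeholder node id, or entity id when no
    mapping is supplied) to all of its recursively expanded component node
    ids.  Also returns component node id → source entity id bookkeeping.
    """
    opts = opts or ConversionOptions()
    idgen = idgen or _IdGen()
    index = p.entity_index()
    container_node_ids = container_node_ids or {
        e.entity_id: e.entity_id for e in p.containers()
    }

    if grid_top is None:
        lows = [e.geometry[1] + e.geometry[3] / 2 for e in p.entities]
        lows += [c.geometry[1] + c.geometry[3] for c in p.compartments]
        grid_top = (max(lows) if lows else 0.0) + opts.component_grid.top_margin

    grid = opts.component_grid
    nodes: list[GpmlDataNode] = []
    node_entities: dict[str, str] = {}
    by_key: dict[tuple, GpmlDataNode] = {}
    occurrences: dict[str, int] = {}
    mapping: dict[str, list[str]] = {}

    def dedup_key(e: SourceEntity) -> tuple:
        x = e.primary_xref()
        return ("xref", x.data_source, x.identifier) if x else ("label", e.display_name)

    for container in p.containers():
        cid = container_node_ids[container.entity_id]
        members: list[str] = []
        for member_id, stoich in iter_leaf_components(p, container):
            member = index[member_id]
            key = dedup_key(member)
            node = by_key.get(key)
            if node is None:
                i = len(by_key)
                col, row = i % grid.columns, i // grid.columns
                center = (
                    grid.cell_width / 2 + col * grid.cell_width,
                    grid_top + grid.cell_height / 2 + row * grid.cell_height,
                )
                xref, _ = annotate(member, opts.preferred_sources)
                # literature stays on the member's main diagram node only,
                # so each source reference appears on exactly one element
                node = GpmlDataNode(
                    graph_id=idgen.next("dn"),
                    text_label=member.display_name,
                    node_type=map_entity_class(member.entity_class),
                    center=center,
                    size=(80.0, 25.0),
                    xref=xref,
                )
                by_key[key] = node
                nodes.append(node)
                node_entities[node.graph_id] = member.entity_id
                occurrences[node.graph_id] = 0
            occurrences[node.graph_id] += 1
            # complex-member stoichiometry is kept as a comment; entity-set
            # members are alternatives, so their stoichiometry is ignored
            if container.entity_class == "complex" and stoich != 1:
                node.comments.append(("Stoichiometry", f"{cid}:{stoich}"))
            if node.graph_id not in members:
                members.append(node.graph_id)
        mapping[cid] = members

    for node in nodes:
        extra = occurrences[node.graph_id] - 1
        if extra > 0:
            node.comments.append(("HiddenDuplicates", str(extra)))
    return nodes, ComplexComponentMap(mapping), node_entities


def convert_pathway(p: SourcePathway, opts: ConversionOptions | None = None) -> GpmlPathway:
    """Convert a validated source pathway to a GPML document."""
    gpml, _report = convert_pathway_with_report(p, opts)
    return gpml


def convert_pathway_with_report(
    p: SourcePathway, opts: ConversionOptions | None = None
) -> tuple[GpmlPathway, ConversionReport]:
    """Convert, returning both the GPML document and bookkeeping.

    The report carries the entity→node id map and the complex-component map,
    which downstream scoring uses directly (they are also recoverable from
    the GPML comments).
    """
    opts = opts or ConversionOptions()
    violations = validate_source_pathway(p)
    if violations:
        raise ValidationError(
            f"source pathway has {len(violations)} violation(s); first: {violations[0]}"
        )

    idgen = _IdGen()
    report = ConversionReport()
    out = GpmlPathway(
        name=p.name,
        organism=p.organism,
        data_source="Reactome",
        source_version=p.source_version,
        authors=list(p.authors),
        maintainers=list(p.maintainers),
        comments=[("DataSource", "Reactome"), ("Version", p.source_version)],
    )
    if p.xref is not None:
        out.comments.append(("PathwayXref", f"{p.xref.data_source}:{p.xref.identifier}"))

    # step (ii): entities
    placeholders: dict[str, GpmlDataNode] = {}
    for e in p.entities:
        if e.is_container:
            group, placeholder, _leaves = convert_container(e, p, idgen, opts.preferred_sources)
            out.groups.append(group)
            out.data_nodes.append(placeholder)
            placeholders[e.entity_id] = placeholder
            report.node_ids[e.entity_id] = placeholder.graph_id
            report.group_ids[e.entity_id] = group.group_id
        else:
            xref, literature = annotate(e, opts.preferred_sources)
            node = GpmlDataNode(
                graph_id=idgen.next("dn"),
                text_label=e.display_name,
                node_type=map_entity_class(e.entity_class),
                center=(e.geometry[0], e.geometry[1]),
                size=(e.geometry[2], e.geometry[3]),
                xref=xref,
                literature=literature,
            )
            out.data_nodes.append(node)
            report.node_ids[e.entity_id] = node.graph_id

    # compartments: a Group holding a labelled rectangle; membership of data
    # nodes is decided by geometric containment of the node center
    node_by_entity = {eid: gid for eid, gid in report.node_ids.items()}
    gpml_nodes = {n.graph_id: n for n in out.data_nodes}
    for c in p.compartments:
        grp = GpmlGroup(group_id=idgen.next("grp"), style="Group")
        out.groups.append(grp)
        x, y, w, h = c.geometry
        out.shapes.append(
            GpmlShape(
                graph_id=idgen.next("sh"),
                shape_kind="Rectangle",
                center=(x + w / 2, y + h / 2),
                size=(w, h),
                group_ref=grp.group_id,
            )
        )
        out.labels.append(
            GpmlLabel(
                graph_id=idgen.next("la"),
                text=c.name,
                center=(x + w / 2, y + 12.0),
                size=(max(w - 10.0, 10.0), 20.0),
                group_ref=grp.group_id,
            )
        )
        for node in out.data_nodes:
            if node.group_ref is None:
                cx, cy = node.center
                if x <= cx <= x + w and y <= cy <= y + h:
                    node.group_ref = grp.group_id

    # reactions
    node_centers = {
        eid: gpml_nodes[gid].center for eid, gid in node_by_entity.items()
    }
    for r in p.reactions:
        backbone, branches = convert_hyperedge(
            r, node_by_entity, node_centers, idgen, opts.preferred_sources
        )
        out.interactions.append(backbone)
        out.interactions.extend(branches)

    # notes -> labels
    for n in p.notes:
        out.labels.append(
            GpmlLabel(
                graph_id=idgen.next("la"),
                text=n.text,
                center=(n.position[0], n.position[1]),
                size=(max(8.0 * len(n.text), 40.0), 20.0),
            )
        )

    # flattened components at the bottom
    if opts.draw_components and p.containers():
        container_node_ids = {
            e.entity_id: placeholders[e.entity_id].graph_id for e in p.containers()
        }
        comp_nodes, comp_map, comp_entities = flatten_components(
            p, opts, container_node_ids, idgen
        )
        out.data_nodes.extend(comp_nodes)
        report.component_map = comp_map
        report.component_entities = comp_entities
        # record the linkage in the GPML so downstream tools can recover it
        for container_gid, member_gids in comp_map.mapping.items():
            gpml_nodes_now = {n.graph_id: n for n in out.data_nodes}
            gpml_nodes_now[container_gid].comments.append(
                (COMPONENT_MAP_COMMENT, ",".join(member_gids))
            )

    # board size encloses everything
    xs: list[float] = [0.0]
    ys: list[float] = [0.0]
    for n in (*out.data_nodes, *out.labels, *out.shapes):
        xs.append(n.center[0] + n.size[0] / 2)
        ys.append(n.center[1] + n.size[1] / 2)
    for ia in out.interactions:
        for pt in ia.points:
            xs.append(pt.coords[0])
            ys.append(pt.coords[1])
    out.board_size = (max(xs) + 20.0, max(ys) + 20.0)
    return out, report


# ---------------------------------------------------------------------------
# Structure recovery (used by conservation checks and downstream tools)

_ROLE_BY_MODIFIER_ARROW = {v: k for k, v in MODIFIER_ARROWS.items()}


def recover_participants(p: GpmlPathway) -> list[tuple[str, str, str]]:
    """Recover (reaction_id, role, node graph_id) triples from a converted GPML.

    Backbones are identified by the reaction-id comment the converter writes;
    branch roles are decoded from arrowheads exactly as the converter assigns
    them, so for any converted pathway this inverts the hyperedge
    decomposition.
    """
    anchor_owner: dict[str, GpmlInteraction] = {}
    backbone_rxn: dict[str, str] = {}
    for ia in p.interactions:
        for a in ia.anchors:
            anchor_owner[a.anchor_id] = ia
        for source, text in ia.comments:
            if source == REACTION_ID_COMMENT:
                backbone_rxn[ia.graph_id] = text

    triples: list[tuple[str, str, str]] = []
    for ia in p.interactions:
        rid = backbone_rxn.get(ia.graph_id)
        if rid is not None:
            first, last = ia.points[0], ia.points[-1]
            if first.graph_ref is not None:
                triples.append((rid, "input", first.graph_ref))
            if last.graph_ref is not None:
                triples.append((rid, "output", last.graph_ref))
            continue
        # branch edge: exactly one endpoint references an anchor
        anchor_pt = node_pt = None
        for pt in ia.points:
            if pt.graph_ref in anchor_owner:
                anchor_pt = pt
            elif pt.graph_ref is not None:
                node_pt = pt
        if anchor_pt is None or node_pt is None:
            continue
        owner = anchor_owner[anchor_pt.graph_ref]
        rid = backbone_rxn.get(owner.graph_id)
        if rid is None:
            continue
        if anchor_pt.arrow_head in _ROLE_BY_MODIFIER_ARROW:
            role = _ROLE_BY_MODIFIER_ARROW[anchor_pt.arrow_head]
        elif node_pt.arrow_head == "arrow":
            role = "output"
        else:
            role = "input"
        triples.append((rid, role, node_pt.graph_ref))
    return triples
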