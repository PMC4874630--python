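"""GPML 2013a document model with a deterministic XML writer and a reader.

GPML (Graphical Pathway Markup Language) is the XML pathway dialect used by
WikiPathways and PathVisio.  The model here covers the element set a
converted reaction-centric pathway needs: DataNodes, Interactions with
Points and Anchors, Groups (styles ``Complex``/``Group``), Labels, Shapes,
pathway-level comments and Biopax literature references (PubMed).

The writer is byte-deterministic: fixed element order (metadata, DataNodes,
Interactions, Labels, Shapes, Groups, InfoBox, Biopax), fixed attribute
order, UTF-8, two-space indentation.  ``read_gpml`` inverts ``write_gpml``
on documents this package writes and ignores unknown attributes with a
logged warning, so hand-edited files still load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

from pathbridge.errors import ParseError, ReferentialIntegrityError

log = logging.getLogger(__name__)

GPML_NS = "http://pathvisio.org/GPML/2013a"
BIOPAX_NS = "http://www.biopax.org/release/biopax-level3.owl#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

NODE_TYPES = ("GeneProduct", "Protein", "Rna", "Metabolite", "Pathway", "Complex", "Unknown")
GROUP_STYLES = ("Complex", "Group", "None")

ARROW_HEADS = {
    "none": None,
    "arrow": "Arrow",
    "t_bar": "TBar",
    "mim_catalysis": "mim-catalysis",
    "mim_stimulation": "mim-stimulation",
    "mim_inhibition": "mim-inhibition",
    "mim_conversion": "mim-conversion",
    "mim_binding": "mim-binding",
}
_ARROW_HEADS_INV = {v: k for k, v in ARROW_HEADS.items() if v is not None}

# Static visual conventions (PathVisio defaults): metabolites blue, pathway
# links green without border, RNA purple.  Configuration, not contract.
NODE_TYPE_COLORS = {
    "Metabolite": "0000ff",
    "Pathway": "14961e",
    "Rna": "990099",
}


@dataclass
class GpmlDataNode:
    graph_id: str
    text_label: str
    node_type: str
    center: tuple[float, float]
    size: tuple[float, float]
    group_ref: str | None = None
    xref: tuple[str, str] | None = None  # (database, identifier)
    comments: list[tuple[str, str]] = field(default_factory=list)  # (source, text)
    literature: list[str] = field(default_factory=list)


@dataclass
class GpmlAnchor:
    anchor_id: str
    position: float  # fraction in [0, 1] along the owning interaction


@dataclass
class GpmlPoint:
    coords: tuple[float, float]
    graph_ref: str | None = None
    arrow_head: str = "none"


@dataclass
class GpmlInteraction:
    graph_id: str
    points: list[GpmlPoint]
    anchors: list[GpmlAnchor] = field(default_factory=list)
    xref: tuple[str, str] | None = None
    comments: list[tuple[str, str]] = field(default_factory=list)
    literature: list[str] = field(default_factory=list)


@dataclass
class GpmlGroup:
    group_id: str
    style: str = "None"


@dataclass
class GpmlLabel:
    graph_id: str
    text: str
    center: tuple[float, float]
    size: tuple[float, float]
    group_ref: str | None = None


@dataclass
class GpmlShape:
    graph_id: str
    shape_kind: str
    center: tuple[float, float]
    size: tuple[float, float]
    group_ref: str | None = None


@dataclass
class GpmlPathway:
    name: str
    organism: str = ""
    data_source: str = ""
    source_version: str = ""
    authors: list[str] = field(default_factory=list)
    maintainers: list[tuple[str, str]] = field(default_factory=list)  # (name, email)
    comments: list[tuple[str, str]] = field(default_factory=list)
    board_size: tuple[float, float] = (0.0, 0.0)
    data_nodes: list[GpmlDataNode] = field(default_factory=list)
    interactions: list[GpmlInteraction] = field(default_factory=list)
    groups: list[GpmlGroup] = field(default_factory=list)
    labels: list[GpmlLabel] = field(default_factory=list)
    shapes: list[GpmlShape] = field(default_factory=list)

    def node_index(self) -> dict[str, GpmlDataNode]:
        return {n.graph_id: n for n in self.data_nodes}

    def anchor_index(self) -> dict[str, str]:
        """Map anchor_id -> owning interaction graph_id."""
        out: dict[str, str] = {}
        for ia in self.interactions:
            for a in ia.anchors:
                out[a.anchor_id] = ia.graph_id
        return out

    def referenceable_ids(self) -> set[str]:
        ids = {n.graph_id for n in self.data_nodes}
        ids |= set(self.anchor_index())
        ids |= {l.graph_id for l in self.labels}
        ids |= {s.graph_id for s in self.shapes}
        return ids


def check_references(p: GpmlPathway) -> None:
    """Raise ReferentialIntegrityError on any dangling GraphRef/GroupRef."""
    ids = p.referenceable_ids()
    group_ids = {g.group_id for g in p.groups}
    for ia in p.interactions:
        for pt in ia.points:
            if pt.graph_ref is not None and pt.graph_ref not in ids:
                raise ReferentialIntegrityError(
                    f"interaction {ia.graph_id!r}: GraphRef {pt.graph_ref!r} does not resolve"
                )
    for el in (*p.data_nodes, *p.labels, *p.shapes):
        if el.group_ref is not None and el.group_ref not in group_ids:
            raise ReferentialIntegrityError(
                f"element {el.graph_id!r}: GroupRef {el.group_ref!r} does not resolve"
            )


# ---------------------------------------------------------------------------
# Writing


def _num(v: float) -> str:
    # repr round-trips doubles exactly, keeping write->read lossless
    return repr(float(v))


def _q(tag: str) -> str:
    return f"{{{GPML_NS}}}{tag}"


def _comment_el(parent, source: str, text: str) -> None:
    c = etree.SubElement(parent, _q("Comment"))
    if source:
        c.set("Source", source)
    c.text = text


class _LiteratureTable:
    """Assigns stable Biopax ids to PubMed identifiers in first-use order."""

    def __init__(self) -> None:
        self.ids: dict[str, str] = {}

    def ref(self, pubmed: str) -> str:
        if pubmed not in self.ids:
            self.ids[pubmed] = f"lit_{len(self.ids) + 1:05d}"
        return self.ids[pubmed]


def _write_common(el, comments, literature, lit: _LiteratureTable) -> None:
    for source, text in comments:
        _comment_el(el, source, text)
    for pm in literature:
        ref = etree.SubElement(el, _q("BiopaxRef"))
        ref.text = lit.ref(pm)


def _write_xref(parent, xref: tuple[str, str] | None) -> None:
    x = etree.SubElement(parent, _q("Xref"))
    x.set("Database", xref[0] if xref else "")
    x.set("ID", xref[1] if xref else "")


def gpml_to_element(p: GpmlPathway) -> etree._Element:
    check_references(p)
    nsmap = {None: GPML_NS, "bp": BIOPAX_NS, "rdf": RDF_NS}
    root = etree.Element(_q("Pathway"), nsmap=nsmap)
    root.set("Name", p.name)
    if p.organism:
        root.set("Organism", p.organism)
    if p.data_source:
        root.set("Data-Source", p.data_source)
    if p.source_version:
        root.set("Version", p.source_version)
    if p.authors:
        root.set("Author", "; ".join(p.authors))
    if p.maintainers:
        root.set("Maintainer", "; ".join(n for n, _ in p.maintainers))

    lit = _LiteratureTable()
    for source, text in p.comments:
        _comment_el(root, source, text)
    # maintainer emails have no GPML attribute; carried as Maintainer comments
    for name, email in p.maintainers:
        _comment_el(root, "Maintainer", f"{name} <{email}>" if email else name)

    g = etree.SubElement(root, _q("Graphics"))
    g.set("BoardWidth", _num(p.board_size[0]))
    g.set("BoardHeight", _num(p.board_size[1]))

    for n in p.data_nodes:
        el = etree.SubElement(root, _q("DataNode"))
        el.set("TextLabel", n.text_label)
        el.set("GraphId", n.graph_id)
        if n.group_ref:
            el.set("GroupRef", n.group_ref)
        el.set("Type", n.node_type)
        _write_common(el, n.comments, n.literature, lit)
        gr = etree.SubElement(el, _q("Graphics"))
        gr.set("CenterX", _num(n.center[0]))
        gr.set("CenterY", _num(n.center[1]))
        gr.set("Width", _num(n.size[0]))
        gr.set("Height", _num(n.size[1]))
        color = NODE_TYPE_COLORS.get(n.node_type)
        if color:
            gr.set("Color", color)
        _write_xref(el, n.xref)

    for ia in p.interactions:
        el = etree.SubElement(root, _q("Interaction"))
        el.set("GraphId", ia.graph_id)
        _write_common(el, ia.comments, ia.literature, lit)
        gr = etree.SubElement(el, _q("Graphics"))
        for pt in ia.points:
            pe = etree.SubElement(gr, _q("Point"))
            pe.set("X", _num(pt.coords[0]))
            pe.set("Y", _num(pt.coords[1]))
            if pt.graph_ref:
                pe.set("GraphRef", pt.graph_ref)
            head = ARROW_HEADS.get(pt.arrow_head)
            if head:
                pe.set("ArrowHead", head)
        for a in ia.anchors:
            ae = etree.SubElement(gr, _q("Anchor"))
            ae.set("Position", _num(a.position))
            ae.set("GraphId", a.anchor_id)
            ae.set("Shape", "None")
        _write_xref(el, ia.xref)

    for lab in p.labels:
        el = etree.SubElement(root, _q("Label"))
        el.set("TextLabel", lab.text)
        el.set("GraphId", lab.graph_id)
        if lab.group_ref:
            el.set("GroupRef", lab.group_ref)
        gr = etree.SubElement(el, _q("Graphics"))
        gr.set("CenterX", _num(lab.center[0]))
        gr.set("CenterY", _num(lab.center[1]))
        gr.set("Width", _num(lab.size[0]))
        gr.set("Height", _num(lab.size[1]))

    for sh in p.shapes:
        el = etree.SubElement(root, _q("Shape"))
        el.set("GraphId", sh.graph_id)
        if sh.group_ref:
            el.set("GroupRef", sh.group_ref)
        gr = etree.SubElement(el, _q("Graphics"))
        gr.set("CenterX", _num(sh.center[0]))
        gr.set("CenterY", _num(sh.center[1]))
        gr.set("Width", _num(sh.size[0]))
        gr.set("Height", _num(sh.size[1]))
        gr.set("ShapeType", sh.shape_kind)

    for grp in p.groups:
        el = etree.SubElement(root, _q("Group"))
        el.set("GroupId", grp.group_id)
        el.set("Style", grp.style)

    info = etree.SubElement(root, _q("InfoBox"))
    info.set("CenterX", "0.0")
    info.set("CenterY", "0.0")

    if lit.ids:
        bp = etree.SubElement(root, _q("Biopax"))
        for pubmed, ref_id in lit.ids.items():
            pub = etree.SubElement(bp, f"{{{BIOPAX_NS}}}PublicationXref")
            pub.set(f"{{{RDF_NS}}}id", ref_id)
            idel = etree.SubElement(pub, f"{{{BIOPAX_NS}}}ID")
            idel.text = pubmed
            db = etree.SubElement(pub, f"{{{BIOPAX_NS}}}Database")
            db.text = "PubMed"
    return root


def gpml_to_bytes(p: GpmlPathway) -> bytes:
    root = gpml_to_element(p)
    etree.indent(root, space="  ")
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=False
    )


def write_gpml(p: GpmlPathway, path) -> None:
    """Serialize to GPML 2013a XML.  Deterministic byte-for-byte."""
    with open(path, "wb") as fh:
        fh.write(gpml_to_bytes(p))
        fh.write(b"\n")


# ---------------------------------------------------------------------------
# Reading

_KNOWN_ATTRS = {
    "Pathway": {"Name", "Organism", "Data-Source", "Version", "Author", "Maintainer",
                "Email", "License", "Last-Modified", "BoardWidth", "BoardHeight"},
    "DataNode": {"TextLabel", "GraphId", "GroupRef", "Type"},
    "Interaction": {"GraphId", "GroupRef"},
    "Label": {"TextLabel", "GraphId", "GroupRef"},
    "Shape": {"GraphId", "GroupRef"},
    "Group": {"GroupId", "GraphId", "Style"},
    "Graphics": {"CenterX", "CenterY", "Width", "Height", "BoardWidth", "BoardHeight",
                 "Color", "ShapeType", "FillColor", "FontSize", "FontWeight",
                 "LineThickness", "LineStyle", "ZOrder", "Valign", "ConnectorType"},
    "Point": {"X", "Y", "GraphRef", "ArrowHead", "RelX", "RelY"},
    "Anchor": {"Position", "GraphId", "Shape"},
    "Xref": {"Database", "ID"},
    "Comment": {"Source"},
}


def _warn_unknown_attrs(el, kind: str) -> None:
    known = _KNOWN_ATTRS.get(kind, set())
    for attr in el.attrib:
        name = etree.QName(attr).localname if "{" in attr else attr
        if name not in known:
            log.warning("ignoring unknown attribute %r on <%s>", name, kind)


def _read_comments(el) -> list[tuple[str, str]]:
    out = []
    for c in el.findall(_q("Comment")):
        _warn_unknown_attrs(c, "Comment")
        out.append((c.get("Source", ""), c.text or ""))
    return out


def _read_literature(el, lit_table: dict[str, str]) -> list[str]:
    out = []
    for ref in el.findall(_q("BiopaxRef")):
        key = (ref.text or "").strip()
        out.append(lit_table.get(key, key))
    return out


def _read_xref(el) -> tuple[str, str] | None:
    x = el.find(_q("Xref"))
    if x is None:
        return None
    _warn_unknown_attrs(x, "Xref")
    db, ident = x.get("Database", ""), x.get("ID", "")
    if not db and not ident:
        return None
    return (db, ident)


def read_gpml(path) -> GpmlPathway:
    """Parse a GPML 2013a file back into the document model.

    Raises ParseError for non-XML input or a wrong root namespace and
    ReferentialIntegrityError for dangling GraphRef/GroupRef ids.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    qname = etree.QName(root.tag)
    if qname.namespace != GPML_NS or qname.localname != "Pathway":
        raise ParseError(
            f"root element {root.tag!r} is not a GPML 2013a Pathway "
            f"(expected namespace {GPML_NS})"
        )
    _warn_unknown_attrs(root, "Pathway")

    # Biopax literature table: rdf id -> PubMed identifier
    lit_table: dict[str, str] = {}
    bp = root.find(_q("Biopax"))
    if bp is not None:
        for pub in bp.findall(f"{{{BIOPAX_NS}}}PublicationXref"):
            rdf_id = pub.get(f"{{{RDF_NS}}}id", "")
            idel = pub.find(f"{{{BIOPAX_NS}}}ID")
            if rdf_id and idel is not None and idel.text:
                lit_table[rdf_id] = idel.text.strip()

    maintainers: list[tuple[str, str]] = []
    comments: list[tuple[str, str]] = []
    for source, text in _read_comments(root):
        if source == "Maintainer":
            if text.endswith(">") and " <" in text:
                name, email = text.rsplit(" <", 1)
                maintainers.append((name, email[:-1]))
            else:
                maintainers.append((text, ""))
        else:
            comments.append((source, text))

    p = GpmlPathway(
        name=root.get("Name", ""),
        organism=root.get("Organism", ""),
        data_source=root.get("Data-Source", ""),
        source_version=root.get("Version", ""),
        authors=[a for a in (root.get("Author") or "").split("; ") if a],
        maintainers=maintainers,
        comments=comments,
    )

    g = root.find(_q("Graphics"))
    if g is not None:
        p.board_size = (float(g.get("BoardWidth", 0)), float(g.get("BoardHeight", 0)))

    for el in root.findall(_q("DataNode")):
        _warn_unknown_attrs(el, "DataNode")
        gr = el.find(_q("Graphics"))
        if gr is None:
            raise ParseError(f"DataNode {el.get('GraphId')!r} lacks Graphics")
        _warn_unknown_attrs(gr, "Graphics")
        p.data_nodes.append(
            GpmlDataNode(
                graph_id=el.get("GraphId", ""),
                text_label=el.get("TextLabel", ""),
                node_type=el.get("Type", "Unknown"),
                center=(float(gr.get("CenterX", 0)), float(gr.get("CenterY", 0))),
                size=(float(gr.get("Width", 0)), float(gr.get("Height", 0))),
                group_ref=el.get("GroupRef"),
                xref=_read_xref(el),
                comments=_read_comments(el),
                literature=_read_literature(el, lit_table),
            )
        )

    for el in root.findall(_q("Interaction")):
        _warn_unknown_attrs(el, "Interaction")
        gr = el.find(_q("Graphics"))
        if gr is None:
            raise ParseError(f"Interaction {el.get('GraphId')!r} lacks Graphics")
        points = []
        for pe in gr.findall(_q("Point")):
            _warn_unknown_attrs(pe, "Point")
            head = pe.get("ArrowHead")
            if head is not None and head not in _ARROW_HEADS_INV:
                log.warning("unknown ArrowHead %r treated as plain arrow", head)
            points.append(
                GpmlPoint(
                    coords=(float(pe.get("X", 0)), float(pe.get("Y", 0))),
                    graph_ref=pe.get("GraphRef"),
                    arrow_head=_ARROW_HEADS_INV.get(head, "none") if head else "none",
                )
            )
        anchors = []
        for ae in gr.findall(_q("Anchor")):
            _warn_unknown_attrs(ae, "Anchor")
            anchors.append(
                GpmlAnchor(
                    anchor_id=ae.get("GraphId", ""),
                    position=float(ae.get("Position", 0)),
                )
            )
        p.interactions.append(
            GpmlInteraction(
                graph_id=el.get("GraphId", ""),
                points=points,
                anchors=anchors,
                xref=_read_xref(el),
                comments=_read_comments(el),
                literature=_read_literature(el, lit_table),
            )
        )

    for el in root.findall(_q("Label")):
        _warn_unknown_attrs(el, "Label")
        gr = el.find(_q("Graphics"))
        p.labels.append(
            GpmlLabel(
                graph_id=el.get("GraphId", ""),
                text=el.get("TextLabel", ""),
                center=(float(gr.get("CenterX", 0)), float(gr.get("CenterY", 0))),
                size=(float(gr.get("Width", 0)), float(gr.get("Height", 0))),
                group_ref=el.get("GroupRef"),
            )
        )

    for el in root.findall(_q("Shape")):
        _warn_unknown_attrs(el, "Shape")
        gr = el.find(_q("Graphics"))
        p.shapes.append(
            GpmlShape(
                graph_id=el.get("GraphId", ""),
                shape_kind=gr.get("ShapeType", "Rectangle"),
                center=(float(gr.get("CenterX", 0)), float(gr.get("CenterY", 0))),
                size=(float(gr.get("Width", 0)), float(gr.get("Height", 0))),
                group_ref=el.get("GroupRef"),
            )
        )

    for el in root.findall(_q("Group")):
        _warn_unknown_attrs(el, "Group")
        p.groups.append(GpmlGroup(group_id=el.get("GroupId", ""), style=el.get("Style", "None")))

    check_references(p)
    return p
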