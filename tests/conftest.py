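import pytest

from pathbridge.source_model import (
    ReactionBranch,
    SourceEntity,
    SourcePathway,
    SourceReaction,
    Xref,
)


@pytest.fixture
def transporter_pathway() -> SourcePathway:
    """Minimal transporter-style pathway: 1 input, 1 output, 1 catalyst.

    Emulates a membrane-transport reaction (substrate outside -> substrate
    inside, catalysed by a transporter protein), the smallest hyperedge that
    exercises anchors.
    """
    return SourcePathway(
        name="Abacavir-like transport",
        organism="Homo sapiens",
        source_version="54",
        authors=["A. Author"],
        maintainers=[("M. Maintainer", "m@example.org")],
        entities=[
            SourceEntity(
                entity_id="sub_out",
                display_name="abacavir (extracellular)",
                entity_class="small_molecule",
                geometry=(100.0, 100.0, 80.0, 25.0),
                xrefs=[Xref("ChEBI", "CHEBI:421707"), Xref("Reactome", "R-ALL-1")],
            ),
            SourceEntity(
                entity_id="sub_in",
                display_name="abacavir (cytosolic)",
                entity_class="small_molecule",
                geometry=(300.0, 100.0, 80.0, 25.0),
                xrefs=[Xref("ChEBI", "CHEBI:421707"), Xref("Reactome", "R-ALL-2")],
            ),
            SourceEntity(
                entity_id="transporter",
                display_name="SLC transporter",
                entity_class="protein",
                geometry=(200.0, 40.0, 80.0, 25.0),
                xrefs=[Xref("Reactome", "R-HSA-3"), Xref("UniProt", "P08183")],
                literature=["15548527"],
            ),
        ],
        reactions=[
            SourceReaction(
                reaction_id="rxn1",
                reaction_type="transition",
                branches=[
                    ReactionBranch(role="input", entity_id="sub_out"),
                    ReactionBranch(role="output", entity_id="sub_in"),
                    ReactionBranch(role="catalyst", entity_id="transporter"),
                ],
                backbone_points=[(140.0, 100.0), (260.0, 100.0)],
                xrefs=[Xref("Reactome", "R-HSA-2161517")],
            )
        ],
    )


@pytest.fixture
def complex_pathway() -> SourcePathway:
    """Two complexes sharing a component, plus a nested complex."""
    proteins = [
        SourceEntity(
            entity_id=f"p{i}",
            display_name=f"PROT{i}",
            entity_class="protein",
            geometry=(100.0 + 90.0 * i, 100.0, 80.0, 25.0),
            xrefs=[Xref("UniProt", f"P0000{i}")],
        )
        for i in range(1, 5)
    ]
    inner = SourceEntity(
        entity_id="cx_inner",
        display_name="inner complex",
        entity_class="complex",
        geometry=(150.0, 220.0, 100.0, 40.0),
        xrefs=[Xref("Reactome", "R-HSA-100")],
        components=[("p3", 1), ("p4", 2)],
    )
    outer = SourceEntity(
        entity_id="cx_outer",
        display_name="outer complex",
        entity_class="complex",
        geometry=(320.0, 220.0, 100.0, 40.0),
        xrefs=[Xref("Reactome", "R-HSA-101")],
        components=[("p1", 1), ("p2", 1), ("cx_inner", 1)],
    )
    eset = SourceEntity(
        entity_id="set1",
        display_name="alternative kinases",
        entity_class="entity_set",
        geometry=(480.0, 220.0, 100.0, 40.0),
        xrefs=[Xref("Reactome", "R-HSA-102")],
        components=[("p2", 1), ("p3", 1)],
    )
    return SourcePathway(
        name="complex fixture",
        organism="Homo sapiens",
        entities=[*proteins, inner, outer, eset],
    )
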