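from collections import Counter

import pytest

from pathbridge.convert import (
    ComplexComponentMap,
    ComponentGrid,
    ConversionOptions,
    annotate,
    convert_container,
    convert_hyperedge,
    convert_pathway,
    convert_pathway_with_report,
    flatten_components,
    map_entity_class,
    recover_participants,
)
from pathbridge.errors import ContractError, ReferentialIntegrityError, ValidationError
from pathbridge.gpml import gpml_to_bytes
from pathbridge.source_model import (
    ReactionBranch,
    SourceEntity,
    SourcePathway,
    SourceReaction,
    Xref,
)
from pathbridge.synth import FixtureSpec, gen_source_pathway


@pytest.mark.parametrize(
    "entity_class,node_type",
    [
        ("protein", "Protein"),
        ("small_molecule", "Metabolite"),
        ("rna", "Rna"),
        ("gene", "GeneProduct"),
        ("process_node", "Pathway"),
        ("other", "Unknown"),
    ],
)
def test_entity_class_mapping(entity_class, node_type):
    assert map_entity_class(entity_class) == node_type


@pytest.mark.parametrize("container", ["complex", "entity_set"])
def test_containers_are_not_plain_nodes(container):
    with pytest.raises(ContractError, match="convert_container"):
        map_entity_class(container)


class TestConvertContainer:
    def test_complex_becomes_complex_style_group(self, complex_pathway):
        outer = complex_pathway.entity_index()["cx_outer"]
        group, placeholder, leaves = convert_container(outer, complex_pathway)
        assert group.style == "Complex"
        assert placeholder.node_type == "Complex"
        assert placeholder.group_ref == group.group_id
        assert placeholder.text_label == "outer complex"

    def test_entity_set_becomes_group_style(self, complex_pathway):
        eset = complex_pathway.entity_index()["set1"]
        group, placeholder, leaves = convert_container(eset, complex_pathway)
        assert group.style == "Group"
        assert set(leaves) == {"p2", "p3"}

    def test_nested_complex_expands_recursively(self, complex_pathway):
        outer = complex_pathway.entity_index()["cx_outer"]
        _, _, leaves = convert_container(outer, complex_pathway)
        # inner complex contributes p3 and p4, not itself
        assert set(leaves) == {"p1", "p2", "p3", "p4"}

    def test_empty_container_rejected(self, complex_pathway):
        bad = SourceEntity("X", "x", "complex", (0, 0, 10, 10))
        with pytest.raises(ValidationError):
            convert_container(bad, complex_pathway)


def _reaction(n_in, n_out, n_cat=0, n_act=0, n_inh=0):
    branches = []
    ids = {}
    k = 0
    for role, count in (
        ("input", n_in), ("output", n_out), ("catalyst", n_cat),
        ("activator", n_act), ("inhibitor", n_inh),
    ):
        for _ in range(count):
            k += 1
            eid = f"e{k}"
            ids[eid] = f"dn_{k:04d}"
            branches.append(ReactionBranch(role=role, entity_id=eid))
    r = SourceReaction(
        reaction_id="r1",
        reaction_type="transition",
        branches=branches,
        backbone_points=[(0.0, 0.0), (100.0, 0.0)],
    )
    return r, ids


class TestConvertHyperedge:
    @pytest.mark.parametrize(
        "shape,expected_edges,expected_anchors",
        [
            ((1, 1, 1, 0, 0), 2, 1),  # the transporter-style hyperedge
            ((2, 1, 0, 0, 0), 2, 1),
            ((1, 1, 0, 0, 0), 1, 0),  # degenerate hyperedge is a plain edge
            ((3, 2, 2, 1, 1), 8, 7),
        ],
    )
    def test_interaction_and_anchor_counts(self, shape, expected_edges, expected_anchors):
        r, ids = _reaction(*shape)
        backbone, branches = convert_hyperedge(r, ids)
        assert 1 + len(branches) == expected_edges
        assert len(backbone.anchors) == expected_anchors

    def test_endpoints_take_first_input_and_output(self):
        r, ids = _reaction(2, 1)
        backbone, branches = convert_hyperedge(r, ids)
        assert backbone.points[0].graph_ref == ids["e1"]
        assert backbone.points[-1].graph_ref == ids["e3"]
        # the second input rides an anchor with no arrowhead
        (edge,) = branches
        assert edge.points[0].graph_ref == ids["e2"]
        assert edge.points[0].arrow_head == "none"

    def test_modifier_arrowheads(self):
        r, ids = _reaction(1, 1, n_cat=1, n_act=1, n_inh=1)
        _, branches = convert_hyperedge(r, ids)
        heads = [e.points[-1].arrow_head for e in branches]
        assert heads == ["mim_catalysis", "mim_stimulation", "t_bar"]

    def test_backbone_arrowhead_follows_reaction_type(self):
        for rtype, head in [("transition", "mim_conversion"), ("binding", "mim_binding"),
                            ("dissociation", "arrow")]:
            r, ids = _reaction(1, 1)
            r.reaction_type = rtype
            backbone, _ = convert_hyperedge(r, ids)
            assert backbone.points[-1].arrow_head == head

    def test_anchor_positions_evenly_spaced(self):
        r, ids = _reaction(1, 1, n_cat=3)
        backbone, _ = convert_hyperedge(r, ids)
        assert [a.position for a in backbone.anchors] == [0.25, 0.5, 0.75]

    def test_unresolved_branch_entity_raises(self):
        r, ids = _reaction(1, 1)
        del ids["e2"]
        with pytest.raises(ReferentialIntegrityError, match="e2"):
            convert_hyperedge(r, ids)


class TestFlattenComponents:
    def test_shared_component_drawn_once_mapped_twice(self, complex_pathway):
        nodes, cmap, _ = flatten_components(complex_pathway)
        labels = [n.text_label for n in nodes]
        assert labels.count("PROT2") == 1
        p2_node = next(n for n in nodes if n.text_label == "PROT2")
        containers = cmap.containers_of(p2_node.graph_id)
        assert set(containers) == {"cx_outer", "set1"}

    def test_no_containers_yields_nothing(self, transporter_pathway):
        nodes, cmap, _ = flatten_components(transporter_pathway)
        assert nodes == []
        assert cmap.mapping == {}

    def test_grid_positions_wrap_after_columns(self):
        proteins = [
            SourceEntity(f"p{i}", f"P{i}", "protein", (10.0 * i, 10.0, 80.0, 25.0),
                         xrefs=[Xref("UniProt", f"Q{i:05d}")])
            for i in range(1, 13)
        ]
        cx = SourceEntity(
            "cx", "big complex", "complex", (50.0, 50.0, 100.0, 40.0),
            components=[(p.entity_id, 1) for p in proteins],
        )
        p = SourcePathway(name="grid", organism="h", entities=[*proteins, cx])
        opts = ConversionOptions(component_grid=ComponentGrid(columns=10))
        nodes, _, _ = flatten_components(p, opts)
        assert len(nodes) == 12
        # node 11 begins row 2: same x as node 1, one cell lower
        assert nodes[10].center[0] == nodes[0].center[0]
        assert nodes[10].center[1] == nodes[0].center[1] + opts.component_grid.cell_height
        rows = {i // 10 for i in range(12)}
        assert rows == {0, 1}

    def test_duplicate_and_stoichiometry_comments_kept(self, complex_pathway):
        nodes, _, _ = flatten_components(complex_pathway)
        by_label = {n.text_label: n for n in nodes}
        # PROT4 appears in the inner complex with stoichiometry 2
        assert ("Stoichiometry", "cx_inner:2") in by_label["PROT4"].comments
        # PROT2 is in two containers; one occurrence is hidden
        assert ("HiddenDuplicates", "1") in by_label["PROT2"].comments


class TestAnnotate:
    def test_protein_prefers_uniprot(self):
        e = SourceEntity("e", "x", "protein", (0, 0, 1, 1),
                         xrefs=[Xref("Reactome", "R-HSA-1"), Xref("UniProt", "P31749")])
        xref, _ = annotate(e)
        assert xref == ("UniProt", "P31749")

    def test_metabolite_falls_back_to_reactome(self):
        e = SourceEntity("e", "x", "small_molecule", (0, 0, 1, 1),
                         xrefs=[Xref("Reactome", "R-ALL-2")])
        xref, _ = annotate(e)
        assert xref == ("Reactome", "R-ALL-2")

    def test_absent_xref_is_permitted(self):
        e = SourceEntity("e", "x", "protein", (0, 0, 1, 1))
        xref, lit = annotate(e)
        assert xref is None and lit == []

    def test_reaction_takes_reactome_only(self):
        r = SourceReaction(
            "r", "transition",
            branches=[ReactionBranch("input", "a")],
            backbone_points=[(0, 0), (1, 1)],
            xrefs=[Xref("UniProt", "P1"), Xref("Reactome", "R-HSA-9")],
        )
        xref, _ = annotate(r)
        assert xref == ("Reactome", "R-HSA-9")


class TestConvertPathway:
    def test_empty_pathway_has_metadata_only(self):
        p = convert_pathway(SourcePathway(name="empty", organism="Homo sapiens"))
        assert p.name == "empty"
        assert p.data_source == "Reactome"
        assert ("DataSource", "Reactome") in p.comments
        assert not p.data_nodes and not p.interactions and not p.groups

    def test_transporter_fixture_shape(self, transporter_pathway):
        """1 input + 1 output + 1 catalyst -> 3 nodes, 2 interactions, 1 anchor."""
        p = convert_pathway(transporter_pathway)
        assert len(p.data_nodes) == 3
        assert len(p.interactions) == 2
        anchors = [a for ia in p.interactions for a in ia.anchors]
        assert len(anchors) == 1
        backbone = next(ia for ia in p.interactions if ia.anchors)
        catalysis = next(ia for ia in p.interactions if not ia.anchors)
        assert catalysis.points[-1].graph_ref == anchors[0].anchor_id
        assert catalysis.points[-1].arrow_head == "mim_catalysis"
        assert backbone.points[-1].arrow_head == "mim_conversion"

    @pytest.mark.parametrize("seed", range(15))
    def test_data_node_counting_law(self, seed):
        source, truth = gen_source_pathway(FixtureSpec(), seed=seed)
        p = convert_pathway(source)
        n_leaf = sum(1 for e in source.entities if not e.is_container)
        n_containers = len(source.containers())
        # unique flattened components, deduplicated the way the converter does
        index = source.entity_index()
        keys = set()
        for leaves in truth.container_leaves.values():
            for eid in leaves:
                e = index[eid]
                x = e.primary_xref()
                keys.add(("x", x.data_source, x.identifier) if x else ("l", e.display_name))
        assert len(p.data_nodes) == n_leaf + n_containers + len(keys)

    @pytest.mark.parametrize("seed", range(15))
    def test_participant_conservation(self, seed):
        source, truth = gen_source_pathway(FixtureSpec(), seed=seed)
        p, report = convert_pathway_with_report(source)
        entity_of = {gid: eid for eid, gid in report.node_ids.items()}
        got = Counter(
            (rid, role, entity_of[gid]) for rid, role, gid in recover_participants(p)
        )
        assert got == Counter(truth.branch_triples)

    @pytest.mark.parametrize("seed", range(10))
    def test_conversion_is_deterministic(self, seed):
        source, _ = gen_source_pathway(FixtureSpec(), seed=seed)
        assert gpml_to_bytes(convert_pathway(source)) == gpml_to_bytes(convert_pathway(source))

    @pytest.mark.parametrize("seed", range(10))
    def test_every_literature_reference_on_exactly_one_element(self, seed):
        source, _ = gen_source_pathway(FixtureSpec(), seed=seed)
        p = convert_pathway(source)
        emitted = Counter()
        for el in (*p.data_nodes, *p.interactions):
            for pm in el.literature:
                emitted[pm] += 1
        expected = Counter()
        for e in source.entities:
            for pm in e.literature:
                expected[pm] += 1
        for r in source.reactions:
            for pm in r.literature:
                expected[pm] += 1
        assert emitted == expected

    def test_component_map_recoverable_from_comments(self, complex_pathway):
        p, report = convert_pathway_with_report(complex_pathway)
        assert ComplexComponentMap.from_gpml(p).mapping == report.component_map.mapping

    def test_compartment_membership_by_containment(self, transporter_pathway):
        from pathbridge.source_model import SourceCompartment

        transporter_pathway.compartments = [
            SourceCompartment("c1", "cytosol", (0.0, 0.0, 400.0, 200.0))
        ]
        p = convert_pathway(transporter_pathway)
        (grp,) = p.groups
        assert {n.group_ref for n in p.data_nodes} == {grp.group_id}
        assert any(l.text == "cytosol" for l in p.labels)

    def test_invalid_source_rejected(self):
        bad = SourcePathway(
            name="bad", organism="h",
            entities=[SourceEntity("E", "e", "complex", (0, 0, 10, 10))],
        )
        with pytest.raises(ValidationError):
            convert_pathway(bad)
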