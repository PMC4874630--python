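# Methods

## The source data model

`pathbridge` consumes a reaction-centric pathway document: entities
(proteins, small molecules, RNAs, genes, process nodes) participate in
reactions through role-typed branches (input, output, catalyst, activator,
inhibitor), and complexes / entity sets group entities with component
stoichiometry.  Production content of this shape lives in a relational
database behind a Java API; this package instead defines a JSON fixture
format capturing the same structure (schema in
`src/pathbridge/schemas/source_pathway.schema.json`) so that conversion and
analysis are testable at desk scale without any database or download.  A
real export can be adapted to the documented format.

Coordinates are diagram units, origin top-left, y increasing downward —
GPML's convention — so conversion performs no axis flip.  Stoichiometry
defaults to 1 when omitted.  Entity-set members are alternatives playing
the same role, not an assembly, so the converter carries but ignores their
stoichiometry.

Validation is two-tier: `read_source_pathway` raises on the first problem
(parse error with byte offset, schema violation naming the field,
referential-integrity error naming the id), while
`validate_source_pathway` returns the complete list of violation records
(element id + rule) for curation workflows.

## Conversion

Three steps: (i) pathway metadata (data source, source version, organism,
authors, maintainers — maintainer e-mail addresses have no GPML attribute
and are encoded as `Comment Source="Maintainer"` entries); (ii) element
conversion; (iii) annotation.

**Hyperedge decomposition.**  The backbone interaction follows the
reaction's polyline and ends in an arrowhead keyed to the reaction type:
mim-conversion (transition), mim-binding (binding), plain arrow
(dissociation, omitted, uncertain).  When a reaction has exactly one input
and one output they attach directly to the backbone endpoints; with more,
the *first of each in document order* takes the endpoint and every further
branch becomes its own interaction bound to a fresh anchor on the backbone.
Anchors sit at fractions k/(m+1) for m extra branches, ordered inputs,
outputs, catalysts, activators, inhibitors — even spacing is a layout
choice; the anchor *structure* (ownership, attachment) is the contract, the
positions are cosmetic.  Branch arrowheads: extra input → none, extra
output → arrow at the node end, catalyst → mim-catalysis, activator →
mim-stimulation, inhibitor → t-bar at the anchor end.  This yields the
counting law `interactions = 1 + max(0,#in−1) + max(0,#out−1) + #cat +
#act + #inh` and `anchors = interactions − 1`, which the tests enforce,
and makes the decomposition invertible: `recover_participants` reads the
(reaction, role, entity) multiset back off the interactions and anchors.

**Containers.**  Complexes map to Groups of style `Complex`, entity sets
to style `Group`; both get a Complex-typed placeholder data node carrying
label and Reactome annotation (entity sets share the Complex node type —
GPML has no dedicated set type).  Components are expanded recursively
(nested containers contribute their members, not themselves), drawn once
each in a left-to-right, top-to-bottom grid below the diagram (default 10
columns, 100×40 cells, 60-unit top margin), and deduplicated by primary
xref, falling back to display name — labels alone are not unique.
Duplicate occurrences and complex-member stoichiometry > 1 are recorded as
comments on the drawn node, so nothing is lost from the document.  The
container → component-node linkage is written as a
`Comment Source="ComplexComponents"` on each placeholder, and
`ComplexComponentMap.from_gpml` recovers it from a file.

**Compartments.**  Each becomes a Group holding a labelled rectangle
shape; data nodes whose *center* falls inside the compartment rectangle
join the group (a geometric rule; the source `compartment_id` field is
metadata only).  A node already in a complex group keeps that membership —
GPML allows one group per element.

**Annotation preference.**  protein → UniProt, else Reactome; metabolite →
ChEBI, else Reactome; RNA/gene → Ensembl first; reactions, containers and
pathway links → Reactome only.  The preference table is a
`ConversionOptions` field.  Absent annotation is permitted and logged.
Each PubMed reference is emitted exactly once, as a Biopax
PublicationXref referenced from its element; flattened component nodes do
not repeat the literature of the member's main node.

**Determinism.**  Graph ids come from per-kind counters (`dn_0001`,
`in_0001`, `an_0001`, `grp_0001`, …) assigned in document order, and the
XML writer fixes element order, attribute order and indentation, so the
same input always produces byte-identical GPML.  Floats are serialized
with `repr`, which round-trips doubles exactly — round-trip equality is
model equality, not approximate.

## Enrichment

The criterion language (comparisons, AND/OR/NOT, `abs`, parentheses,
bracketed column names) is parsed by a small recursive-descent parser; the
grammar is in the README.  Probe rows are collapsed to identifiers before
counting — an identifier qualifies if *any* of its rows does — preventing
multi-probe genes from being counted twice.  A row with a missing value in
a referenced column never qualifies but still counts as measured.

The z statistic standardizes `r` by the hypergeometric mean `n·R/N` and
variance `n·(R/N)·(1−R/N)·(1−(n−1)/(N−1))`.  Degenerate settings (zero
variance) yield NaN; such pathways are reported and ranked last, with
remaining ties broken by pathway name for determinism.  `n` counts
distinct measured identifiers on the pathway's data nodes, excluding
complex placeholder nodes and including the flattened component nodes —
so a pathway drawn with complexes scores identically to the same gene
content drawn flat (a tested invariant).  Whether `n` should count nodes
rather than distinct genes is a genuine ambiguity in diagram-based
pathway statistics; distinct-gene counting was chosen and is flagged here
for anyone comparing against other tools.

A permutation utility (`permuted_mean_z`) shuffles qualification labels
across identifiers to check the null: its mean z is zero in expectation,
and the test suite verifies |mean| < 3·SE per pathway.

## Complex scoring

`percent = 100 · n_qualifying / n_components`, computed over the
components for which the table has data.  Unmeasured components are
excluded from both numerator and denominator (matching the convention
that unmeasured genes are displayed gray, not treated as failing); a
complex with no measured components has an undefined score and takes the
default color.  Entity sets are scored alongside complexes — they share
the component map.  Color rules evaluate in user order, first match wins;
threshold comparisons are exact (the `> 25` rule excludes 25.0), and
gradients interpolate linearly per RGB channel with clamping outside the
anchors.

## Coverage

A term is covered by a collection iff its annotated identifier set
intersects the collection's identifiers — direct annotation only, no
ontology-graph ancestor propagation.  The partition identities
`only_A + only_B + overlap = combined` and `combined + uncovered = total`
hold by construction and are property-tested.  Identifier unification uses
a static two-column mapping file; no web-service lookups, for offline
reproducibility.

## Synthetic fixtures

The generator emulates the *mechanics* of curated reaction-centric
content, not its biology: ~30 entities per pathway (55% proteins, 20%
small molecules, 10% RNAs, 10% genes, 5% process nodes), 20% containers
with Poisson-sized membership (mean 3) and nesting capped at depth 2 to
keep recursive-flattening oracles hand-checkable, 10 reactions with 1–2
inputs/outputs and Bernoulli modifiers, two compartments.  Identifiers
are synthetic but scheme-shaped (P#####, CHEBI:#, ENSG###########), with a
10% chance of a Reactome-only entity to exercise the annotation fallback.

Expression tables implement a two-component mixture: a gene qualifies
under `abs([logFC]) > 1 AND [P.value] < 0.05` with probability 0.8 if it
belongs to the planted pathway and 0.1 otherwise (qualifying rows draw
|logFC| ~ N(2, 0.25) with random sign and P ~ U(0.0005, 0.0495);
non-qualifying rows draw logFC ~ N(0, 0.25) and P ~ U(0.055, 1), placing
the P value safely across the cutoff so the recorded ground truth is exact
rather than probabilistic).  200 background-only genes are appended.
These defaults are the study conditions for the recovery checks: the
planted pathway ranks first in ≥ 95/100 replicates.

What passing these tests does *not* show: robustness to real annotation
noise (wrong or missing xrefs), overlapping gene content between pathways
(collections here use disjoint identifier spaces), probe-level effects
beyond any-qualifies collapsing, or the visual fidelity of real diagram
layouts.  The generator tests the pipeline's arithmetic and format
contracts, not biological realism.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` on explicit
  seeds; generator outputs are byte-reproducible from (spec, seed).
- Monte-Carlo checks of the z formula use 10⁵ draws per setting at 20
  settings; with 40 simultaneous moment comparisons the per-comparison
  acceptance band is Šidák-adjusted so the family carries the same error
  rate as a single two-sided 3·SE check.
- Problem sizes in the test suite (100 round-trip fixtures, 500 reactions,
  100 recovery replicates, 100 scoring fixtures) keep the full suite and
  the acceptance script to seconds while giving each law hundreds of
  independent instances.
- GPML output follows the 2013a namespace, element order and attribute
  conventions; conformance is enforced by round-trip and structural
  invariants rather than XSD validation.  Unknown attributes encountered
  when reading are ignored with a logged warning, so files touched by
  other editors still load.

## Known limitations

- The GPML surface covers the element set conversion needs (DataNodes,
  Interactions, Groups, Labels, Shapes, Biopax literature); States,
  graphical lines and legend elements are out of scope.
- No reverse GPML → source conversion.
- Anchor positions are evenly spaced rather than layout-optimized; no
  diagram beautification beyond the component grid.
- Visual attributes (colors per node type) are written as PathVisio-style
  defaults and are configuration, not contract.
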