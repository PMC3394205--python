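# Methods

## Ontology model and OBO dialect

One parsed file yields one `Ontology`: an ordered map of terms plus a
list of typed relations. The edge convention is fixed package-wide:
**relations point child → parent** (the stanza term is the subject), and
a *root* is a term with no outgoing edge under the active predicate
filter. The parser reads a deliberately small OBO 1.2 dialect — `[Term]`
stanzas with `id`, `name`, `def`, `synonym`, `is_a`, `relationship`,
`is_obsolete`, `xref`, `namespace` — because the tool consumes curated,
pre-processed ontology releases, not arbitrary OWL. Unknown tags and
stanza types are skipped; text after an unescaped `!` is a comment;
`\!`/`\\` escapes are decoded; the first double-quoted span of a
`synonym`/`def` line is the text. A stanza without `id` or a duplicate
id is a hard parse error naming the line; a relation whose target is not
defined in the file is dropped with a warning (real releases contain
dangling references), which keeps parsing total.

## Query resolution

Multi-term queries split on unescaped commas (`\,` → `,`, `\\` → `\`; a
trailing lone backslash is a syntax error). Each part is resolved in
order: (1) the raw string as a full term id — tried first so an id like
`GO:0005739` works whether `GO` is the ontology short name, the id
prefix, or both; (2) a `<short_name>:` prefix naming a loaded ontology,
with the remainder as a term id there (covers ontologies with foreign or
absent id prefixes, e.g. `ZFA:ZFS:0000019`, `NEWT:1234`); (3) the first
autosuggestion. Autosuggest ranks case-insensitively over names and
synonyms by a lexical specificity ladder — exact id, exact name, exact
synonym, name prefix, synonym prefix, substring — with ties broken by
matched text then id. Usage-frequency ranking would need query logs that
a headless library does not have; the lexical ladder is deterministic and
monotone in match specificity, which is what the tests need. Default
suggestion limit: 10. The obsolete-term filter also applies to
suggestions.

## Environment extraction

`local_environment` walks upward from the focus with a FIFO queue and a
visited set, following non-excluded predicates. Every admissible parent
reached is on some path toward a root, so the visited (upward-reachable)
set equals the union of all simple focus→root paths — the test suite
checks this against an exhaustive simple-path enumerator. Edge handling
under cycles: an edge is kept only if it does not close a directed cycle
among the edges already kept (first-traversed direction wins), but the
walk always continues through the parent. This generalises
drop-the-back-edge handling of bidirectional pairs to arbitrary cycles
and guarantees the kept edge set is a DAG, which the level assignment
and the layered placement rely on. Obsolete terms block traversal when
hidden; the focus itself is always kept.

Levels use longest-path layering (the standard layering for hierarchical
DAG drawing): level(t) = longest kept-edge path from any focus; foci,
their children, and anything not upward-reachable sit at level 0.

The display cap keeps the first `cap` (default 500) terms in
breadth-first order from the focus set, children direction before
ancestor direction, neighbour ties by (name, id, predicate). "First" is
not otherwise defined for a set of paths; breadth-first from the focus
retains the most local subgraph, which matches the tool's purpose.
`apply_term_cap` takes the ontology as an optional argument purely for
the name ordering; without it ties fall back to (id, predicate).

The parents-only filter drops the children layer and by default keeps
all ancestor levels; a `direct_parents_only` switch restricts the view
to the focus's direct parents for users who want the minimal simplified
graph. Both readings are reasonable; keeping ancestors preserves the
path-to-root viewing unit, so it is the default.

## Layout

Geometry is y-down (screen frame). Initial placement: primary focus at
the origin; its children on the lower half circle of radius
`length_scale × 120` at angles evenly spaced over the open interval
(0, π), left → right in deterministic child order; additional foci along
the x axis at 260-unit intervals with their own child fans; ancestors at
`y = −level × 110`, spread within each level at 150-unit spacing in name
order. Springs get preferred length `100 × max(1, Δlevel)` and a (0, −1)
orientation preference for hierarchy predicates only (`is_a`, `part_of`,
`develops_from`; configurable) — orienting every relation type would
fight genuinely lateral links.

Forces per step:

- **Repulsion**, every pair: `k_r / max(gap, 1)²` along the centre line,
  with `gap` = centre distance − both rectangles' half-extents projected
  on that line. The projection approximates true rectangle–rectangle
  distance smoothly and cheaply; it is what makes label boxes, not
  points, repel. Coincident centres get a direction drawn from the
  seeded generator, so degenerate starts stay reproducible.
- **Spring**: `k_s (d − L·length_scale)` along the connector.
- **Orientation couple**: `k_o sin θ` applied perpendicular to the
  connector, opposite signs at the two ends, rotating it toward the
  preferred direction.

Integration is damped explicit Euler: `v ← damping·(v + Δt·F)`,
`x ← x + Δt·v`, with speed capped at `max_speed` (default 30 units/step)
— the capped speed plays the role of the temperature in classic
force-directed layouts and keeps the near-contact repulsion impulse from
launching nodes across the canvas. Defaults: `k_r = 2·10⁴`,
`k_s = 0.06`, `k_o = 0.5`, damping 0.85, Δt = 1, tolerance 0.05 units,
max 3000 iterations; all overridable. Convergence requires the largest
per-node displacement to stay below tolerance for 5 consecutive steps —
a single quiet step can be an oscillation turning point. `energy` sums
`k_r/max(gap,1)` per pair, `½k_s(d−L·scale)²` per spring and
`k_o(1−cos θ)` per oriented spring; relaxation descends it on the
test-suite graphs.

On isolated spring pairs with repulsion disabled the closed-form
equilibrium (`d = L·length_scale`) is reached within 1%. Dense graphs
(tens of mutually repelling labels in one layer) can settle into a small
residual jitter above tolerance; `relax` then stops at the iteration cap
and reports `converged=False` — positions are still usable and
overlap-free, and the flag is surfaced by the CLI rather than hidden.

Anchored nodes receive no displacement, ever. `incremental_update`
removes vanished terms, keeps every persisting node's position and
anchored flag bitwise intact, places only new terms by the initial rules,
rebuilds springs, and relaxes — the minimal-reorganisation contract that
makes successive browsing steps visually trackable.

## Rendering and export

SVG: one rounded rectangle + centred label per term, leaf terms (no
children anywhere in the full ontology) filled light orange; one arrow
per relation coloured by predicate (`is_a` blue, `part_of` green,
`develops_from` purple, others grey — the specific shades are this
package's choice), labels longer than 10 characters abbreviated to 9 +
"…" with the full name in the element tooltip. Zoom law: pixel distance
scales as `zoom^1.0`, font size as `zoom^0.6` — distances grow faster
than glyphs, an extra mechanism against label collision when zooming in.
Element order is sorted (terms by id, edges by triple), so output is
byte-stable.

XGMML is the minimal Cytoscape-compatible subset: `graph`/`node`/`att`/
`graphics`/`edge`; node `label` = term name, string attribute `ontID` =
term id, edge `label` = predicate. TSV export writes `id, name,
obsolete, is_leaf, level` and `subject, predicate, object` tables with
embedded tabs/newlines flattened to spaces.

## Synthetic data

The generator emulates the structural features of curated bio-ontologies
that the code paths depend on: multiple-inheritance DAGs (term *k* draws
1…`max_parents` parents uniformly from earlier terms, so hierarchy edges
are acyclic and every term reaches a root), predicate mix defaulting to
is_a 0.7 / part_of 0.2 / develops_from 0.1 (the three most common
relation types), an obsolete fraction among non-roots, and optional
reverse "twin" edges for non-hierarchy predicates to model bidirectional
relations. It does **not** reproduce any real ontology's degree
distribution, depth profile, term-name vocabulary or annotation density —
so passing tests demonstrate structural correctness of traversal, layout
and serialization, not linguistic robustness of the query ranking on
real nomenclature. `big_environment_fixture` builds a star of children
plus a 3-term chain to a root so the focus environment has an exact,
brute-force-verifiable size; it exercises the 500-term display cap.

## Problem sizes

The test suite and the acceptance script run on synthetic ontologies of
up to 50 terms for the traversal-equivalence sweeps (200 ontologies,
every term as focus, several filter sets), 600 terms for the cap check,
20-node trees for layout invariants, and 100 random ontologies for the
OBO round trip — sizes at which the exhaustive oracles (simple-path
enumeration, brute-force scans) are exact and fast, which is the point
of using them.

## Known limitations

- Environments merge within one ontology; cross-ontology merging is out
  of scope.
- The layout is a simulation stepper, not a real-time canvas; animation
  frames can be reconstructed from the step trace.
- Rectangle repulsion uses the projected-extent approximation, not exact
  rectangle distance; extremely elongated labels can over-repel
  diagonally.
- The convergence flag can be false on dense single-layer graphs (see
  above); no overlap has been observed in those states in the test
  conditions, but the equilibrium is not certified.
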