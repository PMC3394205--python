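# ontoscope

A headless browser for OBO-format bio-ontologies. Given one or more
ontology flat files and a query, it extracts a term's **local
environment** — the term itself, its child terms, and every term and
relation on some path from the term up to an ontology root — lays the
subgraph out with a force-based algorithm, and exports the picture and
data as SVG, XGMML (Cytoscape-importable) and tab-delimited tables.

It is aimed at biologists and curators who need a quick, scriptable view
of where a term sits in its ontology: which parents it inherits from
(bio-ontologies have multiple inheritance, so tree views are lossy),
which children it has, and how two terms' ancestries intersect. Large
application ontologies are handled by a display cap (first 500 terms,
breadth-first from the focus) plus filters on relation types, obsolete
terms and children.

## The model

**Environment extraction.** An ontology is a set of terms with typed
directed relations, child → parent (`is_a`, `part_of`, `develops_from`,
…). The local environment of a focus term *f* under a predicate filter
*P* is

&nbsp;&nbsp;&nbsp;&nbsp;E(f) = {f} ∪ children_P(f) ∪ {t : t lies on a directed path f → root over predicates in P},

computed by breadth-first traversal with a visited set, so bidirectional
or cyclic relation structures (they occur in application ontologies such
as cell-cycle resources) terminate; of a bidirectional pair only the
first-traversed direction is kept, which keeps the displayed edge set
acyclic. Ancestors get hierarchy levels by longest-path layering:
level(t) = longest kept-edge path from the focus to t.

**Layout.** Terms are repelling, electrically charged rectangles sized to
their labels; relations are springs with a preferred length (scaled by
level difference) and, for hierarchy predicates, a preferred north–south
orientation so parents settle above children. The force law per
integration step:

- repulsion between every pair: `k_r / max(gap, gap_min)²` along the
  centre line, where `gap` is the centre distance minus both rectangles'
  projected half-extents;
- spring: `k_s · (d − L·scale)` along the connector;
- orientation couple: `k_o · sin θ` perpendicular to the connector,
  θ the angle between connector and preferred direction.

Damped explicit Euler integration runs until the largest per-node
displacement stays below tolerance. Anchored nodes never move. Relayout
after a browsing step is **incremental**: persisting terms keep their
exact positions, so the graph reorganises minimally.

## Worked example

Generate a synthetic 30-term ontology and expand one term:

```
$ ontoscope fixtures --n-terms 30 --seed 5 --out demo.obo
wrote demo.obo (30 terms, 53 relations)

$ ontoscope view --obo demo.obo -q "term 0000030" --svg demo.svg --tsv demo
ontology: DEMO
focus terms: T:0000030
terms shown: 7  edges: 9
layout converged: True (iterations: 282)
wrote demo.svg
wrote demo.nodes.tsv
wrote demo.edges.tsv
```

The query `term 0000030` was matched by autosuggest (names and synonyms,
exact > prefix > substring) and expanded: its environment holds 7 terms
and 9 relations — the focus plus every ancestor path to the root. The
layout relaxed to equilibrium in 282 steps. The nodes table carries the
hierarchy level of each term (longest path from the focus):

```
id	name	obsolete	is_leaf	level
T:0000001	term 0000001	false	false	5
T:0000002	term 0000002	false	false	4
T:0000003	term 0000003	false	false	3
```

Multi-term queries merge environments (`-q "alpha,beta"`; commas inside a
term are escaped `\,`, literal backslashes doubled), identifiers can be
disambiguated with the ontology short name as prefix (`NEWT:1234`,
`ZFA:ZFS:0000019`), `--roots` expands an ontology's root terms, and
`--exclude`, `--hide-obsolete`, `--parents-only`, `--cap` filter the
view. `--seed` fixes the layout's tie-breaking randomness: identical
inputs and seed give byte-identical outputs.

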