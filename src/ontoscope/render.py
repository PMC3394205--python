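"""Serialization of a laid-out environment: SVG, XGMML, tab-delimited tables.

The SVG picture mirrors the on-screen conventions: rounded label boxes
(leaf terms -- terms without children anywhere in the ontology -- get a
light orange fill), coloured arrows for the three most common relation
types, abbreviated relation labels with the full name in a tooltip, and a
zoom law that widens distances faster than it grows fonts (an extra guard
against label overlap when zooming in).

XGMML output is the minimal Cytoscape-importable subset: node labels carry
the term names and an ``ontID`` string attribute stores the term
identifier; edges are labelled with the relation type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .ontology import Ontology
from .subgraph import Subgraph
from .layout import LayoutState

DEFAULT_EDGE_COLORS = {
    "is_a": "#3366cc",          # blue
    "part_of": "#33a02c",       # green
    "develops_from": "#9955bb", # purple
}


@dataclass(frozen=True)
class RenderSpec:
    """Style constants for SVG rendering."""

    edge_colors: dict = field(default_factory=lambda: dict(DEFAULT_EDGE_COLORS))
    default_edge_color: str = "#999999"
    leaf_fill: str = "#ffe0b3"   # slightly orange
    node_fill: str = "#e8eef7"
    font_size_base: float = 11.0
    char_width: float = 7.0
    padding: float = 6.0
    zoom: float = 1.0
    zoom_distance_exponent: float = 1.0
    zoom_font_exponent: float = 0.6
    abbreviation_max_chars: int = 10

    def __post_init__(self):
        if self.zoom <= 0:
            raise ValueError("zoom must be > 0")
        if not (self.zoom_distance_exponent > self.zoom_font_exponent > 0):
            raise ValueError("need zoom_distance_exponent > zoom_font_exponent > 0")


def abbreviate(label: str, max_chars: int) -> str:
    """Shorten labels longer than ``max_chars``: keep max_chars-1 + ellipsis."""
    if len(label) <= max_chars:
        return label
    return label[: max_chars - 1] + "…"


def _leaf_ids(ont: Ontology) -> set[str]:
    has_children = {r.object for r in ont.relations}
    return {tid for tid in ont.terms if tid not in has_children}


def render_svg(env: Subgraph, layout: LayoutState, ont: Ontology, spec: RenderSpec = RenderSpec()) -> str:
    """Render the laid-out environment as an SVG 1.1 document string.

    Element order is deterministic (terms by id, edges by subject/predicate/
    object triple), so identical inputs give byte-identical output.

    Raises ``KeyError`` naming any environment term missing from the layout.
    """
    for tid in env.term_ids:
        if tid not in layout.nodes:
            raise KeyError(f"term {tid!r} has no layout position")

    dscale = spec.zoom ** spec.zoom_distance_exponent
    font_size = spec.font_size_base * spec.zoom ** spec.zoom_font_exponent
    leaves = _leaf_ids(ont)

    def px(tid: str) -> tuple[float, float]:
        x, y = layout.nodes[tid].position
        return x * dscale, y * dscale

    xs, ys = [], []
    for tid in env.term_ids:
        x, y = px(tid)
        hw, hh = layout.nodes[tid].half_extent
        xs += [x - hw - 20, x + hw + 20]
        ys += [y - hh - 20, y + hh + 20]
    min_x, max_x = (min(xs), max(xs)) if xs else (0, 100)
    min_y, max_y = (min(ys), max(ys)) if ys else (0, 100)

    NS = "http://www.w3.org/2000/svg"
    svg = etree.Element(
        "{%s}svg" % NS,
        nsmap={None: NS},
        width=f"{max_x - min_x:.1f}",
        height=f"{max_y - min_y:.1f}",
        viewBox=f"{min_x:.1f} {min_y:.1f} {max_x - min_x:.1f} {max_y - min_y:.1f}",
        version="1.1",
    )
    defs = etree.SubElement(svg, "{%s}defs" % NS)
    marker = etree.SubElement(
        defs, "{%s}marker" % NS, id="arrow", markerWidth="8", markerHeight="8",
        refX="7", refY="3", orient="auto", markerUnits="strokeWidth",
    )
    etree.SubElement(marker, "{%s}path" % NS, d="M0,0 L7,3 L0,6 z", fill="context-stroke")

    edge_group = etree.SubElement(svg, "{%s}g" % NS, attrib={"class": "edges"})
    for e in sorted(env.edges, key=lambda e: (e.subject, e.predicate, e.object)):
        x1, y1 = px(e.subject)
        x2, y2 = px(e.object)
        color = spec.edge_colors.get(e.predicate, spec.default_edge_color)
        g = etree.SubElement(edge_group, "{%s}g" % NS)
        title = etree.SubElement(g, "{%s}title" % NS)
        title.text = e.predicate
        etree.SubElement(
            g, "{%s}line" % NS,
            x1=f"{x1:.2f}", y1=f"{y1:.2f}", x2=f"{x2:.2f}", y2=f"{y2:.2f}",
            stroke=color, attrib={"stroke-width": "1.4", "marker-end": "url(#arrow)"},
        )
        label = etree.SubElement(
            g, "{%s}text" % NS,
            x=f"{(x1 + x2) / 2:.2f}", y=f"{(y1 + y2) / 2 - 2:.2f}",
            fill=color,
            attrib={"font-size": f"{font_size * 0.8:.2f}", "text-anchor": "middle"},
        )
        label.text = abbreviate(e.predicate, spec.abbreviation_max_chars)

    node_group = etree.SubElement(svg, "{%s}g" % NS, attrib={"class": "nodes"})
    for tid in sorted(env.term_ids):
        x, y = px(tid)
        hw, hh = layout.nodes[tid].half_extent
        term = ont.terms.get(tid)
        name = term.name if term is not None else tid
        fill = spec.leaf_fill if tid in leaves else spec.node_fill
        g = etree.SubElement(node_group, "{%s}g" % NS)
        title = etree.SubElement(g, "{%s}title" % NS)
        title.text = f"{tid}: {term.definition}" if term is not None and term.definition else tid
        etree.SubElement(
            g, "{%s}rect" % NS,
            x=f"{x - hw:.2f}", y=f"{y - hh:.2f}",
            width=f"{2 * hw:.2f}", height=f"{2 * hh:.2f}",
            rx="6", ry="6", fill=fill, stroke="#555555",
            attrib={"stroke-width": "1"},
        )
        text = etree.SubElement(
            g, "{%s}text" % NS,
            x=f"{x:.2f}", y=f"{y:.2f}",
            attrib={
                "font-size": f"{font_size:.2f}",
                "text-anchor": "middle",
                "dominant-baseline": "central",
                "font-family": "sans-serif",
            },
        )
        text.text = name
    return etree.tostring(svg, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


def write_xgmml(env: Subgraph, layout: Optional[LayoutState], ont: Ontology) -> str:
    """Serialize the environment as Cytoscape-importable XGMML text.

    One ``<node>`` per term, ``label`` = term name, plus a string attribute
    ``ontID`` holding the term identifier; graphics x/y come from the layout
    when one is given.  One ``<edge>`` per relation with the predicate as
    the edge label.  Ordering matches :func:`render_svg` (deterministic).
    """
    NS = "http://www.cs.rpi.edu/XGMML"
    graph = etree.Element("{%s}graph" % NS, nsmap={None: NS},
                          label=ont.short_name, directed="1")
    index = {tid: i + 1 for i, tid in enumerate(sorted(env.term_ids))}
    for tid in sorted(env.term_ids):
        term = ont.terms.get(tid)
        name = term.name if term is not None else tid
        node = etree.SubElement(graph, "{%s}node" % NS, id=str(index[tid]), label=name)
        etree.SubElement(node, "{%s}att" % NS, name="ontID", type="string", value=tid)
        if layout is not None and tid in layout.nodes:
            x, y = layout.nodes[tid].position
            etree.SubElement(node, "{%s}graphics" % NS, x=f"{x:.4f}", y=f"{y:.4f}",
                             type="RECTANGLE")
    for e in sorted(env.edges, key=lambda e: (e.subject, e.predicate, e.object)):
        etree.SubElement(
            graph, "{%s}edge" % NS,
            source=str(index[e.subject]), target=str(index[e.object]), label=e.predicate,
        )
    return etree.tostring(graph, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


def _clean(text: str) -> str:
    """Tabs/newlines inside field values become single spaces."""
    return text.replace("\t", " ").replace("\n", " ").replace("\r", " ")


def write_tsv(env: Subgraph, ont: Ontology) -> tuple[str, str]:
    """Tab-delimited (nodes, edges) tables for spreadsheet use.

    Nodes: ``id  name  obsolete  is_leaf  level`` (terms in id order).
    Edges: ``subject  predicate  object``.  LF line endings.
    """
    leaves = _leaf_ids(ont)
    node_lines = ["id\tname\tobsolete\tis_leaf\tlevel"]
    for tid in sorted(env.term_ids):
        term = ont.terms.get(tid)
        name = term.name if term is not None else tid
        obsolete = term.obsolete if term is not None else False
        node_lines.append(
            f"{_clean(tid)}\t{_clean(name)}\t{str(obsolete).lower()}"
            f"\t{str(tid in leaves).lower()}\t{env.levels.get(tid, 0)}"
        )
    edge_lines = ["subject\tpredicate\tobject"]
    for e in sorted(env.edges, key=lambda e: (e.subject, e.predicate, e.object)):
        edge_lines.append(f"{_clean(e.subject)}\t{_clean(e.predicate)}\t{_clean(e.object)}")
    return "\n".join(node_lines) + "\n", "\n".join(edge_lines) + "\n"
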