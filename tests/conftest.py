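"""Shared fixtures: tiny hand-built ontologies and independent oracles."""

from __future__ import annotations

import pytest

from ontoscope.ontology import Ontology, Relation, Term


def make_ontology(short_name, terms, relations):
    """Build an Ontology from (id, name[, obsolete]) tuples and triples."""
    ont = Ontology(short_name=short_name)
    for spec in terms:
        tid, name = spec[0], spec[1]
        obsolete = spec[2] if len(spec) > 2 else False
        ont.terms[tid] = Term(id=tid, name=name, obsolete=obsolete)
    for s, p, o in relations:
        ont.relations.append(Relation(s, p, o))
    return ont


@pytest.fixture
def chain_ontology():
    """c -is_a-> b -is_a-> a  (a is the root)."""
    return make_ontology(
        "CHAIN",
        [("T:a", "alpha"), ("T:b", "beta"), ("T:c", "gamma")],
        [("T:c", "is_a", "T:b"), ("T:b", "is_a", "T:a")],
    )


@pytest.fixture
def diamond_ontology():
    """d has two parents b and c, both children of root a."""
    return make_ontology(
        "DIA",
        [("T:a", "apex"), ("T:b", "left"), ("T:c", "right"), ("T:d", "base")],
        [
            ("T:d", "is_a", "T:b"),
            ("T:d", "is_a", "T:c"),
            ("T:b", "is_a", "T:a"),
            ("T:c", "is_a", "T:a"),
        ],
    )


@pytest.fixture
def mixed_predicate_ontology():
    """Diamond whose left path runs over part_of edges."""
    return make_ontology(
        "MIX",
        [("T:a", "apex"), ("T:b", "left"), ("T:c", "right"), ("T:d", "base")],
        [
            ("T:d", "part_of", "T:b"),
            ("T:d", "is_a", "T:c"),
            ("T:b", "part_of", "T:a"),
            ("T:c", "is_a", "T:a"),
        ],
    )


# ---------------------------------------------------------------- oracles

def enumerate_environment(ont, focus, excluded=frozenset(), hide_obsolete=False,
                          parents_only=False):
    """Independent oracle: exhaustive simple-path enumeration upward.

    Returns the set of term ids {focus} | children | {t on some simple
    directed path from focus over allowed edges}.  Recursion over simple
    paths is exponential in the worst case but fine at fixture sizes, and
    entirely independent of the BFS implementation under test.
    """
    allowed = ont.relation_types - set(excluded)

    def ok(tid):
        return not (hide_obsolete and ont.terms[tid].obsolete)

    out_edges = {}
    in_edges = {}
    for r in ont.relations:
        if r.predicate in allowed:
            out_edges.setdefault(r.subject, []).append(r.object)
            in_edges.setdefault(r.object, []).append(r.subject)

    included = {focus}
    if not parents_only:
        for child in in_edges.get(focus, ()):
            if ok(child):
                included.add(child)

    def walk(node, on_path):
        for parent in out_edges.get(node, ()):
            if parent in on_path or not ok(parent):
                continue
            included.add(parent)
            walk(parent, on_path | {parent})

    walk(focus, {focus})
    return included
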