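"""In-memory model of one OBO-format ontology and structural accessors.

Edge direction convention, used throughout the package: relations point
child -> parent, i.e. ``Relation.subject`` is the child (the term whose
stanza declared the tag) and ``Relation.object`` is the parent.  A *root*
is a term with no outgoing edge under the active predicate filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

#: Predicates treated as hierarchy-defining (child-to-parent) by default.
HIERARCHY_PREDICATES = frozenset({"is_a", "part_of", "develops_from"})


class OboParseError(ValueError):
    """Raised on a malformed OBO stanza; the message names the offending line."""


@dataclass(frozen=True)
class Term:
    """One ontology concept.

    ``name`` falls back to ``id`` when the stanza has no name tag, so every
    term is displayable.
    """

    id: str
    name: str
    synonyms: frozenset[str] = frozenset()
    definition: Optional[str] = None
    obsolete: bool = False
    xrefs: frozenset[str] = frozenset()
    namespace: Optional[str] = None


@dataclass(frozen=True)
class Relation:
    """A typed directed edge; ``subject`` is the child, ``object`` the parent."""

    subject: str
    predicate: str
    object: str


@dataclass
class Ontology:
    """Immutable-by-convention store for one parsed OBO file.

    ``terms`` preserves stanza order (dict insertion order); ``relation_types``
    is exactly the set of predicates occurring in ``relations``.
    """

    short_name: str
    terms: dict[str, Term] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)

    @property
    def relation_types(self) -> set[str]:
        return {r.predicate for r in self.relations}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)


_SYNONYM_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _strip_comment(value: str) -> str:
    """Drop everything after the first unescaped '!' (OBO trailing comment)."""
    out = []
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            out.append(value[i : i + 2])
            i += 2
            continue
        if c == "!":
            break
        out.append(c)
        i += 1
    return "".join(out).strip()


def _unescape(value: str) -> str:
    """Decode OBO backslash escapes (``\\!`` -> ``!``, ``\\\\`` -> ``\\`` ...)."""
    return re.sub(r"\\(.)", r"\1", value)


def _first_quoted(value: str) -> Optional[str]:
    m = _SYNONYM_QUOTED.search(value)
    if m is None:
        return None
    return _unescape(m.group(1))


def parse_obo(path, short_name: Optional[str] = None) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Only ``[Term]`` stanzas are read; other stanza types (``[Typedef]`` ...)
    are skipped with a debug log.  Recognised tags: ``id``, ``name``, ``def``,
    ``synonym``, ``is_a``, ``relationship``, ``is_obsolete``, ``xref``,
    ``namespace``; anything else is ignored.  Text after an unescaped ``!``
    is stripped.  Relations whose target id is not defined in the file are
    dropped with a warning naming the line.

    Parameters
    ----------
    path:
        Readable text file (UTF-8).
    short_name:
        Ontology short name; defaults to the file stem upper-cased.

    Raises
    ------
    OboParseError
        For a stanza without an ``id`` tag or a duplicate term id; the
        message carries the line number.
    OSError
        If the file cannot be read.
    """
    import os

    if short_name is None:
        short_name = os.path.splitext(os.path.basename(str(path)))[0].upper()

    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    ont = Ontology(short_name=short_name)
    pending_relations: list[tuple[Relation, int]] = []

    in_term = False
    stanza_start = 0
    cur: dict = {}

    def flush():
        nonlocal cur
        if not in_term:
            return
        if "id" not in cur:
            raise OboParseError(f"[Term] stanza starting at line {stanza_start} has no id: tag")
        tid = cur["id"]
        if tid in ont.terms:
            raise OboParseError(f"duplicate term id {tid!r} at line {stanza_start}")
        ont.terms[tid] = Term(
            id=tid,
            name=cur.get("name", tid),
            synonyms=frozenset(cur.get("synonyms", ())),
            definition=cur.get("definition"),
            obsolete=cur.get("obsolete", False),
            xrefs=frozenset(cur.get("xrefs", ())),
            namespace=cur.get("namespace"),
        )
        cur = {}

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            stanza_start = lineno
            if not in_term and line != "[Term]":
                logger.debug("skipping stanza %s at line %d", line, lineno)
            continue
        if not in_term:
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = _strip_comment(value.strip())
        if tag == "id":
            cur["id"] = _unescape(value)
        elif tag == "name":
            cur["name"] = _unescape(value)
        elif tag == "def":
            q = _first_quoted(value)
            cur["definition"] = q if q is not None else value
        elif tag == "synonym":
            q = _first_quoted(value)
            if q is not None:
                cur.setdefault("synonyms", []).append(q)
        elif tag == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
        elif tag == "xref":
            cur.setdefault("xrefs", []).append(_unescape(value))
        elif tag == "namespace":
            cur["namespace"] = value
        elif tag == "is_a":
            if "id" in cur and value:
                pending_relations.append((Relation(cur["id"], "is_a", value), lineno))
        elif tag == "relationship":
            parts = value.split(None, 1)
            if len(parts) == 2 and "id" in cur:
                pred, target = parts[0], parts[1].strip()
                pending_relations.append((Relation(cur["id"], pred, target), lineno))
        # unknown tags ignored
    flush()

    for rel, lineno in pending_relations:
        if rel.object not in ont.terms:
            logger.warning(
                "line %d: dropping relation %s -[%s]-> %s (target not defined)",
                lineno, rel.subject, rel.predicate, rel.object,
            )
            continue
        ont.relations.append(rel)
    return ont


def find_roots(ont: Ontology, allowed: Iterable[str]) -> list[str]:
    """Non-obsolete terms with no outgoing edge whose predicate is allowed.

    Returned in term insertion (stanza) order.  Unknown predicate names in
    ``allowed`` simply match nothing.
    """
    allowed = set(allowed)
    has_parent = {r.subject for r in ont.relations if r.predicate in allowed}
    return [tid for tid, t in ont.terms.items() if not t.obsolete and tid not in has_parent]


def _check_id(ont: Ontology, term_id: str) -> None:
    if term_id not in ont.terms:
        raise KeyError(f"term {term_id!r} not in ontology {ont.short_name!r}")


def children_of(ont: Ontology, term_id: str, allowed: Iterable[str]) -> list[tuple[str, str]]:
    """Incoming allowed edges of ``term_id``: (child id, predicate) pairs.

    Deterministic order: sorted by child name, then child id, then predicate.
    """
    _check_id(ont, term_id)
    allowed = set(allowed)
    hits = [(r.subject, r.predicate) for r in ont.relations
            if r.object == term_id and r.predicate in allowed]
    hits.sort(key=lambda cp: (ont.terms[cp[0]].name, cp[0], cp[1]))
    return hits


def parents_of(ont: Ontology, term_id: str, allowed: Iterable[str]) -> list[tuple[str, str]]:
    """Outgoing allowed edges of ``term_id``: (parent id, predicate) pairs.

    Mirror image of :func:`children_of`, same ordering rule.
    """
    _check_id(ont, term_id)
    allowed = set(allowed)
    hits = [(r.object, r.predicate) for r in ont.relations
            if r.subject == term_id and r.predicate in allowed]
    hits.sort(key=lambda cp: (ont.terms[cp[0]].name, cp[0], cp[1]))
    return hits
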