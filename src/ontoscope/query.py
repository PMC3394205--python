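"""Query parsing, identifier resolution and autosuggestion ranking.

Multi-term queries are comma-separated; a comma inside a term is escaped as
``\\,`` and a literal backslash is doubled.  Identifiers can be disambiguated
with the ontology short name as a prefix (``NEWT:1234``, ``ZFA:ZFS:0000019``)
because id prefixes are not standardised across ontologies.

Autosuggestion ranks hits by lexical match specificity (exact id, exact
name, exact synonym, name prefix, synonym prefix, substring) — a
deterministic stand-in for usage-based "best known matches" ranking.
Name/synonym matching is case-insensitive; term ids are case-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

from .ontology import Ontology

logger = logging.getLogger(__name__)

#: rank classes in descending priority
RANK_CLASSES = (
    "exact-id",
    "exact-name",
    "exact-synonym",
    "name-prefix",
    "synonym-prefix",
    "substring",
)
_RANK_INDEX = {rc: i for i, rc in enumerate(RANK_CLASSES)}

DEFAULT_SUGGEST_LIMIT = 10


class QuerySyntaxError(ValueError):
    """Malformed query string (e.g. trailing lone backslash)."""


class ResolutionError(LookupError):
    """No part of the query resolved to any term; lists the failed parts."""

    def __init__(self, failed: list[str]):
        self.failed = list(failed)
        super().__init__("no match for query part(s): " + ", ".join(repr(p) for p in failed))


@dataclass(frozen=True)
class QueryHit:
    """One autosuggestion: where it matched and how well."""

    term_id: str
    ontology: str
    matched_text: str
    rank_class: str

    @property
    def sort_key(self):
        return (_RANK_INDEX[self.rank_class], self.matched_text, self.term_id)


def parse_multi_query(raw: str) -> list[str]:
    """Split a raw query on unescaped commas.

    ``\\,`` decodes to a literal comma, ``\\\\`` to a single backslash; each
    part is whitespace-trimmed and empty parts are dropped.

    Raises
    ------
    QuerySyntaxError
        If the string ends in a lone (unpaired) backslash.
    """
    parts: list[str] = []
    buf: list[str] = []
    i = 0
    while i < len(raw):
        c = raw[i]
        if c == "\\":
            if i + 1 >= len(raw):
                raise QuerySyntaxError("query ends in a lone backslash")
            nxt = raw[i + 1]
            if nxt in (",", "\\"):
                buf.append(nxt)
                i += 2
                continue
            # backslash before anything else is kept verbatim
            buf.append(c)
            i += 1
            continue
        if c == ",":
            parts.append("".join(buf))
            buf = []
            i += 1
            continue
        buf.append(c)
        i += 1
    parts.append("".join(buf))
    return [p.strip() for p in parts if p.strip()]


def escape_query_part(part: str) -> str:
    """Inverse of the :func:`parse_multi_query` decoding for one part."""
    return part.replace("\\", "\\\\").replace(",", "\\,")


def resolve_identifier(
    raw: str,
    onts: Mapping[str, Ontology],
    restrict: Optional[str] = None,
) -> Optional[tuple[Ontology, str]]:
    """Resolve ``raw`` as a term identifier, with short-name prefix fallback.

    Order: (1) ``raw`` as a full term id in the restricted ontology (or any
    loaded ontology, in load order); (2) if ``raw`` starts with
    ``<short_name>:`` of a loaded ontology, the remainder as a term id there.
    Returns None when neither applies (caller falls back to autosuggest);
    a prefix naming an unloaded ontology is a no-match, not an error.
    """
    if not onts:
        raise ValueError("no ontologies loaded")
    search = [onts[restrict]] if restrict and restrict in onts else list(onts.values())
    for ont in search:
        if raw in ont.terms:
            return ont, raw
    if ":" in raw:
        prefix, _, rest = raw.partition(":")
        ont = onts.get(prefix)
        if ont is not None and rest in ont.terms:
            return ont, rest
    return None


def autosuggest(
    query: str,
    onts: Mapping[str, Ontology],
    restrict: Optional[str] = None,
    hide_obsolete: bool = False,
    limit: int = DEFAULT_SUGGEST_LIMIT,
) -> list[QueryHit]:
    """Ranked term suggestions for a (partial) query over names and synonyms.

    Obsolete terms are omitted when ``hide_obsolete`` (the obsolete filter
    extends to suggestion lists); ``restrict`` confines hits to one ontology.
    Each term contributes at most one hit, at its best rank class.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    q = query.strip()
    if not q:
        return []
    ql = q.lower()
    search = [onts[restrict]] if restrict and restrict in onts else list(onts.values())

    hits: list[QueryHit] = []
    for ont in search:
        for term in ont.terms.values():
            if hide_obsolete and term.obsolete:
                continue
            best: Optional[tuple[str, str]] = None  # (rank_class, matched_text)

            def consider(rank_class: str, text: str):
                nonlocal best
                cand = (rank_class, text)
                if best is None or (_RANK_INDEX[cand[0]], cand[1]) < (_RANK_INDEX[best[0]], best[1]):
                    best = cand

            if q == term.id:
                consider("exact-id", term.id)
            nl = term.name.lower()
            if nl == ql:
                consider("exact-name", term.name)
            elif nl.startswith(ql):
                consider("name-prefix", term.name)
            elif ql in nl:
                consider("substring", term.name)
            for syn in sorted(term.synonyms):
                sl = syn.lower()
                if sl == ql:
                    consider("exact-synonym", syn)
                elif sl.startswith(ql):
                    consider("synonym-prefix", syn)
                elif ql in sl:
                    consider("substring", syn)
            if best is not None:
                hits.append(QueryHit(term.id, ont.short_name, best[1], best[0]))
    hits.sort(key=lambda h: h.sort_key)
    return hits[:limit]


def resolve_query(
    raw: str,
    onts: Mapping[str, Ontology],
    restrict: Optional[str] = None,
    hide_obsolete: bool = False,
) -> list[tuple[Ontology, str]]:
    """Resolve a full (possibly multi-term) query to (ontology, term id) pairs.

    Each part is tried as an identifier first; otherwise the first
    autosuggestion is taken.  Parts that resolve to nothing are logged and
    skipped; if *no* part resolves, :class:`ResolutionError` is raised.
    """
    parts = parse_multi_query(raw)
    resolved: list[tuple[Ontology, str]] = []
    failed: list[str] = []
    for part in parts:
        hit = resolve_identifier(part, onts, restrict)
        if hit is None:
            suggestions = autosuggest(part, onts, restrict, hide_obsolete, limit=1)
            if suggestions:
                s = suggestions[0]
                hit = (onts[s.ontology], s.term_id)
        if hit is None:
            failed.append(part)
            logger.warning("query part %r matched no term", part)
        else:
            resolved.append(hit)
    if parts and not resolved:
        raise ResolutionError(failed)
    return resolved
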