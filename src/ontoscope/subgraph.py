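"""Local-environment extraction, merging, hierarchy levels and the term cap.

A term's *local environment* is the focus term, its child terms, and every
term and relation lying on some directed path from the focus up to an
ontology root, under the active filters.  Traversal keeps a visited set and
only keeps edges in the direction they were first walked, so bidirectional
or cyclic relation structures (they exist in application ontologies)
terminate and the kept edge set is acyclic — which the hierarchy-level
assignment relies on.

Levels follow longest-path layering, the standard layering for layered DAG
drawing: level(t) is the length of the longest kept-edge path from a focus
to t; foci and their children sit at level 0, ancestors at level >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ontology import Ontology, Relation, children_of, parents_of

#: Display cap on environment size before truncation kicks in.
DEFAULT_TERM_CAP = 500


@dataclass(frozen=True)
class Filters:
    """View filters applied while building an environment.

    ``excluded_predicates`` may name unknown relation types (they match
    nothing).  ``parents_only`` drops the children layer and keeps ancestor
    paths.  ``hide_obsolete`` removes obsolete terms (the focus itself is
    always kept).
    """

    excluded_predicates: frozenset[str] = frozenset()
    hide_obsolete: bool = False
    parents_only: bool = False

    def __post_init__(self):
        object.__setattr__(self, "excluded_predicates", frozenset(self.excluded_predicates))


@dataclass
class Subgraph:
    """A view on an ontology: foci, included terms/edges, levels, cap flag."""

    focus_ids: list[str] = field(default_factory=list)
    term_ids: list[str] = field(default_factory=list)
    edges: set[Relation] = field(default_factory=set)
    truncated: bool = False
    levels: dict[str, int] = field(default_factory=dict)

    def __contains__(self, term_id: str) -> bool:
        return term_id in set(self.term_ids)

    def __len__(self) -> int:
        return len(self.term_ids)


def _allowed_predicates(ont: Ontology, filters: Filters) -> set[str]:
    return ont.relation_types - set(filters.excluded_predicates)


def _would_close_cycle(edges: set[Relation], subject: str, obj: str) -> bool:
    """True if adding subject->obj creates a directed cycle in ``edges``."""
    # DFS from obj over existing edges; cycle iff subject is reachable.
    stack, seen = [obj], set()
    succ: dict[str, list[str]] = {}
    for e in edges:
        succ.setdefault(e.subject, []).append(e.object)
    while stack:
        node = stack.pop()
        if node == subject:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(succ.get(node, ()))
    return False


def local_environment(
    ont: Ontology,
    focus: str,
    filters: Filters = Filters(),
    direct_parents_only: bool = False,
) -> Subgraph:
    """Build the focus term's local environment under ``filters``.

    The result contains the focus, its children via non-excluded predicates
    (unless ``filters.parents_only``), and every term/edge on some path from
    the focus to a root via non-excluded predicates.  Obsolete terms are
    excluded when ``filters.hide_obsolete`` (and block traversal through
    them); the focus itself is always kept.  ``direct_parents_only`` stops
    the upward walk after the focus's direct parents (the narrow reading of
    a parents-only view); by default all ancestor levels are kept.

    Raises ``KeyError`` for an unknown focus id.
    """
    if focus not in ont.terms:
        raise KeyError(f"term {focus!r} not in ontology {ont.short_name!r}")
    allowed = _allowed_predicates(ont, filters)

    env = Subgraph(focus_ids=[focus], term_ids=[focus])
    included = {focus}

    def admissible(tid: str) -> bool:
        return not (filters.hide_obsolete and ont.terms[tid].obsolete)

    # children layer
    if not filters.parents_only:
        for child, pred in children_of(ont, focus, allowed):
            if not admissible(child):
                continue
            if child not in included:
                included.add(child)
                env.term_ids.append(child)
            env.edges.add(Relation(child, pred, focus))

    # ancestor paths: BFS upward; keep first-traversed edge direction,
    # drop any edge that would close a cycle among kept edges
    queue = [focus]
    visited = {focus}
    while queue:
        cur = queue.pop(0)
        if direct_parents_only and cur != focus:
            continue
        for parent, pred in parents_of(ont, cur, allowed):
            if not admissible(parent):
                continue
            # keep the edge only if it does not close a directed cycle among
            # already-kept edges (first-traversed direction wins), but always
            # continue the upward walk through the parent: its own ancestors
            # are still on a path to the root
            if not _would_close_cycle(env.edges, cur, parent):
                if parent not in included:
                    included.add(parent)
                    env.term_ids.append(parent)
                env.edges.add(Relation(cur, pred, parent))
            if parent not in visited:
                visited.add(parent)
                queue.append(parent)

    env.levels = hierarchy_levels(env, ont)
    return env


def merge_environments(envs: Sequence[Subgraph]) -> Subgraph:
    """Set-union of environments from the same ontology.

    Foci are concatenated in input order (first occurrence wins); levels are
    recomputed on the merged edge set; the merge is truncated if any input
    was.
    """
    merged = Subgraph()
    seen_terms: set[str] = set()
    seen_foci: set[str] = set()
    for env in envs:
        for f in env.focus_ids:
            if f not in seen_foci:
                seen_foci.add(f)
                merged.focus_ids.append(f)
        for t in env.term_ids:
            if t not in seen_terms:
                seen_terms.add(t)
                merged.term_ids.append(t)
        for e in env.edges:
            if not _would_close_cycle(merged.edges, e.subject, e.object):
                merged.edges.add(e)
        merged.truncated = merged.truncated or env.truncated
    merged.levels = hierarchy_levels(merged, None)
    return merged


def apply_term_cap(env: Subgraph, cap: int = DEFAULT_TERM_CAP, ont: Optional[Ontology] = None) -> Subgraph:
    """Keep only the first ``cap`` terms in breadth-first order from the foci.

    BFS explores the children direction first, then the ancestor direction;
    neighbour ties follow the deterministic (name, id, predicate) ordering
    when ``ont`` is given, else (id, predicate).  Focus terms always survive.
    Edges with a dropped endpoint are dropped.  ``truncated`` is set iff at
    least one term was removed.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(env.term_ids) <= cap:
        return Subgraph(
            focus_ids=list(env.focus_ids),
            term_ids=list(env.term_ids),
            edges=set(env.edges),
            truncated=False,
            levels=dict(env.levels),
        )

    def name_of(tid: str) -> str:
        return ont.terms[tid].name if ont is not None and tid in ont.terms else tid

    children_adj: dict[str, list[tuple[str, str, str]]] = {}
    parents_adj: dict[str, list[tuple[str, str, str]]] = {}
    for e in env.edges:
        children_adj.setdefault(e.object, []).append((name_of(e.subject), e.subject, e.predicate))
        parents_adj.setdefault(e.subject, []).append((name_of(e.object), e.object, e.predicate))
    for adj in (children_adj, parents_adj):
        for lst in adj.values():
            lst.sort()

    order: list[str] = []
    seen: set[str] = set()
    queue: list[str] = []
    for f in env.focus_ids:
        if f not in seen:
            seen.add(f)
            order.append(f)
            queue.append(f)
    while queue:
        cur = queue.pop(0)
        for adj in (children_adj, parents_adj):
            for _, nbr, _pred in adj.get(cur, ()):
                if nbr not in seen:
                    seen.add(nbr)
                    order.append(nbr)
                    queue.append(nbr)
    # terms disconnected from every focus come last, in original order
    for t in env.term_ids:
        if t not in seen:
            seen.add(t)
            order.append(t)

    kept = set(order[:cap])
    capped = Subgraph(
        focus_ids=[f for f in env.focus_ids if f in kept],
        term_ids=[t for t in env.term_ids if t in kept],
        edges={e for e in env.edges if e.subject in kept and e.object in kept},
        truncated=True,
    )
    capped.levels = {t: lv for t, lv in env.levels.items() if t in kept}
    return capped


def hierarchy_levels(env: Subgraph, ont: Optional[Ontology] = None) -> dict[str, int]:
    """Longest-path layering from the focus set over the kept (acyclic) edges.

    level(t) = length of the longest directed path from any focus to t;
    foci, their children and anything unreachable from a focus get 0.
    """
    terms = list(env.term_ids)
    succ: dict[str, list[str]] = {t: [] for t in terms}
    indeg: dict[str, int] = {t: 0 for t in terms}
    for e in env.edges:
        succ[e.subject].append(e.object)
        indeg[e.object] += 1

    # Kahn topological order over kept edges
    queue = [t for t in terms if indeg[t] == 0]
    topo: list[str] = []
    indeg_w = dict(indeg)
    while queue:
        cur = queue.pop(0)
        topo.append(cur)
        for nxt in succ[cur]:
            indeg_w[nxt] -= 1
            if indeg_w[nxt] == 0:
                queue.append(nxt)

    NEG = float("-inf")
    dist: dict[str, float] = {t: NEG for t in terms}
    for f in env.focus_ids:
        dist[f] = 0
    for cur in topo:
        if dist[cur] == NEG:
            continue
        for nxt in succ[cur]:
            if dist[cur] + 1 > dist[nxt]:
                dist[nxt] = dist[cur] + 1
    return {t: (int(d) if d != NEG else 0) for t, d in dist.items()}
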