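"""Synthetic OBO ontologies with controlled DAG structure.

Real bio-ontologies are multiple-inheritance DAGs with a handful of typed
relations dominated by is_a / part_of / develops_from, occasional obsolete
terms, and (in application ontologies) bidirectional relation pairs.  The
generator reproduces exactly those structural features so every module can
be exercised without downloading anything; it makes no attempt to mimic a
specific ontology's degree or depth statistics.

Construction guarantees: term k (k > n_roots) draws its parents uniformly
from earlier terms, so the hierarchy-edge graph is acyclic and every term
has a directed path to some root.  Reverse "twin" edges, which create
2-cycles, are only added for non-hierarchy predicates so the hierarchy DAG
survives.  Everything is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ontology import HIERARCHY_PREDICATES, Ontology, Relation, Term

DEFAULT_PREDICATE_WEIGHTS = {"is_a": 0.7, "part_of": 0.2, "develops_from": 0.1}


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the random-ontology generator."""

    n_terms: int = 30
    n_roots: int = 1
    max_parents: int = 3
    predicate_weights: dict = field(default_factory=lambda: dict(DEFAULT_PREDICATE_WEIGHTS))
    obsolete_fraction: float = 0.0
    bidirectional_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 1 or self.n_roots < 1 or self.max_parents < 1:
            raise ValueError("n_terms, n_roots and max_parents must be >= 1")
        if self.n_roots > self.n_terms:
            raise ValueError("n_roots cannot exceed n_terms")
        if not (0.0 <= self.obsolete_fraction < 1.0):
            raise ValueError("obsolete_fraction must be in [0, 1)")
        if not (0.0 <= self.bidirectional_fraction < 1.0):
            raise ValueError("bidirectional_fraction must be in [0, 1)")
        total = sum(self.predicate_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"predicate weights sum to {total}, expected 1")


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def random_ontology(cfg: FixtureConfig = FixtureConfig(), short_name: str = "SYN") -> Ontology:
    """Generate a random DAG ontology per ``cfg``; deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    preds = sorted(cfg.predicate_weights)
    weights = np.array([cfg.predicate_weights[p] for p in preds], dtype=float)
    weights /= weights.sum()

    ont = Ontology(short_name=short_name)
    for i in range(1, cfg.n_terms + 1):
        tid = _term_id(i)
        ont.terms[tid] = Term(id=tid, name=f"term {i:07d}")

    ids = list(ont.terms)
    for k in range(cfg.n_roots, cfg.n_terms):
        child = ids[k]
        n_par = int(rng.integers(1, cfg.max_parents + 1))
        n_par = min(n_par, k)
        parents = rng.choice(k, size=n_par, replace=False)
        for p_idx in sorted(int(p) for p in parents):
            pred = preds[int(rng.choice(len(preds), p=weights))]
            ont.relations.append(Relation(child, pred, ids[p_idx]))

    # reverse twins for a fraction of non-hierarchy edges (2-cycles)
    if cfg.bidirectional_fraction > 0:
        twins = []
        for rel in ont.relations:
            if rel.predicate not in HIERARCHY_PREDICATES and \
                    rng.random() < cfg.bidirectional_fraction:
                twins.append(Relation(rel.object, rel.predicate, rel.subject))
        ont.relations.extend(twins)

    if cfg.obsolete_fraction > 0:
        non_roots = ids[cfg.n_roots:]
        n_obs = int(round(cfg.obsolete_fraction * len(non_roots)))
        if n_obs:
            chosen = rng.choice(len(non_roots), size=n_obs, replace=False)
            for i in sorted(int(c) for c in chosen):
                tid = non_roots[i]
                t = ont.terms[tid]
                ont.terms[tid] = Term(
                    id=t.id, name=t.name, synonyms=t.synonyms, definition=t.definition,
                    obsolete=True, xrefs=t.xrefs, namespace=t.namespace,
                )
    return ont


def _obo_escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace("!", "\\!")


def write_obo(ont: Ontology, path) -> None:
    """Write the ontology as OBO 1.2 text that round-trips through the parser."""
    rel_by_subject: dict[str, list[Relation]] = {}
    for r in ont.relations:
        rel_by_subject.setdefault(r.subject, []).append(r)

    lines = ["format-version: 1.2", f"ontology: {ont.short_name.lower()}", ""]
    for tid, term in ont.terms.items():
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {_obo_escape(term.name)}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        if term.definition is not None:
            escaped = term.definition.replace("\\", "\\\\").replace('"', '\\"')
            lines.append(f'def: "{escaped}" []')
        for syn in sorted(term.synonyms):
            escaped = syn.replace("\\", "\\\\").replace('"', '\\"')
            lines.append(f'synonym: "{escaped}" EXACT []')
        for xref in sorted(term.xrefs):
            lines.append(f"xref: {_obo_escape(xref)}")
        for rel in rel_by_subject.get(tid, ()):
            if rel.predicate == "is_a":
                lines.append(f"is_a: {rel.object}")
            else:
                lines.append(f"relationship: {rel.predicate} {rel.object}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def big_environment_fixture(n_env_terms: int, seed: int = 0) -> tuple[Ontology, str]:
    """An ontology whose focus term's unfiltered environment has an exact size.

    Built as a star of children under the focus plus an is_a chain from the
    focus up to a root, so the environment = focus + children + chain.  Used
    to exercise the display cap.  Returns (ontology, focus id).
    """
    if n_env_terms < 1:
        raise ValueError("n_env_terms must be >= 1")
    ont = Ontology(short_name="BIG")
    if n_env_terms == 1:
        ont.terms["T:0000001"] = Term(id="T:0000001", name="focus")
        return ont, "T:0000001"

    chain_len = min(3, n_env_terms - 1)
    n_children = n_env_terms - 1 - chain_len

    # chain: root = C1, ..., C<chain_len>, then focus below it
    for i in range(1, chain_len + 1):
        tid = _term_id(i)
        ont.terms[tid] = Term(id=tid, name=f"ancestor {i}")
        if i > 1:
            ont.relations.append(Relation(tid, "is_a", _term_id(i - 1)))
    focus = _term_id(chain_len + 1)
    ont.terms[focus] = Term(id=focus, name="focus")
    ont.relations.append(Relation(focus, "is_a", _term_id(chain_len)))

    for j in range(n_children):
        tid = _term_id(chain_len + 2 + j)
        ont.terms[tid] = Term(id=tid, name=f"child {j + 1:05d}")
        ont.relations.append(Relation(tid, "is_a", focus))
    return ont, focus
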