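"""Force-based layout: repelling rectangles, oriented springs, anchoring.

Nodes are modelled as electrically charged rectangles sized to their labels
(they repel each other, which keeps labels from overlapping); relations are
mechanical springs with a preferred length and, for hierarchy predicates,
a preferred north-south orientation (parent above child) that aligns the
drawing hierarchically.  The coordinate frame is y-down (screen
convention): ancestors sit at negative y, children at positive y.

Integration is damped explicit Euler.  All randomness (only used to break
the coincident-centre degeneracy of the repulsion force) is drawn from a
generator seeded by ``LayoutParams.rng_seed``, so runs are bit-reproducible.

The layout is *incremental*: re-layouts after a view change keep every
persisting node exactly where it was before relaxation resumes, so the
graph reorganises minimally and the user can track changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, TextIO

import numpy as np

from .ontology import HIERARCHY_PREDICATES
from .subgraph import Subgraph

#: geometry constants (layout units)
BASE_CHILD_RADIUS = 120.0
LEVEL_GAP = 110.0
LEVEL_HSPACING = 150.0
FOCUS_GAP = 260.0
BASE_SPRING_LENGTH = 100.0
GAP_MIN = 1.0

#: default label box sizing (layout units per character / padding)
CHAR_WIDTH = 7.0
BOX_PADDING = 6.0
BOX_HALF_HEIGHT = 10.0


@dataclass
class LayoutNode:
    """Geometry of one term's rectangle."""

    term_id: str
    position: tuple[float, float]
    half_extent: tuple[float, float]
    anchored: bool = False
    displacement_last_step: float = 0.0
    velocity: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class Spring:
    """A connector: child side ``from_id``, parent side ``to_id``.

    ``orientation`` is the preferred unit direction of the child->parent
    connector; ``(0, -1)`` means parent above child in the y-down frame.
    """

    from_id: str
    to_id: str
    preferred_length: float
    predicate: str
    orientation: Optional[tuple[float, float]] = (0.0, -1.0)


@dataclass(frozen=True)
class LayoutParams:
    """Force and integration constants.

    ``length_scale`` is the user-facing global connector-length multiplier
    (connections can be made longer or shorter to loosen or compact the
    graph); everything else is an internal constant of the physics.
    """

    repulsion_k: float = 2.0e4
    spring_k: float = 0.06
    orientation_k: float = 0.5
    damping: float = 0.85
    step_size: float = 1.0
    convergence_tol: float = 0.05
    max_iterations: int = 3000
    length_scale: float = 1.0
    rng_seed: int = 0
    max_speed: float = 30.0
    oriented_predicates: frozenset[str] = HIERARCHY_PREDICATES

    def __post_init__(self):
        if not (0.0 < self.damping < 1.0):
            raise ValueError("damping must be in (0, 1)")
        if self.length_scale < 0.1:
            raise ValueError("length_scale must be >= 0.1")
        for name in ("repulsion_k", "spring_k", "orientation_k", "step_size",
                     "convergence_tol", "max_iterations", "max_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LayoutState:
    """Node geometry + springs + parameters + iteration counter."""

    nodes: dict[str, LayoutNode]
    springs: list[Spring]
    params: LayoutParams
    iteration: int = 0
    converged: bool = False

    def __post_init__(self):
        self._rng = np.random.default_rng(self.params.rng_seed)

    def positions(self) -> dict[str, tuple[float, float]]:
        return {tid: n.position for tid, n in self.nodes.items()}


def default_node_sizes(env: Subgraph, ont) -> dict[str, tuple[float, float]]:
    """Label-derived box half-extents: half width from character count."""
    sizes = {}
    for tid in env.term_ids:
        label = ont.terms[tid].name if ont is not None and tid in ont.terms else tid
        hw = max(1.0, len(label) * CHAR_WIDTH / 2.0 + BOX_PADDING)
        sizes[tid] = (hw, BOX_HALF_HEIGHT)
    return sizes


def initial_placement(
    env: Subgraph,
    node_sizes: dict[str, tuple[float, float]],
    params: LayoutParams = LayoutParams(),
    keep: Optional[LayoutState] = None,
) -> LayoutState:
    """Hierarchical initial placement of an environment.

    The primary focus (first of ``focus_ids``) anchors the frame at the
    origin.  Its children go on the lower half circle at radius
    ``length_scale * BASE_CHILD_RADIUS``, at angles evenly spaced over the
    open interval (0, pi), left to right in the deterministic child order.
    Ancestors go to ``y = -level * LEVEL_GAP``, spread horizontally within
    each level.  Nodes present in ``keep`` retain their previous positions,
    velocities and anchored flags exactly (the incremental contract).
    Springs are created per edge with preferred length scaled by the level
    difference, oriented parent-above-child for hierarchy predicates.
    """
    if not env.term_ids:
        raise ValueError("cannot lay out an empty environment")
    if not env.focus_ids:
        raise ValueError("environment has no focus term")

    primary = env.focus_ids[0]
    levels = env.levels or {t: 0 for t in env.term_ids}
    kept = keep.nodes if keep is not None else {}

    children_of_focus: dict[str, list[str]] = {f: [] for f in env.focus_ids}
    focus_set = set(env.focus_ids)
    for e in env.edges:
        if e.object in focus_set and levels.get(e.subject, 0) == 0 and e.subject not in focus_set:
            children_of_focus[e.object].append(e.subject)
    for lst in children_of_focus.values():
        lst.sort()

    placed: dict[str, tuple[float, float]] = {}

    # foci along the x axis, primary at the origin
    for i, f in enumerate(env.focus_ids):
        placed[f] = (i * FOCUS_GAP * params.length_scale, 0.0)

    # children: lower half circle under their focus, left to right
    radius = params.length_scale * BASE_CHILD_RADIUS
    for f in env.focus_ids:
        kids = [k for k in children_of_focus[f] if k not in placed]
        n = len(kids)
        fx, fy = placed[f]
        for i, kid in enumerate(kids, start=1):
            theta = math.pi * (1.0 - i / (n + 1))  # pi..0 exclusive, left to right
            placed[kid] = (fx + radius * math.cos(theta), fy + radius * math.sin(theta))

    # ancestors: layered above, spread horizontally by name/id order
    by_level: dict[int, list[str]] = {}
    for t in env.term_ids:
        if t in placed:
            continue
        by_level.setdefault(levels.get(t, 0), []).append(t)
    for lv, terms in sorted(by_level.items()):
        terms.sort()
        n = len(terms)
        spacing = LEVEL_HSPACING * params.length_scale
        for i, t in enumerate(terms):
            x = (i - (n - 1) / 2.0) * spacing
            y = -lv * LEVEL_GAP * params.length_scale if lv > 0 else 0.5 * LEVEL_GAP
            placed[t] = (x, y)

    nodes: dict[str, LayoutNode] = {}
    for t in env.term_ids:
        if t in kept:
            old = kept[t]
            nodes[t] = LayoutNode(
                term_id=t,
                position=old.position,
                half_extent=node_sizes.get(t, old.half_extent),
                anchored=old.anchored,
                velocity=old.velocity,
            )
        else:
            hw, hh = node_sizes.get(t, (20.0, BOX_HALF_HEIGHT))
            nodes[t] = LayoutNode(term_id=t, position=placed[t], half_extent=(hw, hh))

    springs = []
    for e in sorted(env.edges, key=lambda e: (e.subject, e.predicate, e.object)):
        ldiff = abs(levels.get(e.object, 0) - levels.get(e.subject, 0))
        pref = BASE_SPRING_LENGTH * max(1, ldiff)
        orient = (0.0, -1.0) if e.predicate in params.oriented_predicates else None
        springs.append(Spring(e.subject, e.object, pref, e.predicate, orient))

    return LayoutState(nodes=nodes, springs=springs, params=params)


def _pair_geometry(state: LayoutState):
    """Vectorized pairwise unit vectors and centre-line gaps.

    Returns (ids, pos (n,2), u (n,n,2) pointing i->j, gap (n,n)); coincident
    centres get a seeded random direction (deterministic pair order).
    """
    ids = list(state.nodes)
    n = len(ids)
    pos = np.array([state.nodes[t].position for t in ids], dtype=float)
    he = np.array([state.nodes[t].half_extent for t in ids], dtype=float)
    diff = pos[None, :, :] - pos[:, None, :]          # diff[i, j] = pos_j - pos_i
    dist = np.hypot(diff[..., 0], diff[..., 1])
    coincident = [(i, j) for i in range(n) for j in range(i + 1, n)
                  if dist[i, j] < 1e-12]
    with np.errstate(invalid="ignore", divide="ignore"):
        u = diff / dist[..., None]
    u[dist < 1e-12] = 0.0
    for i, j in coincident:
        ang = state._rng.uniform(0.0, 2.0 * math.pi)
        u[i, j] = (math.cos(ang), math.sin(ang))
        u[j, i] = -u[i, j]
    # projected half-extents of both rectangles along the centre line
    proj = (he[:, None, :] * np.abs(u)).sum(-1) + (he[None, :, :] * np.abs(u)).sum(-1)
    gap = dist - proj
    return ids, pos, u, gap


def _forces(state: LayoutState) -> dict[str, np.ndarray]:
    """Net force on every node from repulsion, springs and orientation."""
    p = state.params
    ids, pos, u, gap = _pair_geometry(state)
    n = len(ids)
    index = {t: i for i, t in enumerate(ids)}

    # pairwise rectangle repulsion along the centre line
    mag = p.repulsion_k / np.maximum(gap, GAP_MIN) ** 2
    np.fill_diagonal(mag, 0.0)
    force_arr = -(mag[..., None] * u).sum(axis=1)     # push i away from every j

    for s in state.springs:
        i, j = index[s.from_id], index[s.to_id]
        d = pos[j] - pos[i]
        dist = float(np.hypot(*d))
        if dist < 1e-12:
            continue
        uv = d / dist
        # spring: positive when stretched -> pulls ends together
        smag = p.spring_k * (dist - s.preferred_length * p.length_scale)
        force_arr[i] += smag * uv
        force_arr[j] -= smag * uv
        # orientation couple: a force pair perpendicular to the connector
        # rotates it toward the preferred direction (sin_t = cross(u, o))
        if s.orientation is not None and p.orientation_k > 0:
            ox, oy = s.orientation
            sin_t = uv[0] * oy - uv[1] * ox
            perp = np.array([-uv[1], uv[0]])
            tmag = p.orientation_k * sin_t
            force_arr[j] += tmag * perp
            force_arr[i] -= tmag * perp
    return {t: force_arr[i] for i, t in enumerate(ids)}


def step(state: LayoutState) -> LayoutState:
    """One damped-Euler integration step (in place); returns the state.

    Anchored nodes receive no displacement and report zero displacement.
    """
    p = state.params
    force = _forces(state)
    for t, node in state.nodes.items():
        if node.anchored:
            node.velocity = (0.0, 0.0)
            node.displacement_last_step = 0.0
            continue
        vx, vy = node.velocity
        fx, fy = force[t]
        vx = p.damping * (vx + p.step_size * fx)
        vy = p.damping * (vy + p.step_size * fy)
        speed = math.hypot(vx, vy)
        if speed > p.max_speed:
            # capped speed keeps the huge close-range repulsion impulse from
            # launching nodes across the canvas (the usual FR "temperature")
            vx *= p.max_speed / speed
            vy *= p.max_speed / speed
        dx, dy = p.step_size * vx, p.step_size * vy
        x, y = node.position
        node.position = (x + dx, y + dy)
        node.velocity = (vx, vy)
        node.displacement_last_step = math.hypot(dx, dy)
    state.iteration += 1
    return state


def relax(state: LayoutState, trace: Optional[TextIO] = None) -> LayoutState:
    """Step until the largest per-node displacement drops below tolerance.

    Sets ``state.converged``; hitting ``max_iterations`` first is flagged,
    not raised.  ``trace`` receives one ``iteration<TAB>max_disp<TAB>energy``
    line per step for debugging or animation replay.
    """
    p = state.params
    free = [n for n in state.nodes.values() if not n.anchored]
    if not free:
        state.converged = True
        return state
    quiet = 0
    while state.iteration < p.max_iterations:
        step(state)
        max_disp = max(n.displacement_last_step for n in free)
        if trace is not None:
            trace.write(f"{state.iteration}\t{max_disp:.6g}\t{energy(state):.6g}\n")
        # several consecutive quiet steps required: a single small displacement
        # can be an oscillation turning point, not an equilibrium
        quiet = quiet + 1 if max_disp < p.convergence_tol else 0
        if quiet >= 5:
            state.converged = True
            return state
    state.converged = False
    return state


def incremental_update(
    state: LayoutState,
    new_env: Subgraph,
    node_sizes: dict[str, tuple[float, float]],
    params: Optional[LayoutParams] = None,
    do_relax: bool = True,
) -> LayoutState:
    """Minimal re-layout after a view change.

    Nodes absent from ``new_env`` are removed; persisting nodes keep their
    positions and anchored flags exactly; new nodes are placed by the
    initial-placement rules relative to the new focus; springs are rebuilt
    from the new edges; then the state is relaxed (skippable with
    ``do_relax=False`` to inspect the pre-relaxation geometry).
    """
    params = params if params is not None else state.params
    new_state = initial_placement(new_env, node_sizes, params, keep=state)
    if do_relax:
        relax(new_state)
    return new_state


def energy(state: LayoutState) -> float:
    """Total potential: repulsion + spring stretch + orientation misalignment."""
    p = state.params
    ids = list(state.nodes)
    n = len(ids)
    posd = {t: np.array(state.nodes[t].position, dtype=float) for t in ids}
    he = {t: state.nodes[t].half_extent for t in ids}
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            d = posd[b] - posd[a]
            dist = float(np.hypot(*d))
            if dist < 1e-12:
                total += p.repulsion_k / GAP_MIN
                continue
            u = d / dist
            ha, hb = he[a], he[b]
            proj = (ha[0] * abs(u[0]) + ha[1] * abs(u[1])
                    + hb[0] * abs(u[0]) + hb[1] * abs(u[1]))
            total += p.repulsion_k / max(dist - proj, GAP_MIN)
    for s in state.springs:
        d = posd[s.to_id] - posd[s.from_id]
        dist = float(np.hypot(*d))
        total += 0.5 * p.spring_k * (dist - s.preferred_length * p.length_scale) ** 2
        if s.orientation is not None and dist > 1e-12:
            u = d / dist
            cos_t = u[0] * s.orientation[0] + u[1] * s.orientation[1]
            total += p.orientation_k * (1.0 - cos_t)
    return float(total)
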