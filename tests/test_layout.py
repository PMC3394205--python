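"""Force-based layout: placement geometry, dynamics, incremental contract."""

import math

import pytest

from ontoscope.fixtures import FixtureConfig, random_ontology
from ontoscope.layout import (
    BASE_CHILD_RADIUS,
    LEVEL_GAP,
    LayoutParams,
    default_node_sizes,
    energy,
    incremental_update,
    initial_placement,
    relax,
    step,
)
from ontoscope.ontology import Relation
from ontoscope.subgraph import Filters, Subgraph, local_environment

SIZES10 = (20.0, 10.0)


def pair_env():
    return Subgraph(
        focus_ids=["a"], term_ids=["a", "b"],
        edges={Relation("a", "is_a", "b")}, levels={"a": 0, "b": 1},
    )


def no_repulsion(**kw):
    return LayoutParams(repulsion_k=1e-9, **kw)


def distance(state, a, b):
    (ax, ay), (bx, by) = state.nodes[a].position, state.nodes[b].position
    return math.hypot(bx - ax, by - ay)


def tree_environment(seed, n_terms=15):
    ont = random_ontology(FixtureConfig(n_terms=n_terms, max_parents=1, seed=seed))
    focus = list(ont.terms)[-1]
    return ont, local_environment(ont, focus)


class TestInitialPlacement:
    def test_singleton_at_origin(self):
        env = Subgraph(focus_ids=["a"], term_ids=["a"], levels={"a": 0})
        state = initial_placement(env, {"a": SIZES10})
        assert state.nodes["a"].position == (0.0, 0.0)

    def test_three_children_on_half_circle(self):
        env = Subgraph(
            focus_ids=["f"], term_ids=["f", "c1", "c2", "c3"],
            edges={Relation(c, "is_a", "f") for c in ("c1", "c2", "c3")},
            levels={"f": 0, "c1": 0, "c2": 0, "c3": 0},
        )
        state = initial_placement(env, {t: SIZES10 for t in env.term_ids})
        expected_angles = {"c1": 3 * math.pi / 4, "c2": math.pi / 2, "c3": math.pi / 4}
        for child, theta in expected_angles.items():
            x, y = state.nodes[child].position
            assert x == pytest.approx(BASE_CHILD_RADIUS * math.cos(theta))
            assert y == pytest.approx(BASE_CHILD_RADIUS * math.sin(theta))
            assert y > 0  # below the focus in the y-down frame

    def test_ancestor_levels_above(self, chain_ontology):
        env = local_environment(chain_ontology, "T:c")
        state = initial_placement(env, {t: SIZES10 for t in env.term_ids})
        assert state.nodes["T:b"].position[1] == pytest.approx(-LEVEL_GAP)
        assert state.nodes["T:a"].position[1] == pytest.approx(-2 * LEVEL_GAP)

    def test_child_radius_scales_with_length_scale(self):
        env = Subgraph(
            focus_ids=["f"], term_ids=["f", "c"],
            edges={Relation("c", "is_a", "f")}, levels={"f": 0, "c": 0},
        )
        st = initial_placement(env, {t: SIZES10 for t in env.term_ids},
                               LayoutParams(length_scale=2.0))
        assert distance(st, "f", "c") == pytest.approx(2 * BASE_CHILD_RADIUS)

    def test_empty_environment_rejected(self):
        with pytest.raises(ValueError):
            initial_placement(Subgraph(), {})

    def test_kept_nodes_retain_positions_exactly(self, chain_ontology):
        env = local_environment(chain_ontology, "T:c")
        sizes = {t: SIZES10 for t in env.term_ids}
        st = relax(initial_placement(env, sizes))
        st2 = initial_placement(env, sizes, keep=st)
        for t in env.term_ids:
            assert st2.nodes[t].position == st.nodes[t].position


class TestStep:
    def test_single_free_node_stationary(self):
        env = Subgraph(focus_ids=["a"], term_ids=["a"], levels={"a": 0})
        state = step(initial_placement(env, {"a": SIZES10}))
        assert state.nodes["a"].position == (0.0, 0.0)
        assert state.iteration == 1

    def test_spring_at_preferred_length_is_equilibrium(self):
        state = initial_placement(pair_env(), {t: SIZES10 for t in "ab"},
                                  no_repulsion(orientation_k=1e-9))
        # place exactly at preferred length, aligned with the (0,-1) preference
        state.nodes["b"].position = (0.0, -state.springs[0].preferred_length)
        step(state)
        assert state.nodes["a"].displacement_last_step == pytest.approx(0.0, abs=1e-9)
        assert state.nodes["b"].displacement_last_step == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_nodes_separate(self):
        env = Subgraph(focus_ids=["a"], term_ids=["a", "b"], levels={"a": 0, "b": 0})
        state = initial_placement(env, {t: SIZES10 for t in "ab"})
        state.nodes["a"].position = (0.0, 0.0)
        state.nodes["b"].position = (5.0, 0.0)
        d0 = distance(state, "a", "b")
        step(state)
        assert distance(state, "a", "b") > d0

    def test_anchored_node_never_moves(self):
        state = initial_placement(pair_env(), {t: SIZES10 for t in "ab"})
        state.nodes["b"].anchored = True
        before = state.nodes["b"].position
        for _ in range(50):
            step(state)
        assert state.nodes["b"].position == before
        assert state.nodes["b"].displacement_last_step == 0.0


class TestRelax:
    def test_pair_converges_to_preferred_length(self):
        state = relax(initial_placement(pair_env(), {t: SIZES10 for t in "ab"},
                                        no_repulsion()))
        assert state.converged
        target = state.springs[0].preferred_length
        assert distance(state, "a", "b") == pytest.approx(target, rel=0.01)

    def test_already_converged_state_is_fixed_point(self):
        state = relax(initial_placement(pair_env(), {t: SIZES10 for t in "ab"},
                                        no_repulsion()))
        pos = {t: n.position for t, n in state.nodes.items()}
        state2 = relax(state)
        for t in pos:
            moved = math.hypot(state2.nodes[t].position[0] - pos[t][0],
                               state2.nodes[t].position[1] - pos[t][1])
            assert moved < 10 * state.params.convergence_tol

    @pytest.mark.parametrize("seed", range(5))
    def test_parents_above_children_on_trees(self, seed):
        ont, env = tree_environment(seed)
        state = relax(initial_placement(env, default_node_sizes(env, ont)))
        assert state.converged
        for s in state.springs:
            assert state.nodes[s.to_id].position[1] < state.nodes[s.from_id].position[1]

    @pytest.mark.parametrize("seed", range(5))
    def test_no_rectangle_overlap_after_relax(self, seed):
        ont, env = tree_environment(seed, n_terms=20)
        state = relax(initial_placement(env, default_node_sizes(env, ont)))
        ids = list(state.nodes)
        tol = 0.5
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = state.nodes[ids[i]], state.nodes[ids[j]]
                dx = abs(a.position[0] - b.position[0])
                dy = abs(a.position[1] - b.position[1])
                overlap = (dx < a.half_extent[0] + b.half_extent[0] - tol
                           and dy < a.half_extent[1] + b.half_extent[1] - tol)
                assert not overlap, f"{ids[i]} overlaps {ids[j]}"

    def test_energy_descends(self, seed=4):
        ont, env = tree_environment(seed, n_terms=10)
        state = initial_placement(env, default_node_sizes(env, ont))
        e0 = energy(state)
        relax(state)
        assert energy(state) <= e0

    def test_length_scale_doubles_pair_distance(self):
        sizes = {t: SIZES10 for t in "ab"}
        d1 = distance(relax(initial_placement(pair_env(), sizes, no_repulsion())), "a", "b")
        d2 = distance(relax(initial_placement(pair_env(), sizes,
                                              no_repulsion(length_scale=2.0))), "a", "b")
        assert d2 / d1 == pytest.approx(2.0, rel=0.02)

    def test_trace_lines(self, tmp_path):
        import io
        buf = io.StringIO()
        state = relax(initial_placement(pair_env(), {t: SIZES10 for t in "ab"}), trace=buf)
        lines = buf.getvalue().strip().splitlines()
        assert len(lines) == state.iteration
        first = lines[0].split("\t")
        assert len(first) == 3 and int(first[0]) == 1


class TestDeterminism:
    def test_bitwise_reproducible(self):
        ont, env = tree_environment(2)
        sizes = default_node_sizes(env, ont)
        params = LayoutParams(rng_seed=42)
        a = relax(initial_placement(env, sizes, params))
        b = relax(initial_placement(env, sizes, params))
        assert a.positions() == b.positions()  # exact float equality
        assert a.iteration == b.iteration

    def test_coincident_centers_resolved_by_seed(self):
        env = Subgraph(focus_ids=["a"], term_ids=["a", "b"], levels={"a": 0, "b": 0})
        runs = []
        for _ in range(2):
            st = initial_placement(env, {t: SIZES10 for t in "ab"},
                                   LayoutParams(rng_seed=7))
            st.nodes["b"].position = (0.0, 0.0)
            step(st)
            runs.append(st.nodes["b"].position)
        assert runs[0] == runs[1]
        assert runs[0] != (0.0, 0.0)


class TestEnergy:
    def test_single_node_zero(self):
        env = Subgraph(focus_ids=["a"], term_ids=["a"], levels={"a": 0})
        assert energy(initial_placement(env, {"a": SIZES10})) == 0.0

    def test_spring_term_zero_at_preferred_length(self):
        state = initial_placement(pair_env(), {t: SIZES10 for t in "ab"},
                                  no_repulsion(orientation_k=1e-12))
        state.nodes["b"].position = (0.0, -state.springs[0].preferred_length)
        assert energy(state) == pytest.approx(0.0, abs=1e-6)

    def test_nonnegative(self):
        ont, env = tree_environment(1)
        state = initial_placement(env, default_node_sizes(env, ont))
        assert energy(state) >= 0.0


class TestIncrementalUpdate:
    def test_identical_env_is_near_fixed_point(self, diamond_ontology):
        env = local_environment(diamond_ontology, "T:d")
        sizes = default_node_sizes(env, diamond_ontology)
        state = relax(initial_placement(env, sizes))
        updated = incremental_update(state, env, sizes)
        for t in env.term_ids:
            moved = math.hypot(
                updated.nodes[t].position[0] - state.nodes[t].position[0],
                updated.nodes[t].position[1] - state.nodes[t].position[1],
            )
            assert moved < 20 * state.params.convergence_tol

    def test_removed_term_vanishes_others_keep_prerelax_positions(self, diamond_ontology):
        env = local_environment(diamond_ontology, "T:d")
        sizes = default_node_sizes(env, diamond_ontology)
        state = relax(initial_placement(env, sizes))
        # excluding is_a empties the view down to the focus term
        smaller = local_environment(
            diamond_ontology, "T:d", Filters(excluded_predicates={"is_a"}),
        )
        updated = incremental_update(state, smaller, sizes, do_relax=False)
        assert set(updated.nodes) == set(smaller.term_ids)
        for t in updated.nodes:
            assert updated.nodes[t].position == state.nodes[t].position

    def test_refocus_keeps_persisting_nodes_bitwise(self, diamond_ontology):
        sizes_all = {t: SIZES10 for t in diamond_ontology.terms}
        env1 = local_environment(diamond_ontology, "T:d")
        state = relax(initial_placement(env1, sizes_all))
        env2 = local_environment(diamond_ontology, "T:b")  # browse to a neighbour
        updated = incremental_update(state, env2, sizes_all, do_relax=False)
        persisting = set(env1.term_ids) & set(env2.term_ids)
        assert persisting
        for t in persisting:
            assert updated.nodes[t].position == state.nodes[t].position

    def test_anchored_flag_survives_update(self, diamond_ontology):
        env = local_environment(diamond_ontology, "T:d")
        sizes = default_node_sizes(env, diamond_ontology)
        state = relax(initial_placement(env, sizes))
        state.nodes["T:a"].anchored = True
        pos = state.nodes["T:a"].position
        updated = incremental_update(state, env, sizes)
        assert updated.nodes["T:a"].anchored
        assert updated.nodes["T:a"].position == pos
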