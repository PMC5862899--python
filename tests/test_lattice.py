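"""Concept enumeration, Hasse construction, lattice queries, layout."""

import numpy as np
import pytest

import winelattice as wl
from winelattice.lattice import (
    FormalConcept,
    LatticeError,
    lattice_to_dot,
    lattice_to_json,
)

from conftest import random_context


def test_bruce_carlo_concepts(bruce_carlo):
    got = {(c.extent, c.intent) for c in wl.enumerate_concepts(bruce_carlo)}
    expected = {
        (frozenset({"Bruce", "Carlo"}), frozenset({"male"})),
        (frozenset({"Bruce"}), frozenset({"male", "grey hair"})),
        (frozenset({"Carlo"}), frozenset({"male", "black hair"})),
        (frozenset(), frozenset(bruce_carlo.attributes)),
    }
    assert got == expected
    assert {(c.extent, c.intent) for c in wl.brute_force_concepts(bruce_carlo)} == expected


def test_all_ones_context_single_concept():
    ctx = wl.FormalContext(["g1", "g2"], ["m1", "m2"], np.ones((2, 2), bool))
    concepts = wl.enumerate_concepts(ctx)
    assert len(concepts) == 1
    assert concepts[0] == FormalConcept(
        frozenset({"g1", "g2"}), frozenset({"m1", "m2"})
    )


def test_empty_incidence_two_concepts():
    ctx = wl.FormalContext(["g1", "g2"], ["m1", "m2"], np.zeros((2, 2), bool))
    got = {(c.extent, c.intent) for c in wl.brute_force_concepts(ctx)}
    assert got == {
        (frozenset({"g1", "g2"}), frozenset()),
        (frozenset(), frozenset({"m1", "m2"})),
    }
    assert {(c.extent, c.intent) for c in wl.enumerate_concepts(ctx)} == got


def test_brute_force_refuses_large():
    ctx = wl.FormalContext(["g"], [f"m{i}" for i in range(21)],
                           np.zeros((1, 21), bool))
    with pytest.raises(LatticeError):
        wl.brute_force_concepts(ctx)


@pytest.mark.parametrize("density", [0.1, 0.3, 0.5])
def test_enumeration_matches_oracle_random(density):
    """NextClosure output is set-equal to powerset-closure enumeration."""
    rng = np.random.default_rng(int(density * 100))
    for _ in range(30):
        ctx = random_context(rng, int(rng.integers(1, 10)),
                             int(rng.integers(1, 12)), density)
        fast = {(c.extent, c.intent) for c in wl.enumerate_concepts(ctx)}
        slow = {(c.extent, c.intent) for c in wl.brute_force_concepts(ctx)}
        assert fast == slow


def test_concept_count_invariant_under_permutation(animals):
    rng = np.random.default_rng(3)
    base = wl.enumerate_concepts(animals)
    po = rng.permutation(len(animals.objects))
    pa = rng.permutation(len(animals.attributes))
    permuted = wl.FormalContext(
        [animals.objects[i] for i in po],
        [animals.attributes[j] for j in pa],
        animals.incidence[np.ix_(po, pa)],
    )
    other = wl.enumerate_concepts(permuted)
    assert len(other) == len(base)
    assert {(c.extent, c.intent) for c in other} == {
        (c.extent, c.intent) for c in base
    }


def test_hasse_bruce_carlo_diamond(bruce_carlo):
    lat = wl.build_hasse(wl.enumerate_concepts(bruce_carlo))
    assert len(lat.concepts) == 4
    assert len(lat.edges) == 4
    g = lat.graph()
    assert g.out_degree(lat.top) == 2 and g.in_degree(lat.bottom) == 2


def test_hasse_chain_is_path():
    inc = np.tril(np.ones((3, 3), bool))  # nested extents
    ctx = wl.FormalContext(["g1", "g2", "g3"], ["m1", "m2", "m3"], inc[::-1])
    lat = wl.build_hasse(wl.enumerate_concepts(ctx))
    g = lat.graph()
    assert all(g.out_degree(n) <= 1 for n in g)  # path graph


def test_hasse_edges_strictly_decrease_and_no_transitive(animals):
    lat = wl.build_hasse(wl.enumerate_concepts(animals))
    g = lat.graph()
    for u, v in lat.edges:
        assert lat.concepts[u].extent > lat.concepts[v].extent
    import networkx as nx

    assert set(nx.transitive_reduction(
        nx.transitive_closure(g)).edges()) == set(g.edges())


def test_hasse_rejects_incomplete_set(bruce_carlo):
    concepts = wl.enumerate_concepts(bruce_carlo)
    # dropping the bottom concept breaks meet-closure of the two singletons
    broken = [c for c in concepts if c.extent]
    with pytest.raises(LatticeError):
        wl.build_hasse(broken)


def test_meet_closure_random_pairs():
    rng = np.random.default_rng(11)
    ctx = random_context(rng, 8, 8, 0.3)
    concepts = wl.enumerate_concepts(ctx)
    extents = {c.extent for c in concepts}
    for _ in range(50):
        i, j = rng.integers(len(concepts), size=2)
        assert concepts[i].extent & concepts[j].extent in extents


def test_reduced_labelling(animals):
    lat = wl.build_hasse(wl.enumerate_concepts(animals))
    i = lat.attribute_labels["needs water"]
    assert lat.concepts[i].extent == set(animals.objects)  # top attribute
    j = lat.object_labels["Frog"]
    assert lat.concepts[j].extent == {"Frog"}


# ---------------------------------------------------------------------------
# the five classic printed readouts on the animals fixture
def test_animals_frog_identified(animals):
    assert animals.extent_of(["has limbs", "lives in water"]) == {"Frog"}


def test_animals_intent_chain(animals):
    leach = animals.intent_of(["Leach"])
    bream = animals.intent_of(["Bream"])
    frog = animals.intent_of(["Frog"])
    assert leach < bream < frog


def test_animals_two_leaf_implication(animals):
    implied = wl.implies(["2-leaf germination"], animals)
    assert {"needs chlorophyll", "lives on land"} <= implied


def test_animals_common_attributes(animals):
    assert animals.intent_of(["Reed", "Frog"]) == {
        "needs water", "lives in water", "lives on land"
    }
    assert animals.intent_of(["Leach", "Spike-weed"]) == {
        "needs water", "lives in water"
    }


def test_animals_generality(animals):
    assert wl.generality("needs water", animals) == 8
    assert wl.generality("needs water", animals) > wl.generality("has limbs", animals)


# ---------------------------------------------------------------------------
def test_implies_universal_attribute(animals):
    # an attribute held by every object adds nothing to any implication
    with_univ = wl.implies(["lives in water", "needs water"], animals)
    without = wl.implies(["lives in water"], animals)
    assert without - {"needs water"} == with_univ - {"needs water"}


def test_association_balance_arithmetic():
    revs_ctx = wl.FormalContext(
        ["a1", "a2", "b1", "b2"],
        ["only_a", "shared", "skewed"],
        np.array([
            [True, True, True],
            [True, True, False],
            [False, True, True],
            [False, True, True],
        ]),
    )
    part = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    assert wl.association_balance("only_a", revs_ctx, part, ("A", "B")) == 0.0
    assert wl.association_balance("shared", revs_ctx, part, ("A", "B")) == 0.5
    # r_A = 0.5, r_B = 1.0 -> 1/(1.5)
    assert wl.association_balance("skewed", revs_ctx, part, ("A", "B")) == pytest.approx(2 / 3)
    # swapping groups maps b -> 1 - b
    assert wl.association_balance("skewed", revs_ctx, part, ("B", "A")) == pytest.approx(1 / 3)
    with pytest.raises(LatticeError):
        wl.association_balance(
            "only_a",
            wl.FormalContext(["a1", "b1"], ["only_a"], np.zeros((2, 1), bool)),
            {"a1": "A", "b1": "B"},
            ("A", "B"),
        )


def test_layout_layers_and_offsets(bruce_carlo):
    lat = wl.build_hasse(wl.enumerate_concepts(bruce_carlo))
    part = {"Bruce": "B", "Carlo": "C"}
    lay = wl.layout(lat, bruce_carlo, part, ("B", "C"))
    assert lay.layer[lat.top] == 0
    for u, v in lat.edges:
        assert lay.layer[v] > lay.layer[u]
    middles = [i for i in range(4) if i not in (lat.top, lat.bottom)]
    assert lay.layer[middles[0]] == lay.layer[middles[1]]
    # grey hair is Bruce-exclusive, black hair Carlo-exclusive, male shared
    assert lay.centreline_offset["grey hair"] == -1.0
    assert lay.centreline_offset["black hair"] == 1.0
    assert lay.centreline_offset["male"] == 0.0


def test_association_scale_on_synthetic_corpus(default_corpus):
    """Varietal-exclusive planted attributes land at the ends of the
    sliding scale; equally planted ones sit near the middle."""
    _, std, _ = default_corpus
    ctx = wl.build_context(std)
    part = {r.wine_id: r.varietal for r in std}
    groups = ("sauvignon_blanc", "chenin_blanc")
    assert wl.association_balance("capsicum", ctx, part, groups) == 0.0
    assert wl.association_balance("gunpowder", ctx, part, groups) == 0.0
    assert wl.association_balance("biscuit", ctx, part, groups) == 1.0
    assert abs(wl.association_balance("earthy", ctx, part, groups) - 0.5) < 0.2
    lat = wl.build_hasse(wl.enumerate_concepts(
        ctx.subcontext(["capsicum", "biscuit", "earthy"])))
    lay = wl.layout(lat, ctx, part, groups)
    assert lay.centreline_offset["capsicum"] == -1.0
    assert lay.centreline_offset["biscuit"] == 1.0


def test_layout_deterministic(animals):
    lat = wl.build_hasse(wl.enumerate_concepts(animals))
    l1 = wl.layout(lat)
    l2 = wl.layout(lat)
    assert l1.x == l2.x and l1.layer == l2.layer


def test_exports(tmp_path, bruce_carlo):
    lat = wl.build_hasse(wl.enumerate_concepts(bruce_carlo))
    doc = lattice_to_json(lat, tmp_path / "l.json")
    assert len(doc["concepts"]) == 4
    dot = lattice_to_dot(lat, tmp_path / "l.dot")
    assert dot.startswith("digraph") and "male" in dot
    assert (tmp_path / "l.json").exists() and (tmp_path / "l.dot").exists()
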