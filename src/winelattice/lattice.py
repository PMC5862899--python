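"""Concept lattices: enumeration, Hasse diagram, queries and layered layout.

A formal concept of a context (G, M, I) is a pair (A, B) with A ⊆ G, B ⊆ M,
where B is exactly the set of attributes shared by all of A and A is exactly
the set of objects carrying all of B.  Ordered by extent inclusion the
concepts form a complete lattice; its Hasse diagram is the visualisation the
package is built around.  Enumeration uses NextClosure — closures are visited
in lectic order of their intents, which makes the output deterministic for a
fixed attribute order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import networkx as nx
import numpy as np

from .context import ContextError, FormalContext

__all__ = [
    "FormalConcept",
    "ConceptLattice",
    "LatticeLayout",
    "LatticeError",
    "enumerate_concepts",
    "brute_force_concepts",
    "build_hasse",
    "implies",
    "generality",
    "association_balance",
    "layout",
    "lattice_to_json",
    "lattice_to_dot",
]


class LatticeError(ValueError):
    """Inconsistent concept set or lattice query."""


@dataclass(frozen=True)
class FormalConcept:
    extent: frozenset[str]
    intent: frozenset[str]


@dataclass
class ConceptLattice:
    """All concepts of a context with their covering (Hasse) relation."""

    concepts: list[FormalConcept]
    edges: list[tuple[int, int]]  # (upper, lower): extent(upper) ⊃ extent(lower)
    top: int
    bottom: int
    attribute_labels: dict[str, int] = field(default_factory=dict)
    object_labels: dict[str, int] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.concepts)))
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# bitset helpers: attribute sets as ints, one bit per attribute index
def _prepare(context: FormalContext):
    inc = context.incidence
    n_obj, n_attr = inc.shape
    obj_rows = [int("".join("1" if v else "0" for v in inc[i][::-1]), 2) if n_attr else 0
                for i in range(n_obj)]
    full_attrs = (1 << n_attr) - 1
    return obj_rows, n_obj, n_attr, full_attrs


def _closure_bits(bits: int, obj_rows: list[int], full_attrs: int) -> tuple[int, int]:
    """(closed attribute set, extent bitset) of an attribute bitset."""
    intent = full_attrs
    extent = 0
    for i, row in enumerate(obj_rows):
        if bits & ~row == 0:
            intent &= row
            extent |= 1 << i
    if extent == 0:
        intent = full_attrs
    return intent, extent


def _to_concept(intent_bits: int, extent_bits: int, context: FormalContext) -> FormalConcept:
    attrs = frozenset(
        m for j, m in enumerate(context.attributes) if intent_bits >> j & 1
    )
    objs = frozenset(
        g for i, g in enumerate(context.objects) if extent_bits >> i & 1
    )
    return FormalConcept(objs, attrs)


def enumerate_concepts(context: FormalContext) -> list[FormalConcept]:
    """All formal concepts, in lectic order of intents (NextClosure)."""
    obj_rows, n_obj, n_attr, full = _prepare(context)
    out = []
    intent, extent = _closure_bits(0, obj_rows, full)
    out.append(_to_concept(intent, extent, context))
    current = intent
    while current != full:
        nxt = None
        for i in range(n_attr - 1, -1, -1):
            if current >> i & 1:
                continue
            lower_mask = (1 << i) - 1
            candidate = (current & lower_mask) | (1 << i)
            closed, ext = _closure_bits(candidate, obj_rows, full)
            # lectic successor test: closure adds no attribute below i
            if (closed & ~candidate) & lower_mask == 0:
                nxt = (closed, ext)
                break
        if nxt is None:  # pragma: no cover - full is always reachable
            break
        current, extent = nxt
        out.append(_to_concept(current, extent, context))
    return out


def brute_force_concepts(context: FormalContext) -> list[FormalConcept]:
    """Reference enumeration: closures of every attribute subset.

    Exponential in |M|; refuses more than 20 attributes.  Kept as the
    independent oracle that the NextClosure implementation is tested against.
    """
    n_attr = len(context.attributes)
    if n_attr > 20:
        raise LatticeError("brute force limited to 20 attributes")
    obj_rows, _, _, full = _prepare(context)
    seen: dict[int, int] = {}
    for bits in range(1 << n_attr):
        intent, extent = _closure_bits(bits, obj_rows, full)
        seen[intent] = extent
    return [_to_concept(i, e, context) for i, e in sorted(seen.items())]


# ---------------------------------------------------------------------------
def build_hasse(concepts: Sequence[FormalConcept]) -> ConceptLattice:
    """Covering relation of the concept order, plus reduced labelling.

    The order is extent inclusion; edges are its transitive reduction.
    Attribute labels sit on each attribute's maximal concept, object labels
    on each object's minimal concept (standard reduced labelling).
    """
    n = len(concepts)
    if n == 0:
        raise LatticeError("no concepts")
    # integrity: concept set must be closed under pairwise meet of extents
    ext_index = {c.extent: i for i, c in enumerate(concepts)}
    if len(ext_index) != n:
        raise LatticeError("duplicate concepts")
    # in a complete concept set the meet of any two extents is again an extent
    for i, j in combinations(range(min(n, 60)), 2):
        if concepts[i].extent & concepts[j].extent not in ext_index:
            raise LatticeError("concept set is not meet-closed")
    order = nx.DiGraph()
    order.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and concepts[i].extent > concepts[j].extent:
                order.add_edge(i, j)
    hasse = nx.transitive_reduction(order)
    top = max(range(n), key=lambda i: len(concepts[i].extent))
    bottom = max(range(n), key=lambda i: len(concepts[i].intent))
    if any(len(concepts[i].extent) == len(concepts[top].extent) and i != top
           for i in range(n)):
        raise LatticeError("no unique top concept")
    # reduced labels
    attr_labels: dict[str, int] = {}
    obj_labels: dict[str, int] = {}
    all_attrs = set().union(*(c.intent for c in concepts)) if concepts else set()
    all_objs = set().union(*(c.extent for c in concepts)) if concepts else set()
    for m in all_attrs:
        holders = [i for i in range(n) if m in concepts[i].intent]
        attr_labels[m] = max(holders, key=lambda i: len(concepts[i].extent))
    for g in all_objs:
        holders = [i for i in range(n) if g in concepts[i].extent]
        obj_labels[g] = max(holders, key=lambda i: len(concepts[i].intent))
    return ConceptLattice(
        list(concepts),
        sorted(hasse.edges()),
        top,
        bottom,
        attr_labels,
        obj_labels,
    )


# ---------------------------------------------------------------------------
# lattice queries
def implies(premise: Iterable[str], context: FormalContext) -> frozenset[str]:
    """Attributes implied by ``premise``: every object with the premise has them."""
    premise = frozenset(premise)
    closed = context.intent_of(context.extent_of(premise))
    return closed - premise


def generality(attribute: str, context: FormalContext) -> int:
    """How many objects carry the attribute — its height in the lattice."""
    return len(context.extent_of([attribute]))


def association_balance(
    attribute: str,
    context: FormalContext,
    partition: Mapping[str, str],
    groups: tuple[str, str] | None = None,
) -> float:
    """Sliding-scale association of an attribute between two groups.

    With within-group relative frequencies r₁, r₂ (so unequal group sizes do
    not bias the scale), returns r₂/(r₁+r₂): 0 means exclusive to the first
    group, 1 exclusive to the second, 0.5 equally associated.
    """
    if groups is None:
        groups = tuple(sorted(set(partition.values())))  # type: ignore[assignment]
    if len(set(partition.values())) != 2 or len(groups) != 2:
        raise LatticeError("partition must have exactly two groups")
    extent = context.extent_of([attribute])
    rel = []
    for g in groups:
        members = {o for o, lab in partition.items() if lab == g}
        if not members:
            raise LatticeError(f"empty group {g!r}")
        rel.append(len(extent & members) / len(members))
    if rel[0] + rel[1] == 0:
        raise LatticeError(f"attribute {attribute!r} absent from both groups")
    return rel[1] / (rel[0] + rel[1])


# ---------------------------------------------------------------------------
@dataclass
class LatticeLayout:
    """Layered drawing: depth below the top concept, barycenter x positions,
    and a per-attribute centreline offset in [-1, 1] encoding group side."""

    layer: dict[int, int]
    x: dict[int, float]
    centreline_offset: dict[str, float]


def layout(
    lattice: ConceptLattice,
    context: FormalContext | None = None,
    partition: Mapping[str, str] | None = None,
    groups: tuple[str, str] | None = None,
    iterations: int = 8,
) -> LatticeLayout:
    """Layered layout: longest-path depth + iterated barycenter ordering.

    ``iterations`` barycenter sweeps (fixed, deterministic); ties broken by
    lexicographically sorted intent.  When a two-group partition is given,
    each attribute also gets a centreline offset 2·balance − 1.
    """
    g = lattice.graph()
    order = list(nx.topological_sort(g))
    layer = {i: 0 for i in order}
    for u in order:
        for v in g.successors(u):
            layer[v] = max(layer[v], layer[u] + 1)
    layers: dict[int, list[int]] = {}
    for node, lv in layer.items():
        layers.setdefault(lv, []).append(node)

    def tie_key(i: int):
        return tuple(sorted(lattice.concepts[i].intent))

    x = {}
    for lv in layers:
        layers[lv].sort(key=tie_key)
        for pos, node in enumerate(layers[lv]):
            x[node] = float(pos)
    levels = sorted(layers)
    for sweep in range(iterations):
        seq = levels[1:] if sweep % 2 == 0 else levels[-2::-1]
        for lv in seq:
            nbr = (g.predecessors if sweep % 2 == 0 else g.successors)
            bary = {}
            for node in layers[lv]:
                ns = [x[n] for n in nbr(node)]
                bary[node] = sum(ns) / len(ns) if ns else x[node]
            layers[lv].sort(key=lambda n: (bary[n],) + tie_key(n))
            for pos, node in enumerate(layers[lv]):
                x[node] = float(pos)
    offsets: dict[str, float] = {}
    if context is not None and partition is not None:
        for m in lattice.attribute_labels:
            if m not in context._attr_index:
                continue
            try:
                b = association_balance(m, context, partition, groups)
            except LatticeError:
                continue
            offsets[m] = 2.0 * b - 1.0
    return LatticeLayout(layer, x, offsets)


# ---------------------------------------------------------------------------
# exports
def lattice_to_json(lattice: ConceptLattice, path: str | Path | None = None):
    doc = {
        "concepts": [
            {"extent": sorted(c.extent), "intent": sorted(c.intent)}
            for c in lattice.concepts
        ],
        "edges": [list(e) for e in lattice.edges],
        "top": lattice.top,
        "bottom": lattice.bottom,
        "attribute_labels": lattice.attribute_labels,
        "object_labels": lattice.object_labels,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return doc


def lattice_to_dot(lattice: ConceptLattice, path: str | Path | None = None) -> str:
    """Graphviz rendering with reduced labels: attribute labels shaded,
    object labels unshaded, unlabelled nodes aggregate from above."""
    attr_at: dict[int, list[str]] = {}
    obj_at: dict[int, list[str]] = {}
    for m, i in lattice.attribute_labels.items():
        attr_at.setdefault(i, []).append(m)
    for g, i in lattice.object_labels.items():
        obj_at.setdefault(i, []).append(g)
    lines = ["digraph lattice {", "  rankdir=TB;", "  node [shape=box];"]
    for i in range(len(lattice.concepts)):
        parts = []
        if i in attr_at:
            parts.append("|".join(sorted(attr_at[i])))
        if i in obj_at:
            parts.append("|".join(sorted(obj_at[i])))
        label = "\\n".join(parts)
        style = ' style=filled fillcolor=lightgrey' if i in attr_at else ""
        lines.append(f'  n{i} [label="{label}"{style}];')
    for u, v in lattice.edges:
        lines.append(f"  n{u} -> n{v};")
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
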