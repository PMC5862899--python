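"""Formal contexts: binary object × attribute incidence and derivation operators.

A formal context is the triple (G, M, I) of objects (wines), attributes
(canonical descriptors) and a binary incidence relation.  The two derivation
("prime") operators — attributes common to a set of objects, and objects
carrying every attribute of a set — form the Galois connection whose closed
pairs are the formal concepts enumerated in :mod:`winelattice.lattice`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import StandardizedReview

__all__ = [
    "FormalContext",
    "CitationCounts",
    "ContextError",
    "build_context",
    "citation_counts",
    "filter_min_citations",
    "read_cxt",
    "write_cxt",
]

#: citation-frequency cut used for the statistical analyses: an attribute
#: must be mentioned at least this many times within a varietal.
DEFAULT_MIN_CITATIONS = 50


class ContextError(ValueError):
    """Invalid formal-context construction or query."""


@dataclass
class FormalContext:
    """Objects × attributes binary incidence.

    ``attributes`` order is the lectic order used by concept enumeration;
    ``object_groups`` optionally maps each object to a group label
    (the wine's varietal) for counting and association queries.
    """

    objects: list[str]
    attributes: list[str]
    incidence: np.ndarray
    object_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (len(self.objects), len(self.attributes)):
            raise ContextError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.objects)} objects x {len(self.attributes)} attributes"
            )
        if len(set(self.objects)) != len(self.objects):
            raise ContextError("duplicate object names")
        if len(set(self.attributes)) != len(self.attributes):
            raise ContextError("duplicate attribute names")
        self._obj_index = {g: i for i, g in enumerate(self.objects)}
        self._attr_index = {m: j for j, m in enumerate(self.attributes)}

    # ------------------------------------------------------------------
    def extent_of(self, attrs: Iterable[str]) -> frozenset[str]:
        """Objects having every attribute in ``attrs`` (all of G for ∅)."""
        mask = np.ones(len(self.objects), dtype=bool)
        for m in attrs:
            j = self._attr_index.get(m)
            if j is None:
                raise ContextError(f"unknown attribute {m!r}")
            mask &= self.incidence[:, j]
        return frozenset(self.objects[i] for i in np.flatnonzero(mask))

    def intent_of(self, objs: Iterable[str]) -> frozenset[str]:
        """Attributes shared by every object in ``objs`` (all of M for ∅)."""
        mask = np.ones(len(self.attributes), dtype=bool)
        for g in objs:
            i = self._obj_index.get(g)
            if i is None:
                raise ContextError(f"unknown object {g!r}")
            mask &= self.incidence[i, :]
        return frozenset(self.attributes[j] for j in np.flatnonzero(mask))

    def subcontext(self, attributes: Sequence[str]) -> "FormalContext":
        cols = [self._attr_index[m] for m in attributes]
        return FormalContext(
            list(self.objects),
            list(attributes),
            self.incidence[:, cols].copy(),
            dict(self.object_groups) if self.object_groups else None,
        )


@dataclass
class CitationCounts:
    """Per-attribute citation totals within one group (varietal).

    Counting is per-wine binary: a descriptor mentioned twice in one
    description counts once, consistent with within-description
    deduplication at standardisation time.
    """

    counts: dict[str, int]
    group: str | None = None

    def ordered(self) -> list[tuple[str, int]]:
        """Descending count, ties alphabetic."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def retained(self, k: int) -> list[str]:
        """Attributes cited at least ``k`` times (original dict order)."""
        return [m for m, c in self.counts.items() if c >= k]


# ---------------------------------------------------------------------------
def build_context(
    reviews: Sequence[StandardizedReview],
    object_mode: str = "per_wine",
) -> FormalContext:
    """Build the incidence structure from standardised reviews.

    ``per_wine``: one object per wine, attributes are its descriptors.
    ``with_varietal_nodes``: additionally each wine carries its varietal
    name as an attribute, so the lattice grows one aggregate node per
    varietal from which that varietal's wines hang.
    """
    if not reviews:
        raise ContextError("empty corpus")
    if object_mode not in ("per_wine", "with_varietal_nodes"):
        raise ContextError(f"unknown object_mode {object_mode!r}")
    attrs: set[str] = set()
    for r in reviews:
        attrs |= r.descriptors
    attributes = sorted(attrs)
    if object_mode == "with_varietal_nodes":
        attributes = sorted(attrs | {r.varietal for r in reviews})
    objects = [r.wine_id for r in reviews]
    incidence = np.zeros((len(objects), len(attributes)), dtype=bool)
    attr_index = {m: j for j, m in enumerate(attributes)}
    for i, r in enumerate(reviews):
        for d in r.descriptors:
            incidence[i, attr_index[d]] = True
        if object_mode == "with_varietal_nodes":
            incidence[i, attr_index[r.varietal]] = True
    groups = {r.wine_id: r.varietal for r in reviews}
    return FormalContext(objects, attributes, incidence, groups)


def citation_counts(context: FormalContext, group: str | None = None) -> CitationCounts:
    """Citation count per attribute, optionally within one varietal group."""
    if group is None:
        mask = np.ones(len(context.objects), dtype=bool)
    else:
        if context.object_groups is None:
            raise ContextError("context carries no group labels")
        if group not in set(context.object_groups.values()):
            raise ContextError(f"unknown group {group!r}")
        mask = np.array(
            [context.object_groups[g] == group for g in context.objects], dtype=bool
        )
    totals = context.incidence[mask].sum(axis=0)
    counts = {m: int(c) for m, c in zip(context.attributes, totals)}
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return CitationCounts(ordered, group)


def filter_min_citations(
    context: FormalContext, counts: CitationCounts, k: int = DEFAULT_MIN_CITATIONS
) -> FormalContext:
    """Drop attributes cited fewer than ``k`` times; objects stay put."""
    if k < 0:
        raise ContextError("k must be non-negative")
    keep = [m for m in context.attributes if counts.counts.get(m, 0) >= k]
    if not keep:
        warnings.warn("citation filter removed every attribute", stacklevel=2)
    return context.subcontext(keep)


# ---------------------------------------------------------------------------
# Burmeister CXT format: "B", blank, |G|, |M|, blank, names, X/. rows
def write_cxt(context: FormalContext, path: str | Path) -> None:
    lines = ["B", "", str(len(context.objects)), str(len(context.attributes)), ""]
    lines += context.objects
    lines += context.attributes
    for row in context.incidence:
        lines.append("".join("X" if v else "." for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cxt(path: str | Path) -> FormalContext:
    raw = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in raw if ln.strip() != ""]
    if not lines or lines[0].strip() != "B":
        raise ContextError(f"{path}: not a Burmeister CXT file")
    ng, nm = int(lines[1]), int(lines[2])
    names = lines[3 : 3 + ng + nm]
    objects, attributes = names[:ng], names[ng:]
    rows = lines[3 + ng + nm : 3 + ng + nm + ng]
    if len(rows) != ng:
        raise ContextError(f"{path}: expected {ng} incidence rows")
    incidence = np.array(
        [[ch == "X" for ch in row.strip()] for row in rows], dtype=bool
    )
    return FormalContext(objects, attributes, incidence)
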