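"""Style statistics: co-occurrence similarity, MDS, correspondence analysis, CART.

The chain validates lattice readouts with conventional ordination and
classification: pairwise descriptor similarity (the percentage of reviews
mentioning both words among reviews mentioning either — a Jaccard index
× 100) feeds a metric MDS map; an attribute × style citation contingency
table goes through correspondence analysis; and a CART classifier predicts a
wine's style class from binary attribute presence, reporting per-leaf style
percentages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import StandardizedReview

__all__ = [
    "CooccurrenceMatrix",
    "StyleContingency",
    "CAResult",
    "MDSResult",
    "CartNode",
    "CartTree",
    "StatsError",
    "cooccurrence",
    "mds",
    "build_contingency",
    "correspondence_analysis",
    "cart_fit",
    "cart_report",
]


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
@dataclass
class CooccurrenceMatrix:
    """Symmetric attribute × attribute similarity, percentages in [0, 100]."""

    attributes: list[str]
    S: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.S, index=self.attributes, columns=self.attributes).to_csv(
            path
        )


def cooccurrence(
    reviews: Sequence[StandardizedReview], attributes: Sequence[str]
) -> CooccurrenceMatrix:
    """S(a,b) = 100 · |reviews citing both| / |reviews citing either|."""
    support = {}
    for a in attributes:
        s = {r.wine_id for r in reviews if a in r.descriptors}
        if not s:
            raise StatsError(f"attribute {a!r} has zero citations")
        support[a] = s
    k = len(attributes)
    S = np.zeros((k, k))
    for i, a in enumerate(attributes):
        for j in range(i, k):
            b = attributes[j]
            inter = len(support[a] & support[b])
            union = len(support[a] | support[b])
            S[i, j] = S[j, i] = 100.0 * inter / union
    return CooccurrenceMatrix(list(attributes), S)


# ---------------------------------------------------------------------------
@dataclass
class MDSResult:
    attributes: list[str]
    coords: np.ndarray  # (k, dims)
    stress: float  # Kruskal stress-1
    eigenvalues: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        cols = [f"dim{i+1}" for i in range(self.coords.shape[1])]
        pd.DataFrame(self.coords, index=self.attributes, columns=cols).to_csv(path)


def _stress1(D: np.ndarray, coords: np.ndarray) -> float:
    from scipy.spatial.distance import pdist, squareform

    dhat = squareform(pdist(coords))
    iu = np.triu_indices_from(D, k=1)
    denom = np.sum(dhat[iu] ** 2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((D[iu] - dhat[iu]) ** 2) / denom))


def mds(
    S: CooccurrenceMatrix | np.ndarray,
    dims: int = 2,
    *,
    method: str = "classical",
    seed: int | None = 0,
    attributes: Sequence[str] | None = None,
) -> MDSResult:
    """Embed the similarity matrix in ``dims`` dimensions.

    Distances are the complement d = 100 − S.  ``classical`` is the
    Torgerson eigendecomposition (deterministic); ``smacof`` refines it by
    majorisation with a fixed seed.
    """
    if isinstance(S, CooccurrenceMatrix):
        names = S.attributes
        D = 100.0 - S.S
    else:
        names = list(attributes) if attributes is not None else [
            str(i) for i in range(len(S))
        ]
        D = np.asarray(S, dtype=float)
        if np.any(np.diag(D) != 0):  # given a similarity matrix
            D = 100.0 - D
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    if dims < 1:
        raise StatsError("dims must be >= 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int(np.sum(vals > max(1e-9 * max(vals.max(), 1.0), 0.0)))
    if dims > max(rank, 1):
        raise StatsError(f"dims={dims} exceeds rank {rank} of the configuration")
    lam = np.clip(vals[:dims], 0.0, None)
    coords = vecs[:, :dims] * np.sqrt(lam)
    if method == "smacof":
        from sklearn.manifold import smacof

        coords, _ = smacof(
            D,
            n_components=dims,
            init=coords,
            n_init=1,
            random_state=seed,
            normalized_stress=False,
        )
    elif method != "classical":
        raise StatsError(f"unknown MDS method {method!r}")
    return MDSResult(names, coords, _stress1(D, coords), vals)


# ---------------------------------------------------------------------------
@dataclass
class StyleContingency:
    """Attribute × style-class citation counts (wine-level binary)."""

    attributes: list[str]
    styles: list[str]
    N: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.N, index=self.attributes, columns=self.styles)


def build_contingency(
    reviews: Sequence[StandardizedReview],
    attributes: Sequence[str],
    styles: Sequence[str],
) -> StyleContingency:
    N = np.zeros((len(attributes), len(styles)), dtype=int)
    si = {s: j for j, s in enumerate(styles)}
    for r in reviews:
        j = si.get(r.style)
        if j is None:
            continue
        for i, a in enumerate(attributes):
            if a in r.descriptors:
                N[i, j] += 1
    return StyleContingency(list(attributes), list(styles), N)


@dataclass
class CAResult:
    row_names: list[str]
    col_names: list[str]
    row_coords: np.ndarray  # principal coordinates
    col_coords: np.ndarray
    singular_values: np.ndarray
    inertia: np.ndarray  # per-axis, = singular values squared
    total_inertia: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "singular_value": self.singular_values,
                "inertia": self.inertia,
                "inertia_pct": 100 * self.inertia / self.total_inertia
                if self.total_inertia > 0
                else 0.0,
            }
        )


def correspondence_analysis(table: StyleContingency | pd.DataFrame) -> CAResult:
    """Correspondence analysis of a two-way contingency table.

    Standardised residuals D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} are decomposed by
    SVD; principal coordinates scale the singular vectors by the singular
    values, and the per-axis inertias σ² sum to χ²/n.
    """
    if isinstance(table, StyleContingency):
        N = np.asarray(table.N, dtype=float)
        rows, cols = table.attributes, table.styles
    else:
        N = table.to_numpy(dtype=float)
        rows, cols = list(table.index), list(table.columns)
    if np.any(N < 0):
        raise StatsError("contingency table has negative entries")
    rs, cs = N.sum(axis=1), N.sum(axis=0)
    for name, margin in ((rows, rs), (cols, cs)):
        z = np.flatnonzero(margin == 0)
        if z.size:
            raise StatsError(f"all-zero margin for {name[z[0]]!r}")
    n = N.sum()
    P = N / n
    r, c = P.sum(axis=1), P.sum(axis=0)
    resid = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(resid, full_matrices=False)
    keep = min(len(rows), len(cols)) - 1
    U, sv, Vt = U[:, :keep], sv[:keep], Vt[:keep]
    F = U * sv / np.sqrt(r)[:, None]
    G = Vt.T * sv / np.sqrt(c)[:, None]
    inertia = sv**2
    return CAResult(rows, cols, F, G, sv, inertia, float(inertia.sum()))


# ---------------------------------------------------------------------------
# CART on binary attribute indicators, greedy Gini, deterministic tie-breaks
@dataclass
class CartNode:
    support: int
    class_counts: np.ndarray
    attribute: str | None = None  # None for leaves
    attr_index: int | None = None
    present: "CartNode | None" = None
    absent: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def percentages(self) -> np.ndarray:
        return 100.0 * self.class_counts / self.class_counts.sum()


@dataclass
class CartTree:
    root: CartNode
    attributes: list[str]
    classes: list[str]
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def predict(self, X: np.ndarray) -> list[str]:
        out = []
        for row in np.asarray(X, dtype=bool):
            node = self.root
            while not node.is_leaf:
                node = node.present if row[node.attr_index] else node.absent
            out.append(self.classes[int(np.argmax(node.class_counts))])
        return out

    def _walk(self, node: CartNode, depth: int, lines: list[str]) -> None:
        pad = "  " * depth
        pct = ", ".join(
            f"{c}: {p:.1f}%" for c, p in zip(self.classes, node.percentages())
        )
        if node.is_leaf:
            lines.append(f"{pad}leaf (n={node.support}) [{pct}]")
        else:
            lines.append(f"{pad}split on '{node.attribute}' (n={node.support})")
            lines.append(f"{pad} present:")
            self._walk(node.present, depth + 1, lines)
            lines.append(f"{pad} absent:")
            self._walk(node.absent, depth + 1, lines)

    def render(self) -> str:
        lines: list[str] = []
        self._walk(self.root, 0, lines)
        return "\n".join(lines)

    def _node_dict(self, node: CartNode) -> dict:
        d = {
            "support": node.support,
            "percentages": {
                c: round(p, 4) for c, p in zip(self.classes, node.percentages())
            },
        }
        if not node.is_leaf:
            d["attribute"] = node.attribute
            d["present"] = self._node_dict(node.present)
            d["absent"] = self._node_dict(node.absent)
        return d

    def to_json(self, path: str | Path | None = None):
        doc = {"classes": self.classes, "tree": self._node_dict(self.root)}
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return doc


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p**2))


def _grow(
    X: np.ndarray,
    y_idx: np.ndarray,
    n_classes: int,
    attributes: Sequence[str],
    depth: int,
    max_depth: int,
    min_leaf: int,
) -> CartNode:
    counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    node = CartNode(support=len(y_idx), class_counts=counts)
    if depth >= max_depth or len(y_idx) < 2 * min_leaf or _gini(counts) == 0.0:
        return node
    parent_gini = _gini(counts)
    best = None  # (decrease, j)
    for j in range(X.shape[1]):
        mask = X[:, j]
        n1, n0 = int(mask.sum()), int((~mask).sum())
        if n1 < min_leaf or n0 < min_leaf:
            continue
        c1 = np.bincount(y_idx[mask], minlength=n_classes).astype(float)
        c0 = counts - c1
        dec = parent_gini - (n1 * _gini(c1) + n0 * _gini(c0)) / len(y_idx)
        if dec > 1e-12 and (best is None or dec > best[0] + 1e-12):
            best = (dec, j)
    if best is None:
        return node
    _, j = best
    mask = X[:, j]
    node.attribute = attributes[j]
    node.attr_index = j
    node.present = _grow(
        X[mask], y_idx[mask], n_classes, attributes, depth + 1, max_depth, min_leaf
    )
    node.absent = _grow(
        X[~mask], y_idx[~mask], n_classes, attributes, depth + 1, max_depth, min_leaf
    )
    return node


def cart_fit(
    X: np.ndarray,
    y: Sequence[str],
    attributes: Sequence[str],
    *,
    max_depth: int = 5,
    min_leaf: int = 20,
) -> CartTree:
    """Greedy binary CART on attribute presence/absence.

    Splits maximise the Gini impurity decrease; exact ties go to the lowest
    attribute index, so the fitted tree is invariant to attribute
    permutation up to that rule.  A single-class input yields a trivial
    one-leaf tree (with a warning).
    """
    X = np.asarray(X, dtype=bool)
    classes = sorted(set(y))
    if len(classes) < 2:
        warnings.warn("single-class input: returning a one-leaf tree", stacklevel=2)
    ci = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([ci[v] for v in y])
    root = _grow(X, y_idx, len(classes), list(attributes), 0, max_depth, min_leaf)
    return CartTree(root, list(attributes), classes, X, y_idx)


def cart_report(tree: CartTree, group: Sequence[str]) -> dict[str, float]:
    """Style percentage breakdown among wines citing any attribute in ``group``.

    This is the bar-graph statistic accompanying a fitted tree: of the wines
    that mention at least one attribute of the named family, what share
    falls in each style class.  Percentages sum to 100.
    """
    idx = []
    for a in group:
        if a not in tree.attributes:
            raise StatsError(f"unknown attribute {a!r}")
        idx.append(tree.attributes.index(a))
    mask = tree.X[:, idx].any(axis=1)
    n = int(mask.sum())
    if n == 0:
        raise StatsError("no wine cites any attribute in the group")
    counts = np.bincount(tree.y[mask], minlength=len(tree.classes))
    return {c: 100.0 * k / n for c, k in zip(tree.classes, counts)}
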