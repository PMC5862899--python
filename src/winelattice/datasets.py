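"""Packaged reference data: printed citation counts, the style census, and
the small animals context used throughout the lattice examples."""

from __future__ import annotations

import json
from importlib import resources
from io import StringIO

import pandas as pd

from .context import CitationCounts, FormalContext, read_cxt

__all__ = [
    "animals_context",
    "bruce_carlo_context",
    "published_citation_counts",
    "style_census",
    "census_totals",
]


def _data(name: str) -> str:
    return resources.files("winelattice.data").joinpath(name).read_text("utf-8")


def animals_context() -> FormalContext:
    """Eight life forms × nine biological attributes.

    The incidence is reconstructed so that every classic lattice readout
    holds: limbs + lives-in-water identifies the frog uniquely, leach ⊂
    bream ⊂ frog attribute chains, 2-leaf germination implies chlorophyll
    and land, and so on.
    """
    import tempfile, os

    with tempfile.NamedTemporaryFile(
        "w", suffix=".cxt", delete=False, encoding="utf-8"
    ) as fh:
        fh.write(_data("animals.cxt"))
        path = fh.name
    try:
        return read_cxt(path)
    finally:
        os.unlink(path)


def bruce_carlo_context() -> FormalContext:
    """The two-person, four-attribute toy context (gender × hair colour)."""
    import numpy as np

    return FormalContext(
        objects=["Bruce", "Carlo"],
        attributes=["male", "female", "black hair", "grey hair"],
        incidence=np.array(
            [[True, False, False, True], [True, False, True, False]]
        ),
    )


def published_citation_counts(varietal: str) -> CitationCounts:
    """Printed per-attribute citation totals for one varietal (2008–2014)."""
    df = pd.read_csv(StringIO(_data("table_citation_counts.csv")))
    sub = df[df["varietal"] == varietal]
    if sub.empty:
        raise KeyError(f"unknown varietal {varietal!r}")
    return CitationCounts(
        dict(zip(sub["attribute"], sub["citations"].astype(int))), varietal
    )


def style_census() -> pd.DataFrame:
    """Printed per-year wine counts per varietal/style cell."""
    return pd.read_csv(StringIO(_data("style_census.csv"))).set_index("year")


def census_totals() -> dict[str, int]:
    """Total wines per varietal, summed from the census."""
    df = style_census()
    return {
        "chenin_blanc": int(
            df[["chenin_unwooded_dry", "chenin_wooded_dry", "chenin_semi_dry"]]
            .to_numpy().sum()
        ),
        "sauvignon_blanc": int(
            df[["sauvignon_unwooded_dry", "sauvignon_wooded_dry"]].to_numpy().sum()
        ),
    }
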