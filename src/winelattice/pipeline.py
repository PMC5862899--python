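"""End-to-end orchestration: standardise → context → lattice → MDS/CA/CART.

All randomness flows from the single config seed; a run manifest records the
parameter echo and every artifact written, so a rerun with the same config
is byte-identical on the numeric outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .context import build_context, citation_counts, filter_min_citations, write_cxt
from .corpus import (
    STYLES,
    StandardizationLog,
    read_reviews,
    standardize_corpus,
    write_standardized,
)
from .lattice import build_hasse, enumerate_concepts, lattice_to_dot, lattice_to_json
from .lexicon import Lexicon, default_lexicon
from .stats import (
    build_contingency,
    cart_fit,
    cooccurrence,
    correspondence_analysis,
    mds,
)
from .synthetic import default_spec, generate
import numpy as np
import pandas as pd

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    reviews_path: str | None = None  # None: generate the default synthetic corpus
    lexicon_path: str | None = None
    min_citations: int = 50
    mds_dims: int = 2
    cart_max_depth: int = 5
    cart_min_leaf: int = 20
    #: cap on attributes entering the lattice, for tractable concept counts
    lattice_max_attributes: int = 24
    seed: int = 1


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = (
        Lexicon.from_json(config.lexicon_path)
        if config.lexicon_path
        else default_lexicon()
    )
    artifacts: dict[str, list[str]] = {}

    if config.reviews_path:
        reviews = read_reviews(config.reviews_path)
    else:
        reviews, _ = generate(default_spec(seed=config.seed), lexicon)

    log = StandardizationLog()
    std = standardize_corpus(reviews, lexicon, log=log)
    write_standardized(std, out / "standardized.json")
    log.to_json(out / "standardization_log.json")
    artifacts["standardized"] = ["standardized.json", "standardization_log.json"]

    ctx = build_context(std, "per_wine")
    counts_all = citation_counts(ctx)
    fctx = filter_min_citations(ctx, counts_all, config.min_citations)
    write_cxt(fctx, out / "context.cxt")
    artifacts["context"] = ["context.cxt"]

    # lattice on the varietal-node context, trimmed to the most cited
    # attributes so the concept count stays viewable
    lat_ctx = build_context(std, "with_varietal_nodes")
    lat_counts = citation_counts(lat_ctx)
    top_attrs = [m for m, _ in lat_counts.ordered()][: config.lattice_max_attributes]
    lat_ctx = lat_ctx.subcontext(sorted(top_attrs))
    concepts = enumerate_concepts(lat_ctx)
    lattice = build_hasse(concepts)
    lattice_to_json(lattice, out / "lattice.json")
    lattice_to_dot(lattice, out / "lattice.dot")
    artifacts["lattice"] = ["lattice.json", "lattice.dot"]

    attrs = list(fctx.attributes)
    if not attrs:
        raise PipelineError("stage 'mds' failed: no attributes survive the filter")
    co = cooccurrence(std, attrs)
    co.to_csv(out / "cooccurrence.csv")
    m = mds(co, dims=config.mds_dims, seed=config.seed)
    m.to_csv(out / "mds_coords.csv")
    artifacts["mds"] = ["cooccurrence.csv", "mds_coords.csv"]

    chenin = [r for r in std if r.varietal == "chenin_blanc"]
    ch_attrs = sorted({d for r in chenin for d in r.descriptors} & set(attrs))
    tab = build_contingency(chenin, ch_attrs, list(STYLES))
    keep = [i for i, a in enumerate(ch_attrs) if tab.N[i].sum() > 0]
    tab.attributes = [ch_attrs[i] for i in keep]
    tab.N = tab.N[keep]
    ca = correspondence_analysis(tab)
    pd.DataFrame(
        ca.row_coords, index=ca.row_names,
        columns=[f"dim{i+1}" for i in range(ca.row_coords.shape[1])],
    ).to_csv(out / "ca_rows.csv")
    pd.DataFrame(
        ca.col_coords, index=ca.col_names,
        columns=[f"dim{i+1}" for i in range(ca.col_coords.shape[1])],
    ).to_csv(out / "ca_cols.csv")
    (out / "ca_inertia.json").write_text(
        json.dumps(
            {
                "singular_values": ca.singular_values.tolist(),
                "inertia": ca.inertia.tolist(),
                "total_inertia": ca.total_inertia,
            },
            indent=1,
        )
    )
    artifacts["ca"] = ["ca_rows.csv", "ca_cols.csv", "ca_inertia.json"]

    X = np.array(
        [[a in r.descriptors for a in ch_attrs] for r in chenin], dtype=bool
    )
    tree = cart_fit(
        X,
        [r.style for r in chenin],
        ch_attrs,
        max_depth=config.cart_max_depth,
        min_leaf=config.cart_min_leaf,
    )
    tree.to_json(out / "cart.json")
    (out / "cart.txt").write_text(tree.render(), encoding="utf-8")
    artifacts["cart"] = ["cart.json", "cart.txt"]

    missing = [f for fs in artifacts.values() for f in fs if not (out / f).exists()]
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "artifacts": artifacts,
        "incomplete": missing,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if missing:
        raise PipelineError(f"missing artifacts: {missing}")
    return manifest
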