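"""Synthetic review corpora with known statistical structure.

The proprietary review corpus behind the analyses cannot be shipped, so this
module generates one with the structure the pipeline assumes: per-wine
descriptor sets drawn from style- and varietal-conditional Bernoulli
probabilities, rendered into noisy free text through the standardisation
lexicon run backwards (synonym variants, non-sensory filler phrases, stop
words).  The generator's ground truth — the planted sets and the probability
table — makes every downstream stage testable: standardisation must invert
the rendering, citation counts must converge to the planted probabilities,
and CART/CA outputs can be checked against analytic Bayes posteriors.

Default cell sizes follow the real census totals scaled by one tenth
(Chenin 149/85/41 across unwooded-dry/wooded-dry/semi-dry, Sauvignon 408/27
across unwooded-dry/wooded-dry; 710 wines per corpus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import RawReview, STYLES
from .lexicon import Lexicon, default_lexicon

__all__ = ["NoiseSpec", "GeneratorSpec", "GroundTruth", "default_spec", "generate", "render_raw"]


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Raw-text rendering noise (all lexicon-known, so standardisation can
    invert it exactly)."""

    synonym_prob: float = 0.5  # chance a descriptor surfaces as a variant
    filler_rate: float = 0.35  # chance of a non-sensory phrase per slot
    stopword_rate: float = 0.30


#: default varietal/style cell sizes: real census totals / 10
DEFAULT_CELLS: dict[tuple[str, str], int] = {
    ("chenin_blanc", "unwooded_dry"): 149,
    ("chenin_blanc", "wooded_dry"): 85,
    ("chenin_blanc", "semi_dry"): 41,
    ("sauvignon_blanc", "unwooded_dry"): 408,
    ("sauvignon_blanc", "wooded_dry"): 27,
}

DEFAULT_VOCABULARY: dict[str, list[str]] = {
    "shared": ["apple", "tropical", "citrus", "earthy", "peach", "melon"],
    "chenin_specific": ["biscuit", "thatch", "honey", "quince"],
    "sauvignon_specific": [
        "capsicum", "gunpowder", "gooseberry", "grass", "asparagus",
        "nettle", "pineapple", "guava", "blackcurrant", "passionfruit",
    ],
    "wooded_markers": ["oak", "vanilla", "nuts", "spice"],
    "semidry_markers": ["sweet", "semi-dry"],
}

#: descriptor pools coupled to a latent per-wine pole within Sauvignon blanc,
#: emulating the documented herbaceous-versus-fruity style axis
HERBACEOUS_POOL = ("grass", "asparagus", "nettle", "capsicum")
FRUITY_POOL = ("pineapple", "guava", "blackcurrant", "passionfruit")


def _default_p_table() -> dict[tuple[str, str, str], float]:
    p: dict[tuple[str, str, str], float] = {}

    def set_all(d, chenin, sauv):
        for s in STYLES:
            if chenin is not None:
                p[(d, "chenin_blanc", s)] = chenin
            if sauv is not None and s != "semi_dry":
                p[(d, "sauvignon_blanc", s)] = sauv

    set_all("apple", 0.30, 0.30)
    set_all("tropical", 0.35, 0.30)
    set_all("citrus", 0.25, 0.25)
    set_all("earthy", 0.10, 0.10)
    set_all("peach", 0.25, 0.10)
    set_all("melon", 0.20, 0.20)
    set_all("biscuit", 0.15, 0.0)
    set_all("thatch", 0.15, 0.0)
    set_all("honey", 0.20, 0.0)
    set_all("quince", 0.10, 0.0)
    set_all("capsicum", 0.0, 0.25)
    set_all("gunpowder", 0.0, 0.10)
    set_all("gooseberry", 0.0, 0.40)
    set_all("grass", 0.0, 0.45)
    set_all("asparagus", 0.0, 0.20)
    set_all("nettle", 0.0, 0.20)
    set_all("pineapple", 0.10, 0.25)
    set_all("guava", 0.10, 0.15)
    set_all("blackcurrant", 0.0, 0.15)
    set_all("passionfruit", 0.0, 0.30)
    # wood-maturation markers: strong in wooded styles of both varietals
    for v in ("chenin_blanc", "sauvignon_blanc"):
        for d, hi, lo in (
            ("oak", 0.80, 0.10),
            ("vanilla", 0.60, 0.08),
            ("nuts", 0.40, 0.05),
            ("spice", 0.35, 0.10),
        ):
            for s in STYLES:
                if v == "sauvignon_blanc" and s == "semi_dry":
                    continue
                p[(d, v, s)] = hi if s == "wooded_dry" else lo
    # residual-sugar markers: exclusive to the Chenin semi-dry class
    for d, prob in (("sweet", 0.70), ("semi-dry", 0.60)):
        for v in ("chenin_blanc", "sauvignon_blanc"):
            for s in STYLES:
                if v == "sauvignon_blanc" and s == "semi_dry":
                    continue
                p[(d, v, s)] = prob if (v, s) == ("chenin_blanc", "semi_dry") else 0.0
    return p


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic corpus."""

    seed: int = 1
    n_wines: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS)
    )
    vocabulary: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VOCABULARY.items()}
    )
    p_table: Mapping[tuple[str, str, str], float] = field(
        default_factory=_default_p_table
    )
    noise: NoiseSpec = NoiseSpec()
    #: strength of the latent herbaceous/fruity pole within Sauvignon:
    #: 0 = fully independent descriptor draws
    pole_coupling: float = 0.0

    def all_descriptors(self) -> list[str]:
        out: list[str] = []
        for key in sorted(self.vocabulary):
            out.extend(self.vocabulary[key])
        return out

    def validate(self) -> None:
        if not any(self.vocabulary.values()):
            raise GeneratorError("empty vocabulary")
        seen: set[str] = set()
        for key, descs in self.vocabulary.items():
            dup = seen & set(descs)
            if dup:
                raise GeneratorError(f"descriptors in multiple classes: {sorted(dup)}")
            seen |= set(descs)
        for (d, v, s), prob in self.p_table.items():
            if not 0.0 <= prob <= 1.0:
                raise GeneratorError(f"p out of range for {(d, v, s)}: {prob}")
        if any(n < 0 for n in self.n_wines.values()):
            raise GeneratorError("negative cell count")


def default_spec(seed: int = 1) -> GeneratorSpec:
    """The packaged default corpus conditions.

    Pole coupling is on (0.9) so the Sauvignon herbaceous/fruity axis the
    ordination analyses look for actually exists in the corpus.
    """
    return GeneratorSpec(seed=seed, pole_coupling=0.9)


@dataclass
class GroundTruth:
    """What was planted: per-wine descriptor sets, the probability table,
    latent pole assignments, and analytic style posteriors."""

    planted: dict[str, frozenset[str]]
    p_table: Mapping[tuple[str, str, str], float]
    spec: GeneratorSpec
    poles: dict[str, str] = field(default_factory=dict)

    def cite_prob(self, descriptor: str, varietal: str, style: str) -> float:
        """Marginal P(descriptor cited | cell), pole mixture included."""
        base = self.p_table.get((descriptor, varietal, style), 0.0)
        c = self.spec.pole_coupling
        if c == 0 or varietal != "sauvignon_blanc":
            return base
        if descriptor in HERBACEOUS_POOL or descriptor in FRUITY_POOL:
            hi = min(1.0, base * (1 + c))
            lo = max(0.0, base * (1 - c))
            return 0.5 * (hi + lo)
        return base

    def _p_any(self, group: Sequence[str], varietal: str, style: str) -> float:
        """P(at least one descriptor of ``group`` cited | cell)."""
        c = self.spec.pole_coupling
        if c and varietal == "sauvignon_blanc":
            total = 0.0
            for pole in ("herbaceous", "fruity"):
                miss = 1.0
                for d in group:
                    base = self.p_table.get((d, varietal, style), 0.0)
                    if d in HERBACEOUS_POOL:
                        p = base * (1 + c) if pole == "herbaceous" else base * (1 - c)
                    elif d in FRUITY_POOL:
                        p = base * (1 + c) if pole == "fruity" else base * (1 - c)
                    else:
                        p = base
                    miss *= 1.0 - min(1.0, max(0.0, p))
                total += 0.5 * (1.0 - miss)
            return total
        miss = 1.0
        for d in group:
            miss *= 1.0 - self.p_table.get((d, varietal, style), 0.0)
        return 1.0 - miss

    def style_posterior(
        self, group: Sequence[str], varietals: Sequence[str] | None = None
    ) -> dict[str, float]:
        """Bayes posterior P(style | some group descriptor cited)."""
        cells = [
            (v, s, n)
            for (v, s), n in self.spec.n_wines.items()
            if varietals is None or v in varietals
        ]
        weight: dict[str, float] = {}
        for v, s, n in cells:
            weight[s] = weight.get(s, 0.0) + n * self._p_any(group, v, s)
        total = sum(weight.values())
        if total == 0:
            raise GeneratorError("group never cited under these conditions")
        return {s: w / total for s, w in weight.items()}


# ---------------------------------------------------------------------------
def render_raw(
    descriptors: frozenset[str] | set[str],
    lexicon: Lexicon,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> str:
    """Render canonical descriptors into noisy raw text.

    Every descriptor is surfaced through some lexicon-known form, so
    standardisation recovers the planted set exactly; filler phrases come
    from the non-sensory list and stop words from the stop list.
    """
    fillers = sorted(lexicon.nonsensory)
    stops = sorted(lexicon.stopwords)
    pieces: list[str] = []

    def maybe_noise() -> None:
        if fillers and rng.random() < noise.filler_rate:
            pieces.append(fillers[rng.integers(len(fillers))])
        if stops and rng.random() < noise.stopword_rate:
            pieces.append(stops[rng.integers(len(stops))])

    order = sorted(descriptors)
    rng.shuffle(order)
    for d in order:
        variants = lexicon.variants_of(d)
        if not variants:
            raise GeneratorError(f"descriptor {d!r} has no surface form")
        maybe_noise()
        if rng.random() < noise.synonym_prob:
            pieces.append(variants[rng.integers(len(variants))])
        else:
            pieces.append(d if d in variants or d in lexicon.canonicals else variants[0])
    maybe_noise()
    if not pieces:  # a wine with no planted descriptors still gets text
        pieces.append(fillers[rng.integers(len(fillers))] if fillers else "plain")
    return ", ".join(pieces)


def generate(
    spec: GeneratorSpec, lexicon: Lexicon | None = None
) -> tuple[list[RawReview], GroundTruth]:
    """Sample a corpus and its ground truth, reproducibly from ``spec.seed``."""
    spec.validate()
    if lexicon is None:
        lexicon = default_lexicon()
    rng = np.random.default_rng(spec.seed)
    descriptors = spec.all_descriptors()
    unknown = [d for d in descriptors if d not in lexicon.canonicals]
    if unknown:
        raise GeneratorError(f"vocabulary not in lexicon: {unknown}")
    reviews: list[RawReview] = []
    planted: dict[str, frozenset[str]] = {}
    poles: dict[str, str] = {}
    c = spec.pole_coupling
    for (varietal, style) in sorted(spec.n_wines):
        n = spec.n_wines[(varietal, style)]
        tag = f"{varietal.split('_')[0][:2]}-{style}"
        for i in range(n):
            wine_id = f"{tag}-{i:04d}"
            pole = ""
            if c and varietal == "sauvignon_blanc":
                pole = "herbaceous" if rng.random() < 0.5 else "fruity"
                poles[wine_id] = pole
            chosen = set()
            for d in descriptors:
                p = spec.p_table.get((d, varietal, style), 0.0)
                if pole and (d in HERBACEOUS_POOL or d in FRUITY_POOL):
                    boost = (d in HERBACEOUS_POOL) == (pole == "herbaceous")
                    p = min(1.0, p * (1 + c)) if boost else max(0.0, p * (1 - c))
                if rng.random() < p:
                    chosen.add(d)
            text = render_raw(frozenset(chosen), lexicon, spec.noise, rng)
            year = int(rng.integers(2008, 2015))
            reviews.append(RawReview(wine_id, varietal, style, year, text))
            planted[wine_id] = frozenset(chosen)
    return reviews, GroundTruth(planted, dict(spec.p_table), spec, poles)
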