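"""Standardisation lexicon: synonym map, stop/non-sensory lists, and connotation rules.

A :class:`Lexicon` captures the rule set a sensory researcher would apply by
hand when cleaning free-text wine descriptions: surface variants of one
descriptor ("green apple", "ripe apple", "bubblegummy") collapse onto a single
canonical word, function words and non-sensory chatter ("ideal for picnics")
are discarded, a small whitelist of two-word descriptors ("ripe fruit",
"citrus fruit") is preserved as-is, and context-sensitive *connotation rules*
decide when an ambiguous word counts as a sensory attribute at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["ConnotationRule", "Lexicon", "default_lexicon", "LexiconError"]

#: recognised connotation-rule kinds
RULE_KINDS = frozenset({"NEGATION_DROP", "STANDALONE_ONLY", "ALWAYS_KEEP"})


class LexiconError(ValueError):
    """Raised when a lexicon violates its structural invariants."""


@dataclass(frozen=True)
class ConnotationRule:
    """One context-sensitivity rule for a canonical descriptor.

    kind is one of:

    ``NEGATION_DROP``
        drop the descriptor when a negating/comparative cue word occurs
        within a token window around its mention ("lacking acidity").
    ``STANDALONE_ONLY``
        keep the descriptor only when it is not immediately modifying
        another sensory word ("fresh apple" yields only *apple*).
    ``ALWAYS_KEEP``
        the descriptor is always retained when mentioned (e.g. *oak*,
        whether on the nose or the palate).
    """

    descriptor: str
    kind: str
    cues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise LexiconError(f"unknown connotation rule kind: {self.kind!r}")


@dataclass(frozen=True)
class Lexicon:
    synonym_map: Mapping[str, str]
    stopwords: frozenset[str]
    nonsensory: frozenset[str]
    bigram_whitelist: frozenset[str]
    connotation_rules: tuple[ConnotationRule, ...] = ()
    case_lower: bool = True

    # derived lookup tables, built once in __post_init__
    _phrase_table: dict = field(default_factory=dict, compare=False, repr=False)
    _max_key_len: int = field(default=1, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        table: dict[tuple[str, ...], tuple[str, str | None]] = {}
        # priority: lowest number wins at equal phrase length
        for phrase in self.stopwords:
            table[tuple(phrase.split())] = ("stopword", None)
        for phrase in self.nonsensory:
            table[tuple(phrase.split())] = ("nonsensory", None)
        for phrase, canonical in self.synonym_map.items():
            table[tuple(phrase.split())] = ("synonym", canonical)
        for phrase in self.bigram_whitelist:
            table[tuple(phrase.split())] = ("synonym", phrase)
        object.__setattr__(self, "_phrase_table", table)
        object.__setattr__(
            self, "_max_key_len", max((len(k) for k in table), default=1)
        )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        canonicals = self.canonicals
        for phrase, canonical in self.synonym_map.items():
            words = canonical.split()
            if len(words) > 1 and canonical not in self.bigram_whitelist:
                raise LexiconError(
                    f"synonym target {canonical!r} is multi-word but not a "
                    "whitelisted bigram"
                )
            if canonical != canonical.lower():
                raise LexiconError(f"canonical {canonical!r} is not lower case")
        clash = canonicals & (self.stopwords | self.nonsensory)
        if clash:
            raise LexiconError(
                f"canonical descriptors also listed as stop/non-sensory: {sorted(clash)}"
            )
        for rule in self.connotation_rules:
            if rule.descriptor not in canonicals:
                raise LexiconError(
                    f"connotation rule references unknown canonical {rule.descriptor!r}"
                )

    @property
    def canonicals(self) -> frozenset[str]:
        """All canonical descriptors this lexicon can emit."""
        return frozenset(self.synonym_map.values()) | self.bigram_whitelist

    def variants_of(self, canonical: str) -> list[str]:
        """All surface forms that standardise to ``canonical`` (sorted)."""
        out = [k for k, v in self.synonym_map.items() if v == canonical]
        if canonical in self.bigram_whitelist and canonical not in out:
            out.append(canonical)
        return sorted(out)

    # ------------------------------------------------------------------
    # greedy longest-match lookup used by the standardiser
    def match_at(self, tokens: list[str], i: int) -> tuple[int, str, str | None]:
        """Longest phrase match starting at ``tokens[i]``.

        Returns ``(length, kind, canonical)`` where kind is ``synonym`` /
        ``stopword`` / ``nonsensory`` / ``unknown``; unknown consumes one token.
        """
        limit = min(self._max_key_len, len(tokens) - i)
        for n in range(limit, 0, -1):
            key = tuple(tokens[i : i + n])
            hit = self._phrase_table.get(key)
            if hit is not None:
                return n, hit[0], hit[1]
        return 1, "unknown", None

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping) -> "Lexicon":
        rules = tuple(
            ConnotationRule(r["descriptor"], r["kind"], tuple(r.get("cues", ())))
            for r in d.get("connotation_rules", ())
        )
        return cls(
            synonym_map={k.lower(): v.lower() for k, v in d["synonyms"].items()},
            stopwords=frozenset(w.lower() for w in d.get("stopwords", ())),
            nonsensory=frozenset(w.lower() for w in d.get("nonsensory", ())),
            bigram_whitelist=frozenset(b.lower() for b in d.get("bigrams", ())),
            connotation_rules=rules,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "synonyms": dict(self.synonym_map),
            "stopwords": sorted(self.stopwords),
            "nonsensory": sorted(self.nonsensory),
            "bigrams": sorted(self.bigram_whitelist),
            "connotation_rules": [
                {"descriptor": r.descriptor, "kind": r.kind, "cues": list(r.cues)}
                for r in self.connotation_rules
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, ensure_ascii=False), encoding="utf-8"
        )


def default_lexicon() -> Lexicon:
    """The packaged default lexicon for white-wine aroma descriptions."""
    ref = resources.files("winelattice.data").joinpath("default_lexicon.json")
    return Lexicon.from_dict(json.loads(ref.read_text(encoding="utf-8")))
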