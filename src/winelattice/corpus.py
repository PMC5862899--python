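"""Free-text wine descriptions → standardised per-wine descriptor sets.

The pipeline mirrors what a sensory panel-data curator does by hand:
tokenise the blurb, collapse synonym variants onto canonical descriptors,
discard stop words and non-sensory chatter, keep a small set of whitelisted
two-word descriptors, and apply connotation rules so that only positively
connoted sensory mentions survive ("lacking acidity" must not count as
*acid*; "fresh apple" contributes *apple* but not *fresh*).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon import Lexicon

__all__ = [
    "RawReview",
    "StandardizedReview",
    "StandardizationLog",
    "CorpusIntegrityError",
    "EmptyTextError",
    "VARIETALS",
    "STYLES",
    "tokenize",
    "apply_lexicon",
    "apply_connotation_rules",
    "standardize_corpus",
    "read_reviews",
    "write_reviews",
    "write_standardized",
    "read_standardized",
]

VARIETALS = ("chenin_blanc", "sauvignon_blanc")
#: Chenin blanc is entered in three style classes, Sauvignon blanc in two
#: (dry wines only; the semi-dry class exists for Chenin).
STYLES = ("unwooded_dry", "wooded_dry", "semi_dry")


class CorpusIntegrityError(ValueError):
    """Duplicate identifiers or inconsistent review metadata."""


class EmptyTextError(ValueError):
    """A review with no description text."""


@dataclass(frozen=True)
class RawReview:
    """One wine's metadata plus its free-text sensory description."""

    wine_id: str
    varietal: str
    style: str
    vintage_year: int
    text: str

    def __post_init__(self) -> None:
        if self.varietal not in VARIETALS:
            raise CorpusIntegrityError(f"unknown varietal {self.varietal!r}")
        if self.style not in STYLES:
            raise CorpusIntegrityError(f"unknown style {self.style!r}")
        if self.style == "semi_dry" and self.varietal != "chenin_blanc":
            raise CorpusIntegrityError(
                "semi_dry style exists only for chenin_blanc"
            )
        if not self.text or not self.text.strip():
            raise EmptyTextError(f"review {self.wine_id!r} has empty text")


@dataclass(frozen=True)
class StandardizedReview:
    wine_id: str
    varietal: str
    style: str
    vintage_year: int
    descriptors: frozenset[str]


@dataclass
class StandardizationLog:
    """Audit trail: what was dropped and which rules fired, per wine."""

    dropped_unknown: dict[str, list[str]] = field(default_factory=dict)
    dropped_nonsensory: dict[str, list[str]] = field(default_factory=dict)
    fired_rules: dict[str, list[str]] = field(default_factory=dict)

    def record(self, wine_id: str, kind: str, item: str) -> None:
        getattr(self, kind).setdefault(wine_id, []).append(item)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "dropped_unknown": self.dropped_unknown,
                    "dropped_nonsensory": self.dropped_nonsensory,
                    "fired_rules": self.fired_rules,
                },
                indent=2,
            ),
            encoding="utf-8",
        )


# ---------------------------------------------------------------------------
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lower-case, strip punctuation, keep hyphenated compounds whole."""
    if not text or not text.strip():
        raise EmptyTextError("cannot tokenize empty text")
    return _TOKEN_RE.findall(text.lower())


def _match_spans(tokens: Sequence[str], lexicon: Lexicon):
    """Greedy left-to-right longest-match segmentation of a token list.

    Yields ``(start, end, kind, canonical)`` spans; multi-word synonym keys
    and whitelisted bigrams win over unigram readings of the same tokens.
    """
    spans = []
    i = 0
    toks = list(tokens)
    while i < len(toks):
        n, kind, canonical = lexicon.match_at(toks, i)
        spans.append((i, i + n, kind, canonical))
        i += n
    return spans


def apply_lexicon(
    tokens: Sequence[str], lexicon: Lexicon, *, wine_id: str = "?",
    log: StandardizationLog | None = None,
) -> frozenset[str]:
    """Map a token list to its set of canonical descriptors.

    Unknown tokens are dropped (and logged), never raised: the curator's
    manual clean-up removed everything non-sensory, and drop-by-default is
    the automated analogue.
    """
    out = set()
    for start, end, kind, canonical in _match_spans(tokens, lexicon):
        if kind == "synonym":
            out.add(canonical)
        elif log is not None:
            surface = " ".join(tokens[start:end])
            log.record(
                wine_id,
                "dropped_unknown" if kind == "unknown" else "dropped_nonsensory",
                surface,
            )
    return frozenset(out)


def apply_connotation_rules(
    candidates: frozenset[str],
    tokens: Sequence[str],
    lexicon: Lexicon,
    *,
    window: int = 3,
    wine_id: str = "?",
    log: StandardizationLog | None = None,
) -> frozenset[str]:
    """Filter descriptor candidates through the lexicon's connotation rules.

    Rules are applied in lexicon order.  A descriptor survives a
    NEGATION_DROP rule if at least one of its mentions has no cue word
    within ``window`` tokens on either side; it survives STANDALONE_ONLY if
    at least one mention is not immediately followed by another sensory
    descriptor.  ALWAYS_KEEP descriptors are exempt from later drops.
    """
    spans = _match_spans(tokens, lexicon)
    sensory = [(s, e, c) for s, e, k, c in spans if k == "synonym"]
    kept = set(candidates)
    protected = {
        r.descriptor for r in lexicon.connotation_rules if r.kind == "ALWAYS_KEEP"
    }
    for rule in lexicon.connotation_rules:
        d = rule.descriptor
        if d not in kept or rule.kind == "ALWAYS_KEEP" or d in protected:
            continue
        mentions = [(s, e) for s, e, c in sensory if c == d]
        if not mentions:
            continue
        if rule.kind == "NEGATION_DROP":
            cues = set(rule.cues)
            ok = []
            for s, e in mentions:
                lo, hi = max(0, s - window), min(len(tokens), e + window)
                ctx = set(tokens[lo:s]) | set(tokens[e:hi])
                ok.append(not (ctx & cues))
            if not any(ok):
                kept.discard(d)
                if log is not None:
                    log.record(wine_id, "fired_rules", f"NEGATION_DROP:{d}")
        elif rule.kind == "STANDALONE_ONLY":
            standalone = []
            for s, e in mentions:
                modifying = any(
                    s2 == e and c2 != d for s2, e2, c2 in sensory
                )
                standalone.append(not modifying)
            if not any(standalone):
                kept.discard(d)
                if log is not None:
                    log.record(wine_id, "fired_rules", f"STANDALONE_ONLY:{d}")
    return frozenset(kept)


def standardize_corpus(
    reviews: Iterable[RawReview],
    lexicon: Lexicon,
    *,
    window: int = 3,
    log: StandardizationLog | None = None,
) -> list[StandardizedReview]:
    """tokenize → apply_lexicon → apply_connotation_rules, per review."""
    seen: set[str] = set()
    out = []
    for r in reviews:
        if r.wine_id in seen:
            raise CorpusIntegrityError(f"duplicate wine_id {r.wine_id!r}")
        seen.add(r.wine_id)
        tokens = tokenize(r.text)
        cand = apply_lexicon(tokens, lexicon, wine_id=r.wine_id, log=log)
        desc = apply_connotation_rules(
            cand, tokens, lexicon, window=window, wine_id=r.wine_id, log=log
        )
        out.append(
            StandardizedReview(r.wine_id, r.varietal, r.style, r.vintage_year, desc)
        )
    return out


# ---------------------------------------------------------------------------
# file formats: CSV (RFC 4180, quoted text field) and JSON array
_FIELDS = ["wine_id", "varietal", "style", "vintage_year", "text"]


def read_reviews(path: str | Path) -> list[RawReview]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    return [
        RawReview(
            wine_id=str(row["wine_id"]),
            varietal=row["varietal"],
            style=row["style"],
            vintage_year=int(row["vintage_year"]),
            text=row["text"],
        )
        for row in rows
    ]


def write_reviews(reviews: Sequence[RawReview], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps([r.__dict__ for r in reviews], indent=1), encoding="utf-8"
        )
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_FIELDS, quoting=csv.QUOTE_MINIMAL)
        w.writeheader()
        for r in reviews:
            w.writerow({f: getattr(r, f) for f in _FIELDS})


def write_standardized(reviews: Sequence[StandardizedReview], path: str | Path) -> None:
    rows = [
        {
            "wine_id": r.wine_id,
            "varietal": r.varietal,
            "style": r.style,
            "vintage_year": r.vintage_year,
            "descriptors": sorted(r.descriptors),
        }
        for r in reviews
    ]
    Path(path).write_text(json.dumps(rows, indent=1), encoding="utf-8")


def read_standardized(path: str | Path) -> list[StandardizedReview]:
    rows = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        StandardizedReview(
            row["wine_id"],
            row["varietal"],
            row["style"],
            int(row["vintage_year"]),
            frozenset(row["descriptors"]),
        )
        for row in rows
    ]
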