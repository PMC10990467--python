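"""Lexicon-driven multi-label classification of free-text aggressive utterances.

Utterances are matched against a small configurable lexicon of three explicit
aggression categories; anything that matches no explicit category falls into a
residual ``other`` class.  Matching is substring/regex on the whole normalized
utterance (NFKC + lowercase), so multi-word patterns work regardless of the
tokenizer.  Tokenization is only used for building word-frequency tables and is
pluggable, so a real morphological analyzer can be dropped in.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import yaml

JOB_PERFORMANCE = "job_performance"
PERSONALITY_LOOKS = "personality_looks"
LIFE_THREAT = "life_threat"
OTHER = "other"

#: The three categories that carry patterns, in canonical order.
EXPLICIT_CATEGORIES: tuple[str, ...] = (JOB_PERFORMANCE, PERSONALITY_LOOKS, LIFE_THREAT)
#: All categories including the residual class.
ALL_CATEGORIES: tuple[str, ...] = EXPLICIT_CATEGORIES + (OTHER,)

Tokenizer = Callable[[str], list[str]]


class LexiconError(ValueError):
    """Raised for structurally invalid lexicons (bad regex, missing category...)."""


def normalize(text: str) -> str:
    """Unicode NFKC normalization followed by lowercasing."""
    return unicodedata.normalize("NFKC", text).lower()


@dataclass(frozen=True)
class Pattern:
    """A single match pattern: a literal substring or a regular expression."""

    text: str
    kind: str = "literal"  # "literal" | "regex"

    def __post_init__(self) -> None:
        if not self.text:
            raise LexiconError("empty pattern")
        if self.kind not in ("literal", "regex"):
            raise LexiconError(f"unknown pattern type {self.kind!r} for pattern {self.text!r}")


@dataclass
class Lexicon:
    """Category -> pattern lists plus a surface-form -> lemma map.

    The residual ``other`` category never appears here: it is defined by the
    absence of any explicit-category match.
    """

    patterns: dict[str, list[Pattern]]
    lemma_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in EXPLICIT_CATEGORIES:
            if cat not in self.patterns:
                raise LexiconError(f"lexicon is missing category {cat!r}")
        if OTHER in self.patterns:
            raise LexiconError(f"{OTHER!r} is residual and must not carry patterns")
        unknown = set(self.patterns) - set(EXPLICIT_CATEGORIES)
        if unknown:
            raise LexiconError(f"unknown categories in lexicon: {sorted(unknown)}")
        for cat, pats in self.patterns.items():
            if not pats:
                raise LexiconError(f"category {cat!r} has no patterns")
        # lemma_map must be idempotent: mapping a lemma again must be a no-op
        for surface, lemma in self.lemma_map.items():
            if self.lemma_map.get(lemma, lemma) != lemma:
                raise LexiconError(
                    f"lemma_map is not idempotent: {surface!r} -> {lemma!r} -> "
                    f"{self.lemma_map[lemma]!r}"
                )
        self._compiled: dict[str, list[tuple[Pattern, re.Pattern | str]]] = {}
        for cat, pats in self.patterns.items():
            compiled: list[tuple[Pattern, re.Pattern | str]] = []
            for pat in pats:
                if pat.kind == "regex":
                    try:
                        compiled.append((pat, re.compile(pat.text, re.IGNORECASE)))
                    except re.error as exc:
                        raise LexiconError(
                            f"invalid regex {pat.text!r} in category {cat!r}: {exc}"
                        ) from exc
                else:
                    compiled.append((pat, normalize(pat.text)))
            self._compiled[cat] = compiled

    def matches(self, category: str, text: str) -> list[str]:
        """Patterns of ``category`` that fire on the normalized ``text``."""
        norm = normalize(text)
        hits = []
        for pat, matcher in self._compiled[category]:
            if isinstance(matcher, str):
                if matcher in norm:
                    hits.append(pat.text)
            elif matcher.search(norm):
                hits.append(pat.text)
        return hits


def default_lexicon() -> Lexicon:
    """Illustrative default lexicon seeded from the published example words.

    The authoritative pattern list lives in the study's supplementary material
    and is not reproduced here; analyses intended to mirror it must supply
    their own lexicon file.
    """
    return Lexicon(
        patterns={
            JOB_PERFORMANCE: [
                Pattern("idiot"),
                Pattern("useless"),
                Pattern("poor memory"),
                Pattern("quit"),
                Pattern("resign"),
            ],
            PERSONALITY_LOOKS: [
                Pattern("bald head"),
                Pattern("shit"),
                Pattern("ugly"),
            ],
            LIFE_THREAT: [
                Pattern("die"),
                Pattern("kill"),
            ],
        },
        lemma_map=default_lemma_map(),
    )


def default_lemma_map() -> dict[str, str]:
    """Conjugation-grouping map for the default English example words."""
    return {
        "dies": "die", "died": "die", "dying": "die",
        "kills": "kill", "killed": "kill", "killing": "kill",
        "idiots": "idiot",
        "quits": "quit", "quitting": "quit",
        "resigns": "resign", "resigned": "resign", "resigning": "resign",
    }


@dataclass(frozen=True)
class UtteranceRecord:
    """One reported utterance; ``perpetrator`` is carried through untouched."""

    participant_id: str
    text: str
    perpetrator: str | None = None

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")


@dataclass
class UtteranceFlags:
    """Multi-label classification of one participant's utterance(s)."""

    participant_id: str
    flags: dict[str, bool]
    matched_patterns: dict[str, list[str]]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CATEGORIES if self.flags[c])


def tokenize(text: str, lemma_map: Mapping[str, str] | None = None) -> list[str]:
    """Split normalized text into word tokens and map each through the lemma map.

    Total function: empty text yields an empty list.  ``\\w+`` tokenization is a
    stand-in for morphological analysis; swap in a different :data:`Tokenizer`
    for languages where it is too crude.
    """
    tokens = re.findall(r"\w+", normalize(text))
    if lemma_map:
        tokens = [lemma_map.get(tok, tok) for tok in tokens]
    return tokens


def flag_utterance(record: UtteranceRecord, lexicon: Lexicon) -> UtteranceFlags:
    """Flag one utterance against every explicit category; ``other`` is residual.

    A category fires iff at least one of its patterns matches the normalized
    text, so one utterance may carry several flags.
    """
    matched = {cat: lexicon.matches(cat, record.text) for cat in EXPLICIT_CATEGORIES}
    flags = {cat: bool(matched[cat]) for cat in EXPLICIT_CATEGORIES}
    flags[OTHER] = not any(flags.values())
    matched[OTHER] = []
    return UtteranceFlags(record.participant_id, flags, matched)


def flag_records(
    records: Iterable[UtteranceRecord], lexicon: Lexicon
) -> dict[str, UtteranceFlags]:
    """Person-level flags: the OR-union over a participant's utterances.

    ``other`` is recomputed residually after the union so that a participant
    with one matching and one non-matching utterance is not counted as both.
    """
    merged: dict[str, UtteranceFlags] = {}
    for record in records:
        new = flag_utterance(record, lexicon)
        old = merged.get(record.participant_id)
        if old is None:
            merged[record.participant_id] = new
            continue
        for cat in EXPLICIT_CATEGORIES:
            old.flags[cat] = old.flags[cat] or new.flags[cat]
            old.matched_patterns[cat] = sorted(
                set(old.matched_patterns[cat]) | set(new.matched_patterns[cat])
            )
        old.flags[OTHER] = not any(old.flags[c] for c in EXPLICIT_CATEGORIES)
    return merged


@dataclass
class TokenFrequencyTable:
    """Lemma counts for one category, filtered at export by ``min_frequency``."""

    counts: dict[str, int]           # full counts, every value >= 1
    min_frequency: int = 1

    def __post_init__(self) -> None:
        if self.min_frequency < 1:
            raise ValueError("min_frequency must be >= 1")
        if any(v < 1 for v in self.counts.values()):
            raise ValueError("raw counts must all be >= 1")

    @property
    def total_tokens(self) -> int:
        return sum(self.counts.values())

    @property
    def entries(self) -> list[tuple[str, int]]:
        """Filtered entries, descending count with lexicographic tie-break."""
        kept = [(w, c) for w, c in self.counts.items() if c >= self.min_frequency]
        return sorted(kept, key=lambda wc: (-wc[1], wc[0]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["lemma", "count"])
            writer.writerows(self.entries)


def build_frequency_table(
    records: Sequence[UtteranceRecord],
    category: str,
    lexicon: Lexicon,
    min_frequency: int = 2,
    tokenizer: Tokenizer | None = None,
) -> TokenFrequencyTable:
    """Lemma-frequency table over the records flagged with ``category``."""
    if category not in ALL_CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {ALL_CATEGORIES}")
    tok = tokenizer or (lambda text: tokenize(text, lexicon.lemma_map))
    counter: Counter[str] = Counter()
    for record in records:
        if flag_utterance(record, lexicon).flags[category]:
            counter.update(tok(record.text))
    return TokenFrequencyTable(dict(counter), min_frequency=min_frequency)


@dataclass(frozen=True)
class FlagCounts:
    """Exposed-participant counts per category; categories may overlap."""

    overall: int
    by_category: dict[str, int]


def tabulate_flag_counts(flags: Iterable[UtteranceFlags]) -> FlagCounts:
    """Count flagged participants per category (one UtteranceFlags per person).

    The per-category counts may sum to more than ``overall`` because flags are
    multi-label.
    """
    seen: set[str] = set()
    by_cat = {cat: 0 for cat in ALL_CATEGORIES}
    overall = 0
    for fl in flags:
        if fl.participant_id in seen:
            raise ValueError(f"duplicate participant_id {fl.participant_id!r}")
        seen.add(fl.participant_id)
        overall += 1
        for cat in ALL_CATEGORIES:
            if fl.flags[cat]:
                by_cat[cat] += 1
    return FlagCounts(overall=overall, by_category=by_cat)


# ---------------------------------------------------------------------------
# File formats


def load_lexicon(path: str | Path, lemma_map_path: str | Path | None = None) -> Lexicon:
    """Load a lexicon from YAML or TSV.

    YAML layout::

        categories:
          job_performance:
            - pattern: useless
            - pattern: "resign|quit"
              type: regex

    TSV layout: ``category<TAB>pattern<TAB>pattern_type`` with a header row.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        raw = doc.get("categories", doc) if isinstance(doc, dict) else None
        if not isinstance(raw, dict):
            raise LexiconError(f"cannot parse lexicon file {path}")
        patterns: dict[str, list[Pattern]] = {}
        for cat, pats in raw.items():
            plist = []
            for item in pats or []:
                if isinstance(item, str):
                    plist.append(Pattern(item))
                else:
                    plist.append(Pattern(item["pattern"], item.get("type", "literal")))
            patterns[cat] = plist
    else:
        patterns = {}
        with open(path, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                patterns.setdefault(row["category"], []).append(
                    Pattern(row["pattern"], row.get("pattern_type") or "literal")
                )
    lemma_map = load_lemma_map(lemma_map_path) if lemma_map_path else {}
    return Lexicon(patterns=patterns, lemma_map=lemma_map)


def load_lemma_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (surface, lemma), no header required."""
    lemma_map: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "surface" and row[1] == "lemma":
                continue
            lemma_map[row[0]] = row[1]
    return lemma_map


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    doc = {
        "categories": {
            cat: [{"pattern": p.text, "type": p.kind} for p in pats]
            for cat, pats in lexicon.patterns.items()
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, allow_unicode=True, sort_keys=False)


def read_utterances(path: str | Path) -> list[UtteranceRecord]:
    """Read a ``participant_id,text,perpetrator`` CSV (UTF-8)."""
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                UtteranceRecord(
                    participant_id=row["participant_id"],
                    text=row.get("text") or "",
                    perpetrator=row.get("perpetrator") or None,
                )
            )
    return records
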