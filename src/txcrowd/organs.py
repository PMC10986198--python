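"""Bigram-adjacency organ-type classification of campaign stories.

A story is labeled with the organ it fundraises for by looking for a
clinically relevant word immediately adjacent (before or after) to an organ
term in the preprocessed token sequence.  Stories qualifying for two or more
distinct organs are labeled ``multiple``; stories with no qualifying
adjacency are labeled ``missing``.  The lexicon of organ terms and relevant
adjacent words ships as a data file and is fully overridable.
"""
from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import LABEL_MISSING, LABEL_MULTIPLE, SOLID_ORGANS

_PUNCT_RE = re.compile(r"[^\w\s]")


@dataclass(frozen=True)
class OrganLexicon:
    """Organ terms with their clinically relevant before/after word sets.

    ``organs`` maps each organ token to a pair of frozensets: words that make
    the organ mention clinically relevant when they immediately precede it
    (before-words) or follow it (after-words).  Two-word organs are carried
    as a single underscore-joined compound token; ``compounds`` lists the
    surface phrase to collapse.  All lexicon words are lowercase and
    punctuation-free.
    """

    organs: Mapping[str, tuple[frozenset[str], frozenset[str]]]
    stopwords: frozenset[str]
    solid: frozenset[str] = field(default=SOLID_ORGANS)
    compounds: tuple[tuple[str, str], ...] = (("bone marrow", "bone_marrow"),)

    @classmethod
    def default(cls) -> "OrganLexicon":
        """The lexicon shipped with the package (a documented stand-in)."""
        pkg = resources.files("txcrowd.data")
        spec = json.loads(pkg.joinpath("lexicon.json").read_text())
        stops = frozenset(
            w for w in pkg.joinpath("stopwords.txt").read_text().split() if w
        )
        return cls._from_spec(spec, stops)

    @classmethod
    def from_json(cls, path: str, stopwords: Iterable[str] | None = None) -> "OrganLexicon":
        with open(path, encoding="utf-8") as fh:
            spec = json.load(fh)
        if stopwords is None:
            stops = OrganLexicon.default().stopwords
        else:
            stops = frozenset(w.lower() for w in stopwords)
        return cls._from_spec(spec, stops)

    @classmethod
    def _from_spec(cls, spec: dict, stops: frozenset[str]) -> "OrganLexicon":
        organs = {
            organ: (frozenset(sides["before"]), frozenset(sides["after"]))
            for organ, sides in spec["organs"].items()
        }
        return cls(
            organs=organs,
            stopwords=stops,
            solid=frozenset(spec.get("solid", sorted(SOLID_ORGANS))),
            compounds=tuple((a, b) for a, b in spec.get("compounds", [["bone marrow", "bone_marrow"]])),
        )


def preprocess(story: str, lexicon: OrganLexicon) -> list[str]:
    """Tokenize a story: lowercase, strip punctuation, drop stop words.

    Hyphens act as token separators; digits are retained.  Compound organ
    phrases are collapsed to their single token before stop-word removal, so
    removal of intervening stop words can never split or fabricate one.
    Token order is preserved; removal of stop words deliberately creates new
    adjacencies, which is what the bigram rule operates on.
    """
    text = story.lower().replace("-", " ")
    text = _PUNCT_RE.sub(" ", text)
    for phrase, token in lexicon.compounds:
        text = re.sub(rf"\b{re.escape(phrase)}\b", token, text)
    return [t for t in text.split() if t not in lexicon.stopwords]


@dataclass
class BigramTable:
    """Ranked before/after word-pair counts per organ over a story collection."""

    before: dict[str, Counter]
    after: dict[str, Counter]

    def ranked(self, organ: str, side: str) -> list[tuple[str, int]]:
        """(word, count) sorted by count descending, ties lexicographic."""
        counts = (self.before if side == "before" else self.after).get(organ, Counter())
        return sorted(counts.items(), key=lambda wc: (-wc[1], wc[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for side, table in (("before", self.before), ("after", self.after)):
            for organ in sorted(table):
                for rank, (word, count) in enumerate(self.ranked(organ, side), start=1):
                    rows.append((organ, side, rank, word, count))
        return pd.DataFrame(rows, columns=["organ", "side", "rank", "word", "count"])


def collect_bigrams(stories: Iterable[Sequence[str]], lexicon: OrganLexicon) -> BigramTable:
    """Aggregate before- and after-pairs around every organ token occurrence.

    For each occurrence of an organ token, its immediate predecessor is
    recorded as a before-pair and its immediate successor as an after-pair;
    occurrences at a sequence boundary contribute only the side that exists.
    """
    before: dict[str, Counter] = {}
    after: dict[str, Counter] = {}
    organ_set = set(lexicon.organs)
    for tokens in stories:
        for i, tok in enumerate(tokens):
            if tok not in organ_set:
                continue
            if i > 0:
                before.setdefault(tok, Counter())[tokens[i - 1]] += 1
            if i + 1 < len(tokens):
                after.setdefault(tok, Counter())[tokens[i + 1]] += 1
    return BigramTable(before=before, after=after)


def classify(tokens: Sequence[str], lexicon: OrganLexicon) -> str:
    """Label a preprocessed story: one organ, ``multiple``, or ``missing``.

    An organ qualifies if any of its occurrences has a clinically relevant
    word immediately before or after it.  The label depends only on the
    story and the lexicon, never on corpus context.
    """
    qualifying: set[str] = set()
    for i, tok in enumerate(tokens):
        sides = lexicon.organs.get(tok)
        if sides is None or tok in qualifying:
            continue
        before_words, after_words = sides
        if (i > 0 and tokens[i - 1] in before_words) or (
            i + 1 < len(tokens) and tokens[i + 1] in after_words
        ):
            qualifying.add(tok)
    if not qualifying:
        return LABEL_MISSING
    if len(qualifying) > 1:
        return LABEL_MULTIPLE
    return next(iter(qualifying))


def classify_stories(stories: Iterable[str], lexicon: OrganLexicon | None = None) -> list[str]:
    """Preprocess and classify raw story texts."""
    lex = lexicon if lexicon is not None else OrganLexicon.default()
    return [classify(preprocess(s, lex), lex) for s in stories]


def is_solid_organ(label: str, lexicon: OrganLexicon | None = None) -> bool:
    solid = lexicon.solid if lexicon is not None else SOLID_ORGANS
    return label in solid
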