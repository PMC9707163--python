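"""LIWC-format category dictionaries and per-document percentage scoring.

A category lexicon maps token patterns (literal words, or stems with a
trailing ``*`` wildcard) to one or more categories.  Scoring a document is
bag-of-words: each token is looked up in the lexicon, a literal entry takes
precedence over stem entries for the same surface form, and each category's
score is the percentage of the document's tokens that matched any of its
patterns.

Alongside dictionary categories the module supports *computed* categories
defined by a predicate on the token (e.g. words of six or more letters),
mirroring the non-lexical counters that style word-count tools include.

The proprietary LIWC 2015 dictionary is not redistributable, so the package
ships an open stand-in style lexicon with 41 function-word/style categories
and a 10-category personal-values stand-in; users with a licensed ``.dic``
file can load it with :func:`load_dictionary` instead.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np

from .corpus_io import Comment, tokenize

logger = logging.getLogger(__name__)


class DicParseError(ValueError):
    """Raised when a ``.dic`` file violates the format contract."""


@dataclass(frozen=True)
class StyleVector:
    """Per-document percentages over an ordered category set."""

    values: np.ndarray
    n_tokens: int


@dataclass
class CategoryLexicon:
    """Mapping from token patterns to category names.

    ``literals`` maps exact lowercased tokens to category-name sets;
    ``stems`` maps wildcard prefixes (the ``*`` removed) likewise.
    ``computed`` holds predicate-defined categories evaluated on every
    token regardless of dictionary matches.
    """

    categories: list[str]
    literals: dict[str, frozenset[str]] = field(default_factory=dict)
    stems: dict[str, frozenset[str]] = field(default_factory=dict)
    computed: dict[str, Callable[[str], bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise DicParseError("duplicate category names")
        declared = set(self.categories)
        referenced = set().union(*self.literals.values(), *self.stems.values(), set()) | set(
            self.computed
        )
        undeclared = referenced - declared
        if undeclared:
            raise DicParseError(f"patterns reference undeclared categories: {sorted(undeclared)}")
        # stems sorted by length lets matching probe only existing lengths
        self._stem_lengths = sorted({len(s) for s in self.stems})

    def match(self, token: str) -> set[str]:
        """Categories incremented by ``token`` (lowercased).

        A literal entry takes precedence over stem entries for the same
        surface form; otherwise all matching stems contribute.  Computed
        categories are evaluated in addition.
        """
        cats: set[str] = set()
        lit = self.literals.get(token)
        if lit is not None:
            cats |= lit
        else:
            for L in self._stem_lengths:
                if L <= len(token):
                    hit = self.stems.get(token[:L])
                    if hit is not None:
                        cats |= hit
        for name, pred in self.computed.items():
            if pred(token):
                cats.add(name)
        return cats

    def add_computed(self, name: str, predicate: Callable[[str], bool]) -> None:
        if name in self.categories:
            raise DicParseError(f"category {name!r} already declared")
        self.categories.append(name)
        self.computed[name] = predicate
        self.__post_init__()


def parse_dictionary(text: str, source: str = "<string>") -> CategoryLexicon:
    """Parse LIWC ``.dic`` dialect text into a :class:`CategoryLexicon`.

    The format is a ``%``-delimited header of ``id name`` lines followed by
    ``word id id ...`` lines; a trailing ``*`` on a word marks a stem.
    Undeclared or duplicate category ids are fatal, with the offending line
    number in the message.
    """
    lines = text.splitlines()
    id_to_name: dict[str, str] = {}
    literals: dict[str, set[str]] = {}
    stems: dict[str, set[str]] = {}

    in_header = False
    header_done = False
    for no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line == "%":
            if not in_header and not header_done:
                in_header = True
            elif in_header:
                in_header = False
                header_done = True
            continue
        parts = line.split()
        if in_header:
            if len(parts) < 2:
                raise DicParseError(f"{source}:{no}: malformed header line {line!r}")
            cid, name = parts[0], parts[1]
            if cid in id_to_name:
                raise DicParseError(f"{source}:{no}: duplicate category id {cid}")
            if name in id_to_name.values():
                raise DicParseError(f"{source}:{no}: duplicate category name {name!r}")
            id_to_name[cid] = name
        else:
            if not header_done:
                raise DicParseError(f"{source}:{no}: body before '%' header")
            if len(parts) < 2:
                raise DicParseError(f"{source}:{no}: pattern {parts[0]!r} lists no categories")
            word, ids = parts[0].lower(), parts[1:]
            names = set()
            for cid in ids:
                if cid not in id_to_name:
                    raise DicParseError(f"{source}:{no}: undeclared category id {cid}")
                names.add(id_to_name[cid])
            if word.endswith("*"):
                stems.setdefault(word[:-1], set()).update(names)
            else:
                literals.setdefault(word, set()).update(names)

    if not header_done:
        raise DicParseError(f"{source}: missing '%'-delimited header")
    if not literals and not stems:
        logger.warning("%s: dictionary declares categories but no patterns", source)
    return CategoryLexicon(
        categories=list(id_to_name.values()),
        literals={w: frozenset(c) for w, c in literals.items()},
        stems={w: frozenset(c) for w, c in stems.items()},
    )


def load_dictionary(path) -> CategoryLexicon:
    """Load a ``.dic`` dictionary file (UTF-8)."""
    with open(path, encoding="utf-8") as fh:
        return parse_dictionary(fh.read(), source=str(path))


def six_letter_word(token: str) -> bool:
    """Six or more letters/digits, apostrophes not counted."""
    return len(token.replace("'", "")) >= 6


def contraction(token: str) -> bool:
    """Token written with an internal apostrophe (don't, it's, ...)."""
    return "'" in token


def load_default_style_lexicon() -> CategoryLexicon:
    """Open stand-in style lexicon: 39 dictionary categories of function
    words plus two computed counters (six-letter-plus words and
    apostrophe contractions), 41 categories in all."""
    text = resources.files("stylemap.data").joinpath("style41.dic").read_text("utf-8")
    lex = parse_dictionary(text, source="style41.dic")
    lex.add_computed("sixltr", six_letter_word)
    lex.add_computed("contraction", contraction)
    return lex


def load_default_value_lexicon() -> CategoryLexicon:
    """Open stand-in lexicon for the ten basic personal values."""
    text = resources.files("stylemap.data").joinpath("values10.dic").read_text("utf-8")
    return parse_dictionary(text, source="values10.dic")


def score_document(
    body: str, lexicon: CategoryLexicon, categories: Sequence[str] | None = None
) -> StyleVector:
    """Percentage of tokens matching each configured category.

    ``categories`` defaults to the lexicon's full ordered category list.
    A token may increment several categories.  A document with zero tokens
    is an error: the percentage denominator is undefined (upstream cleaning
    guarantees at least one token).
    """
    cats = list(categories) if categories is not None else list(lexicon.categories)
    unknown = set(cats) - set(lexicon.categories)
    if unknown:
        raise KeyError(f"categories not in lexicon: {sorted(unknown)}")
    tokens = tokenize(body)
    if not tokens:
        raise ValueError("cannot score a document with zero tokens")
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros(len(cats))
    for tok in tokens:
        for c in lexicon.match(tok):
            i = idx.get(c)
            if i is not None:
                counts[i] += 1
    return StyleVector(values=100.0 * counts / len(tokens), n_tokens=len(tokens))


def featurize_group(
    comments: Iterable[Comment],
    lexicon: CategoryLexicon,
    categories: Sequence[str] | None = None,
) -> np.ndarray:
    """Stack per-comment style vectors into an (n_comments, n_categories)
    matrix, rows in input order."""
    cats = list(categories) if categories is not None else list(lexicon.categories)
    rows = [score_document(c.body, lexicon, cats).values for c in comments]
    if not rows:
        return np.empty((0, len(cats)))
    return np.vstack(rows)


def write_feature_csv(matrix: np.ndarray, ids: Sequence[str], categories: Sequence[str], path) -> None:
    """Write a feature matrix as CSV with a leading comment-id column."""
    import pandas as pd

    pd.DataFrame(matrix, index=list(ids), columns=list(categories)).to_csv(
        path, index_label="comment_id"
    )
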