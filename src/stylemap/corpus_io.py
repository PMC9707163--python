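"""Reading, validating and cleaning per-group comment corpora.

A corpus is a sequence of :class:`Comment` records (one authored text unit
with a timestamp and a group label), read from JSON Lines or CSV.  Cleaning
applies the exclusion rules standard in dictionary-based psycholinguistic
work on forum data: drop bot authors, deleted/removed authors and bodies,
URL-only posts, and short posts; strip URLs from everything that survives.

Every rule is applied in a fixed order and each removed comment is
attributed to exactly the first rule that matched, so the resulting
:class:`CleaningReport` is an exact account: ``input_count`` equals
``output_count`` plus the sum of per-rule removals.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ("id", "author", "body", "created_utc")
GROUP_FIELDS = ("group", "subreddit")

#: Tokens are maximal runs of letters/digits with internal apostrophes
#: allowed; everything else separates.  Matching is on lowercased text.
TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)

#: Schemeful URLs plus bare ``www.`` prefixes.
URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)

DELETED_AUTHOR = "[deleted]"
DELETED_BODIES = frozenset({"[deleted]", "[removed]"})


@dataclass(frozen=True)
class Comment:
    """One authored text unit with timestamp and group label."""

    id: str
    author: str
    body: str
    created_utc: int
    group: str


@dataclass
class CleaningRules:
    """Configuration for :func:`clean_comments`.

    ``min_words`` is the minimum token count a comment must retain after
    URL stripping (default 50).  ``bot_blacklist`` supplements the built-in
    heuristic that any author name ending in ``bot`` is a self-identifying
    bot.
    """

    min_words: int = 50
    bot_blacklist: frozenset[str] = frozenset()
    deleted_authors: frozenset[str] = frozenset({DELETED_AUTHOR})
    deleted_bodies: frozenset[str] = DELETED_BODIES

    def is_bot(self, author: str) -> bool:
        a = author.strip().lower()
        return a.endswith("bot") or a in {b.lower() for b in self.bot_blacklist}


#: Order in which removal rules are applied; first match wins.
RULE_ORDER = ("bot_author", "deleted_author", "deleted_body", "url_only", "min_words")


@dataclass
class CleaningReport:
    """Per-rule removal tally for one cleaning pass."""

    input_count: int = 0
    output_count: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "output_count": self.output_count,
                "removed": self.removed,
            },
            indent=2,
        )


def word_count(body: str) -> int:
    """Number of tokens in ``body`` under the canonical tokenizer."""
    return len(TOKEN_RE.findall(body.lower()))


def tokenize(body: str) -> list[str]:
    """Lowercased tokens of ``body``: runs of letters/digits, internal
    apostrophes allowed, everything else a separator."""
    return TOKEN_RE.findall(body.lower())


def strip_urls(body: str) -> str:
    """Remove schemeful and ``www.`` URLs, collapsing leftover whitespace."""
    stripped = URL_RE.sub(" ", body)
    return re.sub(r"[ \t]+", " ", stripped).strip()


def _record_to_comment(rec: dict, line_no: int) -> Comment | None:
    for f in REQUIRED_FIELDS:
        if f not in rec or rec[f] is None or rec[f] == "":
            logger.warning("record %d rejected: missing field %r", line_no, f)
            return None
    group = None
    for f in GROUP_FIELDS:
        if rec.get(f):
            group = str(rec[f])
            break
    if group is None:
        logger.warning("record %d rejected: missing group/subreddit", line_no)
        return None
    body = str(rec["body"])
    # A title, when present, is scored jointly with the body.
    if rec.get("title"):
        body = f"{rec['title']} {body}"
    try:
        created = int(rec["created_utc"])
    except (TypeError, ValueError):
        logger.warning("record %d rejected: bad created_utc %r", line_no, rec["created_utc"])
        return None
    return Comment(
        id=str(rec["id"]),
        author=str(rec["author"]),
        body=body,
        created_utc=created,
        group=group,
    )


def read_comments(path, fmt: str | None = None) -> list[Comment]:
    """Read comments from a JSON Lines or CSV file.

    ``fmt`` is ``"jsonl"`` or ``"csv"``; when omitted it is inferred from
    the file suffix.  Malformed records (missing required fields,
    unparseable lines) are rejected individually and logged; an unreadable
    file raises.
    """
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "jsonl"
    if fmt not in {"jsonl", "csv"}:
        raise ValueError(f"unknown format {fmt!r}")

    comments: list[Comment] = []
    n_bad = 0
    with open(path, encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError:
                    logger.warning("line %d rejected: invalid JSON", i)
                    n_bad += 1
                    continue
                c = _record_to_comment(rec, i)
                if c is None:
                    n_bad += 1
                else:
                    comments.append(c)
        else:
            reader = csv.DictReader(fh)
            for i, rec in enumerate(reader, start=2):
                c = _record_to_comment(rec, i)
                if c is None:
                    n_bad += 1
                else:
                    comments.append(c)
    logger.info("read %d comments from %s (%d malformed)", len(comments), path, n_bad)
    return comments


def _removal_rule(c: Comment, rules: CleaningRules) -> tuple[str | None, Comment]:
    """First matching removal rule for ``c``, or the cleaned survivor."""
    if rules.is_bot(c.author):
        return "bot_author", c
    if c.author in rules.deleted_authors:
        return "deleted_author", c
    if c.body.strip() in rules.deleted_bodies:
        return "deleted_body", c
    had_url = URL_RE.search(c.body) is not None
    stripped = strip_urls(c.body)
    if had_url and word_count(stripped) == 0:
        return "url_only", c
    survivor = replace(c, body=stripped) if had_url else c
    if word_count(survivor.body) < rules.min_words:
        return "min_words", survivor
    return None, survivor


def clean_comments(
    comments: Iterable[Comment], rules: CleaningRules | None = None
) -> tuple[list[Comment], CleaningReport]:
    """Apply the exclusion rules in fixed order and strip URLs.

    Rule order: bot author -> deleted author -> deleted/removed body ->
    URL-only body -> (URL stripping) -> minimum word count.  Each removal
    is attributed to the first matching rule.  Surviving comments have
    URLs removed and at least ``rules.min_words`` tokens.
    """
    rules = rules or CleaningRules()
    report = CleaningReport()
    kept: list[Comment] = []
    for c in comments:
        report.input_count += 1
        rule, survivor = _removal_rule(c, rules)
        if rule is None:
            kept.append(survivor)
        else:
            report.removed[rule] += 1
    report.output_count = len(kept)
    return kept, report


def write_comments_jsonl(comments: Sequence[Comment], path) -> None:
    """Write comments in the JSONL schema :func:`read_comments` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(
                json.dumps(
                    {
                        "id": c.id,
                        "author": c.author,
                        "body": c.body,
                        "created_utc": c.created_utc,
                        "subreddit": c.group,
                    }
                )
                + "\n"
            )
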