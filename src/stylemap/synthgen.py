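"""Synthetic group corpora with controlled style-category usage.

The generator emulates the statistical structure that dictionary-based
style scoring assumes: each document is a bag of tokens drawn
independently from per-category vocabularies according to a group's
:class:`StyleProfile` (token-emission probabilities per category, with the
remaining mass going to a "filler" category matched by no dictionary
pattern).  Category vocabularies are disjoint synthetic token sets, and a
matching ``.dic`` dictionary is available for every generated corpus, so
lexicon scoring recovers the emission percentages exactly by construction.

Document lengths follow a negative binomial shifted to a minimum of 50
tokens — heavy-tailed like real forum comments, and guaranteed to pass
the minimum-word cleaning rule.

Two higher-level constructions support end-to-end testing: archetype sets
(a few base profiles laid out in a two-dimensional latent style space,
each with several small within-type perturbations) and drift corpora
(time slices interpolating between two profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Comment
from .lexicon import CategoryLexicon, parse_dictionary

#: Default number of style categories, matching the default style set size.
DEFAULT_N_CATEGORIES = 41
DEFAULT_VOCAB_SIZE = 20
FILLER = "filler"


def synthetic_categories(n: int = DEFAULT_N_CATEGORIES) -> list[str]:
    """Zero-padded synthetic category names ``c00 .. c<n-1>``."""
    width = len(str(n - 1))
    return [f"c{i:0{width}d}" for i in range(n)]


def synthetic_dictionary_text(
    categories: Sequence[str], vocab_size: int = DEFAULT_VOCAB_SIZE
) -> str:
    """``.dic`` text whose stems match exactly the generator's vocabularies.

    Category ``c`` owns tokens ``<c>w0 .. <c>w<vocab_size-1>``, matched by
    the single stem ``<c>w*``; filler tokens match nothing.
    """
    lines = ["%"]
    for i, c in enumerate(categories, start=1):
        lines.append(f"{i}\t{c}")
    lines.append("%")
    for i, c in enumerate(categories, start=1):
        lines.append(f"{c}w*\t{i}")
    return "\n".join(lines) + "\n"


def synthetic_lexicon(
    categories: Sequence[str], vocab_size: int = DEFAULT_VOCAB_SIZE
) -> CategoryLexicon:
    return parse_dictionary(synthetic_dictionary_text(categories, vocab_size), "<synthetic>")


@dataclass
class StyleProfile:
    """Token-emission probabilities per category plus a length model.

    ``category_probs`` need not sum to 1; the remainder is filler mass.
    ``doc_length`` is (mean, dispersion) of a negative binomial shifted to
    ``min_length`` tokens, so generated documents always survive the
    minimum-word cleaning rule.
    """

    category_probs: dict[str, float]
    doc_length: tuple[float, float] = (100.0, 8.0)
    min_length: int = 50

    def __post_init__(self) -> None:
        probs = np.array(list(self.category_probs.values()), dtype=float)
        if probs.size and probs.min() < 0:
            raise ValueError("category probabilities must be non-negative")
        if probs.sum() > 1.0 + 1e-9:
            raise ValueError(f"category probabilities sum to {probs.sum():.4f} > 1")
        mean, disp = self.doc_length
        if mean < self.min_length:
            raise ValueError("mean document length below the minimum length")
        if disp <= 0:
            raise ValueError("dispersion must be positive")
        if self.min_length < 50:
            raise ValueError("minimum length must satisfy the 50-word cleaning rule")

    @property
    def categories(self) -> list[str]:
        return list(self.category_probs)


@dataclass
class DriftSchedule:
    """Interpolation schedule between two profiles across time slices."""

    start_profile: StyleProfile
    end_profile: StyleProfile
    n_slices: int
    mixing: Sequence[float]

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("need at least 2 slices")
        w = np.asarray(self.mixing, dtype=float)
        if w.shape != (self.n_slices,):
            raise ValueError("mixing must have one weight per slice")
        if w.min() < 0 or w.max() > 1 or np.any(np.diff(w) < 0):
            raise ValueError("mixing weights must be monotone non-decreasing in [0, 1]")
        if set(self.start_profile.category_probs) != set(self.end_profile.category_probs):
            raise ValueError("start and end profiles must share a category set")

    @classmethod
    def linear(cls, start: StyleProfile, end: StyleProfile, n_slices: int) -> "DriftSchedule":
        return cls(start, end, n_slices, np.linspace(0.0, 1.0, n_slices))

    def profile_at(self, s: int) -> StyleProfile:
        w = float(self.mixing[s])
        probs = {
            c: (1 - w) * self.start_profile.category_probs[c]
            + w * self.end_profile.category_probs[c]
            for c in self.start_profile.category_probs
        }
        return StyleProfile(
            category_probs=probs,
            doc_length=self.start_profile.doc_length,
            min_length=self.start_profile.min_length,
        )


def _draw_length(profile: StyleProfile, rng: np.random.Generator) -> int:
    mean, r = profile.doc_length
    extra = mean - profile.min_length
    if extra <= 0:
        return profile.min_length
    p = r / (r + extra)
    return profile.min_length + int(rng.negative_binomial(r, p))


def make_group_corpus(
    profile: StyleProfile,
    n_docs: int,
    seed: int,
    group: str = "synthetic",
    year: int = 2018,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
) -> list[Comment]:
    """Generate a seeded corpus of ``n_docs`` comments under ``profile``.

    Each token independently picks a category (filler for the remaining
    mass) and then a token uniformly from that category's vocabulary.
    Timestamps are uniform within the given UTC calendar year.
    """
    if n_docs < 1:
        raise ValueError(f"n_docs must be >= 1, got {n_docs}")
    rng = np.random.default_rng(seed)
    cats = profile.categories
    probs = np.array([profile.category_probs[c] for c in cats], dtype=float)
    full_probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    full_probs /= full_probs.sum()
    names = cats + [FILLER]

    t0 = int(datetime(year, 1, 1, tzinfo=timezone.utc).timestamp())
    t1 = int(datetime(year + 1, 1, 1, tzinfo=timezone.utc).timestamp())
    comments = []
    for d in range(n_docs):
        length = _draw_length(profile, rng)
        cat_idx = rng.choice(len(names), size=length, p=full_probs)
        tok_idx = rng.integers(0, vocab_size, size=length)
        body = " ".join(f"{names[c]}w{t}" for c, t in zip(cat_idx, tok_idx))
        comments.append(
            Comment(
                id=f"{group}-{d}",
                author=f"user_{group}_{d % max(1, n_docs // 3)}",
                body=body,
                created_utc=int(rng.integers(t0, t1)),
                group=group,
            )
        )
    return comments


@dataclass
class ArchetypeSet:
    """Labelled corpora drawn from a few archetype profiles.

    ``type_of`` records the ground-truth archetype of every group for
    recovery checks; ``lexicon`` scores the corpora exactly.
    """

    corpora: dict[str, list[Comment]]
    type_of: dict[str, int]
    profiles: dict[str, StyleProfile]
    categories: list[str]
    lexicon: CategoryLexicon


def _latent_directions(n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Two mean-zero direction vectors with disjoint category support.

    Latent axis 1 raises categories 0-4 and lowers 5-9; axis 2 likewise on
    categories 10-19.  Groups separated along these axes differ in which
    style categories they over- and under-use, the way real communities
    differ in pronoun or certainty usage.
    """
    if n_categories < 20:
        raise ValueError("need at least 20 categories for the two latent axes")
    d1 = np.zeros(n_categories)
    d2 = np.zeros(n_categories)
    d1[0:5], d1[5:10] = 1.0, -1.0
    d2[10:15], d2[15:20] = 1.0, -1.0
    return d1, d2


def profile_from_latent(
    z: np.ndarray,
    categories: Sequence[str],
    base_mass: float = 0.5,
    doc_length: tuple[float, float] = (100.0, 8.0),
) -> StyleProfile:
    """Profile whose category probabilities encode a 2-D latent position.

    Each category's probability is the uniform base rate modulated
    multiplicatively along two fixed disjoint-support directions; the
    latent coordinate ``z`` must keep every factor positive (floored at
    2% of base to be safe)."""
    K = len(categories)
    d1, d2 = _latent_directions(K)
    p0 = base_mass / K
    factors = 1.0 + z[0] * d1 + z[1] * d2
    probs = np.maximum(p0 * factors, 0.02 * p0)
    return StyleProfile(
        category_probs=dict(zip(categories, probs)), doc_length=doc_length
    )


def make_archetype_set(
    n_types: int = 5,
    groups_per_type: int = 3,
    separation: float = 0.5,
    seed: int = 0,
    n_docs: int = 200,
    n_categories: int = DEFAULT_N_CATEGORIES,
    within_sd: float = 0.01,
) -> ArchetypeSet:
    """Corpora for ``n_types`` archetypes laid out on a latent circle.

    Type centers sit on a circle of radius ``separation`` in the 2-D
    latent style space; each type's groups are small seeded multiplicative
    perturbations (sd ``within_sd``) of the type center.  ``separation``
    up to ~0.7 keeps all probabilities valid; 0 makes all groups
    exchangeable.
    """
    if n_types < 2:
        raise ValueError("need at least 2 archetypes")
    if not 0 <= separation <= 0.7:
        raise ValueError("separation must lie in [0, 0.7]")
    rng = np.random.default_rng(seed)
    categories = synthetic_categories(n_categories)
    corpora: dict[str, list[Comment]] = {}
    type_of: dict[str, int] = {}
    profiles: dict[str, StyleProfile] = {}
    for t in range(n_types):
        theta = 2.0 * np.pi * t / n_types
        z_type = separation * np.array([np.cos(theta), np.sin(theta)])
        for g in range(groups_per_type):
            z = z_type + within_sd * rng.standard_normal(2)
            label = f"type{t}_g{g}"
            profile = profile_from_latent(z, categories)
            profiles[label] = profile
            type_of[label] = t
            corpora[label] = make_group_corpus(
                profile, n_docs, seed=int(rng.integers(2**31)), group=label
            )
    return ArchetypeSet(
        corpora=corpora,
        type_of=type_of,
        profiles=profiles,
        categories=categories,
        lexicon=synthetic_lexicon(categories),
    )


def make_drift_corpus(
    schedule: DriftSchedule,
    docs_per_slice: int,
    seed: int,
    slice_labels: Sequence | None = None,
    group: str = "focal",
) -> dict:
    """One corpus per time slice, drawn from the interpolated profile.

    Slice ``s`` mixes the start and end profiles with weight
    ``schedule.mixing[s]``.  ``slice_labels`` defaults to 0..n_slices-1;
    integer labels (e.g. years) are used as generation years when they
    look like calendar years.
    """
    labels = list(slice_labels) if slice_labels is not None else list(range(schedule.n_slices))
    if len(labels) != schedule.n_slices:
        raise ValueError("slice_labels must match n_slices")
    rng = np.random.default_rng(seed)
    out = {}
    for s, lab in enumerate(labels):
        year = int(lab) if isinstance(lab, int) and 1970 <= lab <= 2100 else 2018
        out[lab] = make_group_corpus(
            schedule.profile_at(s),
            docs_per_slice,
            seed=int(rng.integers(2**31)),
            group=f"{group}_{lab}",
            year=year,
        )
    return out


def expected_percentages(profile: StyleProfile) -> dict[str, float]:
    """Expected per-document category percentages under ``profile``
    (100x the emission probabilities, by construction)."""
    return {c: 100.0 * p for c, p in profile.category_probs.items()}
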