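"""Lexicon-based word-category counting (LIWC-style .dic dictionaries).

A dictionary file in the .dic dialect has a ``%``-delimited header of
``index<TAB>category`` lines followed by ``word<TAB>index...`` body lines;
entries ending in ``*`` are prefix stems.  A window's category profile is
the proportion of its tokens matching each category, normalized by the total
token count of all queries concatenated — so profiles are comparable across
windows with very different search volumes.

The analysis expects the 51-category inventory; :func:`load_dic` enforces
that by default but accepts toy dictionaries with ``expected_categories=None``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

N_CATEGORIES = 51
WILDCARD = "*"

_TOKEN_RE = re.compile(r"[a-z']+")


class LexiconError(ValueError):
    """Malformed .dic file or invariant violation."""


@dataclass
class Lexicon:
    """Category names plus exact-word and wildcard-stem entries.

    Entry category indices are 0-based positions into ``category_names``.
    """

    category_names: list[str]
    exact: dict[str, tuple[int, ...]] = field(default_factory=dict)
    stems: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.category_names)
        for word, cats in list(self.exact.items()) + list(self.stems.items()):
            if any(c < 0 or c >= n for c in cats):
                raise LexiconError(f"entry {word!r} references an unknown category index")

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    def categories_for(self, token: str) -> tuple[int, ...]:
        """Categories matched by one token: exact entry beats stem; among
        stems the longest matching prefix wins."""
        hit = self.exact.get(token)
        if hit is not None:
            return hit
        for length in range(len(token), 0, -1):
            hit = self.stems.get(token[:length])
            if hit is not None:
                return hit
        return ()

    def words_in_category(self, name: str) -> list[str]:
        """Exact (non-stem) entries belonging to a named category."""
        idx = self.category_names.index(name)
        return sorted(w for w, cats in self.exact.items() if idx in cats)


@dataclass
class CategoryProfile:
    """Per-category token proportions for one window."""

    values: np.ndarray
    total_words: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.total_words < 0:
            raise LexiconError("total_words must be nonnegative")
        if self.total_words == 0 and self.values.any():
            raise LexiconError("profile of an empty window must be all zero")
        if ((self.values < 0) | (self.values > 1)).any():
            raise LexiconError("category proportions must lie in [0, 1]")


def load_dic(
    path: str | Path, expected_categories: int | None = N_CATEGORIES
) -> Lexicon:
    """Parse a .dic dictionary file.

    Raises :class:`LexiconError` when the header does not declare exactly
    ``expected_categories`` categories (pass ``None`` to accept any size,
    e.g. for toy dictionaries) or when a body line references an undeclared
    category index.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: list[tuple[int, str]] = []
    body_start = None
    delims = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(delims) < 2:
        raise LexiconError(f"{path}: header must be delimited by two '%' lines")
    for ln in lines[delims[0] + 1 : delims[1]]:
        if not ln.strip():
            continue
        idx_s, _, name = ln.strip().partition("\t")
        if not name:
            raise LexiconError(f"{path}: bad header line {ln!r}")
        header.append((int(idx_s), name.strip()))
    body_start = delims[1] + 1

    header.sort()
    index_map = {idx: pos for pos, (idx, _) in enumerate(header)}
    names = [name for _, name in header]
    if expected_categories is not None and len(names) != expected_categories:
        raise LexiconError(
            f"{path}: expected {expected_categories} categories, found {len(names)} "
            "(pass expected_categories=None to override)"
        )

    exact: dict[str, tuple[int, ...]] = {}
    stems: dict[str, tuple[int, ...]] = {}
    for lineno, ln in enumerate(lines[body_start:], start=body_start + 1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        word, idx_strs = parts[0].strip().lower(), [p for p in parts[1:] if p.strip()]
        if not idx_strs:
            raise LexiconError(f"{path}:{lineno}: entry {word!r} has no categories")
        cats = []
        for s in idx_strs:
            idx = int(s)
            if idx not in index_map:
                raise LexiconError(
                    f"{path}:{lineno}: entry {word!r} references unknown category index {idx}"
                )
            cats.append(index_map[idx])
        cats_t = tuple(sorted(set(cats)))
        if word.endswith(WILDCARD):
            stems[word[:-1]] = cats_t
        else:
            exact[word] = cats_t
    return Lexicon(names, exact, stems)


def tokenize(text: str) -> list[str]:
    """LIWC-convention word splitting: lowercase, split on anything that is
    not a letter or apostrophe, drop empty and purely numeric residues."""
    tokens = _TOKEN_RE.findall(text.lower())
    return [t for t in tokens if any(c.isalpha() for c in t)]


def profile_texts(texts: Iterable[str], lexicon: Lexicon) -> CategoryProfile:
    """Category profile of a stream of texts concatenated in the given order."""
    counts = np.zeros(lexicon.n_categories, dtype=float)
    total = 0
    for text in texts:
        for token in tokenize(text):
            total += 1
            for c in lexicon.categories_for(token):
                counts[c] += 1
    values = counts / total if total else counts
    return CategoryProfile(values, total)


def category_profile(window, lexicon: Lexicon) -> CategoryProfile:
    """Profile of an :class:`~searchtrace.windowing.ObservationWindow`:
    all query texts concatenated in time order, one proportion per category."""
    return profile_texts((q.text for q in window.queries), lexicon)
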