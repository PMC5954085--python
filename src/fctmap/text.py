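"""Food-name normalization and fuzzy similarity scoring.

The scorer used everywhere downstream is :func:`partial_token_sort_ratio`:
names are upper-cased and stripped of punctuation, split into tokens which
are sorted, and the sorted strings are compared with a partial-ratio
similarity built on a recursive longest-common-substring decomposition.
Scores are integer percents in [0, 100]; 100 means the names are identical
(or one is fully contained in the other), 0 means no common substring.
"""

from __future__ import annotations

import math
import re
import unicodedata
import warnings
from dataclasses import dataclass, field

__all__ = [
    "EmptyNameError",
    "NormalizedName",
    "normalize",
    "levenshtein",
    "matching_blocks",
    "simple_ratio",
    "partial_ratio",
    "token_sort",
    "partial_token_sort_ratio",
]


class EmptyNameError(ValueError):
    """Raised when a name is empty (or empty after normalization).

    Callers treat this as "unmappable record": skip with a warning rather
    than abort a whole run.
    """


# Any run of characters that is neither alphanumeric nor whitespace.
# Unicode-aware: digits and accented letters survive normalization.
_PUNCT_RE = re.compile(r"[^\w\s]|_", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class NormalizedName:
    """An upper-cased, punctuation-free name and its token list."""

    text: str
    tokens: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.tokens:
            object.__setattr__(self, "tokens", tuple(self.text.split()))


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def normalize(name: str, strip_diacritics: bool = False) -> NormalizedName:
    """Normalize a raw food name for fuzzy comparison.

    Punctuation is replaced by a space (so ``"apple,raw"`` becomes two
    tokens, not one fused token), letters are upper-cased
    locale-independently, and whitespace is collapsed.  Diacritics are kept
    by default; pass ``strip_diacritics=True`` to fold them away.

    Raises
    ------
    EmptyNameError
        If the input is empty or nothing remains after normalization.
    """
    if name is None or not name.strip():
        raise EmptyNameError("empty food name")
    text = _PUNCT_RE.sub(" ", name)
    if strip_diacritics:
        text = _strip_diacritics(text)
    text = _WS_RE.sub(" ", text).strip().upper()
    if not text:
        raise EmptyNameError(f"name {name!r} is empty after normalization")
    return NormalizedName(text=text)


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character edits turning ``a`` into ``b``."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i]
        for j, cb in enumerate(b, start=1):
            cost = 0 if ca == cb else 1
            curr.append(min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + cost))
        prev = curr
    return prev[-1]


def _longest_common_block(
    a: str, b: str, alo: int, ahi: int, blo: int, bhi: int
) -> tuple[int, int, int]:
    """Longest contiguous common substring of a[alo:ahi] and b[blo:bhi].

    Ties break to the smallest start in ``a``, then the smallest start in
    ``b``.  Returns (start_a, start_b, length); length 0 if none.
    """
    b2j: dict[str, list[int]] = {}
    for j in range(blo, bhi):
        b2j.setdefault(b[j], []).append(j)
    besti, bestj, bestsize = alo, blo, 0
    # j2len[j] = length of the common suffix ending at a[i-1], b[j-1]
    j2len: dict[int, int] = {}
    for i in range(alo, ahi):
        newj2len: dict[int, int] = {}
        for j in b2j.get(a[i], ()):
            k = j2len.get(j - 1, 0) + 1
            newj2len[j] = k
            if k > bestsize:
                besti, bestj, bestsize = i - k + 1, j - k + 1, k
        j2len = newj2len
    return besti, bestj, bestsize


def matching_blocks(a: str, b: str) -> list[tuple[int, int, int]]:
    """Non-overlapping common substrings of ``a`` and ``b``.

    Recursive longest-common-substring decomposition: find the longest
    common substring, then recurse on the prefix pair and the suffix pair.
    Blocks are returned ordered by position and never overlap.
    """
    blocks: list[tuple[int, int, int]] = []
    queue: list[tuple[int, int, int, int]] = [(0, len(a), 0, len(b))]
    while queue:
        alo, ahi, blo, bhi = queue.pop()
        i, j, k = _longest_common_block(a, b, alo, ahi, blo, bhi)
        if k:
            blocks.append((i, j, k))
            queue.append((alo, i, blo, j))
            queue.append((i + k, ahi, j + k, bhi))
    blocks.sort()
    return blocks


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def simple_ratio(a: str, b: str) -> int:
    """Similarity of two strings as round(100 * 2M / (|a| + |b|)).

    M is the total length of :func:`matching_blocks`.  Empty-vs-empty
    scores 0 (with a warning); rounding is half away from zero.
    """
    total = len(a) + len(b)
    if total == 0:
        warnings.warn("simple_ratio of two empty strings; returning 0", stacklevel=2)
        return 0
    m = sum(k for _, _, k in matching_blocks(a, b))
    return _round_half_away(200.0 * m / total)


def partial_ratio(a: str, b: str) -> int:
    """Best :func:`simple_ratio` of the shorter string against aligned
    same-length windows of the longer one.

    Returns 100 when one string is fully contained in the other; 0 when
    there is no common substring.
    """
    if len(a) <= len(b):
        s, l = a, b
    else:
        s, l = b, a
    blocks = matching_blocks(s, l)
    if not blocks:
        return 0 if (s or l) else simple_ratio(s, l)
    best = 0
    seen: set[int] = set()
    for i, j, _n in blocks:
        start = max(0, j - i)
        if start in seen:
            continue
        seen.add(start)
        window = l[start : start + len(s)]
        score = simple_ratio(s, window)
        if score > best:
            best = score
            if best == 100:
                break
    return best


def token_sort(n: NormalizedName | str) -> str:
    """Tokens sorted ascending by code point, joined with single spaces."""
    tokens = n.tokens if isinstance(n, NormalizedName) else tuple(n.split())
    return " ".join(sorted(tokens))


def partial_token_sort_ratio(a: str, b: str, strip_diacritics: bool = False) -> int:
    """THE fuzzy score: partial ratio of the token-sorted normalized names.

    Raises :class:`EmptyNameError` if either name normalizes to nothing.
    """
    na = token_sort(normalize(a, strip_diacritics=strip_diacritics))
    nb = token_sort(normalize(b, strip_diacritics=strip_diacritics))
    return partial_ratio(na, nb)
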