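"""Independent oracles used by the unit and acceptance tests.

Everything here deliberately avoids the code paths under test: string
similarity is recomputed with the stdlib difflib machinery (the basis of
the original fuzzy-matching reference library), block decomposition by
naive enumeration, splits and confusion counts by exhaustive loops.
"""

from __future__ import annotations

import difflib
import math


def brute_matching_blocks(a: str, b: str) -> list[tuple[int, int, int]]:
    """LCS-block decomposition by O(n^2 m) enumeration (strings <= ~12)."""

    def longest(alo, ahi, blo, bhi):
        best = (alo, blo, 0)
        for i in range(alo, ahi):
            for j in range(blo, bhi):
                k = 0
                while i + k < ahi and j + k < bhi and a[i + k] == b[j + k]:
                    k += 1
                if k > best[2]:
                    best = (i, j, k)
        return best

    out = []

    def rec(alo, ahi, blo, bhi):
        i, j, k = longest(alo, ahi, blo, bhi)
        if k == 0:
            return
        rec(alo, i, blo, j)
        out.append((i, j, k))
        rec(i + k, ahi, j + k, bhi)

    rec(0, len(a), 0, len(b))
    return out


def _difflib_ratio(a: str, b: str) -> int:
    if not a and not b:
        return 0
    sm = difflib.SequenceMatcher(None, a, b, autojunk=False)
    return int(round(100 * sm.ratio()))


def _difflib_partial(a: str, b: str) -> int:
    s, l = (a, b) if len(a) <= len(b) else (b, a)
    sm = difflib.SequenceMatcher(None, s, l, autojunk=False)
    blocks = sm.get_matching_blocks()
    best = 0
    for blk in blocks:
        if blk.size == 0:
            continue
        start = max(0, blk.b - blk.a)
        window = l[start : start + len(s)]
        best = max(best, _difflib_ratio(s, window))
    return best


def oracle_partial_token_sort(a: str, b: str) -> int:
    """Reference partial token sort on pre-normalized (upper, clean) input."""
    sa = " ".join(sorted(a.split()))
    sb = " ".join(sorted(b.split()))
    return _difflib_partial(sa, sb)


def brute_best_split(values, labels, min_cases=2):
    """Exhaustive midpoint search for the best gain-ratio split."""

    def h(c0, c1):
        tot = c0 + c1
        out = 0.0
        for c in (c0, c1):
            if c > 0:
                p = c / tot
                out -= p * math.log2(p)
        return out

    pairs = sorted((v, l) for v, l in zip(values, labels) if not math.isnan(v))
    n = len(pairs)
    tot1 = sum(l for _, l in pairs)
    tot0 = n - tot1
    parent = h(tot0, tot1)
    best = None
    for i in range(n - 1):
        if pairs[i][0] == pairs[i + 1][0]:
            continue
        thr = (pairs[i][0] + pairs[i + 1][0]) / 2
        l1 = sum(l for v, l in pairs if v <= thr)
        l0 = sum(1 for v, l in pairs if v <= thr) - l1
        nl, nr = l0 + l1, n - l0 - l1
        if nl < min_cases or nr < min_cases:
            continue
        gain = parent - (nl * h(l0, l1) + nr * h(tot0 - l0, tot1 - l1)) / n
        pl, pr = nl / n, nr / n
        si = -(pl * math.log2(pl) + pr * math.log2(pr))
        ratio = gain / si if si > 0 else 0.0
        if best is None or ratio > best[1] + 1e-12:
            best = (thr, ratio, gain)
    return best


def brute_confusion(annotated, metric, threshold):
    """Confusion counts by direct enumeration (predicted iff >= threshold)."""
    tp = fp = fn = tn = 0
    for a in annotated:
        v = a.fuzzy_score if metric == "fuzzy" else 100.0 * a.c5_probability
        pred = v >= threshold
        pos = a.label == "plausible"
        tp += pred and pos
        fp += pred and not pos
        fn += (not pred) and pos
        tn += (not pred) and not pos
    return tp, fp, fn, tn
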