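"""End-to-end mapping of diary items onto a food composition table.

Scores every (query, FCT item) pair with the fuzzy name score and the
percent energy difference, picks the best match per query, and applies a
threshold policy — either on the fuzzy score directly or on the boosted
tree's probability.  Also: id-based cross-matching into "directly
mappable" vs "other" items, the dual training-pair filter, and
reproducible FCT subsampling.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from fctmap.classifier import BoostedTreeModel
from fctmap.features import EnergyDiffPct, FoodItem, energy_diff_pct, scale_to_100g
from fctmap.text import EmptyNameError, normalize, partial_ratio, token_sort

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCandidate",
    "MappingResult",
    "CrossmatchResult",
    "score_all_pairs",
    "best_match",
    "crossmatch_by_id",
    "select_training_pairs",
    "subsample_fct",
    "map_items",
]


@dataclass(frozen=True)
class MatchCandidate:
    """A scored (query, FCT candidate) pair."""

    query_id: str
    candidate_id: str
    fuzzy_score: int
    ediff: EnergyDiffPct
    c5_probability: Optional[float] = None
    name_variant: str = "original"

    @property
    def ediff_value(self) -> float:
        return self.ediff.value if self.ediff.defined else math.nan


@dataclass(frozen=True)
class MappingResult:
    """Outcome for one query: its best candidate and the mapping decision."""

    query_id: str
    best: Optional[MatchCandidate]
    decision: str  # "mapped" or "unmapped"
    rule: str
    runners_up: tuple = ()


@dataclass(frozen=True)
class CrossmatchResult:
    """Disjoint, exhaustive partition of queries by food identifier code."""

    directly_mappable: tuple
    other: tuple
    matches: dict  # query item_id -> FCT item_id

    def item_class(self, query_id: str) -> str:
        return "directly_mappable" if query_id in self.matches else "other"


def _sorted_name(item: FoodItem, variant: str) -> Optional[str]:
    raw = item.name(variant)
    if raw is None:
        return None
    try:
        return token_sort(normalize(raw))
    except EmptyNameError:
        return None


def score_all_pairs(
    queries: Sequence[FoodItem],
    fct: Sequence[FoodItem],
    name_variant: str = "original",
    model: Optional[BoostedTreeModel] = None,
) -> Iterator[MatchCandidate]:
    """Yield one scored candidate per (query, FCT item) pair.

    Items whose name is missing or empty under the selected variant are
    skipped with a logged warning.  Streaming: memory stays flat in the
    number of pairs.  Items are scaled to 100 g before the energy feature
    is computed.
    """
    fct_prepared = []
    skipped_fct = 0
    for item in fct:
        name = _sorted_name(item, name_variant)
        if name is None:
            skipped_fct += 1
            logger.warning("FCT item %s has no usable %s name; skipped", item.item_id, name_variant)
            continue
        fct_prepared.append((scale_to_100g(item), name))
    skipped_queries = 0
    n_pairs = 0
    for query in queries:
        qname = _sorted_name(query, name_variant)
        if qname is None:
            skipped_queries += 1
            logger.warning("query %s has no usable %s name; skipped", query.item_id, name_variant)
            continue
        q100 = scale_to_100g(query)
        for cand, cname in fct_prepared:
            ediff = energy_diff_pct(q100, cand)
            fuzzy = partial_ratio(qname, cname)
            prob = None
            if model is not None:
                prob = model.predict_proba(fuzzy, ediff.value if ediff.defined else None)
            n_pairs += 1
            yield MatchCandidate(
                query_id=query.item_id,
                candidate_id=cand.item_id,
                fuzzy_score=fuzzy,
                ediff=ediff,
                c5_probability=prob,
                name_variant=name_variant,
            )
    logger.info(
        "scored %d pairs (%d queries and %d FCT items skipped for missing names)",
        n_pairs,
        skipped_queries,
        skipped_fct,
    )


def best_match(candidates: Iterable[MatchCandidate]) -> Optional[MatchCandidate]:
    """The candidate with maximal fuzzy score, deterministically tie-broken.

    Ties go to the smaller energy difference (undefined sorts last), then
    to the lexicographically smallest candidate id.  None when empty.
    """

    def key(c: MatchCandidate):
        ediff = c.ediff.value if c.ediff.defined else math.inf
        return (-c.fuzzy_score, ediff, c.candidate_id)

    best = None
    best_key = None
    for c in candidates:
        k = key(c)
        if best is None or k < best_key:
            best, best_key = c, k
    return best


def rank_candidates(candidates: Iterable[MatchCandidate], top_k: int) -> list:
    """Top-k candidates under the best_match ordering."""

    def key(c: MatchCandidate):
        ediff = c.ediff.value if c.ediff.defined else math.inf
        return (-c.fuzzy_score, ediff, c.candidate_id)

    return sorted(candidates, key=key)[:top_k]


def crossmatch_by_id(queries: Sequence[FoodItem], fct: Sequence[FoodItem]) -> CrossmatchResult:
    """Partition queries by exact (country, food identifier code) join.

    Queries whose id exists in the FCT for the same country are "directly
    mappable"; the rest (including empty ids) are "other".  Duplicate
    (country, id) keys in the FCT are an error.
    """
    fct_keys: dict[tuple, str] = {}
    duplicates = []
    for item in fct:
        if not item.item_id:
            continue
        key = (item.country, item.item_id)
        if key in fct_keys:
            duplicates.append(key)
        fct_keys[key] = item.item_id
    if duplicates:
        raise ValueError(f"duplicate (country, id) keys in FCT: {sorted(set(duplicates))}")
    direct, other, matches = [], [], {}
    for q in queries:
        key = (q.country, q.item_id)
        if q.item_id and key in fct_keys:
            direct.append(q)
            matches[q.item_id] = fct_keys[key]
        else:
            other.append(q)
    logger.info("cross-matched %d/%d queries by identifier code", len(direct), len(queries))
    return CrossmatchResult(directly_mappable=tuple(direct), other=tuple(other), matches=matches)


def select_training_pairs(candidates: Iterable[MatchCandidate]) -> list:
    """The dual filter for pairs worth annotating.

    Keep a pair iff (fuzzy > 75 and ediff defined and ediff < 25) or
    fuzzy > 90; all inequalities strict.
    """
    kept = []
    for c in candidates:
        if c.fuzzy_score > 90:
            kept.append(c)
        elif c.fuzzy_score > 75 and c.ediff.defined and c.ediff.value < 25:
            kept.append(c)
    return kept


def subsample_fct(fct: Sequence[FoodItem], fraction: float, seed: int) -> list:
    """Reproducible uniform sample (without replacement) of the FCT.

    Size rounds to the nearest integer, minimum 1; input order preserved.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(fct)
    n = max(1, int(round(len(fct) * fraction)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(fct), size=n, replace=False))
    return [fct[i] for i in idx]


def map_items(
    queries: Sequence[FoodItem],
    fct: Sequence[FoodItem],
    metric: str = "fuzzy",
    threshold: float = 63.0,
    name_variant: str = "original",
    model: Optional[BoostedTreeModel] = None,
    top_k: int = 1,
) -> Iterator[MappingResult]:
    """Map each query to its best FCT candidate under a threshold policy.

    ``metric`` is "fuzzy" (0-100 score) or "c5" (classifier probability,
    also on a 0-100 percent scale for threshold comparison).  A query is
    mapped iff its best candidate's metric value is >= threshold;
    unmapped queries keep their best candidate for review export.
    """
    if metric not in ("fuzzy", "c5"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "c5" and model is None:
        raise ValueError("metric 'c5' requires a fitted model")
    rule = f"{metric}>={threshold:g}"
    n_mapped = 0
    n_queries = 0
    stream = score_all_pairs(queries, fct, name_variant=name_variant, model=model)
    # score_all_pairs is query-major, so one query's candidates are contiguous
    for qid, group in itertools.groupby(stream, key=lambda c: c.query_id):
        ranked = rank_candidates(group, max(top_k, 1))
        best = ranked[0]
        if metric == "fuzzy":
            value = float(best.fuzzy_score)
        else:
            value = 100.0 * best.c5_probability
        decision = "mapped" if value >= threshold else "unmapped"
        n_queries += 1
        if decision == "mapped":
            n_mapped += 1
        yield MappingResult(
            query_id=qid,
            best=best,
            decision=decision,
            rule=rule,
            runners_up=tuple(ranked[1:]),
        )
    logger.info("mapped %d/%d queries under rule %s", n_mapped, n_queries, rule)
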