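"""Synthetic FCTs, diary queries, and ground-truth labels.

Emulates the structure the mapping method assumes: a multi-country FCT, a
query list where ~80% of items are perturbed copies of FCT entries
(sharing the FCT identifier code) and ~20% are "difficult" items without a
code — some with a semantically close FCT neighbor, some with no plausible
match at all.  Names exist in two variants: English and a pseudo-language
"original" produced by a deterministic token dictionary, so the
original-vs-translated comparison is testable offline.  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from fctmap.evaluation import AnnotatedMatch
from fctmap.features import FoodItem

__all__ = [
    "GeneratorConfig",
    "DEFAULT_TRANSLATION",
    "generate_fct",
    "generate_queries",
    "generate_annotations",
]

# (class name, lognormal mean of log kcal/100 g, sd of log) and its nouns
FOOD_CLASSES: dict[str, tuple[float, float, tuple[str, ...]]] = {
    "vegetable": (3.4, 0.35, ("CARROT", "ONION", "SPINACH", "CABBAGE", "TOMATO",
                              "PEPPER", "LEEK", "BROCCOLI", "COURGETTE", "BEETROOT")),
    "fruit": (3.9, 0.30, ("APPLE", "PEAR", "BANANA", "ORANGE", "PLUM",
                          "CHERRY", "GRAPE", "APRICOT")),
    "meat": (5.2, 0.30, ("BEEF", "PORK", "LAMB", "CHICKEN", "TURKEY",
                         "DUCK", "VEAL", "RABBIT")),
    "fish": (4.8, 0.30, ("HAKE", "SALMON", "TROUT", "COD", "HERRING",
                         "MACKEREL", "TUNA", "PLAICE")),
    "grain": (5.8, 0.20, ("BREAD", "RICE", "PASTA", "OAT", "BARLEY",
                          "RYE", "MAIZE", "COUSCOUS")),
    "dairy": (4.7, 0.40, ("MILK", "YOGHURT", "CHEESE", "BUTTER", "CREAM", "QUARK")),
}

QUALIFIERS = ("RAW", "BOILED", "FRIED", "GRILLED", "ROASTED", "STEAMED", "SMOKED",
              "DRIED", "FRESH", "FROZEN", "CANNED", "SALTED", "PEELED", "LEAN")

# Nouns reserved for "difficult" queries with no plausible FCT equivalent.
RARE_NOUNS = ("QUINCE", "OSTRICH", "EEL", "SEAWEED", "CHESTNUT", "GOOSE",
              "SNAIL", "VENISON", "LYCHEE", "PHEASANT", "OKRA", "TEMPEH")

_VOWEL_SHIFT = str.maketrans("AEIOU", "EIOUA")


def pseudo_translate(token: str) -> str:
    """Deterministic pseudo-language form of an English token."""
    return token.translate(_VOWEL_SHIFT) + "A"


def _default_translation() -> dict[str, str]:
    tokens = list(QUALIFIERS) + list(RARE_NOUNS)
    for _, _, nouns in FOOD_CLASSES.values():
        tokens.extend(nouns)
    return {t: pseudo_translate(t) for t in tokens}


DEFAULT_TRANSLATION = _default_translation()


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the generator; every fraction lives in [0, 1]."""

    seed: int = 0
    n_fct_items: int = 200
    n_queries: int = 100
    frac_directly_mappable: float = 0.80
    typo_rate: float = 0.3
    token_swap_rate: float = 0.2
    token_drop_rate: float = 0.1
    qualifier_add_rate: float = 0.2
    untranslated_rate: float = 0.0
    energy_noise_sd: float = 10.0  # percent
    frac_missing_energy: float = 0.0
    frac_difficult_with_neighbor: float = 0.5
    annotator_error_rate: float = 0.0
    min_qualifiers: int = 0  # raise to 2 for maximally distinctive FCT names
    max_qualifiers: int = 2
    countries: tuple = ("NL", "DK", "UK")
    translation_dictionary: dict = field(default_factory=lambda: dict(DEFAULT_TRANSLATION))

    def __post_init__(self) -> None:
        for name in ("frac_directly_mappable", "typo_rate", "token_swap_rate",
                     "token_drop_rate", "qualifier_add_rate", "untranslated_rate",
                     "frac_missing_energy", "frac_difficult_with_neighbor",
                     "annotator_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_fct_items < self.n_queries * self.frac_directly_mappable:
            raise ValueError("n_fct_items must cover the directly-mappable query fraction")
        if not 0 <= self.min_qualifiers <= self.max_qualifiers <= 2:
            raise ValueError("qualifier counts must satisfy 0 <= min <= max <= 2")


def _translate_tokens(tokens: Sequence[str], dictionary: dict) -> list[str]:
    return [dictionary.get(t, t) for t in tokens]


def _compose_space(min_qualifiers: int = 0, max_qualifiers: int = 2) -> list:
    """Deterministic enumeration of (noun, qualifiers, food class) combos."""
    combos = []
    for cls, (_, _, nouns) in FOOD_CLASSES.items():
        for noun in nouns:
            if min_qualifiers == 0:
                combos.append((noun, (), cls))
            if min_qualifiers <= 1 <= max_qualifiers:
                for q in QUALIFIERS:
                    combos.append((noun, (q,), cls))
            if max_qualifiers >= 2:
                for q1, q2 in itertools.combinations(QUALIFIERS, 2):
                    combos.append((noun, (q1, q2), cls))
    return combos


def generate_fct(config: GeneratorConfig) -> list[FoodItem]:
    """A synthetic multi-country FCT, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    space = _compose_space(config.min_qualifiers, config.max_qualifiers)
    if config.n_fct_items > len(space):
        raise ValueError(f"n_fct_items > composable name space ({len(space)})")
    picks = rng.permutation(len(space))[: config.n_fct_items]
    items = []
    for i, k in enumerate(sorted(picks)):
        noun, quals, cls = space[k]
        meanlog, sdlog, _ = FOOD_CLASSES[cls]
        energy = float(np.exp(rng.normal(meanlog, sdlog)))
        tokens = [noun, *quals]
        items.append(
            FoodItem(
                item_id=f"F{i:05d}",
                source="fct",
                country=config.countries[i % len(config.countries)],
                name_original=" ".join(_translate_tokens(tokens, config.translation_dictionary)),
                name_english=" ".join(tokens),
                energy=round(energy, 1),
                portion_g=100.0,
                food_group=cls,
            )
        )
    return items


def _perturb_tokens(tokens: list[str], config: GeneratorConfig, rng: np.random.Generator,
                    qualifier_pool: Sequence[str]) -> list[str]:
    tokens = list(tokens)
    if rng.random() < config.qualifier_add_rate:
        tokens.append(str(rng.choice(qualifier_pool)))
    if len(tokens) >= 2 and rng.random() < config.token_swap_rate:
        i = int(rng.integers(0, len(tokens) - 1))
        tokens[i], tokens[i + 1] = tokens[i + 1], tokens[i]
    if len(tokens) >= 2 and rng.random() < config.token_drop_rate:
        i = int(rng.integers(0, len(tokens)))
        del tokens[i]
    if rng.random() < config.typo_rate:
        i = int(rng.integers(0, len(tokens)))
        tokens[i] = _typo(tokens[i], rng)
    return [t for t in tokens if t]


def _typo(token: str, rng: np.random.Generator) -> str:
    """One random single-character edit (substitution, insertion, deletion)."""
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    op = rng.choice(["sub", "ins", "del"]) if len(token) > 1 else rng.choice(["sub", "ins"])
    pos = int(rng.integers(0, len(token)))
    c = alphabet[int(rng.integers(0, len(alphabet)))]
    if op == "sub":
        return token[:pos] + c + token[pos + 1 :]
    if op == "ins":
        return token[:pos] + c + token[pos:]
    return token[:pos] + token[pos + 1 :]


def _energy_noise(energy: Optional[float], sd_pct: float, rng: np.random.Generator) -> Optional[float]:
    if energy is None:
        return None
    return round(float(energy * np.exp(rng.normal(0.0, sd_pct / 100.0))), 1)


def generate_queries(
    fct: Sequence[FoodItem], config: GeneratorConfig
) -> tuple[list[FoodItem], pd.DataFrame]:
    """Diary queries plus the ground-truth table.

    Exactly ``round(n_queries * frac_directly_mappable)`` queries are
    perturbed copies of distinct FCT items carrying the same identifier
    code.  The rest are "difficult": a configured fraction has a close FCT
    neighbor (same noun, reshuffled qualifiers, near-identical energy) and
    is plausibly mappable; the others are built from nouns absent from the
    FCT and have no plausible match.  The truth table has one row per
    query: query_id, item_class, true_candidate_id (empty if none), and
    the plausibility flag.
    """
    rng = np.random.default_rng(config.seed + 1)
    dictionary = config.translation_dictionary
    n_direct = int(round(config.n_queries * config.frac_directly_mappable))
    n_difficult = config.n_queries - n_direct
    n_neighbor = int(round(n_difficult * config.frac_difficult_with_neighbor))

    queries: list[FoodItem] = []
    truth_rows: list[dict] = []

    def perturbed_names(item: FoodItem) -> tuple[str, str]:
        eng = _perturb_tokens(item.name_english.split(), config, rng, QUALIFIERS)
        orig_pool = _translate_tokens(QUALIFIERS, dictionary)
        orig = _perturb_tokens(item.name_original.split(), config, rng, orig_pool)
        if eng and config.untranslated_rate > 0:
            for i, tok in enumerate(eng):
                if rng.random() < config.untranslated_rate:
                    eng[i] = dictionary.get(tok, tok)
        return " ".join(orig) or item.name_original, " ".join(eng) or item.name_english

    sources = rng.choice(len(fct), size=n_direct, replace=False)
    for idx in sorted(int(i) for i in sources):
        src = fct[idx]
        name_orig, name_eng = perturbed_names(src)
        energy = _energy_noise(src.energy, config.energy_noise_sd, rng)
        if rng.random() < config.frac_missing_energy:
            energy = None
        queries.append(
            FoodItem(
                item_id=src.item_id,
                source="diary",
                country=src.country,
                name_original=name_orig,
                name_english=name_eng,
                energy=energy,
                portion_g=100.0,
                food_group=src.food_group,
            )
        )
        truth_rows.append(
            {"query_id": src.item_id, "item_class": "directly_mappable",
             "true_candidate_id": src.item_id, "plausible": True}
        )

    # Difficult items with a close neighbor: same noun, different qualifiers,
    # near-identical energy (the signal the classifier can exploit).
    neighbor_sources = rng.choice(len(fct), size=n_neighbor, replace=False)
    for j, idx in enumerate(int(i) for i in neighbor_sources):
        src = fct[idx]
        src_tokens = src.name_english.split()
        noun = src_tokens[0]
        kept = [src_tokens[1]] if len(src_tokens) > 1 else []
        new_q = str(rng.choice([q for q in QUALIFIERS if q not in src_tokens]))
        eng_tokens = [noun, *kept, new_q]
        qid = f"QD{j:05d}"
        energy = _energy_noise(src.energy, min(config.energy_noise_sd, 2.0), rng)
        queries.append(
            FoodItem(
                item_id=qid,
                source="diary",
                country=src.country,
                name_original=" ".join(_translate_tokens(eng_tokens, dictionary)),
                name_english=" ".join(eng_tokens),
                energy=energy,
                portion_g=100.0,
                food_group=src.food_group,
            )
        )
        truth_rows.append(
            {"query_id": qid, "item_class": "other",
             "true_candidate_id": src.item_id, "plausible": True}
        )

    # Difficult items with no plausible equivalent: rare nouns, random energy.
    for j in range(n_difficult - n_neighbor):
        noun = RARE_NOUNS[j % len(RARE_NOUNS)]
        quals = list(rng.choice(QUALIFIERS, size=int(rng.integers(0, 2)), replace=False))
        eng_tokens = [noun, *quals]
        qid = f"QX{j:05d}"
        energy = round(float(np.exp(rng.normal(4.5, 0.8))), 1)
        queries.append(
            FoodItem(
                item_id=qid,
                source="diary",
                country=config.countries[j % len(config.countries)],
                name_original=" ".join(_translate_tokens(eng_tokens, dictionary)),
                name_english=" ".join(eng_tokens),
                energy=energy,
                portion_g=100.0,
            )
        )
        truth_rows.append(
            {"query_id": qid, "item_class": "other", "true_candidate_id": "", "plausible": False}
        )

    order = rng.permutation(len(queries))
    queries = [queries[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return queries, truth


def generate_annotations(
    candidates: Sequence,
    truth: pd.DataFrame,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[AnnotatedMatch]:
    """Labels for candidate pairs, from ground truth, with optional noise.

    A pair is truly plausible iff its candidate is the query's recorded
    true match.  ``error_rate`` flips each label independently (simulated
    annotator mistakes).  Unknown query ids are an error.
    """
    rng = np.random.default_rng(seed)
    by_query = truth.set_index("query_id")
    annotated = []
    for cand in candidates:
        if cand.query_id not in by_query.index:
            raise ValueError(f"query id {cand.query_id!r} not present in the truth table")
        row = by_query.loc[cand.query_id]
        plausible = bool(row["plausible"]) and cand.candidate_id == row["true_candidate_id"]
        if error_rate > 0 and rng.random() < error_rate:
            plausible = not plausible
        ediff = cand.ediff.value if cand.ediff.defined else None
        annotated.append(
            AnnotatedMatch(
                query_id=cand.query_id,
                candidate_id=cand.candidate_id,
                fuzzy_score=cand.fuzzy_score,
                ediff=ediff,
                c5_probability=cand.c5_probability,
                label="plausible" if plausible else "non_plausible",
                item_class=str(row["item_class"]),
            )
        )
    return annotated
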