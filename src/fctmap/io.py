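"""Delimited-table readers/writers and model/config (de)serialization.

TSV is the default dialect; comma and semicolon are selectable (European
FCT exports commonly use semicolons).  Encoding defaults to UTF-8 with an
explicit latin-1 option for legacy original-language names.  Energy can be
declared in kJ and is then converted to kcal at read time (factor 4.184)
— never silently inferred.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from fctmap.classifier import BoostedTreeModel
from fctmap.evaluation import AnnotatedMatch, PRCurve
from fctmap.features import KJ_PER_KCAL, FoodItem, InvalidRecordError
from fctmap.pipeline import MappingResult
from fctmap.synthetic import GeneratorConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_items",
    "write_items",
    "read_annotated",
    "write_annotated",
    "write_results",
    "write_pr_curve",
    "read_model",
    "write_model",
    "load_generator_config",
]

REQUIRED_COLUMNS = ("item_id", "name_original", "energy_kcal_100g")
OPTIONAL_COLUMNS = ("name_english", "portion_g", "country", "food_group")


class SchemaError(ValueError):
    """The table does not conform to the declared schema."""


def _read_table(path, delimiter: str, encoding: str) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=delimiter,
        encoding=encoding,
        dtype=str,
        keep_default_na=False,
    )


def _parse_float(value: str) -> Optional[float]:
    if value is None or str(value).strip() == "":
        return None
    return float(value)


def read_items(
    path,
    delimiter: str = "\t",
    encoding: str = "utf-8",
    energy_unit: str = "kcal",
    source: str = "fct",
) -> list[FoodItem]:
    """Read food items from a delimited table.

    Required columns: item_id, name_original, energy_kcal_100g (the energy
    cell may be empty: that is a missing value, never zero).  Rows failing
    validation are skipped with a logged warning naming the row number;
    duplicate item_ids are a hard error.
    """
    if energy_unit not in ("kcal", "kJ"):
        raise SchemaError(f"energy_unit must be 'kcal' or 'kJ', got {energy_unit!r}")
    df = _read_table(path, delimiter, encoding)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    ids = df["item_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1 and i != ""})
    if dupes:
        raise SchemaError(f"{path}: duplicate item_id values: {dupes}")
    items: list[FoodItem] = []
    n_skipped = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            energy = _parse_float(rec["energy_kcal_100g"])
            if energy is not None and energy_unit == "kJ":
                energy /= KJ_PER_KCAL
            portion = _parse_float(rec.get("portion_g", "")) or 100.0
            item = FoodItem(
                item_id=rec["item_id"],
                source=source,
                country=rec.get("country", "") or "",
                name_original=rec["name_original"] or None,
                name_english=rec.get("name_english", "") or None,
                energy=energy,
                portion_g=portion,
                food_group=rec.get("food_group", "") or None,
            )
        except (InvalidRecordError, ValueError) as exc:
            n_skipped += 1
            logger.warning("%s row %d: %s; skipped", path, row_no, exc)
            continue
        if energy is None:
            logger.warning("%s row %d (item %s): missing energy", path, row_no, rec["item_id"])
        items.append(item)
    logger.info("%s: read %d items (%d rows skipped)", path, len(items), n_skipped)
    return items


def write_items(items: Sequence[FoodItem], path, delimiter: str = "\t") -> None:
    rows = [
        {
            "item_id": it.item_id,
            "name_original": it.name_original or "",
            "name_english": it.name_english or "",
            "energy_kcal_100g": "" if it.energy is None else f"{it.energy:g}",
            "portion_g": f"{it.portion_g:g}",
            "country": it.country,
            "food_group": it.food_group or "",
        }
        for it in items
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def _fmt_ediff(value: float) -> str:
    return "" if value is None or (isinstance(value, float) and math.isnan(value)) else f"{value:.4f}"


def write_results(results: Iterable[MappingResult], path, delimiter: str = "\t") -> None:
    """Mapping results as a delimited table, sorted by query_id.

    Scores are integers, probabilities carry 4 decimals; round-tripping
    the file reproduces the values exactly.
    """
    rows = []
    for r in results:
        best = r.best
        rows.append(
            {
                "query_id": r.query_id,
                "candidate_id": best.candidate_id if best else "",
                "fuzzy_score": str(best.fuzzy_score) if best else "",
                "ediff": _fmt_ediff(best.ediff_value) if best else "",
                "c5_probability": (
                    f"{best.c5_probability:.4f}"
                    if best is not None and best.c5_probability is not None
                    else ""
                ),
                "decision": r.decision,
                "rule": r.rule,
            }
        )
    rows.sort(key=lambda r: r["query_id"])
    pd.DataFrame(
        rows,
        columns=["query_id", "candidate_id", "fuzzy_score", "ediff", "c5_probability",
                 "decision", "rule"],
    ).to_csv(path, sep=delimiter, index=False, encoding="utf-8")


ANNOTATED_COLUMNS = ("query_id", "candidate_id", "fuzzy_score", "ediff",
                     "c5_probability", "label", "item_class")


def write_annotated(annotated: Sequence[AnnotatedMatch], path, delimiter: str = "\t") -> None:
    rows = [
        {
            "query_id": a.query_id,
            "candidate_id": a.candidate_id,
            "fuzzy_score": f"{a.fuzzy_score:g}",
            "ediff": "" if a.ediff is None else f"{a.ediff:.4f}",
            "c5_probability": "" if a.c5_probability is None else f"{a.c5_probability:.4f}",
            "label": a.label,
            "item_class": a.item_class,
        }
        for a in annotated
    ]
    pd.DataFrame(rows, columns=list(ANNOTATED_COLUMNS)).to_csv(
        path, sep=delimiter, index=False, encoding="utf-8"
    )


def read_annotated(path, delimiter: str = "\t", encoding: str = "utf-8") -> list[AnnotatedMatch]:
    df = _read_table(path, delimiter, encoding)
    for col in ("query_id", "candidate_id", "fuzzy_score", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        out.append(
            AnnotatedMatch(
                query_id=rec["query_id"],
                candidate_id=rec["candidate_id"],
                fuzzy_score=float(rec["fuzzy_score"]),
                ediff=_parse_float(rec.get("ediff", "")),
                c5_probability=_parse_float(rec.get("c5_probability", "")),
                label=rec["label"],
                item_class=rec.get("item_class", "") or "any",
            )
        )
    return out


def write_pr_curve(curve: PRCurve, path, delimiter: str = "\t") -> None:
    rows = [
        {
            "threshold": f"{p.threshold:g}",
            "precision": "" if p.precision is None else f"{p.precision:.4f}",
            "recall": "" if p.recall is None else f"{p.recall:.4f}",
            "tp": p.counts.tp,
            "fp": p.counts.fp,
            "fn": p.counts.fn,
            "tn": p.counts.tn,
            "metric": curve.metric,
            "item_class": curve.item_class,
        }
        for p in curve.points
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def read_model(path) -> BoostedTreeModel:
    return BoostedTreeModel.from_json(Path(path).read_text(encoding="utf-8"))


def write_model(model: BoostedTreeModel, path) -> None:
    Path(path).write_text(model.to_json(), encoding="utf-8")


def load_generator_config(path) -> GeneratorConfig:
    """Generator configuration from a YAML mapping of field names."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a YAML mapping")
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    if "countries" in doc:
        doc["countries"] = tuple(doc["countries"])
    return GeneratorConfig(**doc)
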