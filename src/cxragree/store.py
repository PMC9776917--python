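"""Ingestion of raw annotation records and case-level binary matrices.

The statistics in this package operate on *case-level presence*: for one
case, one rater and one annotation round, a reporting category either was or
was not used.  A rater may have drawn several bounding boxes with the same
label across the frontal and lateral projections of one case; all of that
collapses to a single 0/1 cell.  Bounding boxes are carried through ingestion
untouched but play no role in any statistic.

Absence of a record is a negative, not missing data: the case/rater universe
is declared explicitly (or inferred from the data) so that raters who made no
marks on a case contribute zeros.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .ontology import Category, LabelScheme

__all__ = [
    "AnnotationRecord",
    "AnnotationMatrix",
    "Universe",
    "read_annotations",
    "load_universe",
    "collapse",
    "frequency_table",
]

log = logging.getLogger(__name__)

PROJECTIONS = ("frontal", "lateral", "unspecified")
CSV_HEADER = (
    "case_id,rater_id,round,projection,label,bbox_x,bbox_y,bbox_w,bbox_h"
)


@dataclass(frozen=True)
class AnnotationRecord:
    """One label applied by one rater to one projection of one case."""

    case_id: str
    rater_id: str
    round: int
    projection: str
    label: str
    bbox: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.round not in (1, 2):
            raise ValueError(f"round must be 1 or 2, got {self.round}")
        if self.projection not in PROJECTIONS:
            raise ValueError(f"unknown projection {self.projection!r}")
        if self.bbox is not None:
            _, _, w, h = self.bbox
            if w <= 0 or h <= 0:
                raise ValueError(f"bbox must have positive size, got {self.bbox}")


@dataclass
class Universe:
    """Declared case/rater universe with rater experience levels."""

    case_ids: list[str]
    rater_ids: list[str]
    experience: dict[str, str] = field(default_factory=dict)

    def raters_by_experience(self, level: str) -> list[str]:
        return [r for r in self.rater_ids if self.experience.get(r) == level]


def load_universe(path: str | Path) -> Universe:
    """Read a universe config (YAML: case_ids, raters with experience)."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    raters = doc.get("raters", doc.get("rater_ids", []))
    rater_ids, experience = [], {}
    for entry in raters:
        if isinstance(entry, str):
            rater_ids.append(entry)
        else:
            rater_ids.append(entry["id"])
            if "experience" in entry:
                experience[entry["id"]] = entry["experience"]
    case_ids = [str(c) for c in doc["case_ids"]]
    return Universe(case_ids=case_ids, rater_ids=rater_ids, experience=experience)


def read_annotations(path: str | Path, scheme: LabelScheme) -> list[AnnotationRecord]:
    """Read and validate an annotations CSV.

    Expected header: ``case_id,rater_id,round,projection,label`` with
    optional ``bbox_x,bbox_y,bbox_w,bbox_h`` columns (empty cells allowed).
    Labels must be exact scheme identifiers; violations report the offending
    row number.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"case_id", "rater_id", "round", "projection", "label"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            label = row["label"]
            if label not in scheme.labels:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            try:
                rnd = int(row["round"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: bad round value {row['round']!r}"
                ) from exc
            bbox = None
            if row.get("bbox_x") not in (None, ""):
                bbox = tuple(float(row[f"bbox_{k}"]) for k in ("x", "y", "w", "h"))
            try:
                rec = AnnotationRecord(
                    case_id=row["case_id"],
                    rater_id=row["rater_id"],
                    round=rnd,
                    projection=row["projection"] or "unspecified",
                    label=label,
                    bbox=bbox,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


@dataclass
class AnnotationMatrix:
    """Binary case x rater x category x round indicator array.

    ``values[i, j, k, r]`` is 1 iff rater ``raters[j]`` used any member
    label of ``categories[k]`` on case ``cases[i]`` in round ``rounds[r]``.
    """

    cases: list[str]
    raters: list[str]
    categories: list[Category]
    rounds: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = (
            len(self.cases),
            len(self.raters),
            len(self.categories),
            len(self.rounds),
        )
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != {expected}"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix values must be binary")
        if len(self.cases) < 1 or len(self.raters) < 1:
            raise ValueError("need at least one case and one rater")

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    def category_ids(self) -> list[str]:
        return [c.id for c in self.categories]

    def _cat_index(self, category: str) -> int:
        for k, cat in enumerate(self.categories):
            if cat.id == category:
                return k
        raise KeyError(f"unknown category {category!r}")

    def _round_index(self, rnd: int) -> int:
        try:
            return self.rounds.index(rnd)
        except ValueError:
            raise KeyError(f"round {rnd} not present (have {self.rounds})")

    def column(self, category: str, rnd: int) -> np.ndarray:
        """Case x rater indicator block for one category and round."""
        return self.values[:, :, self._cat_index(category), self._round_index(rnd)]

    def rater_column(self, rater: str, category: str, rnd: int) -> np.ndarray:
        """One rater's indicator vector over cases."""
        try:
            j = self.raters.index(rater)
        except ValueError:
            raise KeyError(f"unknown rater {rater!r}")
        return self.column(category, rnd)[:, j]


def collapse(
    records: Iterable[AnnotationRecord],
    scheme: LabelScheme,
    *,
    cases: Sequence[str] | None = None,
    raters: Sequence[str] | None = None,
    rounds: Sequence[int] | None = None,
) -> AnnotationMatrix:
    """Collapse raw records to the case-level binary matrix.

    A category cell is 1 iff at least one record with any member label
    exists, regardless of projection or number of bounding boxes.  When the
    universe (``cases``/``raters``/``rounds``) is not given it is inferred
    from the records, sorted; declared universes should be preferred so that
    silent raters contribute negatives.
    """
    records = list(records)
    if cases is None:
        cases = sorted({r.case_id for r in records})
    if raters is None:
        raters = sorted({r.rater_id for r in records})
    if rounds is None:
        rounds = sorted({r.round for r in records}) or [1]
    cases, raters, rounds = list(cases), list(raters), list(rounds)

    categories = scheme.category_columns()
    label_to_cats: dict[str, list[int]] = {lab: [] for lab in scheme.labels}
    for k, cat in enumerate(categories):
        for member in cat.members:
            label_to_cats[member].append(k)

    ci = {c: i for i, c in enumerate(cases)}
    rj = {r: j for j, r in enumerate(raters)}
    ri = {r: k for k, r in enumerate(rounds)}

    values = np.zeros((len(cases), len(raters), len(categories), len(rounds)), dtype=np.uint8)
    seen: set[tuple] = set()
    for rec in records:
        key = (rec.case_id, rec.rater_id, rec.round, rec.projection, rec.label, rec.bbox)
        if key in seen:
            log.debug("duplicate record dropped: %s", key)
            continue
        seen.add(key)
        try:
            i, j, k = ci[rec.case_id], rj[rec.rater_id], ri[rec.round]
        except KeyError as exc:
            raise ValueError(f"record outside declared universe: {rec}") from exc
        for c in label_to_cats[rec.label]:
            values[i, j, c, k] = 1
    return AnnotationMatrix(cases, raters, categories, rounds, values)


def frequency_table(matrix: AnnotationMatrix, rnd: int) -> pd.DataFrame:
    """Per-rater positive case counts per raw label (one annotation round).

    Mirrors the study's frequency table: for each rater, the number of cases
    on which each raw label was used at least once.
    """
    r = matrix._round_index(rnd)
    rows = {}
    for k, cat in enumerate(matrix.categories):
        if cat.kind != "raw":
            continue
        rows[cat.id] = matrix.values[:, :, k, r].sum(axis=0)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=matrix.raters, dtype=int
    )
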