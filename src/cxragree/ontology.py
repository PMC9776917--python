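"""Hierarchical diagnostic labeling schemes.

A labeling scheme is a forest of diagnostic labels: a broad finding such as
``Decreased Translucency`` is subdivided into increasingly specific child
labels (``Infiltrate``, then ``Infection``, ``Abscess``, ...).  Besides the
raw labels, two kinds of derived reporting categories exist:

* a *congregate* category ("<label> incl. sub-categories") for every non-leaf
  label, positive whenever the label itself or any descendant is positive;
* a *composite* category, an explicitly declared merged set of labels
  (e.g. costophrenic angle blunting merged with pleural effusion), positive
  whenever any member is positive.

Both use union semantics: a category is positive for a case/rater iff at
least one member label is positive.

Two schemes ship with the package: :func:`fig1_lung_scheme`, the 20-label
lung-tissue scheme used throughout, and :func:`fig6_lung_scheme`, a
provisional synthetic revision with descriptive leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Category",
    "LabelScheme",
    "SchemeError",
    "load_scheme",
    "fig1_lung_scheme",
    "fig6_lung_scheme",
]

CONGREGATE_SUFFIX = " incl. sub-categories"


class SchemeError(ValueError):
    """Raised when a scheme definition violates its invariants."""


@dataclass(frozen=True)
class Category:
    """One reportable column of the analysis.

    Attributes
    ----------
    id : str
        Category name as it appears in report tables.
    kind : str
        ``"raw"`` (a scheme label), ``"congregate"`` (a label together with
        all its descendants) or ``"composite"`` (a declared merged set).
    members : frozenset[str]
        Raw labels whose union defines positivity of the category.
    """

    id: str
    kind: str
    members: frozenset[str]


@dataclass
class LabelScheme:
    """A rooted forest of diagnostic labels plus composite categories.

    Parameters
    ----------
    labels : list[str]
        Label identifiers in declaration order (pre-order of the forest).
    names : Mapping[str, str]
        Display name per label.
    parent : Mapping[str, str]
        Child -> parent mapping; roots are absent.
    composites : Mapping[str, tuple[str, ...]]
        Composite category id -> member labels, in declaration order.
    """

    labels: list[str]
    names: dict[str, str] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)
    name: str = "scheme"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        seen = set()
        for lab in self.labels:
            if lab in seen:
                raise SchemeError(f"duplicate label: {lab!r}")
            seen.add(lab)
        for child, par in self.parent.items():
            if child not in seen:
                raise SchemeError(f"parent declared for unknown label {child!r}")
            if par not in seen:
                raise SchemeError(f"unknown parent {par!r} of {child!r}")
        # acyclicity: walk each label to its root, bounded by forest size
        for lab in self.labels:
            hops, cur = 0, lab
            while cur in self.parent:
                cur = self.parent[cur]
                hops += 1
                if hops > len(self.labels):
                    raise SchemeError(f"cycle in parent chain at {lab!r}")
        for comp, members in self.composites.items():
            if comp in seen:
                raise SchemeError(f"composite id {comp!r} collides with a label")
            unknown = [m for m in members if m not in seen]
            if unknown:
                raise SchemeError(f"composite {comp!r} has unknown members {unknown}")

    # -- structure queries ----------------------------------------------

    def children(self, label: str) -> list[str]:
        """Direct children of *label*, in declaration order."""
        self._check(label)
        return [c for c in self.labels if self.parent.get(c) == label]

    def descendants(self, label: str) -> set[str]:
        """Transitive closure of children of *label* (the label excluded)."""
        self._check(label)
        out: set[str] = set()
        stack = self.children(label)
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(self.children(c))
        return out

    def ancestors(self, label: str) -> list[str]:
        """Strict ancestors of *label*, nearest first."""
        self._check(label)
        out, cur = [], label
        while cur in self.parent:
            cur = self.parent[cur]
            out.append(cur)
        return out

    def is_leaf(self, label: str) -> bool:
        self._check(label)
        return not any(self.parent.get(c) == label for c in self.labels)

    def leaves(self) -> list[str]:
        return [lab for lab in self.labels if self.is_leaf(lab)]

    def roots(self) -> list[str]:
        return [lab for lab in self.labels if lab not in self.parent]

    def _check(self, label: str) -> None:
        if label not in self.names and label not in self.labels:
            raise KeyError(f"unknown label {label!r}")

    # -- reportable categories ------------------------------------------

    def category_columns(self) -> list[Category]:
        """All reportable categories, in report-table order.

        Labels are visited in declaration (pre-order) sequence.  A non-leaf
        label is preceded by its congregate category; a composite is emitted
        immediately after the last of its members has been visited.
        """
        cols: list[Category] = []
        visited: set[str] = set()
        pending = dict(self.composites)
        for lab in self.labels:
            desc = self.descendants(lab)
            if desc:
                cols.append(
                    Category(
                        id=lab + CONGREGATE_SUFFIX,
                        kind="congregate",
                        members=frozenset({lab} | desc),
                    )
                )
            cols.append(Category(id=lab, kind="raw", members=frozenset({lab})))
            visited.add(lab)
            for comp in list(pending):
                if set(pending[comp]) <= visited:
                    cols.append(
                        Category(id=comp, kind="composite", members=frozenset(pending[comp]))
                    )
                    del pending[comp]
        return cols

    def category(self, category_id: str) -> Category:
        """Look up one reportable category by its id."""
        for cat in self.category_columns():
            if cat.id == category_id:
                return cat
        raise KeyError(f"unknown category {category_id!r}")


def _scheme_from_dict(doc: Mapping, name: str) -> LabelScheme:
    try:
        raw_labels = doc["labels"]
    except KeyError as exc:
        raise SchemeError("scheme document lacks a 'labels' array") from exc
    labels, names, parent = [], {}, {}
    for entry in raw_labels:
        lid = entry["id"]
        labels.append(lid)
        names[lid] = entry.get("name", lid)
        if "parent" in entry and entry["parent"] is not None:
            parent[lid] = entry["parent"]
    composites = {
        c["id"]: tuple(c["members"]) for c in doc.get("composites", [])
    }
    return LabelScheme(
        labels=labels,
        names=names,
        parent=parent,
        composites=composites,
        name=doc.get("name", name),
    )


def load_scheme(path: str | Path) -> LabelScheme:
    """Load and validate a labeling scheme from its JSON file.

    The dialect is ``{"labels": [{"id", "name", "parent"?}, ...],
    "composites": [{"id", "members"}, ...]}``.

    Raises
    ------
    SchemeError
        On parse failure or any invariant violation (cycle, unknown parent,
        duplicate label, unknown composite member).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemeError(f"cannot parse scheme file {path}: {exc}") from exc
    return _scheme_from_dict(doc, name=path.stem)


def _packaged(filename: str) -> LabelScheme:
    text = resources.files("cxragree.data").joinpath(filename).read_text("utf-8")
    return _scheme_from_dict(json.loads(text), name=filename.rsplit(".", 1)[0])


def fig1_lung_scheme() -> LabelScheme:
    """The packaged 20-label lung-tissue labeling scheme."""
    return _packaged("fig1_lung.json")


def fig6_lung_scheme() -> LabelScheme:
    """Provisional revised lung-tissue scheme (synthetic reconstruction).

    The published revision replaces the interpretive leaves under
    ``Infiltrate`` with descriptive appearance labels; its exact label set is
    not recoverable from text, so this fixture is a clearly marked
    best-effort stand-in suitable for exercising the pipeline only.
    """
    return _packaged("fig6_lung_synthetic.json")
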