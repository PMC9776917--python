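"""Rebuild case-level matrices from per-rater marginal counts.

Raw case-level annotations are rarely deposited with reliability studies,
but a frequency table (per-rater positive counts per label) often is.  For
labels whose reported proportion of positive agreement is 0, no case was
positively labeled by two or more raters ("zero co-positivity"), and that
constraint plus the marginals pins the annotation configuration down up to a
permutation of cases — which every statistic here is invariant to.  Those
labels' kappa and negative-agreement values are therefore exactly
recomputable from the frequency table alone.

Only the zero-co-positivity constraint class is supported: general
marginal-plus-PPA inversion is underdetermined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ontology import Category
from .store import AnnotationMatrix

__all__ = ["MarginalSpec", "feasible", "reconstruct"]


@dataclass(frozen=True)
class MarginalSpec:
    """Per-rater positive counts for one label over N cases.

    With ``no_copositivity`` set, no case may receive the label from more
    than one rater, which requires sum(counts) <= n_cases.
    """

    label: str
    counts: tuple[int, ...]
    n_cases: int
    no_copositivity: bool = True

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for c in self.counts:
            if not 0 <= c <= self.n_cases:
                raise ValueError(f"count {c} outside [0, {self.n_cases}]")


def feasible(spec: MarginalSpec) -> tuple[bool, str]:
    """Whether any binary matrix satisfies the marginal spec, with reason."""
    total = sum(spec.counts)
    if spec.no_copositivity and total > spec.n_cases:
        return False, (
            f"sum of counts ({total}) exceeds n_cases ({spec.n_cases}) "
            "under zero co-positivity"
        )
    return True, "feasible"


def reconstruct(
    spec: MarginalSpec,
    rater_ids: Sequence[str] | None = None,
) -> AnnotationMatrix:
    """Build the single-label, single-round matrix realizing the marginals.

    Positives are assigned deterministically to the lowest-index free cases
    in the given rater order; since all downstream statistics are invariant
    to case permutation, this choice cannot affect any result.  Under
    ``no_copositivity`` no case ends up with two or more positive raters.
    """
    ok, reason = feasible(spec)
    if not ok:
        raise ValueError(reason)
    n_raters = len(spec.counts)
    if rater_ids is None:
        rater_ids = [f"rater_{j + 1}" for j in range(n_raters)]
    elif len(rater_ids) != n_raters:
        raise ValueError("rater_ids length must match counts")
    cases = [f"case_{i + 1:03d}" for i in range(spec.n_cases)]

    col = np.zeros((spec.n_cases, n_raters), dtype=np.uint8)
    if spec.no_copositivity:
        cursor = 0
        for j, cnt in enumerate(spec.counts):
            col[cursor : cursor + cnt, j] = 1
            cursor += cnt
    else:
        for j, cnt in enumerate(spec.counts):
            col[:cnt, j] = 1

    values = col[:, :, np.newaxis, np.newaxis]
    category = Category(id=spec.label, kind="raw", members=frozenset({spec.label}))
    return AnnotationMatrix(
        cases=cases,
        raters=list(rater_ids),
        categories=[category],
        rounds=[1],
        values=values,
    )
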