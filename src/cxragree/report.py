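"""Study-level analysis tables.

Three views mirror the standard reporting layout of a two-round,
multi-reader annotation study:

* **all-reader**: per reporting category, free-marginal kappa (with
  bootstrap 95% CI), multi-rater PPA/PNA and the Landis–Koch band, over the
  first annotation round;
* **pair**: PABAK, PPA, PNA for selected two-rater pairs (typically the two
  readers sharing an experience level), first round;
* **intra-rater**: per rater and category, PABAK and PPA/PNA between the
  two rounds, plus a pooled (mean over raters) row per category.

Undefined statistics (zero denominators) are NaN in the returned frames and
render as blanks in the written tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .store import AnnotationMatrix

__all__ = [
    "run_all_reader_analysis",
    "run_pair_analysis",
    "run_intra_analysis",
    "write_table",
]

log = logging.getLogger(__name__)


def run_all_reader_analysis(
    matrix: AnnotationMatrix,
    *,
    rnd: int = 1,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """All-reader agreement per category: kappa, 95% CI, PPA, PNA, band."""
    if matrix.n_raters < 2:
        raise ValueError("all-reader analysis needs at least two raters")
    rows = []
    rng = np.random.default_rng(seed)
    for cat in matrix.categories:
        col = matrix.column(cat.id, rnd)
        res = stats.randolph_kappa(col)
        ci_low, ci_high = stats.bootstrap_ci(
            col, lambda c: stats.randolph_kappa(c).value, n_boot=n_boot, seed=rng
        )
        ppa, pna = stats.specific_agreement_multi(col)
        if np.isnan(ppa) or np.isnan(pna):
            log.info("undefined specific agreement for category %r", cat.id)
        rows.append(
            {
                "category": cat.id,
                "kappa": res.value,
                "ci_low": min(ci_low, res.value),
                "ci_high": max(ci_high, res.value),
                "ppa": ppa,
                "pna": pna,
                "interpretation": res.interpretation,
            }
        )
    log.info("all-reader analysis: %d categories, %d raters, %d cases",
             len(rows), matrix.n_raters, matrix.n_cases)
    return pd.DataFrame(rows).set_index("category")


def run_pair_analysis(
    matrix: AnnotationMatrix,
    pairs: list[tuple[str, str]],
    *,
    rnd: int = 1,
) -> pd.DataFrame:
    """Two-rater agreement (PABAK, PPA, PNA) per pair and category."""
    for a, b in pairs:
        for r in (a, b):
            if r not in matrix.raters:
                raise KeyError(f"unknown rater {r!r} in pair ({a!r}, {b!r})")
    rows = []
    for a, b in pairs:
        for cat in matrix.categories:
            col_a = matrix.rater_column(a, cat.id, rnd)
            col_b = matrix.rater_column(b, cat.id, rnd)
            res = stats.pabak(col_a, col_b)
            ppa, pna = stats.specific_agreement_pair(col_a, col_b)
            rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "category": cat.id,
                    "pabak": res.value,
                    "ppa": ppa,
                    "pna": pna,
                    "interpretation": res.interpretation,
                }
            )
    return pd.DataFrame(rows)


def run_intra_analysis(matrix: AnnotationMatrix) -> pd.DataFrame:
    """Round-1 vs round-2 agreement per rater and category, plus pooled mean.

    The pooled rows average each statistic over raters for whom it is
    defined; category order follows the scheme's reporting order.
    """
    rows = []
    for cat in matrix.categories:
        per_rater = []
        for rater in matrix.raters:
            res = stats.intra_rater(matrix, rater, cat.id)
            rows.append(
                {
                    "rater": rater,
                    "category": cat.id,
                    "pabak": res["pabak"].value,
                    "ppa": res["ppa"],
                    "pna": res["pna"],
                }
            )
            per_rater.append(rows[-1])
        rows.append(
            {
                "rater": "pooled",
                "category": cat.id,
                "pabak": float(np.nanmean([r["pabak"] for r in per_rater])),
                "ppa": float(np.nanmean([r["ppa"] for r in per_rater]))
                if not all(np.isnan(r["ppa"]) for r in per_rater)
                else float("nan"),
                "pna": float(np.nanmean([r["pna"] for r in per_rater]))
                if not all(np.isnan(r["pna"]) for r in per_rater)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _fmt(value, precision: int) -> str:
    if isinstance(value, float):
        if np.isnan(value):
            return ""
        return f"{stats.round_half_up(value, precision):.{precision}f}"
    return str(value)


def write_table(df: pd.DataFrame, path: str | Path, precision: int = 2) -> None:
    """Write one analysis table as CSV and aligned markdown side by side.

    Values are rounded half-up to ``precision`` decimals; undefined values
    become empty cells.  ``path`` is the CSV path; the markdown twin takes
    the same stem with ``.md``.
    """
    path = Path(path)
    out = df.reset_index() if df.index.name else df.copy()
    formatted = out.map(lambda v: _fmt(v, precision))
    formatted.to_csv(path, index=False)

    widths = [
        max(len(str(col)), *(len(v) for v in formatted[col]), 3)
        for col in formatted.columns
    ]
    lines = [
        "| " + " | ".join(str(c).ljust(w) for c, w in zip(formatted.columns, widths)) + " |",
        "|" + "|".join("-" * (w + 2) for w in widths) + "|",
    ]
    for _, row in formatted.iterrows():
        lines.append(
            "| " + " | ".join(str(v).ljust(w) for v, w in zip(row, widths)) + " |"
        )
    path.with_suffix(".md").write_text("\n".join(lines) + "\n", encoding="utf-8")
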