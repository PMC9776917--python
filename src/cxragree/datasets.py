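"""Packaged reference tables from the annotation study.

``table1_counts`` is the round-1 frequency table: for each of the 20 raw
lung-tissue labels, the number of cases (out of 100) each of the six
radiologists annotated with that label.  ``table2_agreement`` is the
published all-reader agreement table (free-marginal kappa with its 95% CI,
multi-rater PPA and PNA, per reporting category), kept for regression
comparison against values this package can recompute.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

__all__ = ["table1_counts", "table2_agreement"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    text = resources.files("cxragree.data").joinpath(name).read_text("utf-8")
    return pd.read_csv(StringIO(text), **kwargs)


def table1_counts() -> pd.DataFrame:
    """Frequency table: raw labels x six raters, positive case counts."""
    return _read("table1_counts.csv", index_col="label")


def table2_agreement() -> pd.DataFrame:
    """Published all-reader agreement values per reporting category."""
    return _read("table2_agreement.csv", index_col="category")
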