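"""Agreement statistics for binary multi-rater annotation data.

Per reporting category the data are an N x n binary matrix (N cases, n
raters; 1 = label used).  The battery mirrors common practice for
reliability studies with free label marginals:

* **Observed agreement** P̄o: mean over cases of the fraction of concordant
  rater pairs.  With s_i positive and d_i = n - s_i negative raters on case
  i,  P̄o = (1/N) Σ_i [s_i(s_i-1) + d_i(d_i-1)] / (n(n-1)).
* **Randolph's free-marginal multi-rater kappa**:
  κ_free = (P̄o - 1/q)/(1 - 1/q), with q the number of categories a rater
  could assign (q = 2 for used/not-used).  Unlike fixed-marginal kappa it
  does not condition on the observed label prevalences, which is the
  appropriate choice when raters are free to use a label as often or as
  rarely as they see fit.
* **PABAK** (prevalence- and bias-adjusted kappa) for two raters:
  2·Po - 1 with Po the raw proportion of concordant cases.
* **Specific agreement**: proportion of positive agreement
  PPA = 2a/(2a+b+c) and of negative agreement PNA = 2d/(2d+b+c) for two
  raters (a/d concordant positive/negative, b/c discordant), with the
  multi-rater generalizations PPA = Σ s_i(s_i-1) / Σ s_i(n-1) and
  PNA = Σ d_i(d_i-1) / Σ d_i(n-1).

Statistics whose denominator is zero are *undefined* and returned as NaN;
report tables render them blank, never as 0.  Kappa-family values carry the
conventional Landis–Koch verbal band.  Confidence intervals are
nonparametric case-resampling percentile bootstraps.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AgreementResult",
    "observed_agreement_multi",
    "observed_agreement_counts",
    "randolph_kappa",
    "randolph_kappa_counts",
    "pabak",
    "specific_agreement_pair",
    "specific_agreement_multi",
    "bootstrap_ci",
    "interpret_kappa",
    "intra_rater",
    "round_half_up",
]

#: Landis–Koch verbal bands: (inclusive upper bound, name); kappa <0 is poor.
KAPPA_BANDS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)


@dataclass
class AgreementResult:
    """One agreement statistic with context and optional bootstrap CI."""

    statistic: str
    value: float
    n_cases: int
    n_raters: int
    n_categories: int = 2
    ci_low: float | None = None
    ci_high: float | None = None
    interpretation: str | None = None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)

    def __post_init__(self) -> None:
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.defined
            and not (self.ci_low <= self.value + 1e-12 and self.value - 1e-12 <= self.ci_high)
        ):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket {self.value}"
            )


def _as_binary_matrix(column: np.ndarray) -> np.ndarray:
    col = np.asarray(column)
    if col.ndim != 2:
        raise ValueError("expected a cases x raters matrix")
    if col.shape[0] < 1:
        raise ValueError("empty column")
    if not np.isin(col, (0, 1)).all():
        raise ValueError("ratings must be binary 0/1")
    return col


def observed_agreement_multi(column: np.ndarray) -> float:
    """Mean pairwise observed agreement P̄o for an N x n binary matrix."""
    col = _as_binary_matrix(column)
    n = col.shape[1]
    if n < 2:
        raise ValueError(f"need at least 2 raters, got {n}")
    s = col.sum(axis=1)
    d = n - s
    per_case = (s * (s - 1) + d * (d - 1)) / (n * (n - 1))
    return float(per_case.mean())


def observed_agreement_counts(counts: np.ndarray) -> float:
    """P̄o from an N x q table of per-case category counts (general q).

    Row sums must be constant (= n raters).  The binary form is the special
    case q = 2 with columns (s_i, d_i).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ValueError("expected a cases x categories count table")
    n_per_case = c.sum(axis=1)
    n = n_per_case[0]
    if n < 2 or not np.all(n_per_case == n):
        raise ValueError("each case needs the same number (>=2) of ratings")
    per_case = (c * (c - 1)).sum(axis=1) / (n * (n - 1))
    return float(per_case.mean())


def _kappa_from_po(po: float, q: int) -> float:
    if q < 2:
        raise ValueError("q must be >= 2")
    return (po - 1.0 / q) / (1.0 - 1.0 / q)


def randolph_kappa(
    column: np.ndarray,
    q: int = 2,
    *,
    ci: tuple[float, float] | None = None,
) -> AgreementResult:
    """Free-marginal multi-rater kappa for one binary category column."""
    col = _as_binary_matrix(column)
    po = observed_agreement_multi(col)
    kappa = _kappa_from_po(po, q)
    lo, hi = ci if ci is not None else (None, None)
    return AgreementResult(
        statistic="randolph_kappa",
        value=kappa,
        n_cases=col.shape[0],
        n_raters=col.shape[1],
        n_categories=q,
        ci_low=lo,
        ci_high=hi,
        interpretation=interpret_kappa(kappa),
    )


def randolph_kappa_counts(counts: np.ndarray) -> AgreementResult:
    """Free-marginal kappa from an N x q per-case count table (q >= 2)."""
    c = np.asarray(counts, dtype=float)
    po = observed_agreement_counts(c)
    q = c.shape[1]
    kappa = _kappa_from_po(po, q)
    return AgreementResult(
        statistic="randolph_kappa",
        value=kappa,
        n_cases=c.shape[0],
        n_raters=int(c[0].sum()),
        n_categories=q,
        interpretation=interpret_kappa(kappa),
    )


def _pair(col_a: np.ndarray, col_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(col_a).ravel()
    b = np.asarray(col_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("empty columns")
    for v in (a, b):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("ratings must be binary 0/1")
    return a, b


def pabak(col_a: np.ndarray, col_b: np.ndarray, *, ci=None) -> AgreementResult:
    """Prevalence- and bias-adjusted kappa, 2·Po − 1, for two raters."""
    a, b = _pair(col_a, col_b)
    po = float((a == b).mean())
    value = 2.0 * po - 1.0
    lo, hi = ci if ci is not None else (None, None)
    return AgreementResult(
        statistic="pabak",
        value=value,
        n_cases=a.size,
        n_raters=2,
        n_categories=2,
        ci_low=lo,
        ci_high=hi,
        interpretation=interpret_kappa(value),
    )


def specific_agreement_pair(col_a: np.ndarray, col_b: np.ndarray) -> tuple[float, float]:
    """Two-rater (PPA, PNA); NaN marks an undefined (0/0) proportion."""
    x, y = _pair(col_a, col_b)
    a = int(((x == 1) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    bc = int((x != y).sum())
    ppa = 2.0 * a / (2 * a + bc) if 2 * a + bc > 0 else float("nan")
    pna = 2.0 * d / (2 * d + bc) if 2 * d + bc > 0 else float("nan")
    return ppa, pna


def specific_agreement_multi(column: np.ndarray) -> tuple[float, float]:
    """Multi-rater (PPA, PNA) over per-case positive/negative rater counts."""
    col = _as_binary_matrix(column)
    n = col.shape[1]
    if n < 2:
        raise ValueError(f"need at least 2 raters, got {n}")
    s = col.sum(axis=1)
    d = n - s
    num_p, den_p = float((s * (s - 1)).sum()), float((s * (n - 1)).sum())
    num_n, den_n = float((d * (d - 1)).sum()), float((d * (n - 1)).sum())
    ppa = num_p / den_p if den_p > 0 else float("nan")
    pna = num_n / den_n if den_n > 0 else float("nan")
    return ppa, pna


def bootstrap_ci(
    data: np.ndarray | Sequence[np.ndarray],
    statistic: Callable[..., float],
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    *,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Case-resampling percentile bootstrap interval for a statistic.

    ``data`` is one array (first axis = cases) or a sequence of arrays
    resampled jointly; ``statistic`` receives the resampled array(s).
    Deterministic given the seed.  Raises if the statistic is undefined
    (NaN) on the original data.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap replicate")
    arrays = [np.asarray(data)] if isinstance(data, np.ndarray) else [np.asarray(d) for d in data]
    n = arrays[0].shape[0]
    point = statistic(*arrays)
    if np.isnan(point):
        raise ValueError("statistic undefined on the original data")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = statistic(*(arr[idx] for arr in arrays))
    reps = reps[~np.isnan(reps)]
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def interpret_kappa(value: float) -> str:
    """Landis–Koch verbal band for a kappa-family value (≤ 1)."""
    if np.isnan(value):
        return "undefined"
    if value > 1 + 1e-9:
        raise ValueError(f"kappa cannot exceed 1, got {value}")
    if value < 0:
        return "poor"
    for upper, name in KAPPA_BANDS:
        if value <= upper + 1e-12:
            return name
    return "almost perfect"


def intra_rater(matrix, rater: str, category: str) -> dict:
    """Test–retest agreement of one rater between annotation rounds.

    Compares the rater's round-1 and round-2 indicator vectors for the
    category; returns PABAK plus the (PPA, PNA) pair.
    """
    for rnd in (1, 2):
        if rnd not in matrix.rounds:
            raise KeyError(f"round {rnd} missing; both rounds required")
    r1 = matrix.rater_column(rater, category, 1)
    r2 = matrix.rater_column(rater, category, 2)
    ppa, pna = specific_agreement_pair(r1, r2)
    return {"pabak": pabak(r1, r2), "ppa": ppa, "pna": pna}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as agreement tables conventionally do."""
    if np.isnan(value):
        return value
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )
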