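"""Correlation of model scores with measured binding affinities.

The evaluation procedure is a Pearson product-moment correlation between a
measurement column (EMSA log value, PBM z-score, SELEX-Seq fold enrichment)
and one or more model-score columns, computed over pairwise-complete rows,
with a two-sided p value from the t transform
``t = r sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.  |r| is mapped
onto the conventional verbal scale: [0,0.2) very weak, [0.2,0.4) weak,
[0.4,0.6) medium, [0.6,0.8) strong, [0.8,1] very strong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "pearson_r",
    "pearson_p",
    "strength_category",
    "correlate_models",
]

_STRENGTH_EDGES = (0.2, 0.4, 0.6, 0.8)
_STRENGTH_LABELS = ("very weak", "weak", "medium", "strong", "very strong")


class CorrelationError(ValueError):
    """Undefined correlation (constant input or too few complete pairs)."""


@dataclass(frozen=True)
class CorrelationResult:
    """One model-vs-measurement comparison.

    ``error`` is set (and the numeric fields are NaN) when the correlation
    was undefined for this column, e.g. fewer than 3 complete pairs.
    """

    column: str
    n: int
    r: float
    p: float
    strength: str
    sign: str
    error: str | None = None


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise CorrelationError("need at least two observations")
    for arr, label in ((x, "x"), (y, "y")):
        if np.ptp(arr) == 0:
            raise CorrelationError(f"undefined correlation: column {label} is constant")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient, in [-1, 1]."""
    x, y = _validate_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def pearson_p(r: float, n: int) -> float:
    """Two-sided p value for an observed Pearson r at sample size n.

    Uses the exact null distribution via ``t = r sqrt((n-2)/(1-r^2))``
    against Student's t with n-2 degrees of freedom; r = ±1 gives p = 0.
    """
    if n < 3:
        raise CorrelationError(f"need n >= 3 for a defined p value, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def strength_category(r: float) -> str:
    """Verbal strength of |r|: very weak / weak / medium / strong / very strong.

    Intervals are half-open on the left ([0.6, 0.8) is "strong"), so 0.8
    itself is "very strong".
    """
    a = abs(float(r))
    if not a <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    return _STRENGTH_LABELS[int(np.searchsorted(_STRENGTH_EDGES, a, side="right"))]


def _sign_label(r: float) -> str:
    if r > 0:
        return "positive"
    if r < 0:
        return "negative"
    return "none"


def correlate_models(
    dataset: pd.DataFrame,
    reference_column: str,
    model_columns: Sequence[str],
) -> list[CorrelationResult]:
    """Correlate each model column against the measurement column.

    Rows where either value is missing are dropped per comparison
    (pairwise-complete deletion), so each result carries its own n.
    Columns with fewer than 3 complete pairs or zero variance produce an
    error entry rather than raising.
    """
    missing = [c for c in (reference_column, *model_columns) if c not in dataset]
    if missing:
        raise KeyError(f"columns not in dataset: {missing}")
    results: list[CorrelationResult] = []
    ref = pd.to_numeric(dataset[reference_column], errors="coerce")
    for col in model_columns:
        vals = pd.to_numeric(dataset[col], errors="coerce")
        mask = ref.notna() & vals.notna()
        n = int(mask.sum())
        try:
            if n < 3:
                raise CorrelationError(
                    f"only {n} complete pairs for {col!r}; need at least 3"
                )
            r = pearson_r(ref[mask].to_numpy(), vals[mask].to_numpy())
            p = pearson_p(r, n)
            results.append(
                CorrelationResult(col, n, r, p, strength_category(r), _sign_label(r))
            )
        except CorrelationError as exc:
            results.append(
                CorrelationResult(col, n, float("nan"), float("nan"), "", "", str(exc))
            )
    return results
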