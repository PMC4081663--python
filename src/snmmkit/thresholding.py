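"""Decision-threshold optimization for site prediction.

Given SNMM scores for a positive set S1 (N known binding sites) and a
negative set S2 (M non-sites), every threshold x on the grid 0, 0.001, ...,
1 is evaluated:

* rFN(x) = (# S1 scores predicted negative) / N — false-negative ratio,
* rFP(x) = (# S2 scores predicted positive) / M — false-positive ratio,

where a score counts as a predicted site iff round(score, 3) >= x.  The
optimum minimizes rFN + rFP; ties are broken by smaller rFN, then by the
largest threshold (the most stringent predictor among equals).  On cleanly
separable inputs this returns exactly the smallest rounded S1 score with
rFN = rFP = 0.

:class:`ThresholdOptimizer` exposes the procedure as a scikit-learn-style
estimator; :func:`optimal_threshold` is the functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .matrices import SITE_WIDTH
from .scoring import PWMScorer
from .seqs import BASES

__all__ = [
    "ThresholdResult",
    "ThresholdOptimizer",
    "classification_rates",
    "optimal_threshold",
    "select_s1",
    "generate_s2",
]

#: decimals used when comparing scores with grid thresholds; matches the
#: grid resolution so a site whose printed score equals the threshold is
#: classified positive.
SCORE_DECIMALS = 3


@dataclass(frozen=True)
class ThresholdResult:
    """Optimal threshold plus the full rFN/rFP curve for audit."""

    threshold: float
    rfn: float
    rfp: float
    curve: pd.DataFrame = field(repr=False)
    policy: dict = field(default_factory=dict, repr=False)


def _check_scores(scores, label: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{label} scores must be a non-empty 1-D array")
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError(f"{label} scores must lie in [0, 1]")
    return np.round(arr, SCORE_DECIMALS)


def classification_rates(
    s1_scores: Sequence[float], s2_scores: Sequence[float], threshold: float
) -> tuple[float, float]:
    """(rFN, rFP) at one threshold; predicted site iff round(score, 3) >= x."""
    s1 = _check_scores(s1_scores, "S1")
    s2 = _check_scores(s2_scores, "S2")
    # nudge by half a grid step so binary float noise cannot flip >= at equality
    eps = 10.0 ** (-SCORE_DECIMALS) / 2
    rfn = float(np.mean(s1 < threshold - eps))
    rfp = float(np.mean(s2 >= threshold - eps))
    return rfn, rfp


def optimal_threshold(
    s1_scores: Sequence[float],
    s2_scores: Sequence[float],
    step: float = 0.001,
) -> ThresholdResult:
    """Grid-search the threshold minimizing rFN + rFP over [0, 1].

    Ties are broken by smaller rFN, then by the largest threshold.  The
    returned curve has one row per grid point (threshold, rfn, rfp).
    """
    s1 = _check_scores(s1_scores, "S1")
    s2 = _check_scores(s2_scores, "S2")
    if not 0 < step <= 1:
        raise ValueError("step must lie in (0, 1]")
    n_steps = int(round(1.0 / step))
    grid = np.arange(n_steps + 1) / n_steps
    eps = 10.0 ** (-SCORE_DECIMALS) / 2
    # counts below each threshold via a sorted scan: rFN is a step function
    s1_sorted = np.sort(s1)
    s2_sorted = np.sort(s2)
    rfn = np.searchsorted(s1_sorted, grid - eps, side="left") / s1.size
    rfp = 1.0 - np.searchsorted(s2_sorted, grid - eps, side="left") / s2.size
    loss = rfn + rfp
    # lexicographic minimum of (loss, rfn, -threshold); grid order is
    # ascending threshold, so take the *last* index among ties
    key = np.stack([loss, rfn])
    best = np.lexsort((-grid, key[1], key[0]))[0]
    curve = pd.DataFrame({"threshold": grid, "rfn": rfn, "rfp": rfp})
    return ThresholdResult(
        threshold=float(grid[best]),
        rfn=float(rfn[best]),
        rfp=float(rfp[best]),
        curve=curve,
        policy={
            "predicate": f"round(score, {SCORE_DECIMALS}) >= threshold",
            "loss": "rfn + rfp",
            "tie_break": "smaller rfn, then largest threshold",
            "step": step,
        },
    )


class ThresholdOptimizer(BaseEstimator):
    """Grid-search threshold selector as a scikit-learn-style estimator.

    ``fit(s1_scores, s2_scores)`` runs the grid search; ``predict(scores)``
    then classifies scores with the fitted threshold (1 = predicted site).

    Attributes
    ----------
    threshold_ : float
        The selected optimal threshold (a grid point).
    rfn_, rfp_ : float
        Error ratios at the optimum.
    result_ : ThresholdResult
        Full curve and tie-break policy.
    """

    def __init__(self, step: float = 0.001) -> None:
        self.step = step

    def fit(self, X: Sequence[float], y: Sequence[float]) -> "ThresholdOptimizer":
        """X: positive-set (S1) scores; y: negative-set (S2) scores."""
        result = optimal_threshold(X, y, step=self.step)
        self.result_ = result
        self.threshold_ = result.threshold
        self.rfn_ = result.rfn
        self.rfp_ = result.rfp
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        check_is_fitted(self)
        eps = 10.0 ** (-SCORE_DECIMALS) / 2
        scores = np.round(np.asarray(X, dtype=float), SCORE_DECIMALS)
        return (scores >= self.threshold_ - eps).astype(int)


# ---------------------------------------------------------------------------
# Assembling the S1 / S2 groups
# ---------------------------------------------------------------------------


def select_s1(
    dataset: pd.DataFrame,
    measurement_column: str,
    n: int = 30,
    sequence_column: str = "sequence",
) -> list[str]:
    """The n sequences with the highest measured affinity.

    Rows with a missing measurement are ignored; ties at the cut are broken
    by lexicographic sequence order so the selection is deterministic.
    """
    if measurement_column not in dataset or sequence_column not in dataset:
        raise KeyError(
            f"dataset needs columns {sequence_column!r} and {measurement_column!r}"
        )
    if n == 0:
        return []
    usable = dataset[[sequence_column, measurement_column]].dropna()
    if len(usable) < n:
        raise ValueError(
            f"only {len(usable)} rows with a {measurement_column!r} value; need {n}"
        )
    ordered = usable.sort_values(
        [measurement_column, sequence_column],
        ascending=[False, True],
        kind="stable",
    )
    return ordered[sequence_column].head(n).tolist()


def generate_s2(
    n: int,
    pwm,
    mss_cutoff: float = 0.5,
    rng_seed: int | np.random.Generator = 0,
    max_draws: int = 1_000_000,
) -> list[str]:
    """Rejection-sample n distinct random 10-mers rejected by the Match model.

    Uniform random 10-mers are drawn until n distinct sequences with
    ``match_mss < mss_cutoff`` are collected; fully reproducible for a fixed
    seed.  Raises with diagnostics if the sampling budget is exhausted
    (cutoff too strict for the motif's information content).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scorer = pwm if isinstance(pwm, PWMScorer) else PWMScorer.from_pwm(pwm, "match")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    chosen: list[str] = []
    seen: set[str] = set()
    draws = 0
    while len(chosen) < n:
        if draws >= max_draws:
            raise RuntimeError(
                f"exhausted {max_draws} draws with only {len(chosen)}/{n} "
                f"sequences below MSS cutoff {mss_cutoff}; relax the cutoff"
            )
        batch = rng.integers(0, 4, size=(min(256, max_draws - draws), SITE_WIDTH))
        draws += batch.shape[0]
        for row in batch:
            seq = "".join(BASES[i] for i in row)
            if seq in seen:
                continue
            seen.add(seq)
            if scorer.score_sequence(seq) < mss_cutoff:
                chosen.append(seq)
                if len(chosen) == n:
                    break
    return chosen
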