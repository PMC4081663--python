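"""Scoring 10-bp sites and scanning longer sequences.

Three scorers, all returning values on [0, 1]:

* SNMM: the mutation-matrix score
  ``(S_ref + sum_n dS(base_n, n) - S_min) / (S_max - S_min)`` with
  ``S_ref = 0`` — a min-max-normalized sum of per-position affinity deltas.
* PWMSA: Stormo-style log-odds ``sum_i ln(f(b_i, i) / bg(b_i))``,
  min-max normalized over the per-column extreme log-odds.
* Match: the Kel matrix similarity score (MSS)
  ``sum_i I(i) f(b_i, i)``, likewise min-max normalized.

The estimators :class:`SNMMScorer` and :class:`PWMScorer` follow the
scikit-learn protocol (parameters in ``__init__``, data in ``fit``,
fitted attributes with a trailing underscore, ``predict`` for scores) so
they compose with sklearn pipelines and model selection.  The
module-level functions :func:`snmm_score`, :func:`pwmsa_score` and
:func:`match_mss` are thin wrappers for one-off use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .matrices import (
    PWM,
    SITE_WIDTH,
    IntensityTable,
    MatrixError,
    MutationMatrix,
    build_pwm,
    build_snmm,
    read_transfac,
)
from .seqs import canonical_seq, reverse_complement, seq_to_indices

__all__ = [
    "ScoredHit",
    "SNMMScorer",
    "PWMScorer",
    "snmm_score",
    "pwmsa_score",
    "match_mss",
    "reverse_complement",
    "scan_sequence",
]


@dataclass(frozen=True)
class ScoredHit:
    """A scan hit: 0-based half-open window [start, start+10) on the input.

    ``site`` is the 10-mer read 5'->3' on the reported strand, so for a
    minus-strand hit it is the reverse complement of the input window.
    """

    start: int
    strand: str
    site: str
    score: float
    model: str

    @property
    def end(self) -> int:
        return self.start + len(self.site)


def _as_sequences(X) -> list[str]:
    if isinstance(X, str):
        return [X]
    return [str(s) for s in X]


class _SequenceScorer(BaseEstimator):
    """Shared predict machinery: vectorized scoring of fixed-width sites."""

    model_name: str = ""

    def _score_one(self, seq: str) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def width_(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        """Score sequences; X is a string or an iterable of strings."""
        check_is_fitted(self)
        return np.array([self._score_one(canonical_seq(s, length=self.width_))
                         for s in _as_sequences(X)])

    def score_sequence(self, seq: str) -> float:
        """Score a single site (scalar convenience around :meth:`predict`)."""
        return float(self.predict([seq])[0])


class SNMMScorer(_SequenceScorer):
    """Mutation-matrix affinity scorer for 10-bp NF-κB sites.

    Fit from raw microarray intensities (an :class:`IntensityTable` holding
    the reference probe and its 30 single-base mutants), or wrap an existing
    matrix with :meth:`from_matrix`.  ``predict`` maps each 10-mer to
    ``(sum of its per-position deltas - S_min) / (S_max - S_min)``, which is
    1 for the per-column argmax sequence and 0 for the argmin sequence.

    Parameters
    ----------
    aggregator : {"mean", "median"}
        Replicate aggregation used when fitting from intensities.
    missing : {"error", "nan", "impute_min"}
        Policy for absent mutant probes (see :func:`~snmmkit.matrices.build_snmm`).

    Attributes
    ----------
    matrix_ : MutationMatrix
        The fitted 4 x 10 delta matrix.
    s_min_, s_max_ : float
        Sums of per-column minima / maxima, the normalization range.
    """

    model_name = "snmm"

    def __init__(self, aggregator: str = "mean", missing: str = "error") -> None:
        self.aggregator = aggregator
        self.missing = missing

    def fit(self, X: IntensityTable, y=None) -> "SNMMScorer":
        """Estimate the delta matrix from replicate probe intensities."""
        if not isinstance(X, IntensityTable):
            raise TypeError("X must be an IntensityTable (reference + mutant probes)")
        matrix = build_snmm(X, aggregator=self.aggregator, missing=self.missing)
        return self._set_matrix(matrix)

    def _set_matrix(self, matrix: MutationMatrix) -> "SNMMScorer":
        self.matrix_ = matrix
        self.s_min_ = matrix.s_min
        self.s_max_ = matrix.s_max
        if self.s_max_ <= self.s_min_:
            raise MatrixError("degenerate matrix: S_max must exceed S_min")
        return self

    @classmethod
    def from_matrix(cls, matrix: MutationMatrix) -> "SNMMScorer":
        """Fitted scorer wrapping an already-constructed matrix."""
        return cls()._set_matrix(matrix)

    @property
    def width_(self) -> int:
        check_is_fitted(self)
        return SITE_WIDTH

    def _score_one(self, seq: str) -> float:
        deltas = self.matrix_.delta[seq_to_indices(seq), np.arange(SITE_WIDTH)]
        if np.isnan(deltas).any():
            raise MatrixError(
                f"cannot score {seq}: the matrix is degraded (missing cells) "
                "at one or more of its positions"
            )
        return (float(deltas.sum()) - self.s_min_) / (self.s_max_ - self.s_min_)


class PWMScorer(_SequenceScorer):
    """Comparator PWM scorer: Stormo log-odds ("pwmsa") or Kel MSS ("match").

    Fit from aligned binding sites, or wrap an existing matrix with
    :meth:`from_pwm` / :meth:`from_transfac`.

    Parameters
    ----------
    method : {"match", "pwmsa"}
        Scoring rule; both are min-max normalized to [0, 1].
    pseudocount : float
        Laplace pseudocount spread by the background when fitting counts.
        Must be positive for "pwmsa" (log-odds needs nonzero frequencies).
    background : mapping or length-4 sequence, optional
        Base probabilities; uniform 0.25 by default.

    Attributes
    ----------
    pwm_ : PWM
        Count/frequency matrix with background and information vector.
    raw_min_, raw_max_ : float
        The per-column extreme raw scores used for normalization.
    """

    def __init__(
        self,
        method: Literal["match", "pwmsa"] = "match",
        pseudocount: float = 1.0,
        background: Mapping[str, float] | Sequence[float] | None = None,
    ) -> None:
        self.method = method
        self.pseudocount = pseudocount
        self.background = background

    @property
    def model_name(self) -> str:  # type: ignore[override]
        return self.method

    def fit(self, X: Iterable[str], y=None) -> "PWMScorer":
        """Tally aligned equal-length sites into a PWM."""
        pwm = build_pwm(X, pseudocount=self.pseudocount, background=self.background)
        return self._set_pwm(pwm)

    def _set_pwm(self, pwm: PWM) -> "PWMScorer":
        if self.method not in ("match", "pwmsa"):
            raise ValueError('method must be "match" or "pwmsa"')
        if self.method == "pwmsa":
            if (pwm.frequencies <= 0).any():
                raise MatrixError(
                    "pwmsa log-odds needs strictly positive frequencies; "
                    "refit with a positive pseudocount"
                )
            per_col = np.log(pwm.frequencies / pwm.background[:, None])
        else:
            per_col = pwm.information[None, :] * pwm.frequencies
        self.pwm_ = pwm
        self._per_column_ = per_col
        self.raw_min_ = float(per_col.min(axis=0).sum())
        self.raw_max_ = float(per_col.max(axis=0).sum())
        return self

    @classmethod
    def from_pwm(cls, pwm: PWM, method: str = "match") -> "PWMScorer":
        return cls(method=method)._set_pwm(pwm)

    @classmethod
    def from_transfac(
        cls, path, method: str = "match", pseudocount: float = 1.0, background=None
    ) -> "PWMScorer":
        pwm = read_transfac(path, pseudocount=pseudocount, background=background)
        return cls(method=method, pseudocount=pseudocount, background=background)._set_pwm(pwm)

    @property
    def width_(self) -> int:
        check_is_fitted(self)
        return self.pwm_.width

    def _score_one(self, seq: str) -> float:
        raw = float(
            self._per_column_[seq_to_indices(seq), np.arange(self.pwm_.width)].sum()
        )
        if self.raw_max_ == self.raw_min_:  # flat matrix: every site is equally good
            return 1.0
        return (raw - self.raw_min_) / (self.raw_max_ - self.raw_min_)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def snmm_score(seq: str, matrix: MutationMatrix) -> float:
    """SNMM score of a 10-mer on [0, 1]; 1 at the per-column argmax site."""
    return SNMMScorer.from_matrix(matrix).score_sequence(seq)


def pwmsa_score(seq: str, pwm: PWM) -> float:
    """Min-max-normalized log-odds score of a site against a PWM."""
    return PWMScorer.from_pwm(pwm, method="pwmsa").score_sequence(seq)


def match_mss(seq: str, pwm: PWM) -> float:
    """Match matrix similarity score (information-weighted frequency sum)."""
    return PWMScorer.from_pwm(pwm, method="match").score_sequence(seq)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def scan_sequence(
    seq: str,
    scorer: _SequenceScorer,
    threshold: float = 0.747,
    strands: str = "both",
) -> list[ScoredHit]:
    """Slide a fitted scorer over every window of ``seq`` on the requested strands.

    Hits with score >= ``threshold`` are returned sorted by start, then
    strand ('+' before '-').  Minus-strand hits carry plus-strand (input)
    coordinates with ``site`` given as the reverse complement of the window.
    A sequence shorter than the site width yields an empty list with a
    warning rather than an error.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError('strands must be "+", "-" or "both"')
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    w = scorer.width_
    s = canonical_seq(seq)
    if len(s) < w:
        warnings.warn(
            f"sequence of length {len(s)} is shorter than the site width {w}; "
            "nothing to scan",
            stacklevel=2,
        )
        return []
    hits: list[ScoredHit] = []
    for start in range(len(s) - w + 1):
        window = s[start:start + w]
        if strands in ("+", "both"):
            score = scorer.score_sequence(window)
            if score >= threshold:
                hits.append(ScoredHit(start, "+", window, score, scorer.model_name))
        if strands in ("-", "both"):
            site = reverse_complement(window)
            score = scorer.score_sequence(site)
            if score >= threshold:
                hits.append(ScoredHit(start, "-", site, score, scorer.model_name))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
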