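"""Harrell's concordance index for censored survival data.

The C-index is the fraction of comparable patient pairs whose predicted risk
ordering agrees with their observed survival ordering.  A pair ``(i, j)`` is
*comparable* when ``time_i < time_j`` and patient ``i`` experienced the event:
we then know patient ``i`` truly fared worse.  The pair is *concordant* when
the model assigns ``i`` the higher risk score; tied scores count one half.
Pairs with tied times are not comparable.

Orientation is fixed package-wide: **higher score means higher risk** (shorter
expected survival).  C = 0.5 is a coin flip, 1.0 a perfect ordering and 0.0 a
perfectly inverted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RiskPrediction", "ConcordanceUndefinedError", "harrell_c"]


class ConcordanceUndefinedError(ValueError):
    """Raised when no comparable pair exists (e.g. everything censored)."""


@dataclass(frozen=True)
class RiskPrediction:
    """Per-sample risk scores paired with the observed outcome.

    Attributes
    ----------
    score : array-like
        Risk scores; higher means worse prognosis.
    time : array-like
        Survival or censoring times.
    event : array-like
        Event indicators, 1 = event observed, 0 = censored.
    """

    score: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        score = np.asarray(self.score, dtype=float)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if not (score.shape == time.shape == event.shape) or score.ndim != 1:
            raise ValueError("score, time and event must be 1-D and equal length")
        if not np.all(np.isfinite(score)):
            raise ValueError("risk scores must be finite")
        ev = np.asarray(event, dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "score", score)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", ev.astype(int))


def harrell_c(pred: RiskPrediction) -> float:
    """Harrell's C-index of a :class:`RiskPrediction`.

    Returns
    -------
    float
        ``(concordant + 0.5 * tied_scores) / comparable`` over all comparable
        pairs.

    Raises
    ------
    ConcordanceUndefinedError
        If no comparable pair exists, which is distinct from any numeric
        return value.
    """
    score, time, event = pred.score, pred.time, pred.event
    n = score.shape[0]
    if n < 2:
        raise ConcordanceUndefinedError("need at least two samples")
    # comparable[i, j]: i had the event strictly before j's recorded time
    earlier = time[:, None] < time[None, :]
    comparable = earlier & (event[:, None] == 1)
    n_comparable = int(comparable.sum())
    if n_comparable == 0:
        raise ConcordanceUndefinedError("no comparable pair (all censored or all times tied)")
    higher = score[:, None] > score[None, :]
    tied = score[:, None] == score[None, :]
    concordant = int((comparable & higher).sum())
    ties = int((comparable & tied).sum())
    return (concordant + 0.5 * ties) / n_comparable


def concordance(score, time, event) -> float:
    """Convenience wrapper around :func:`harrell_c` taking raw arrays."""
    return harrell_c(RiskPrediction(np.asarray(score), np.asarray(time), np.asarray(event)))
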