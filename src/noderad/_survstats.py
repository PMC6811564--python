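"""Small survival-statistics helpers shared by selection and modelling."""

from __future__ import annotations

import numpy as np


def harrell_cindex(score: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index of a risk score (higher = worse).

    A pair (i, j) is comparable if t_i < t_j and patient i had the event;
    it counts 1 if score_i > score_j, 0.5 on score ties.  Returns 0.5 when
    no pair is comparable.
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    i, j = np.nonzero((time[:, None] < time[None, :]) & event[:, None])
    if len(i) == 0:
        return 0.5
    d = score[i] - score[j]
    return float(((d > 0) + 0.5 * (d == 0)).mean())


def columnwise_cindex(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Harrell's c-index of every column of X against (time, event)."""
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    i, j = np.nonzero((time[:, None] < time[None, :]) & event[:, None])
    if len(i) == 0:
        return np.full(X.shape[1], 0.5)
    d = X[i] - X[j]
    return ((d > 0) + 0.5 * (d == 0)).mean(axis=0)


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a fixed linear predictor."""
    lp = np.asarray(lp, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    log_risk = np.logaddexp.accumulate(lp)
    # with ties, the risk set includes everyone at the same time:
    # map each position to the last index of its tie group
    tie_end = np.empty(len(time), dtype=int)
    start = 0
    while start < len(time):
        end = start
        while end + 1 < len(time) and time[end + 1] == time[start]:
            end += 1
        tie_end[start : end + 1] = end
        start = end + 1
    ll = lp[event] - log_risk[tie_end[event]]
    return float(ll.sum())
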