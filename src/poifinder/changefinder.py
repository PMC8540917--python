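"""Two-stage change scoring with sequentially discounting AR (SDAR) models.

An SDAR model maintains exponentially discounted estimates of the mean,
autocovariances, AR coefficients (via Yule-Walker) and one-step prediction
variance of a scalar stream.  The change score of a series is obtained in
two rounds: the first SDAR scores each sample by the negative log density
of its one-step Gaussian prediction, the scores are smoothed with a causal
moving average of width ``w``, and the identical machinery is run a second
time on the smoothed scores (smoothing width ``round(w/2)``).  The second
round suppresses isolated noise spikes, so sustained model shifts — not
single odd samples — dominate the final score.

Update recurrences, with discount rate ``r`` in (0, 1) and AR order ``k``::

    mu_t    = (1 - r) mu_{t-1} + r x_t
    C_{t,i} = (1 - r) C_{t-1,i} + r (x_t - mu_t)(x_{t-i} - mu_t)   i = 0..k
    a_{t,.} solves the Yule-Walker system  C_i = sum_j a_j C_{i-j},  C_{-i} = C_i
    xhat_t  = sum_i a_{t,i} (x_{t-i} - mu_t) + mu_t
    sigma_t = (1 - r) sigma_{t-1} + r (x_t - xhat_t)^2

The score of ``x_t`` is the log loss under the *previous* step's model,
``y_t = 0.5 log(2 pi sigma) + (x_t - xhat)^2 / (2 sigma)`` with ``sigma``
a variance (floored at 1e-12 to keep constant stretches finite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NotReadyError

#: variance floor applied inside the Gaussian log loss
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class ChangeFinderParams:
    """Parameters of the two-stage detector.

    order
        AR order ``k`` (default 1).
    discount
        Discounting rate ``r`` in (0, 1) (default 0.025); larger values
        forget history faster.
    smooth_width
        Causal moving-average width ``w`` for the first round (default 5).
    second_width
        Smoothing width of the second round; defaults to
        ``round(w / 2.0)`` (banker's rounding, so w=5 gives 2), floored
        at 1.
    """

    order: int = 1
    discount: float = 0.025
    smooth_width: int = 5
    second_width: int | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0.0 < self.discount < 1.0:
            raise ValueError("discount must be in (0, 1)")
        if self.smooth_width < 1:
            raise ValueError("smooth_width must be >= 1")
        if self.second_width is not None and self.second_width < 1:
            raise ValueError("second_width must be >= 1")

    @property
    def resolved_second_width(self) -> int:
        if self.second_width is not None:
            return self.second_width
        return max(1, round(self.smooth_width / 2.0))


@dataclass
class ChangeScoreSeries:
    """Per-timestamp change scores S(t), aligned 1:1 with the input.

    Leading positions produced before the sequential models have enough
    history are zero and flagged; ``burn_in`` records the leading span
    (seconds) that threshold estimation and metrics must additionally
    drop while the discounted learner converges.
    """

    times: np.ndarray
    scores: np.ndarray
    flagged: np.ndarray
    burn_in: float = 30.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if not (len(self.times) == len(self.scores) == len(self.flagged)):
            raise ValueError("times/scores/flagged length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return len(self.scores)

    def eligible_mask(self) -> np.ndarray:
        """Samples usable for thresholding/extraction: past burn-in and
        not flagged as warm-up output."""
        if self.n == 0:
            return np.zeros(0, dtype=bool)
        return (self.times >= self.times[0] + self.burn_in) & ~self.flagged


def solve_yule_walker(autocov: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
    """Solve the order-``k`` Yule-Walker system for AR coefficients.

    ``autocov`` holds C_0..C_k; the symmetry C_{-i} = C_i makes the system
    matrix Toeplitz.  Returns ``(a, singular)``; a singular (or otherwise
    unsolvable) system yields the zero vector with ``singular=True`` —
    the caller's predictor then degrades to the running mean.
    """
    autocov = np.asarray(autocov, dtype=float)
    if k < 1 or len(autocov) < k + 1:
        raise ValueError("need k >= 1 and k+1 autocovariances")
    if k == 1:
        if autocov[0] > 0:
            return np.array([autocov[1] / autocov[0]]), False
        return np.zeros(1), True
    mat = autocov[np.abs(np.subtract.outer(np.arange(k), np.arange(k)))]
    rhs = autocov[1 : k + 1]
    try:
        a = np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError:
        return np.zeros(k), True
    if not np.all(np.isfinite(a)):
        return np.zeros(k), True
    return a, False


def log_loss(x: float, predicted: float, variance: float) -> float:
    """Negative log Gaussian density of ``x`` under N(predicted, variance).

    ``variance`` is floored at 1e-12 so constant stretches (variance
    decaying to zero) never produce infinite scores.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    v = max(variance, VARIANCE_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * v) + (x - predicted) ** 2 / (2.0 * v)


def smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Causal (trailing) moving average of the last ``width`` values.

    Positions with fewer than ``width`` predecessors average over the
    available prefix, keeping the output aligned 1:1 with the input.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return values.copy()
    # local window sums (not a global cumsum difference, which loses all
    # precision when an early value dwarfs the rest)
    sums = np.convolve(values, np.ones(width))[:n]
    counts = np.minimum(np.arange(n) + 1, width)
    return sums / counts


class SDAR:
    """Sequentially discounting AR model of one scalar stream.

    State is initialised lazily: the mean starts at the first observation
    and autocovariances, coefficients and variance start at zero, which
    makes a constant input an exact fixed point.  ``score_step`` performs
    predict-then-update: the returned log loss of ``x_t`` uses the model
    as it stood *before* seeing ``x_t``.
    """

    def __init__(self, order: int = 1, discount: float = 0.025):
        if order < 1:
            raise ValueError("order must be >= 1")
        if not 0.0 < discount < 1.0:
            raise ValueError("discount must be in (0, 1)")
        self.order = order
        self.discount = discount
        self.t = 0
        self.mean = 0.0
        self.autocov = np.zeros(order + 1)
        self.coeffs = np.zeros(order)
        self.variance = 0.0
        self.singular = True
        self._history: list[float] = []  # last `order` observations, newest last

    @property
    def ready(self) -> bool:
        """True once `order` observations are buffered and a real one-step
        prediction can be formed."""
        return len(self._history) >= self.order

    def predict(self) -> tuple[float, float]:
        """One-step prediction (mean, variance) from the current state."""
        if not self.ready:
            raise NotReadyError(
                f"need {self.order} observations before predicting "
                f"(have {len(self._history)})"
            )
        dev = sum(
            self.coeffs[i - 1] * (self._history[-i] - self.mean)
            for i in range(1, self.order + 1)
        )
        return self.mean + dev, self.variance

    def update(self, x: float) -> None:
        """Fold ``x_t`` into the discounted statistics (no scoring)."""
        r = self.discount
        if self.t == 0:
            self.mean = x
        if self.ready:
            xhat, _ = self.predict()
        else:
            xhat = self.mean  # mean predictor while history is short
        self.mean = (1.0 - r) * self.mean + r * x
        for i in range(self.order + 1):
            if i == 0:
                lag = x
            elif len(self._history) >= i:
                lag = self._history[-i]
            else:
                lag = self.mean  # unavailable lag contributes nothing
            self.autocov[i] = (1.0 - r) * self.autocov[i] + r * (x - self.mean) * (
                lag - self.mean
            )
        self.coeffs, self.singular = solve_yule_walker(self.autocov, self.order)
        self.variance = (1.0 - r) * self.variance + r * (x - xhat) ** 2
        self._history.append(x)
        if len(self._history) > self.order:
            self._history.pop(0)
        self.t += 1

    def score_step(self, x: float) -> float | None:
        """Score ``x_t`` under the pre-update model, then update.

        Returns None while the model cannot score yet: before ``order``
        observations are buffered, and while the variance estimate is
        still exactly zero (no residual observed, so the Gaussian density
        is degenerate).  Callers emit flagged zeros there.
        """
        if self.ready and self.variance > 0.0:
            xhat, var = self.predict()
            y = log_loss(x, xhat, var)
        else:
            y = None
        self.update(x)
        return y


def _scored_pass(values: np.ndarray, order: int, discount: float) -> tuple[np.ndarray, np.ndarray]:
    model = SDAR(order=order, discount=discount)
    n = len(values)
    y = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    for t, x in enumerate(values):
        out = model.score_step(float(x))
        if out is None:
            flagged[t] = True
        else:
            y[t] = out
    return y, flagged


def change_score(
    values: np.ndarray,
    params: ChangeFinderParams | None = None,
    start_time: float = 0.0,
    step: float = 1.0,
    burn_in: float = 30.0,
) -> ChangeScoreSeries:
    """Full two-stage change score S(t) of a single-feature sequence.

    Stage 1 scores the raw values with an SDAR log loss and smooths with
    ``smooth_width``; stage 2 runs the identical machinery on the smoothed
    stage-1 scores with width ``resolved_second_width``.  Output length
    equals input length; positions either stage produced before it could
    predict are zero and flagged.
    """
    params = params or ChangeFinderParams()
    values = np.asarray(values, dtype=float)
    y1, flag1 = _scored_pass(values, params.order, params.discount)
    score1 = smooth(y1, params.smooth_width)
    y2, flag2 = _scored_pass(score1, params.order, params.discount)
    final = smooth(y2, params.resolved_second_width)
    times = start_time + step * np.arange(len(values))
    return ChangeScoreSeries(
        times=times, scores=final, flagged=flag1 | flag2, burn_in=burn_in
    )
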