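"""Point-of-interest extraction from change-score series.

A PoI candidate is the highest-scoring sample of an *excursion*: a maximal
run of consecutive samples whose score strictly exceeds the threshold
gamma.  The default threshold is gamma = mu_S + sigma_S over the
post-burn-in score values; a raw-value baseline applies the same
excursion-argmax rule directly to the (unscored) composite values with
threshold mu + n*sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .changefinder import ChangeScoreSeries
from .errors import InsufficientDataError


@dataclass(frozen=True)
class PoICandidate:
    """One extracted point of interest and its excursion.

    ``time`` is the argmax of the score within [excursion_start,
    excursion_end); ties go to the earliest sample.  An excursion still
    open at the end of the series closes one step past its last sample.
    """

    time: float
    score: float
    excursion_start: float
    excursion_end: float


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the extraction threshold is formed.

    ``score_mean_sd``: gamma = mu_S + sigma_S of the post-burn-in change
    scores.  ``raw_mean_nsd``: mu + n_sigma * sigma of the raw composite
    values (the baseline design).  ``burn_in`` seconds of leading data are
    excluded from extraction (and, for the score mode, from the threshold
    statistics) while the discounted learner converges.
    """

    mode: str = "score_mean_sd"
    n_sigma: float = 1.0
    burn_in: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("score_mean_sd", "raw_mean_nsd"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


def compute_threshold(
    scores: ChangeScoreSeries, policy: ThresholdPolicy | None = None
) -> float:
    """gamma = mean + multiplier * sd over post-burn-in, unflagged scores.

    The multiplier is 1 in the default ``score_mean_sd`` mode and
    ``n_sigma`` otherwise; sd is the population standard deviation.
    """
    policy = policy or ThresholdPolicy()
    mask = (scores.times >= scores.times[0] + policy.burn_in) & ~scores.flagged
    vals = scores.scores[mask]
    if len(vals) == 0:
        raise InsufficientDataError(
            f"no scores remain after {policy.burn_in} s burn-in"
        )
    mult = 1.0 if policy.mode == "score_mean_sd" else policy.n_sigma
    return float(vals.mean() + mult * vals.std())


def _runs_above(eligible_idx: np.ndarray, values: np.ndarray, gamma: float):
    """Yield maximal runs (as index arrays) of consecutive eligible samples
    with values strictly above gamma."""
    run: list[int] = []
    prev = None
    for i in eligible_idx:
        if values[i] > gamma:
            if run and prev is not None and i == prev + 1:
                run.append(i)
            else:
                if run:
                    yield np.array(run)
                run = [i]
            prev = i
        else:
            if run:
                yield np.array(run)
            run = []
            prev = None
    if run:
        yield np.array(run)


def extract_poi(
    scores: ChangeScoreSeries, gamma: float, burn_in: float | None = None
) -> list[PoICandidate]:
    """Extract one candidate per threshold excursion.

    Post-burn-in samples with S(t) > gamma (strict) are grouped into
    maximal consecutive runs; each run contributes exactly one candidate
    at its (earliest) argmax.  An excursion open at series end still
    yields its candidate.
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    burn = scores.burn_in if burn_in is None else burn_in
    n = scores.n
    if n == 0:
        return []
    step = scores.times[1] - scores.times[0] if n > 1 else 1.0
    eligible = np.flatnonzero(
        (scores.times >= scores.times[0] + burn) & ~scores.flagged
    )
    out = []
    for run in _runs_above(eligible, scores.scores, gamma):
        best = run[np.argmax(scores.scores[run])]  # argmax: earliest tie wins
        end_idx = run[-1] + 1
        end_time = scores.times[end_idx] if end_idx < n else scores.times[-1] + step
        out.append(
            PoICandidate(
                time=float(scores.times[best]),
                score=float(scores.scores[best]),
                excursion_start=float(scores.times[run[0]]),
                excursion_end=float(end_time),
            )
        )
    return out


def count_exceedance(
    scores: ChangeScoreSeries, gamma: float, burn_in: float | None = None
) -> int:
    """n_o: number of post-burn-in samples strictly above gamma."""
    burn = scores.burn_in if burn_in is None else burn_in
    mask = (scores.times >= scores.times[0] + burn) & ~scores.flagged
    return int(np.sum(scores.scores[mask] > gamma))


def raw_threshold_baseline(
    values: np.ndarray,
    n_sigma: float,
    burn_in: float = 30.0,
    start_time: float = 0.0,
    step: float = 1.0,
) -> tuple[list[PoICandidate], float]:
    """Baseline: excursion-argmax extraction on the *raw* composite values.

    The threshold is mu + n_sigma * sigma computed over all raw values
    (population sigma, no burn-in exclusion); extraction itself still
    skips the burn-in window.  Returns (candidates, threshold).
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise InsufficientDataError("empty series")
    gamma = float(values.mean() + n_sigma * values.std())
    series = ChangeScoreSeries(
        times=start_time + step * np.arange(len(values)),
        scores=values,
        flagged=np.zeros(len(values), dtype=bool),
        burn_in=burn_in,
    )
    return extract_poi(series, gamma, burn_in=burn_in), gamma
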