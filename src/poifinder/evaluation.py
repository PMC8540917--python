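"""Tolerance-window evaluation of PoI candidates against event points.

An event point counts as captured (contributes to n_c) when at least one
candidate lies within the tolerance window (default +-10 s, closed
interval); each event point is counted at most once however many
candidates fall near it, and one candidate may serve several event
points.  Reported metrics:

    Recall    = n_c / n_e   (fraction of event points captured)
    Precision = n_c / n_p   (fraction of candidates that are valid)
    n_p / n, n_o / n        (how much data must still be inspected)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EventAnnotation
from .poi import PoICandidate


@dataclass
class EvalReport:
    """Counts and derived ratios of one detection run."""

    n: int
    n_p: int
    n_o: int
    n_e: int
    n_c: int
    recall: float
    precision: float
    ratio_p: float
    ratio_o: float
    correct_pois: list[float]
    recall_defined: bool = True
    precision_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_p": self.n_p,
            "n_o": self.n_o,
            "n_e": self.n_e,
            "n_c": self.n_c,
            "recall": self.recall,
            "precision": self.precision,
            "ratio_p": self.ratio_p,
            "ratio_o": self.ratio_o,
            "correct_pois": list(self.correct_pois),
            "recall_defined": self.recall_defined,
            "precision_defined": self.precision_defined,
        }


def _candidate_times(candidates) -> np.ndarray:
    times = [
        c.time if isinstance(c, PoICandidate) else float(c) for c in candidates
    ]
    return np.asarray(times, dtype=float)


def _event_times(events) -> np.ndarray:
    if isinstance(events, EventAnnotation):
        return events.times
    return np.asarray([float(t) for t in events], dtype=float)


def match_events(
    candidates, events, tolerance: float = 10.0
) -> tuple[int, list[float]]:
    """Count captured event points and collect the matched candidates.

    Returns ``(n_c, correct_pois)`` where n_c is the number of event
    points with at least one candidate within ``|t_c - t_e| <= tolerance``
    and correct_pois lists the distinct candidate times matched to at
    least one event point (sorted).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    cand = _candidate_times(candidates)
    ev = _event_times(events)
    if len(cand) == 0 or len(ev) == 0:
        return 0, []
    dist = np.abs(cand[:, None] - ev[None, :])  # candidates x events
    hit = dist <= tolerance
    n_c = int(hit.any(axis=0).sum())
    correct = sorted(set(cand[hit.any(axis=1)].tolist()))
    return n_c, correct


def evaluate(
    series_len: int,
    candidates,
    n_o: int,
    events=None,
    tolerance: float = 10.0,
) -> EvalReport:
    """Assemble the full report; ``events=None`` yields the ratio-only view.

    Degenerate denominators never raise: with n_p = 0 precision is
    reported as 0 with ``precision_defined=False``, and likewise recall
    when n_e = 0, so batch runs always complete.
    """
    if series_len <= 0:
        raise ValueError("series_len must be positive")
    n_p = len(candidates)
    ev = _event_times(events) if events is not None else np.zeros(0)
    n_e = len(ev)
    n_c, correct = match_events(candidates, ev, tolerance)
    recall_defined = n_e > 0
    precision_defined = n_p > 0
    return EvalReport(
        n=series_len,
        n_p=n_p,
        n_o=n_o,
        n_e=n_e,
        n_c=n_c,
        recall=n_c / n_e if recall_defined else 0.0,
        precision=n_c / n_p if precision_defined else 0.0,
        ratio_p=n_p / series_len,
        ratio_o=n_o / series_len,
        correct_pois=correct,
        recall_defined=recall_defined,
        precision_defined=precision_defined,
    )
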