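"""Model/Results interface tying the pipeline together.

:class:`PoIModel` is constructed from a uniformly sampled feature series
(or a DataFrame / CSV) plus the detection configuration; ``fit()`` runs
standardisation, composite construction (or single-feature selection),
two-stage change scoring, thresholding and excursion extraction, and
returns a :class:`PoIResults` carrying the scores, threshold, candidates
and summary/plot/evaluate methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composite as comp
from .changefinder import ChangeFinderParams, ChangeScoreSeries, change_score
from .errors import CompositeSpecError
from .evaluation import EvalReport, evaluate
from .io import EventAnnotation, FeatureSeries, read_feature_csv, regularize
from .poi import (
    PoICandidate,
    ThresholdPolicy,
    compute_threshold,
    count_exceedance,
    extract_poi,
    raw_threshold_baseline,
)


class PoIModel:
    """Point-of-interest detector over a facial-feature time series.

    Parameters
    ----------
    series : FeatureSeries
        Uniform, gap-free feature series (see :func:`poifinder.io.regularize`).
    spec : CompositeSpec, optional
        Composite to score (default: the Smile scale).  Ignored when
        ``feature`` is given.
    feature : str, optional
        Score this single standardised feature instead of a composite.
    params : ChangeFinderParams, optional
        Detector parameters (default order=1, r=0.025, w=5).
    threshold : ThresholdPolicy, optional
        Threshold mode/burn-in (default gamma = mu_S + sigma_S, 30 s
        burn-in).
    tolerance : float
        Event-matching window in seconds (default 10).
    """

    def __init__(
        self,
        series: FeatureSeries,
        spec: comp.CompositeSpec | None = None,
        feature: str | None = None,
        params: ChangeFinderParams | None = None,
        threshold: ThresholdPolicy | None = None,
        tolerance: float = 10.0,
        ddof: int = 0,
    ):
        self.series = series
        self.spec = spec if spec is not None else comp.SMILE_SCALE
        self.feature = feature
        if feature is not None and feature not in series.names:
            raise CompositeSpecError(f"feature {feature!r} not in series")
        self.params = params or ChangeFinderParams()
        self.threshold_policy = threshold or ThresholdPolicy()
        self.tolerance = tolerance
        self.ddof = ddof

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_column: str = "t", step: float = 1.0, **kwargs
    ) -> "PoIModel":
        """Build from a tidy DataFrame with a time column in seconds; the
        raw rows are regularised (forward fill) onto a ``step`` grid."""
        records = []
        names = [c for c in df.columns if c != time_column]
        for _, row in df.iterrows():
            for name in names:
                v = row[name]
                records.append(
                    (float(row[time_column]), name, float(v) if pd.notna(v) else np.nan)
                )
        from .io import RawRecording

        raw = RawRecording(records=records, feature_names=names)
        return cls(regularize(raw, step=step), **kwargs)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        column_spec: dict[str, str] | None = None,
        step: float = 1.0,
        **kwargs,
    ) -> "PoIModel":
        raw = read_feature_csv(path, column_spec=column_spec)
        return cls(regularize(raw, step=step), **kwargs)

    def fit(self) -> "PoIResults":
        z, stats = comp.standardize(self.series, ddof=self.ddof)
        if self.feature is not None:
            target = z.column(self.feature)
            target_name = self.feature
        else:
            target = comp.compose(z, self.spec)
            target_name = self.spec.name
        scores = change_score(
            target,
            self.params,
            start_time=self.series.start_time,
            step=self.series.step,
            burn_in=self.threshold_policy.burn_in,
        )
        if self.threshold_policy.mode == "raw_mean_nsd":
            candidates, gamma = raw_threshold_baseline(
                target,
                self.threshold_policy.n_sigma,
                burn_in=self.threshold_policy.burn_in,
                start_time=self.series.start_time,
                step=self.series.step,
            )
            raw_series = ChangeScoreSeries(
                times=scores.times,
                scores=target,
                flagged=np.zeros(len(target), dtype=bool),
                burn_in=self.threshold_policy.burn_in,
            )
            n_o = count_exceedance(raw_series, gamma)
        else:
            gamma = compute_threshold(scores, self.threshold_policy)
            candidates = extract_poi(scores, gamma)
            n_o = count_exceedance(scores, gamma)
        return PoIResults(
            model=self,
            target_name=target_name,
            target=target,
            standardization=stats,
            scores=scores,
            gamma=gamma,
            candidates=candidates,
            n_o=n_o,
        )


@dataclass
class PoIResults:
    """Fitted detection results.

    Attributes
    ----------
    target : the scored sequence (composite X(t) or a z-scored feature)
    scores : two-stage change scores S(t)
    gamma : extraction threshold
    candidates : extracted PoI candidates (one per excursion)
    n_o : post-burn-in samples above gamma
    """

    model: PoIModel
    target_name: str
    target: np.ndarray
    standardization: comp.StandardizationStats
    scores: ChangeScoreSeries
    gamma: float
    candidates: list[PoICandidate]
    n_o: int

    @property
    def n(self) -> int:
        return self.scores.n

    @property
    def n_p(self) -> int:
        return len(self.candidates)

    @property
    def candidate_times(self) -> np.ndarray:
        return np.array([c.time for c in self.candidates])

    def evaluate(
        self, events: EventAnnotation, tolerance: float | None = None
    ) -> EvalReport:
        """Recall/precision of the candidates against annotated events."""
        tol = self.model.tolerance if tolerance is None else tolerance
        return evaluate(self.n, self.candidates, self.n_o, events, tol)

    def summary(self, events: EventAnnotation | None = None) -> str:
        """Plain-text summary table of the fit (and metrics if events given)."""
        p = self.model.params
        lines = [
            "Point-of-interest detection results",
            "=" * 45,
            f"{'target':<28}{self.target_name}",
            f"{'samples (n)':<28}{self.n}",
            f"{'AR order / discount r':<28}{p.order} / {p.discount}",
            f"{'smoothing w / w2':<28}{p.smooth_width} / {p.resolved_second_width}",
            f"{'threshold mode':<28}{self.model.threshold_policy.mode}",
            f"{'burn-in [s]':<28}{self.model.threshold_policy.burn_in}",
            f"{'gamma':<28}{self.gamma:.6g}",
            f"{'candidates (n_p)':<28}{self.n_p}",
            f"{'exceedances (n_o)':<28}{self.n_o}",
            f"{'n_p/n':<28}{self.n_p / self.n:.4f}",
            f"{'n_o/n':<28}{self.n_o / self.n:.4f}",
        ]
        if events is not None:
            rep = self.evaluate(events)
            lines += [
                f"{'event points (n_e)':<28}{rep.n_e}",
                f"{'correct (n_c)':<28}{rep.n_c}",
                f"{'recall n_c/n_e':<28}{rep.recall:.4f}",
                f"{'precision n_c/n_p':<28}{rep.precision:.4f}",
            ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample table: t, target value, score, gamma, candidate flag."""
        cand_times = set(self.candidate_times.tolist())
        return pd.DataFrame(
            {
                "t": self.scores.times,
                "value": self.target,
                "score": self.scores.scores,
                "gamma": self.gamma,
                "is_candidate": [t in cand_times for t in self.scores.times],
                "flagged": self.scores.flagged,
            }
        )

    def plot(self, ax=None, events: EventAnnotation | None = None):
        """Score/threshold plot: S(t), the raw target, gamma, candidates
        and (optionally) event points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        ax.plot(self.scores.times, self.scores.scores, color="tab:red",
                lw=1.0, label="change score S(t)")
        ax.axhline(self.gamma, color="black", ls="--", lw=0.8,
                   label=r"threshold $\gamma$")
        if self.n_p:
            ax.plot(self.candidate_times,
                    [c.score for c in self.candidates],
                    "o", color="tab:red", ms=5, label="PoI candidates")
        if events is not None:
            for t, pol in events.events:
                ax.axvline(t, color="gold" if pol == "happy_onset" else "tab:cyan",
                           lw=0.8, alpha=0.8)
        ax2 = ax.twinx()
        ax2.plot(self.scores.times, self.target, color="tab:blue", lw=0.6,
                 alpha=0.5, label=self.target_name)
        ax.set_xlabel("elapsed time [s]")
        ax.set_ylabel("change score")
        ax2.set_ylabel(self.target_name)
        ax.legend(loc="upper right", fontsize=8)
        return ax
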