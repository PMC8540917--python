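"""Synthetic facial-feature recordings with ground-truth event points.

No public dataset of per-second facial feature values from care recipients
exists, so every stage of the pipeline is exercised on generated data: a
neutral baseline per feature, smile episodes that shift each feature by a
signed delta (ramped linearly over 2 s), Gaussian measurement noise,
optional sparse outlier spikes, and an observation cadence of 1 s (or ~3 s
for the padded regime).  Baselines and deltas default to measured
neutral/smiling averages of an expressive adult face: h9 0.8199 (+0.0715),
a1 0.4270 (-0.0289), a3 0.0901 (-0.0398), a4 1.0431 (-0.0614).

``expression_gain`` scales all deltas at once: 1 emulates an expressive
subject, values well below 1 emulate the attenuated, micro-expression
regime seen in subjects with hardened facial muscles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelConfigError
from .io import EventAnnotation, RawRecording

DEFAULT_BASELINE = {"h9": 0.8199, "a1": 0.4270, "a3": 0.0901, "a4": 1.0431}
DEFAULT_DELTAS = {"h9": 0.0715, "a1": -0.0289, "a3": -0.0398, "a4": -0.0614}
DEFAULT_EPISODES = [(120.0, 300.0), (500.0, 680.0), (880.0, 1060.0)]

#: duration of the linear on/off ramp at episode boundaries (seconds)
RAMP_SECONDS = 2.0


@dataclass
class EpisodeModel:
    """Generative model of one recording session.

    Parameters
    ----------
    n_seconds : total recording length (default 1200 s, a 20 min session).
    episodes : (onset, offset) pairs in seconds; must not overlap.
        Defaults to three three-minute smiles separated by similar
        neutral stretches, the minute-scale episodic regime of a filmed
        care session.
    expression_gain : multiplier in (0, 1] on all feature deltas;
        1 = expressive face, << 1 = micro-expressions.
    feature_deltas / baseline : per-feature episode shift and neutral level.
    noise_sd : Gaussian measurement noise sd (default 0.005, roughly a
        tenth of the smallest feature delta).
    frame_interval : seconds between raw observations (1, or ~3 for the
        sparse-camera regime that needs forward-fill padding).
    outlier_rate : per-sample probability of a +-10*noise_sd spike.
    seed : RNG seed; output is fully reproducible from it.
    """

    n_seconds: float = 1200.0
    episodes: list[tuple[float, float]] | None = None
    expression_gain: float = 1.0
    feature_deltas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELTAS)
    )
    baseline: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    noise_sd: float = 0.005
    frame_interval: float = 1.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.episodes is None:
            # default episodes, keeping only those inside the chosen span
            self.episodes = [
                e for e in DEFAULT_EPISODES if e[1] <= self.n_seconds
            ]
        if self.expression_gain <= 0:
            raise ModelConfigError("expression_gain must be > 0")
        if set(self.feature_deltas) != set(self.baseline):
            raise ModelConfigError("feature_deltas and baseline must share features")
        eps = sorted(self.episodes)
        for onset, offset in eps:
            if not (0 <= onset < offset <= self.n_seconds):
                raise ModelConfigError(
                    f"episode ({onset}, {offset}) outside [0, {self.n_seconds}]"
                )
        for (_, off_a), (on_b, _) in zip(eps, eps[1:]):
            if on_b < off_a:
                raise ModelConfigError("episodes must not overlap")


def _episode_level(t: np.ndarray, episodes: list[tuple[float, float]]) -> np.ndarray:
    """Smoothed 0/1 indicator: linear rise over [onset, onset+2], plateau,
    linear fall over [offset, offset+2]."""
    level = np.zeros_like(t, dtype=float)
    for onset, offset in episodes:
        up = np.clip((t - onset) / RAMP_SECONDS, 0.0, 1.0)
        down = np.clip((t - offset) / RAMP_SECONDS, 0.0, 1.0)
        level += up - down
    return np.clip(level, 0.0, 1.0)


def generate(model: EpisodeModel) -> tuple[RawRecording, EventAnnotation]:
    """Draw one labelled recording from the model.

    Each feature follows baseline + gain * delta * episode_level(t) plus
    i.i.d. Gaussian noise, sampled every ``frame_interval`` seconds;
    outliers are isolated spikes of +-10 noise sd.  One ``happy_onset``
    event is emitted per episode start and one ``happy_offset`` per end.
    """
    rng = np.random.default_rng(model.seed)
    t = np.arange(0.0, model.n_seconds, model.frame_interval)
    level = _episode_level(t, model.episodes)
    names = list(model.feature_deltas)
    records: list[tuple[float, str, float]] = []
    columns = {}
    for name in names:
        x = (
            model.baseline[name]
            + model.expression_gain * model.feature_deltas[name] * level
        )
        x = x + rng.normal(0.0, model.noise_sd, size=len(t))
        if model.outlier_rate > 0:
            spikes = rng.random(len(t)) < model.outlier_rate
            signs = rng.choice([-1.0, 1.0], size=len(t))
            x = x + spikes * signs * 10.0 * model.noise_sd
        columns[name] = x
    for i, ti in enumerate(t):
        for name in names:
            records.append((float(ti), name, float(columns[name][i])))
    events = []
    for onset, offset in sorted(model.episodes):
        events.append((float(onset), "happy_onset"))
        events.append((float(offset), "happy_offset"))
    return (
        RawRecording(records=records, feature_names=names),
        EventAnnotation(events=events),
    )


def generate_score_testvector(kind: str, **params) -> np.ndarray:
    """Small deterministic vectors for excursion/matching oracle tests."""
    if kind == "constant":
        length = int(params.get("length", 10))
        value = float(params.get("value", 3.0))
        return np.full(length, value)
    if kind == "step":
        length = int(params.get("length", 10))
        change_at = int(params.get("change_at", length // 2))
        pre = float(params.get("pre", 0.0))
        post = float(params.get("post", 5.0))
        out = np.full(length, pre)
        out[change_at:] = post
        return out
    if kind == "two_excursions":
        return np.array([0.0, 3.0, 0.0, 0.0, 5.0, 6.0, 0.0])
    raise ValueError(f"unknown test-vector kind {kind!r}")
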