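"""Composite feature construction: z-standardisation, weighted combination,
and derivation of weight reports from paired neutral/smiling samples.

A composite feature value is a purpose-built linear combination of
z-standardised single features.  The built-in "Smile scale"

    X = 2 z(h9) - z(a1) - z(a3) - 2 z(a4)

targets happiness-related facial movement: mouth width (h9) grows with a
smile while eyebrow height (a1), eyes opening (a3) and mouth-corner
lowering (a4) shrink, and the mouth-related movements are roughly twice
the size of the eye-related ones — hence the +-2/+-1 integer weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CompositeSpecError, DegenerateFeatureError
from .io import FeatureSeries


@dataclass(frozen=True)
class CompositeSpec:
    """A named linear combination over standardised features."""

    name: str
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise CompositeSpecError("composite needs at least one nonzero weight")

    def to_config(self) -> dict:
        return {"name": self.name, "coefficients": dict(self.coefficients)}

    @classmethod
    def from_config(cls, cfg: dict) -> "CompositeSpec":
        return cls(name=cfg["name"], coefficients=dict(cfg["coefficients"]))


#: default composite: Smile scale X = 2 h9 - a1 - a3 - 2 a4 (on z-values)
SMILE_SCALE = CompositeSpec(
    name="smile_scale", coefficients={"h9": 2.0, "a1": -1.0, "a3": -1.0, "a4": -2.0}
)


@dataclass
class StandardizationStats:
    """Per-feature mean and standard deviation used for z-scoring."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class WeightReport:
    """Per-feature neutral/smiling means, their difference, and the ratio
    of each |difference| to the reference feature's."""

    names: list[str]
    reference: str
    neutral_mean: np.ndarray
    smiling_mean: np.ndarray
    difference: np.ndarray
    ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neutral_mean": self.neutral_mean,
                "smiling_mean": self.smiling_mean,
                "difference": self.difference,
                "ratio": self.ratio,
            },
            index=self.names,
        )


def standardize(
    series: FeatureSeries, ddof: int = 0
) -> tuple[FeatureSeries, StandardizationStats]:
    """Z-score every feature column: z(t) = (x(t) - mu_x) / sigma_x.

    Statistics are computed retrospectively over the full series
    (population sigma by default, ``ddof`` configurable).  A constant
    feature has sigma_x = 0 and raises, naming the offending feature.
    """
    mu = series.values.mean(axis=0)
    sd = series.values.std(axis=0, ddof=ddof)
    for name, s in zip(series.names, sd):
        if s == 0 or not np.isfinite(s):
            raise DegenerateFeatureError(f"feature {name!r} is constant (sigma=0)")
    z = (series.values - mu) / sd
    stats = StandardizationStats(names=list(series.names), mean=mu, sd=sd)
    return series.replace(values=z), stats


def compose(z_series: FeatureSeries, spec: CompositeSpec) -> np.ndarray:
    """Pointwise linear combination X(t) of standardised features."""
    missing = [f for f in spec.coefficients if f not in z_series.names]
    if missing:
        raise CompositeSpecError(
            f"composite {spec.name!r} references absent features: {missing}"
        )
    out = np.zeros(z_series.n)
    for feature, weight in spec.coefficients.items():
        out += weight * z_series.column(feature)
    return out


def derive_weights(
    neutral: pd.DataFrame, smiling: pd.DataFrame, reference: str
) -> WeightReport:
    """Summarise paired neutral/smiling samples into a weight report.

    For each feature: the two state means, their difference
    (smiling - neutral), and |difference| / |reference difference|.  The
    ratios inform — but deliberately do not equal — composite weights,
    since the degree of facial movement varies between individuals.
    """
    names = list(neutral.columns)
    if list(smiling.columns) != names:
        raise CompositeSpecError("neutral and smiling tables must share features")
    if len(neutral) == 0 or len(smiling) == 0:
        raise CompositeSpecError("sample tables must be non-empty")
    if reference not in names:
        raise CompositeSpecError(f"reference feature {reference!r} not in tables")
    n_mean = neutral.to_numpy(dtype=float).mean(axis=0)
    s_mean = smiling.to_numpy(dtype=float).mean(axis=0)
    diff = s_mean - n_mean
    ref_diff = diff[names.index(reference)]
    if ref_diff == 0:
        raise DegenerateFeatureError(
            f"reference feature {reference!r} has zero difference"
        )
    ratio = np.abs(diff) / abs(ref_diff)
    return WeightReport(
        names=names,
        reference=reference,
        neutral_mean=n_mean,
        smiling_mean=s_mean,
        difference=diff,
        ratio=ratio,
    )
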