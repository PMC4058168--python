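"""Threshold classification of cases and cohort-level metrics.

Each case contributes two scalars: the FT-squared area (pathological cases
fall *below* its threshold) and the ramp-weighted std-envelope feature
(pathological cases fall *above* its threshold).  The two votes can be
combined in several ways; the default calls a case pathological when either
feature votes pathological.  Ties at a threshold resolve to healthy.  The
default threshold values are carried over from the clinical study that
motivated the features; they are not transferable across feature
normalizations and should be recalibrated on a labeled cohort
(:func:`calibrate_thresholds`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ClassifierConfig",
    "CaseCall",
    "CohortMetrics",
    "call_case",
    "cohort_metrics",
    "best_threshold_accuracy",
    "calibrate_thresholds",
    "LABELS",
    "COMBINE_RULES",
]

LABELS = ("pathological", "healthy_elderly_like", "healthy_young_like")
COMBINE_RULES = ("either_positive", "either_agrees", "single_ft2", "single_ramp")


@dataclass
class ClassifierConfig:
    ft2_threshold: float = 27.3
    ramp_threshold: float = -0.1
    young_ft2_floor: float = 33.8
    combine_rule: Literal[
        "either_positive", "either_agrees", "single_ft2", "single_ramp"
    ] = "either_positive"
    suspected_margin: float = 0.0  # width of an optional "suspected" band

    def __post_init__(self) -> None:
        for name in ("ft2_threshold", "ramp_threshold", "young_ft2_floor"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.combine_rule not in COMBINE_RULES:
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")


@dataclass
class CaseCall:
    label: str
    per_feature_calls: tuple[bool, bool]  # (ft2 votes pathological, ramp votes)


@dataclass
class CohortMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float


def _feature_pair(features) -> tuple[float, float]:
    if isinstance(features, (tuple, list)) and len(features) == 2:
        ft2, ramp = features
    else:
        ft2 = getattr(features, "ft2_area", None)
        ramp = getattr(features, "ramp_feature", None)
    if ft2 is None or ramp is None or not (
        math.isfinite(ft2) and math.isfinite(ramp)
    ):
        raise ValueError("both ft2_area and ramp_feature must be present and finite")
    return float(ft2), float(ramp)


def call_case(features, config: ClassifierConfig | None = None) -> CaseCall:
    """Three-way call from the two feature scalars.

    ``features`` is a :class:`~cartwave.spectral_features.CaseFeatures` (or
    any object with ``ft2_area`` and ``ramp_feature``, or a ``(ft2, ramp)``
    pair).  The FT2 vote is pathological iff ``ft2 < ft2_threshold``; the
    ramp vote iff ``ramp > ramp_threshold`` (strict: ties are healthy).
    A non-pathological case is young-like when its FT2 area reaches
    ``young_ft2_floor`` and the ramp vote is negative; otherwise it is
    elderly-like.  With ``suspected_margin > 0`` a case whose features all
    sit within the margin of their thresholds is labeled ``"suspected"``.
    """
    cfg = config or ClassifierConfig()
    ft2, ramp = _feature_pair(features)
    v_ft2 = ft2 < cfg.ft2_threshold
    v_ramp = ramp > cfg.ramp_threshold
    if cfg.combine_rule == "either_positive":
        pathological = v_ft2 or v_ramp
    elif cfg.combine_rule == "either_agrees":
        pathological = v_ft2 and v_ramp
    elif cfg.combine_rule == "single_ft2":
        pathological = v_ft2
    else:
        pathological = v_ramp
    if cfg.suspected_margin > 0 and (
        abs(ft2 - cfg.ft2_threshold) <= cfg.suspected_margin
        and abs(ramp - cfg.ramp_threshold) <= cfg.suspected_margin
    ):
        return CaseCall(label="suspected", per_feature_calls=(v_ft2, v_ramp))
    if pathological:
        label = "pathological"
    elif ft2 >= cfg.young_ft2_floor and not v_ramp:
        label = "healthy_young_like"
    else:
        label = "healthy_elderly_like"
    return CaseCall(label=label, per_feature_calls=(v_ft2, v_ramp))


def cohort_metrics(
    calls: Sequence[CaseCall | str], truth: Sequence[str]
) -> CohortMetrics:
    """Confusion counts and rates with ``pathological`` as the positive class.

    A rate with a zero denominator is reported as NaN with a warning.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have equal length")
    pred = [
        (c.label if isinstance(c, CaseCall) else c) == "pathological" for c in calls
    ]
    actual = [t == "pathological" for t in truth]
    tp = sum(p and a for p, a in zip(pred, actual))
    fp = sum(p and not a for p, a in zip(pred, actual))
    tn = sum(not p and not a for p, a in zip(pred, actual))
    fn = sum(not p and a for p, a in zip(pred, actual))
    if tp + fn:
        sens = tp / (tp + fn)
    else:
        warnings.warn("no positive cases in truth; sensitivity undefined")
        sens = math.nan
    if tn + fp:
        spec = tn / (tn + fp)
    else:
        warnings.warn("no negative cases in truth; specificity undefined")
        spec = math.nan
    return CohortMetrics(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec)


def best_threshold_accuracy(
    values: Iterable[float], truth: Iterable[int]
) -> tuple[float, float]:
    """Best single-threshold accuracy over an exhaustive midpoint scan.

    Candidate thresholds are the midpoints of consecutive sorted unique
    values plus one candidate below the minimum (the trivial one-sided
    split); for each candidate the better of the two orientations of
    ``value > threshold`` is scored.  Ties resolve to the lowest threshold.
    """
    values = np.asarray(list(values), dtype=float)
    truth = np.asarray(list(truth))
    if values.shape != truth.shape or values.size == 0:
        raise ValueError("values and truth must be equal-length and non-empty")
    classes = np.unique(truth)
    if classes.size < 2:
        raise ValueError("need at least one case per class")
    y = (truth == classes[1]).astype(int)
    uniq = np.unique(values)
    if uniq.size == 1:
        maj = max(y.mean(), 1 - y.mean())
        return float(uniq[0]), float(maj)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best_thr, best_acc = candidates[0], -1.0
    for thr in candidates:
        pred = (values > thr).astype(int)
        acc = max((pred == y).mean(), (1 - pred == y).mean())
        if acc > best_acc + 1e-12:
            best_thr, best_acc = thr, acc
    return float(best_thr), float(best_acc)


def calibrate_thresholds(
    ft2_values: Sequence[float],
    ramp_values: Sequence[float],
    pathological: Sequence[bool],
    combine_rule: str = "either_positive",
) -> ClassifierConfig:
    """Fit both thresholds on a labeled cohort by the exhaustive scan.

    The FT2 floor for the young-like call is set to the fitted FT2
    threshold, i.e. any clearly non-pathological FT2 area qualifies.
    """
    y = np.asarray(pathological, dtype=bool).astype(int)
    thr_ft2, _ = best_threshold_accuracy(ft2_values, y)
    thr_ramp, _ = best_threshold_accuracy(ramp_values, y)
    return ClassifierConfig(
        ft2_threshold=thr_ft2,
        ramp_threshold=thr_ramp,
        young_ft2_floor=thr_ft2,
        combine_rule=combine_rule,
    )
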