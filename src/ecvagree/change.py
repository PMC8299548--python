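"""Uncertainty-interval change detection for consecutive observations.

Each observation of an essential climate variable (ECV) carries a value
``v`` and a one-sigma uncertainty half-width ``u``, defining the interval
``[v - u, v + u]`` of plausible true values.  The confidence that a change
between two consecutive observations is real is the non-overlap fraction
of the two intervals,

    C_f = 100 * (1 - O_l / f_l),

where ``O_l`` is the length of the intersection of the two intervals
(clamped at zero when they are disjoint) and ``f_l`` the length of their
union envelope, i.e. the span from the lower of the two interval floors to
the higher of the two ceilings.  Disjoint intervals give 100% confidence;
a zero value difference (or a degenerate zero-width envelope) gives 0%.

A change is classified as an *increase* or *decrease* only when its
confidence strictly exceeds a threshold (default 50%); otherwise it is
*non-significant* (NC).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ChangeClass",
    "Observation",
    "ChangeRecord",
    "ClassificationConfig",
    "confidence_level",
    "classify_change",
    "classify_series",
    "confidence_level_arrays",
    "classify_arrays",
]


class ChangeClass(enum.IntEnum):
    """Change category; integer codes match contingency-table indices."""

    DECREASE = 1
    NON_SIGNIFICANT = 2
    INCREASE = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class Observation:
    """A single ECV observation: value, one-sigma uncertainty, validity.

    Parameters
    ----------
    value : float
        ECV magnitude. LAI is a dimensionless area ratio >= 0; FAPAR is a
        fraction in [0, 1].
    uncertainty : float
        One-sigma half-width in the same units, >= 0.
    time_index : int
        Ordinal composite index (position in the series).
    valid : bool
        False when the observation is missing or QC-flagged.
    """

    value: float
    uncertainty: float
    time_index: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.uncertainty < 0:
            raise ValueError(
                f"uncertainty must be >= 0, got {self.uncertainty!r}"
            )

    @property
    def lower(self) -> float:
        return self.value - self.uncertainty

    @property
    def upper(self) -> float:
        return self.value + self.uncertainty


@dataclass(frozen=True)
class ChangeRecord:
    """One consecutive-step change with its confidence diagnostics.

    Attributes
    ----------
    delta : float
        Signed value difference ``v_{t+1} - v_t``.
    confidence : float
        Confidence level C_f in percent, in [0, 100].
    overlap_length : float
        Interval intersection length O_l (>= 0; 0 when disjoint).
    full_range : float
        Union envelope length f_l (>= 0).
    """

    delta: float
    confidence: float
    overlap_length: float
    full_range: float

    def classify(self, config: "ClassificationConfig | None" = None,
                 threshold: float | None = None) -> ChangeClass:
        cfg = config if config is not None else ClassificationConfig()
        thr = threshold if threshold is not None else cfg.confidence_threshold
        return classify_change(self, ClassificationConfig(confidence_threshold=thr))


@dataclass(frozen=True)
class ClassificationConfig:
    """Threshold configuration for change classification.

    ``confidence_threshold`` applies to both ECVs unless an independent
    per-ECV threshold is given.  Comparison is strict: a change is
    significant only when C_f is *above* the threshold.
    """

    confidence_threshold: float = 50.0
    lai_threshold: float | None = None
    fapar_threshold: float | None = None

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "lai_threshold", "fapar_threshold"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {val!r}")

    @property
    def lai(self) -> float:
        return self.confidence_threshold if self.lai_threshold is None else self.lai_threshold

    @property
    def fapar(self) -> float:
        return self.confidence_threshold if self.fapar_threshold is None else self.fapar_threshold


def confidence_level(prev: Observation, next: Observation) -> ChangeRecord:
    """Confidence level of the change between two consecutive observations.

    Computes the interval-overlap statistic: O_l is the (clamped)
    intersection length of ``[v-u, v+u]`` at t and t+1, f_l the span of
    their union envelope, and C_f = 100 * (1 - O_l / f_l).  Disjoint
    intervals yield C_f = 100; a zero delta or degenerate envelope yields
    C_f = 0.

    Raises
    ------
    ValueError
        If either observation is invalid or carries a negative uncertainty.
    """
    for obs in (prev, next):
        if not obs.valid:
            raise ValueError("confidence_level requires valid observations; "
                             "mask invalid steps upstream")
        if obs.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")

    delta = next.value - prev.value
    overlap = max(0.0, min(prev.upper, next.upper) - max(prev.lower, next.lower))
    full = max(prev.upper, next.upper) - min(prev.lower, next.lower)
    if delta == 0.0 or full <= 0.0:
        conf = 0.0
        overlap = min(overlap, full)
    else:
        conf = 100.0 * (1.0 - overlap / full)
    # guard tiny negatives from float cancellation
    conf = min(100.0, max(0.0, conf))
    return ChangeRecord(delta=delta, confidence=conf,
                        overlap_length=overlap, full_range=full)


def classify_change(record: ChangeRecord,
                    config: ClassificationConfig | None = None) -> ChangeClass:
    """Classify a change record as increase / decrease / non-significant.

    Significant only when ``C_f > threshold`` (strict); the sign of delta
    decides the direction.
    """
    cfg = config or ClassificationConfig()
    thr = cfg.confidence_threshold
    if record.confidence > thr:
        if record.delta > 0:
            return ChangeClass.INCREASE
        if record.delta < 0:
            return ChangeClass.DECREASE
    return ChangeClass.NON_SIGNIFICANT


def classify_series(
    lai: Sequence[Observation],
    fapar: Sequence[Observation],
    config: ClassificationConfig | None = None,
) -> list[tuple[ChangeClass, ChangeClass]]:
    """Classify simultaneous consecutive changes of two aligned ECV series.

    A step t -> t+1 is emitted only when both ECVs are valid at both ends
    (pairwise-complete masking; no gap filling).  Output length is at most
    ``len(series) - 1``.

    Raises
    ------
    ValueError
        If the series differ in length, are shorter than 2, or their time
        indices disagree.
    """
    cfg = config or ClassificationConfig()
    if len(lai) != len(fapar):
        raise ValueError(f"series misaligned: {len(lai)} vs {len(fapar)} observations")
    if len(lai) < 2:
        raise ValueError("need at least two observations per series")
    for a, b in zip(lai, fapar):
        if a.time_index != b.time_index:
            raise ValueError(
                f"time misalignment at indices {a.time_index} vs {b.time_index}")

    pairs: list[tuple[ChangeClass, ChangeClass]] = []
    for t in range(len(lai) - 1):
        quad = (lai[t], lai[t + 1], fapar[t], fapar[t + 1])
        if not all(o.valid for o in quad):
            continue
        rec_l = confidence_level(lai[t], lai[t + 1])
        rec_f = confidence_level(fapar[t], fapar[t + 1])
        cls_l = classify_change(rec_l, ClassificationConfig(confidence_threshold=cfg.lai))
        cls_f = classify_change(rec_f, ClassificationConfig(confidence_threshold=cfg.fapar))
        pairs.append((cls_l, cls_f))
    return pairs


# ---------------------------------------------------------------------------
# vectorised forms used by the gridded pipeline


def confidence_level_arrays(values: np.ndarray, uncertainties: np.ndarray,
                            axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised C_f along the time axis of a stack.

    Parameters
    ----------
    values, uncertainties : ndarray
        Arrays with a leading (or ``axis``) time dimension of length T.

    Returns
    -------
    delta, confidence : ndarray
        Arrays of shape (T-1, ...) with the signed step difference and the
        confidence level in percent.  NaN inputs propagate to NaN outputs.
    """
    v = np.moveaxis(np.asarray(values, dtype=float), axis, 0)
    u = np.moveaxis(np.asarray(uncertainties, dtype=float), axis, 0)
    if v.shape != u.shape:
        raise ValueError("values and uncertainties must share a shape")
    if u.size and np.any(u < 0):
        raise ValueError("uncertainty must be >= 0")

    lo, hi = v - u, v + u
    lo0, lo1 = lo[:-1], lo[1:]
    hi0, hi1 = hi[:-1], hi[1:]
    delta = v[1:] - v[:-1]
    overlap = np.maximum(0.0, np.minimum(hi0, hi1) - np.maximum(lo0, lo1))
    full = np.maximum(hi0, hi1) - np.minimum(lo0, lo1)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = 100.0 * (1.0 - overlap / full)
    conf = np.where((delta == 0.0) | (full <= 0.0), 0.0, conf)
    conf = np.clip(conf, 0.0, 100.0)
    nan = np.isnan(delta)
    conf = np.where(nan, np.nan, conf)
    return (np.moveaxis(delta, 0, axis), np.moveaxis(conf, 0, axis))


def classify_arrays(delta: np.ndarray, confidence: np.ndarray,
                    threshold: float = 50.0) -> np.ndarray:
    """Vectorised classification from precomputed deltas and confidences.

    Returns an integer array with codes 1 (decrease), 2 (non-significant),
    3 (increase) and 0 where inputs are NaN (masked step).
    """
    delta = np.asarray(delta, dtype=float)
    confidence = np.asarray(confidence, dtype=float)
    out = np.full(delta.shape, int(ChangeClass.NON_SIGNIFICANT), dtype=np.int8)
    sig = confidence > threshold
    out[sig & (delta > 0)] = int(ChangeClass.INCREASE)
    out[sig & (delta < 0)] = int(ChangeClass.DECREASE)
    out[np.isnan(delta) | np.isnan(confidence)] = 0
    return out
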