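"""Contingency table and agreement/bias metrics for simultaneous changes.

Simultaneous LAI x FAPAR change classes populate a 3x3 contingency table
with rows = LAI class and columns = FAPAR class, where index 1 = decrease,
2 = non-significant, 3 = increase.  Five metrics summarise one table:

* ``OA``  overall agreement, the diagonal fraction (n11+n22+n33)/N;
* ``Si``  increase sensitivity, the Dice coefficient of simultaneous
  significant increases, 2*n33 / (2*n33 + n32 + n31 + n23 + n13);
* ``Sd``  decrease sensitivity, 2*n11 / (2*n11 + n12 + n13 + n21 + n31);
* ``Bnc`` non-coherent bias (n13 - n31)/N, the imbalance between the two
  physically contradictory significant cells;
* ``Bns`` non-significant bias ((n21 + n23) - (n12 + n32))/N, positive
  when LAI changes are non-significant while FAPAR's are significant more
  often than the converse.

Metrics are carried internally as fractions in [0, 1] (biases in [-1, 1]);
undefined cases (N = 0, zero Dice denominator) propagate as NaN, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .change import ChangeClass

__all__ = [
    "ContingencyTable",
    "AgreementMetrics",
    "METRIC_NAMES",
    "tabulate",
    "overall_agreement",
    "sensitivity_increase",
    "sensitivity_decrease",
    "bias_noncoherent",
    "bias_nonsignificant",
    "compute_metrics",
    "metrics_from_counts",
]

METRIC_NAMES = ("OA", "Si", "Sd", "Bnc", "Bns")


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 counts of simultaneous change classes (rows LAI, cols FAPAR)."""

    counts: np.ndarray  # shape (3, 3), int

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def cell(self, lai_class: int, fapar_class: int) -> int:
        """Count n_ij with 1-based class codes (1=dec, 2=NC, 3=inc)."""
        return int(self.counts[lai_class - 1, fapar_class - 1])

    def transpose(self) -> "ContingencyTable":
        """Swap the roles of the two ECVs."""
        return ContingencyTable(self.counts.T.copy())

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        labels = ["decrease", "non_significant", "increase"]
        return pd.DataFrame(self.counts,
                            index=pd.Index(labels, name="lai"),
                            columns=pd.Index(labels, name="fapar"))


@dataclass(frozen=True)
class AgreementMetrics:
    """The five agreement/bias metrics of one contingency table.

    All values are fractions (OA, Si, Sd in [0, 1]; Bnc, Bns in [-1, 1]);
    NaN marks an undefined metric.  ``processed_fraction`` is the share of
    candidate pixels/steps that actually contributed cases.
    """

    OA: float
    Si: float
    Sd: float
    Bnc: float
    Bns: float
    n: int
    processed_fraction: float = np.nan

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        out = {k: getattr(self, k) * scale for k in METRIC_NAMES}
        out["n"] = self.n
        out["processed_fraction"] = self.processed_fraction
        return out


def tabulate(pairs: Iterable[tuple[int, int]]) -> ContingencyTable:
    """Count simultaneous (lai_class, fapar_class) pairs into a 3x3 table.

    Accepts ``ChangeClass`` members or their integer codes.  An empty
    input yields a table with N = 0 (all metrics then undefined).
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    for lai_cls, fapar_cls in pairs:
        i, j = int(lai_cls), int(fapar_cls)
        if not (1 <= i <= 3 and 1 <= j <= 3):
            raise ValueError(f"invalid change class pair ({lai_cls!r}, {fapar_cls!r})")
        counts[i - 1, j - 1] += 1
    return ContingencyTable(counts)


def tabulate_codes(lai_codes: np.ndarray, fapar_codes: np.ndarray) -> ContingencyTable:
    """Vectorised tabulation of coded class arrays (0 = masked, dropped)."""
    li = np.asarray(lai_codes).ravel()
    fi = np.asarray(fapar_codes).ravel()
    if li.shape != fi.shape:
        raise ValueError("class arrays must share a shape")
    keep = (li > 0) & (fi > 0)
    flat = (li[keep] - 1) * 3 + (fi[keep] - 1)
    counts = np.bincount(flat, minlength=9).reshape(3, 3)
    return ContingencyTable(counts)


def _require_cases(t: ContingencyTable) -> None:
    if t.n == 0:
        raise ZeroDivisionError("metric undefined: empty contingency table (N = 0)")


def overall_agreement(t: ContingencyTable) -> float:
    """Diagonal fraction of coherent simultaneous changes, in [0, 1]."""
    _require_cases(t)
    return float(np.trace(t.counts)) / t.n


def sensitivity_increase(t: ContingencyTable) -> float:
    """Dice coefficient of simultaneous significant increases (growing season)."""
    c = t.counts
    denom = 2 * c[2, 2] + c[2, 1] + c[2, 0] + c[1, 2] + c[0, 2]
    if denom == 0:
        raise ZeroDivisionError("Si undefined: no significant-increase cases")
    return 2.0 * c[2, 2] / denom


def sensitivity_decrease(t: ContingencyTable) -> float:
    """Dice coefficient of simultaneous significant decreases (senescence)."""
    c = t.counts
    denom = 2 * c[0, 0] + c[0, 1] + c[0, 2] + c[1, 0] + c[2, 0]
    if denom == 0:
        raise ZeroDivisionError("Sd undefined: no significant-decrease cases")
    return 2.0 * c[0, 0] / denom


def bias_noncoherent(t: ContingencyTable) -> float:
    """(n13 - n31)/N: imbalance of the two contradictory significant cells."""
    _require_cases(t)
    c = t.counts
    return float(c[0, 2] - c[2, 0]) / t.n


def bias_nonsignificant(t: ContingencyTable) -> float:
    """((n21 + n23) - (n12 + n32))/N: imbalance of one-sided NC changes.

    Positive when the LAI change is the non-significant one more often
    than the FAPAR change.
    """
    _require_cases(t)
    c = t.counts
    return float((c[1, 0] + c[1, 2]) - (c[0, 1] + c[2, 1])) / t.n


def compute_metrics(t: ContingencyTable,
                    processed_fraction: float = np.nan) -> AgreementMetrics:
    """All five metrics of a table; undefined metrics become NaN."""

    def _maybe(fn) -> float:
        try:
            return fn(t)
        except ZeroDivisionError:
            return np.nan

    return AgreementMetrics(
        OA=_maybe(overall_agreement),
        Si=_maybe(sensitivity_increase),
        Sd=_maybe(sensitivity_decrease),
        Bnc=_maybe(bias_noncoherent),
        Bns=_maybe(bias_nonsignificant),
        n=t.n,
        processed_fraction=processed_fraction,
    )


def metrics_from_counts(counts: np.ndarray,
                        processed: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Vectorised metrics over stacked 3x3 count arrays.

    Parameters
    ----------
    counts : ndarray, shape (..., 3, 3)
        Contingency counts; the trailing two axes index (lai, fapar) class.
    processed : ndarray, optional
        Candidate-case counts per table (same leading shape); when given,
        the result includes ``processed_fraction`` = N / processed.

    Returns
    -------
    dict
        Arrays of shape ``counts.shape[:-2]`` for each metric plus ``n``.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape[-2:] != (3, 3):
        raise ValueError("counts must end in a 3x3 block")
    n = c.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        oa = (c[..., 0, 0] + c[..., 1, 1] + c[..., 2, 2]) / n
        si_den = 2 * c[..., 2, 2] + c[..., 2, 1] + c[..., 2, 0] + c[..., 1, 2] + c[..., 0, 2]
        sd_den = 2 * c[..., 0, 0] + c[..., 0, 1] + c[..., 0, 2] + c[..., 1, 0] + c[..., 2, 0]
        si = np.where(si_den > 0, 2 * c[..., 2, 2] / np.where(si_den > 0, si_den, 1), np.nan)
        sd = np.where(sd_den > 0, 2 * c[..., 0, 0] / np.where(sd_den > 0, sd_den, 1), np.nan)
        bnc = (c[..., 0, 2] - c[..., 2, 0]) / n
        bns = ((c[..., 1, 0] + c[..., 1, 2]) - (c[..., 0, 1] + c[..., 2, 1])) / n
    out = {"OA": oa, "Si": si, "Sd": sd, "Bnc": bnc, "Bns": bns, "n": n}
    if processed is not None:
        p = np.asarray(processed, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["processed_fraction"] = np.where(p > 0, n / np.where(p > 0, p, 1), np.nan)
    return out
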