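"""Sensitivity of the agreement metrics to the confidence threshold.

The confidence level C_f of each change is threshold-independent, so a
sweep computes C_f once and re-classifies cheaply at every threshold.
Two sweeps are provided: a *joint* sweep applying one threshold to both
ECVs, and an *independent* sweep over a (LAI threshold x FAPAR threshold)
grid that maps out the non-significant bias ``Bns`` surface.  The zero
locus of that surface — where the count of one-sided non-significant LAI
changes balances FAPAR's — diagnoses how the two products' relative
uncertainties compare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .change import ClassificationConfig, confidence_level_arrays
from .metrics import METRIC_NAMES, metrics_from_counts
from .stack import GriddedStack, RegionSpec

__all__ = [
    "ChangeCache",
    "precompute_changes",
    "sweep_joint",
    "sweep_independent",
    "zero_bias_locus",
    "ZeroBiasLocus",
]


@dataclass(frozen=True)
class ChangeCache:
    """Flattened per-case deltas and confidences of all valid pixel-steps.

    A "case" is one (pixel, consecutive step) with both ECVs valid at both
    step ends.  C_f does not depend on the threshold, so every sweep
    re-uses this single classification pass.
    """

    lai_delta: np.ndarray
    lai_conf: np.ndarray
    fapar_delta: np.ndarray
    fapar_conf: np.ndarray

    @property
    def n(self) -> int:
        return len(self.lai_delta)


def precompute_changes(
    lai: GriddedStack,
    fapar: GriddedStack,
    region: RegionSpec | None = None,
) -> ChangeCache:
    """One pass of confidence levels over all valid pixel-steps."""
    lai.check_aligned(fapar)
    dl, cl = confidence_level_arrays(lai.masked_values(), lai.masked_uncertainties())
    df_, cf = confidence_level_arrays(fapar.masked_values(), fapar.masked_uncertainties())
    valid = (lai.mask[:-1] & lai.mask[1:] & fapar.mask[:-1] & fapar.mask[1:])
    valid &= np.isfinite(cl) & np.isfinite(cf)
    if region is not None:
        valid &= region.membership[None, :, :]
    return ChangeCache(dl[valid], cl[valid], df_[valid], cf[valid])


def _codes(delta: np.ndarray, conf: np.ndarray, threshold: float) -> np.ndarray:
    codes = np.full(delta.shape, 2, dtype=np.int8)
    sig = conf > threshold
    codes[sig & (delta > 0)] = 3
    codes[sig & (delta < 0)] = 1
    return codes


def _counts_at(cache: ChangeCache, thr_lai: float, thr_fapar: float) -> np.ndarray:
    li = _codes(cache.lai_delta, cache.lai_conf, thr_lai)
    fi = _codes(cache.fapar_delta, cache.fapar_conf, thr_fapar)
    flat = (li - 1) * 3 + (fi - 1)
    return np.bincount(flat, minlength=9).reshape(3, 3)


def sweep_joint(
    lai: GriddedStack,
    fapar: GriddedStack,
    thresholds=(25.0, 50.0, 75.0),
    region: RegionSpec | None = None,
    cache: ChangeCache | None = None,
) -> pd.DataFrame:
    """Agreement metrics with one threshold applied to both ECVs.

    Returns a frame indexed by threshold with the five metrics, the full
    cell counts n11..n33, and the non-coherent count ``n13 + n31``.
    ``n22`` is non-decreasing and ``n13 + n31`` non-increasing in the
    threshold by construction of the classification.
    """
    cc = cache if cache is not None else precompute_changes(lai, fapar, region)
    rows = []
    for thr in thresholds:
        if not (0.0 <= thr <= 100.0):
            raise ValueError(f"threshold must be in [0, 100], got {thr}")
        counts = _counts_at(cc, thr, thr)
        m = metrics_from_counts(counts.astype(float))
        row = {k: float(m[k]) for k in METRIC_NAMES}
        row["n"] = int(counts.sum())
        for i in range(3):
            for j in range(3):
                row[f"n{i + 1}{j + 1}"] = int(counts[i, j])
        row["noncoherent"] = int(counts[0, 2] + counts[2, 0])
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(list(thresholds), name="threshold"))
    return df


def sweep_independent(
    lai: GriddedStack,
    fapar: GriddedStack,
    lai_thresholds: np.ndarray | None = None,
    fapar_thresholds: np.ndarray | None = None,
    region: RegionSpec | None = None,
    cache: ChangeCache | None = None,
) -> xr.DataArray:
    """Bns surface on an independent (LAI x FAPAR) threshold grid.

    Defaults to 1%-step grids from 0 to 100 inclusive.  For each pair of
    thresholds, ``Bns = (count(LAI NC & FAPAR significant) - count(LAI
    significant & FAPAR NC)) / N``; N (the valid-case count) is
    threshold-independent.  Computed with sorted-confidence counting so
    the full 101 x 101 grid needs a single pass over the cases.
    """
    thr_l = np.arange(0.0, 101.0) if lai_thresholds is None else np.asarray(lai_thresholds, float)
    thr_f = np.arange(0.0, 101.0) if fapar_thresholds is None else np.asarray(fapar_thresholds, float)
    cc = cache if cache is not None else precompute_changes(lai, fapar, region)
    n = cc.n
    if n == 0:
        raise ValueError("no valid cases to sweep")

    surface = np.empty((len(thr_l), len(thr_f)))
    for i, tl in enumerate(thr_l):
        lai_sig = cc.lai_conf > tl
        # LAI non-significant cases: how many have significant FAPAR?
        cf_nc = np.sort(cc.fapar_conf[~lai_sig])
        n21_23 = len(cf_nc) - np.searchsorted(cf_nc, thr_f, side="right")
        # LAI significant cases: how many have non-significant FAPAR?
        cf_sig = np.sort(cc.fapar_conf[lai_sig])
        n12_32 = np.searchsorted(cf_sig, thr_f, side="right")
        surface[i] = (n21_23 - n12_32) / n

    da = xr.DataArray(
        surface,
        coords={"lai_threshold": thr_l, "fapar_threshold": thr_f},
        dims=("lai_threshold", "fapar_threshold"),
        name="Bns",
        attrs={"n_cases": n},
    )
    return da


@dataclass(frozen=True)
class ZeroBiasLocus:
    """Zero-crossing structure of a Bns threshold surface."""

    points: list[tuple[float, float]]      # grid cells on/straddling zero
    diagonal_crossing: float | None        # joint threshold where Bns crosses 0
    diagnostic: str | None                 # set when the locus is empty


def zero_bias_locus(surface: xr.DataArray, tolerance: float | None = None) -> ZeroBiasLocus:
    """Locate where the Bns surface vanishes or changes sign.

    A grid cell belongs to the locus when |Bns| falls below the tolerance
    (default 1/(2N), i.e. below one-count resolution) or when its sign
    differs from a forward neighbour along either threshold axis.  The
    joint-threshold crossing is the first sign change along the diagonal,
    linearly interpolated.
    """
    b = np.asarray(surface.values)
    thr_l = surface["lai_threshold"].values
    thr_f = surface["fapar_threshold"].values
    n_cases = surface.attrs.get("n_cases", 0)
    tol = tolerance if tolerance is not None else (0.5 / n_cases if n_cases else 0.0)

    on = np.abs(b) <= tol
    cross = np.zeros_like(on)
    cross[:-1, :] |= np.sign(b[:-1, :]) * np.sign(b[1:, :]) < 0
    cross[:, :-1] |= np.sign(b[:, :-1]) * np.sign(b[:, 1:]) < 0
    locus_mask = on | cross
    pts = [(float(thr_l[i]), float(thr_f[j])) for i, j in zip(*np.nonzero(locus_mask))]

    diag_cross = None
    if len(thr_l) == len(thr_f) and np.allclose(thr_l, thr_f):
        d = np.diag(b)
        nz = np.nonzero(np.abs(d) > tol)[0]
        if nz.size == 0:
            # the whole diagonal balances: report its start
            diag_cross = float(thr_l[0])
        else:
            # genuine crossing: first sign change between consecutive
            # decisively non-zero cells (zero runs in between are part of
            # the locus, trivial zeros at the sweep ends are not)
            signs = np.sign(d[nz])
            change = np.nonzero(signs[:-1] != signs[1:])[0]
            if change.size:
                i, j = nz[change[0]], nz[change[0] + 1]
                frac = d[i] / (d[i] - d[j])
                diag_cross = float(thr_l[i] + frac * (thr_l[j] - thr_l[i]))

    diagnostic = None
    if not pts:
        side = "positive" if np.nanmean(b) > 0 else "negative"
        diagnostic = (f"Bns surface has no zero crossing: uniformly {side} "
                      f"(min |Bns| = {np.nanmin(np.abs(b)):.4f}, tolerance {tol:.4g})")
    return ZeroBiasLocus(pts, diag_cross, diagnostic)
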