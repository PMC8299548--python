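"""Uncertainty-weighted spatial aggregation of ECV stacks.

Coarsening uses the inverse-variance weighted mean: within each target
cell the aggregated value is ``Rs = sum(w_i * a_i) / sum(w_i)`` with
weights ``w_i = 1 / d_i**2`` from the per-pixel uncertainties ``d_i``,
and the propagated uncertainty is ``sigma_s = 1 / sqrt(sum(w_i))``.
Source pixels nest exactly into target cells (membership by pixel centre,
half-open cells anchored at the grid origin); cells with too few valid
pixels are invalidated.  Land-cover class maps are coarsened with a
majority filter, ties broken toward the smallest class code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change import ClassificationConfig
from .metrics import METRIC_NAMES, metrics_from_counts, tabulate_codes
from .stack import GriddedStack, RegionSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AggregationSpec",
    "weighted_aggregate",
    "aggregate_uncertainty",
    "landcover_majority",
    "multiscale_agreement",
]


@dataclass(frozen=True)
class AggregationSpec:
    """Target resolution and validity rules for one aggregation.

    Attributes
    ----------
    cell_size : float
        Target cell size in degrees; must be an integer multiple of the
        source cell size.
    min_valid_fraction : float
        Minimum fraction of valid source pixels for a target cell to be
        considered valid (default 0.5).
    eps : float
        Uncertainty floor in native units; zero or negative uncertainties
        are raised to this value so weights stay finite.
    """

    cell_size: float
    min_valid_fraction: float = 0.5
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (0.0 <= self.min_valid_fraction <= 1.0):
            raise ValueError("min_valid_fraction must be in [0, 1]")
        if self.eps <= 0:
            raise ValueError("uncertainty floor eps must be > 0")

    def factor(self, source_cell_size: float) -> int:
        ratio = self.cell_size / source_cell_size
        f = int(round(ratio))
        if f < 1 or abs(ratio - f) > 1e-6:
            raise ValueError(
                f"target cell size {self.cell_size} is not an integer "
                f"multiple of source {source_cell_size}")
        return f


def _blocks(arr: np.ndarray, f: int) -> np.ndarray:
    """Reshape trailing (ny, nx) into (ny/f, nx/f, f*f) blocks."""
    *lead, ny, nx = arr.shape
    if ny % f or nx % f:
        raise ValueError(f"grid {ny}x{nx} does not tile by factor {f}")
    a = arr.reshape(*lead, ny // f, f, nx // f, f)
    a = np.moveaxis(a, -3, -2)
    return a.reshape(*lead, ny // f, nx // f, f * f)


def _aggregate_arrays(values, uncerts, mask, spec: AggregationSpec, f: int):
    n_floored = int(np.sum((uncerts <= 0) & mask))
    if n_floored:
        logger.warning("flooring %d non-positive uncertainties at eps=%g",
                       n_floored, spec.eps)
    u = np.maximum(uncerts, spec.eps)
    w = np.where(mask, 1.0 / u ** 2, 0.0)
    wv = np.where(mask, w * np.where(np.isfinite(values), values, 0.0), 0.0)

    wb = _blocks(w, f).sum(axis=-1)
    wvb = _blocks(wv, f).sum(axis=-1)
    nb = _blocks(mask.astype(float), f).sum(axis=-1)
    frac = nb / (f * f)
    valid = (frac >= spec.min_valid_fraction) & (wb > 0) & (nb > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(valid, wvb / np.where(wb > 0, wb, 1.0), np.nan)
        sigma = np.where(valid, 1.0 / np.sqrt(np.where(wb > 0, wb, 1.0)), np.nan)
    return rs, sigma, valid


def weighted_aggregate(stack: GriddedStack, spec: AggregationSpec) -> GriddedStack:
    """Inverse-variance weighted coarsening of a stack.

    Values become ``Rs = sum(w v)/sum(w)``, uncertainties the propagated
    ``sigma_s = 1/sqrt(sum w)``; target cells whose valid-pixel fraction
    falls below ``spec.min_valid_fraction`` are invalid.
    """
    f = spec.factor(stack.cell_size)
    rs, sigma, valid = _aggregate_arrays(
        stack.masked_values(), stack.uncertainties, stack.mask, spec, f)
    lat = stack.lat.reshape(-1, f).mean(axis=1)
    lon = stack.lon.reshape(-1, f).mean(axis=1)
    return GriddedStack(values=rs, uncertainties=sigma, times=stack.times,
                        lat=lat, lon=lon, cell_size=spec.cell_size,
                        variable=stack.variable, crs=stack.crs, mask=valid)


def aggregate_uncertainty(stack: GriddedStack, spec: AggregationSpec) -> np.ndarray:
    """Propagated uncertainty grid ``sigma_s = 1/sqrt(sum w)`` alone."""
    f = spec.factor(stack.cell_size)
    _, sigma, _ = _aggregate_arrays(
        stack.masked_values(), stack.uncertainties, stack.mask, spec, f)
    return sigma


def landcover_majority(lc: np.ndarray, spec: AggregationSpec,
                       source_cell_size: float) -> np.ndarray:
    """Majority-filter coarsening of a categorical class grid.

    Codes <= 0 are treated as invalid; ties go to the smallest class
    code; all-invalid cells come out 0.
    """
    lc = np.asarray(lc)
    f = spec.factor(source_cell_size)
    blocks = _blocks(lc, f)  # (ny/f, nx/f, f*f)
    classes = np.unique(lc[lc > 0])
    if classes.size == 0:
        return np.zeros(blocks.shape[:2], dtype=lc.dtype)
    # counts per class, class axis ordered by ascending code so that
    # argmax resolves ties toward the smallest code
    counts = np.stack([(blocks == c).sum(axis=-1) for c in classes], axis=0)
    best = classes[np.argmax(counts, axis=0)]
    any_valid = counts.sum(axis=0) > 0
    return np.where(any_valid, best, 0).astype(lc.dtype)


def multiscale_agreement(
    lai: GriddedStack,
    fapar: GriddedStack,
    landcover: np.ndarray,
    specs: list[AggregationSpec],
    config: ClassificationConfig | None = None,
    class_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Agreement metrics per resolution and land-cover stratum.

    Both ECVs are aggregated with their own uncertainties at each target
    resolution, land cover is majority-resampled, and the full
    classification + tabulation pipeline is re-run per stratum (plus an
    ``all`` stratum).  Returns a tidy frame indexed by (cell_size,
    stratum).
    """
    from .consistency import classify_stacks  # avoid import cycle

    rows = []
    index = []
    for spec in specs:
        lai_c = weighted_aggregate(lai, spec)
        fapar_c = weighted_aggregate(fapar, spec)
        lc_c = landcover_majority(landcover, spec, lai.cell_size)
        lai_codes, fapar_codes = classify_stacks(lai_c, fapar_c, config)

        strata: list[tuple[str, np.ndarray]] = [("all", lc_c >= 0)]
        for cls in np.unique(lc_c[lc_c > 0]):
            name = (class_names or {}).get(int(cls), f"class_{int(cls)}")
            strata.append((name, lc_c == cls))
        for name, member in strata:
            if not member.any():
                continue
            table = tabulate_codes(lai_codes[:, member], fapar_codes[:, member])
            m = metrics_from_counts(table.counts.astype(float))
            row = {k: float(m[k]) for k in METRIC_NAMES}
            row["n"] = table.n
            rows.append(row)
            index.append((spec.cell_size, name))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["cell_size", "stratum"]))
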