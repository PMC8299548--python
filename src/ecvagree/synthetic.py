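"""Synthetic paired LAI/FAPAR product generator.

Builds co-registered raster stacks of the two physically linked vegetation
variables so that every stage of the agreement pipeline can be exercised
with known ground truth.  The generator emulates the statistical structure
of real satellite products rather than their radiative-transfer detail:

* a seasonal LAI cycle per land-cover class — a clipped, sharpened
  sinusoid ``LAI(t) = baseline + amplitude * max(0, sin(2*pi*(doy -
  phase)/365))**sharpness``;
* the radiation-absorption link ``FAPAR = 1 - exp(-k * LAI)`` (Beer-
  Lambert with extinction coefficient ``k``), so that true LAI and FAPAR
  always change in the same direction;
* per-product uncertainty archetypes: ``propagated`` (two-stream-style
  products with large relative LAI uncertainty and smaller relative FAPAR
  uncertainty), ``retrieval`` (LUT-spread products with small
  uncertainties, FAPAR's relatively larger) and ``decoupled`` (independent
  per-ECV uncertainty models);
* controlled pathologies: sign-flipped FAPAR increments with probability
  ``p`` per pixel-step (physical non-coherence), a multiplicative
  uncertainty trend after a sensor-transition break, and random QC
  dropout.

Gaussian observation noise has standard deviation equal to the stated
uncertainty, truncated at the physical bounds (LAI >= 0, FAPAR in (0,1));
truncation events are counted in the truth record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import GriddedStack

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "TruthRecord", "generate", "CLASS_NAMES"]

CLASS_NAMES = {1: "cropland", 2: "forest", 3: "shrub", 4: "grassland"}

# per-class seasonal parameters: baseline LAI, amplitude, phase (day of
# year of cycle start), sharpness exponent
_DEFAULT_SEASONS = {
    1: (0.30, 2.5, 90.0, 2.0),   # cropland: strong, short season
    2: (2.00, 2.0, 60.0, 1.0),   # forest: high baseline, broad season
    3: (0.20, 1.0, 120.0, 2.0),  # shrub
    4: (0.10, 1.5, 105.0, 2.0),  # grassland
}

_ARCHETYPES = ("propagated", "retrieval", "decoupled")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic paired-product scenario.

    The defaults describe a 32 x 32 pixel tile at 0.01 deg resolution with
    dekadal (10-day) compositing over three years, four land-cover classes
    in quadrant blocks, a Beer-Lambert link coefficient k = 0.5, and the
    ``retrieval`` uncertainty archetype with no injected pathologies.
    """

    seed: int
    ny: int = 32
    nx: int = 32
    cell_size: float = 0.01
    lat0: float = -20.0
    lon0: float = 20.0
    start: str = "2010-01-01"
    n_years: int = 3
    cadence_days: int = 10         # 8, 10 (dekadal) or 16
    seasons: dict[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SEASONS))
    k: float = 0.5                 # FAPAR = 1 - exp(-k * LAI)
    archetype: str = "retrieval"
    uncertainty_scale: float = 1.0  # multiplies the stated archetype uncertainties
    noise_scale: float = 1.0       # multiplies the stated-uncertainty noise sd
    p_noncoherent: float = 0.0     # sign-flip probability per pixel-step
    beta: float = 0.0              # uncertainty trend slope per step after break
    trend_on: str = "fapar"        # which ECV the trend/break affects
    t_break: int | None = None     # composite index of the sensor transition
    post_break_noise: float = 1.0  # extra noise sd factor after the break
    dropout: float = 0.0           # QC dropout probability per observation

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("link coefficient k must be > 0")
        if not (0.0 <= self.p_noncoherent <= 1.0):
            raise ValueError("p_noncoherent must be in [0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.archetype not in _ARCHETYPES:
            raise ValueError(f"archetype must be one of {_ARCHETYPES}")
        if self.cadence_days not in (8, 10, 16):
            raise ValueError("cadence_days must be 8, 10 or 16")
        if self.trend_on not in ("lai", "fapar", "both"):
            raise ValueError("trend_on must be 'lai', 'fapar' or 'both'")


@dataclass
class TruthRecord:
    """Everything injected by the generator, for parameter recovery."""

    scenario: ScenarioConfig
    lai_true: np.ndarray
    fapar_true: np.ndarray        # after non-coherence injection
    flip_mask: np.ndarray         # bool (T-1, ny, nx): flipped increments
    n_flipped: int
    n_clipped_lai: int
    n_clipped_fapar: int
    landcover: np.ndarray


def composite_dates(start: str, n_years: int, cadence_days: int) -> pd.DatetimeIndex:
    """Composite start dates for a given cadence.

    Dekadal products use days 1, 11, 21 of each month (36 per year);
    8- and 16-day products restart a fixed step on 1 January each year,
    as MODIS-style composites do.
    """
    t0 = pd.Timestamp(start)
    dates: list[pd.Timestamp] = []
    for year in range(t0.year, t0.year + n_years):
        if cadence_days == 10:
            for month in range(1, 13):
                for day in (1, 11, 21):
                    dates.append(pd.Timestamp(year=year, month=month, day=day))
        else:
            d = pd.Timestamp(year=year, month=1, day=1)
            end = pd.Timestamp(year=year, month=12, day=31)
            while d <= end:
                dates.append(d)
                d += pd.Timedelta(days=cadence_days)
    return pd.DatetimeIndex([d for d in dates if d >= t0])


def landcover_blocks(ny: int, nx: int, classes=(1, 2, 3, 4)) -> np.ndarray:
    """Quadrant block layout of land-cover classes."""
    lc = np.empty((ny, nx), dtype=np.int16)
    hy, hx = ny // 2, nx // 2
    lc[:hy, :hx] = classes[0]
    lc[:hy, hx:] = classes[1]
    lc[hy:, :hx] = classes[2]
    lc[hy:, hx:] = classes[3]
    return lc


def _seasonal_lai(doy: np.ndarray, params: tuple[float, float, float, float]) -> np.ndarray:
    base, amp, phase, sharp = params
    cyc = np.sin(2.0 * np.pi * (doy - phase) / 365.0)
    return base + amp * np.clip(cyc, 0.0, None) ** sharp


def _uncertainties(archetype: str, lai: np.ndarray, fapar: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    # relative levels chosen to mirror the qualitative archetypes: the
    # propagated-link family carries large relative LAI uncertainty and
    # smaller relative FAPAR uncertainty; the retrieval-spread family is
    # tight with FAPAR's relatively larger; the decoupled family uses
    # independent additive+relative models per ECV.
    if archetype == "propagated":
        u_lai = np.maximum(0.05, 0.35 * lai)
        u_fapar = np.maximum(0.02, 0.12 * fapar)
    elif archetype == "retrieval":
        u_lai = np.maximum(0.02, 0.05 * lai)
        u_fapar = np.maximum(0.015, 0.10 * fapar)
    else:  # decoupled
        u_lai = 0.05 + 0.05 * lai
        u_fapar = 0.02 + 0.05 * fapar
    return u_lai, u_fapar


def generate(scenario: ScenarioConfig
             ) -> tuple[GriddedStack, GriddedStack, np.ndarray, TruthRecord]:
    """Generate one paired scenario.

    Returns
    -------
    (lai_stack, fapar_stack, landcover, truth)
        Two aligned :class:`GriddedStack` cubes, the land-cover class grid
        and the :class:`TruthRecord` of injected quantities.  The same
        seed reproduces bit-identical stacks.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    times = composite_dates(sc.start, sc.n_years, sc.cadence_days)
    nt = len(times)
    if nt < 2:
        raise ValueError("scenario produces fewer than two composites")
    doy = times.dayofyear.values.astype(float)

    lc = landcover_blocks(sc.ny, sc.nx, classes=tuple(sorted(sc.seasons)))
    lat = sc.lat0 + sc.cell_size * (np.arange(sc.ny) + 0.5)
    lon = sc.lon0 + sc.cell_size * (np.arange(sc.nx) + 0.5)

    # true LAI: class seasonal cycle plus a small static per-pixel
    # heterogeneity so pixels within a class are not bit-identical
    lai_true = np.empty((nt, sc.ny, sc.nx))
    for cls, params in sc.seasons.items():
        sel = lc == cls
        lai_true[:, sel] = _seasonal_lai(doy, params)[:, None]
    hetero = 1.0 + 0.05 * rng.standard_normal((sc.ny, sc.nx))
    lai_true *= np.clip(hetero, 0.5, 1.5)[None, :, :]
    np.clip(lai_true, 0.0, None, out=lai_true)

    fapar_linked = 1.0 - np.exp(-sc.k * lai_true)

    # non-coherence: flip the sign of FAPAR increments with probability p,
    # then rebuild the series by cumulative summation so only the local
    # direction of change is perturbed, not the marginal level
    incr = np.diff(fapar_linked, axis=0)
    flip = rng.random((nt - 1, sc.ny, sc.nx)) < sc.p_noncoherent
    incr = np.where(flip, -incr, incr)
    fapar_true = np.concatenate(
        [fapar_linked[:1], fapar_linked[:1] + np.cumsum(incr, axis=0)], axis=0)
    np.clip(fapar_true, 1e-6, 1.0 - 1e-6, out=fapar_true)

    u_lai, u_fapar = _uncertainties(sc.archetype, lai_true, fapar_true)
    u_lai = sc.uncertainty_scale * u_lai
    u_fapar = sc.uncertainty_scale * u_fapar

    # observation noise follows the *base* uncertainties: the trend/break
    # below models reported-uncertainty drift (miscalibration over a
    # sensor transition), not a change in the actual retrieval noise
    noise_lai = sc.noise_scale * u_lai * rng.standard_normal(u_lai.shape)
    noise_fapar = sc.noise_scale * u_fapar * rng.standard_normal(u_fapar.shape)

    if sc.beta != 0.0:
        tb = sc.t_break if sc.t_break is not None else 0
        ramp = np.ones(nt)
        steps = np.arange(nt, dtype=float)
        after = steps >= tb
        ramp[after] = 1.0 + sc.beta * (steps[after] - tb)
        ramp = np.clip(ramp, 0.05, None)[:, None, None]
        if sc.trend_on in ("lai", "both"):
            u_lai = u_lai * ramp
        if sc.trend_on in ("fapar", "both"):
            u_fapar = u_fapar * ramp
    if sc.t_break is not None and sc.post_break_noise != 1.0:
        after = (np.arange(nt) >= sc.t_break)[:, None, None]
        noise_lai = np.where(after, noise_lai * sc.post_break_noise, noise_lai)
        noise_fapar = np.where(after, noise_fapar * sc.post_break_noise, noise_fapar)

    lai_obs = lai_true + noise_lai
    fapar_obs = fapar_true + noise_fapar
    n_clip_lai = int(np.sum(lai_obs < 0.0))
    n_clip_fapar = int(np.sum((fapar_obs < 0.0) | (fapar_obs > 1.0)))
    np.clip(lai_obs, 0.0, None, out=lai_obs)
    np.clip(fapar_obs, 0.0, 1.0, out=fapar_obs)
    if n_clip_lai or n_clip_fapar:
        logger.info("physical-bound truncation: %d LAI, %d FAPAR observations",
                    n_clip_lai, n_clip_fapar)

    mask = np.ones((nt, sc.ny, sc.nx), dtype=bool)
    if sc.dropout > 0.0:
        mask &= rng.random((nt, sc.ny, sc.nx)) >= sc.dropout

    common = dict(times=times, lat=lat, lon=lon, cell_size=sc.cell_size)
    lai_stack = GriddedStack(values=lai_obs, uncertainties=u_lai,
                             mask=mask.copy(), variable="lai", **common)
    fapar_stack = GriddedStack(values=fapar_obs, uncertainties=u_fapar,
                               mask=mask.copy(), variable="fapar", **common)
    truth = TruthRecord(scenario=sc, lai_true=lai_true, fapar_true=fapar_true,
                        flip_mask=flip, n_flipped=int(flip.sum()),
                        n_clipped_lai=n_clip_lai, n_clipped_fapar=n_clip_fapar,
                        landcover=lc)
    return lai_stack, fapar_stack, lc, truth
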