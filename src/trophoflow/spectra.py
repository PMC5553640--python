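"""Trophodynamic transformation: species values to trophic spectra.

Taxon-level quantities are distributed over trophic-level classes of
width 0.1, using a log-normal kernel in (TL - 1) that mimics the
within-taxon variability of trophic levels (TL = 1 is the food-web
origin: primary producers and detritus). Summing the smoothed,
catch-weighted values per class yields a *trophic spectrum* — the
distribution of catch, P/B or P/Q along the food-web structure.

Per-class rates are catch-weighted averages of taxon rates: the class
P/B is sum(pb_i * Y_i) / sum(Y_i) and the class P/Q is
sum(pb_i * Y_i) / sum(qb_i * Y_i) — a ratio of sums, not a mean of
ratios — where Y_i is taxon i's smoothed catch falling in the class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrophicGrid",
    "TrophicSpectrum",
    "smooth_weights",
    "weights_matrix",
    "build_catch_spectrum",
    "class_flow_spectra",
    "compute_spectrum",
]


@dataclass(frozen=True)
class TrophicGrid:
    """Uniform grid of half-open trophic classes [tau, tau + width).

    The default spans [1.0, 5.5) in steps of 0.1 (45 classes). Bounds are
    built from integers to keep class membership exact under floating
    point.
    """

    start: float = 1.0
    stop: float = 5.5
    width: float = 0.1

    def __post_init__(self) -> None:
        n = (self.stop - self.start) / self.width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("grid width must divide (stop - start) exactly")

    @property
    def n_classes(self) -> int:
        return round((self.stop - self.start) / self.width)

    @property
    def lower_bounds(self) -> np.ndarray:
        scale = round(1.0 / self.width)
        lo = round(self.start * scale)
        return np.arange(lo, lo + self.n_classes) / scale

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower_bounds + self.width / 2.0

    def index_of(self, tl: float) -> int:
        """Index of the class whose half-open interval contains ``tl``."""
        i = int(np.floor((tl - self.start) / self.width + 1e-9))
        if not 0 <= i < self.n_classes:
            raise ValueError(f"trophic level {tl} outside grid")
        return i

    def range_slice(self, tl_low: float, tl_high: float) -> slice:
        """Slice of classes with lower bound in [tl_low, tl_high)."""
        lo = self.index_of(tl_low)
        hi = lo + round((tl_high - tl_low) / self.width)
        return slice(lo, hi)


DEFAULT_GRID = TrophicGrid()


@dataclass
class TrophicSpectrum:
    """Per-class catch and flow rates for one ecosystem-year.

    ``pb`` and ``pq`` are NaN on classes with zero catch (the weighted
    average is undefined there); :func:`interpolated` fills them from the
    nearest non-empty classes when an indicator needs a complete range.
    """

    grid: TrophicGrid
    catch: np.ndarray
    pb: np.ndarray
    pq: np.ndarray

    def interpolated(self) -> "TrophicSpectrum":
        """Linearly interpolate pb and pq across empty classes.

        Interpolation is in class midpoint; outside the support of
        non-empty classes the nearest defined value is carried (constant
        extrapolation). If no class is defined, rates stay all-NaN.
        """
        mid = self.grid.midpoints
        out = {}
        for name, values in (("pb", self.pb), ("pq", self.pq)):
            mask = np.isfinite(values)
            if mask.all():
                out[name] = values.copy()
            elif not mask.any():
                out[name] = values.copy()
            else:
                out[name] = np.interp(mid, mid[mask], values[mask])
        return TrophicSpectrum(self.grid, self.catch.copy(), out["pb"], out["pq"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tl_class": self.grid.lower_bounds,
                "catch": self.catch,
                "pb": self.pb,
                "pq": self.pq,
            }
        )


def smooth_weights(
    tl_mean: float, grid: TrophicGrid = DEFAULT_GRID, sigma: float = 0.12
) -> np.ndarray:
    """Log-normal smoothing weights of one taxon over the grid.

    The kernel is a log-normal density in (TL - 1) with median at
    (tl_mean - 1) and shape ``sigma``, evaluated at class midpoints and
    renormalised to sum to 1 over the grid (conservation of the smoothed
    quantity takes precedence over the exact density shape at the grid
    truncation). Classes whose midpoint is at or below TL = 1 get zero
    weight.
    """
    if not tl_mean > 1.0:
        raise ValueError("smooth_weights: tl_mean must exceed 1")
    if sigma <= 0:
        raise ValueError("smooth_weights: sigma must be positive")
    x = grid.midpoints - 1.0
    w = np.zeros(grid.n_classes)
    pos = x > 0
    z = (np.log(x[pos]) - np.log(tl_mean - 1.0)) / sigma
    w[pos] = np.exp(-0.5 * z**2) / x[pos]
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        # sigma so small the density underflows everywhere: delta kernel
        w[:] = 0.0
        w[grid.index_of(tl_mean)] = 1.0
        return w
    return w / total


def weights_matrix(
    tls: np.ndarray, grid: TrophicGrid = DEFAULT_GRID, sigma: float = 0.12
) -> np.ndarray:
    """Stack of smoothing weights, one row per taxon trophic level."""
    return np.vstack([smooth_weights(tl, grid, sigma) for tl in np.asarray(tls)])


def build_catch_spectrum(
    catch_year: Mapping[str, float] | pd.Series,
    trophic_levels: Mapping[str, float] | pd.Series,
    grid: TrophicGrid = DEFAULT_GRID,
    sigma: float = 0.12,
) -> np.ndarray:
    """Distribute per-taxon catch over trophic classes.

    Returns the per-class catch vector; its sum equals the total input
    catch (each taxon's weights sum to one).
    """
    catch_year = pd.Series(catch_year, dtype=float)
    out = np.zeros(grid.n_classes)
    for taxon, y in catch_year.items():
        if taxon not in trophic_levels:
            raise KeyError(f"no trophic level for taxon {taxon!r}")
        if y == 0.0:
            continue
        out += y * smooth_weights(float(trophic_levels[taxon]), grid, sigma)
    return out


def class_flow_spectra(
    catch_year: Mapping[str, float] | pd.Series,
    flow: pd.DataFrame,
    grid: TrophicGrid = DEFAULT_GRID,
    sigma: float = 0.12,
) -> tuple[np.ndarray, np.ndarray]:
    """Catch-weighted per-class P/B and P/Q.

    ``flow`` is indexed by taxon_id with columns ``pb`` and ``qb``.
    Classes with zero smoothed catch are NaN.
    """
    catch_year = pd.Series(catch_year, dtype=float)
    active = catch_year[catch_year > 0]
    n = grid.n_classes
    if active.empty:
        return np.full(n, np.nan), np.full(n, np.nan)
    missing = [t for t in active.index if t not in flow.index]
    if missing:
        raise KeyError(f"no flow parameters for taxa {missing}")
    W = weights_matrix(
        flow.loc[active.index, "tl"].to_numpy()
        if "tl" in flow.columns
        else _require_tl(flow, active.index),
        grid,
        sigma,
    )
    y = active.to_numpy()
    pb = flow.loc[active.index, "pb"].to_numpy()
    qb = flow.loc[active.index, "qb"].to_numpy()
    smoothed = W * y[:, None]  # taxon x class catch
    denom = smoothed.sum(axis=0)
    num_p = (smoothed * pb[:, None]).sum(axis=0)
    num_q = (smoothed * qb[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pb_class = np.where(denom > 0, num_p / denom, np.nan)
        pq_class = np.where(denom > 0, num_p / num_q, np.nan)
    return pb_class, pq_class


def _require_tl(flow: pd.DataFrame, taxa) -> np.ndarray:
    raise KeyError("flow table must carry a 'tl' column with taxon trophic levels")


def compute_spectrum(
    catch_year: Mapping[str, float] | pd.Series,
    flow: pd.DataFrame,
    grid: TrophicGrid = DEFAULT_GRID,
    sigma: float = 0.12,
) -> TrophicSpectrum:
    """Full trophic spectrum (catch, P/B, P/Q) for one ecosystem-year.

    ``flow`` is indexed by taxon_id with columns ``tl``, ``pb``, ``qb``.
    """
    catch_year = pd.Series(catch_year, dtype=float)
    tls = {t: float(flow.at[t, "tl"]) for t in catch_year.index}
    catch = build_catch_spectrum(catch_year, tls, grid, sigma)
    pb, pq = class_flow_spectra(catch_year, flow, grid, sigma)
    return TrophicSpectrum(grid=grid, catch=catch, pb=pb, pq=pq)
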