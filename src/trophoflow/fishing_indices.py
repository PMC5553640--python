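"""Fishing-pressure and catch-composition indices.

Classic catch-based indices used as explanatory variables alongside the
trophodynamic indicators:

* **MTL** — catch-weighted mean trophic level of the catch;
* **FiB** — fishing-in-balance index, detecting fisheries expansion or
  contraction once trophic-level shifts are discounted by the transfer
  efficiency;
* **Shannon** — diversity of the catch composition (nats);
* **PPR** — primary production required to sustain the catch,
  back-calculated through the transfer efficiency with a wet-weight to
  carbon ratio; reported both absolute and as a fraction of the
  ecosystem's primary production;
* **L-index** — loss in secondary production caused by fishing
  (Libralato-style), combining PPR, the catch MTL and the ecosystem's
  primary production;
* **SSP** — stock-status plots: each stock-year classified as
  developing / exploited / overexploited / collapsed / rebuilding from
  the catch relative to the stock's historical peak, summarised as the
  fraction of overexploited + collapsed stocks per year;
* **finfish fraction** — share of the catch taken from fish taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import IndexConfig, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "mtl",
    "fib",
    "shannon",
    "ppr",
    "l_index",
    "ssp_classify",
    "ssp_fractions",
    "finfish_fraction",
    "compute_index_table",
    "STATUSES",
]

STATUSES = ("developing", "exploited", "overexploited", "collapsed", "rebuilding")


def _as_arrays(catch, tls=None):
    y = np.asarray(pd.Series(catch, dtype=float).to_numpy(), dtype=float)
    if tls is None:
        return y
    if np.isscalar(tls):
        t = np.full_like(y, float(tls))
    else:
        t = np.asarray(pd.Series(tls, dtype=float).to_numpy(), dtype=float)
    return y, t


def mtl(catch, tls) -> float:
    """Catch-weighted mean trophic level; NaN at zero total catch."""
    y, t = _as_arrays(catch, tls)
    total = y.sum()
    if total <= 0:
        return float("nan")
    return float((t * y).sum() / total)


def fib(
    total_catch: float,
    mtl_year: float,
    baseline_catch: float,
    baseline_mtl: float,
    te: float = 0.1,
) -> float:
    """Fishing-in-balance index relative to a baseline year.

    ``log10(Y * (1/TE)**MTL) - log10(Y0 * (1/TE)**MTL0)``: zero when the
    catch change is exactly balanced by the trophic-level change, positive
    under expansion.
    """
    if total_catch <= 0 or baseline_catch <= 0:
        return float("nan")
    inv = 1.0 / te
    return float(
        np.log10(total_catch * inv**mtl_year)
        - np.log10(baseline_catch * inv**baseline_mtl)
    )


def shannon(catch) -> float:
    """Shannon diversity of catch shares, in nats (0 for a monoculture)."""
    y = _as_arrays(catch)
    total = y.sum()
    if total <= 0:
        return float("nan")
    p = y[y > 0] / total
    return float(-(p * np.log(p)).sum())


def ppr(catch, tls, te: float = 0.1, cr: float = 9.0) -> float:
    """Primary production required to sustain the catch (tonnes PP).

    ``sum_i (Y_i / CR) * (1/TE)**(TL_i - 1)``: each catch converted to
    primary-production equivalents through the carbon ratio CR and
    back-calculated down the food web with transfer efficiency TE.
    """
    if not 0 < te <= 1:
        raise ValueError("ppr: te must be in (0, 1]")
    y, t = _as_arrays(catch, tls)
    return float(((y / cr) * (1.0 / te) ** (t - 1.0)).sum())


def l_index(
    catch, tls, pp_total: float, te: float = 0.1, cr: float = 9.0
) -> float:
    """Loss in secondary production caused by fishing.

    ``L = PPR * TE**(MTLc - 1) / (PP_total * ln(1/TE))`` with MTLc the
    mean trophic level of the catch and PP_total the ecosystem's total
    primary production (tonnes, i.e. areal production times area). Zero
    at zero catch; doubles when all catches double.
    """
    if not pp_total > 0:
        return float("nan")
    y, t = _as_arrays(catch, tls)
    if y.sum() <= 0:
        return 0.0
    ppr_val = ppr(y, t, te=te, cr=cr)
    tlc = mtl(y, t)
    return float(ppr_val * te ** (tlc - 1.0) / (pp_total * np.log(1.0 / te)))


def ssp_classify(
    series: pd.Series,
    min_years: int = 10,
    min_total: float = 1000.0,
) -> pd.Series | None:
    """Classify each year of one stock's catch series by peak-relative rules.

    The peak is the first year reaching the series maximum C_max. Rules:

    * catch > 50% of C_max -> ``exploited`` (any year);
    * at or before the peak, catch <= 50% -> ``developing``;
    * after the peak, catch <= 10% -> ``collapsed``;
    * after the peak, 10% < catch <= 50% -> ``overexploited``, or
      ``rebuilding`` if a collapsed year occurred earlier.

    Series with fewer than ``min_years`` years of positive catch or less
    than ``min_total`` cumulative tonnes do not count as a stock and
    return None (logged).
    """
    series = series.sort_index()
    if int((series > 0).sum()) < min_years or series.sum() < min_total:
        logger.debug("ssp_classify: series excluded by stock criteria")
        return None
    cmax = series.max()
    if cmax <= 0:
        return None
    peak_year = series.index[series.to_numpy().argmax()]
    statuses = []
    collapsed_seen = False
    for year, y in series.items():
        frac = y / cmax
        if frac > 0.5:
            statuses.append("exploited")
        elif year <= peak_year:
            statuses.append("developing")
        elif frac <= 0.1:
            statuses.append("collapsed")
            collapsed_seen = True
        else:
            statuses.append("rebuilding" if collapsed_seen else "overexploited")
    return pd.Series(statuses, index=series.index, name="status")


def ssp_fractions(
    statuses: pd.DataFrame, include_rebuilding: bool = False
) -> pd.DataFrame:
    """Per-year fractions of stocks in each status.

    ``statuses`` is long format with columns ``taxon_id, year, status``
    (one row per stock-year). Adds ``overexploited_collapsed``, the
    headline fraction; ``include_rebuilding`` counts rebuilding stocks in
    it as well.
    """
    counts = (
        statuses.groupby(["year", "status"]).size().unstack(fill_value=0)
    )
    for s in STATUSES:
        if s not in counts.columns:
            counts[s] = 0
    counts = counts[list(STATUSES)]
    frac = counts.div(counts.sum(axis=1), axis=0)
    headline = frac["overexploited"] + frac["collapsed"]
    if include_rebuilding:
        headline = headline + frac["rebuilding"]
    frac["overexploited_collapsed"] = headline
    return frac


def finfish_fraction(catch, groups) -> float:
    """Share of the catch from taxa of group 'fish'."""
    y = pd.Series(catch, dtype=float)
    total = y.sum()
    if total <= 0:
        return float("nan")
    g = pd.Series(groups).reindex(y.index)
    return float(y[g == "fish"].sum() / total)


def compute_index_table(
    catch: pd.DataFrame,
    traits: TraitTable,
    ecosystems: pd.DataFrame,
    config: IndexConfig = IndexConfig(),
    ssp_min_years: int = 10,
    ssp_min_total: float = 1000.0,
) -> pd.DataFrame:
    """All fishing indices per ecosystem-year.

    Columns: ``ecosystem_id, year, total_catch, mtl, fib, shannon, ppr,
    ppr_pp, l_index, ssp_overexploited_collapsed, finfish_fraction``.
    The FiB baseline is the first year with positive catch at or after
    ``config.baseline_year``. PPR/PP and the L-index use the ecosystem's
    total primary production (areal production times area).
    """
    te, cr = config.transfer_efficiency, config.carbon_ratio
    rows = []
    for eco_id, sub in catch.groupby("ecosystem_id", sort=True):
        meta = ecosystems.loc[eco_id]
        pp_total = float(meta["primary_production"]) * float(meta["area"])
        tl_map = {
            t: traits.get(t, eco_id).trophic_level
            for t in sub["taxon_id"].unique()
        }
        group_map = {
            t: traits.get(t, eco_id).group for t in sub["taxon_id"].unique()
        }

        # stock-status classification over full series
        status_rows = []
        for taxon, s in sub.pivot_table(
            index="year", columns="taxon_id", values="catch", aggfunc="sum"
        ).fillna(0.0).items():
            st = ssp_classify(s, min_years=ssp_min_years, min_total=ssp_min_total)
            if st is None:
                continue
            for year, status in st.items():
                status_rows.append(
                    {"taxon_id": taxon, "year": year, "status": status}
                )
        if status_rows:
            frac = ssp_fractions(pd.DataFrame(status_rows))
        else:
            frac = None

        yearly = sub.groupby("year")
        base_catch = base_mtl = None
        for year, yr in yearly:
            y = yr.set_index("taxon_id")["catch"]
            tls = pd.Series({t: tl_map[t] for t in y.index})
            total = float(y.sum())
            m = mtl(y, tls)
            if base_catch is None and total > 0 and int(year) >= config.baseline_year:
                base_catch, base_mtl = total, m
            rows.append(
                {
                    "ecosystem_id": eco_id,
                    "year": int(year),
                    "total_catch": total,
                    "mtl": m,
                    "fib": fib(total, m, base_catch, base_mtl, te)
                    if base_catch
                    else float("nan"),
                    "shannon": shannon(y),
                    "ppr": ppr(y, tls, te, cr),
                    "ppr_pp": ppr(y, tls, te, cr) / pp_total
                    if pp_total > 0
                    else float("nan"),
                    "l_index": l_index(y, tls, pp_total, te, cr),
                    "ssp_overexploited_collapsed": float(
                        frac.at[year, "overexploited_collapsed"]
                    )
                    if frac is not None and year in frac.index
                    else float("nan"),
                    "finfish_fraction": finfish_fraction(
                        y, pd.Series(group_map)
                    ),
                }
            )
    return pd.DataFrame(rows)
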