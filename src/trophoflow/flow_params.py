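"""Empirical estimation of biomass-flow parameters per taxon.

Two community-level rates describe how biomass moves up a food web:

* **P/B**, the production-to-biomass ratio, read as the speed of the
  biomass flow (TL yr^-1); its inverse is the residence time of biomass
  at a trophic level;
* **Q/B**, the consumption-to-biomass ratio (yr^-1).

Their ratio **P/Q** is the gross food-conversion efficiency — the
fraction of consumed food turned into production — used here as a
partial trophic transfer efficiency.

For fish both rates are predicted from life-history traits and mean
sea-surface temperature with published empirical equations (P/B from the
von Bertalanffy K; Q/B from asymptotic weight, caudal-fin aspect ratio
and feeding mode, with the temperature entering as 1000/Kelvin).
Invertebrates carry directly estimated rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import TaxonTraits, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "FlowParams",
    "pb_fish",
    "qb_fish",
    "winf_from_linf",
    "resolve_flow_params",
    "resolve_flow_table",
]


@dataclass(frozen=True)
class FlowParams:
    """Biomass-flow rates of one taxon: pb, qb (yr^-1) and pq = pb/qb."""

    taxon_id: str
    pb: float
    qb: float

    @property
    def pq(self) -> float:
        return self.pb / self.qb


def pb_fish(K, T):
    """Production/biomass ratio of a fish taxon.

    ``1.06 * exp(0.018 * T) * K**0.75`` with ``K`` the von Bertalanffy
    growth coefficient (yr^-1) and ``T`` the mean sea-surface temperature
    (deg C). Accepts scalars or arrays.
    """
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("pb_fish: K must be non-negative")
    out = 1.06 * np.exp(0.018 * np.asarray(T, dtype=float)) * K**0.75
    return out if out.ndim else float(out)


def qb_fish(W_inf, T, A, h=0, d=0):
    """Consumption/biomass ratio of a fish taxon.

    ``10**(7.964 - 0.204*log10(W_inf) - 1.965*T' + 0.083*A + 0.532*h +
    0.398*d)`` with ``W_inf`` the asymptotic weight (g), ``A`` the
    caudal-fin aspect ratio, ``h``/``d`` herbivory/detritivory flags and
    ``T' = 1000/(T + 273.15)`` the inverse absolute temperature term
    (the Kelvin convention of the source regression; a Celsius
    denominator produces astronomically wrong rates).
    """
    W_inf = np.asarray(W_inf, dtype=float)
    if np.any(W_inf <= 0):
        raise ValueError("qb_fish: W_inf must be positive")
    t_prime = 1000.0 / (np.asarray(T, dtype=float) + 273.15)
    exponent = (
        7.964
        - 0.204 * np.log10(W_inf)
        - 1.965 * t_prime
        + 0.083 * np.asarray(A, dtype=float)
        + 0.532 * np.asarray(h, dtype=float)
        + 0.398 * np.asarray(d, dtype=float)
    )
    out = 10.0**exponent
    return out if out.ndim else float(out)


def winf_from_linf(L_inf, a: float = 0.01, b: float = 3.0):
    """Convert asymptotic length (cm) to asymptotic weight (g), W = a L^b."""
    L_inf = np.asarray(L_inf, dtype=float)
    if np.any(L_inf <= 0):
        raise ValueError("winf_from_linf: L_inf must be positive")
    out = a * L_inf**b
    return out if out.ndim else float(out)


def resolve_flow_params(
    traits: TaxonTraits, sst: float, strict: bool = False
) -> FlowParams:
    """Resolve pb/qb for one taxon at the ecosystem's mean SST.

    Direct rates, when present, take precedence over the empirical
    equations (they exist for all invertebrates and for fish with
    meta-analytic estimates). A gross conversion efficiency pq >= 1 is
    biologically implausible: it is logged, and clamped to just below 1
    only under ``strict=True``.
    """
    if traits.has_direct:
        pb, qb = float(traits.direct_pb), float(traits.direct_qb)
    else:
        missing = [
            name
            for name in ("K", "W_inf", "aspect_ratio")
            if getattr(traits, name) is None
        ]
        if missing:
            raise ValueError(
                f"taxon {traits.taxon_id!r}: missing trait(s) {missing} "
                "for the empirical equations"
            )
        pb = pb_fish(traits.K, sst)
        qb = qb_fish(
            traits.W_inf,
            sst,
            traits.aspect_ratio,
            traits.herbivore_flag,
            traits.detritivore_flag,
        )
    if pb / qb >= 1.0:
        logger.warning(
            "taxon %r: P/Q = %.3f >= 1 (production exceeds consumption)",
            traits.taxon_id,
            pb / qb,
        )
        if strict:
            pb = qb * (1.0 - 1e-9)
    return FlowParams(taxon_id=traits.taxon_id, pb=pb, qb=qb)


def resolve_flow_table(
    traits: TraitTable,
    ecosystems: pd.DataFrame,
    taxa_by_ecosystem: dict[str, set[str]] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Resolve flow parameters for every (ecosystem, taxon) pair.

    ``taxa_by_ecosystem`` restricts which taxa are resolved per ecosystem
    (e.g. the taxa actually caught there); by default every known taxon is
    resolved in every ecosystem. Returns a DataFrame with columns
    ``ecosystem_id, taxon_id, pb, qb, pq``.
    """
    rows = []
    for eco_id, eco in ecosystems.iterrows():
        taxa = (
            sorted(taxa_by_ecosystem.get(eco_id, set()))
            if taxa_by_ecosystem is not None
            else sorted(traits.taxa)
        )
        for taxon in taxa:
            fp = resolve_flow_params(
                traits.get(taxon, eco_id), float(eco["sst_mean"]), strict=strict
            )
            rows.append(
                {
                    "ecosystem_id": eco_id,
                    "taxon_id": taxon,
                    "pb": fp.pb,
                    "qb": fp.qb,
                    "pq": fp.pq,
                }
            )
    return pd.DataFrame(rows, columns=["ecosystem_id", "taxon_id", "pb", "qb", "pq"])
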