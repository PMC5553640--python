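"""Data model, validation and CSV readers/writers.

Three tables drive every analysis:

* the **catch table** — long format, one row per (ecosystem, taxon, year)
  with the catch in tonnes;
* the **trait table** — one row per taxon (optionally per taxon x
  ecosystem) carrying the trophic level and either von Bertalanffy growth
  parameters (fish) or directly estimated P/B and Q/B rates
  (invertebrates, or fish with meta-analytic estimates);
* the **ecosystem table** — one row per ecosystem with mean sea-surface
  temperature, primary production, surface area and a climatic type.

All readers validate invariants up front so downstream numerical code can
assume clean inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ECO_TYPES = frozenset({"polar", "temperate", "tropical", "upwelling"})

CATCH_COLUMNS = ["ecosystem_id", "taxon_id", "year", "catch"]
ECOSYSTEM_COLUMNS = [
    "ecosystem_id",
    "name",
    "sst_mean",
    "primary_production",
    "area",
    "eco_type",
]
TRAIT_COLUMNS = [
    "taxon_id",
    "ecosystem_id",
    "group",
    "trophic_level",
    "K",
    "W_inf",
    "aspect_ratio",
    "herbivore_flag",
    "detritivore_flag",
    "direct_pb",
    "direct_qb",
]


class SchemaError(ValueError):
    """A required column is missing or a table is structurally invalid."""


@dataclass(frozen=True)
class TaxonTraits:
    """Life-history and trophic parameters of one taxon.

    Fish carry von Bertalanffy ``K`` (year^-1), asymptotic weight ``W_inf``
    (g wet weight) and caudal-fin aspect ratio ``aspect_ratio`` so that
    P/B and Q/B can be predicted from the empirical equations; any taxon
    may instead carry ``direct_pb`` / ``direct_qb`` (year^-1) which take
    precedence. Invertebrates must carry the direct rates.
    """

    taxon_id: str
    group: str  # 'fish' | 'invertebrate'
    trophic_level: float
    K: float | None = None
    W_inf: float | None = None
    aspect_ratio: float | None = None
    herbivore_flag: int = 0
    detritivore_flag: int = 0
    direct_pb: float | None = None
    direct_qb: float | None = None
    ecosystem_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("fish", "invertebrate"):
            raise ValueError(
                f"taxon {self.taxon_id!r}: group must be 'fish' or "
                f"'invertebrate', got {self.group!r}"
            )
        if not (self.trophic_level >= 1.0) or not math.isfinite(self.trophic_level):
            raise ValueError(
                f"taxon {self.taxon_id!r}: trophic_level must be finite and >= 1"
            )
        if self.has_direct:
            if self.direct_pb is None or self.direct_qb is None:
                raise ValueError(
                    f"taxon {self.taxon_id!r}: direct_pb and direct_qb must "
                    "be given together"
                )
            if self.direct_pb <= 0 or self.direct_qb <= 0:
                raise ValueError(
                    f"taxon {self.taxon_id!r}: direct rates must be positive"
                )
        elif self.group == "invertebrate":
            raise ValueError(
                f"taxon {self.taxon_id!r}: invertebrates need direct_pb and "
                "direct_qb (no empirical equation applies)"
            )
        else:  # fish on the empirical path
            if self.K is None or self.W_inf is None:
                raise ValueError(
                    f"taxon {self.taxon_id!r}: fish need K and W_inf "
                    "(or direct_pb/direct_qb)"
                )
            if self.K <= 0 or self.W_inf <= 0:
                raise ValueError(
                    f"taxon {self.taxon_id!r}: K and W_inf must be positive"
                )

    @property
    def has_direct(self) -> bool:
        return self.direct_pb is not None or self.direct_qb is not None


class TraitTable:
    """Lookup of :class:`TaxonTraits`, with optional per-ecosystem overrides.

    A trait row without ``ecosystem_id`` is the global fallback for a taxon;
    a row with ``ecosystem_id`` overrides it inside that ecosystem (growth
    parameters may be ecosystem specific).
    """

    def __init__(self, traits: Iterable[TaxonTraits]):
        self._global: dict[str, TaxonTraits] = {}
        self._local: dict[tuple[str, str], TaxonTraits] = {}
        for t in traits:
            if t.ecosystem_id is None:
                if t.taxon_id in self._global:
                    raise SchemaError(f"duplicate global trait row for {t.taxon_id!r}")
                self._global[t.taxon_id] = t
            else:
                key = (t.ecosystem_id, t.taxon_id)
                if key in self._local:
                    raise SchemaError(f"duplicate trait row for {key!r}")
                self._local[key] = t

    def get(self, taxon_id: str, ecosystem_id: str | None = None) -> TaxonTraits:
        if ecosystem_id is not None:
            hit = self._local.get((ecosystem_id, taxon_id))
            if hit is not None:
                return hit
        try:
            return self._global[taxon_id]
        except KeyError:
            raise KeyError(f"no traits for taxon {taxon_id!r}") from None

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._global or any(
            t == taxon_id for (_, t) in self._local
        )

    def __len__(self) -> int:
        return len(self._global) + len(self._local)

    @property
    def taxa(self) -> set[str]:
        return set(self._global) | {t for (_, t) in self._local}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in list(self._global.values()) + list(self._local.values()):
            rows.append({f.name: getattr(t, f.name) for f in fields(TaxonTraits)})
        df = pd.DataFrame(rows)
        return df[TRAIT_COLUMNS]


@dataclass(frozen=True)
class IndexConfig:
    """Shared configuration for spectra and indicators.

    ``transfer_efficiency`` (TE) and ``carbon_ratio`` (CR, wet weight :
    carbon) enter the fishing-pressure indices; the trophic-level window
    ``[tl_low, tl_high)`` with classes of ``class_width`` defines the
    cumulation range of the TCI/ECI indicators; ``smoothing_sigma`` is the
    shape parameter of the log-normal trophic-level smoothing; indicator
    series are expressed relative to ``baseline_year``.
    """

    transfer_efficiency: float = 0.1
    carbon_ratio: float = 9.0
    tl_low: float = 2.0
    tl_high: float = 4.0
    class_width: float = 0.1
    smoothing_sigma: float = 0.12
    baseline_year: int = 1950

    def __post_init__(self) -> None:
        if not 0.0 < self.transfer_efficiency <= 1.0:
            raise ValueError("transfer_efficiency must be in (0, 1]")
        if self.carbon_ratio <= 0:
            raise ValueError("carbon_ratio must be positive")
        if not self.tl_low < self.tl_high:
            raise ValueError("tl_low must be below tl_high")
        n = (self.tl_high - self.tl_low) / self.class_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("class_width must divide (tl_high - tl_low) exactly")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be positive")

    @property
    def n_classes(self) -> int:
        return round((self.tl_high - self.tl_low) / self.class_width)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def gap_fill_years(catch: pd.DataFrame) -> pd.DataFrame:
    """Complete each ecosystem's year span, zero-filling missing years.

    Within each ecosystem the observed years define a contiguous span
    [min, max]; every (taxon, year) cell of that span absent from the input
    is added with zero catch (catch reconstructions report all years, so a
    missing year means nothing was caught).
    """
    out = []
    for eco, sub in catch.groupby("ecosystem_id", sort=True):
        years = np.arange(sub["year"].min(), sub["year"].max() + 1)
        taxa = sorted(sub["taxon_id"].unique())
        full = pd.MultiIndex.from_product([taxa, years], names=["taxon_id", "year"])
        filled = (
            sub.set_index(["taxon_id", "year"])["catch"]
            .reindex(full, fill_value=0.0)
            .reset_index()
        )
        filled.insert(0, "ecosystem_id", eco)
        out.append(filled)
    return pd.concat(out, ignore_index=True)


def validate_catch_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, CATCH_COLUMNS, "catch table")
    df = df[CATCH_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    df["catch"] = df["catch"].astype(float)
    if df["catch"].isna().any():
        raise ValueError("catch table: NaN catch values")
    if (df["catch"] < 0).any():
        bad = df.loc[df["catch"] < 0].iloc[0]
        raise ValueError(
            f"catch table: negative catch for taxon {bad['taxon_id']!r} "
            f"in {bad['ecosystem_id']!r}, year {int(bad['year'])}"
        )
    dup = df.duplicated(["ecosystem_id", "taxon_id", "year"])
    if dup.any():
        raise ValueError("catch table: duplicate (ecosystem, taxon, year) keys")
    return df


def read_catch_table(
    path: str | Path, taxa_filter: set[str] | None = None
) -> pd.DataFrame:
    """Read and validate a long-format catch CSV.

    Returns a DataFrame with columns ``ecosystem_id, taxon_id, year, catch``
    whose year span is complete (gap years zero-filled) per ecosystem.
    ``taxa_filter`` optionally restricts to a set of taxon ids before
    validation.
    """
    df = pd.read_csv(path)
    _require_columns(df, CATCH_COLUMNS, "catch table")
    if taxa_filter is not None:
        df = df[df["taxon_id"].isin(taxa_filter)]
    df = validate_catch_table(df)
    return gap_fill_years(df)


def write_catch_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CATCH_COLUMNS].to_csv(path, index=False)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_traits(path: str | Path) -> TraitTable:
    """Read a trait CSV into a :class:`TraitTable`.

    Row-level invariants (fish need growth parameters or direct rates,
    invertebrates need direct rates) are enforced; errors name the
    offending taxon.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["taxon_id", "group", "trophic_level"], "trait table")
    traits = []
    for _, row in df.iterrows():
        eco = row.get("ecosystem_id")
        if isinstance(eco, float) and math.isnan(eco):
            eco = None
        traits.append(
            TaxonTraits(
                taxon_id=str(row["taxon_id"]),
                group=str(row["group"]),
                trophic_level=float(row["trophic_level"]),
                K=_opt(row.get("K")),
                W_inf=_opt(row.get("W_inf")),
                aspect_ratio=_opt(row.get("aspect_ratio")),
                herbivore_flag=int(_opt(row.get("herbivore_flag")) or 0),
                detritivore_flag=int(_opt(row.get("detritivore_flag")) or 0),
                direct_pb=_opt(row.get("direct_pb")),
                direct_qb=_opt(row.get("direct_qb")),
                ecosystem_id=None if eco is None else str(eco),
            )
        )
    return TraitTable(traits)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.to_frame().to_csv(path, index=False)


def read_ecosystems(path: str | Path) -> pd.DataFrame:
    """Read the ecosystem metadata CSV, indexed by ``ecosystem_id``."""
    df = pd.read_csv(path)
    _require_columns(df, ECOSYSTEM_COLUMNS, "ecosystem table")
    df = df[ECOSYSTEM_COLUMNS].copy()
    if not np.isfinite(df["sst_mean"].astype(float)).all():
        raise ValueError("ecosystem table: sst_mean must be finite")
    bad_types = set(df["eco_type"]) - ECO_TYPES
    if bad_types:
        raise ValueError(
            f"ecosystem table: unknown eco_type {sorted(bad_types)}; "
            f"expected one of {sorted(ECO_TYPES)}"
        )
    if df["ecosystem_id"].duplicated().any():
        raise ValueError("ecosystem table: duplicate ecosystem_id")
    return df.set_index("ecosystem_id", drop=False)


def write_ecosystems(df: pd.DataFrame, path: str | Path) -> None:
    df[ECOSYSTEM_COLUMNS].to_csv(path, index=False)


def filter_rare_taxa(
    catch: pd.DataFrame, threshold: float = 0.001, scope: str = "ecosystem"
) -> pd.DataFrame:
    """Drop taxa that never reach ``threshold`` of the total annual catch.

    A taxon is retained if its share of the total catch is at least
    ``threshold`` (default 0.1%) in at least one year. With
    ``scope='ecosystem'`` shares are computed within each ecosystem and the
    retention decision is made per ecosystem; with ``scope='global'``
    shares are computed over the summed catch of all ecosystems and a
    retained taxon is kept everywhere.
    """
    if catch.empty:
        raise ValueError("filter_rare_taxa: empty catch table")
    if scope not in ("ecosystem", "global"):
        raise ValueError("scope must be 'ecosystem' or 'global'")

    if scope == "global":
        annual = catch.groupby(["taxon_id", "year"])["catch"].sum().reset_index()
        totals = annual.groupby("year")["catch"].transform("sum")
        share = annual["catch"] / totals.replace(0.0, np.nan)
        keep_taxa = set(annual.loc[share >= threshold, "taxon_id"])
        kept = catch[catch["taxon_id"].isin(keep_taxa)]
    else:
        totals = catch.groupby(["ecosystem_id", "year"])["catch"].transform("sum")
        share = catch["catch"] / totals.replace(0.0, np.nan)
        flag = share >= threshold
        keep = (
            pd.DataFrame(
                {
                    "ecosystem_id": catch["ecosystem_id"],
                    "taxon_id": catch["taxon_id"],
                    "keep": flag,
                }
            )
            .groupby(["ecosystem_id", "taxon_id"])["keep"]
            .any()
        )
        idx = pd.MultiIndex.from_frame(catch[["ecosystem_id", "taxon_id"]])
        kept = catch[keep.reindex(idx).to_numpy()]

    if kept.empty:
        logger.warning("filter_rare_taxa removed every taxon")
    return kept.reset_index(drop=True)
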