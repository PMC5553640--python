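"""Worldwide trends, trajectory clustering and cluster characterisation.

Three analysis stages operate on per-ecosystem indicator time series:

* **global trend** — the cross-ecosystem mean per year with a bootstrap
  percentile confidence interval (resampling ecosystems with
  replacement), plus a trend test combining an OLS slope with a
  rank-based (Kendall) monotonic-trend statistic;
* **trajectory clustering** — PCA of the ecosystems x years matrix
  (years as variables, scaled) followed by ascending hierarchical
  classification with the Ward criterion on the component scores;
* **cluster characterisation** — for each qualitative modality (e.g.
  "FiB decreasing", "polar ecosystem") a one-tailed hypergeometric test
  of over/under-representation inside each cluster.

The PCA uses population scaling (divisor n), so the eigenvalues of the
standardised data sum to the number of retained variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

__all__ = [
    "TrendResult",
    "PCAResult",
    "ClusterResult",
    "EnrichmentRow",
    "mean_trend_with_bootstrap",
    "trend_significance",
    "pca_trajectories",
    "ahc_ward",
    "cluster_trajectories",
    "hypergeom_enrichment",
    "enrich_modalities",
    "apply_modality_rules",
    "default_modality_rules",
]


def mean_trend_with_bootstrap(
    matrix: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cross-ecosystem mean per year with bootstrap percentile CI.

    ``matrix`` has one row per ecosystem and one column per year.
    Ecosystems (rows) are resampled with replacement ``n_boot`` times;
    per-year NaNs are ignored in the means. With a single ecosystem the
    CI is NaN. Returns columns ``year, mean, ci_low, ci_high``.
    """
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    mean = np.nanmean(X, axis=0)
    if n < 2:
        lo = hi = np.full(X.shape[1], np.nan)
    else:
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.nanmean(X[idx], axis=1)  # n_boot x years
        alpha = (1.0 - level) / 2.0
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {"year": matrix.columns, "mean": mean, "ci_low": lo, "ci_high": hi}
    )


@dataclass(frozen=True)
class TrendResult:
    """Slope (per year, OLS) and monotonic-trend test of a yearly series."""

    slope: float
    slope_p: float
    tau: float
    tau_p: float

    @property
    def significant(self) -> bool:
        return self.tau_p < 0.05


def trend_significance(series: pd.Series) -> TrendResult:
    """OLS slope and Kendall rank trend test of a yearly mean series.

    The rank statistic (Kendall's tau of value against year, a
    Mann-Kendall-style test) is robust to non-linearity; the OLS slope
    quantifies the magnitude per year.
    """
    series = series.dropna().sort_index()
    if len(series) < 10:
        raise ValueError("trend_significance: need at least 10 years")
    years = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    if np.allclose(vals, vals[0]):
        return TrendResult(slope=0.0, slope_p=1.0, tau=0.0, tau_p=1.0)
    ols = stats.linregress(years, vals)
    kt = stats.kendalltau(years, vals)
    return TrendResult(
        slope=float(ols.slope),
        slope_p=float(ols.pvalue),
        tau=float(kt.statistic),
        tau_p=float(kt.pvalue),
    )


@dataclass
class PCAResult:
    """Scores, eigenvalues and the variables retained by the PCA."""

    scores: pd.DataFrame  # ecosystems x components
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variables x components
    dropped_columns: list = field(default_factory=list)


def pca_trajectories(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of an ecosystems x years trajectory matrix.

    Columns (years) are centred and, with ``scale=True``, standardised to
    unit population variance; constant columns cannot be scaled and are
    dropped (logged). Eigenvalues are the variances (divisor n) of the
    component scores and sum to the number of retained variables when
    scaling.
    """
    if matrix.isna().any().any():
        raise ValueError("pca_trajectories: matrix must be complete (no NaN)")
    X = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    dropped: list = []
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)  # population sd, FactoMineR-style
        keep = sd > 0
        dropped = [c for c, k in zip(cols, keep) if not k]
        if dropped:
            logger.info("pca_trajectories: dropping constant column(s) %s", dropped)
        Xc = Xc[:, keep] / sd[keep]
        cols = [c for c, k in zip(cols, keep) if k]
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / n
    scores = U * s
    comp_names = [f"PC{i + 1}" for i in range(len(eig))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        eigenvalues=eig,
        loadings=pd.DataFrame(Vt.T, index=cols, columns=comp_names),
        dropped_columns=dropped,
    )


def ahc_ward(scores: pd.DataFrame, k: int = 4) -> pd.Series:
    """Ward-criterion hierarchical clustering of PCA scores.

    Cuts the Ward dendrogram (Euclidean distances over all supplied
    components) at ``k`` clusters. Labels are integers 1..k, renumbered
    in order of first appearance so the result is deterministic for a
    given row ordering.
    """
    n = len(scores)
    if k < 1 or k > n:
        raise ValueError(f"ahc_ward: k must be in [1, {n}]")
    if k == 1:
        return pd.Series(1, index=scores.index, name="cluster")
    Z = hierarchy.linkage(scores.to_numpy(dtype=float), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        out.append(relabel[r])
    return pd.Series(out, index=scores.index, name="cluster")


@dataclass
class ClusterResult:
    """Cluster labels with the PCA geometry they were derived from."""

    labels: pd.Series
    pc_scores: pd.DataFrame
    eigenvalues: np.ndarray
    k: int


def cluster_trajectories(
    matrix: pd.DataFrame, k: int = 4, scale: bool = True
) -> ClusterResult:
    """PCA + Ward clustering of relative-indicator trajectories."""
    pca = pca_trajectories(matrix, scale=scale)
    labels = ahc_ward(pca.scores, k=k)
    return ClusterResult(
        labels=labels, pc_scores=pca.scores, eigenvalues=pca.eigenvalues, k=k
    )


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> tuple[float, str]:
    """One-tailed hypergeometric enrichment of a modality in a cluster.

    ``N`` ecosystems in total, ``K`` carrying the modality, cluster size
    ``n``, ``k`` carriers inside the cluster. Returns the smaller of the
    over-representation tail P(X >= k) and the under-representation tail
    P(X <= k), with its direction.
    """
    if not (0 <= K <= N and 0 < n <= N and 0 <= k <= min(K, n)):
        raise ValueError("hypergeom_enrichment: inconsistent counts")
    p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_under = float(stats.hypergeom.cdf(k, N, K, n))
    if p_over <= p_under:
        return p_over, "over"
    return p_under, "under"


@dataclass(frozen=True)
class EnrichmentRow:
    """One (cluster, modality) enrichment record, Table-style percentages.

    ``occ_all`` is the share of all ecosystems carrying the modality,
    ``selected`` the share of carriers falling in the cluster and
    ``occ_cluster`` the share of the cluster carrying it (all percent).
    """

    cluster: int
    modality: str
    occ_all: float
    selected: float
    occ_cluster: float
    p_value: float
    direction: str


def enrich_modalities(
    labels: pd.Series, modalities: pd.DataFrame
) -> pd.DataFrame:
    """Hypergeometric characterisation of clusters by binary modalities.

    ``modalities`` is a boolean DataFrame (ecosystems x modalities)
    aligned with ``labels``. Modalities absent everywhere are skipped.
    Rows are sorted by cluster, then p-value.
    """
    modalities = modalities.loc[labels.index].astype(bool)
    N = len(labels)
    rows = []
    for cluster in sorted(labels.unique()):
        in_cluster = labels == cluster
        n = int(in_cluster.sum())
        for name, col in modalities.items():
            K = int(col.sum())
            if K == 0:
                continue
            k = int(col[in_cluster].sum())
            p, direction = hypergeom_enrichment(N, K, n, k)
            rows.append(
                EnrichmentRow(
                    cluster=int(cluster),
                    modality=str(name),
                    occ_all=100.0 * K / N,
                    selected=100.0 * k / K,
                    occ_cluster=100.0 * k / n,
                    p_value=p,
                    direction=direction,
                )
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df = df.sort_values(["cluster", "p_value"]).reset_index(drop=True)
    return df


# --- declarative modality rules -------------------------------------------
#
# Qualitative modalities are derived from the fishing-index table by small
# declarative rules, so the set tested can be configured from YAML:
#   kind: trend      -> sign of the Kendall trend of `column` (alpha 0.05)
#   kind: mean_gt /
#         mean_lt    -> mean of `column` over `window` versus `value`
#   kind: mean_between -> mean within (low, high]
#   kind: eco_type   -> ecosystem type equals `value`


def default_modality_rules() -> dict[str, dict]:
    """Built-in modality definitions over the fishing-index columns."""
    return {
        "FiB decreasing": {"kind": "trend", "column": "fib", "sign": "decreasing"},
        "FiB increasing": {"kind": "trend", "column": "fib", "sign": "increasing"},
        "MTL decreasing": {"kind": "trend", "column": "mtl", "sign": "decreasing"},
        "MTL stable": {"kind": "trend", "column": "mtl", "sign": "stable"},
        "Catch increase": {
            "kind": "trend",
            "column": "total_catch",
            "sign": "increasing",
        },
        "PPR/PP decreasing": {
            "kind": "trend",
            "column": "ppr_pp",
            "sign": "decreasing",
        },
        "PPR/PP increasing": {
            "kind": "trend",
            "column": "ppr_pp",
            "sign": "increasing",
        },
        "Prop. of fish species decreasing": {
            "kind": "trend",
            "column": "finfish_fraction",
            "sign": "decreasing",
        },
        "High Lindex >0.05 (1990-2010)": {
            "kind": "mean_gt",
            "column": "l_index",
            "value": 0.05,
            "window": [1990, 2010],
        },
        "Lindex low (<0.01)": {"kind": "mean_lt", "column": "l_index", "value": 0.01},
        "Overexploitation>50% (1990-2010)": {
            "kind": "mean_gt",
            "column": "ssp_overexploited_collapsed",
            "value": 0.5,
            "window": [1990, 2010],
        },
        "Polar ecosystems": {"kind": "eco_type", "value": "polar"},
        "Temperate ecosystems": {"kind": "eco_type", "value": "temperate"},
        "Tropical ecosystems": {"kind": "eco_type", "value": "tropical"},
        "Upwelling ecosystems": {"kind": "eco_type", "value": "upwelling"},
        "High MTL (>3.60)": {"kind": "mean_gt", "column": "mtl", "value": 3.60},
    }


def apply_modality_rules(
    indices: pd.DataFrame,
    ecosystems: pd.DataFrame,
    rules: dict[str, dict] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate modality rules to a boolean ecosystems x modalities table.

    ``indices`` is the per-ecosystem-year fishing-index table; ``rules``
    defaults to :func:`default_modality_rules`.
    """
    if rules is None:
        rules = default_modality_rules()
    ecos = sorted(indices["ecosystem_id"].unique())
    out = pd.DataFrame(index=pd.Index(ecos, name="ecosystem_id"))
    for name, rule in rules.items():
        kind = rule["kind"]
        vals = []
        for eco in ecos:
            sub = indices[indices["ecosystem_id"] == eco].set_index("year")
            if kind == "eco_type":
                vals.append(str(ecosystems.at[eco, "eco_type"]) == rule["value"])
                continue
            col = sub[rule["column"]]
            if "window" in rule:
                y0, y1 = rule["window"]
                col = col.loc[(col.index >= y0) & (col.index <= y1)]
            col = col.dropna()
            if kind == "trend":
                if len(col) < 10 or np.allclose(col, col.iloc[0]):
                    tr = None
                else:
                    tr = trend_significance(col)
                if rule["sign"] == "decreasing":
                    vals.append(tr is not None and tr.tau_p < alpha and tr.slope < 0)
                elif rule["sign"] == "increasing":
                    vals.append(tr is not None and tr.tau_p < alpha and tr.slope > 0)
                else:  # stable
                    vals.append(tr is None or tr.tau_p >= alpha)
            elif kind == "mean_gt":
                vals.append(bool(len(col)) and col.mean() > rule["value"])
            elif kind == "mean_lt":
                vals.append(bool(len(col)) and col.mean() < rule["value"])
            elif kind == "mean_between":
                vals.append(
                    bool(len(col))
                    and rule["low"] < col.mean() <= rule["high"]
                )
            else:
                raise ValueError(f"unknown modality rule kind {kind!r}")
        out[name] = vals
    return out
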