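"""Metric comparison analyses.

Normalization, within-category correlation structure, dominance
regressions against Berger-Parker, LOESS fits (Faith against observed
richness / singletons), Kruskal-Wallis group tests, key-factor
summaries, and the recommended reporting panel (one metric per
category: observed_features, robbins, berger_parker, shannon, and
faith_pd when a tree was available).

Missing metric values are handled pairwise-complete throughout:
evenness metrics are undefined for single-taxon samples, and dropping
whole samples listwise would bias every other pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_io import AlphaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix", "RegressionFit", "LoessFit", "PanelReport",
    "minmax_normalize", "correlate_category", "correlate_metrics",
    "regress_on_berger_parker", "loess_fit", "kruskal_wallis",
    "key_factor_summary", "top_two_ratio", "recommended_panel",
    "PANEL_METRICS",
]

PANEL_METRICS = ("observed_features", "robbins", "berger_parker", "faith_pd", "shannon")


# ----------------------------------------------------------- normalization

def minmax_normalize(matrix: AlphaMatrix) -> AlphaMatrix:
    """Rescale every metric column to [0, 1] across samples.

    Constant columns carry no comparative signal and map to all-zero
    with a warning; missing values propagate. Idempotent.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("min-max normalization needs at least 2 samples")
    out = {}
    for name in matrix.values.columns:
        col = matrix.values[name]
        lo, hi = col.min(), col.max()
        if pd.isna(lo) or hi == lo:
            if col.notna().any():
                logger.warning("metric %s is constant; normalized to 0", name)
            out[name] = col - col  # zeros, NaN where missing
        else:
            out[name] = (col - lo) / (hi - lo)
    return AlphaMatrix(values=pd.DataFrame(out, index=matrix.values.index),
                       categories=dict(matrix.categories))


# ------------------------------------------------------------ correlations

@dataclass
class CorrelationMatrix:
    """Pairwise Pearson + Spearman coefficients with per-pair n."""

    metric_names: list[str]
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    n_pairs: pd.DataFrame
    n_samples: int


def correlate_metrics(values: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson and Spearman over metric columns.

    Constant metrics yield undefined (NaN) off-diagonal entries; the
    diagonal is 1 wherever the metric has any variation.
    """
    if values.shape[0] < 3:
        raise ValueError("correlation needs at least 3 samples")
    pearson = values.corr(method="pearson", min_periods=3)
    spearman = values.corr(method="spearman", min_periods=3)
    notna = values.notna().astype(int)
    n_pairs = notna.T @ notna
    return CorrelationMatrix(
        metric_names=list(values.columns),
        pearson=pearson,
        spearman=spearman,
        n_pairs=n_pairs,
        n_samples=values.shape[0],
    )


def correlate_category(matrix: AlphaMatrix, category: str) -> CorrelationMatrix:
    """Correlation structure among one category's metrics."""
    names = matrix.metrics_in_category(category)
    if not names:
        raise ValueError(f"no metrics in category {category!r}")
    return correlate_metrics(matrix.values[names])


# ------------------------------------------------------------- regressions

@dataclass
class RegressionFit:
    predictor: str
    response: str
    transform: str
    slope: float
    intercept: float
    r_squared: float
    n: int


def regress_on_berger_parker(
    matrix: AlphaMatrix, response: str, transform: str = "identity"
) -> RegressionFit:
    """OLS of a metric on Berger-Parker dominance.

    ``transform="exponential"`` regresses log(response) on the
    predictor — appropriate when the response decays or grows
    exponentially in dominance (e.g. ENSPIE).
    """
    if transform not in ("identity", "exponential"):
        raise ValueError(f"unknown transform {transform!r}")
    if "berger_parker" not in matrix.values.columns:
        raise ValueError("matrix lacks a berger_parker column")
    if response not in matrix.values.columns:
        raise ValueError(f"matrix lacks response column {response!r}")
    pair = matrix.values[["berger_parker", response]].dropna()
    if pair.shape[0] < 3:
        raise ValueError("regression needs at least 3 complete observations")
    x = pair["berger_parker"].to_numpy(float)
    y = pair[response].to_numpy(float)
    if transform == "exponential":
        bad = pair.index[y <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive response under exponential transform: {list(bad[:10])}"
            )
        y = np.log(y)
    res = stats.linregress(x, y)
    return RegressionFit(
        predictor="berger_parker", response=response, transform=transform,
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2, n=int(pair.shape[0]),
    )


@dataclass
class LoessFit:
    predictor: str
    response: str
    span: float
    degree: int
    fitted: np.ndarray = field(repr=False)
    r_squared: float = float("nan")


def loess_fit(
    x, y, span: float = 0.75, degree: int = 2,
    predictor: str = "x", response: str = "y",
) -> LoessFit:
    """Tricube-weighted local polynomial regression (LOESS).

    For each point the ``span`` fraction of nearest neighbours (by
    predictor distance) is fitted with a weighted degree-``degree``
    polynomial and evaluated there. R^2 is 1 - SS_res/SS_tot over the
    fitted values. No robustness iterations.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 10:
        raise ValueError("loess needs at least 10 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = x.size
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    fitted = np.empty(n)
    for idx in range(n):
        d = np.abs(x - x[idx])
        nearest = np.argpartition(d, k - 1)[:k]
        dmax = d[nearest].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = (1 - np.clip(d[nearest] / dmax, 0, 1) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        # weighted polynomial LS, centred at x[idx] for conditioning
        coeffs = np.polyfit(x[nearest] - x[idx], y[nearest], degree, w=np.sqrt(w))
        fitted[idx] = coeffs[-1]
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LoessFit(predictor=predictor, response=response, span=span,
                    degree=degree, fitted=fitted, r_squared=r2)


# ------------------------------------------------------------- group tests

def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    All-equal inputs make the tie correction degenerate and are
    rejected explicitly rather than returning NaN.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.size != groups.size:
        raise ValueError("values and groups lengths differ")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if values.size < 3:
        raise ValueError("kruskal_wallis needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("all observations identical: H undefined under ties")
    arrays = [values[groups == lbl] for lbl in labels]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


# ---------------------------------------------------------- summaries

def key_factor_summary(matrix: AlphaMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """How each metric tracks the two key generative factors: total
    richness (S) and singletons (F1).

    ``design`` must cover all samples with columns ``s_target`` and
    ``f1_target``. Returns one row per metric: Spearman against each
    factor plus a coarse direction label (|rho| >= 0.3).
    """
    missing = set(matrix.sample_ids) - set(design.index)
    if missing:
        raise ValueError(f"design lacks samples: {sorted(missing)[:5]}")
    for col in ("s_target", "f1_target"):
        if col not in design.columns:
            raise ValueError(f"design lacks column {col!r}")
    aligned = design.loc[matrix.sample_ids]

    def direction(rho: float) -> str:
        if np.isnan(rho) or abs(rho) < 0.3:
            return "weak"
        return "increasing" if rho > 0 else "decreasing"

    rows = []
    for name in matrix.metric_names:
        col = matrix.values[name]
        ok = col.notna()
        rho_s = stats.spearmanr(aligned.loc[ok, "s_target"], col[ok]).statistic
        rho_f1 = stats.spearmanr(aligned.loc[ok, "f1_target"], col[ok]).statistic
        rows.append({
            "metric": name,
            "category": matrix.categories[name],
            "spearman_vs_richness": float(rho_s),
            "spearman_vs_singletons": float(rho_f1),
            "trend_vs_richness": direction(rho_s),
            "trend_vs_singletons": direction(rho_f1),
        })
    return pd.DataFrame(rows).set_index("metric")


def top_two_ratio(counts) -> float:
    """Second-most-abundant over most-abundant count, in (0, 1]."""
    arr = np.asarray(counts, dtype=float)
    pos = arr[arr > 0]
    if pos.size < 2:
        raise ValueError("top_two_ratio needs at least 2 observed taxa")
    top2 = np.sort(pos)[-2:]
    return float(top2[0] / top2[1])


# ------------------------------------------------------------------- panel

@dataclass
class PanelReport:
    """The recommended one-per-category reporting panel."""

    panel: pd.DataFrame
    summary: pd.DataFrame | None
    notes: list[str]


def recommended_panel(
    matrix: AlphaMatrix,
    metadata: pd.DataFrame | None = None,
    group_column: str | None = None,
) -> PanelReport:
    """Per-sample panel of one representative metric per category.

    Richness: observed_features (plus robbins as the unseen-taxa
    likelihood), dominance: berger_parker, information: shannon,
    phylogenetic: faith_pd when present (a note is emitted otherwise).
    With a metadata grouping, per-group median and quartiles are added.
    """
    required = [m for m in PANEL_METRICS if m != "faith_pd"]
    for name in required:
        if name not in matrix.values.columns:
            raise ValueError(f"panel metric {name!r} absent from matrix")
    notes: list[str] = []
    cols = list(PANEL_METRICS)
    if "faith_pd" not in matrix.values.columns:
        cols = [c for c in cols if c != "faith_pd"]
        notes.append(
            "faith_pd absent (no phylogenetic tree supplied); panel covers "
            "richness, dominance and information categories only"
        )
    panel = matrix.values[cols].copy()

    summary = None
    if group_column is not None:
        if metadata is None:
            raise ValueError("group_column given without metadata")
        if group_column not in metadata.columns:
            raise ValueError(f"metadata lacks column {group_column!r}")
        joined = panel.join(metadata[[group_column]], how="inner")
        if joined.empty:
            raise ValueError("no samples shared between panel and metadata")
        stats_rows = []
        for metric in cols:
            g = joined.groupby(group_column)[metric]
            q = g.quantile([0.25, 0.5, 0.75]).unstack()
            for grp, row in q.iterrows():
                stats_rows.append({
                    "metric": metric, "group": grp,
                    "q1": row[0.25], "median": row[0.5], "q3": row[0.75],
                    "n": int(g.count().loc[grp]),
                })
        summary = pd.DataFrame(stats_rows)
    return PanelReport(panel=panel, summary=summary, notes=notes)
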