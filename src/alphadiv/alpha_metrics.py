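"""Abundance-based alpha-diversity metrics and the category registry.

Eighteen within-sample metrics computed from a single count vector,
grouped with Faith PD into four complementary categories:

* richness — how many taxa: observed_features, chao1, ace, fisher_alpha,
  margalef, menhinick, robbins
* dominance — how concentrated the abundances are: berger_parker,
  simpson, dominance, enspie, gini, mcintosh, strong
* information — entropy blends of both: shannon, brillouin, heip, pielou
* phylogenetic — faith_pd (see :mod:`alphadiv.phylo_metrics`)

All functions take one sample's counts (any sequence of non-negative
numbers); zeros are absences and are ignored, so zero-padding never
changes a value. Counts must be integral where the estimator relies on
singleton/doubleton bookkeeping (Chao1, ACE, Brillouin).

Conventions for degenerate samples: all-zero vectors raise; evenness
measures undefined at S = 1 (Heip, Pielou) return NaN rather than
raising, so whole-table runs keep going.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .feature_io import AlphaMatrix, FeatureTable
from .phylo_metrics import faith_pd

logger = logging.getLogger(__name__)

__all__ = [
    "observed_features", "singleton_count", "doubleton_count",
    "chao1", "ace", "fisher_alpha", "margalef", "menhinick", "robbins",
    "berger_parker", "simpson", "dominance_index", "enspie", "gini",
    "mcintosh_dominance", "strong", "shannon", "brillouin", "heip",
    "pielou", "MetricRegistry", "RegistryEntry", "default_registry",
    "default_categories", "compute_all", "compute_alpha_stream",
]


def _positive(counts, require_integer: bool = False) -> np.ndarray:
    """Strictly positive entries of a count vector, validated."""
    a = np.asarray(counts, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty count vector")
    if not np.isfinite(a).all():
        raise ValueError("counts must be finite")
    if (a < 0).any():
        raise ValueError("counts must be non-negative")
    if require_integer and (a % 1 != 0).any():
        raise ValueError("metric requires integer counts")
    pos = a[a > 0]
    if pos.size == 0:
        raise ValueError("all-zero count vector: no metric is defined")
    return pos


# ---------------------------------------------------------------- richness

def observed_features(counts) -> int:
    """S: number of taxa with at least one read."""
    return int(_positive(counts).size)


def singleton_count(counts) -> int:
    """F1: taxa observed exactly once."""
    return int((_positive(counts, require_integer=True) == 1).sum())


def doubleton_count(counts) -> int:
    """F2: taxa observed exactly twice."""
    return int((_positive(counts, require_integer=True) == 2).sum())


def chao1(counts) -> float:
    """Chao1 unseen-species estimator, S + F1^2 / (2 F2).

    With no doubletons the classic form divides by zero; the
    bias-corrected variant S + F1(F1-1)/(2(F2+1)) is used instead.
    """
    pos = _positive(counts, require_integer=True)
    s = pos.size
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based Coverage Estimator (Chao & Lee).

    Taxa with counts above ``rare_threshold`` are taken at face value;
    the rare group is coverage-corrected, with a coefficient-of-variation
    term (floored at zero) absorbing heterogeneity among rare taxa.
    Undefined when every rare taxon is a singleton (coverage 0).
    """
    pos = _positive(counts, require_integer=True).astype(np.int64)
    rare = pos[pos <= rare_threshold]
    s_abund = int((pos > rare_threshold).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_rare = 1.0 - f1 / n_rare
    if c_rare == 0.0:
        raise ValueError("ACE undefined: all rare taxa are singletons")
    if n_rare > 1:
        ssum = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_threshold + 1))
        gamma2 = max(s_rare / c_rare * ssum / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return s_abund + s_rare / c_rare + f1 / c_rare * gamma2


def fisher_alpha(counts, tol: float = 1e-10) -> float:
    """Fisher's log-series alpha: the root of S = a ln(1 + N/a).

    Solved by bracketed root search; diverges when every taxon is a
    singleton (S = N) and is meaningless below two taxa.
    """
    pos = _positive(counts)
    s = pos.size
    n = float(pos.sum())
    if s < 2:
        raise ValueError("fisher_alpha requires at least 2 taxa")
    if s >= n:
        raise ValueError("fisher_alpha diverges: S = N (all singletons)")

    def f(a: float) -> float:
        return a * math.log1p(n / a) - s

    alpha = brentq(f, 1e-8, 1e8, xtol=tol, rtol=8.9e-16, maxiter=200)
    if abs(f(alpha)) > max(tol, 1e-8):
        raise RuntimeError("fisher_alpha root search did not converge")
    return float(alpha)


def margalef(counts) -> float:
    """(S - 1) / ln N; 0 for a single taxon (covers the N = 1 case)."""
    pos = _positive(counts)
    s = pos.size
    if s == 1:
        return 0.0
    return (s - 1) / math.log(pos.sum())


def menhinick(counts) -> float:
    """S / sqrt(N)."""
    pos = _positive(counts)
    return pos.size / math.sqrt(pos.sum())


def robbins(counts, denominator: str = "reads") -> float:
    """Robbins' unseen-probability estimator.

    ``reads`` (default) is F1/(N+1), Robbins' 1968 estimator of the
    probability that the next read is a new taxon — the form the usual
    toolchains compute. ``features`` is the F1/(S+1) variant seen in
    some summaries.
    """
    pos = _positive(counts, require_integer=True)
    f1 = int((pos == 1).sum())
    if denominator == "reads":
        return f1 / (float(pos.sum()) + 1.0)
    if denominator == "features":
        return f1 / (pos.size + 1.0)
    raise ValueError(f"unknown denominator {denominator!r}")


# --------------------------------------------------------------- dominance

def berger_parker(counts) -> float:
    """Relative abundance of the single most abundant taxon, n_max/N."""
    pos = _positive(counts)
    return float(pos.max() / pos.sum())


def simpson(counts) -> float:
    """Simpson diversity 1 - sum p_i^2 (probability two random reads differ)."""
    pos = _positive(counts)
    p = pos / pos.sum()
    return float(1.0 - (p * p).sum())


def dominance_index(counts) -> float:
    """Simpson concentration sum p_i^2 (= 1 - simpson)."""
    pos = _positive(counts)
    p = pos / pos.sum()
    return float((p * p).sum())


def enspie(counts) -> float:
    """Effective number of species (PIE): 1 / sum p_i^2, in [1, S]."""
    return 1.0 / dominance_index(counts)


def gini(counts) -> float:
    """Gini inequality of the observed abundances.

    Mean-absolute-difference form, G = sum_ij |x_i - x_j| / (2 S^2 m):
    0 for a perfectly even sample, upper bound 1 - 1/S. Computed via the
    sorted identity G = sum_i (2i - S - 1) x_(i) / (S^2 m), O(S log S).
    """
    pos = np.sort(_positive(counts))
    s = pos.size
    if s == 1:
        return 0.0
    i = np.arange(1, s + 1)
    return float(((2 * i - s - 1) * pos).sum() / (s * pos.sum()))


def mcintosh_dominance(counts) -> float:
    """McIntosh dominance (N - U)/(N - sqrt N), U the Euclidean norm of counts.

    0 when one taxon holds all reads, 1 when every read is its own taxon.
    """
    pos = _positive(counts)
    n = float(pos.sum())
    if n < 2:
        raise ValueError("mcintosh requires N >= 2")
    u = math.sqrt(float((pos.astype(float) ** 2).sum()))
    return (n - u) / (n - math.sqrt(n))


def strong(counts) -> float:
    """Strong's dominance: max_i (b_i/N - i/S) over the descending
    cumulative abundance curve b_i — the largest gap between the sample's
    Lorenz-style curve and perfect evenness."""
    pos = np.sort(_positive(counts))[::-1]
    s = pos.size
    n = pos.sum()
    b = np.cumsum(pos)
    i = np.arange(1, s + 1)
    # counts stay integral until the final division to avoid FP ties
    return float(np.max(b / n - i / s))


# ------------------------------------------------------------- information

def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy -sum p_i log_base p_i (base 2 by default)."""
    pos = _positive(counts)
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def brillouin(counts) -> float:
    """Brillouin index (ln N! - sum ln n_i!)/N, via log-gamma."""
    pos = _positive(counts, require_integer=True)
    n = float(pos.sum())
    return float((gammaln(n + 1) - gammaln(pos + 1).sum()) / n)


def heip(counts) -> float:
    """Heip evenness (e^H - 1)/(S - 1), H the natural-log entropy.

    Undefined (0/0) for a single taxon: returns NaN.
    """
    pos = _positive(counts)
    if pos.size == 1:
        logger.debug("heip undefined for S=1; returning missing value")
        return float("nan")
    h = shannon(pos, base=math.e)
    return (math.exp(h) - 1.0) / (pos.size - 1.0)


def pielou(counts) -> float:
    """Pielou evenness H/ln S (base-invariant); NaN for a single taxon."""
    pos = _positive(counts)
    if pos.size == 1:
        logger.debug("pielou undefined for S=1; returning missing value")
        return float("nan")
    return shannon(pos, base=math.e) / math.log(pos.size)


# ---------------------------------------------------------------- registry

@dataclass(frozen=True)
class RegistryEntry:
    name: str
    category: str
    func: Callable
    requires_integers: bool = False
    requires_tree: bool = False


@dataclass
class MetricRegistry:
    """Ordered set of metrics with their category labels."""

    entries: list[RegistryEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate metric names in registry")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def categories(self) -> dict[str, str]:
        return {e.name: e.category for e in self.entries}

    def subset(self, names: Sequence[str]) -> "MetricRegistry":
        keep = set(names)
        return MetricRegistry([e for e in self.entries if e.name in keep])

    def without_tree_metrics(self) -> "MetricRegistry":
        return MetricRegistry([e for e in self.entries if not e.requires_tree])

    @property
    def needs_tree(self) -> bool:
        return any(e.requires_tree for e in self.entries)


def default_registry(include_tree_metrics: bool = True) -> MetricRegistry:
    """The full 19-metric panel (7 richness, 7 dominance, 4 information,
    1 phylogenetic)."""
    entries = [
        RegistryEntry("observed_features", "richness", observed_features),
        RegistryEntry("chao1", "richness", chao1, requires_integers=True),
        RegistryEntry("ace", "richness", ace, requires_integers=True),
        RegistryEntry("fisher_alpha", "richness", fisher_alpha),
        RegistryEntry("margalef", "richness", margalef),
        RegistryEntry("menhinick", "richness", menhinick),
        RegistryEntry("robbins", "richness", robbins, requires_integers=True),
        RegistryEntry("berger_parker", "dominance", berger_parker),
        RegistryEntry("simpson", "dominance", simpson),
        RegistryEntry("dominance", "dominance", dominance_index),
        RegistryEntry("enspie", "dominance", enspie),
        RegistryEntry("gini", "dominance", gini),
        RegistryEntry("mcintosh", "dominance", mcintosh_dominance),
        RegistryEntry("strong", "dominance", strong),
        RegistryEntry("shannon", "information", shannon),
        RegistryEntry("brillouin", "information", brillouin, requires_integers=True),
        RegistryEntry("heip", "information", heip),
        RegistryEntry("pielou", "information", pielou),
        RegistryEntry("faith_pd", "phylogenetic", faith_pd, requires_tree=True),
    ]
    reg = MetricRegistry(entries)
    return reg if include_tree_metrics else reg.without_tree_metrics()


def default_categories() -> dict[str, str]:
    return default_registry().categories


# -------------------------------------------------------------- batch runs

def compute_alpha_stream(
    samples: Iterable[tuple[str, "pd.Series | np.ndarray"]],
    registry: MetricRegistry | None = None,
    tree=None,
) -> AlphaMatrix:
    """Compute every registered metric for a stream of (sample_id, counts).

    Per-sample failures (all-zero sample, undefined estimator) become
    missing values with a logged warning — one bad sample never aborts a
    table run. Tree metrics need labelled counts (a Series) and a tree.
    """
    if registry is None:
        registry = default_registry(include_tree_metrics=tree is not None)
    if registry.needs_tree and tree is None:
        raise ValueError("registry includes tree-requiring metrics but no tree given")

    rows: list[list[float]] = []
    ids: list[str] = []
    for sample_id, counts in samples:
        ids.append(str(sample_id))
        arr = counts.to_numpy() if isinstance(counts, pd.Series) else np.asarray(counts)
        if not (np.asarray(arr, dtype=float) > 0).any():
            logger.warning("sample %s is all-zero: metrics recorded as missing", sample_id)
            rows.append([math.nan] * len(registry.entries))
            continue
        row = []
        for entry in registry.entries:
            try:
                if entry.requires_tree:
                    if not isinstance(counts, pd.Series):
                        raise ValueError("tree metrics need feature-labelled counts")
                    value = float(entry.func(counts, tree))
                else:
                    value = float(entry.func(arr))
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                logger.warning("sample %s, metric %s: %s", sample_id, entry.name, exc)
                value = math.nan
            row.append(value)
        rows.append(row)

    values = pd.DataFrame(rows, index=ids, columns=registry.names, dtype=float)
    return AlphaMatrix(values=values, categories=registry.categories)


def _iter_table(table: FeatureTable) -> Iterator[tuple[str, pd.Series]]:
    for sample_id in table.sample_ids:
        yield sample_id, table.sample_counts(sample_id)


def compute_all(
    table: FeatureTable,
    tree=None,
    registry: MetricRegistry | None = None,
) -> AlphaMatrix:
    """Full metric panel for every sample of a feature table.

    If tree metrics are registered, the tree must cover every feature
    that is present (positive) in any sample — checked up front so a
    coverage problem fails fast instead of surfacing as per-sample NaNs.
    """
    if registry is None:
        registry = default_registry(include_tree_metrics=tree is not None)
    if registry.needs_tree:
        if tree is None:
            raise ValueError("tree required by registry but not provided")
        present = table.counts.columns[(table.counts > 0).any(axis=0)]
        tips = {t.name for t in tree.tips()}
        missing = sorted(set(present) - tips)
        if missing:
            raise ValueError(f"features absent from tree: {missing[:10]}")
    return compute_alpha_stream(_iter_table(table), registry=registry, tree=tree)
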