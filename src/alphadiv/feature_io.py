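"""Readers and writers for the formats the pipeline touches.

Feature tables are plain TSV count matrices (QIIME-style ``#OTU ID``
header tolerated), trees are newick, metadata and metric tables are TSV.
Counts are strictly non-negative integers: several estimators (Chao1,
ACE, Brillouin, Fisher) are undefined on fractional abundances, so
rarefied/normalised tables are rejected at the door.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

CATEGORIES = ("richness", "dominance", "information", "phylogenetic")


@dataclass
class FeatureTable:
    """Samples x features count matrix.

    ``counts`` is a DataFrame indexed by sample id with feature ids as
    columns; every cell is a non-negative integer. ``metadata``, when
    present, is indexed by a subset of the sample ids.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                frac = values.astype(float) % 1 != 0
                if frac.any():
                    i, j = np.argwhere(frac)[0]
                    raise ValueError(
                        "non-integer count at sample "
                        f"{self.counts.index[i]!r}, feature {self.counts.columns[j]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise ValueError(
                    "negative count at sample "
                    f"{self.counts.index[i]!r}, feature {self.counts.columns[j]!r}"
                )
        if self.metadata is not None:
            extra = self.metadata.index.difference(self.counts.index)
            if len(extra):
                raise ValueError(f"metadata rows not in table: {list(extra[:5])}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def sample_counts(self, sample_id: str) -> pd.Series:
        """One sample's counts as a feature-labelled Series."""
        return self.counts.loc[sample_id]


@dataclass
class AlphaMatrix:
    """Samples x metrics result table with per-metric category labels.

    Missing values (metric undefined for a sample, e.g. evenness at
    S = 1) are NaN in memory and empty fields on disk.
    """

    values: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.values.columns:
            cat = self.categories.get(name)
            if cat is None:
                raise ValueError(f"metric {name!r} has no category label")
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for metric {name!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metric_names(self) -> list[str]:
        return list(self.values.columns)

    def metrics_in_category(self, category: str) -> list[str]:
        return [m for m in self.values.columns if self.categories[m] == category]


def _parse_counts(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        out[col] = pd.to_numeric(df[col])
    return pd.DataFrame(out, index=df.index)


def read_feature_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    layout: str = "wide",
) -> FeatureTable:
    """Read a TSV count table.

    ``orientation`` is explicit (no sniffing): ``samples_as_rows`` or
    ``features_as_rows`` (the QIIME export convention, first column
    ``#OTU ID``). ``layout="long"`` reads the sparse three-column form
    (sample_id, feature_id, count) written for very wide tables; zero
    cells are implicit there.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if layout == "long":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        wide = (
            df.pivot_table(
                index=df.columns[0], columns=df.columns[1],
                values=df.columns[2], fill_value=0, aggfunc="sum",
            )
            .rename_axis(index=None, columns=None)
        )
        return FeatureTable(counts=_parse_counts(wide))
    if layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df = _parse_counts(df)
    if orientation == "features_as_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return FeatureTable(counts=df)


def write_feature_table(
    table: FeatureTable, path: str | Path, layout: str = "wide"
) -> None:
    """Write counts as TSV; metadata is never mixed into the count file."""
    if layout == "wide":
        table.counts.to_csv(path, sep="\t", index_label="sample_id")
    elif layout == "long":
        # nonzero cells only; features absent from a sample are implicit zeros
        stacked = table.counts.stack()
        stacked = stacked[stacked > 0]
        long = stacked.rename_axis(["sample_id", "feature_id"]).rename("count")
        long.reset_index().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV keyed by its first column (sample id)."""
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    md.index = md.index.astype(str)
    md.index.name = None
    return md


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted newick tree; tips must be labelled.

    Missing branch lengths are set to 0 with a warning, so topologies
    exported without lengths still parse (Faith PD on them is 0).
    """
    tree = skbio.TreeNode.read(str(path), format="newick")
    defaulted = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            defaulted += 1
        if node.is_tip() and not node.name:
            raise ValueError("tree contains an unlabelled tip")
    if defaulted:
        logger.warning("tree %s: %d branch length(s) missing, set to 0", path, defaulted)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_alpha_matrix(
    matrix: AlphaMatrix, path: str | Path, layout: str = "wide"
) -> None:
    """Serialize a metric table; missing values become empty fields."""
    if layout == "wide":
        matrix.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")
    elif layout == "long":
        long = (
            matrix.values.stack(future_stack=True)
            .rename_axis(["sample_id", "metric"])
            .rename("value")
            .reset_index()
        )
        long["category"] = long["metric"].map(matrix.categories)
        long = long[["sample_id", "metric", "category", "value"]]
        long.to_csv(path, sep="\t", index=False, na_rep="")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_alpha_matrix(
    path: str | Path, categories: dict[str, str] | None = None
) -> AlphaMatrix:
    """Read a wide metric table back; categories default to the registry's."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if categories is None:
        from .alpha_metrics import default_categories

        known = default_categories()
        categories = {m: known[m] for m in df.columns if m in known}
        unknown = [m for m in df.columns if m not in known]
        if unknown:
            raise ValueError(f"metrics with unknown category: {unknown}")
    return AlphaMatrix(values=df.astype(float), categories=categories)
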