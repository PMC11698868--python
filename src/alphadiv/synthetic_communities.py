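"""Synthetic ASV community generator.

Emulates the statistical structure of denoised 16S stool profiles well
enough to exercise every alpha-diversity metric without touching real
sequencing data: each sample gets an exact number of observed taxa (S),
an exact number of singletons (F1) and doubletons (F2 = 40% of F1), and
the remaining taxa draw their abundances from one of five parametric
families. Dominance is manipulated directly by pinning the ratio
between the two most abundant taxa (2x / 10x / 100x).

Design grid defaults: S from 50 to 500 in steps of 10; singletons from
0 in steps of 3 up to min(100, 40% of S). Exact rare-class control
comes from offsetting every non-rare draw by +3, so a drawn abundance
can never collide with the bookkeeping counts 1 and 2.

Features are sample-private (no taxon is shared between samples):
alpha diversity is strictly within-sample, so shared identity would add
nothing but an enormous, almost entirely zero union table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
import pandas as pd
import skbio

from .feature_io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig", "SampleDesign", "SyntheticDataset",
    "build_design_grid", "generate_sample", "apply_unevenness",
    "generate_dataset", "generate_random_tree", "DISTRIBUTION_DEFAULTS",
]

DISTRIBUTION_DEFAULTS: dict[str, dict[str, float]] = {
    # abundance scale ~50 reads/taxon, matching typical non-rarefied
    # per-sample depths of a few thousand to a few tens of thousands reads
    "normal": {"mean": 50.0, "sd": 15.0},
    "negative_binomial": {"mean": 50.0, "dispersion": 0.5},
    "uniform": {"low": 0.0, "high": 100.0},
    "exponential": {"mean": 50.0},
    "poisson": {"lam": 50.0},
}


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic dataset."""

    richness_levels: tuple[int, ...] = tuple(range(50, 501, 10))
    singleton_step: int = 3
    singleton_cap_absolute: int = 100
    singleton_cap_fraction: float = 0.40
    doubleton_fraction: float = 0.40
    distribution: str = "negative_binomial"
    distribution_params: dict[str, float] = field(default_factory=dict)
    unevenness_ratio: float | None = None
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTION_DEFAULTS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; "
                f"choose from {sorted(DISTRIBUTION_DEFAULTS)}"
            )
        if not self.richness_levels:
            raise ValueError("richness_levels is empty")
        if any(s < 3 for s in self.richness_levels):
            raise ValueError("richness levels must all be >= 3")
        if not 0 < self.singleton_cap_fraction < 1:
            raise ValueError("singleton_cap_fraction must be in (0, 1)")
        if self.doubleton_fraction < 0:
            raise ValueError("doubleton_fraction must be >= 0")
        if self.singleton_step < 1:
            raise ValueError("singleton_step must be >= 1")
        if self.unevenness_ratio is not None and self.unevenness_ratio <= 1:
            raise ValueError("unevenness_ratio must be > 1 when set")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        params = dict(DISTRIBUTION_DEFAULTS[self.distribution])
        unknown = set(self.distribution_params) - set(params)
        if unknown:
            raise ValueError(f"unknown distribution parameters: {sorted(unknown)}")
        params.update(self.distribution_params)
        self.distribution_params = params

    def to_dict(self) -> dict:
        d = asdict(self)
        d["richness_levels"] = list(self.richness_levels)
        return d


@dataclass(frozen=True)
class SampleDesign:
    """Target composition of one sample."""

    sample_id: str
    s_target: int
    f1_target: int
    f2_target: int
    distribution: str
    unevenness_ratio: float | None
    replicate: int
    seed: int


def build_design_grid(config: GeneratorConfig) -> list[SampleDesign]:
    """Cartesian grid of richness x singleton schedule.

    Singleton values run 0, step, 2*step, ... up to (inclusive)
    min(absolute cap, floor(fraction * S)); F2 = round(fraction_d * F1).
    Designs that would leave no non-rare taxon are dropped.
    """
    rng = np.random.default_rng(config.seed)
    designs: list[SampleDesign] = []
    for rep in range(config.replicates):
        for s in config.richness_levels:
            cap = min(
                config.singleton_cap_absolute,
                math.floor(config.singleton_cap_fraction * s),
            )
            for f1 in range(0, cap + 1, config.singleton_step):
                f2 = round(config.doubleton_fraction * f1)
                if s - f1 - f2 < 1:
                    continue
                sid = f"S{s:03d}_F1{f1:03d}"
                if config.replicates > 1:
                    sid += f"_r{rep}"
                designs.append(
                    SampleDesign(
                        sample_id=sid,
                        s_target=int(s),
                        f1_target=int(f1),
                        f2_target=int(f2),
                        distribution=config.distribution,
                        unevenness_ratio=config.unevenness_ratio,
                        replicate=rep,
                        seed=int(rng.integers(0, 2**31)),
                    )
                )
    if not designs:
        raise ValueError("design grid is empty under this configuration")
    return designs


def _draw_nonrare(rng: np.random.Generator, distribution: str,
                  params: dict[str, float], k: int) -> np.ndarray:
    if distribution == "normal":
        x = rng.normal(params["mean"], params["sd"], size=k)
        x = np.clip(x, 0.0, None)  # truncate at zero
    elif distribution == "negative_binomial":
        m, disp = params["mean"], params["dispersion"]
        p = disp / (disp + m)
        x = rng.negative_binomial(disp, p, size=k).astype(float)
    elif distribution == "uniform":
        x = rng.uniform(params["low"], params["high"], size=k)
    elif distribution == "exponential":
        x = rng.exponential(params["mean"], size=k)
    elif distribution == "poisson":
        x = rng.poisson(params["lam"], size=k).astype(float)
    else:  # pragma: no cover - config validates earlier
        raise ValueError(f"unknown distribution {distribution!r}")
    return x


def generate_sample(design: SampleDesign, config: GeneratorConfig) -> np.ndarray:
    """One sample's counts: exactly F1 ones, F2 twos, and S-F1-F2 taxa at
    3 + round(draw). Deterministic given the design's seed."""
    k = design.s_target - design.f1_target - design.f2_target
    if k < 1:
        raise ValueError("design leaves no non-rare taxa (S - F1 - F2 < 1)")
    rng = np.random.default_rng(design.seed)
    draws = _draw_nonrare(rng, design.distribution, config.distribution_params, k)
    nonrare = 3 + np.rint(draws).astype(np.int64)
    counts = np.concatenate([
        np.ones(design.f1_target, dtype=np.int64),
        np.full(design.f2_target, 2, dtype=np.int64),
        nonrare,
    ])
    rng.shuffle(counts)
    if design.unevenness_ratio is not None:
        counts = apply_unevenness(counts, design.unevenness_ratio)
    return counts


def apply_unevenness(counts: np.ndarray, ratio: float) -> np.ndarray:
    """Pin the top-two abundance ratio: the most abundant taxon's count
    becomes round(ratio * second-most-abundant count); everything else,
    including the singleton/doubleton bookkeeping, is untouched."""
    counts = np.asarray(counts)
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    if (counts > 0).sum() < 2:
        raise ValueError("unevenness needs at least 2 observed taxa")
    order = np.argsort(counts)
    top, second = order[-1], counts[order[-2]]
    if second < 3:
        raise ValueError(
            "second-most-abundant count < 3: boosting would collide with "
            "singleton/doubleton bookkeeping"
        )
    out = counts.copy()
    out[top] = int(round(ratio * second))
    return out


@dataclass
class SyntheticDataset:
    """A generated dataset: per-sample count vectors plus the design table.

    Count vectors are kept per sample (features are sample-private, so a
    union matrix is almost entirely zeros); ``to_feature_table`` builds
    the dense union on demand for modest grids.
    """

    samples: dict[str, np.ndarray]
    design: pd.DataFrame
    config: GeneratorConfig
    tree: skbio.TreeNode | None = None

    def feature_labels(self, sample_id: str) -> list[str]:
        n = len(self.samples[sample_id])
        return [f"ASV_{sample_id}_{k:04d}" for k in range(n)]

    def iter_labeled(self) -> Iterator[tuple[str, pd.Series]]:
        """Stream (sample_id, feature-labelled counts) in design order."""
        for sample_id in self.design.index:
            counts = self.samples[sample_id]
            yield sample_id, pd.Series(counts, index=self.feature_labels(sample_id))

    def iter_counts(self) -> Iterator[tuple[str, np.ndarray]]:
        for sample_id in self.design.index:
            yield sample_id, self.samples[sample_id]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def all_feature_ids(self) -> list[str]:
        out: list[str] = []
        for sample_id in self.design.index:
            out.extend(self.feature_labels(sample_id))
        return out

    def to_feature_table(self) -> FeatureTable:
        """Dense union table (block structure; zeros off-block)."""
        features = self.all_feature_ids()
        n_cells = len(features) * len(self.samples)
        if n_cells > 5e7:
            logger.warning(
                "materializing a %d x %d union table (%.1e cells); "
                "consider the streaming interfaces instead",
                len(self.samples), len(features), n_cells,
            )
        mat = np.zeros((len(self.samples), len(features)), dtype=np.int64)
        col = 0
        ids = list(self.design.index)
        for row, sample_id in enumerate(ids):
            counts = self.samples[sample_id]
            mat[row, col:col + len(counts)] = counts
            col += len(counts)
        return FeatureTable(
            counts=pd.DataFrame(mat, index=ids, columns=features)
        )

    def write_table(self, path, layout: str = "long") -> None:
        """Stream the table to TSV without building the dense union."""
        if layout == "wide":
            from .feature_io import write_feature_table

            write_feature_table(self.to_feature_table(), path, layout="wide")
            return
        if layout != "long":
            raise ValueError(f"unknown layout {layout!r}")
        with open(path, "w") as fh:
            fh.write("sample_id\tfeature_id\tcount\n")
            for sample_id, series in self.iter_labeled():
                for feature, count in series.items():
                    if count > 0:
                        fh.write(f"{sample_id}\t{feature}\t{int(count)}\n")


def generate_dataset(config: GeneratorConfig, with_tree: bool = False) -> SyntheticDataset:
    """Generate the full design grid under one configuration.

    Fully reproducible from ``config.seed``; two configs differing only
    in seed share an identical design table but different counts.
    """
    designs = build_design_grid(config)
    samples = {d.sample_id: generate_sample(d, config) for d in designs}
    design_df = pd.DataFrame(
        {
            "s_target": [d.s_target for d in designs],
            "f1_target": [d.f1_target for d in designs],
            "f2_target": [d.f2_target for d in designs],
            "distribution": [d.distribution for d in designs],
            "unevenness_ratio": [d.unevenness_ratio for d in designs],
            "replicate": [d.replicate for d in designs],
            "seed": [d.seed for d in designs],
        },
        index=[d.sample_id for d in designs],
    )
    design_df.index.name = "sample_id"
    logger.info(
        "generated %d samples (distribution=%s, ratio=%s, seed=%d)",
        len(designs), config.distribution, config.unevenness_ratio, config.seed,
    )
    dataset = SyntheticDataset(samples=samples, design=design_df, config=config)
    if with_tree:
        dataset.tree = generate_random_tree(
            dataset.all_feature_ids(), seed=config.seed + 1
        )
    return dataset


def generate_random_tree(feature_ids, seed: int) -> skbio.TreeNode:
    """Random rooted binary tree over the given tips.

    Coalescent-style: repeatedly join two uniformly chosen lineages
    under a new parent; branch lengths are i.i.d. exponential(mean 1).
    Byte-identical newick for identical seed.
    """
    ids = [str(f) for f in feature_ids]
    if len(ids) < 2:
        raise ValueError("need at least 2 features to build a tree")
    if len(ids) != len(set(ids)):
        raise ValueError("feature ids must be unique")
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=name) for name in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        nodes.append(skbio.TreeNode(children=[a, b]))
    root = nodes[0]
    root.length = None
    return root
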