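"""Faith's phylogenetic diversity.

Faith PD is the sum of branch lengths of the subtree spanning a
sample's observed taxa. It ignores abundances entirely: a taxon with
one read contributes its full branch path. By default paths run to the
root of the tree (the convention of the common toolchains); set
``include_root=False`` to count only branches below the most recent
common ancestor of the observed set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

__all__ = ["faith_pd", "total_branch_length"]


def _observed_labels(counts: pd.Series) -> list[str]:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or not (arr > 0).any():
        raise ValueError("all-zero sample: faith_pd undefined")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return [str(lbl) for lbl, v in zip(counts.index, arr) if v > 0]


def faith_pd(
    counts: pd.Series,
    tree: skbio.TreeNode,
    include_root: bool = True,
) -> float:
    """Sum of branch lengths over the union of root-to-tip paths of the
    observed features.

    ``counts`` must be indexed by feature id; every feature with a
    positive count must be a tip of ``tree`` (missing features are a
    hard error — silently dropping them would bias PD downward).
    """
    observed = _observed_labels(counts)
    tips = {t.name: t for t in tree.tips()}
    if len(tree.children) == 0:
        # degenerate single-node tree: the root is itself the only tip
        tips.setdefault(tree.name, tree)
    missing = sorted(set(observed) - set(tips))
    if missing:
        raise ValueError(f"observed features absent from tree: {missing[:10]}")

    on_path: dict[int, skbio.TreeNode] = {}
    for label in observed:
        node = tips[label]
        while node.parent is not None and id(node) not in on_path:
            on_path[id(node)] = node
            node = node.parent

    if not include_root:
        # drop the shared tail above the MRCA: nodes whose parent chain is
        # an ancestor of every observed tip
        if len(observed) == 1:
            return 0.0
        mrca = tree.lca([tips[label] for label in observed])
        node = mrca
        while node.parent is not None:
            on_path.pop(id(node), None)
            node = node.parent

    return float(sum(n.length or 0.0 for n in on_path.values()))


def total_branch_length(tree: skbio.TreeNode) -> float:
    """Sum of all branch lengths — the upper bound of faith_pd."""
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=True)))
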