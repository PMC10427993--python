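"""Blomberg's K: phylogenetic signal of a tip-level trait.

K compares the observed ratio of non-phylogenetic to phylogenetically
weighted trait variance against its Brownian-motion expectation on the same
tree, so K = 1 is the Brownian benchmark, K → 0 means relatives resemble
each other no more than random tips, and K > 1 means stronger-than-Brownian
clustering. The Brownian covariance of tips i and j is the shared root-to-
MRCA path length, assembled here without any MRCA-pair scan (one pass over
internal nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import DataError, ValidationError
from .taxa_io import Phylogeny

_SINGULARITY_TOL = 1e-10


@dataclass
class PhyloSignalResult:
    trait_name: str
    k_statistic: float
    n_tips: int
    randomization_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "trait": self.trait_name,
            "K": self.k_statistic,
            "n_tips": self.n_tips,
            "p": self.randomization_p,
        }


def phylo_vcv(phylogeny: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """Brownian variance-covariance matrix of the tips.

    Entry (i, j) is the root-to-MRCA path length of tips i and j; the
    diagonal is the root-to-tip distance. Tip order matches the returned
    label list (the tree's leaf iteration order).
    """
    tree = phylogeny.tree
    labels = phylogeny.tip_labels
    if len(labels) < 2:
        raise ValidationError("need at least 2 tips for a VCV")
    index = {}
    for i, leaf in enumerate(tree.leaf_node_iter()):
        index[id(leaf)] = i
    n = len(labels)
    V = np.zeros((n, n))
    # root-to-node depths; a missing internal/terminal branch length is an error
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = node.edge.length or 0.0
        else:
            if node.edge.length is None:
                raise ValidationError("missing branch length in tree")
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    # leaf sets per node, then off-diagonal fill per internal node
    leafsets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = np.array([index[id(node)]], dtype=int)
            V[index[id(node)], index[id(node)]] = depth[id(node)]
        else:
            children = [leafsets[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    V[np.ix_(children[a], children[b])] = d
                    V[np.ix_(children[b], children[a])] = d
            leafsets[id(node)] = np.concatenate(children)
    return V, labels


def _k_from_vcv(V: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    try:
        factor = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises LinAlgError
        raise DataError(f"singular phylogenetic covariance matrix: {exc}") from exc
    piv = np.diag(factor[0]) ** 2
    if piv.min() < _SINGULARITY_TOL * piv.max():
        raise DataError(
            "phylogenetic covariance matrix numerically singular "
            f"(pivot ratio {piv.min() / piv.max():.2e})"
        )
    ones = np.ones(n)
    Vinv_one = cho_solve(factor, ones)
    Vinv_x = cho_solve(factor, x)
    one_Vinv_one = ones @ Vinv_one
    ahat = (ones @ Vinv_x) / one_Vinv_one  # GLS phylogenetic mean
    r = x - ahat
    mse0 = (r @ r) / (n - 1)
    mse = (r @ cho_solve(factor, r)) / (n - 1)
    expected = (np.trace(V) - n / one_Vinv_one) / (n - 1)
    return float((mse0 / mse) / expected)


def blomberg_k(
    phylogeny: Phylogeny | tuple[np.ndarray, Sequence[str]],
    trait: Mapping[str, float] | Sequence[float],
    trait_name: str = "trait",
    n_shuffles: int = 0,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Blomberg's K for a trait on the tips of a phylogeny.

    ``phylogeny`` may be a :class:`Phylogeny` or a precomputed
    ``(vcv, labels)`` pair (useful when scoring many traits on one tree).
    ``trait`` is a label -> value mapping or a vector in tip order; it must
    cover every tip and have positive variance. With ``n_shuffles`` > 0 a
    tip-label randomization p-value is computed as the fraction of shuffled
    K values at least as large as the observed K.
    """
    if isinstance(phylogeny, Phylogeny):
        V, labels = phylo_vcv(phylogeny)
    else:
        V, labels = phylogeny
        V = np.asarray(V, dtype=float)
    if isinstance(trait, Mapping):
        missing = [lab for lab in labels if lab not in trait]
        if missing:
            raise DataError(f"trait missing for tips {missing[:5]}")
        x = np.array([float(trait[lab]) for lab in labels])
    else:
        x = np.asarray(trait, dtype=float)
        if len(x) != len(labels):
            raise DataError(
                f"trait vector length {len(x)} does not match {len(labels)} tips"
            )
    if np.var(x) == 0:
        raise DataError("constant trait: phylogenetic signal undefined")
    k = _k_from_vcv(V, x)
    p = None
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_shuffles):
            if _k_from_vcv(V, rng.permutation(x)) >= k:
                hits += 1
        p = hits / n_shuffles
    return PhyloSignalResult(
        trait_name=trait_name, k_statistic=k, n_tips=len(labels), randomization_p=p
    )


def trait_from_tally(
    tally: pd.DataFrame, labels: Sequence[str], column: str
) -> tuple[np.ndarray, dict]:
    """Vector of per-genus counts aligned to tree tips.

    Tips absent from the tally score 0 (the genus simply has no such taxa);
    tallied genera absent from the tree are dropped and reported.
    """
    series = tally.set_index("genus")[column]
    x = np.array([float(series.get(lab, 0.0)) for lab in labels])
    dropped = sorted(set(series.index) - set(labels))
    return x, {"n_dropped_not_in_tree": len(dropped), "dropped_genera": dropped[:20]}
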