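"""Pairwise (beta) dissimilarities and all-pairs distance matrices.

Ten built-in metrics: Bray-Curtis, binary Jaccard, Jensen-Shannon
divergence, weighted and unweighted UniFrac, plus the common geometric
distances euclidean, manhattan, canberra, chebyshev, hellinger and
whittaker. The standard geometric cores come from
``scipy.spatial.distance``; the UniFrac pair is computed over a per-branch
descendant-mask table (see :mod:`contribdiv.phylo`).

Missing-value convention: a pair for which the metric is undefined (for
instance Bray-Curtis between two all-zero vectors) yields NaN, which is
propagated symmetrically into distance matrices. Presence, for the binary
metrics and unweighted UniFrac, means a value strictly greater than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

from .exceptions import ValidationError
from .phylo import BranchTable, PhyloTree, branch_table

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "jaccard_binary",
    "jensen_shannon",
    "unweighted_unifrac",
    "weighted_unifrac",
    "euclidean",
    "manhattan",
    "canberra",
    "chebyshev",
    "hellinger",
    "whittaker",
    "BetaMetric",
    "register_beta_metric",
    "available_beta_metrics",
    "get_beta_metric",
    "pairwise_matrix",
]


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            raise ValidationError("vectors have different label order")
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.shape != ya.shape:
        raise ValidationError(
            f"vectors have different lengths: {xa.shape[0]} vs {ya.shape[0]}"
        )
    if (xa < 0).any() or (ya < 0).any():
        raise ValidationError("abundance vectors must be non-negative")
    return xa, ya


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); NaN for two all-zero
    vectors."""
    xa, ya = _pair(x, y)
    if xa.sum() == 0 and ya.sum() == 0:
        return math.nan
    return float(_ssd.braycurtis(xa, ya))


def jaccard_binary(x, y) -> float:
    """Binary Jaccard distance 1 - |A&B|/|A|B| on presence sets."""
    xa, ya = _pair(x, y)
    a = xa > 0
    b = ya > 0
    union = (a | b).sum()
    if union == 0:
        return math.nan
    return float(1.0 - (a & b).sum() / union)


def jensen_shannon(x, y, base: Optional[float] = None) -> float:
    """Jensen-Shannon divergence between the normalised vectors.

    Natural log by default (maximum ln 2); pass ``base`` to rescale. The
    divergence itself is reported, not its square root.
    """
    xa, ya = _pair(x, y)
    if xa.sum() == 0 or ya.sum() == 0:
        return math.nan
    div = float(_ssd.jensenshannon(xa, ya)) ** 2
    if base is not None:
        div /= math.log(base)
    return div


def euclidean(x, y) -> float:
    xa, ya = _pair(x, y)
    return float(_ssd.euclidean(xa, ya))


def manhattan(x, y) -> float:
    xa, ya = _pair(x, y)
    return float(_ssd.cityblock(xa, ya))


def canberra(x, y) -> float:
    xa, ya = _pair(x, y)
    return float(_ssd.canberra(xa, ya))


def chebyshev(x, y) -> float:
    xa, ya = _pair(x, y)
    return float(_ssd.chebyshev(xa, ya))


def hellinger(x, y) -> float:
    """Hellinger distance: euclidean distance between square-rooted
    relative-abundance vectors (range [0, sqrt(2)])."""
    xa, ya = _pair(x, y)
    if xa.sum() == 0 or ya.sum() == 0:
        return math.nan
    p = np.sqrt(xa / xa.sum())
    q = np.sqrt(ya / ya.sum())
    return float(np.linalg.norm(p - q))


def whittaker(x, y) -> float:
    """Whittaker's index of association: half the manhattan distance
    between relative-abundance vectors (range [0, 1])."""
    xa, ya = _pair(x, y)
    if xa.sum() == 0 or ya.sum() == 0:
        return math.nan
    return float(0.5 * np.abs(xa / xa.sum() - ya / ya.sum()).sum())


def _labels_of(x) -> list[str]:
    if not isinstance(x, pd.Series):
        raise ValidationError("UniFrac requires labelled vectors (pandas Series)")
    return [str(l) for l in x.index]


def _branches_for_pair(x, y, tree: Optional[PhyloTree], branches: Optional[BranchTable]) -> BranchTable:
    labels = _labels_of(x)
    if branches is not None:
        if list(branches.taxa) != labels:
            raise ValidationError("branch table does not match vector labels")
        return branches
    if tree is None:
        raise ValidationError("UniFrac requires a tree")
    tips = {t.name for t in tree.tips()}
    present = (np.asarray(x, float) > 0) | (np.asarray(y, float) > 0)
    missing = [l for l, p in zip(labels, present) if p and l not in tips]
    if missing:
        raise ValidationError(f"present taxa missing from the tree: {missing}")
    # branches over the in-tree labels only; absent-from-tree labels all
    # have zero abundance, so they cannot influence the result
    keep = [l for l in labels if l in tips]
    bt = branch_table(tree, keep)
    if keep != labels:
        col = {l: i for i, l in enumerate(keep)}
        masks = np.zeros((bt.masks.shape[0], len(labels)), dtype=bool)
        for j, l in enumerate(labels):
            if l in col:
                masks[:, j] = bt.masks[:, col[l]]
        bt = BranchTable(taxa=tuple(labels), lengths=bt.lengths, masks=masks)
    return bt


def unweighted_unifrac(
    x, y, tree: Optional[PhyloTree] = None, *, branches: Optional[BranchTable] = None
) -> float:
    """Unweighted UniFrac: unshared branch length over observed branch length.

    A branch counts as observed in a sample when any tip below it is
    present (> 0). NaN when neither sample has any present tip.
    """
    bt = _branches_for_pair(x, y, tree, branches)
    xa, ya = _pair(x, y)
    a = bt.masks @ (xa > 0)
    b = bt.masks @ (ya > 0)
    observed = a | b
    if not observed.any():
        return math.nan
    total = bt.lengths[observed].sum()
    if total == 0:
        return math.nan
    unshared = bt.lengths[a ^ b].sum()
    return float(unshared / total)


def weighted_unifrac(
    x,
    y,
    tree: Optional[PhyloTree] = None,
    normalized: bool = True,
    *,
    branches: Optional[BranchTable] = None,
) -> float:
    """Weighted UniFrac: sum_b l_b |p_b - q_b| over branches, where p_b is
    the fraction of sample x's total abundance descending branch b.

    With ``normalized`` (the default) the sum is divided by
    sum_b l_b (p_b + q_b), bounding the result to [0, 1]. NaN when either
    vector sums to zero.
    """
    bt = _branches_for_pair(x, y, tree, branches)
    xa, ya = _pair(x, y)
    if xa.sum() == 0 or ya.sum() == 0:
        return math.nan
    p = bt.masks @ (xa / xa.sum())
    q = bt.masks @ (ya / ya.sum())
    raw = float((bt.lengths * np.abs(p - q)).sum())
    if not normalized:
        return raw
    denom = float((bt.lengths * (p + q)).sum())
    if denom == 0:
        return math.nan
    return raw / denom


@dataclass(frozen=True)
class BetaMetric:
    name: str
    func: Callable
    requires_tree: bool = False


_BETA_REGISTRY: dict[str, BetaMetric] = {}

for _m in (
    BetaMetric("bray_curtis", bray_curtis),
    BetaMetric("jaccard_binary", jaccard_binary),
    BetaMetric("jensen_shannon", jensen_shannon),
    BetaMetric("unweighted_unifrac", unweighted_unifrac, requires_tree=True),
    BetaMetric("weighted_unifrac", weighted_unifrac, requires_tree=True),
    BetaMetric("euclidean", euclidean),
    BetaMetric("manhattan", manhattan),
    BetaMetric("canberra", canberra),
    BetaMetric("chebyshev", chebyshev),
    BetaMetric("hellinger", hellinger),
    BetaMetric("whittaker", whittaker),
):
    _BETA_REGISTRY[_m.name] = _m

BUILTIN_BETA_METRICS = tuple(_BETA_REGISTRY)


def register_beta_metric(
    name: str,
    func: Callable,
    *,
    requires_tree: bool = False,
    override: bool = False,
) -> None:
    """Add a user-defined pairwise dissimilarity to the registry."""
    if name in _BETA_REGISTRY and not override:
        raise ValidationError(
            f"beta metric {name!r} is already registered (pass override=True)"
        )
    _BETA_REGISTRY[name] = BetaMetric(name=name, func=func, requires_tree=requires_tree)


def available_beta_metrics() -> list[str]:
    return list(_BETA_REGISTRY)


def get_beta_metric(name: str) -> BetaMetric:
    if name not in _BETA_REGISTRY:
        raise ValidationError(
            f"unknown beta metric {name!r}; available: {available_beta_metrics()}"
        )
    return _BETA_REGISTRY[name]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity matrix; NaN marks pairs for
    which the metric is undefined."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.data.columns):
            raise ValidationError("distance matrix rows and columns differ")
        v = self.data.to_numpy(dtype=float)
        both = np.isnan(v) | np.isnan(v.T)
        if not np.allclose(
            np.where(both, 0.0, v), np.where(both, 0.0, v.T), atol=1e-12
        ) or not (np.isnan(v) == np.isnan(v.T)).all():
            raise ValidationError("distance matrix is not symmetric")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.data.at[i, j])

    def to_tsv(self, path, delimiter: str = "\t", condensed: bool = False) -> None:
        """Write square TSV (default) or a condensed lower-triangle long
        format with columns sample_i, sample_j, value."""
        if not condensed:
            self.data.to_csv(path, sep=delimiter, index_label="sample")
            return
        ids = self.sample_ids
        rows = [
            (ids[i], ids[j], self.data.iat[i, j])
            for i in range(1, len(ids))
            for j in range(i)
        ]
        pd.DataFrame(rows, columns=["sample_i", "sample_j", "value"]).to_csv(
            path, sep=delimiter, index=False
        )


def pairwise_matrix(
    table,
    metric_name: str,
    tree: Optional[PhyloTree] = None,
    **metric_kwargs,
) -> DistanceMatrix:
    """All-pairs distance matrix over the samples (columns) of an abundance
    table.

    ``table`` is a :class:`~contribdiv.tables_io.TaxonAbundanceTable` or a
    taxa x samples DataFrame. Tree metrics precompute the branch table once
    for all pairs. Entry (i, j) is metric(column i, column j); the diagonal
    is 0 wherever the metric defines it.
    """
    df = table.data if hasattr(table, "data") else pd.DataFrame(table)
    if df.shape[1] < 2:
        raise ValidationError("pairwise_matrix needs at least 2 samples")
    metric = get_beta_metric(metric_name)
    kwargs = dict(metric_kwargs)
    if metric.requires_tree:
        if tree is None:
            raise ValidationError(f"metric {metric_name!r} requires a tree")
        labels = [str(l) for l in df.index]
        tips = {t.name for t in tree.tips()}
        observed = df.to_numpy(dtype=float).sum(axis=1) > 0
        missing = [l for l, o in zip(labels, observed) if o and l not in tips]
        if missing:
            raise ValidationError(f"present taxa missing from the tree: {missing}")
        keep = [l for l in labels if l in tips]
        bt = branch_table(tree, keep)
        if keep != labels:
            col = {l: i for i, l in enumerate(keep)}
            masks = np.zeros((bt.masks.shape[0], len(labels)), dtype=bool)
            for j, l in enumerate(labels):
                if l in col:
                    masks[:, j] = bt.masks[:, col[l]]
            bt = BranchTable(taxa=tuple(labels), lengths=bt.lengths, masks=masks)
        kwargs["branches"] = bt
        kwargs.pop("tree", None)

    samples = list(df.columns)
    n = len(samples)
    out = np.zeros((n, n), dtype=float)
    cols = [df.iloc[:, i] for i in range(n)]
    for i in range(n):
        out[i, i] = metric.func(cols[i], cols[i], **kwargs)
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = metric.func(cols[i], cols[j], **kwargs)
    return DistanceMatrix(pd.DataFrame(out, index=samples, columns=samples))
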