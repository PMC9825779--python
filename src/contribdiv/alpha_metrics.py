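"""Within-sample (alpha) diversity metrics and the metric registry.

Fifteen built-in metrics are provided, the classical richness, evenness
and dominance family plus Faith's phylogenetic diversity:

========================  =====================================================
name                      definition (p_i = v_i / sum(v); S = richness;
                          N = sum(v), counts)
========================  =====================================================
richness                  number of entries with v_i > 0
shannon_index             H = -sum p_i log2 p_i (log base configurable)
gini_simpson              1 - sum p_i^2
inverse_simpson           1 / sum p_i^2
simpsons_evenness         (1 / sum p_i^2) / S
pielou_evenness           H / log2 S
berger_parker_dominance   max p_i
ens_pie                   1 / sum p_i^2 (effective number of species of PIE)
faiths_pd                 sum of branch lengths spanning present tips' root
                          paths on a rooted phylogeny
fishers_alpha             alpha solving S = alpha * ln(1 + N / alpha)
heips_evenness            (e^{H_e} - 1) / (S - 1), natural-log Shannon
margalefs_richness        (S - 1) / ln N
mcintoshs_dominance       (N - U) / (N - sqrt(N)),  U = sqrt(sum v_i^2)
mcintoshs_evenness        U / sqrt((N - S + 1)^2 + S - 1)
menhinicks_richness       S / sqrt(N)
========================  =====================================================

Metrics in the lower block interpret the vector as counts (they depend on
the total N, not only on proportions) and are flagged ``requires_counts``;
given non-integer input they proceed on the totals as given, without
rounding. Undefined cases (zero-sum vector; evenness at S <= 1;
non-convergent Fisher's alpha) return NaN rather than raising — absence is
information the caller keeps.

Custom metrics can be added to the registry with :func:`register_metric`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .phylo import BranchTable, PhyloTree, branch_table

__all__ = [
    "richness",
    "shannon_index",
    "gini_simpson",
    "inverse_simpson",
    "simpsons_evenness",
    "pielou_evenness",
    "berger_parker_dominance",
    "ens_pie",
    "faiths_pd",
    "fishers_alpha",
    "heips_evenness",
    "margalefs_richness",
    "mcintoshs_dominance",
    "mcintoshs_evenness",
    "menhinicks_richness",
    "AlphaMetric",
    "register_metric",
    "available_metrics",
    "get_metric",
    "compute_alpha",
]


def _as_vector(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if (arr < 0).any():
        raise ValidationError("abundance vector contains negative values")
    return arr


def _proportions(v: np.ndarray) -> Optional[np.ndarray]:
    total = v.sum()
    if total <= 0:
        return None
    return v / total


def richness(v) -> int:
    """Observed richness: number of strictly positive entries."""
    return int(np.count_nonzero(_as_vector(v) > 0))


def shannon_index(v, base: float = 2.0) -> float:
    """Shannon entropy H of the relative abundances (default bits).

    ``0 * log 0`` is taken as 0; a zero-sum vector gives NaN.
    """
    p = _proportions(_as_vector(v))
    if p is None:
        return math.nan
    p = p[p > 0]
    return float(-(p * (np.log(p) / math.log(base))).sum() + 0.0)


def gini_simpson(v) -> float:
    """Gini-Simpson index 1 - sum p_i^2: probability that two random
    individuals belong to different taxa."""
    p = _proportions(_as_vector(v))
    if p is None:
        return math.nan
    return float(1.0 - (p**2).sum())


def inverse_simpson(v) -> float:
    """Inverse Simpson concentration 1 / sum p_i^2."""
    p = _proportions(_as_vector(v))
    if p is None:
        return math.nan
    return float(1.0 / (p**2).sum())


def simpsons_evenness(v) -> float:
    """Inverse Simpson divided by richness (E_1/D)."""
    arr = _as_vector(v)
    s = richness(arr)
    if s == 0:
        return math.nan
    return inverse_simpson(arr) / s


def pielou_evenness(v, base: float = 2.0) -> float:
    """Pielou's J = H / log S; NaN when S <= 1 (log S = 0)."""
    arr = _as_vector(v)
    s = richness(arr)
    if s <= 1 or arr.sum() <= 0:
        return math.nan
    return shannon_index(arr, base=base) / (math.log(s) / math.log(base))


def berger_parker_dominance(v) -> float:
    """Berger-Parker dominance: the largest relative abundance."""
    p = _proportions(_as_vector(v))
    if p is None:
        return math.nan
    return float(p.max())


def ens_pie(v) -> float:
    """Effective number of species based on the probability of
    interspecific encounter; numerically the inverse Simpson index."""
    return inverse_simpson(v)


def faiths_pd(v, tree: Optional[PhyloTree] = None, *, branches: Optional[BranchTable] = None) -> float:
    """Faith's phylogenetic diversity of the taxa present in ``v``.

    ``v`` must be label-aware (a pandas Series indexed by taxon). The value
    is the total branch length of the union of root-to-tip paths of present
    tips (strictly positive abundance); 0 when nothing is present. A
    precomputed :class:`~contribdiv.phylo.BranchTable` over exactly the
    vector's labels may be passed to amortise the tree traversal.
    """
    if not isinstance(v, pd.Series):
        raise ValidationError("faiths_pd requires a labelled vector (pandas Series)")
    values = _as_vector(v.to_numpy())
    present = values > 0
    if not present.any():
        return 0.0
    labels = [str(x) for x in v.index]
    if branches is None:
        if tree is None:
            raise ValidationError("faiths_pd requires a tree")
        tips = {t.name for t in tree.tips()}
        missing = [l for l, p in zip(labels, present) if p and l not in tips]
        if missing:
            raise ValidationError(
                f"present taxa missing from the tree: {missing}"
            )
        branches = branch_table(tree, [l for l, p in zip(labels, present) if p])
        return branches.total_length
    if list(branches.taxa) != labels:
        raise ValidationError("branch table does not match vector labels")
    return branches.faith_pd(present)


def fishers_alpha(v, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Fisher's log-series alpha: the root of S = alpha * ln(1 + N/alpha).

    Solved by Newton iteration from alpha = S; non-convergence (e.g. S = N,
    where no finite root exists) returns NaN with a warning.
    """
    arr = _as_vector(v)
    s = richness(arr)
    n = float(arr.sum())
    if s == 0 or n <= 0:
        return math.nan
    if s >= n:
        # sup_a a*ln(1+N/a) = N, so S >= N has no finite root
        warnings.warn(
            f"fishers_alpha has no finite solution when S >= N (S={s}, N={n}); "
            "returning NaN",
            stacklevel=2,
        )
        return math.nan
    alpha = float(s)
    for _ in range(max_iter):
        f = alpha * math.log1p(n / alpha) - s
        fprime = math.log1p(n / alpha) - n / (alpha + n)
        if fprime == 0:
            break
        step = f / fprime
        new = alpha - step
        if new <= 0:
            new = alpha / 2.0
        if abs(new - alpha) < tol:
            alpha = new
            break
        alpha = new
    if abs(alpha * math.log1p(n / alpha) - s) >= tol:
        warnings.warn(
            f"fishers_alpha did not converge (S={s}, N={n}); returning NaN",
            stacklevel=2,
        )
        return math.nan
    return alpha


def heips_evenness(v) -> float:
    """Heip's evenness (e^H - 1) / (S - 1) with natural-log Shannon H."""
    arr = _as_vector(v)
    s = richness(arr)
    if s <= 1 or arr.sum() <= 0:
        return math.nan
    h = shannon_index(arr, base=math.e)
    return (math.exp(h) - 1.0) / (s - 1.0)


def margalefs_richness(v) -> float:
    """Margalef's richness (S - 1) / ln N; NaN when ln N = 0."""
    arr = _as_vector(v)
    s = richness(arr)
    n = float(arr.sum())
    if s == 0 or n <= 0 or n == 1.0:
        return math.nan
    return (s - 1.0) / math.log(n)


def mcintoshs_dominance(v) -> float:
    """McIntosh dominance (N - U) / (N - sqrt(N)), U = sqrt(sum v_i^2)."""
    arr = _as_vector(v)
    n = float(arr.sum())
    if n <= 0 or n == 1.0:
        return math.nan
    u = math.sqrt(float((arr**2).sum()))
    return (n - u) / (n - math.sqrt(n))


def mcintoshs_evenness(v) -> float:
    """McIntosh evenness U / sqrt((N - S + 1)^2 + S - 1)."""
    arr = _as_vector(v)
    s = richness(arr)
    n = float(arr.sum())
    if s == 0 or n <= 0:
        return math.nan
    u = math.sqrt(float((arr**2).sum()))
    return u / math.sqrt((n - s + 1.0) ** 2 + s - 1.0)


def menhinicks_richness(v) -> float:
    """Menhinick's richness S / sqrt(N)."""
    arr = _as_vector(v)
    s = richness(arr)
    n = float(arr.sum())
    if s == 0 or n <= 0:
        return math.nan
    return s / math.sqrt(n)


@dataclass(frozen=True)
class AlphaMetric:
    """Registry entry: the callable plus its input requirements."""

    name: str
    func: Callable
    requires_tree: bool = False
    requires_counts: bool = False


_REGISTRY: dict[str, AlphaMetric] = {}


def register_metric(
    name: str,
    func: Callable,
    *,
    requires_tree: bool = False,
    requires_counts: bool = False,
    override: bool = False,
) -> None:
    """Add a user-defined alpha metric to the registry.

    ``func`` receives the (label-aware, when the metric needs labels)
    abundance vector, plus ``tree=`` when ``requires_tree``. Re-registering
    an existing name is an error unless ``override`` is requested.
    """
    if name in _REGISTRY and not override:
        raise ValidationError(
            f"metric {name!r} is already registered (pass override=True to replace)"
        )
    _REGISTRY[name] = AlphaMetric(
        name=name,
        func=func,
        requires_tree=requires_tree,
        requires_counts=requires_counts,
    )


def available_metrics() -> list[str]:
    """Names of all registered alpha metrics, in registration order."""
    return list(_REGISTRY)


def get_metric(name: str) -> AlphaMetric:
    if name not in _REGISTRY:
        raise ValidationError(
            f"unknown alpha metric {name!r}; available: {available_metrics()}"
        )
    return _REGISTRY[name]


def compute_alpha(v, metric_name: str, tree: Optional[PhyloTree] = None, **kwargs) -> float:
    """Dispatch an abundance vector to a registered metric.

    ``v`` may be a pandas Series (required for tree metrics) or any
    array-like. Metric-specific undefined cases come back as NaN; unknown
    names and a missing tree for a tree-requiring metric raise.
    """
    metric = get_metric(metric_name)
    if metric.requires_tree:
        if tree is None and "branches" not in kwargs:
            raise ValidationError(f"metric {metric_name!r} requires a tree")
        return float(metric.func(v, tree=tree, **kwargs))
    return float(metric.func(v, **kwargs))


for _m in (
    AlphaMetric("richness", richness),
    AlphaMetric("shannon_index", shannon_index),
    AlphaMetric("gini_simpson", gini_simpson),
    AlphaMetric("inverse_simpson", inverse_simpson),
    AlphaMetric("simpsons_evenness", simpsons_evenness),
    AlphaMetric("pielou_evenness", pielou_evenness),
    AlphaMetric("berger_parker_dominance", berger_parker_dominance),
    AlphaMetric("ens_pie", ens_pie),
    AlphaMetric("faiths_pd", faiths_pd, requires_tree=True),
    AlphaMetric("fishers_alpha", fishers_alpha, requires_counts=True),
    AlphaMetric("heips_evenness", heips_evenness),
    AlphaMetric("margalefs_richness", margalefs_richness, requires_counts=True),
    AlphaMetric("mcintoshs_dominance", mcintoshs_dominance, requires_counts=True),
    AlphaMetric("mcintoshs_evenness", mcintoshs_evenness, requires_counts=True),
    AlphaMetric("menhinicks_richness", menhinicks_richness, requires_counts=True),
):
    _REGISTRY[_m.name] = _m

#: the 15 built-in metric names (frozen tuple; user metrics come after)
BUILTIN_METRICS = tuple(_REGISTRY)
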