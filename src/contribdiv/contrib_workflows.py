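"""Per-function contributional diversity workflows.

Contributional diversity asks, for every function in a linked taxa-function
dataset: how diverse are the taxa that encode this function? The alpha
workflow answers it within each sample (one value per function x sample);
the beta workflow answers it between samples (one sample x sample distance
matrix per function).

The contributor rule is binary: a taxon contributes a function when its
copy number for that function is strictly positive; multiplicity is
ignored. Restricted abundance vectors are the raw abundances of the
contributing taxa — no renormalisation against whole-community totals —
since the quantity of interest is the diversity of the contributors
themselves, and proportion-based metrics normalise internally.

Missing-value semantics: a (function, sample) cell where no contributor is
present (or a function with no contributors at all) is NaN, or 0 when
``zero_fill`` is requested; it is never an exception. For beta, per-pair
NaN rules come from :mod:`contribdiv.beta_metrics`.

Work is partitioned across functions; results are gathered in input
function order, so outputs are bit-identical for any worker count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import alpha_metrics, beta_metrics
from .beta_metrics import DistanceMatrix
from .exceptions import ContribDivError, ValidationError
from .phylo import PhyloTree
from .tables_io import FunctionCopyNumberTable, TaxonAbundanceTable

__all__ = [
    "AlphaResult",
    "BetaResult",
    "contributors_of",
    "alpha_div_contrib",
    "beta_div_contrib",
    "run_parallel",
]


def contributors_of(function_id: str, cn: FunctionCopyNumberTable) -> list:
    """Taxa encoding a function: copy number strictly greater than zero.

    Returned in the copy-number table's row order; copy-number magnitude is
    discarded (single- and multi-copy contributors are equivalent).
    """
    if function_id not in cn.data.columns:
        raise ValidationError(
            f"unknown function {function_id!r} (table has {cn.data.shape[1]} functions)"
        )
    col = cn.data[function_id].to_numpy(dtype=float)
    return list(cn.data.index[col > 0])


@dataclass(frozen=True)
class AlphaResult:
    """Per-metric functions x samples matrices of alpha diversity values."""

    tables: dict[str, pd.DataFrame] = field(repr=False)

    @property
    def metric_names(self) -> list[str]:
        return list(self.tables)

    def __getitem__(self, metric_name: str) -> pd.DataFrame:
        return self.tables[metric_name]

    def write(self, outdir, delimiter: str = "\t") -> None:
        """One functions x samples TSV per metric under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables.items():
            tab.to_csv(out / f"alpha_{name}.tsv", sep=delimiter, index_label="function")


@dataclass(frozen=True)
class BetaResult:
    """Per-metric, per-function sample x sample distance matrices."""

    matrices: dict[str, dict[str, DistanceMatrix]] = field(repr=False)

    @property
    def metric_names(self) -> list[str]:
        return list(self.matrices)

    def __getitem__(self, metric_name: str) -> dict[str, DistanceMatrix]:
        return self.matrices[metric_name]

    def write(self, outdir, delimiter: str = "\t") -> None:
        """Write ``outdir/<metric>/<function>.tsv`` square matrices.

        Function ids are sanitised for filesystem safety; a
        ``function_id_map.tsv`` mapping file records the correspondence.
        """
        from pathlib import Path

        out = Path(outdir)
        for metric, per_func in self.matrices.items():
            mdir = out / metric
            mdir.mkdir(parents=True, exist_ok=True)
            mapping = []
            used: set[str] = set()
            for fid, dm in per_func.items():
                safe = _sanitize(fid, used)
                mapping.append((fid, f"{safe}.tsv"))
                dm.to_tsv(mdir / f"{safe}.tsv", delimiter=delimiter)
            pd.DataFrame(mapping, columns=["function_id", "filename"]).to_csv(
                mdir / "function_id_map.tsv", sep=delimiter, index=False
            )


def _sanitize(fid: str, used: set) -> str:
    import re

    safe = re.sub(r"[^A-Za-z0-9._-]", "_", str(fid)) or "function"
    base, k = safe, 1
    while safe in used:
        k += 1
        safe = f"{base}.{k}"
    used.add(safe)
    return safe


def run_parallel(items: Sequence, fn: Callable, n_workers: int = 1) -> list:
    """Apply ``fn`` to each item, optionally across threads.

    Results come back in input order whatever the worker count, so parallel
    output is bit-identical to the sequential path. A failure inside a
    worker is re-raised tagged with the offending item.
    """
    if n_workers < 1:
        raise ValidationError("n_workers must be >= 1")

    def _safe(item):
        try:
            return fn(item)
        except ContribDivError:
            raise
        except Exception as exc:  # tag internal failures with the item id
            raise ContribDivError(f"while processing {item!r}: {exc}") from exc

    if n_workers == 1:
        return [_safe(item) for item in items]
    return Parallel(n_jobs=n_workers, prefer="threads")(
        delayed(_safe)(item) for item in items
    )


def _align(
    abund: TaxonAbundanceTable, cn: FunctionCopyNumberTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align the two wide tables on a shared taxon index.

    Taxa only in the copy-number table get zero abundance everywhere; taxa
    only in the abundance table encode no functions. Either mismatch warns;
    zero overlap is an error.
    """
    a, c = abund.data, cn.data
    shared = set(a.index) & set(c.index)
    if not shared:
        raise ValidationError(
            "no overlap between abundance-table and copy-number-table taxa"
        )
    only_a = [t for t in a.index if t not in shared]
    only_c = [t for t in c.index if t not in shared]
    if only_a or only_c:
        warnings.warn(
            f"taxon label mismatch: {len(only_a)} taxa lack copy-number rows "
            f"(treated as encoding no functions), {len(only_c)} lack abundance "
            "rows (treated as abundance 0 everywhere)",
            stacklevel=3,
        )
    taxa = list(a.index) + only_c
    a2 = a.reindex(taxa, fill_value=0.0).astype(float)
    c2 = c.reindex(taxa, fill_value=0.0).astype(float)
    return a2, c2


def _resolve_alpha_metrics(metrics) -> list[str]:
    if isinstance(metrics, str):
        metrics = list(alpha_metrics.BUILTIN_METRICS) if metrics == "all" else [metrics]
    names = list(metrics)
    for name in names:
        alpha_metrics.get_metric(name)
    return names


def alpha_div_contrib(
    abund: TaxonAbundanceTable,
    cn: FunctionCopyNumberTable,
    metrics="all",
    tree: Optional[PhyloTree] = None,
    zero_fill: bool = False,
    n_workers: int = 1,
) -> AlphaResult:
    """Contributional alpha diversity: metric values per function and sample.

    For each requested metric, cell (f, s) is the metric applied to the
    abundance vector of f's contributing taxa in sample s. ``metrics`` is a
    name list or ``"all"`` (every built-in metric; requires a tree when it
    includes Faith's PD).
    """
    names = _resolve_alpha_metrics(metrics)
    infos = [alpha_metrics.get_metric(n) for n in names]
    if any(m.requires_tree for m in infos) and tree is None:
        need = [m.name for m in infos if m.requires_tree]
        raise ValidationError(f"metrics {need} require a tree")
    a2, c2 = _align(abund, cn)
    samples = list(a2.columns)
    functions = list(c2.columns)
    fill = 0.0 if zero_fill else math.nan

    branches = None
    if any(m.requires_tree for m in infos):
        from .phylo import branch_table

        labels = [str(t) for t in a2.index]
        tips = {t.name for t in tree.tips()}
        observed = a2.to_numpy(dtype=float).sum(axis=1) > 0
        missing = [l for l, o in zip(labels, observed) if o and l not in tips]
        if missing:
            raise ValidationError(f"present taxa missing from the tree: {missing}")
        keep = [l for l in labels if l in tips]
        bt = branch_table(tree, keep)
        col = {l: i for i, l in enumerate(keep)}
        masks = np.zeros((bt.masks.shape[0], len(labels)), dtype=bool)
        for j, l in enumerate(labels):
            if l in col:
                masks[:, j] = bt.masks[:, col[l]]
        branches = (bt.lengths, masks)

    a_values = a2.to_numpy(dtype=float)
    taxa_index = {t: i for i, t in enumerate(a2.index)}

    def _one_function(func: str) -> dict[str, np.ndarray]:
        contrib = c2.index[c2[func].to_numpy(dtype=float) > 0]
        rows = np.array([taxa_index[t] for t in contrib], dtype=int)
        out = {name: np.full(len(samples), fill) for name in names}
        if rows.size == 0:
            return out
        sub = a_values[rows, :]
        sub_labels = pd.Index(contrib)
        for s_i in range(len(samples)):
            vec = sub[:, s_i]
            if not (vec > 0).any():
                continue  # stays at fill
            series = pd.Series(vec, index=sub_labels)
            for name, info in zip(names, infos):
                if info.requires_tree and info.func is alpha_metrics.faiths_pd:
                    lengths, masks = branches
                    present = np.zeros(masks.shape[1], dtype=bool)
                    present[rows] = vec > 0
                    out[name][s_i] = float(lengths[masks @ present].sum())
                elif info.requires_tree:
                    out[name][s_i] = float(info.func(series, tree=tree))
                else:
                    out[name][s_i] = float(info.func(series.to_numpy()))
        return out

    per_func = run_parallel(functions, _one_function, n_workers=n_workers)
    tables = {
        name: pd.DataFrame(
            np.vstack([res[name] for res in per_func]) if functions else
            np.zeros((0, len(samples))),
            index=functions,
            columns=samples,
        )
        for name in names
    }
    return AlphaResult(tables)


def _resolve_beta_metrics(metrics) -> list[str]:
    if isinstance(metrics, str):
        metrics = (
            list(beta_metrics.BUILTIN_BETA_METRICS) if metrics == "all" else [metrics]
        )
    names = list(metrics)
    for name in names:
        beta_metrics.get_beta_metric(name)
    return names


def beta_div_contrib(
    abund: TaxonAbundanceTable,
    cn: FunctionCopyNumberTable,
    metrics="bray_curtis",
    tree: Optional[PhyloTree] = None,
    normalized: bool = True,
    n_workers: int = 1,
) -> BetaResult:
    """Contributional beta diversity: per-function all-sample distance
    matrices.

    For each function f, the abundance table is restricted to f's
    contributing taxa and an all-pairs distance matrix over the full sample
    set is computed. ``normalized`` selects the bounded weighted-UniFrac
    variant.
    """
    names = _resolve_beta_metrics(metrics)
    infos = [beta_metrics.get_beta_metric(n) for n in names]
    if any(m.requires_tree for m in infos) and tree is None:
        need = [m.name for m in infos if m.requires_tree]
        raise ValidationError(f"metrics {need} require a tree")
    a2, c2 = _align(abund, cn)
    samples = list(a2.columns)
    if len(samples) < 2:
        raise ValidationError("beta diversity needs at least 2 samples")
    functions = list(c2.columns)

    def _one_function(func: str) -> dict[str, DistanceMatrix]:
        contrib = list(c2.index[c2[func].to_numpy(dtype=float) > 0])
        out: dict[str, DistanceMatrix] = {}
        if not contrib:
            nanmat = pd.DataFrame(
                np.full((len(samples), len(samples)), math.nan),
                index=samples,
                columns=samples,
            )
            for name in names:
                out[name] = DistanceMatrix(nanmat)
            return out
        sub = TaxonAbundanceTable(a2.loc[contrib])
        for name, info in zip(names, infos):
            kwargs = {"normalized": normalized} if name == "weighted_unifrac" else {}
            out[name] = beta_metrics.pairwise_matrix(
                sub, name, tree=tree if info.requires_tree else None, **kwargs
            )
        return out

    per_func = run_parallel(functions, _one_function, n_workers=n_workers)
    matrices = {
        name: {f: res[name] for f, res in zip(functions, per_func)} for name in names
    }
    return BetaResult(matrices)
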