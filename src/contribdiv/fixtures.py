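"""Deterministic synthetic linked taxa-function datasets.

Everything the package needs for testing and demonstration is generated in
memory from a single integer seed: a taxon abundance table, a function
copy-number table and a random rooted phylogeny whose tips are exactly the
taxon set. The generator emulates the shape of MAG-based datasets — sparse
gene repertoires, right-skewed abundances, occasional absences — not their
ecological covariance structure.

RNG stream order is fixed and documented so fixtures are stable across
versions: (1) abundances, (2) abundance dropout mask, (3) copy-number
presence mask, (4) copy-number magnitudes, (5) tree topology choices,
(6) branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .exceptions import ValidationError
from .phylo import PhyloTree
from .tables_io import (
    ContributionalTable,
    FunctionCopyNumberTable,
    TaxonAbundanceTable,
    wide_to_contrib,
)

__all__ = ["FixtureSpec", "generate_fixture", "random_tree", "generate_toy_worked_example", "ToyBundle"]

#: probability that a taxon is absent from a sample (fixed; emulates patchy
#: occupancy so missing-value paths are exercised)
_ABUNDANCE_DROPOUT = 0.2


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dataset.

    sparsity is the probability that a (taxon, function) copy number is
    zero: 0 gives a strictly positive table, 1 an all-zero one.
    """

    n_taxa: int = 10
    n_samples: int = 6
    n_functions: int = 8
    sparsity: float = 0.3
    seed: int = 0
    abundance_model: str = "lognormal"

    def __post_init__(self) -> None:
        if min(self.n_taxa, self.n_samples, self.n_functions) < 1:
            raise ValidationError("n_taxa, n_samples and n_functions must be >= 1")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValidationError("sparsity must be in [0, 1]")
        if self.abundance_model not in ("uniform", "lognormal"):
            raise ValidationError("abundance_model must be 'uniform' or 'lognormal'")


def random_tree(tip_names, rng: np.random.Generator) -> PhyloTree:
    """Random bifurcating rooted tree over ``tip_names`` with exponential
    (mean 1) branch lengths."""
    tips = [TreeNode(name=str(n)) for n in tip_names]
    if len(tips) == 1:
        root = TreeNode()
        root.append(tips[0])
        tips[0].length = float(rng.exponential(1.0))
        return root
    root = TreeNode()
    root.append(tips[0])
    root.append(tips[1])
    attached = [tips[0], tips[1]]
    for tip in tips[2:]:
        # split a uniformly chosen existing tip edge
        target = attached[int(rng.integers(0, len(attached)))]
        parent = target.parent
        joint = TreeNode()
        parent.remove(target)
        parent.append(joint)
        joint.append(target)
        joint.append(tip)
        attached.append(tip)
    for n in root.traverse(include_self=False):
        n.length = float(rng.exponential(1.0))
    return root


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[TaxonAbundanceTable, FunctionCopyNumberTable, PhyloTree]:
    """Generate linked tables and a tree; identical spec gives identical
    output."""
    rng = np.random.default_rng(spec.seed)
    taxa = [f"T{i + 1:03d}" for i in range(spec.n_taxa)]
    samples = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    functions = [f"F{k + 1:03d}" for k in range(spec.n_functions)]

    shape = (spec.n_taxa, spec.n_samples)
    if spec.abundance_model == "uniform":
        ab = rng.uniform(0.1, 1.0, size=shape)
    else:
        ab = rng.lognormal(mean=0.0, sigma=1.0, size=shape)
    dropout = rng.random(size=shape) < _ABUNDANCE_DROPOUT
    ab = np.where(dropout, 0.0, ab)
    # keep every sample non-empty: re-seat the most abundant taxon per
    # empty column deterministically
    for j in range(spec.n_samples):
        if ab[:, j].sum() == 0:
            ab[0, j] = 1.0
    abund = TaxonAbundanceTable(pd.DataFrame(ab, index=taxa, columns=samples))

    present = rng.random(size=(spec.n_taxa, spec.n_functions)) >= spec.sparsity
    copies = rng.integers(1, 4, size=(spec.n_taxa, spec.n_functions)).astype(float)
    cn = FunctionCopyNumberTable(
        pd.DataFrame(np.where(present, copies, 0.0), index=taxa, columns=functions)
    )
    tree = random_tree(taxa, rng)
    return abund, cn, tree


@dataclass(frozen=True)
class ToyBundle:
    """The fixed worked example used throughout the documentation."""

    abund: TaxonAbundanceTable
    cn: FunctionCopyNumberTable
    tree: PhyloTree
    contrib: ContributionalTable


def generate_toy_worked_example() -> ToyBundle:
    """Three taxa on the tree ((A:1,B:1):1,C:2); two samples, two functions.

    Sample s1 contains A and C, sample s2 contains B and C. Function f1 is
    encoded by A and B (copy numbers 2 and 1); f2 is encoded by all three
    taxa (single copies). Handy closed-form values on this bundle: Faith's
    PD of {A, B} on the tree is 3.0 (branches A + B + their stem); the
    unweighted UniFrac between the two samples under f2 is 2/5 (the A and B
    tip branches are unshared out of 5 total observed length).
    """
    from .phylo import parse_newick

    tree = parse_newick("((A:1,B:1):1,C:2);")
    abund = TaxonAbundanceTable(
        pd.DataFrame(
            {"s1": [5.0, 0.0, 2.0], "s2": [0.0, 3.0, 1.0]},
            index=["A", "B", "C"],
        )
    )
    cn = FunctionCopyNumberTable(
        pd.DataFrame(
            {"f1": [2.0, 1.0, 0.0], "f2": [1.0, 1.0, 1.0]},
            index=["A", "B", "C"],
        )
    )
    contrib = wide_to_contrib(abund, cn)
    return ToyBundle(abund=abund, cn=cn, tree=tree, contrib=contrib)
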