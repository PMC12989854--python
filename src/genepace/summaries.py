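"""Downstream statistics over outlier gene sets.

Per-taxon outlier sets, Jaccard similarity and genomic uniqueness,
overlap versus divergence time on a dated species tree, cross-metric
intersections, Fisher's exact overlap test, and lineages-through-time.
The dated tree plays no role in outlier detection itself; it only
enters these summaries (and the simulator).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DatedTree",
    "ConstantInput",
    "outlier_sets_by_taxon",
    "jaccard_matrix",
    "genomic_uniqueness",
    "overlap_vs_divergence",
    "metric_intersections",
    "fisher_exact_overlap",
    "lineages_through_time",
    "pearson",
]


class ConstantInput(ValueError):
    """A correlation input has zero variance."""


class NotUltrametric(ValueError):
    pass


class DatedTree:
    """A rooted, time-calibrated (ultrametric) tree.

    Branch lengths are in time units (Myr); node ages are derived with
    leaves at age zero.  Ultrametricity is enforced within a relative
    tolerance on the root age.
    """

    def __init__(self, tree: dendropy.Tree, rel_tol: float = 1e-6) -> None:
        self.tree = tree
        self.tree.is_rooted = True
        self._compute_ages(rel_tol)

    def _compute_ages(self, rel_tol: float) -> None:
        root = self.tree.seed_node
        depth = {root: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        leaf_depths = [depth[leaf] for leaf in self.tree.leaf_node_iter()]
        height = max(leaf_depths)
        if height <= 0:
            raise NotUltrametric("tree has zero height")
        if max(abs(d - height) for d in leaf_depths) > rel_tol * height:
            raise NotUltrametric("leaf depths differ beyond tolerance")
        self.age = {node: height - d for node, d in depth.items()}
        self.root_age = height
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        self.leaf_labels = tuple(sorted(labels))

    @classmethod
    def from_newick(cls, source: str | Path, rel_tol: float = 1e-6) -> "DatedTree":
        path = Path(source) if not str(source).lstrip().startswith("(") else None
        if path is not None:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                data=str(source), schema="newick", preserve_underscores=True
            )
        return cls(tree, rel_tol)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def pruned_to(self, panel: Iterable[str]) -> "DatedTree":
        """Restrict to panel taxa, warning about pruned leaves."""
        panel = set(panel)
        extra = [l for l in self.leaf_labels if l not in panel]
        if not extra:
            return self
        warnings.warn(
            f"pruning {len(extra)} tree taxa absent from the panel: {extra}",
            stacklevel=2,
        )
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(panel & set(self.leaf_labels)))
        return DatedTree(clone)

    def internal_nodes(self) -> list[tuple[float, tuple[str, ...]]]:
        """(age, descendant leaf labels) for every internal node."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            tips = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            out.append((self.age[node], tips))
        return out

    def mrca_age(self, a: str, b: str) -> float:
        mrca = self.tree.mrca(taxon_labels=[a, b])
        return self.age[mrca]

    def patristic_matrix(self) -> pd.DataFrame:
        """Path-length distances between all leaf pairs, in time units."""
        labels = self.leaf_labels
        pdm = self.tree.phylogenetic_distance_matrix()
        taxon = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        values = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            d = pdm.patristic_distance(taxon[labels[i]], taxon[labels[j]])
            values[i, j] = values[j, i] = d
        return pd.DataFrame(values, index=labels, columns=labels)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ConstantInput("zero variance in a correlation input")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    n = len(x)
    if abs(r) >= 1.0:
        return (math.copysign(1.0, r) if abs(r) == 1.0 else r, 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, p


def outlier_sets_by_taxon(
    driver_report: pd.DataFrame, taxa: Sequence[str] | None = None
) -> dict[str, set[str]]:
    """Map each taxon to the genes for which it was flagged as a driver."""
    sets: dict[str, set[str]] = {t: set() for t in (taxa or [])}
    if len(driver_report):
        flagged = driver_report[driver_report["is_driver"]]
        for taxon, sub in flagged.groupby("taxon"):
            sets.setdefault(taxon, set()).update(sub["gene_id"])
        for taxon in driver_report["taxon"].unique():
            sets.setdefault(taxon, set())
    return sets


def jaccard_matrix(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise Jaccard similarities |A∩B| / |A∪B| between taxon gene sets.

    Entries where both sets are empty are NaN; the diagonal is 1 for
    nonempty sets.
    """
    taxa = sorted(sets)
    n = len(taxa)
    values = np.full((n, n), np.nan)
    for i in range(n):
        a = sets[taxa[i]]
        values[i, i] = 1.0 if a else np.nan
        for j in range(i + 1, n):
            b = sets[taxa[j]]
            union = len(a | b)
            if union == 0:
                continue
            values[i, j] = values[j, i] = len(a & b) / union
    return pd.DataFrame(values, index=taxa, columns=taxa)


def intersection_counts(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise |A∩B| counts between taxon gene sets."""
    taxa = sorted(sets)
    values = np.zeros((len(taxa), len(taxa)), dtype=int)
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            values[i, j] = len(sets[a] & sets[b])
    return pd.DataFrame(values, index=taxa, columns=taxa)


def genomic_uniqueness(jaccard: pd.DataFrame) -> pd.Series:
    """Average Jaccard index of each taxon against all others.

    The mean is over off-diagonal, non-missing entries of the taxon's
    row; lower values mean a more unique accelerated-gene complement.
    """
    values = jaccard.to_numpy(dtype=float).copy()
    np.fill_diagonal(values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(values, axis=1)
    return pd.Series(means, index=jaccard.index, name="genomic_uniqueness")


def overlap_vs_divergence(
    tree: DatedTree,
    sets: Mapping[str, set[str]],
    mode: str = "node_sum",
) -> tuple[pd.DataFrame, float, float]:
    """Relate outlier-gene load to divergence time.

    mode ``"node_sum"``: for each internal node, the statistic is the
    summed outlier-set size over its descendant tips, against node age.
    mode ``"pair_intersection"``: for each unordered leaf pair, the
    statistic is the intersection size of the two tips' sets, against
    the age of their most recent common ancestor.  Returns the table
    plus the Pearson correlation and its two-sided p-value.
    """
    missing = [t for t in sets if t not in tree.leaf_labels]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    rows = []
    if mode == "node_sum":
        for k, (age, tips) in enumerate(tree.internal_nodes()):
            stat = sum(len(sets.get(t, set())) for t in tips)
            rows.append({"id": f"node_{k}", "age": age, "statistic": stat})
    elif mode == "pair_intersection":
        for a, b in combinations(tree.leaf_labels, 2):
            stat = len(sets.get(a, set()) & sets.get(b, set()))
            rows.append({"id": f"{a}|{b}", "age": tree.mrca_age(a, b), "statistic": stat})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(rows) < 3:
        raise ValueError("need at least 3 nodes or pairs")
    table = pd.DataFrame(rows)
    r, p = pearson(table["age"], table["statistic"])
    return table, r, p


def metric_intersections(
    outlier_sets: Mapping[str, set[str]]
) -> dict[str, int]:
    """Venn-region counts over metric-wise outlier gene sets.

    Keys are ``&``-joined sorted metric names; each count is the number
    of genes belonging to exactly that combination of sets.
    """
    metrics = sorted(outlier_sets)
    universe: set[str] = set()
    for s in outlier_sets.values():
        universe |= s
    regions: dict[str, int] = {}
    for k in range(1, len(metrics) + 1):
        for combo in combinations(metrics, k):
            inside = set(universe)
            for m in combo:
                inside &= outlier_sets[m]
            for m in metrics:
                if m not in combo:
                    inside -= outlier_sets[m]
            regions["&".join(combo)] = len(inside)
    return regions


def fisher_exact_overlap(
    set_a: set[str], set_b: set[str], universe_size: int
) -> tuple[float, float]:
    """One-sided (greater) Fisher's exact test on the overlap of two sets.

    The 2×2 table is [[|A∩B|, |A\\B|], [|B\\A|, U−|A∪B|]]; the p-value
    is the hypergeometric upper-tail probability of an overlap at least
    as large.  An empty set gives odds ratio 0 and p = 1 by convention.
    """
    na, nb = len(set_a), len(set_b)
    if na > universe_size or nb > universe_size:
        raise ValueError("set larger than the universe")
    k = len(set_a & set_b)
    if na == 0 or nb == 0:
        return 0.0, 1.0
    a, b = k, na - k
    c, d = nb - k, universe_size - na - nb + k
    if d < 0:
        raise ValueError("sets are not subsets of the stated universe")
    if b * c == 0:
        odds = math.inf if a > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    p = float(stats.hypergeom.sf(k - 1, universe_size, na, nb))
    return odds, min(p, 1.0)


def lineages_through_time(tree: DatedTree) -> pd.DataFrame:
    """Step table of lineage counts through time.

    One row per internal node, ordered from the root (2 lineages) to
    the present (n leaves); each node at age ``age`` raises the count
    by its number of children minus one.
    """
    nodes = []
    for node in tree.tree.preorder_node_iter():
        if not node.is_leaf():
            nodes.append((tree.age[node], len(node.child_nodes())))
    nodes.sort(key=lambda t: -t[0])
    count = 1
    rows = []
    for age, children in nodes:
        count += children - 1
        rows.append({"age": age, "lineages": count})
    return pd.DataFrame(rows)
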