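"""Mahalanobis outlier detection on stacked pairwise-distance matrices.

The central idea: treat each gene's pairwise distance matrix as one
observation of a multivariate quantity whose dimensions are taxon
pairs.  After imputing missing cells and log-transforming, genes become
rows of an i × P matrix (P = N(N-1)/2 upper-triangle pairs); squared
Mahalanobis distances of rows from the multivariate mean flag genes
whose evolutionary rates deviate from the genome-wide pattern while
respecting the covariance among pairs (which absorbs relatedness and
gene-tree discordance without requiring a phylogeny).  A second pass
over the flagged genes stacks full per-taxon distance rows
((i_outlier × N) × N) to locate the taxa driving each outlier gene.

Outlier sets are *defined* by the empirical 95th-quantile rule; the
chi-square p-values (with Bonferroni adjustment) are annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceTensor

__all__ = [
    "DegenerateMatrix",
    "UnimputableCell",
    "MissingValues",
    "StackedGeneMatrix",
    "DetectionParams",
    "impute_missing",
    "impute_diagonal",
    "log_transform",
    "stack_genes",
    "mahalanobis_sq",
    "chi2_pvalue",
    "flag_outlier_genes",
    "flag_driver_taxa",
    "detect_outliers",
]


class DegenerateMatrix(ValueError):
    """All rows identical: the covariance carries no information."""


class UnimputableCell(ValueError):
    """Neither the gene mean nor the pair mean is defined for a cell."""


class MissingValues(ValueError):
    """Stacking requires a fully imputed tensor."""


class NegativeDistance(ValueError):
    pass


@dataclass
class StackedGeneMatrix:
    """genes × taxon-pairs matrix of (log) distances."""

    gene_ids: tuple[str, ...]
    pair_labels: tuple[tuple[str, str], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.pair_labels)):
            raise ValueError("stacked matrix shape mismatch")
        if np.isnan(v).any():
            raise MissingValues("stacked matrix contains missing values")
        self.values = v


def impute_missing(tensor: DistanceTensor) -> DistanceTensor:
    """Fill missing off-diagonal cells from gene and pair means.

    A missing cell (g, a, b) receives the arithmetic mean of two
    components: the mean of observed off-diagonal values in gene g, and
    the mean of observed values for the pair (a, b) across genes.  When
    only one component is defined it is used alone; when neither is,
    :class:`UnimputableCell` is raised (the caller should drop the gene
    or pair).  Imputation always happens on the raw distance scale,
    before any log transform, and preserves symmetry.
    """
    values = tensor.values.copy()
    g_count, n, _ = values.shape
    iu = np.triu_indices(n, k=1)
    off = values[:, iu[0], iu[1]]  # (G, P)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gene_means = np.nanmean(off, axis=1)  # (G,)
        pair_means = np.nanmean(off, axis=0)  # (P,)
    missing = np.isnan(off)
    if not missing.any():
        return tensor.copy()
    filled = off.copy()
    for g, p in zip(*np.nonzero(missing)):
        components = [
            m for m in (gene_means[g], pair_means[p]) if not np.isnan(m)
        ]
        if not components:
            raise UnimputableCell(
                f"gene {tensor.gene_ids[g]} pair "
                f"({tensor.taxa[iu[0][p]]},{tensor.taxa[iu[1][p]]}) has no "
                f"observed gene-level or pair-level values"
            )
        filled[g, p] = float(np.mean(components))
    values[:, iu[0], iu[1]] = filled
    values[:, iu[1], iu[0]] = filled
    # a taxon absent from a gene also leaves a NaN diagonal cell behind
    for a in range(n):
        col = values[:, a, a]
        col[np.isnan(col)] = 0.0
        values[:, a, a] = col
    return DistanceTensor(
        tensor.metric, tensor.taxa, tensor.gene_ids, values, tensor.provenance
    )


def impute_diagonal(tensor: DistanceTensor) -> DistanceTensor:
    """Set each diagonal cell to the mean of that taxon's row in the gene.

    Used only for the taxon-level driver analysis, where full N-vectors
    per taxon (including self) are stacked; off-diagonal imputation must
    already have run.
    """
    values = tensor.values.copy()
    n = values.shape[1]
    if np.isnan(values).any():
        raise MissingValues("run impute_missing before impute_diagonal")
    mask = ~np.eye(n, dtype=bool)
    for a in range(n):
        values[:, a, a] = values[:, a, mask[a]].mean(axis=1)
    return DistanceTensor(
        tensor.metric, tensor.taxa, tensor.gene_ids, values, tensor.provenance
    )


def log_transform(tensor: DistanceTensor, eps: float = 1e-6) -> DistanceTensor:
    """x -> ln(x + eps), elementwise; strictly order-preserving."""
    if np.nanmin(tensor.values) < 0:
        raise NegativeDistance("negative distances cannot be log-transformed")
    return DistanceTensor(
        tensor.metric,
        tensor.taxa,
        tensor.gene_ids,
        np.log(tensor.values + eps),
        tensor.provenance,
    )


def pair_labels(taxa: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Ordered upper-triangle taxon pairs in panel order."""
    return tuple(combinations(taxa, 2))


def stack_genes(tensor: DistanceTensor) -> StackedGeneMatrix:
    """Collapse the i × N × N tensor to i × N(N-1)/2 upper triangles."""
    n = tensor.n_taxa
    iu = np.triu_indices(n, k=1)
    values = tensor.values[:, iu[0], iu[1]]
    if np.isnan(values).any():
        raise MissingValues("tensor must be imputed before stacking")
    return StackedGeneMatrix(tensor.gene_ids, pair_labels(tensor.taxa), values)


def mahalanobis_sq(
    matrix: np.ndarray, shrinkage: float = 0.0, rtol: float = 1e-10
) -> np.ndarray:
    """Squared Mahalanobis distance of each row from the column mean.

    Uses the sample covariance (denominator rows - 1); its inverse when
    full rank, otherwise the Moore–Penrose pseudo-inverse with relative
    tolerance ``rtol``.  ``shrinkage`` in [0, 1] blends the covariance
    with its own diagonal, which regularizes near-singular panels.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")
    centred = x - x.mean(axis=0)
    if not centred.any():
        raise DegenerateMatrix("all rows are identical")
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if shrinkage:
        cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    p = cov.shape[0]
    rank = np.linalg.matrix_rank(cov, tol=rtol * np.linalg.norm(cov, 2))
    if rank < p:
        warnings.warn(
            f"covariance rank {rank} < dimension {p}; using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        inv = np.linalg.pinv(cov, rcond=rtol, hermitian=True)
    else:
        inv = np.linalg.inv(cov)
    return np.einsum("ij,jk,ik->i", centred, inv, centred)


def chi2_pvalue(d2: np.ndarray | float, df: int) -> np.ndarray | float:
    """Upper-tail chi-square probability of a squared Mahalanobis distance."""
    return stats.chi2.sf(d2, df)


@dataclass
class DetectionParams:
    """Knobs of the detection pipeline, recorded in report headers."""

    quantile: float = 0.95
    log_eps: float = 1e-6
    shrinkage: float = 0.0
    apply_log: bool = True


def _quantile_flags(d2: np.ndarray, quantile: float) -> tuple[np.ndarray, float]:
    threshold = float(np.quantile(d2, quantile))
    return d2 > threshold, threshold


def flag_outlier_genes(
    d2: np.ndarray,
    gene_ids: Sequence[str],
    quantile: float = 0.95,
    df: int | None = None,
) -> pd.DataFrame:
    """Rank genes by D² and flag those above the empirical quantile.

    Flags are strict (> threshold), so ties at the threshold are all
    excluded and at most 5% of genes are flagged at the default.  The
    chi-square p-values use ``df`` degrees of freedom (the number of
    taxon-pair columns) and a Bonferroni adjustment over all genes.
    """
    d2 = np.asarray(d2, dtype=float)
    flags, threshold = _quantile_flags(d2, quantile)
    raw_p = chi2_pvalue(d2, df) if df is not None else np.full(d2.shape, np.nan)
    report = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "D2": d2,
            "raw_p": raw_p,
            "bonferroni_p": np.minimum(1.0, raw_p * len(d2)),
            "is_outlier": flags,
        }
    )
    report = report.sort_values(
        ["D2", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    report.attrs["threshold"] = threshold
    report.attrs["quantile"] = quantile
    report.attrs["df"] = df
    return report


class EmptyOutlierSet(ValueError):
    pass


def flag_driver_taxa(
    tensor: DistanceTensor,
    outlier_gene_ids: Sequence[str],
    quantile: float = 0.95,
    shrinkage: float = 0.0,
) -> pd.DataFrame:
    """Locate the taxa driving each outlier gene.

    The tensor (already imputed, diagonal included, log-transformed) is
    subset to the outlier genes and collapsed to an
    (i_outlier × N) × N matrix by stacking full per-taxon distance
    rows.  Rows are scored by squared Mahalanobis distance; the top 5%
    strictly above the empirical quantile are flagged as drivers, with
    chi-square p-values at N degrees of freedom Bonferroni-adjusted
    over the row count.
    """
    if len(outlier_gene_ids) == 0:
        raise EmptyOutlierSet("no outlier genes to re-analyze")
    index = {g: k for k, g in enumerate(tensor.gene_ids)}
    rows = []
    labels = []
    for gene_id in outlier_gene_ids:
        g = index[gene_id]
        for a, taxon in enumerate(tensor.taxa):
            rows.append(tensor.values[g, a, :])
            labels.append((gene_id, taxon))
    matrix = np.vstack(rows)
    d2 = mahalanobis_sq(matrix, shrinkage=shrinkage)
    flags, threshold = _quantile_flags(d2, quantile)
    n = tensor.n_taxa
    raw_p = chi2_pvalue(d2, n)
    report = pd.DataFrame(
        {
            "gene_id": [g for g, _ in labels],
            "taxon": [t for _, t in labels],
            "D2": d2,
            "raw_p": raw_p,
            "bonferroni_p": np.minimum(1.0, raw_p * len(d2)),
            "is_driver": flags,
        }
    )
    report = report.sort_values(
        ["D2", "gene_id", "taxon"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    report.attrs["threshold"] = threshold
    report.attrs["quantile"] = quantile
    report.attrs["df"] = n
    return report


def detect_outliers(
    tensor: DistanceTensor,
    params: DetectionParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline: impute, log, stack, score, flag, re-analyze.

    Returns the gene-level report and the taxon-level driver report for
    one metric.  The driver report is empty (but well-formed) when no
    gene is flagged.
    """
    params = params or DetectionParams()
    imputed = impute_missing(tensor)
    with_diag = impute_diagonal(imputed)
    if params.apply_log:
        transformed = log_transform(with_diag, params.log_eps)
    else:
        transformed = with_diag
    stacked = stack_genes(transformed)
    d2 = mahalanobis_sq(stacked.values, shrinkage=params.shrinkage)
    p_cols = len(stacked.pair_labels)
    gene_report = flag_outlier_genes(
        d2, stacked.gene_ids, params.quantile, df=p_cols
    )
    outliers = gene_report.loc[gene_report["is_outlier"], "gene_id"].tolist()
    if outliers:
        taxon_report = flag_driver_taxa(
            transformed, outliers, params.quantile, params.shrinkage
        )
    else:
        taxon_report = pd.DataFrame(
            columns=["gene_id", "taxon", "D2", "raw_p", "bonferroni_p", "is_driver", "rank"]
        )
    for report in (gene_report, taxon_report):
        report.attrs.setdefault("metric", tensor.metric)
        report.attrs["log_eps"] = params.log_eps if params.apply_log else None
        report.attrs["shrinkage"] = params.shrinkage
    return gene_report, taxon_report
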