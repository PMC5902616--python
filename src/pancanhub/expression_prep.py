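"""Per-dataset expression preparation: profile selection, quantile
normalisation, missing-value filtering and outlier-sample removal.

The output of this module is the matrix the co-expression network is built
from. Quantile normalisation forces every sample onto the common reference
distribution (the across-sample mean of order statistics); outlier samples
are detected by average-linkage hierarchical clustering of samples and a
static tree cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix
from .mutation_filtering import (
    DEFAULT_ALLOWED_SAMPLE_TYPES,
    DEFAULT_ANNOTATION_WHITELIST,
)

logger = logging.getLogger(__name__)


@dataclass
class PrepReport:
    """Counts of what each preparation stage removed for one dataset."""

    dataset_id: str
    seed: int
    n_aliquots_in: int
    n_profiles_dropped_by_filters: int
    n_duplicate_cases_resolved: int
    n_genes_removed_missing: int
    n_samples_removed_outlier: int
    n_genes_out: int
    n_samples_out: int

    def to_dict(self) -> dict:
        return asdict(self)


def select_profiles(
    matrix: ExpressionMatrix,
    aliquot_annotations: dict[str, set[str]] | None = None,
    sample_type_of_aliquot: dict[str, str] | None = None,
    seed: int = 0,
    allowed_sample_types=DEFAULT_ALLOWED_SAMPLE_TYPES,
    annotation_whitelist=DEFAULT_ANNOTATION_WHITELIST,
) -> tuple[ExpressionMatrix, int, int]:
    """Filter profiles and keep exactly one per case.

    Sample-type and annotation filters use the same semantics as the
    mutation filters. When a case retains more than one profile, one is
    chosen uniformly at random under the seeded RNG.

    Returns ``(matrix, n_dropped_by_filters, n_duplicate_cases_resolved)``.
    """
    if not matrix.case_of_aliquot:
        raise ValueError("case_of_aliquot mapping required to select profiles")
    rng = np.random.default_rng(seed)
    annotations = aliquot_annotations or {}
    sample_types = sample_type_of_aliquot or {}

    keep = []
    for bc in matrix.values.columns:
        st = sample_types.get(bc, "Primary Tumour")
        if st not in allowed_sample_types:
            continue
        cats = annotations.get(bc, set())
        if any(c not in annotation_whitelist for c in cats):
            continue
        keep.append(bc)
    n_dropped = matrix.values.shape[1] - len(keep)

    by_case: dict[str, list[str]] = {}
    for bc in keep:
        by_case.setdefault(matrix.case_of_aliquot[bc], []).append(bc)

    chosen: list[str] = []
    n_dup = 0
    for case in sorted(by_case):
        profiles = sorted(by_case[case])
        if len(profiles) == 1:
            chosen.append(profiles[0])
        else:
            n_dup += 1
            chosen.append(profiles[int(rng.integers(len(profiles)))])
    # preserve original column order
    chosen_set = set(chosen)
    cols = [bc for bc in matrix.values.columns if bc in chosen_set]
    out = ExpressionMatrix(
        matrix.dataset_id,
        matrix.values.loc[:, cols],
        {bc: matrix.case_of_aliquot[bc] for bc in cols},
    )
    return out, n_dropped, n_dup


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean order-statistic reference.

    Ties within a sample receive the mean of the reference values at their
    rank positions. The transform is idempotent and preserves within-sample
    rank order.
    """
    df = matrix.values
    if df.shape[1] < 2:
        logger.warning(
            "%s: quantile normalisation needs >= 2 samples; returning input",
            matrix.dataset_id,
        )
        return matrix
    vals = df.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            out[order[i : k + 1], j] = ref[i : k + 1].mean()
            i = k + 1
    return ExpressionMatrix(
        matrix.dataset_id,
        pd.DataFrame(out, index=df.index, columns=df.columns),
        dict(matrix.case_of_aliquot),
    )


def filter_missing(
    matrix: ExpressionMatrix,
    max_missing_gene: float = 0.1,
    min_variance: float = 0.0,
    max_missing_sample: float = 0.5,
) -> tuple[ExpressionMatrix, int]:
    """Remove genes with excessive missingness or no variance, and samples
    with excessive missingness.

    Returns ``(matrix, n_genes_removed)``.
    """
    df = matrix.values
    gene_missing = df.isna().mean(axis=1)
    variance = df.var(axis=1, ddof=1).fillna(0.0)
    gene_ok = (gene_missing <= max_missing_gene) & (variance > min_variance)
    sample_missing = df.isna().mean(axis=0)
    sample_ok = sample_missing <= max_missing_sample
    out_df = df.loc[gene_ok, sample_ok]
    out = ExpressionMatrix(
        matrix.dataset_id,
        out_df,
        {bc: matrix.case_of_aliquot.get(bc, bc) for bc in out_df.columns}
        if matrix.case_of_aliquot
        else {},
    )
    return out, int((~gene_ok).sum())


def remove_outlier_samples(
    matrix: ExpressionMatrix, cut_height: float | str = "auto"
) -> tuple[ExpressionMatrix, int]:
    """Drop samples outside the dominant cluster of the sample dendrogram.

    Samples are clustered by average linkage on Euclidean distance; the tree
    is cut at ``cut_height`` (``"auto"`` = mean merge height + 3 sd of merge
    heights) and only the largest resulting cluster is retained.

    Returns ``(matrix, n_samples_removed)``.
    """
    df = matrix.values
    n = df.shape[1]
    if n < 3:
        logger.warning(
            "%s: < 3 samples; outlier removal skipped", matrix.dataset_id
        )
        return matrix, 0
    dist = pdist(df.to_numpy(dtype=float).T, metric="euclidean")
    if np.allclose(dist, 0):
        return matrix, 0
    link = linkage(dist, method="average")
    heights = link[:, 2]
    if cut_height == "auto":
        cut = float(heights.mean() + 3.0 * heights.std(ddof=0))
    else:
        cut = float(cut_height)
    labels = fcluster(link, t=cut, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    best = sizes.idxmax()  # ties: value_counts orders by first occurrence
    keep_mask = labels == best
    if keep_mask.all():
        return matrix, 0
    cols = df.columns[keep_mask]
    out = ExpressionMatrix(
        matrix.dataset_id,
        df.loc[:, cols],
        {bc: matrix.case_of_aliquot.get(bc, bc) for bc in cols}
        if matrix.case_of_aliquot
        else {},
    )
    return out, int((~keep_mask).sum())


def prepare(
    matrix: ExpressionMatrix,
    aliquot_annotations: dict[str, set[str]] | None = None,
    sample_type_of_aliquot: dict[str, str] | None = None,
    seed: int = 0,
    max_missing_gene: float = 0.1,
    min_variance: float = 0.0,
    cut_height: float | str = "auto",
) -> tuple[ExpressionMatrix, PrepReport]:
    """Run the full preparation chain for one dataset."""
    n_in = matrix.values.shape[1]
    selected, n_dropped, n_dup = select_profiles(
        matrix, aliquot_annotations, sample_type_of_aliquot, seed=seed
    )
    normalized = quantile_normalize(selected)
    filtered, n_genes_removed = filter_missing(
        normalized, max_missing_gene=max_missing_gene, min_variance=min_variance
    )
    cleaned, n_outliers = remove_outlier_samples(filtered, cut_height=cut_height)
    report = PrepReport(
        dataset_id=matrix.dataset_id,
        seed=seed,
        n_aliquots_in=n_in,
        n_profiles_dropped_by_filters=n_dropped,
        n_duplicate_cases_resolved=n_dup,
        n_genes_removed_missing=n_genes_removed,
        n_samples_removed_outlier=n_outliers,
        n_genes_out=cleaned.values.shape[0],
        n_samples_out=cleaned.values.shape[1],
    )
    return cleaned, report
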