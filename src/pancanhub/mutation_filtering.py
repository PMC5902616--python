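"""Somatic-mutation filtering and burden statistics.

Three filters are applied to MAF-derived records, in the order sample type,
aliquot annotation, read depth, followed by restriction to the genes shared
by the two annotation releases:

1. keep only aliquots of primary-tumour sample types;
2. drop every record of an aliquot that carries any annotation category
   outside a benign whitelist (e.g. 'Prior malignancy' disqualifies);
3. drop calls with tumour read depth < 14 or normal read depth < 8.

The sample-type and depth filters are record-local, the annotation filter is
aliquot-local, so the three commute; the staged counts in the report refer
to the canonical order above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import pandas as pd

logger = logging.getLogger(__name__)

#: default sample types retained (primary disease only)
DEFAULT_ALLOWED_SAMPLE_TYPES = frozenset(
    {
        "Primary Blood Derived Cancer - Peripheral Blood",
        "Primary Tumour",
        "Additional - New Primary",
    }
)

#: annotation categories that do not disqualify an aliquot
DEFAULT_ANNOTATION_WHITELIST = frozenset(
    {
        "Acceptable treatment for TCGA tumour",
        "Alternate sample pipeline",
        "Item in special subset",
        "Item is noncanonical",
    }
)

DEFAULT_T_DEPTH_MIN = 14
DEFAULT_N_DEPTH_MIN = 8


@dataclass
class FilterReport:
    """Record counts surviving each filtering stage for one dataset."""

    dataset_id: str
    n_input: int
    n_after_sample_type: int
    n_after_annotation: int
    n_after_depth: int
    n_after_release: int

    @property
    def fraction_removed(self) -> float:
        if self.n_input == 0:
            return 0.0
        return 1.0 - self.n_after_release / self.n_input

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fraction_removed"] = self.fraction_removed
        return d


def filter_sample_type(
    table: pd.DataFrame,
    allowed: frozenset[str] | set[str] = DEFAULT_ALLOWED_SAMPLE_TYPES,
) -> pd.DataFrame:
    """Keep records whose sample type is in ``allowed``."""
    return table[table["sample_type"].isin(allowed)]


def filter_annotations(
    table: pd.DataFrame,
    aliquot_annotations: dict[str, set[str]],
    whitelist: frozenset[str] | set[str] = DEFAULT_ANNOTATION_WHITELIST,
) -> pd.DataFrame:
    """Drop all records of aliquots with a non-whitelisted annotation.

    An aliquot is removed iff it carries at least one annotation category
    outside the whitelist; aliquots with only whitelisted annotations (or
    none at all) are kept.
    """
    bad = {
        aliquot
        for aliquot, cats in aliquot_annotations.items()
        if any(c not in whitelist for c in cats)
    }
    if not bad:
        return table
    return table[~table["aliquot_barcode"].isin(bad)]


def filter_depth(
    table: pd.DataFrame,
    t_min: int = DEFAULT_T_DEPTH_MIN,
    n_min: int = DEFAULT_N_DEPTH_MIN,
) -> pd.DataFrame:
    """Keep calls with t_depth >= ``t_min`` and n_depth >= ``n_min``.

    Removal is by strict inequality on either side, so a call at exactly
    (14, 8) survives the defaults.
    """
    keep = (table["t_depth"] >= t_min) & (table["n_depth"] >= n_min)
    return table[keep]


def restrict_to_release_intersection(
    table: pd.DataFrame, release_members: set[str]
) -> pd.DataFrame:
    """Drop records of genes outside the annotation-release intersection."""
    return table[table["gene_id"].isin(release_members)]


def apply_filters(
    table: pd.DataFrame,
    aliquot_annotations: dict[str, set[str]],
    release_members: set[str],
    dataset_id: str | None = None,
    allowed_sample_types: frozenset[str] | set[str] = DEFAULT_ALLOWED_SAMPLE_TYPES,
    annotation_whitelist: frozenset[str] | set[str] = DEFAULT_ANNOTATION_WHITELIST,
    t_min: int = DEFAULT_T_DEPTH_MIN,
    n_min: int = DEFAULT_N_DEPTH_MIN,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply all four stages in canonical order; return table and report."""
    if dataset_id is None:
        ids = table["dataset_id"].unique()
        dataset_id = ids[0] if len(ids) == 1 else ",".join(sorted(map(str, ids)))
    n_input = len(table)
    t1 = filter_sample_type(table, allowed_sample_types)
    t2 = filter_annotations(t1, aliquot_annotations, annotation_whitelist)
    t3 = filter_depth(t2, t_min, n_min)
    t4 = restrict_to_release_intersection(t3, release_members)
    report = FilterReport(
        dataset_id=str(dataset_id),
        n_input=n_input,
        n_after_sample_type=len(t1),
        n_after_annotation=len(t2),
        n_after_depth=len(t3),
        n_after_release=len(t4),
    )
    return t4.reset_index(drop=True), report


def mutation_gene_set(table: pd.DataFrame, dataset_id: str) -> set[str]:
    """Genes with at least one surviving call in ``dataset_id``.

    All variant classifications count, including synonymous calls.
    """
    sub = table[table["dataset_id"] == dataset_id]
    return set(sub["gene_id"].unique())


def burden(
    table: pd.DataFrame,
    n_aliquots: dict[str, int],
    exon_lengths: pd.Series | dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per (dataset, gene) mutation burden.

    ``calls_per_aliquot`` divides the raw call count by the dataset's aliquot
    count; ``calls_per_aliquot_per_kb`` additionally divides by the gene's
    summed exon length in kilobases. Genes without a known exon length get
    NaN in the per-kb column (with a warning) but keep the per-aliquot value.
    """
    for ds, n in n_aliquots.items():
        if n <= 0:
            raise ValueError(f"n_aliquots for {ds!r} must be positive")
    counts = (
        table.groupby(["dataset_id", "gene_id"], sort=True)
        .size()
        .rename("call_count")
        .reset_index()
    )
    missing_ds = set(counts["dataset_id"]) - set(n_aliquots)
    if missing_ds:
        raise ValueError(f"n_aliquots missing for dataset(s) {sorted(missing_ds)}")
    counts["calls_per_aliquot"] = counts["call_count"] / counts["dataset_id"].map(n_aliquots)
    if exon_lengths is not None:
        lengths = pd.Series(exon_lengths, dtype=float)
        kb = counts["gene_id"].map(lengths) / 1000.0
        n_missing = int(kb.isna().sum())
        if n_missing:
            logger.warning(
                "%d gene(s) lack exon length; per-kb burden set to NaN", n_missing
            )
        counts["calls_per_aliquot_per_kb"] = counts["calls_per_aliquot"] / kb
    return counts
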