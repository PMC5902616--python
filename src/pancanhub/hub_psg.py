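"""Module hub selection and pan-cancer-wide selected genes (PSGs).

Per dataset, about 5% of genes are granted hub candidacy, distributed over
modules in proportion to module size (cap_m = ceil(target * size_m / total)),
ranked within each module by own-module kME; candidates must then clear
kME >= 0.9 and membership p <= 0.01. A dataset's selected genes are the
intersection of its hubs with its mutation-associated genes; the integrated
union over datasets is the PSG set, with per-gene dataset-membership counts
and a coding / non-coding split by annotation biotype.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .annotations import GeneUniverse, category_of_biotype
from .coexpression import ModuleAssignment

logger = logging.getLogger(__name__)


@dataclass
class HubSelection:
    """Hub genes of one dataset with the quota and thresholds that produced them."""

    dataset_id: str
    hubs: set[str]
    target_fraction: float
    kme_min: float
    p_max: float
    per_module_caps: dict[int, int] = field(default_factory=dict)
    per_module_counts: dict[int, int] = field(default_factory=dict)


def select_hubs(
    assignment: ModuleAssignment,
    target_fraction: float = 0.05,
    kme_min: float = 0.9,
    p_max: float = 0.01,
) -> HubSelection:
    """Select module hub genes under the proportional quota rule.

    ``target = round(target_fraction * n_genes)`` over all genes in the
    assignment; each module m may contribute at most
    ``ceil(target * size_m / sum(sizes))`` genes, taken in decreasing order
    of own-module kME (ties by gene id). Candidates within quota must also
    satisfy kME >= ``kme_min`` and p <= ``p_max``. Unassigned genes are
    never hubs, so the quota is an upper bound.
    """
    labels = assignment.labels
    n_genes = len(labels)
    target = int(round(target_fraction * n_genes))
    sizes = assignment.module_sizes
    total = int(sizes.sum())
    hubs: set[str] = set()
    caps: dict[int, int] = {}
    counts: dict[int, int] = {}
    if total > 0 and assignment.kme is not None:
        for m, size in sizes.items():
            cap = math.ceil(target * int(size) / total)
            caps[int(m)] = cap
            members = labels.index[labels == m]
            kme_m = assignment.kme.loc[members, m]
            p_m = assignment.kme_p.loc[members, m]
            ranked = sorted(members, key=lambda g: (-kme_m[g], g))
            picked = [
                g
                for g in ranked[:cap]
                if kme_m[g] >= kme_min and p_m[g] <= p_max
            ]
            counts[int(m)] = len(picked)
            hubs.update(picked)
    return HubSelection(
        dataset_id=assignment.dataset_id,
        hubs=hubs,
        target_fraction=target_fraction,
        kme_min=kme_min,
        p_max=p_max,
        per_module_caps=caps,
        per_module_counts=counts,
    )


def select_dataset_genes(hubs: set[str], mutation_genes: set[str]) -> set[str]:
    """Genes that are both module hubs and mutation-associated."""
    return set(hubs) & set(mutation_genes)


@dataclass
class PSGSet:
    """Integrated pan-cancer-wide selected genes.

    ``membership`` maps each PSG to the number of datasets that selected it.
    """

    per_dataset: dict[str, set[str]]
    union: set[str]
    membership: pd.Series = field(repr=False)

    @property
    def overlap_histogram(self) -> pd.Series:
        """Number of genes per dataset-membership level."""
        return self.membership.value_counts().sort_index()

    def datasets_of(self, gene: str) -> list[str]:
        return sorted(d for d, s in self.per_dataset.items() if gene in s)


def integrate_psgs(per_dataset: dict[str, set[str]]) -> PSGSet:
    """Union per-dataset selections with per-gene membership counts."""
    union: set[str] = set()
    for s in per_dataset.values():
        union |= set(s)
    counts = {
        g: sum(1 for s in per_dataset.values() if g in s) for g in sorted(union)
    }
    membership = pd.Series(counts, dtype=int, name="m")
    return PSGSet(
        per_dataset={d: set(s) for d, s in per_dataset.items()},
        union=union,
        membership=membership,
    )


def split_coding(psgs: PSGSet, universe: GeneUniverse) -> tuple[set[str], set[str]]:
    """Partition PSGs into protein-coding (pcPSG) and non-coding (ncPSG)."""
    coding = universe.coding_genes
    pc = {g for g in psgs.union if g in coding}
    nc = psgs.union - pc
    return pc, nc


def categorize_noncoding(
    psgs: PSGSet, universe: GeneUniverse
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category and biotype per non-coding PSG, plus per-dataset occupancy.

    Returns ``(per_gene, per_dataset_fractions)``; the first is indexed by
    ncPSG with columns ``biotype`` and ``category``, the second gives the
    fraction of each dataset's ncPSGs per category (rows sum to 1). Genes
    absent from the universe are categorised as ``problematic`` with a
    warning.
    """
    _, nc = split_coding(psgs, universe)
    rows = {}
    for g in sorted(nc):
        if g in universe:
            bt = universe.table.at[g, "biotype"]
            rows[g] = {"biotype": bt, "category": category_of_biotype(bt)}
        else:
            logger.warning("gene %s absent from universe; category 'problematic'", g)
            rows[g] = {"biotype": "unknown", "category": "problematic"}
    per_gene = pd.DataFrame.from_dict(rows, orient="index")
    per_gene.index.name = "gene_id"

    frac_rows = {}
    for d, selected in sorted(psgs.per_dataset.items()):
        nc_d = [g for g in selected if g in per_gene.index]
        if not nc_d:
            continue
        counts = per_gene.loc[nc_d, "category"].value_counts()
        frac_rows[d] = (counts / counts.sum()).to_dict()
    per_dataset = pd.DataFrame.from_dict(frac_rows, orient="index").fillna(0.0)
    per_dataset.index.name = "dataset_id"
    return per_gene, per_dataset
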