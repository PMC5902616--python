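"""Enrichment and occupation analytics.

One-tailed Fisher's exact tests (upper tail: enrichment) compare flag gene
sets — programmed-cell-death types and known/candidate cancer genes —
across partitions of the gene universe (complexes vs the rest of the
network, the network vs the rest of the universe, selected genes vs the
rest). A generic hypergeometric over-representation test with Bonferroni
correction covers arbitrary term collections. Occupation ratios quantify
how much of a complex's selected-gene content each dataset contributes,
attributing genes selected by several datasets fractionally (1/m each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSetCollection
from .hub_psg import PSGSet
from .ppi_network import Complex, PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class FisherResult:
    """A 2x2 enrichment test: target x flag membership over a universe."""

    a: int  # target & flag
    b: int  # target & not flag
    c: int  # flag & not target
    d: int  # neither
    odds_ratio: float
    p_one_tailed: float
    alpha: float = 0.05

    @property
    def enriched(self) -> bool:
        return self.p_one_tailed <= self.alpha

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_from_counts(a: int, n_target: int, n_flag: int, n_universe: int, alpha: float = 0.05) -> FisherResult:
    """Upper-tail Fisher test from pre-tabulated marginal counts.

    ``a`` flagged genes among ``n_target`` target genes, ``n_flag`` flagged
    genes overall, ``n_universe`` genes in total. The p-value is the exact
    hypergeometric upper tail P(X >= a), evaluated in log space.
    """
    if n_universe <= 0:
        raise ValueError("universe must be non-empty")
    b = n_target - a
    c = n_flag - a
    d = n_universe - n_target - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent contingency counts")
    # survival function of the hypergeometric: P(X >= a)
    p = float(np.exp(stats.hypergeom.logsf(a - 1, n_universe, n_flag, n_target)))
    p = min(1.0, max(0.0, p))
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    return FisherResult(a=a, b=b, c=c, d=d, odds_ratio=float(odds), p_one_tailed=p, alpha=alpha)


def fisher_enrichment(
    target_genes: set[str],
    flag_genes: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> FisherResult:
    """One-tailed Fisher enrichment of ``flag_genes`` within ``target_genes``."""
    target = set(target_genes) & set(universe)
    flag = set(flag_genes) & set(universe)
    a = len(target & flag)
    return fisher_from_counts(a, len(target), len(flag), len(universe), alpha)


def enrichment_battery(
    complexes: list[Complex],
    network: PPINetwork,
    psgs: set[str],
    universe: set[str],
    flag_collections: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All flag-set enrichment comparisons as one long-form table.

    For each flag set the comparisons are: each complex vs the other network
    genes; each complex vs the genes of the other complexes; the union of
    complexes vs non-complex network genes; the network vs the rest of the
    universe; selected genes vs the rest of the universe.
    """
    network_genes = set(network.graph.nodes)
    cx_union: set[str] = set()
    for cx in complexes:
        cx_union |= cx.members
    rows = []

    def _emit(flag_name, flag, comparison, target, background):
        if not background:
            logger.warning("comparison %s skipped: empty background", comparison)
            return
        res = fisher_enrichment(target, flag, background, alpha)
        rows.append(
            {
                "flag_set": flag_name,
                "comparison": comparison,
                "n_target": res.a + res.b,
                "n_universe": res.universe_size,
                "a": res.a,
                "odds_ratio": res.odds_ratio,
                "p": res.p_one_tailed,
                "enriched": res.enriched,
            }
        )

    for flag_name, flag in sorted(flag_collections.items()):
        for i, cx in enumerate(complexes, start=1):
            _emit(flag_name, flag, f"complex_{i}_vs_network", cx.members, network_genes)
            others = (cx_union - cx.members) | cx.members
            _emit(flag_name, flag, f"complex_{i}_vs_other_complexes", cx.members, others)
        _emit(flag_name, flag, "complexes_vs_network", cx_union, network_genes)
        _emit(flag_name, flag, "network_vs_universe", network_genes, set(universe))
        _emit(flag_name, flag, "psgs_vs_universe", set(psgs), set(universe))
    return pd.DataFrame(rows)


def over_representation(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term over-representation with Bonferroni correction.

    Query members outside the background are dropped with a warning. Only
    terms with at least one query member are reported; the Bonferroni factor
    is the number of reported terms.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    query = set(query)
    outside = query - set(background)
    if outside:
        logger.warning("%d query gene(s) outside background dropped", len(outside))
        query &= set(background)
    n_universe = len(background)
    rows = []
    for name, members in sorted(collection.items()):
        members = set(members) & set(background)
        a = len(query & members)
        if a == 0:
            continue
        p = float(
            np.exp(stats.hypergeom.logsf(a - 1, n_universe, len(members), len(query)))
        )
        rows.append(
            {
                "term": name,
                "n_term": len(members),
                "n_query": len(query),
                "overlap": a,
                "p": min(1.0, max(0.0, p)),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "n_term", "n_query", "overlap", "p"])
    n_tests = len(df)
    df["p_adjusted"] = np.minimum(1.0, df["p"] * n_tests)
    df["significant"] = df["p_adjusted"] <= alpha
    return df.sort_values(["p_adjusted", "term"], kind="mergesort").reset_index(drop=True)


def occupation_ratios(
    complexes: list[Complex], psgs: PSGSet
) -> pd.DataFrame:
    """Per-(complex, dataset) occupation ratios with fractional attribution.

    occ(c, d) = sum over PSGs g in complex c selected by dataset d of 1/m_g,
    divided by the number of PSGs in c. Rows sum to 1 for complexes with at
    least one PSG member; a complex without PSG members gets an all-zero row
    (flagged with a warning).
    """
    datasets = sorted(psgs.per_dataset)
    m = psgs.membership
    rows = {}
    for i, cx in enumerate(complexes, start=1):
        members_psg = cx.members & psgs.union
        name = f"complex_{i}"
        if not members_psg:
            logger.warning("%s has no selected-gene member; zero occupation row", name)
            rows[name] = {d: 0.0 for d in datasets}
            continue
        denom = float(len(members_psg))
        row = {}
        for d in datasets:
            selected = psgs.per_dataset[d]
            row[d] = sum(1.0 / m[g] for g in members_psg if g in selected) / denom
        rows[name] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=datasets)
    out.index.name = "complex"
    return out


def ranked_occupation_profiles(occupation: pd.DataFrame) -> pd.DataFrame:
    """Rank-ordered ratio profile per complex plus dataset presence counts."""
    ranked = pd.DataFrame(
        np.sort(occupation.to_numpy(), axis=1)[:, ::-1],
        index=occupation.index,
        columns=[f"rank_{i + 1}" for i in range(occupation.shape[1])],
    )
    ranked["n_datasets_present"] = (occupation > 0).sum(axis=1)
    return ranked


def expression_group_summary(
    matrices: list[ExpressionMatrix],
    groups: dict[str, str],
    pseudo: float = 1e-3,
) -> pd.DataFrame:
    """Log-average-expression summaries per gene group per dataset.

    Per gene and dataset the statistic is log10(mean FPKM + pseudo); the
    pseudo-count keeps zero-expression genes finite. Returns a long-form
    table with per-group medians and sample counts, plus the two-sample
    Kolmogorov-Smirnov distances between group distributions (descriptive).
    """
    rows = []
    for em in matrices:
        log_mean = np.log10(em.values.mean(axis=1) + pseudo)
        by_group: dict[str, np.ndarray] = {}
        for grp in sorted(set(groups.values())):
            members = [g for g in em.values.index if groups.get(g) == grp]
            if not members:
                logger.warning("%s: group %r empty, omitted", em.dataset_id, grp)
                continue
            by_group[grp] = log_mean.loc[members].to_numpy()
        for grp, vals in by_group.items():
            rows.append(
                {
                    "dataset_id": em.dataset_id,
                    "group": grp,
                    "n": len(vals),
                    "median_log10": float(np.median(vals)),
                    "mean_log10": float(np.mean(vals)),
                }
            )
        names = sorted(by_group)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ks = stats.ks_2samp(by_group[names[i]], by_group[names[j]])
                rows.append(
                    {
                        "dataset_id": em.dataset_id,
                        "group": f"KS({names[i]},{names[j]})",
                        "n": len(by_group[names[i]]) + len(by_group[names[j]]),
                        "median_log10": float(ks.statistic),
                        "mean_log10": float(ks.pvalue),
                    }
                )
    return pd.DataFrame(rows)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative distribution function points (x sorted, F(x))."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y
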