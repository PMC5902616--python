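"""Signed weighted co-expression networks, modules, eigengenes and kME.

The network is built from the signed soft-thresholded Pearson correlation,

    a_ij = ((1 + r_ij) / 2) ** beta,

so perfectly anti-correlated genes get adjacency 0 rather than folding onto
positive correlations. Shared-neighbour structure is summarised by the
topological overlap measure

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij  = sum_{u != i,j} a_iu * a_uj,

and modules are clusters of the 1 - TOM dissimilarity (average linkage,
static tree cut, minimum module size). A module eigengene is the first
principal component of its members' standardised expression; module
membership kME is the Pearson correlation of a gene with an eigengene, with
a two-sided Student-t p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# soft-threshold selection
# ---------------------------------------------------------------------------

@dataclass
class SoftThresholdFit:
    """Scale-free-topology fit per candidate power, and the chosen power."""

    fit_table: pd.DataFrame = field(repr=False)  # power, signed_r2, mean_k, median_k
    chosen_power: int = 0


def _corr(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance gene; filter constant genes first")
    r = np.corrcoef(values)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(matrix: pd.DataFrame, power: float) -> pd.DataFrame:
    """Signed soft-thresholded adjacency ((1 + r) / 2) ** power, diagonal 1."""
    if power < 1:
        raise ValueError("power must be >= 1")
    r = _corr(matrix.to_numpy(dtype=float))
    a = ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.index)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10 of
    the per-bin frequency is regressed on the log10 of the per-bin mean
    connectivity over non-empty bins. The fit index is R^2 times the negated
    sign of the slope, so scale-free-like (decreasing) distributions score
    positively.
    """
    k = np.asarray(k, dtype=float)
    n = len(k)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        mean_k.append(mk)
        freq.append(mask.sum() / n)
    if len(mean_k) < 3:
        return 0.0
    lx, ly = np.log10(mean_k), np.log10(freq)
    res = stats.linregress(lx, ly)
    if np.isnan(res.rvalue) or res.slope == 0:
        return 0.0
    return float(res.rvalue**2 * -np.sign(res.slope))


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_cut: float = 0.8,
) -> SoftThresholdFit:
    """Pick the smallest power reaching the scale-free fit criterion.

    If no candidate reaches ``r2_cut`` the power with the best fit is used
    and a warning logged.
    """
    powers = sorted(int(p) for p in candidate_powers)
    if len(powers) != len(set(powers)):
        raise ValueError("candidate powers must be strictly increasing")
    values = matrix.to_numpy(dtype=float)
    r = _corr(values)
    base = (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)

    rows = []
    for p in powers:
        a = base**p
        k = a.sum(axis=1)
        rows.append(
            {
                "power": p,
                "signed_r2": _scale_free_fit(k),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
            }
        )
    fit = pd.DataFrame(rows)
    ok = fit[fit["signed_r2"] >= r2_cut]
    if len(ok):
        chosen = int(ok["power"].iloc[0])
    else:
        chosen = int(fit.loc[fit["signed_r2"].idxmax(), "power"])
        logger.warning(
            "no candidate power reached signed R^2 >= %.2f; using best fit %d",
            r2_cut,
            chosen,
        )
    return SoftThresholdFit(fit_table=fit, chosen_power=chosen)


# ---------------------------------------------------------------------------
# topological overlap
# ---------------------------------------------------------------------------

def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM of a symmetric [0, 1] adjacency; diagonal 1 by convention."""
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    # l_ij = sum_u a_iu a_uj over u != i, j; the matrix product counts all u,
    # and the diagonal entries of a0 are zero, so u = i and u = j contribute 0
    l = a0 @ a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleAssignment:
    """Per-gene module labels plus eigengenes and membership statistics.

    ``labels`` maps gene -> module (0 = unassigned). ``eigengenes`` is a
    modules x samples frame; ``kme`` and ``kme_p`` are genes x modules.
    """

    dataset_id: str
    labels: pd.Series = field(repr=False)
    eigengenes: pd.DataFrame | None = field(default=None, repr=False)
    kme: pd.DataFrame | None = field(default=None, repr=False)
    kme_p: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.labels[self.labels > 0]
        return assigned.value_counts().sort_index()

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float | str = "auto",
    dataset_id: str = "",
) -> ModuleAssignment:
    """Cluster genes on 1 - TOM and assign module labels.

    Average-linkage hierarchical clustering with a static cut. ``"auto"``
    places the cut at the midpoint of the largest gap in the sorted merge
    heights: tight clusters finish merging well below the band where
    unrelated genes join, so the widest gap separates within-module from
    between-module merges. Clusters smaller than ``min_module_size`` are
    unassigned (label 0); surviving modules are relabelled 1..M by
    decreasing size, ties broken by smallest member id.
    """
    genes = tom.index
    n = len(genes)
    if n < min_module_size:
        logger.warning("fewer genes (%d) than min module size; all unassigned", n)
        return ModuleAssignment(dataset_id, pd.Series(0, index=genes, dtype=int))
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)  # symmetrise fp noise
    link = linkage(squareform(diss, checks=False), method="average")
    heights = link[:, 2]
    if cut_height == "auto":
        if len(heights) < 2:
            cut = float(heights.max()) if len(heights) else 0.0
        else:
            hs = np.sort(heights)
            gap = int(np.argmax(np.diff(hs)))
            cut = float((hs[gap] + hs[gap + 1]) / 2.0)
    else:
        cut = float(cut_height)
    raw = fcluster(link, t=cut, criterion="distance")

    labels = pd.Series(0, index=genes, dtype=int)
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    keep = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    keep.sort(key=lambda ms: (-len(ms), min(ms)))
    for new_label, members in enumerate(keep, start=1):
        labels.loc[members] = new_label
    return ModuleAssignment(dataset_id, labels)


# ---------------------------------------------------------------------------
# eigengenes and module membership
# ---------------------------------------------------------------------------

def module_eigengenes(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    Member expression is z-scored per gene before the PCA; each eigengene is
    oriented so its mean correlation with member genes is positive.
    """
    modules = sorted(set(labels[labels > 0]))
    rows = {}
    for m in modules:
        members = labels.index[labels == m]
        if len(members) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        x = matrix.loc[members].to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"module {m} contains a constant gene")
        z = (x - mu) / sd
        # first right-singular vector = PC1 sample scores
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        if s[0] == 0:
            raise ValueError(f"module {m} expression is degenerate (rank 0)")
        e = vt[0]
        e = e / e.std(ddof=1)
        mean_cor = np.mean([np.corrcoef(z[i], e)[0, 1] for i in range(z.shape[0])])
        if mean_cor < 0:
            e = -e
        rows[m] = e
    return pd.DataFrame(
        rows, index=matrix.columns
    ).T.rename_axis("module")


def module_membership(
    matrix: pd.DataFrame, eigengenes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME (gene x eigengene Pearson correlation) and its two-sided p-value.

    The p-value comes from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2
    degrees of freedom; |r| = 1 gives p = 0.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("module membership needs >= 3 samples")
    x = matrix.to_numpy(dtype=float)
    e = eigengenes.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True))
    xsd = xz.std(axis=1)
    ez = (e - e.mean(axis=1, keepdims=True))
    esd = ez.std(axis=1)
    if (xsd == 0).any() or (esd == 0).any():
        raise ValueError("constant gene or eigengene")
    r = (xz @ ez.T) / n / np.outer(xsd, esd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    kme = pd.DataFrame(r, index=matrix.index, columns=eigengenes.index)
    kme_p = pd.DataFrame(p, index=matrix.index, columns=eigengenes.index)
    return kme, kme_p


def analyze(
    matrix: pd.DataFrame,
    power: int | None = None,
    candidate_powers=tuple(range(1, 13)),
    r2_cut: float = 0.8,
    min_module_size: int = 30,
    cut_height: float | str = "auto",
    dataset_id: str = "",
    log_transform: bool = True,
    pseudo: float = 1e-3,
) -> tuple[ModuleAssignment, SoftThresholdFit | None]:
    """Full per-dataset co-expression analysis.

    Picks a soft threshold (unless ``power`` is given), builds the signed
    TOM, detects modules, and attaches eigengenes and kME statistics.

    ``log_transform`` applies log2(x + pseudo) before computing
    correlations; Pearson correlation on heavily right-skewed FPKM-scale
    values is dominated by the largest observations, so correlation
    networks are conventionally built on the log scale. The pseudo-count
    guards zero FPKM and matches the ECDF summary convention.
    """
    if log_transform:
        matrix = np.log2(matrix + pseudo)
    fit = None
    if power is None:
        fit = pick_soft_threshold(matrix, candidate_powers, r2_cut)
        power = fit.chosen_power
    adj = signed_adjacency(matrix, power)
    tom = topological_overlap(adj)
    assignment = detect_modules(tom, min_module_size, cut_height, dataset_id)
    if (assignment.labels > 0).any():
        assignment.eigengenes = module_eigengenes(matrix, assignment.labels)
        assignment.kme, assignment.kme_p = module_membership(
            matrix, assignment.eigengenes
        )
    return assignment, fit
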