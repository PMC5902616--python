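"""Synthetic multi-dataset cohorts with known ground truth.

Every downstream stage of the pipeline (mutation filtering, co-expression
module detection, hub selection, PPI complex discovery, enrichment) is tested
against cohorts generated here, where the planted structure is known exactly:

- expression matrices carry planted correlated modules on a log-normal
  positive scale, so quantile normalisation and signed-correlation networks
  see FPKM-like skewed data;
- mutation tables carry per-aliquot Poisson call counts with planted
  high-rate genes and controllable depth/annotation failure rates;
- PPI edge lists carry planted dense complexes whose combined scores sit
  above the thresholding cut-off, on a sparse background below it.

All generators draw from a single numpy Generator seeded per call, so equal
seeds give byte-identical artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import BIOTYPE_CATEGORY, FLAG_NAMES, GeneUniverse
from .io_formats import ExpressionMatrix

# non-coding biotypes with sampling weights loosely shaped like the human
# annotation (pseudogenes dominate the non-coding space)
_NONCODING_BIOTYPES = [bt for bt in BIOTYPE_CATEGORY if bt != "protein_coding"]
_NONCODING_WEIGHTS = {
    "pseudogene": 0.60,
    "short_non_coding": 0.20,
    "long_non_coding": 0.15,
    "problematic": 0.05,
}

#: annotation categories that do NOT disqualify an aliquot
BENIGN_ANNOTATIONS = (
    "Acceptable treatment for TCGA tumour",
    "Alternate sample pipeline",
    "Item in special subset",
    "Item is noncanonical",
)

#: annotation categories that disqualify an aliquot
DISQUALIFYING_ANNOTATIONS = (
    "Prior malignancy",
    "Item may not meet study protocol",
    "Barcode incorrect",
    "BCR notification",
)

_VARIANT_CLASSES = (
    "Missense_Mutation",
    "Silent",
    "Nonsense_Mutation",
    "Splice_Site",
    "Frame_Shift_Del",
)


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class ModuleTruth:
    """Planted co-expression structure for one dataset.

    ``module_of_gene`` maps gene -> module label (0 = background);
    ``loading_of_gene`` maps gene -> beta, the target correlation between the
    gene's latent profile and its module's latent eigengene.
    ``latent_eigengenes`` keeps the latent per-sample eigengene draws so
    recovery tests can correlate estimated eigengenes against the truth.
    """

    dataset_id: str
    module_of_gene: dict[str, int]
    loading_of_gene: dict[str, float]
    latent_eigengenes: pd.DataFrame = field(repr=False)

    def members(self, module: int) -> set[str]:
        return {g for g, m in self.module_of_gene.items() if m == module}


@dataclass
class ComplexTruth:
    """Planted dense complexes for the PPI generator."""

    planted_complexes: list[set[str]]
    p_in: float = 1.0
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        seen: set[str] = set()
        for cx in self.planted_complexes:
            if seen & set(cx):
                raise ValueError("planted complexes must be pairwise disjoint")
            seen |= set(cx)


@dataclass
class MutationTruth:
    """Planted mutation-rate structure."""

    planted_hot_genes: set[str] = field(default_factory=set)
    base_rate: float = 0.01
    hot_multiplier: float = 1.0
    depth_fail_rate: float = 0.0
    annotation_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("base_rate", "hot_multiplier", "depth_fail_rate", "annotation_fail_rate"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.hot_multiplier < 1:
            raise ValueError("hot_multiplier must be >= 1")


@dataclass
class MutationGenStats:
    """What the mutation generator actually drew, per dataset.

    Filter tests compare survivor counts against these numbers, which are
    recorded at draw time and are independent of any filtering code.
    """

    n_records: int
    n_depth_pass: int
    n_primary: int
    n_clean_aliquot: int  # records on aliquots without disqualifying annotations
    bad_aliquots: set[str]
    n_aliquots: int


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_universe(
    n_genes: int,
    coding_fraction: float = 0.7,
    flag_rates: dict[str, float] | None = None,
    release_member_rate: float = 1.0,
    seed: int = 0,
) -> GeneUniverse:
    """Draw a gene universe with coding status, biotypes, lengths and flags.

    The first ``round(coding_fraction * n_genes)`` genes are protein-coding;
    non-coding genes get a biotype drawn with pseudogene-heavy weights. Flags
    are independent Bernoulli draws per gene at the given rates.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 < coding_fraction <= 1):
        raise ValueError("coding_fraction must be in (0, 1]")
    flag_rates = dict(flag_rates or {})
    for name in flag_rates:
        if name not in FLAG_NAMES:
            raise ValueError(f"unknown flag {name!r}")
    rng = np.random.default_rng(seed)

    gene_ids = [f"ENSG{i:08d}" for i in range(n_genes)]
    n_coding = int(round(coding_fraction * n_genes))
    coding = np.zeros(n_genes, dtype=bool)
    coding[:n_coding] = True

    biotypes = np.array(["protein_coding"] * n_genes, dtype=object)
    n_nc = n_genes - n_coding
    if n_nc:
        probs = np.array(
            [_NONCODING_WEIGHTS[BIOTYPE_CATEGORY[bt]] for bt in _NONCODING_BIOTYPES]
        )
        # normalise within categories so each biotype in a category is equally
        # likely and categories follow the weights above
        cat_counts = {}
        for bt in _NONCODING_BIOTYPES:
            cat_counts[BIOTYPE_CATEGORY[bt]] = cat_counts.get(BIOTYPE_CATEGORY[bt], 0) + 1
        probs = probs / np.array([cat_counts[BIOTYPE_CATEGORY[bt]] for bt in _NONCODING_BIOTYPES])
        probs = probs / probs.sum()
        biotypes[n_coding:] = rng.choice(_NONCODING_BIOTYPES, size=n_nc, p=probs)

    exon_length = np.maximum(1, rng.lognormal(mean=7.5, sigma=0.9, size=n_genes)).astype(int)

    flags = [set() for _ in range(n_genes)]
    for name, rate in flag_rates.items():
        hits = rng.random(n_genes) < rate
        for i in np.nonzero(hits)[0]:
            flags[i].add(name)

    release_member = rng.random(n_genes) < release_member_rate

    table = pd.DataFrame(
        {
            "coding": coding,
            "biotype": biotypes,
            "exon_length_bp": exon_length,
            "flags": [frozenset(f) for f in flags],
            "release_member": release_member,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneUniverse(table)


def generate_expression(
    universe: GeneUniverse,
    n_samples: int,
    modules: list[tuple[int, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    dataset_id: str = "SYN",
    extra_profile_rate: float = 0.0,
    min_module_size: int = 30,
) -> tuple[ExpressionMatrix, ModuleTruth]:
    """Draw an FPKM-like matrix with planted correlated modules.

    For module ``m`` a latent eigengene ``e_m ~ N(0, 1)`` is drawn per
    sample. A member gene with loading ``beta`` has latent value
    ``beta * e_m + eps`` with ``eps ~ N(0, (noise_sd * sqrt(1 - beta^2))^2)``,
    so at the default ``noise_sd = 1`` the latent gene-eigengene correlation
    is exactly ``beta``. Background genes are pure ``N(0, 1)`` noise. The
    observed value is ``exp(latent + per-gene offset)``: positive and
    log-normally skewed like FPKM.
    """
    modules = list(modules or [])
    coding_ids = [g for g in universe.gene_ids if universe.table.at[g, "coding"]]
    total = sum(size for size, _ in modules)
    if total > len(coding_ids):
        raise ValueError("module sizes exceed number of coding genes")
    for size, beta in modules:
        if size < min_module_size:
            raise ValueError(f"module size {size} below minimum {min_module_size}")
        if not (0 <= beta <= 1):
            raise ValueError("module loading beta must be in [0, 1]")

    rng = np.random.default_rng(seed)
    gene_ids = list(universe.gene_ids)
    n_genes = len(gene_ids)

    assigned = list(rng.permutation(coding_ids))
    module_of: dict[str, int] = {g: 0 for g in gene_ids}
    loading: dict[str, float] = {g: 0.0 for g in gene_ids}
    cursor = 0
    for m, (size, beta) in enumerate(modules, start=1):
        for g in assigned[cursor : cursor + size]:
            module_of[g] = m
            loading[g] = float(beta)
        cursor += size

    eigengenes = rng.standard_normal((len(modules), n_samples))
    latent = np.empty((n_genes, n_samples))
    for i, g in enumerate(gene_ids):
        m = module_of[g]
        if m == 0:
            latent[i] = rng.standard_normal(n_samples)
        else:
            beta = loading[g]
            eps_sd = noise_sd * np.sqrt(max(0.0, 1.0 - beta * beta))
            latent[i] = beta * eigengenes[m - 1] + rng.normal(0.0, eps_sd, n_samples)

    offsets = rng.normal(1.0, 1.0, n_genes)
    values = np.exp(latent + offsets[:, None])

    barcodes = [f"{dataset_id}-S{i:04d}-01A" for i in range(n_samples)]
    cases = {bc: f"{dataset_id}-C{i:04d}" for i, bc in enumerate(barcodes)}
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=barcodes)

    # optionally add duplicate profiles for a subset of cases (exercises the
    # one-profile-per-case selection step)
    if extra_profile_rate > 0:
        dup_mask = rng.random(n_samples) < extra_profile_rate
        for i in np.nonzero(dup_mask)[0]:
            bc = f"{dataset_id}-S{i:04d}-01B"
            jitter = rng.normal(0.0, 0.05, n_genes)
            df[bc] = np.exp(latent[:, i] + offsets + jitter)
            cases[bc] = f"{dataset_id}-C{i:04d}"

    matrix = ExpressionMatrix(dataset_id, df, cases)
    truth = ModuleTruth(
        dataset_id,
        module_of,
        loading,
        pd.DataFrame(
            eigengenes,
            index=pd.RangeIndex(1, len(modules) + 1, name="module"),
            columns=barcodes,
        ),
    )
    return matrix, truth


def generate_mutations(
    universe: GeneUniverse,
    datasets: list[tuple[str, int]],
    truth: MutationTruth,
    seed: int = 0,
    nonprimary_rate: float = 0.1,
    benign_annotation_rate: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, set[str]], dict[str, MutationGenStats]]:
    """Draw MAF-like mutation records for one or more datasets.

    Per gene x aliquot the call count is Poisson with rate ``base_rate``
    (times ``hot_multiplier`` for planted hot genes). Each record gets
    depths that pass the depth filter (t >= 14, n >= 8) unless it is drawn
    as a failure with probability ``depth_fail_rate``, in which case one of
    the two depths is drawn uniformly below its threshold. Aliquots carry a
    disqualifying annotation with probability ``annotation_fail_rate``.

    Returns the record table, the aliquot -> annotation-categories map and
    per-dataset draw statistics (the ground truth for filter tests).
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.array(list(universe.gene_ids))
    hot = np.isin(gene_ids, list(truth.planted_hot_genes))
    rates = np.where(hot, truth.base_rate * truth.hot_multiplier, truth.base_rate)

    frames = []
    annotations: dict[str, set[str]] = {}
    stats: dict[str, MutationGenStats] = {}
    for dataset_id, n_aliquots in datasets:
        if n_aliquots < 1:
            raise ValueError("n_aliquots must be >= 1")
        barcodes = [f"TCGA-{dataset_id}-{i:04d}-01A" for i in range(n_aliquots)]

        sample_types = np.where(
            rng.random(n_aliquots) < nonprimary_rate, "Metastatic", "Primary Tumour"
        )
        if nonprimary_rate > 0 and (sample_types == "Primary Tumour").all():
            sample_types[-1] = "Metastatic"

        bad_aliquots: set[str] = set()
        for i, bc in enumerate(barcodes):
            cats: set[str] = set()
            if rng.random() < truth.annotation_fail_rate:
                cats.add(str(rng.choice(DISQUALIFYING_ANNOTATIONS)))
                bad_aliquots.add(bc)
            if rng.random() < benign_annotation_rate:
                cats.add(str(rng.choice(BENIGN_ANNOTATIONS)))
            if cats:
                annotations[bc] = cats

        counts = rng.poisson(rates[:, None], size=(len(gene_ids), n_aliquots))
        gi, ai = np.nonzero(counts)
        reps = counts[gi, ai]
        rec_gene = np.repeat(gene_ids[gi], reps)
        rec_aliquot = np.repeat(np.array(barcodes, dtype=object)[ai], reps)
        rec_sample_type = np.repeat(sample_types[ai], reps)
        n_records = len(rec_gene)

        depth_fail = rng.random(n_records) < truth.depth_fail_rate
        t_depth = rng.integers(14, 121, n_records)
        n_depth = rng.integers(8, 81, n_records)
        fail_side = rng.random(n_records) < 0.5
        t_depth = np.where(depth_fail & fail_side, rng.integers(0, 14, n_records), t_depth)
        n_depth = np.where(depth_fail & ~fail_side, rng.integers(0, 8, n_records), n_depth)

        variant_class = rng.choice(_VARIANT_CLASSES, size=n_records)

        frame = pd.DataFrame(
            {
                "gene_id": rec_gene,
                "dataset_id": dataset_id,
                "aliquot_barcode": rec_aliquot,
                "sample_type": rec_sample_type,
                "t_depth": t_depth.astype(int),
                "n_depth": n_depth.astype(int),
                "variant_classification": variant_class,
            }
        )
        frames.append(frame)
        clean = ~frame["aliquot_barcode"].isin(bad_aliquots)
        stats[dataset_id] = MutationGenStats(
            n_records=n_records,
            n_depth_pass=int((~depth_fail).sum()),
            n_primary=int((rec_sample_type == "Primary Tumour").sum()),
            n_clean_aliquot=int(clean.sum()),
            bad_aliquots=bad_aliquots,
            n_aliquots=n_aliquots,
        )

    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[
            "gene_id",
            "dataset_id",
            "aliquot_barcode",
            "sample_type",
            "t_depth",
            "n_depth",
            "variant_classification",
        ]
    )
    return table, annotations, stats


def _triu_pair(flat: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map flat indices of the strict upper triangle of an n x n matrix to (i, j)."""
    # row i occupies indices [i*n - i*(i+1)/2 - i, ...); invert by solving the
    # quadratic for i, then recover j
    i = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(int)
    j = (flat + i + 1 - i * n + i * (i + 1) // 2).astype(int)
    return i, j


def generate_ppi(
    universe: GeneUniverse,
    truth: ComplexTruth,
    seed: int = 0,
    score_low: tuple[int, int] = (150, 949),
    score_high: tuple[int, int] = (900, 1000),
) -> pd.DataFrame:
    """Draw an undirected, deduplicated PPI edge list with integer scores.

    Pairs inside a planted complex get an edge with probability ``p_in`` and
    a score from ``score_high`` (inclusive range, >= 900 by default); pairs
    between coding genes otherwise get an edge with probability ``p_out`` and
    a score from ``score_low`` (< 950 by default, so only a minority survive
    the 900 threshold). Nodes are the coding genes of the universe.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(universe.coding_genes)
    node_set = set(nodes)
    for cx in truth.planted_complexes:
        if not set(cx) <= node_set:
            raise ValueError("planted complexes must be subsets of the coding genes")
    index_of = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)

    complex_pairs: set[tuple[int, int]] = set()
    rows: list[tuple[str, str, int]] = []
    for cx in truth.planted_complexes:
        members = sorted(cx)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = index_of[members[a]], index_of[members[b]]
                pair = (min(i, j), max(i, j))
                complex_pairs.add(pair)
                if rng.random() < truth.p_in:
                    score = int(rng.integers(score_high[0], score_high[1] + 1))
                    rows.append((nodes[pair[0]], nodes[pair[1]], score))

    n_pairs = n * (n - 1) // 2
    if truth.p_out > 0 and n_pairs:
        m = rng.binomial(n_pairs, truth.p_out)
        flat = rng.choice(n_pairs, size=m, replace=False)
        ii, jj = _triu_pair(np.sort(flat), n)
        for i, j in zip(ii, jj):
            if (i, j) in complex_pairs:
                continue
            score = int(rng.integers(score_low[0], score_low[1] + 1))
            rows.append((nodes[i], nodes[j], score))

    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    edges = edges.sort_values(["protein1", "protein2"], kind="mergesort").reset_index(drop=True)
    return edges


# ---------------------------------------------------------------------------
# whole-cohort simulation to disk
# ---------------------------------------------------------------------------

def simulate_cohort(config: dict, out_dir, seed: int) -> dict:
    """Generate a full multi-dataset cohort and write it to ``out_dir``.

    ``config`` keys (all optional, with small defaults):

    - ``n_genes``, ``coding_fraction``, ``flag_rates``, ``release_member_rate``
    - ``datasets``: list of ``{id, n_samples, n_aliquots, modules}`` where
      ``modules`` is a list of ``[size, beta]`` pairs
    - ``mutation``: ``{base_rate, hot_multiplier, n_hot_genes,
      depth_fail_rate, annotation_fail_rate}``
    - ``ppi``: ``{n_complexes, complex_size, p_in, p_out}``

    Returns a manifest of written paths plus the ground-truth objects, so
    callers can hand the paths to :class:`pancanhub.pipeline.RunConfig` and
    check recovered structure against the truth.
    """
    from pathlib import Path

    from . import io_formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_genes = int(config.get("n_genes", 800))
    universe = generate_universe(
        n_genes,
        coding_fraction=float(config.get("coding_fraction", 0.7)),
        flag_rates=config.get("flag_rates", {"PCD1": 0.01, "known_cancer": 0.01}),
        release_member_rate=float(config.get("release_member_rate", 0.97)),
        seed=int(rng.integers(2**31)),
    )
    annotation_path = out / "annotation.tsv"
    io_formats.write_annotation(universe, annotation_path)

    flag_sets = {
        name: frozenset(universe.flag_set(name))
        for name in ("PCD1", "PCD2", "PCD3", "known_cancer", "candidate_cancer")
        if universe.flag_set(name)
    }
    flags_path = out / "flags.gmt"
    io_formats.write_gmt(
        io_formats.GeneSetCollection(flag_sets, {k: "synthetic flag set" for k in flag_sets}),
        flags_path,
    )

    mut_cfg = config.get("mutation", {})
    n_hot = int(mut_cfg.get("n_hot_genes", 10))
    hot_genes = set(
        rng.choice(list(universe.gene_ids), size=min(n_hot, n_genes), replace=False)
    )
    mutation_truth = MutationTruth(
        planted_hot_genes=hot_genes,
        base_rate=float(mut_cfg.get("base_rate", 0.02)),
        hot_multiplier=float(mut_cfg.get("hot_multiplier", 20.0)),
        depth_fail_rate=float(mut_cfg.get("depth_fail_rate", 0.1)),
        annotation_fail_rate=float(mut_cfg.get("annotation_fail_rate", 0.05)),
    )

    datasets = config.get(
        "datasets",
        [
            {"id": "AA", "n_samples": 60, "n_aliquots": 60, "modules": [[40, 0.9], [40, 0.9]]},
            {"id": "BB", "n_samples": 60, "n_aliquots": 60, "modules": [[40, 0.9], [40, 0.9]]},
        ],
    )
    table, annotations, stats = generate_mutations(
        universe,
        [(d["id"], int(d["n_aliquots"])) for d in datasets],
        mutation_truth,
        seed=int(rng.integers(2**31)),
    )
    annotations_path = out / "aliquot_annotations.tsv"
    io_formats.write_aliquot_annotations(annotations, annotations_path)

    manifest = {
        "annotation": str(annotation_path),
        "flags_gmt": str(flags_path),
        "aliquot_annotations": str(annotations_path),
        "datasets": [],
        "universe": universe,
        "mutation_truth": mutation_truth,
        "mutation_stats": stats,
        "module_truths": {},
    }

    for d in datasets:
        dsid = d["id"]
        maf_path = out / f"{dsid}.maf.tsv"
        io_formats.write_maf(table[table["dataset_id"] == dsid], maf_path)
        matrix, mtruth = generate_expression(
            universe,
            int(d["n_samples"]),
            modules=[(int(s), float(b)) for s, b in d.get("modules", [])],
            seed=int(rng.integers(2**31)),
            dataset_id=dsid,
        )
        expr_path = out / f"{dsid}.fpkm.tsv"
        io_formats.write_expression(matrix, expr_path)
        meta = pd.DataFrame(
            {
                "aliquot_barcode": list(matrix.values.columns),
                "case_id": [matrix.case_of_aliquot[bc] for bc in matrix.values.columns],
                "sample_type": "Primary Tumour",
            }
        )
        meta_path = out / f"{dsid}.aliquots.tsv"
        io_formats.write_aliquot_metadata(meta, meta_path)
        manifest["module_truths"][dsid] = mtruth
        manifest["datasets"].append(
            {
                "dataset_id": dsid,
                "maf": str(maf_path),
                "expression": str(expr_path),
                "aliquot_metadata": str(meta_path),
                "aliquot_annotations": str(annotations_path),
            }
        )

    ppi_cfg = config.get("ppi", {})
    coding = sorted(universe.coding_genes)
    n_cx = int(ppi_cfg.get("n_complexes", 3))
    cx_size = int(ppi_cfg.get("complex_size", 12))
    chosen = rng.choice(coding, size=min(n_cx * cx_size, len(coding)), replace=False)
    planted = [set(chosen[i * cx_size : (i + 1) * cx_size]) for i in range(n_cx)]
    complex_truth = ComplexTruth(
        planted_complexes=planted,
        p_in=float(ppi_cfg.get("p_in", 1.0)),
        p_out=float(ppi_cfg.get("p_out", 0.002)),
    )
    edges = generate_ppi(universe, complex_truth, seed=int(rng.integers(2**31)))
    ppi_path = out / "ppi_edges.tsv"
    io_formats.write_ppi_edges(edges, ppi_path)
    manifest["ppi_edges"] = str(ppi_path)
    manifest["complex_truth"] = complex_truth
    return manifest
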