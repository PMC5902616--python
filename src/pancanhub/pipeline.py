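"""End-to-end orchestration: filter -> prep -> coexpress -> hubs -> PSGs ->
PPI -> complexes -> enrichment, across datasets, from one YAML config.

Per-dataset stages are independent of each other; integration stages (PSG
union, PPI network, complexes, enrichment) run after all datasets finish.
Every intermediate artefact is written next to the report so each number in
the report can be re-derived from disk. The run is deterministic under a
fixed seed and the report is byte-stable across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import (
    coexpression,
    enrichment_stats,
    expression_prep,
    hub_psg,
    io_formats,
    mutation_filtering,
    ppi_network,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetPaths:
    """Input file locations for one dataset."""

    dataset_id: str
    maf: str
    expression: str
    aliquot_metadata: str | None = None
    aliquot_annotations: str | None = None


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Thresholds default to the values the analysis is defined with: depth
    cut-offs 14/8, 5% hub quota, kME >= 0.9 at p <= 0.01, combined score
    >= 900, K-core filter 10, minimum module size 30, alpha 0.05.
    """

    datasets: list[DatasetPaths]
    annotation: str
    ppi_edges: str
    flags_gmt: str
    seed: int
    t_depth_min: int = 14
    n_depth_min: int = 8
    target_fraction: float = 0.05
    kme_min: float = 0.9
    kme_p_max: float = 0.01
    score_min: int = 900
    kcore_filter: int = 10
    min_module_size: int = 30
    alpha: float = 0.05
    candidate_powers: tuple[int, ...] = tuple(range(1, 13))
    r2_cut: float = 0.8
    cut_height: float | str = "auto"
    fluff: bool = True
    vwp: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io_formats.read_yaml(path)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        datasets = [DatasetPaths(**d) for d in raw.pop("datasets", [])]
        powers = raw.pop("candidate_powers", None)
        cfg = cls(datasets=datasets, **raw)
        if powers is not None:
            cfg.candidate_powers = tuple(int(p) for p in powers)
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        d["candidate_powers"] = list(self.candidate_powers)
        return d

    def validate(self) -> None:
        if not self.datasets:
            raise ValueError("config lists no datasets")
        if not (0 < self.target_fraction <= 1):
            raise ValueError("target_fraction must be in (0, 1]")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if not (0 <= self.score_min <= 1000):
            raise ValueError("score_min must be in [0, 1000]")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and dataset names."""

    def __init__(self, stage: str, dataset: str | None, cause: Exception):
        self.stage = stage
        self.dataset = dataset
        where = f"stage {stage!r}" + (f", dataset {dataset!r}" if dataset else "")
        super().__init__(f"{where}: {cause}")


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; write intermediates and return the report."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    universe = io_formats.read_annotation(config.annotation)
    release_members = universe.release_members
    flags = io_formats.read_gmt(config.flags_gmt)

    report: dict = {"config": config.echo(), "datasets": {}}
    per_dataset_selected: dict[str, set[str]] = {}

    for ds in config.datasets:
        dsid = ds.dataset_id
        logger.info("[%s] mutation filtering", dsid)
        try:
            maf = io_formats.read_maf(ds.maf, dsid)
            annotations = (
                io_formats.read_aliquot_annotations(ds.aliquot_annotations)
                if ds.aliquot_annotations
                else {}
            )
            filtered, filter_report = mutation_filtering.apply_filters(
                maf,
                annotations,
                release_members,
                dataset_id=dsid,
                t_min=config.t_depth_min,
                n_min=config.n_depth_min,
            )
            mutation_genes = mutation_filtering.mutation_gene_set(filtered, dsid)
            io_formats.write_maf(filtered, out / f"{dsid}.filtered.maf.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("mutation_filtering", dsid, exc) from exc

        logger.info("[%s] expression preparation", dsid)
        try:
            case_map = {}
            sample_types = {}
            if ds.aliquot_metadata:
                meta = io_formats.read_aliquot_metadata(ds.aliquot_metadata)
                case_map = dict(zip(meta["aliquot_barcode"], meta["case_id"]))
                sample_types = dict(zip(meta["aliquot_barcode"], meta["sample_type"]))
            matrix = io_formats.read_expression(ds.expression, dsid, case_map)
            matrix.values = matrix.values.loc[
                [g for g in matrix.values.index if g in release_members]
            ]
            prepared, prep_report = expression_prep.prepare(
                matrix,
                annotations,
                sample_types,
                seed=config.seed,
                cut_height=config.cut_height,
            )
            io_formats.write_expression(prepared, out / f"{dsid}.prepared.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("expression_prep", dsid, exc) from exc

        logger.info("[%s] co-expression network", dsid)
        try:
            assignment, fit = coexpression.analyze(
                prepared.values,
                candidate_powers=config.candidate_powers,
                r2_cut=config.r2_cut,
                min_module_size=config.min_module_size,
                cut_height=config.cut_height,
                dataset_id=dsid,
            )
            module_table = pd.DataFrame({"module": assignment.labels})
            if assignment.kme is not None:
                own = assignment.labels[assignment.labels > 0]
                module_table["kme"] = pd.Series(
                    {
                        g: assignment.kme.at[g, m]
                        for g, m in own.items()
                    }
                )
                module_table["kme_p"] = pd.Series(
                    {
                        g: assignment.kme_p.at[g, m]
                        for g, m in own.items()
                    }
                )
            module_table.index.name = "gene_id"
            module_table.to_csv(out / f"{dsid}.modules.tsv", sep="\t", float_format="%.6g")
            if fit is not None:
                fit.fit_table.to_csv(
                    out / f"{dsid}.soft_threshold.tsv", sep="\t", index=False, float_format="%.6g"
                )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("coexpression", dsid, exc) from exc

        logger.info("[%s] hub selection", dsid)
        try:
            hubs = hub_psg.select_hubs(
                assignment,
                target_fraction=config.target_fraction,
                kme_min=config.kme_min,
                p_max=config.kme_p_max,
            )
            selected = hub_psg.select_dataset_genes(hubs.hubs, mutation_genes)
            per_dataset_selected[dsid] = selected
        except StageError:
            raise
        except Exception as exc:
            raise StageError("hub_selection", dsid, exc) from exc

        report["datasets"][dsid] = {
            "filter": filter_report.to_dict(),
            "prep": prep_report.to_dict(),
            "n_mutation_genes": len(mutation_genes),
            "n_modules": int(len(assignment.module_sizes)),
            "module_coverage": float((assignment.labels > 0).mean()),
            "chosen_power": int(fit.chosen_power) if fit else None,
            "n_hubs": len(hubs.hubs),
            "n_selected": len(selected),
        }

    # ---- integration stages (after the per-dataset barrier) ----
    logger.info("integrating selected genes")
    try:
        psgs = hub_psg.integrate_psgs(per_dataset_selected)
        pc, nc = hub_psg.split_coding(psgs, universe)
        nc_table, nc_fractions = hub_psg.categorize_noncoding(psgs, universe)
        psg_rows = []
        for g in sorted(psgs.union):
            psg_rows.append(
                {
                    "gene_id": g,
                    "datasets": ",".join(psgs.datasets_of(g)),
                    "m": int(psgs.membership[g]),
                    "coding": g in pc,
                    "category": nc_table.at[g, "category"] if g in nc_table.index else "protein_coding",
                }
            )
        pd.DataFrame(psg_rows).to_csv(out / "psg.tsv", sep="\t", index=False)
        nc_fractions.to_csv(out / "ncpsg_category_fractions.tsv", sep="\t", float_format="%.6g")
    except Exception as exc:
        raise StageError("psg_integration", None, exc) from exc

    logger.info("PPI network and complexes")
    try:
        edges = io_formats.read_ppi_edges(config.ppi_edges)
        thresholded = ppi_network.threshold_edges(edges, config.score_min)
        network = ppi_network.build_single_depth(thresholded, pc)
        weights = ppi_network.mcode_weights(network.graph)
        complexes = ppi_network.mcode_complexes(
            network.graph,
            weights,
            vwp=config.vwp,
            fluff=config.fluff,
            kcore_filter=config.kcore_filter,
        )
        nodes_rows = []
        degrees = network.degrees()
        comp_of = {}
        for ci, comp in enumerate(network.components(), start=1):
            for g in comp:
                comp_of[g] = ci
        for g in sorted(network.graph.nodes):
            nodes_rows.append(
                {
                    "gene_id": g,
                    "role": "representor" if g in network.representors else "interactor",
                    "degree": degrees[g],
                    "component": comp_of[g],
                }
            )
        pd.DataFrame(nodes_rows).to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        cx_rows = []
        for i, cx in enumerate(complexes, start=1):
            for g in sorted(cx.core):
                cx_rows.append(
                    {"complex_id": i, "score": round(cx.score, 6), "seed": cx.seed,
                     "gene_id": g, "fluffed": False}
                )
            for g in sorted(cx.fluffed):
                cx_rows.append(
                    {"complex_id": i, "score": round(cx.score, 6), "seed": cx.seed,
                     "gene_id": g, "fluffed": True}
                )
        pd.DataFrame(
            cx_rows, columns=["complex_id", "score", "seed", "gene_id", "fluffed"]
        ).to_csv(out / "complexes.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("ppi_network", None, exc) from exc

    logger.info("enrichment analytics")
    try:
        battery = enrichment_stats.enrichment_battery(
            complexes, network, psgs.union, set(universe.gene_ids), flags, config.alpha
        )
        battery.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        occupation = enrichment_stats.occupation_ratios(complexes, psgs)
        occupation.to_csv(out / "occupation.tsv", sep="\t", float_format="%.6g")
    except Exception as exc:
        raise StageError("enrichment", None, exc) from exc

    report["integration"] = {
        "n_psgs": len(psgs.union),
        "n_pcpsg": len(pc),
        "n_ncpsg": len(nc),
        "overlap_histogram": {
            str(k): int(v) for k, v in psgs.overlap_histogram.items()
        },
        "network_nodes": network.n_nodes,
        "network_edges": network.n_edges,
        "n_representors": len(network.representors),
        "n_interactors": len(network.interactors),
        "n_complexes": len(complexes),
        "complex_sizes": [len(c) for c in complexes],
        "n_enrichment_tests": int(len(battery)),
    }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
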