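"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain tab-separated text: MAF-like mutation tables,
genes x samples FPKM matrices, GMT gene-set collections, PPI edge lists with
combined scores, gene annotation tables and per-aliquot metadata. Readers
validate strictly and raise :class:`FormatError` naming the problem; writers
are bit-stable given identical inputs so round trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotations import GeneUniverse, category_of_biotype

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its expected format."""


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

#: required MAF columns (the only ones the pipeline consumes; real-world MAF
#: files carry >100 columns which are ignored on read)
MAF_COLUMNS = (
    "Hugo_Symbol",
    "Gene",
    "Tumor_Sample_Barcode",
    "t_depth",
    "n_depth",
    "Variant_Classification",
)

#: canonical in-memory mutation-table columns
MUTATION_COLUMNS = (
    "gene_id",
    "dataset_id",
    "aliquot_barcode",
    "sample_type",
    "t_depth",
    "n_depth",
    "variant_classification",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples quantification values (FPKM) for one dataset.

    ``values`` is a DataFrame indexed by gene id with aliquot barcodes as
    columns. ``case_of_aliquot`` maps each barcode to its case id so that
    one profile per case can be selected downstream.
    """

    dataset_id: str
    values: pd.DataFrame = field(repr=False)
    case_of_aliquot: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise FormatError("duplicate gene ids in expression matrix")
        if not self.values.columns.is_unique:
            raise FormatError("duplicate aliquot barcodes in expression matrix")
        vals = self.values.to_numpy()
        finite = vals[np.isfinite(vals)]
        if (finite < 0).any():
            raise FormatError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if any(m == "" for m in members):
                raise FormatError(f"gene set {name!r} has an empty member id")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# MAF-like mutation tables
# ---------------------------------------------------------------------------

def read_maf(path, dataset_id: str) -> pd.DataFrame:
    """Read a MAF-like TSV into the canonical mutation-record frame.

    Comment lines starting with ``#`` are skipped. A missing or
    non-numeric depth is coerced to 0 with a logged warning. Sample type,
    if absent from the file, is filled with ``Primary Tumour`` (GDC MAF
    files carry the sample type in separate biospecimen metadata; a
    ``Sample_Type`` column is honoured when present).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"Gene", "Tumor_Sample_Barcode", "t_depth", "n_depth"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing mandatory MAF column(s): {', '.join(sorted(missing))}"
        )
    out = pd.DataFrame(
        {
            "gene_id": df["Gene"],
            "dataset_id": dataset_id,
            "aliquot_barcode": df["Tumor_Sample_Barcode"],
            "sample_type": df["Sample_Type"]
            if "Sample_Type" in df.columns
            else "Primary Tumour",
            "t_depth": _coerce_depth(df["t_depth"], "t_depth", path),
            "n_depth": _coerce_depth(df["n_depth"], "n_depth", path),
            "variant_classification": df["Variant_Classification"]
            if "Variant_Classification" in df.columns
            else "Missense_Mutation",
        }
    )
    if out["gene_id"].isna().any() or out["aliquot_barcode"].isna().any():
        raise FormatError(f"{path}: record lacking gene id or aliquot barcode")
    return out


def _coerce_depth(col: pd.Series, name: str, path) -> pd.Series:
    num = pd.to_numeric(col, errors="coerce")
    bad = num.isna()
    if bad.any():
        logger.warning(
            "%s: %d %s values missing/non-numeric, coerced to 0", path, bad.sum(), name
        )
        num = num.fillna(0)
    if (num < 0).any():
        raise FormatError(f"{path}: negative {name}")
    return num.astype(int)


def write_maf(table: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": table["gene_id"],
            "Gene": table["gene_id"],
            "Tumor_Sample_Barcode": table["aliquot_barcode"],
            "t_depth": table["t_depth"],
            "n_depth": table["n_depth"],
            "Variant_Classification": table["variant_classification"],
            "Sample_Type": table["sample_type"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices and aliquot metadata
# ---------------------------------------------------------------------------

def read_expression(path, dataset_id: str, case_of_aliquot: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id) into a matrix."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows with extra fields
        raise FormatError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        row = int(np.where(df.isna().any(axis=1))[0][0])
        raise FormatError(f"{path}: ragged or missing values at data line {row + 1}")
    if not df.index.is_unique:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene ids {dups[:5]}")
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression value")
    return ExpressionMatrix(dataset_id, df, dict(case_of_aliquot or {}))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_aliquot_metadata(path) -> pd.DataFrame:
    """Read per-aliquot metadata TSV: aliquot_barcode, case_id, sample_type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"aliquot_barcode", "case_id", "sample_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {sorted(missing)}")
    return df


def write_aliquot_metadata(meta: pd.DataFrame, path) -> None:
    meta.loc[:, ["aliquot_barcode", "case_id", "sample_type"]].to_csv(
        path, sep="\t", index=False
    )


def read_aliquot_annotations(path) -> dict[str, set[str]]:
    """Read aliquot annotation TSV (barcode TAB comma-joined categories)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("aliquot_barcode"):
            raise FormatError(f"{path}: expected 'aliquot_barcode' header")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 fields")
            cats = {c for c in parts[1].split(",") if c}
            out[parts[0]] = cats
    return out


def write_aliquot_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("aliquot_barcode\tcategories\n")
        for barcode in sorted(annotations):
            fh.write(f"{barcode}\t{','.join(sorted(annotations[barcode]))}\n")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description and >=1 member")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise FormatError(f"{path}:{ln}: duplicate gene set name {name!r}")
            sets[name] = frozenset(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_ppi_edges(path) -> pd.DataFrame:
    """Read a STRING-detail-style edge list: protein1, protein2, combined_score."""
    df = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing edge column(s): {sorted(missing)}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        raise FormatError(f"{path}: non-numeric combined_score")
    if ((scores < 0) | (scores > 1000)).any():
        raise FormatError(f"{path}: combined_score outside [0, 1000]")
    df["combined_score"] = scores.astype(int)
    return df


def write_ppi_edges(edges: pd.DataFrame, path) -> None:
    edges.loc[:, ["protein1", "protein2", "combined_score"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene annotation tables
# ---------------------------------------------------------------------------

def read_annotation(path) -> GeneUniverse:
    """Read the gene annotation TSV into a :class:`GeneUniverse`.

    Unknown biotypes are kept verbatim but categorise as ``problematic``
    (a warning is logged on first sight of each).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "biotype", "coding", "exon_length_bp", "flags", "release_member"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation column(s): {sorted(missing)}")
    bool_map = {"True": True, "False": False, "1": True, "0": False}
    table = pd.DataFrame(
        {
            "coding": df["coding"].map(bool_map).to_numpy(),
            "biotype": df["biotype"].to_numpy(),
            "exon_length_bp": pd.to_numeric(df["exon_length_bp"]).astype(int).to_numpy(),
            "flags": df["flags"]
            .fillna("")
            .map(lambda s: frozenset(f for f in s.split(",") if f))
            .to_numpy(),
            "release_member": df["release_member"].map(bool_map).to_numpy(),
        },
        index=pd.Index(df["gene_id"], name="gene_id"),
    )
    if table["coding"].isna().any() or table["release_member"].isna().any():
        raise FormatError(f"{path}: boolean column with unparseable value")
    for bt in table["biotype"].unique():
        category_of_biotype(bt)  # warn once per unknown biotype
    return GeneUniverse(table)


def write_annotation(universe: GeneUniverse, path) -> None:
    t = universe.table
    out = pd.DataFrame(
        {
            "gene_id": t.index,
            "biotype": t["biotype"].to_numpy(),
            "coding": t["coding"].to_numpy(),
            "exon_length_bp": t["exon_length_bp"].to_numpy(),
            "flags": [",".join(sorted(fs)) for fs in t["flags"]],
            "release_member": t["release_member"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return data


def write_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
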