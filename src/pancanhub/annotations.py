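"""Gene annotation model: biotypes, coding status and flag gene sets.

The pipeline works on Ensembl-style gene annotations. Every gene carries a
biotype; biotypes collapse onto five categories used when partitioning hub
genes into coding and non-coding classes: ``protein_coding``, ``pseudogene``,
``short_non_coding``, ``long_non_coding`` and ``problematic``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: category labels, in presentation order
CATEGORIES = (
    "protein_coding",
    "pseudogene",
    "short_non_coding",
    "long_non_coding",
    "problematic",
)

#: biotype -> category. 19 Ensembl-style biotypes; anything unknown maps to
#: "problematic" (see :func:`category_of_biotype`).
BIOTYPE_CATEGORY: dict[str, str] = {
    "protein_coding": "protein_coding",
    # pseudogenes
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "polymorphic_pseudogene": "pseudogene",
    "IG_V_pseudogene": "pseudogene",
    # short non-coding RNA
    "miRNA": "short_non_coding",
    "snoRNA": "short_non_coding",
    "snRNA": "short_non_coding",
    "rRNA": "short_non_coding",
    "misc_RNA": "short_non_coding",
    "scaRNA": "short_non_coding",
    # long non-coding RNA
    "lincRNA": "long_non_coding",
    "antisense": "long_non_coding",
    "sense_intronic": "long_non_coding",
    "processed_transcript": "long_non_coding",
    # problematic / to-be-experimentally-confirmed
    "TEC": "problematic",
}

#: recognised gene flags (programmed cell death types 1-3 and cancer genes)
FLAG_NAMES = ("PCD1", "PCD2", "PCD3", "known_cancer", "candidate_cancer")


def category_of_biotype(biotype: str) -> str:
    """Map a biotype onto its category; unknown biotypes are ``problematic``."""
    cat = BIOTYPE_CATEGORY.get(biotype)
    if cat is None:
        logger.warning("unknown biotype %r mapped to category 'problematic'", biotype)
        return "problematic"
    return cat


@dataclass
class GeneUniverse:
    """Annotation table for all genes considered by a run.

    ``table`` is indexed by unique gene id with columns:

    - ``coding`` (bool): protein-coding status,
    - ``biotype`` (str): Ensembl-style biotype,
    - ``exon_length_bp`` (int >= 1): summed exon length,
    - ``flags`` (frozenset[str]): membership in flag gene sets,
    - ``release_member`` (bool): gene is present in both annotation releases
      whose intersection defines the analysable gene space.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.table["exon_length_bp"] < 1).any():
            raise ValueError("exon_length_bp must be >= 1")

    # -- accessors -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    @property
    def coding_genes(self) -> set[str]:
        return set(self.table.index[self.table["coding"]])

    @property
    def noncoding_genes(self) -> set[str]:
        return set(self.table.index[~self.table["coding"]])

    @property
    def release_members(self) -> set[str]:
        return set(self.table.index[self.table["release_member"]])

    @property
    def exon_lengths(self) -> pd.Series:
        return self.table["exon_length_bp"]

    def categories(self) -> pd.Series:
        """Per-gene category derived from the biotype mapping."""
        return self.table["biotype"].map(category_of_biotype)

    def flag_set(self, name: str) -> set[str]:
        """Genes carrying flag ``name`` (e.g. ``'PCD1'``, ``'known_cancer'``)."""
        mask = self.table["flags"].map(lambda fs: name in fs)
        return set(self.table.index[mask])
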