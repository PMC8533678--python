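"""Functional-category summaries of differential expression.

Joins DE status with a gene → COG (Clusters of Orthologous Groups) annotation
table and tallies up/down-regulated genes per one-letter category, the way
stress-response studies present their category bar charts. The annotation is
an input table (deterministic join), never a live database lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .dge import DETable
from .errors import FormatError

__all__ = ["COG_CODES", "UNASSIGNED", "AnnotationTable", "CategoryCounts", "summarize_by_category"]

#: the 23 one-letter COG functional categories used for prokaryotic genomes
#: (A RNA processing, C energy, D cell cycle, E amino acids, F nucleotides,
#: G carbohydrates, H coenzymes, I lipids, J translation, K transcription,
#: L replication/repair, M cell wall/membrane, N motility, O post-translational,
#: P inorganic ions, Q secondary metabolites, R general prediction, S unknown,
#: T signal transduction, U trafficking/secretion, V defense, W extracellular
#: structures, X mobilome)
COG_CODES = tuple("ACDEFGHIJKLMNOPQRSTUVWX")

#: reserved bucket for DE genes without any annotation entry
UNASSIGNED = "unassigned"


@dataclass
class AnnotationTable:
    """gene id → string of COG one-letter codes (+ optional description)."""

    frame: pd.DataFrame  # columns: codes, description; index: gene

    def __post_init__(self) -> None:
        if "codes" not in self.frame.columns:
            raise FormatError("annotation table missing 'codes' column")
        if "description" not in self.frame.columns:
            self.frame = self.frame.assign(description="")
        self.frame = self.frame.fillna({"codes": "", "description": ""})
        offenders = {}
        for gene, codes in self.frame["codes"].items():
            bad = sorted(set(codes) - set(COG_CODES))
            if bad:
                offenders[gene] = bad
        if offenders:
            raise FormatError(
                f"annotation codes outside the COG vocabulary {''.join(COG_CODES)}: {offenders}"
            )

    def codes_for(self, gene: str) -> str:
        if gene in self.frame.index:
            return str(self.frame.loc[gene, "codes"])
        return ""

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        frame = pd.read_csv(path, sep="\t", index_col="gene", keep_default_na=False)
        return cls(frame)


@dataclass
class CategoryCounts:
    """Up/down DE tallies per COG category (legend letter order) + unassigned."""

    frame: pd.DataFrame  # index: category code (+ UNASSIGNED); columns n_up, n_down

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("category").to_csv(path, sep="\t")

    def __getitem__(self, code: str) -> tuple[int, int]:
        row = self.frame.loc[code]
        return int(row["n_up"]), int(row["n_down"])


def summarize_by_category(
    de: DETable, annot: AnnotationTable, multi_count: bool = True
) -> CategoryCounts:
    """Count DE-up and DE-down genes per COG category.

    A gene carrying several category codes contributes one count to *each* of
    them (``multi_count=True``, the default); with ``multi_count=False`` only
    its first listed code is counted. DE genes with no annotation row or an
    empty code string fall into the reserved ``unassigned`` bucket so the
    tallies remain auditable.
    """
    index = list(COG_CODES) + [UNASSIGNED]
    counts = pd.DataFrame(0, index=index, columns=["n_up", "n_down"])
    for direction, col in (("up", "n_up"), ("down", "n_down")):
        for gene in sorted(de.genes_with_status(direction).index):
            codes = annot.codes_for(gene)
            if not codes:
                counts.loc[UNASSIGNED, col] += 1
                continue
            # a (gene, code) pair counts at most once per direction
            uniq = list(dict.fromkeys(codes))
            if not multi_count:
                uniq = uniq[:1]
            for code in uniq:
                counts.loc[code, col] += 1
    return CategoryCounts(counts)
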