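"""Tissue-resolved expression weighting of gene lists.

Given a gene x tissue transcript-abundance matrix in transcripts per million
(TPM; each full-transcriptome tissue column closes to 10^6), a gene list's
expression is distributed over tissues: the summed TPM per tissue, the
percentage each tissue contributes to the list's total expression (columns of
percentages add to 100), and the fraction of one tissue's whole transcriptome
that the list represents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError

TPM_CLOSURE = 1_000_000.0


@dataclass
class TissueMatrix:
    """Gene x tissue non-negative TPM matrix (genes as index, tissues as columns)."""

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise InputError("TPM values must be non-negative")
        sums = self.tpm.sum(axis=0)
        if (sums > TPM_CLOSURE + 0.5).any():
            bad = sums[sums > TPM_CLOSURE + 0.5].index.tolist()
            raise InputError(f"tissue columns exceed the 1e6 TPM closure: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass
class TissueWeightTable:
    """Per-tissue summed TPM and column percentages for one gene list."""

    list_id: str
    sum_tpm: dict[str, float]
    percent: dict[str, float]
    n_genes: int
    n_missing: int  # list genes absent from the matrix (contribute 0)


def tissue_weights(gene_list: Iterable[str], matrix: TissueMatrix, list_id: str = "list") -> TissueWeightTable:
    """Distribute a gene list's expression over tissues.

    ``percent[t] = 100 * sum_tpm[t] / total`` so percentages add to 100 across
    tissues. Genes absent from the matrix contribute nothing and are counted in
    ``n_missing``; an empty intersection is an error (no expression data).
    """
    gene_list = set(gene_list)
    present = gene_list & set(matrix.tpm.index)
    if not present:
        raise InputError(f"no genes of list {list_id!r} occur in the expression matrix")
    sums = matrix.tpm.loc[sorted(present)].sum(axis=0)
    total = float(sums.sum())
    if total == 0:
        raise InputError(f"list {list_id!r} has zero total expression in the matrix")
    return TissueWeightTable(
        list_id=list_id,
        sum_tpm={t: float(v) for t, v in sums.items()},
        percent={t: 100.0 * float(v) / total for t, v in sums.items()},
        n_genes=len(gene_list),
        n_missing=len(gene_list) - len(present),
    )


def tissue_fraction(gene_list: Iterable[str], matrix: TissueMatrix, tissue: str) -> float:
    """Fraction of a tissue's whole transcriptome represented by the gene list.

    Divides by the 10^6 TPM closure of the full tissue transcriptome (not the
    matrix column sum, which may cover only a gene subset).
    """
    if tissue not in matrix.tpm.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    present = set(gene_list) & set(matrix.tpm.index)
    if not present:
        return 0.0
    return float(matrix.tpm.loc[sorted(present), tissue].sum()) / TPM_CLOSURE


# ---------------------------------------------------------------------------
# I/O


def read_tissue_matrix(path: str | Path) -> TissueMatrix:
    """Read a TSV matrix: first column gene ids, header row of tissue names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TissueMatrix(df.astype(float))


def write_tissue_matrix(matrix: TissueMatrix, path: str | Path) -> None:
    out = matrix.tpm.copy()
    out.index.name = "gene_id"
    out.round(2).to_csv(path, sep="\t")


def write_weight_tables(tables: Sequence[TissueWeightTable], path: str | Path) -> None:
    """Write one or more lists' tissue weights side by side (tpm and % per list)."""
    if not tables:
        raise InputError("no tables to write")
    tissues = list(tables[0].sum_tpm)
    with open(path, "w") as handle:
        header = ["tissue"]
        for t in tables:
            header += [f"{t.list_id}_tpm", f"{t.list_id}_pct"]
        handle.write("\t".join(header) + "\n")
        for tissue in tissues:
            row = [tissue]
            for t in tables:
                row += [f"{t.sum_tpm[tissue]:.2f}", f"{t.percent[tissue]:.2f}"]
            handle.write("\t".join(row) + "\n")
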