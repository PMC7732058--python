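"""Gene-list and peak-overlap comparisons.

Covers the comparative statistics downstream of target calling: strand-aware
3 kb promoter windows, interval intersection of those windows with ChIP-seq
peaks (narrowPeak), overlap percentages, and chi-square tests of list overlap
against a gene universe. All coordinates are 0-based half-open; overlap means
at least one shared base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, ParseError
from .genomap import GeneModel

Interval = tuple[str, int, int]  # (chrom, start, end), half-open

DEFAULT_PROMOTER_WIDTH = 3000


@dataclass
class PeakInterval:
    """One narrowPeak record (10 columns)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    peak_offset: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(f"peak {self.name}: start must be < end")
        if self.strand not in "+-.":
            raise ParseError(f"peak {self.name}: strand must be +, - or .")


@dataclass
class OverlapResult:
    """Overlap of a query gene list with a reference set over a universe."""

    n_list: int
    n_overlap: int
    percent: float
    chi2: float
    p: float
    table: np.ndarray  # 2x2: (in-list / not-in-list) x (has-peak / no-peak)


def promoter_window(
    gene: GeneModel,
    width: int = DEFAULT_PROMOTER_WIDTH,
    chrom_length: Optional[int] = None,
) -> Interval:
    """The ``width``-bp window immediately upstream of the gene start, strand-aware.

    Clipped at chromosome edges; may be empty (start == end) for a + strand gene
    at position 0 or a - strand gene ending at the chromosome end.
    """
    if gene.strand == "+":
        return (gene.chrom, max(0, gene.start - width), gene.start)
    end = gene.end + width
    if chrom_length is not None:
        end = min(chrom_length, end)
    return (gene.chrom, gene.end, end)


def intersect(
    windows: Mapping[str, Interval],
    peaks: Sequence[PeakInterval],
) -> set[str]:
    """Gene ids whose window shares >= 1 bp with any peak (strand-blind)."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in peaks}:
        chrom_peaks = [p for p in peaks if p.chrom == chrom]
        starts[chrom] = np.array([p.start for p in chrom_peaks])
        ends[chrom] = np.array([p.end for p in chrom_peaks])
    hits = set()
    for gene_id, (chrom, ws, we) in windows.items():
        if ws >= we or chrom not in starts:
            continue
        if np.any((starts[chrom] < we) & (ends[chrom] > ws)):
            hits.add(gene_id)
    return hits


def _chi_square_overlap(
    list_genes: set[str],
    ref_genes: set[str],
    universe: set[str],
    continuity: bool = True,
) -> OverlapResult:
    if not list_genes:
        raise InputError("query gene list is empty")
    if not universe:
        raise InputError("gene universe is empty")
    if not (list_genes <= universe and ref_genes <= universe):
        raise InputError("both gene sets must be subsets of the universe")
    n_overlap = len(list_genes & ref_genes)
    table = np.array(
        [
            [n_overlap, len(list_genes) - n_overlap],
            [
                len(ref_genes) - n_overlap,
                len(universe) - len(list_genes) - len(ref_genes) + n_overlap,
            ],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return OverlapResult(
        n_list=len(list_genes),
        n_overlap=n_overlap,
        percent=100.0 * n_overlap / len(list_genes),
        chi2=float(chi2),
        p=float(p),
        table=table,
    )


def overlap_stats(
    list_genes: set[str],
    peak_genes: set[str],
    universe: set[str],
    continuity: bool = True,
) -> OverlapResult:
    """Percentage of the query list with peak support, plus a 2x2 chi-square test.

    The 2x2 table classifies the universe by (in-list) x (has-peak); Yates
    continuity correction is applied by default.
    """
    return _chi_square_overlap(list_genes, peak_genes, universe, continuity)


def compare_target_lists(
    list_a: set[str],
    list_b: set[str],
    universe: set[str],
    continuity: bool = True,
) -> OverlapResult:
    """Overlap of two target lists; the percentage is relative to ``list_a``."""
    return _chi_square_overlap(list_a, list_b, universe, continuity)


# ---------------------------------------------------------------------------
# I/O


def read_narrowpeak(path: str | Path) -> list[PeakInterval]:
    peaks = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: narrowPeak needs >= 3 columns")
            fields += ["."] * (10 - len(fields))
            peaks.append(
                PeakInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=int(fields[4]) if fields[4] != "." else 0,
                    strand=fields[5],
                    signal_value=float(fields[6]) if fields[6] != "." else 0.0,
                    p_value=float(fields[7]) if fields[7] != "." else -1.0,
                    q_value=float(fields[8]) if fields[8] != "." else -1.0,
                    peak_offset=int(fields[9]) if fields[9] != "." else -1,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[PeakInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for p in peaks:
            handle.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t{p.strand}\t"
                f"{p.signal_value:g}\t{p.p_value:g}\t{p.q_value:g}\t{p.peak_offset}\n"
            )


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def write_overlap_result(result: OverlapResult, path: str | Path, label: str = "overlap") -> None:
    with open(path, "w") as handle:
        handle.write("metric\tvalue\n")
        handle.write(f"label\t{label}\n")
        handle.write(f"n_list\t{result.n_list}\n")
        handle.write(f"n_overlap\t{result.n_overlap}\n")
        handle.write(f"percent\t{result.percent:.4f}\n")
        handle.write(f"chi2\t{result.chi2:.6g}\n")
        handle.write(f"p\t{result.p:.6g}\n")
        t = result.table
        handle.write(f"table\t{t[0, 0]},{t[0, 1]},{t[1, 0]},{t[1, 1]}\n")
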