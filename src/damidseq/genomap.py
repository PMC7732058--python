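"""GATC-anchored read mapping, per-site and per-gene counting, normalization, QC.

DamID signal lives at GATC motifs, so mapping is anchored there: a trimmed read
begins with a genomic GATC and is placed by exact comparison of its first
``seed_len`` bases against the reference at every GATC site, on both strands.
GATC is palindromic and Dam methylates both adenines, so a reverse-strand read
whose GATC coincides with a genomic site is credited to the same (strandless)
site coordinate. Counts are summed per gene body and scaled to reads-per-million
uniquely assigned reads per sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO

from .errors import AnnotationError, EmptySampleError, InputError, ParseError, StatisticsError
from .readproc import ReadRecord

Site = tuple[str, int]  # (chromosome, 0-based start of the GATC motif)

_GATC_RE = re.compile("(?=GATC)")
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Reference containers


@dataclass
class GatcMap:
    """Sorted 0-based start coordinates of every GATC motif, per chromosome."""

    sites: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, arr in self.sites.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.size and not np.all(np.diff(arr) > 0):
                raise ValueError(f"GATC sites on {chrom} are not strictly increasing")
            self.sites[chrom] = arr

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GatcMap":
        """Scan chromosome sequences for every GATC occurrence."""
        sites = {
            chrom: np.array([m.start() for m in _GATC_RE.finditer(seq)], dtype=np.int64)
            for chrom, seq in sequences.items()
        }
        lengths = {chrom: len(seq) for chrom, seq in sequences.items()}
        return cls(sites, lengths)

    def n_sites(self) -> int:
        return int(sum(arr.size for arr in self.sites.values()))

    def all_sites(self) -> list[Site]:
        return [(chrom, int(s)) for chrom, arr in sorted(self.sites.items()) for s in arr]


@dataclass(frozen=True)
class GeneModel:
    """A named, stranded gene interval in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"gene {self.gene_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")


class GeneSet:
    """Non-overlapping genes usable as count bins; sorted by (chrom, start)."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = sorted(genes, key=lambda g: (g.chrom, g.start))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
        self._check_disjoint()
        self._by_id = {g.gene_id: g for g in self.genes}

    def _check_disjoint(self) -> None:
        for a, b in zip(self.genes, self.genes[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise AnnotationError(
                    f"genes {a.gene_id} and {b.gene_id} overlap on {a.chrom}; "
                    "bins must be disjoint"
                )

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


# ---------------------------------------------------------------------------
# Mapping


class Assignment(Enum):
    UNIQUE = "unique"
    MULTI = "multi"
    UNMAPPED = "unmapped"


DEFAULT_SEED_LEN = 32


class GatcIndex:
    """Exact-match seed index over GATC sites on both strands.

    For each site *s* the forward key is ``ref[s : s+seed_len]`` and the reverse
    key is ``revcomp(ref[s+4-seed_len : s+4])`` (a reverse-strand read whose GATC
    coincides with the genomic motif). Keys map to the set of site coordinates
    carrying them; a read maps uniquely iff its seed hits exactly one site.
    """

    def __init__(self, seed_len: int, index: dict[str, set[Site]]):
        self.seed_len = seed_len
        self._index = index

    @classmethod
    def build(
        cls,
        genome: Mapping[str, str],
        gatc_map: GatcMap,
        seed_len: int = DEFAULT_SEED_LEN,
    ) -> "GatcIndex":
        index: dict[str, set[Site]] = {}
        for chrom, sites in gatc_map.sites.items():
            seq = genome[chrom]
            for s in sites:
                s = int(s)
                if s + seed_len <= len(seq):
                    index.setdefault(seq[s : s + seed_len], set()).add((chrom, s))
                if s + 4 - seed_len >= 0:
                    key = revcomp(seq[s + 4 - seed_len : s + 4])
                    index.setdefault(key, set()).add((chrom, s))
        return cls(seed_len, index)

    def map_sequence(self, sequence: str) -> tuple[Assignment, Optional[Site]]:
        if len(sequence) < self.seed_len:
            return Assignment.UNMAPPED, None
        hits = self._index.get(sequence[: self.seed_len])
        if not hits:
            return Assignment.UNMAPPED, None
        if len(hits) == 1:
            return Assignment.UNIQUE, next(iter(hits))
        return Assignment.MULTI, None


def map_read(trimmed: ReadRecord, index: GatcIndex) -> tuple[Assignment, Optional[Site]]:
    """Assign one trimmed read (must start with GATC) to a GATC site."""
    return index.map_sequence(trimmed.sequence)


def count_sites(
    assignments: Iterable[tuple[Assignment, Optional[Site]]],
) -> tuple[dict[Site, int], int]:
    """Tally uniquely assigned reads per site; multi/unmapped are excluded.

    Returns ``(site_counts, total_assigned)``.
    """
    counts: dict[Site, int] = {}
    total = 0
    for status, site in assignments:
        if status is Assignment.UNIQUE:
            counts[site] = counts.get(site, 0) + 1
            total += 1
    return counts, total


def bin_to_genes(site_counts: Mapping[Site, int], genes: GeneSet) -> dict[str, int]:
    """Sum site counts into gene bodies (half-open containment: start <= s < end).

    Sites outside every gene are dropped. Every gene appears in the result,
    zero-filled if it received no reads.
    """
    per_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g)
    starts = {c: np.array([g.start for g in gs]) for c, gs in per_chrom.items()}

    out = {g.gene_id: 0 for g in genes}
    for (chrom, pos), n in site_counts.items():
        gs = per_chrom.get(chrom)
        if not gs:
            continue
        i = int(np.searchsorted(starts[chrom], pos, side="right")) - 1
        if i >= 0 and gs[i].start <= pos < gs[i].end:
            out[gs[i].gene_id] += n
    return out


def normalize(gene_counts_raw: Mapping[str, int], total_assigned: int) -> dict[str, float]:
    """Scale raw per-gene counts to reads per million uniquely assigned reads."""
    if total_assigned <= 0:
        raise EmptySampleError("cannot normalize a sample with zero assigned reads")
    scale = 1e6 / total_assigned
    return {g: n * scale for g, n in gene_counts_raw.items()}


@dataclass
class SampleCounts:
    """All per-site and per-gene counts for one sequencing sample."""

    sample_id: str
    condition: str  # "fusion" or "control"
    replicate: int
    site_counts: dict[Site, int]
    gene_counts_raw: dict[str, int]
    gene_counts_norm: dict[str, float]
    total_assigned: int


def quantify_sample(
    trimmed_reads: Iterable[ReadRecord],
    index: GatcIndex,
    genes: GeneSet,
    sample_id: str,
    condition: str = "fusion",
    replicate: int = 1,
) -> SampleCounts:
    """Map, count, bin and normalize one sample's trimmed reads."""
    assignments = (map_read(r, index) for r in trimmed_reads)
    site_counts, total = count_sites(assignments)
    raw = bin_to_genes(site_counts, genes)
    norm = normalize(raw, total)
    return SampleCounts(sample_id, condition, replicate, site_counts, raw, norm, total)


# ---------------------------------------------------------------------------
# Replicate QC


def spearman_qc(
    samples: Sequence[SampleCounts],
    min_reads: int = 2,
) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-site counts across samples.

    For each pair, only GATC sites where BOTH samples have at least ``min_reads``
    reads enter the correlation (low-count sites carry rank noise, not signal).
    Pairs with fewer than 3 surviving sites get NaN. Ties receive average ranks.
    """
    if len(samples) < 2:
        raise StatisticsError("need at least two samples for correlation QC")
    ids = [s.sample_id for s in samples]
    universe = sorted({site for s in samples for site in s.site_counts})
    vectors = np.array(
        [[s.site_counts.get(site, 0) for site in universe] for s in samples], dtype=float
    )
    n = len(samples)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = (vectors[i] >= min_reads) & (vectors[j] >= min_reads)
            if mask.sum() < 3:
                rho = np.nan
            else:
                rho = stats.spearmanr(vectors[i][mask], vectors[j][mask]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for chrom in sequences:
            handle.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_genes_bed6(path: str | Path) -> GeneSet:
    """Read genes from BED6 (column 4 = gene id); BED is already 0-based half-open."""
    genes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(GeneModel(name, chrom, int(start), int(end), strand))
    return GeneSet(genes)


def write_genes_bed6(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for g in genes:
            handle.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_gff3(path: str | Path) -> GeneSet:
    """Read gene features from GFF3 (type == 'gene', ID attribute as gene id).

    GFF3 is 1-based closed; converted to 0-based half-open on read.
    """
    genes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 requires 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            match = re.search(r"(?:^|;)ID=([^;]+)", attrs)
            if not match:
                raise ParseError(f"{path}:{lineno}: gene feature lacks ID attribute")
            gene_id = match.group(1).removeprefix("gene:")
            genes.append(GeneModel(gene_id, chrom, int(start) - 1, int(end), strand))
    return GeneSet(genes)


def write_sample_counts(sample: SampleCounts, genes: GeneSet, path: str | Path) -> None:
    """Write one sample's gene counts: gene_id, chrom, start, end, raw, norm."""
    with open(path, "w") as handle:
        handle.write("gene_id\tchrom\tstart\tend\traw\tnorm\n")
        for g in genes:
            handle.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t"
                f"{sample.gene_counts_raw[g.gene_id]}\t"
                f"{sample.gene_counts_norm[g.gene_id]:.6f}\n"
            )


def read_gene_counts(path: str | Path) -> dict[str, float]:
    """Read the normalized column of a per-sample gene-count TSV."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "norm" not in df.columns:
        raise ParseError(f"{path}: expected columns gene_id and norm")
    return dict(zip(df["gene_id"], df["norm"].astype(float)))


def write_site_counts(sample: SampleCounts, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tsite\tcount\n")
        for (chrom, pos), n in sorted(sample.site_counts.items()):
            handle.write(f"{chrom}\t{pos}\t{n}\n")


def read_site_counts(path: str | Path) -> dict[Site, int]:
    df = pd.read_csv(path, sep="\t")
    return {(str(c), int(s)): int(n) for c, s, n in zip(df["chrom"], df["site"], df["count"])}


def validate_gatc_map(gatc_map: GatcMap, genome: Mapping[str, str]) -> None:
    """Check every recorded site actually carries the motif in the reference."""
    for chrom, sites in gatc_map.sites.items():
        seq = genome[chrom]
        for s in sites:
            if seq[int(s) : int(s) + 4] != "GATC":
                raise InputError(f"site {chrom}:{int(s)} does not carry GATC in the reference")
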