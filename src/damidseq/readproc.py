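"""Adapter-anchored filtering and trimming of raw DamID reads.

DamID libraries are amplified from a constant adapter that ends right before the
genomic GATC of a methylated fragment, so a well-formed read is

    [0-4 random bases] + adapter + GATC + genomic sequence ...

Reads that do not contain the adapter followed immediately by the GATC motif are
discarded; for the rest the adapter (and anything before it) is trimmed so the
retained sequence starts at the genomic GATC.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError

#: Constant 3' portion of the DamID amplification primer; the genomic fragment
#: starts (with GATC) immediately after it.
DEFAULT_ADAPTER = "GGTCGCGGCCGAGGA"

#: Maximum adapter start offset searched; accommodates the 0-4 random bases
#: the amplification primer prepends, plus slack.
DEFAULT_MAX_OFFSET = 8

#: Minimum retained (post-trim) length for a read to be usable downstream.
DEFAULT_MIN_TAIL = 20

_MOTIF = "GATC"


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases and per-base quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ParseError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class TrimResult:
    """Outcome of :func:`filter_and_trim` over one read stream.

    The three category counters partition the input exactly:
    ``n_input == n_kept + n_no_adapter + n_no_gatc_after_adapter``.
    Reads whose post-trim tail is shorter than ``min_tail`` are counted under
    ``n_no_gatc_after_adapter`` (and additionally under the informational
    ``n_short_tail`` sub-counter) so the three-way partition holds.
    """

    kept: list[ReadRecord] = field(default_factory=list)
    n_input: int = 0
    n_kept: int = 0
    n_no_adapter: int = 0
    n_no_gatc_after_adapter: int = 0
    n_short_tail: int = 0  # subset of n_no_gatc_after_adapter

    def check(self) -> None:
        assert self.n_input == self.n_kept + self.n_no_adapter + self.n_no_gatc_after_adapter


def locate_adapter(sequence: str, adapter: str, max_offset: int = DEFAULT_MAX_OFFSET) -> Optional[int]:
    """Return the smallest start ``<= max_offset`` of an exact adapter match, else None.

    An empty adapter matches at offset 0 (trim-disabled plumbing mode).
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    pos = sequence.find(adapter, 0, max_offset + len(adapter))
    return pos if pos != -1 else None


def filter_and_trim(
    reads: Iterable[ReadRecord],
    adapter: str = DEFAULT_ADAPTER,
    max_offset: int = DEFAULT_MAX_OFFSET,
    min_tail: int = DEFAULT_MIN_TAIL,
) -> TrimResult:
    """Classify reads by adapter/GATC structure and trim the kept ones.

    A read is kept iff the adapter occurs exactly at some offset ``<= max_offset``
    and the bases immediately following it are ``GATC`` with a tail of at least
    ``min_tail`` bases. The retained sequence (and quality) starts at that GATC.
    """
    result = TrimResult()
    for read in reads:
        result.n_input += 1
        offset = locate_adapter(read.sequence, adapter, max_offset)
        if offset is None:
            result.n_no_adapter += 1
            continue
        cut = offset + len(adapter)
        tail = read.sequence[cut:]
        if not tail.startswith(_MOTIF):
            result.n_no_gatc_after_adapter += 1
            continue
        if len(tail) < min_tail:
            # Structurally valid but unusably short; folded into the GATC-failure
            # counter to preserve the three-way partition reported downstream.
            result.n_no_gatc_after_adapter += 1
            result.n_short_tail += 1
            continue
        result.n_kept += 1
        result.kept.append(ReadRecord(read.id, tail, read.quality[cut:]))
    result.check()
    return result


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (optionally gzipped) FASTQ file."""
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield ReadRecord(title.split()[0], seq.upper(), qual)
        except ValueError as exc:  # Biopython signals malformed records this way
            raise ParseError(f"malformed FASTQ in {path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


def write_trim_report(result: TrimResult, path: str | Path) -> None:
    """Write the TrimResult category counts as a two-column TSV."""
    with open(path, "w") as handle:
        handle.write("metric\tcount\n")
        for key in ("n_input", "n_kept", "n_no_adapter", "n_no_gatc_after_adapter", "n_short_tail"):
            handle.write(f"{key}\t{getattr(result, key)}\n")
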