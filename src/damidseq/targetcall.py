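"""Candidate target calling from replicated fusion vs control gene counts.

A gene is called a candidate transcription-factor target when two criteria hold
jointly over the normalized (reads-per-million) gene counts:

1. **Replicate consistency** — every fusion (dam::TF) replicate's count is
   strictly higher than every control (gfp::dam) replicate's count, and
2. **Fold change** — the ratio of mean fusion over mean control counts is
   strictly greater than the fold-change threshold (default 1.7).

The reported log2 fold change adds a small pseudocount to both means so the
value stays finite for zero-control genes; the pseudocount never influences the
call itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, StatisticsError
from .genomap import GeneSet


@dataclass
class CallParams:
    fc_threshold: float = 1.7
    pseudocount: float = 0.5  # normalized units; reported log2FC only

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise InputError("fc_threshold must be > 1")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be >= 0")


@dataclass
class TargetCall:
    """Per-gene calling record: replicate counts, means, fold change and flags."""

    gene_id: str
    fusion_norm: tuple[float, ...]
    control_norm: tuple[float, ...]
    fusion_mean: float
    control_mean: float
    fold_change: float  # may be +inf when controls are all zero
    log2fc: float
    passes_consistency: bool
    passes_fc: bool
    is_target: bool


def call_targets(
    fusion: Sequence[Mapping[str, float]],
    control: Sequence[Mapping[str, float]],
    params: CallParams | None = None,
    genes: Optional[GeneSet] = None,
) -> list[TargetCall]:
    """Apply the two-part calling rule to every gene.

    ``fusion`` and ``control`` are per-replicate normalized gene-count maps over
    an identical gene universe (at least two replicates each; the study used
    three). When a ``genes`` annotation is supplied the output is sorted by
    genomic position (chromosome, then start), otherwise by gene id.
    """
    params = params or CallParams()
    if len(fusion) < 2 or len(control) < 2:
        raise InputError("need at least two replicates per condition")
    universe = set(fusion[0])
    for rep in list(fusion) + list(control):
        if set(rep) != universe:
            raise InputError("all replicates must share an identical gene universe")

    calls = []
    for gene_id in universe:
        f = tuple(float(rep[gene_id]) for rep in fusion)
        c = tuple(float(rep[gene_id]) for rep in control)
        f_mean = sum(f) / len(f)
        c_mean = sum(c) / len(c)
        if c_mean > 0:
            fc = f_mean / c_mean
        else:
            fc = math.inf if f_mean > 0 else 0.0
        log2fc = math.log2((f_mean + params.pseudocount) / (c_mean + params.pseudocount))
        consistency = min(f) > max(c)
        passes_fc = fc > params.fc_threshold
        calls.append(
            TargetCall(
                gene_id=gene_id,
                fusion_norm=f,
                control_norm=c,
                fusion_mean=f_mean,
                control_mean=c_mean,
                fold_change=fc,
                log2fc=log2fc,
                passes_consistency=consistency,
                passes_fc=passes_fc,
                is_target=consistency and passes_fc,
            )
        )
    if genes is not None:
        missing = universe - set(genes.ids())
        if missing:
            raise InputError(f"genes absent from annotation: {sorted(missing)[:5]} ...")
        calls.sort(key=lambda t: (genes[t.gene_id].chrom, genes[t.gene_id].start))
    else:
        calls.sort(key=lambda t: t.gene_id)
    return calls


def called_set(calls: Iterable[TargetCall]) -> set[str]:
    return {t.gene_id for t in calls if t.is_target}


def compare_signal(
    calls: Sequence[TargetCall],
    subset_a: set[str],
    subset_b: set[str],
) -> tuple[float, float, float]:
    """Compare mean log2FC between two disjoint gene subsets.

    Returns ``(mean_a, mean_b, p)`` with p from Welch's unequal-variance
    two-sample t-test. When both subsets are constant, p is 1.0 for equal
    means and 0.0 otherwise (the degenerate zero-variance limit).
    """
    if subset_a & subset_b:
        raise InputError("subsets must be disjoint")
    by_id = {t.gene_id: t for t in calls}
    missing = (subset_a | subset_b) - set(by_id)
    if missing:
        raise InputError(f"gene ids absent from calls: {sorted(missing)[:5]} ...")
    a = np.array([by_id[g].log2fc for g in sorted(subset_a)])
    b = np.array([by_id[g].log2fc for g in sorted(subset_b)])
    if len(a) < 2 or len(b) < 2:
        raise StatisticsError("each subset needs at least two genes")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return float(a.mean()), float(b.mean()), p


def write_target_table(
    calls: Sequence[TargetCall],
    path: str | Path,
    genes: Optional[GeneSet] = None,
    only_targets: bool = False,
) -> None:
    """Write the per-gene call table as TSV (gene_id, position, log2FC, flags)."""
    n_rep = len(calls[0].fusion_norm) if calls else 0
    cols = ["gene_id", "chrom", "start", "stop", "log2FC", "fold_change"]
    cols += [f"fusion_{i + 1}" for i in range(n_rep)]
    cols += [f"control_{i + 1}" for i in range(len(calls[0].control_norm) if calls else 0)]
    cols += ["passes_consistency", "passes_fc", "is_target"]
    with open(path, "w") as handle:
        handle.write("\t".join(cols) + "\n")
        for t in calls:
            if only_targets and not t.is_target:
                continue
            if genes is not None and t.gene_id in genes:
                g = genes[t.gene_id]
                pos = [g.chrom, str(g.start), str(g.end)]
            else:
                pos = [".", ".", "."]
            row = (
                [t.gene_id, *pos, f"{t.log2fc:.6f}", f"{t.fold_change:.6f}"]
                + [f"{v:.6f}" for v in t.fusion_norm]
                + [f"{v:.6f}" for v in t.control_norm]
                + [str(int(t.passes_consistency)), str(int(t.passes_fc)), str(int(t.is_target))]
            )
            handle.write("\t".join(row) + "\n")
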