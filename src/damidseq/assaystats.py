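"""Behavioral assay statistics: the chemotaxis index.

In a plate chemotaxis assay, animals are released at an origin between an
attractant spot (butanone) and a solvent-control spot (ethanol). The chemotaxis
index is

    CI = (n_butanone - n_EtOH) / (n_total - n_origin)

Animals still at the origin are excluded from the denominator; animals elsewhere
on the plate dilute it exactly as the formula dictates. CI ranges from -1
(full repulsion) to +1 (full attraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import InputError


@dataclass
class ChemotaxisCounts:
    n_butanone: int
    n_etoh: int
    n_origin: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_butanone, self.n_etoh, self.n_origin, self.n_total) < 0:
            raise InputError("all counts must be non-negative")
        if self.n_butanone + self.n_etoh + self.n_origin > self.n_total:
            raise InputError("spot and origin counts exceed the total")
        if self.n_total <= self.n_origin:
            raise InputError("chemotaxis index undefined: every animal is at the origin")


def chemotaxis_index(c: ChemotaxisCounts) -> float:
    """CI = (n_butanone - n_etoh) / (n_total - n_origin); always in [-1, 1]."""
    return (c.n_butanone - c.n_etoh) / (c.n_total - c.n_origin)


def batch_chemotaxis(assays: Sequence[ChemotaxisCounts]) -> pd.DataFrame:
    """Per-assay CI plus a summary row (mean and sd across assays)."""
    if not assays:
        raise InputError("no assays provided")
    ci = [chemotaxis_index(c) for c in assays]
    df = pd.DataFrame(
        {
            "n_butanone": [c.n_butanone for c in assays],
            "n_etoh": [c.n_etoh for c in assays],
            "n_origin": [c.n_origin for c in assays],
            "n_total": [c.n_total for c in assays],
            "ci": ci,
        }
    )
    return df


def read_assay_tsv(path: str | Path) -> list[ChemotaxisCounts]:
    """Read one assay per row: columns n_butanone, n_etoh, n_origin, n_total."""
    df = pd.read_csv(path, sep="\t")
    return [
        ChemotaxisCounts(int(r.n_butanone), int(r.n_etoh), int(r.n_origin), int(r.n_total))
        for r in df.itertuples()
    ]
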