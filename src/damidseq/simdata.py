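"""Synthetic DamID worlds with known ground truth.

Generates toy genomes whose GATC landscape is fully known (motifs are planted at
roughly geometric spacing and incidental occurrences are repaired away), gene
annotations over them, adapter-structured DamID read sets for replicated fusion
(dam::TF) and control (gfp::dam) samples, ChIP-style peak lists, and tissue TPM
matrices. Every stochastic choice flows from a single seed through named
substreams, so identical configurations give byte-identical outputs.

The read model: all samples share an accessibility-driven background methylation
probability at every GATC site; fusion samples additionally multiply the
probability at sites inside designated target genes by an enrichment factor.
Each read samples a site (multinomially, proportional to probability), a strand,
and a 0-4 bp random prefix, and reads

    prefix + adapter + genomic-fragment-starting-at-GATC

to a fixed total length. Fragment-length size selection, sequencing error and
PCR duplication are deliberately not modeled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .genomap import GatcMap, GeneModel, GeneSet, Site, revcomp
from .readproc import DEFAULT_ADAPTER, ReadRecord
from .setcompare import DEFAULT_PROMOTER_WIDTH, PeakInterval, promoter_window
from .tissueweight import TPM_CLOSURE, TissueMatrix

import pandas as pd

# Named RNG substreams, combined with the config seed.
_S_GENOME, _S_ANNOT, _S_TARGETS, _S_READS, _S_PEAKS, _S_TISSUE, _S_ACCESS = range(1, 8)

_BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MOTIF_CODES = np.frombuffer(b"GATC", dtype=np.uint8)

FUSION = "fusion"
CONTROL = "control"


@dataclass
class SimConfig:
    """Parameters of one synthetic DamID world.

    Defaults describe a desk-scale world: a two-chromosome 160 kb genome with
    GATC sites every ~200 bp, 20 genes of 1-2 kb of which 5 are true targets,
    background methylation probability 0.1 with 4x enrichment at target sites,
    and triplicate 75 bp read sets of 100,000 reads per sample.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_lengths: tuple[int, ...] = (100_000, 60_000)
    gatc_spacing_mean: float = 200.0
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (1000, 2000)
    n_targets: int = 5
    target_enrichment: float = 4.0
    background_methylation: float = 0.1
    #: lognormal sigma of the per-site accessibility multiplier (mean 1) shared
    #: by all samples; 0 disables accessibility variation.
    accessibility_sigma: float = 0.5
    n_reads_per_sample: int = 100_000
    read_length: int = 75
    adapter_seq: str = DEFAULT_ADAPTER
    n_replicates: int = 3

    def validate(self, promoter_width: int = DEFAULT_PROMOTER_WIDTH) -> None:
        if self.n_chrom != len(self.chrom_lengths):
            raise ConfigError("n_chrom must equal len(chrom_lengths)")
        if self.gatc_spacing_mean <= 5:
            raise ConfigError("GATC spacing too small to fit distinct sites")
        if not (0 < self.background_methylation <= 1):
            raise ConfigError("background_methylation must be in (0, 1]")
        if self.target_enrichment < 1:
            raise ConfigError("target_enrichment must be >= 1")
        if self.accessibility_sigma < 0:
            raise ConfigError("accessibility_sigma must be >= 0")
        if self.n_targets > self.n_genes:
            raise ConfigError("n_targets cannot exceed n_genes")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ConfigError("gene_length_range must be (lo, hi) with lo <= hi")
        if min(self.chrom_lengths) <= self.gene_length_range[1] + 2 * promoter_width:
            raise ConfigError(
                "every chromosome must be longer than the maximum gene length "
                f"plus two promoter widths ({self.gene_length_range[1] + 2 * promoter_width} bp)"
            )
        if self.read_length <= len(self.adapter_seq) + 4 + 4:
            raise ConfigError("read_length leaves no room for adapter + prefix + GATC tail")
        if self.n_replicates < 2:
            raise ConfigError("need at least two replicates per condition")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Ground truth of a simulated world, for closed-loop testing."""

    target_gene_ids: set[str]
    #: per sample: "chrom:pos" -> methylation probability used for sampling
    site_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    #: per sample: "chrom:pos" -> number of reads actually emitted from the site
    site_draws: dict[str, dict[str, int]] = field(default_factory=dict)
    peak_overlap_gene_ids: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_gene_ids": sorted(self.target_gene_ids),
            "site_probs": self.site_probs,
            "site_draws": self.site_draws,
            "peak_overlap_gene_ids": sorted(self.peak_overlap_gene_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            target_gene_ids=set(payload["target_gene_ids"]),
            site_probs=payload.get("site_probs", {}),
            site_draws=payload.get("site_draws", {}),
            peak_overlap_gene_ids=set(payload.get("peak_overlap_gene_ids", [])),
        )


def _rng(config_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config_seed),) + tuple(stream)))


def _find_motif(arr: np.ndarray) -> np.ndarray:
    g, a, t, c = _MOTIF_CODES
    if arr.size < 4:
        return np.empty(0, dtype=np.int64)
    mask = (arr[:-3] == g) & (arr[1:-2] == a) & (arr[2:-1] == t) & (arr[3:] == c)
    return np.nonzero(mask)[0]


def generate_genome(config: SimConfig) -> tuple[dict[str, str], GatcMap]:
    """Build chromosome sequences with GATC planted at ~geometric spacing.

    The emitted GatcMap is exhaustive: incidental GATC occurrences produced by
    the background base sampler are repaired by point mutation (rejection
    resampling), so a brute-force motif scan of the FASTA reproduces the map.
    """
    config.validate()
    rng = _rng(config.seed, _S_GENOME)
    sequences: dict[str, str] = {}
    sites: dict[str, np.ndarray] = {}
    gap_mean = config.gatc_spacing_mean - 4
    for chrom, length in zip(config.chrom_names(), config.chrom_lengths):
        arr = _BASE_CODES[rng.integers(0, 4, size=length)]
        # Plant sites: start positions separated by 4 bp of motif plus a
        # geometric gap with the configured mean spacing.
        planted = []
        pos = int(rng.geometric(1.0 / gap_mean))
        while pos + 4 <= length:
            planted.append(pos)
            pos += 4 + int(rng.geometric(1.0 / gap_mean))
        if not planted:
            raise ConfigError(f"no GATC site fits on {chrom} (length {length})")
        planted_arr = np.array(planted, dtype=np.int64)
        for s in planted:
            arr[s : s + 4] = _MOTIF_CODES
        planted_cover = np.zeros(length, dtype=bool)
        for s in planted:
            planted_cover[s : s + 4] = True
        planted_set = set(planted)
        # Repair incidental motifs without touching planted bases.
        for _ in range(100):
            occ = [o for o in _find_motif(arr) if int(o) not in planted_set]
            if not occ:
                break
            for o in occ:
                o = int(o)
                mutable = [p for p in range(o, o + 4) if not planted_cover[p]]
                p = mutable[0]
                choices = [b for b in _BASE_CODES if b != arr[p]]
                arr[p] = choices[int(rng.integers(0, len(choices)))]
        else:  # pragma: no cover - rejection loop converges in practice
            raise ConfigError(f"could not purge incidental GATC motifs on {chrom}")
        sequences[chrom] = arr.tobytes().decode("ascii")
        sites[chrom] = planted_arr
    return sequences, GatcMap(sites, {c: len(s) for c, s in sequences.items()})


def generate_annotation(
    config: SimConfig, gatc_map: GatcMap, seed: Optional[int] = None
) -> tuple[GeneSet, frozenset[str]]:
    """Place non-overlapping stranded genes, each spanning >= 2 GATC sites.

    Returns the GeneSet (ids assigned in positional order) and the planted set
    of true target gene ids (size ``config.n_targets``).
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, _S_ANNOT)
    chroms = config.chrom_names()
    lengths = np.array(config.chrom_lengths, dtype=float)
    weights = lengths / lengths.sum()
    placed: list[tuple[str, int, int, str]] = []
    attempts = 0
    max_attempts = 500 * config.n_genes
    while len(placed) < config.n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not place {config.n_genes} non-overlapping genes "
                f"after {max_attempts} attempts"
            )
        ci = int(rng.choice(len(chroms), p=weights))
        chrom = chroms[ci]
        glen = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        chrom_len = config.chrom_lengths[ci]
        start = int(rng.integers(0, chrom_len - glen))
        end = start + glen
        if any(c == chrom and start < e and s < end for c, s, e, _ in placed):
            continue
        site_arr = gatc_map.sites[chrom]
        n_inside = int(np.searchsorted(site_arr, end) - np.searchsorted(site_arr, start))
        if n_inside < 2:
            continue
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        placed.append((chrom, start, end, strand))
    placed.sort(key=lambda t: (t[0], t[1]))
    genes = GeneSet(
        GeneModel(f"gene_{i + 1:03d}", chrom, start, end, strand)
        for i, (chrom, start, end, strand) in enumerate(placed)
    )
    rng_t = _rng(config.seed if seed is None else seed, _S_TARGETS)
    target_ids = frozenset(
        rng_t.choice(genes.ids(), size=config.n_targets, replace=False).tolist()
    )
    return genes, target_ids


def _site_key(site: Site) -> str:
    return f"{site[0]}:{site[1]}"


def sample_ids(config: SimConfig) -> dict[str, list[str]]:
    return {
        FUSION: [f"{FUSION}_{r + 1}" for r in range(config.n_replicates)],
        CONTROL: [f"{CONTROL}_{r + 1}" for r in range(config.n_replicates)],
    }


def simulate_damid_reads(
    config: SimConfig,
    genome: Mapping[str, str],
    gatc_map: GatcMap,
    genes: GeneSet,
    target_ids: frozenset[str],
) -> tuple[dict[str, list[ReadRecord]], SimTruth]:
    """Emit replicate read sets for both conditions plus the ground truth.

    All samples share a chromatin-accessibility background: each site's
    methylation probability is the background probability times a per-site
    lognormal accessibility multiplier (mean 1), drawn once per world. Fusion
    samples additionally multiply sites inside target genes by the enrichment
    factor. Probabilities are capped at 1; reads are drawn multinomially over
    sites with independent per-replicate substreams.
    """
    config.validate()
    adapter = config.adapter_seq
    frag_max = config.read_length - len(adapter)  # genomic bases when prefix is empty

    # Eligible sites: those from which a maximal fragment fits on >= 1 strand.
    site_list: list[Site] = []
    fwd_ok: list[bool] = []
    rev_ok: list[bool] = []
    for chrom in sorted(gatc_map.sites):
        chrom_len = gatc_map.chrom_lengths[chrom]
        for s in gatc_map.sites[chrom]:
            s = int(s)
            f = s + frag_max <= chrom_len
            r = s + 4 - frag_max >= 0
            if f or r:
                site_list.append((chrom, s))
                fwd_ok.append(f)
                rev_ok.append(r)
    fwd_ok_arr = np.array(fwd_ok)
    rev_ok_arr = np.array(rev_ok)

    target_intervals: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.gene_id in target_ids:
            target_intervals.setdefault(g.chrom, []).append((g.start, g.end))

    def in_target(site: Site) -> bool:
        return any(s <= site[1] < e for s, e in target_intervals.get(site[0], ()))

    sigma = config.accessibility_sigma
    rng_acc = _rng(config.seed, _S_ACCESS)
    accessibility = (
        rng_acc.lognormal(-sigma * sigma / 2.0, sigma, size=len(site_list))
        if sigma > 0
        else np.ones(len(site_list))
    )
    control_p = np.minimum(1.0, config.background_methylation * accessibility)
    is_target_site = np.array([in_target(s) for s in site_list])
    fusion_p = np.where(
        is_target_site, np.minimum(1.0, control_p * config.target_enrichment), control_p
    )
    probs = {CONTROL: control_p, FUSION: fusion_p}

    truth = SimTruth(target_gene_ids=set(target_ids))
    samples: dict[str, list[ReadRecord]] = {}
    for cond_idx, condition in enumerate((FUSION, CONTROL)):
        p = probs[condition]
        weights = p / p.sum()
        for rep in range(1, config.n_replicates + 1):
            sid = f"{condition}_{rep}"
            rng = _rng(config.seed, _S_READS, cond_idx, rep)
            counts = rng.multinomial(config.n_reads_per_sample, weights)
            idx = np.repeat(np.arange(len(site_list)), counts)
            rng.shuffle(idx)
            reads = _build_reads(
                sid, idx, site_list, fwd_ok_arr, rev_ok_arr, genome, config, rng
            )
            samples[sid] = reads
            truth.site_probs[sid] = {_site_key(s): float(pi) for s, pi in zip(site_list, p)}
            truth.site_draws[sid] = {
                _site_key(site_list[i]): int(c) for i, c in enumerate(counts) if c > 0
            }
    return samples, truth


def _build_reads(
    sample_id: str,
    site_idx: np.ndarray,
    site_list: list[Site],
    fwd_ok: np.ndarray,
    rev_ok: np.ndarray,
    genome: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    n = site_idx.size
    adapter = config.adapter_seq
    alen = len(adapter)
    prefix_lens = rng.integers(0, 5, size=n)
    prefix_codes = rng.integers(0, 4, size=(n, 4))
    strand_pick = rng.integers(0, 2, size=n)
    qual = "I" * config.read_length
    reads: list[ReadRecord] = []
    for i in range(n):
        si = int(site_idx[i])
        chrom, s = site_list[si]
        pl = int(prefix_lens[i])
        frag_len = config.read_length - pl - alen
        if fwd_ok[si] and rev_ok[si]:
            use_rev = bool(strand_pick[i])
        else:
            use_rev = bool(rev_ok[si])
        seq = genome[chrom]
        if use_rev:
            frag = revcomp(seq[s + 4 - frag_len : s + 4])
            strand = "-"
        else:
            frag = seq[s : s + frag_len]
            strand = "+"
        prefix = "".join(_BASES[c] for c in prefix_codes[i, :pl])
        reads.append(
            ReadRecord(
                id=f"{sample_id}:{i}:{chrom}:{s}:{strand}",
                sequence=prefix + adapter + frag,
                quality=qual[: pl + alen + frag_len],
            )
        )
    return reads


def generate_peaks(
    genes: GeneSet,
    chrom_lengths: Mapping[str, int],
    overlap_gene_ids: set[str],
    jitter: int = 200,
    seed: int = 0,
    n_decoys: int = 10,
    peak_width: int = 200,
    promoter_width: int = DEFAULT_PROMOTER_WIDTH,
) -> list[PeakInterval]:
    """Place one peak inside each listed gene's promoter window, plus decoys.

    Decoy peaks land in space overlapping no gene's promoter window, so the
    downstream window/peak intersection recovers exactly ``overlap_gene_ids``
    (minus any gene whose window is empty at a chromosome edge, which is
    skipped with a warning). ``jitter`` bounds the peak's random displacement
    from the window center.
    """
    unknown = overlap_gene_ids - set(genes.ids())
    if unknown:
        raise ConfigError(f"overlap gene ids not in the annotation: {sorted(unknown)}")
    rng = _rng(seed, _S_PEAKS)
    windows = {
        g.gene_id: promoter_window(g, promoter_width, chrom_lengths[g.chrom]) for g in genes
    }
    peaks: list[PeakInterval] = []
    for k, gene_id in enumerate(sorted(overlap_gene_ids)):
        chrom, ws, we = windows[gene_id]
        if ws >= we:
            warnings.warn(f"promoter window of {gene_id} is empty; no peak placed")
            continue
        if we - ws > peak_width:
            center = (ws + we) // 2
            lo = max(ws, center - jitter)
            hi = min(we - peak_width, center + jitter)
            start = int(rng.integers(lo, max(lo + 1, hi + 1)))
            end = start + peak_width
        else:
            start, end = ws, we
        peaks.append(_random_peak(rng, f"peak_{k + 1:03d}", chrom, start, end))
    n_placed = 0
    attempts = 0
    while n_placed < n_decoys and attempts < 200 * max(1, n_decoys):
        attempts += 1
        chrom = sorted(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
        start = int(rng.integers(0, chrom_lengths[chrom] - peak_width))
        end = start + peak_width
        clash = any(
            c == chrom and start < e and s < end for c, s, e in windows.values()
        )
        if clash:
            continue
        n_placed += 1
        peaks.append(_random_peak(rng, f"decoy_{n_placed:03d}", chrom, start, end))
    return peaks


def _random_peak(
    rng: np.random.Generator, name: str, chrom: str, start: int, end: int
) -> PeakInterval:
    return PeakInterval(
        chrom=chrom,
        start=start,
        end=end,
        name=name,
        score=int(rng.integers(100, 1000)),
        strand=".",
        signal_value=float(np.round(rng.uniform(1, 20), 3)),
        p_value=float(np.round(rng.uniform(2, 30), 3)),  # -log10 scale
        q_value=float(np.round(rng.uniform(2, 30), 3)),
        peak_offset=(end - start) // 2,
    )


def generate_tissue_matrix(
    genes: GeneSet,
    tissues: Sequence[str],
    dominant_tissue: str,
    seed: int = 0,
    elevated_gene_ids: frozenset[str] = frozenset(),
    elevation: float = 10.0,
) -> TissueMatrix:
    """Gene x tissue TPM matrix; each tissue column closes to 1,000,000.

    ``elevated_gene_ids`` (typically the planted targets) receive ``elevation``-
    fold higher abundance in ``dominant_tissue`` before per-column closure, so a
    tissue-weight analysis of that list reports the dominant tissue on top.
    """
    if dominant_tissue not in tissues:
        raise ConfigError(f"dominant tissue {dominant_tissue!r} not in tissue list")
    rng = _rng(seed, _S_TISSUE)
    ids = genes.ids()
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=(len(ids), len(tissues)))
    if elevated_gene_ids:
        rows = [i for i, g in enumerate(ids) if g in elevated_gene_ids]
        col = list(tissues).index(dominant_tissue)
        abundance[rows, col] *= elevation
    tpm = abundance / abundance.sum(axis=0, keepdims=True) * TPM_CLOSURE
    return TissueMatrix(pd.DataFrame(tpm, index=ids, columns=list(tissues)))


# ---------------------------------------------------------------------------
# One-call world


@dataclass
class SimulatedWorld:
    """Everything one seed buys: reference, annotation, reads and truth."""

    config: SimConfig
    genome: dict[str, str]
    gatc_map: GatcMap
    genes: GeneSet
    target_ids: frozenset[str]
    samples: dict[str, list[ReadRecord]]
    truth: SimTruth


def simulate_world(config: SimConfig) -> SimulatedWorld:
    genome, gatc_map = generate_genome(config)
    genes, target_ids = generate_annotation(config, gatc_map)
    samples, truth = simulate_damid_reads(config, genome, gatc_map, genes, target_ids)
    return SimulatedWorld(config, genome, gatc_map, genes, target_ids, samples, truth)


def config_from_dict(data: Mapping) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML)."""
    cfg = SimConfig(**{k: v for k, v in data.items()})
    if isinstance(cfg.chrom_lengths, list):
        cfg.chrom_lengths = tuple(cfg.chrom_lengths)
    if isinstance(cfg.gene_length_range, list):
        cfg.gene_length_range = tuple(cfg.gene_length_range)
    cfg.validate()
    return cfg
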