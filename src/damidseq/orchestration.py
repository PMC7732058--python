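"""End-to-end pipeline runs: configuration, stage wiring, manifest.

One call takes a simulated (or user-supplied) DamID experiment through
trim -> count -> call -> compare -> overlap -> tissues and leaves a
self-describing output directory behind: every stage's files, plus a
``manifest.json`` recording parameters, seeds, per-stage counts and sha256
checksums. Outputs carry no timestamps, so rerunning an identical
configuration reproduces every checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, genomap, readproc, setcompare, simdata, targetcall, tissueweight
from .errors import DamidError
from .genomap import GatcIndex, SampleCounts
from .readproc import DEFAULT_ADAPTER, DEFAULT_MAX_OFFSET, DEFAULT_MIN_TAIL
from .simdata import CONTROL, FUSION, SimConfig, SimTruth
from .targetcall import CallParams

logger = logging.getLogger("damidseq")

#: Tissue panel mirroring the seven broad tissues of the L2 worm single-cell atlas.
DEFAULT_TISSUES = (
    "Body wall muscle",
    "Glia",
    "Gonad",
    "Hypodermis",
    "Intestine",
    "Neurons",
    "Pharynx",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-loadable via :meth:`from_yaml`."""

    outdir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    # stage toggles
    do_simulate: bool = True
    do_trim: bool = True
    do_count: bool = True
    do_call: bool = True
    do_compare: bool = True
    do_overlap: bool = True
    do_tissues: bool = True
    # stage parameters (defaults mirror the analysis this package implements)
    adapter: str = DEFAULT_ADAPTER
    max_offset: int = DEFAULT_MAX_OFFSET
    min_tail: int = DEFAULT_MIN_TAIL
    seed_len: int = genomap.DEFAULT_SEED_LEN
    min_reads: int = 2
    call_params: CallParams = field(default_factory=CallParams)
    promoter_width: int = setcompare.DEFAULT_PROMOTER_WIDTH
    peak_fraction: float = 0.6  # fraction of planted targets given a simulated peak
    n_decoy_peaks: int = 10
    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    dominant_tissue: str = "Body wall muscle"
    # optional externally supplied inputs (paths), used when a stage is disabled
    input_genome: Optional[Path] = None
    input_genes: Optional[Path] = None
    input_reads: dict[str, Path] = field(default_factory=dict)
    input_trimmed: dict[str, Path] = field(default_factory=dict)
    input_peaks: Optional[Path] = None
    input_tissue_matrix: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "outdir" not in data:
            raise DamidError("run config must name an output directory (outdir)")
        kwargs: dict = {"outdir": Path(data.pop("outdir"))}
        if "sim" in data:
            kwargs["sim"] = simdata.config_from_dict(data.pop("sim"))
        if "call" in data:
            kwargs["call_params"] = CallParams(**data.pop("call"))
        for stage, enabled in (data.pop("stages", {}) or {}).items():
            key = f"do_{stage}"
            if not hasattr(cls, key):
                raise DamidError(f"unknown stage toggle {stage!r}")
            kwargs[key] = bool(enabled)
        for key in ("input_genome", "input_genes", "input_peaks", "input_tissue_matrix"):
            if key in data:
                kwargs[key] = Path(data.pop(key))
        for key in ("input_reads", "input_trimmed"):
            if key in data:
                kwargs[key] = {k: Path(v) for k, v in data.pop(key).items()}
        if "tissue_names" in data:
            kwargs["tissue_names"] = tuple(data.pop("tissue_names"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DamidError(f"unknown run-config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages and return the manifest (also written as JSON).

    Any stage failure raises with the stage named; files written by completed
    stages are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.sim.seed,
        "parameters": {
            "adapter": config.adapter,
            "max_offset": config.max_offset,
            "min_tail": config.min_tail,
            "seed_len": config.seed_len,
            "min_reads": config.min_reads,
            "fc_threshold": config.call_params.fc_threshold,
            "pseudocount": config.call_params.pseudocount,
            "promoter_width": config.promoter_width,
            "sim": dataclasses.asdict(config.sim),
        },
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def emit(name: str, path: Path) -> Path:
        written.append(path)
        manifest["outputs"][name] = str(path.relative_to(outdir))
        return path

    stage = "simulate"
    try:
        genome, gatc_map, genes, target_ids, truth, raw_samples, peaks, matrix = _stage_inputs(
            config, outdir, emit
        )
        manifest["stages"]["simulate"] = {
            "enabled": config.do_simulate,
            "n_sites": gatc_map.n_sites(),
            "n_genes": len(genes),
            "n_targets": len(target_ids) if target_ids else None,
        }

        stage = "trim"
        trimmed: dict[str, list[readproc.ReadRecord]] = {}
        trim_counts: dict[str, dict] = {}
        if config.do_trim:
            for sid, reads in raw_samples.items():
                result = readproc.filter_and_trim(
                    reads, config.adapter, config.max_offset, config.min_tail
                )
                trimmed[sid] = result.kept
                trim_counts[sid] = {
                    "n_input": result.n_input,
                    "n_kept": result.n_kept,
                    "n_no_adapter": result.n_no_adapter,
                    "n_no_gatc_after_adapter": result.n_no_gatc_after_adapter,
                }
                readproc.write_fastq(result.kept, emit(f"trimmed_{sid}", outdir / f"trimmed_{sid}.fastq"))
                readproc.write_trim_report(result, emit(f"trim_stats_{sid}", outdir / f"trim_stats_{sid}.tsv"))
                logger.info("trim %s: kept %d / %d", sid, result.n_kept, result.n_input)
        else:
            for sid, path in config.input_trimmed.items():
                trimmed[sid] = list(readproc.read_fastq(path))
        manifest["stages"]["trim"] = {"enabled": config.do_trim, "samples": trim_counts}

        stage = "count"
        samples: list[SampleCounts] = []
        if config.do_count:
            index = GatcIndex.build(genome, gatc_map, config.seed_len)
            for sid in sorted(trimmed):
                condition = FUSION if sid.startswith(FUSION) else CONTROL
                replicate = int(sid.rsplit("_", 1)[1])
                sc = genomap.quantify_sample(trimmed[sid], index, genes, sid, condition, replicate)
                samples.append(sc)
                genomap.write_sample_counts(sc, genes, emit(f"counts_{sid}", outdir / f"counts_{sid}.tsv"))
                genomap.write_site_counts(sc, emit(f"sites_{sid}", outdir / f"sites_{sid}.tsv"))
                logger.info("count %s: %d reads uniquely assigned", sid, sc.total_assigned)
            corr = genomap.spearman_qc(samples, config.min_reads)
            corr.to_csv(emit("spearman", outdir / "spearman.tsv"), sep="\t", float_format="%.6f")
            manifest["stages"]["count"] = {
                "enabled": True,
                "total_assigned": {s.sample_id: s.total_assigned for s in samples},
            }
        else:
            manifest["stages"]["count"] = {"enabled": False}

        stage = "call"
        calls = None
        called: set[str] = set()
        if config.do_call:
            fusion = [s.gene_counts_norm for s in samples if s.condition == FUSION]
            control = [s.gene_counts_norm for s in samples if s.condition == CONTROL]
            calls = targetcall.call_targets(fusion, control, config.call_params, genes)
            called = targetcall.called_set(calls)
            targetcall.write_target_table(calls, emit("targets", outdir / "targets.tsv"), genes)
            (outdir / "targets.txt").write_text("".join(f"{g}\n" for g in sorted(called)))
            emit("target_ids", outdir / "targets.txt")
            manifest["stages"]["call"] = {"enabled": True, "n_called": len(called)}
            logger.info("call: %d candidate targets", len(called))
        else:
            manifest["stages"]["call"] = {"enabled": False}

        stage = "compare"
        if config.do_compare and calls is not None and target_ids:
            universe = set(genes.ids())
            if called:
                res = setcompare.compare_target_lists(called, set(target_ids), universe)
                setcompare.write_overlap_result(
                    res, emit("compare_truth", outdir / "compare_truth.tsv"), "called_vs_planted"
                )
                manifest["stages"]["compare"] = {
                    "enabled": True,
                    "n_called": len(called),
                    "n_planted": len(target_ids),
                    "n_shared": res.n_overlap,
                }
            else:
                manifest["stages"]["compare"] = {"enabled": True, "n_called": 0}
        else:
            manifest["stages"]["compare"] = {"enabled": False}

        stage = "overlap"
        if config.do_overlap and calls is not None and peaks is not None and called:
            windows = {
                g.gene_id: setcompare.promoter_window(
                    g, config.promoter_width, gatc_map.chrom_lengths[g.chrom]
                )
                for g in genes
            }
            peak_genes = setcompare.intersect(windows, peaks)
            res = setcompare.overlap_stats(called, peak_genes, set(genes.ids()))
            setcompare.write_overlap_result(res, emit("overlap", outdir / "overlap.tsv"), "called_vs_peaks")
            manifest["stages"]["overlap"] = {
                "enabled": True,
                "n_peak_genes": len(peak_genes),
                "n_overlap": res.n_overlap,
                "percent": round(res.percent, 4),
            }
        else:
            manifest["stages"]["overlap"] = {"enabled": False}

        stage = "tissues"
        if config.do_tissues and matrix is not None and called:
            table = tissueweight.tissue_weights(called, matrix, "called")
            tissueweight.write_weight_tables([table], emit("tissues", outdir / "tissue_weights.tsv"))
            frac = tissueweight.tissue_fraction(called, matrix, config.dominant_tissue)
            manifest["stages"]["tissues"] = {
                "enabled": True,
                "top_tissue": max(table.percent, key=table.percent.get),
                "dominant_fraction": round(frac, 6),
            }
        else:
            manifest["stages"]["tissues"] = {"enabled": False}
    except DamidError as exc:
        raise DamidError(f"stage {stage!r} failed: {exc}") from exc

    manifest["checksums"] = {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_inputs(config: RunConfig, outdir: Path, emit):
    """Simulate (or load) the reference, annotation, reads, peaks and matrix."""
    truth: Optional[SimTruth] = None
    target_ids: frozenset[str] = frozenset()
    peaks = None
    matrix = None
    if config.do_simulate:
        world = simdata.simulate_world(config.sim)
        genome, gatc_map = world.genome, world.gatc_map
        genes, target_ids, truth = world.genes, world.target_ids, world.truth
        raw_samples = world.samples
        genomap.write_fasta(genome, emit("genome", outdir / "genome.fa"))
        genomap.write_genes_bed6(genes, emit("genes", outdir / "genes.bed"))
        if config.do_trim:
            for sid, reads in raw_samples.items():
                readproc.write_fastq(reads, emit(f"raw_{sid}", outdir / f"raw_{sid}.fastq"))
        n_overlap = int(round(config.peak_fraction * len(target_ids)))
        overlap_ids = set(sorted(target_ids)[:n_overlap])
        peaks = simdata.generate_peaks(
            genes,
            gatc_map.chrom_lengths,
            overlap_ids,
            seed=config.sim.seed,
            n_decoys=config.n_decoy_peaks,
            promoter_width=config.promoter_width,
        )
        truth.peak_overlap_gene_ids = overlap_ids
        setcompare.write_narrowpeak(peaks, emit("peaks", outdir / "peaks.narrowPeak"))
        matrix = simdata.generate_tissue_matrix(
            genes,
            config.tissue_names,
            config.dominant_tissue,
            seed=config.sim.seed,
            elevated_gene_ids=frozenset(target_ids),
        )
        tissueweight.write_tissue_matrix(matrix, emit("tissue_tpm", outdir / "tissue_tpm.tsv"))
        truth.to_json(emit("truth", outdir / "truth.json"))
    else:
        if config.input_genome is None or config.input_genes is None:
            raise DamidError("simulate disabled: input_genome and input_genes are required")
        genome = genomap.read_fasta(config.input_genome)
        gatc_map = genomap.GatcMap.from_sequences(genome)
        genes = genomap.read_genes_bed6(config.input_genes)
        raw_samples = {
            sid: list(readproc.read_fastq(path)) for sid, path in config.input_reads.items()
        }
        if config.input_peaks is not None:
            peaks = setcompare.read_narrowpeak(config.input_peaks)
        if config.input_tissue_matrix is not None:
            matrix = tissueweight.read_tissue_matrix(config.input_tissue_matrix)
    return genome, gatc_map, genes, target_ids, truth, raw_samples, peaks, matrix


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
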