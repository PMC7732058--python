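# damidseq

Target-gene identification from DamID sequencing data, for researchers mapping
transcription-factor/genome interactions in organisms such as *C. elegans*.

In DamID, a protein of interest is fused to bacterial Dam methyltransferase,
which methylates the adenine of GATC motifs near the protein's genomic binding
sites; a freely diffusing GFP::Dam fusion serves as the accessibility control.
Sequencing libraries amplified from methylated GATC fragments carry a fixed
adapter immediately followed by the genomic GATC, and the analysis exploits that
structure end to end:

1. **Read filtering/trimming** (`readproc`) — discard reads lacking
   `adapter + GATC`; trim so the retained sequence starts at the genomic GATC.
2. **GATC-anchored mapping and gene binning** (`genomap`) — assign each trimmed
   read to a unique GATC site (both strands; GATC is palindromic so site
   identity is strandless), sum site counts over gene bodies, and scale each
   sample to reads per million assigned reads. Replicate quality is checked by
   pairwise Spearman correlation of site counts after dropping sites with < 2
   reads in either sample.
3. **Target calling** (`targetcall`) — with triplicate fusion (dam::TF) and
   control (gfp::dam) samples, gene *g* is a candidate target iff

   ```
   min_i fusion_i(g) > max_j control_j(g)      (replicate consistency)
   mean(fusion(g)) / mean(control(g)) > 1.7    (fold change, strict)
   ```

   and the reported effect size is
   `log2FC = log2((mean_fusion + 0.5) / (mean_control + 0.5))`.
   Under the null (exchangeable replicates) the consistency filter alone passes
   with probability 1/C(6,3) = 0.05.
4. **Comparative statistics** (`setcompare`, `tissueweight`, `assaystats`) —
   strand-aware 3 kb promoter windows intersected with ChIP-seq narrowPeak
   lists, chi-square (Yates) tests of list overlap over a gene universe,
   distribution of a gene list's expression over tissues from a gene x tissue
   TPM matrix, and the chemotaxis index
   `CI = (n_butanone - n_EtOH) / (n_total - n_origin)`.
5. **Synthetic data** (`simdata`) — fully ground-truthed toy worlds: genomes
   with a known GATC map, planted target genes, adapter-structured reads with a
   shared chromatin-accessibility background, peak lists and tissue matrices,
   so every stage is testable without external data.
6. **Orchestration** (`orchestration`, `damid` CLI) — one reproducible run,
   simulate → trim → count → call → compare → overlap → tissues, with a
   checksummed manifest.

## Worked example

```python
from damidseq import simdata, readproc, genomap, targetcall

cfg = simdata.SimConfig(seed=42, n_reads_per_sample=50_000)
world = simdata.simulate_world(cfg)              # 5 planted targets among 20 genes
index = genomap.GatcIndex.build(world.genome, world.gatc_map)

samples = []
for sid, reads in world.samples.items():         # fusion_1..3, control_1..3
    trimmed = readproc.filter_and_trim(reads)    # every simulated read passes
    samples.append(genomap.quantify_sample(
        trimmed.kept, index, world.genes, sid, sid.split("_")[0]))

fusion = [s.gene_counts_norm for s in samples if s.condition == "fusion"]
control = [s.gene_counts_norm for s in samples if s.condition == "control"]
calls = targetcall.call_targets(fusion, control, genes=world.genes)
print(sorted(t.gene_id for t in calls if t.is_target))
```

prints exactly the planted target set

```
['gene_004', 'gene_011', 'gene_012', 'gene_013', 'gene_020']
```

with per-gene records such as `gene_004: fusion_mean=76953, control_mean=22973,
FC=3.35, log2FC=1.74` (normalized units are reads per million; the planted 4x
enrichment is attenuated to ~3.3x by per-sample renormalization). Replicate QC
on the same run gives Spearman 0.92 within fusion replicates versus 0.84
between fusion and control — the signature of a shared accessibility background
plus fusion-specific signal.

The same pipeline runs from the shell:

```sh
damid run --config run.yaml        # full pipeline + manifest.json
damid trim --in raw.fastq --out trimmed.fastq --report stats.tsv
damid call --fusion f1.tsv f2.tsv f3.tsv --control c1.tsv c2.tsv c3.tsv \
           --fc 1.7 --genes genes.bed --out targets.tsv
damid ci --butanone 30 --etoh 10 --origin 20 --total 100   # CI = 0.2500
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates a complete DamID experiment at the given seed, runs every pipeline
stage (trim, map, bin, normalize, QC, call, truth comparison, peak overlap,
tissue weighting) and writes the results JSON to `--out`, logging a one-line
recovery summary to stderr.
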