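# Methods

This note documents the models, conventions and design choices behind
`damidseq`: what each stage computes, what the synthetic worlds do and do not
emulate, and where the design was genuinely open.

## The measurement model

DamID reads out protein-genome proximity through adenine methylation of GATC
motifs. The unit of signal is therefore the *GATC site*, not the base pair:
all mapping, counting and QC operate on the set of GATC start coordinates of
the reference (the `GatcMap`). Because GATC is its own reverse complement and
Dam methylates both adenines of the palindrome, a site has no strand; reads
mapping to either strand of a site are pooled under one coordinate.

A well-formed library read is

    [0-4 random bases] + adapter + GATC + genomic sequence ...

where the adapter is the constant 3' portion of the amplification primer
(`GGTCGCGGCCGAGGA` by default). The primer itself ends `...GAGGATC`,
overlapping the genomic site: the trimmer removes through the adapter and
requires the next four bases to be GATC, keeping that GATC in the read so the
mapper can anchor it.

## Stage contracts

**Filtering/trimming** (`readproc.filter_and_trim`). A read is kept iff the
adapter occurs exactly (no mismatches) at an offset ≤ `max_offset` (default 8,
covering the up-to-4 random prefix bases plus slack) and is immediately
followed by GATC with at least `min_tail` (default 20) retained bases. The
three rejection/acceptance counters partition the input exactly; short-tail
reads are folded into the no-GATC counter (with a separate informational
sub-count) to keep the three-way partition. Discard-on-absence is deliberate —
no fuzzy adapter matching — because the filter defines the library structure
rather than rescuing reads.

**Mapping** (`genomap.GatcIndex`). Desk-scale references make full alignment
unnecessary: the first `seed_len` bases (default 32) of a trimmed read are
compared exactly against the reference at every GATC site on the forward
strand, and against the reverse complement anchored so the read's GATC
coincides with a genomic GATC. Exactly one hit → unique; several → multi;
none → unmapped. Multi-mapping and unmapped reads are discarded — unique-site
attribution keeps counts well-defined. The index is a hash over per-site seeds,
so mapping is O(1) per read; tests check it against a brute-force text scan of
both strands.

**Counting and normalization.** Site counts are summed into gene bodies using
0-based half-open containment (`start ≤ site < end`); gene bins must be
disjoint (enforced at annotation load) so each site contributes to at most one
gene. Per-gene counts are scaled to reads per million *uniquely assigned*
reads in that sample. The choice of denominator (assigned reads rather than
raw reads) is an interpretation: selection operates on relative lane
composition, and assigned reads are the lane total the counts actually live
in.

**Replicate QC.** Pairwise Spearman correlation over sites where *both*
samples of the pair have ≥ `min_reads` (default 2) reads. The low-count filter
is applied per pair, not per sample: a site's rank at 0–1 reads is sampling
noise, and the pairwise reading lets every comparison use its own maximal
informative site set. Pairs with < 3 surviving sites are reported absent
(NaN). Ties get average ranks.

**Target calling.** Gene `g` is a candidate target iff
`min(fusion) > max(control)` (every fusion lane strictly above every control
lane) and `mean(fusion)/mean(control) > fc_threshold` (default 1.7, strict).
Both inequalities are strict; ties fail. All-zero controls give fold change
+infinity (a target if every fusion lane is positive and the consistency
filter passes) and all-zero genes give fold change 0 (never a target). The
pseudocount (0.5 normalized units) enters only the *reported*
`log2FC = log2((mean_f + 0.5)/(mean_c + 0.5))`, never the call, so the
published rule is applied unmodified while the effect size stays finite.
Under exchangeable replicates the consistency filter passes with probability
`1/C(6,3) = 1/20`; the acceptance suite verifies this calibration by
simulation. `compare_signal` tests subset mean log2FC differences with
Welch's unequal-variance t-test (no test is canonical here; Welch is the
default-safe choice and is named in the output).

**Set comparisons.** Promoter windows are the `width` bp (default 3000)
immediately upstream of the annotated gene start, strand-aware, clipped at
chromosome edges (possibly empty). Overlap means ≥ 1 shared base in half-open
coordinates; abutting intervals do not overlap. Chi-square tests classify the
gene universe into (in-list) × (has-peak) with Yates continuity correction on
by default (toggleable); the universe is an explicit required argument because
overlap percentages are universe-invariant but p-values are not.

**Tissue weighting.** For a gene list and a gene × tissue TPM matrix,
`sum_tpm[t]` is the list's summed TPM in tissue `t` and
`percent[t] = 100 · sum_tpm[t] / Σ_t sum_tpm[t]` (columns of percentages close
to 100). `tissue_fraction` divides the list's TPM in one tissue by the
1,000,000 TPM closure of the full transcriptome — not by the matrix column
sum, which may cover only a gene subset. List genes missing from the matrix
contribute zero and are counted, not fatal.

**Chemotaxis index.** `CI = (n_butanone − n_EtOH)/(n_total − n_origin)`,
verbatim; animals elsewhere on the plate dilute the denominator exactly as the
formula dictates, with no re-normalization. The count invariants guarantee
CI ∈ [−1, 1].

## The synthetic worlds

`simdata` builds worlds in which every quantity the pipeline estimates is
known exactly:

- **Genome.** GATC motifs are *planted* at geometrically distributed spacing
  (mean 200 bp by default, matching the ~256 bp expectation for a 4-mer plus
  the motif's own footprint) and incidental motifs arising from the background
  base sampler are repaired by point mutation. The GATC map is therefore
  analytically known, and a brute-force motif scan of the emitted FASTA
  reproduces it exactly — the anchor for oracle tests.
- **Annotation.** Non-overlapping stranded genes (default 20 of 1–2 kb over a
  160 kb two-chromosome genome), each containing ≥ 2 GATC sites; a designated
  subset (default 5) are true targets.
- **Reads.** Every site carries a methylation probability
  `p = background · accessibility`, where `background` defaults to 0.1 and
  `accessibility` is a per-site lognormal multiplier (mean 1, sigma 0.5) drawn
  once per world and shared by all six samples — the chromatin-accessibility
  background that makes replicate correlations high both within and between
  conditions, as observed in real DamID. Fusion samples multiply target-gene
  sites by the enrichment factor (default 4; probabilities capped at 1). Each
  sample draws its reads multinomially over sites in an independent seeded
  substream, then emits `prefix + adapter + fragment` reads of fixed length
  (default 75 bp, 100,000 reads/sample — depth and length are simulation
  choices; the source study does not state them). Strands are sampled
  uniformly among those on which a fragment fits.
- **Peaks and tissue matrix.** One peak inside the promoter window of each
  chosen gene plus decoy peaks overlapping no promoter window, as valid
  10-column narrowPeak; a gene × tissue matrix with exact per-column TPM
  closure and elevated target-gene abundance in a designated dominant tissue.

Not modeled, deliberately: fragment-length size selection (it affects library
efficiency, not the per-site counting contract), PCR duplicates, GC bias,
sequencing error, paired ends, and any real genome's sequence composition. A
green closed-loop test therefore establishes that the pipeline's arithmetic
and bookkeeping are correct under the stated generative model — not that the
calling rule is robust to artifacts the generator omits.

Determinism: all randomness descends from `SimConfig.seed` through named
substreams (genome, annotation, targets, accessibility, per-replicate reads,
peaks, tissue matrix), so identical configurations give byte-identical
outputs; pipeline reruns reproduce all output checksums.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; BED round-trips
  losslessly, GFF3 gene features are converted on read.
- Normalization refuses samples with zero assigned reads.
- Correlation entries with < 3 surviving sites, and signal comparisons of
  constant subsets, are handled explicitly (NaN entry; p = 1 for equal
  constants, 0 otherwise).
- Reads shorter than the seed length are unmapped by contract (the default
  trimming floor of 20 bp cannot occur with default read length 75).
- The fold-change threshold comparison is strict at exactly 1.7 by
  construction; the boundary is pinned by tests.

## Known limitations

- The exact-match mapper is collision-safe on toy genomes but unsuitable for
  real references with repeats; the counting interfaces accept pre-computed
  per-sample count tables so externally mapped data can be slotted in.
- The simulator's multinomial read model has no overdispersion beyond the
  accessibility layer, so real-data replicate variance will exceed simulated
  variance at matched depth.
- Chi-square p-values depend on the chosen gene universe; published overlap
  p-values are generally not recoverable without the original universe, which
  is why only overlap percentages are pinned by tests.
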