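"""Site-anchored mapping, counting, binning, normalization and Spearman QC."""

import dataclasses
import random

import numpy as np
import pytest

from damidseq import genomap, readproc, simdata
from damidseq.errors import AnnotationError, EmptySampleError, StatisticsError
from damidseq.genomap import (
    Assignment,
    GatcIndex,
    GatcMap,
    GeneModel,
    GeneSet,
    SampleCounts,
    bin_to_genes,
    count_sites,
    map_read,
    normalize,
    revcomp,
    spearman_qc,
)
from damidseq.readproc import ReadRecord


def mkread(seq, rid="r"):
    return ReadRecord(rid, seq, "I" * len(seq))


def mksample(sid, site_counts, condition="fusion"):
    return SampleCounts(sid, condition, 1, dict(site_counts), {}, {}, sum(site_counts.values()))


class TestMapRead:
    def test_read_from_unique_site_maps_there(self, small_world, small_index):
        chrom = small_world.config.chrom_names()[0]
        s = int(small_world.gatc_map.sites[chrom][3])
        read = mkread(small_world.genome[chrom][s : s + 50])
        status, site = map_read(read, small_index)
        assert status is Assignment.UNIQUE
        assert site == (chrom, s)

    def test_reverse_strand_read_maps_to_same_site(self, small_world, small_index):
        chrom = small_world.config.chrom_names()[0]
        s = int(small_world.gatc_map.sites[chrom][5])
        read = mkread(revcomp(small_world.genome[chrom][s + 4 - 50 : s + 4]))
        assert read.sequence.startswith("GATC")
        status, site = map_read(read, small_index)
        assert status is Assignment.UNIQUE
        assert site == (chrom, s)

    def test_planted_duplication_is_multi(self):
        x = "A" * 28
        seq = "T" * 20 + "GATC" + x + "T" * 20 + "GATC" + x + "T" * 20
        genome = {"chrA": seq}
        gatc_map = GatcMap.from_sequences(genome)
        assert gatc_map.sites["chrA"].size == 2
        index = GatcIndex.build(genome, gatc_map, seed_len=32)
        status, site = map_read(mkread("GATC" + x), index)
        assert status is Assignment.MULTI
        assert site is None

    def test_foreign_sequence_is_unmapped(self, small_index):
        status, _ = map_read(mkread("GATC" + "T" * 46), small_index)
        assert status is Assignment.UNMAPPED

    def test_agrees_with_full_scan_oracle(self, small_world, small_index):
        """Hash-index mapping equals a brute-force text scan of both strands."""
        seed_len = small_index.seed_len
        genome = small_world.genome
        site_sets = {c: set(map(int, arr)) for c, arr in small_world.gatc_map.sites.items()}

        def oracle(seq: str):
            seed = seq[:seed_len]
            rc = revcomp(seed)
            hits = set()
            for chrom, ref in genome.items():
                p = ref.find(seed)
                while p != -1:
                    if p in site_sets[chrom]:
                        hits.add((chrom, p))
                    p = ref.find(seed, p + 1)
                q = ref.find(rc)
                while q != -1:
                    if q + seed_len - 4 in site_sets[chrom]:
                        hits.add((chrom, q + seed_len - 4))
                    q = ref.find(rc, q + 1)
            if not hits:
                return (Assignment.UNMAPPED, None)
            if len(hits) == 1:
                return (Assignment.UNIQUE, next(iter(hits)))
            return (Assignment.MULTI, None)

        reads = readproc.filter_and_trim(small_world.samples["fusion_1"][:500]).kept
        for read in reads:
            assert map_read(read, small_index) == oracle(read.sequence)


class TestCounting:
    def test_count_sites_tallies_unique_only(self):
        a, b = ("chr1", 10), ("chr1", 50)
        assignments = (
            [(Assignment.UNIQUE, a)] * 10
            + [(Assignment.UNIQUE, b)] * 5
            + [(Assignment.MULTI, None), (Assignment.UNMAPPED, None)]
        )
        counts, total = count_sites(assignments)
        assert counts == {a: 10, b: 5}
        assert total == 15

    def test_all_multi_gives_empty(self):
        counts, total = count_sites([(Assignment.MULTI, None)] * 7)
        assert counts == {} and total == 0

    def test_counts_match_simulator_emission_tally(self, small_world, small_index):
        """Closed loop: mapped per-site counts equal what the simulator drew."""
        trimmed = readproc.filter_and_trim(small_world.samples["fusion_1"]).kept
        counts, total = count_sites(map_read(r, small_index) for r in trimmed)
        drawn = small_world.truth.site_draws["fusion_1"]
        assert total == sum(drawn.values())
        assert {f"{c}:{p}": n for (c, p), n in counts.items()} == drawn

    def test_read_order_invariance(self, small_world, small_index):
        trimmed = readproc.filter_and_trim(small_world.samples["control_1"]).kept
        counts1, _ = count_sites(map_read(r, small_index) for r in trimmed)
        shuffled = trimmed[:]
        random.Random(3).shuffle(shuffled)
        counts2, _ = count_sites(map_read(r, small_index) for r in shuffled)
        assert counts1 == counts2


class TestBinning:
    GENES = GeneSet([GeneModel("g1", "chr1", 100, 200), GeneModel("g2", "chr1", 400, 500)])

    def test_containment(self):
        counts = bin_to_genes({("chr1", 150): 7, ("chr1", 300): 9}, self.GENES)
        assert counts == {"g1": 7, "g2": 0}

    def test_half_open_boundaries(self):
        counts = bin_to_genes({("chr1", 100): 3, ("chr1", 200): 5}, self.GENES)
        assert counts["g1"] == 3  # start included, end excluded

    def test_overlapping_genes_refused(self):
        with pytest.raises(AnnotationError):
            GeneSet([GeneModel("a", "chr1", 0, 100), GeneModel("b", "chr1", 50, 150)])

    def test_quadratic_oracle(self, small_world, small_index):
        trimmed = readproc.filter_and_trim(small_world.samples["fusion_2"]).kept
        site_counts, _ = count_sites(map_read(r, small_index) for r in trimmed)
        fast = bin_to_genes(site_counts, small_world.genes)
        slow = {g.gene_id: 0 for g in small_world.genes}
        for (chrom, pos), n in site_counts.items():
            for g in small_world.genes:
                if g.chrom == chrom and g.start <= pos < g.end:
                    slow[g.gene_id] += n
        assert fast == slow


class TestNormalize:
    def test_arithmetic(self):
        assert normalize({"g1": 50}, 1000) == {"g1": 50_000.0}

    def test_scale_invariance(self):
        raw = {"g1": 10, "g2": 30}
        assert normalize(raw, 200) == normalize({g: 3 * n for g, n in raw.items()}, 600)

    def test_per_million_closure(self):
        raw = {"g1": 10, "g2": 30, "g3": 0}
        total = 80  # genes need not tile the genome
        norm = normalize(raw, total)
        assert sum(norm.values()) == pytest.approx(1e6 * sum(raw.values()) / total, rel=1e-9)

    def test_empty_sample_error(self):
        with pytest.raises(EmptySampleError):
            normalize({"g1": 0}, 0)


class TestSpearmanQC:
    def test_self_correlation_is_one(self):
        s = mksample("a", {("chr1", i * 10): i + 2 for i in range(6)})
        t = mksample("b", dict(s.site_counts))
        mat = spearman_qc([s, t], min_reads=2)
        assert mat.loc["a", "a"] == 1.0
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        sites = [("chr1", i * 10) for i in range(4)]
        s = mksample("a", dict(zip(sites, [1, 2, 3, 4])))
        t = mksample("b", dict(zip(sites, [4, 3, 2, 1])))
        mat = spearman_qc([s, t], min_reads=1)
        assert mat.loc["a", "b"] == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "y, expected",
        [((6, 8, 1, 10, 3), 1.0), ((8, 6, 1, 10, 3), 0.9)],
    )
    def test_hand_ranked_oracle(self, y, expected):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) on hand-ranked distinct vectors."""
        sites = [("chr1", i * 10) for i in range(5)]
        s = mksample("a", dict(zip(sites, [5, 7, 2, 9, 4])))
        t = mksample("b", dict(zip(sites, y)))
        mat = spearman_qc([s, t], min_reads=1)
        assert mat.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_low_count_sites_removed_pairwise(self):
        sites = [("chr1", i * 10) for i in range(5)]
        s = mksample("a", dict(zip(sites, [0, 1, 5, 6, 7])))
        t = mksample("b", dict(zip(sites, [9, 9, 5, 6, 7])))
        # Only the last three sites have >= 2 reads in both samples; they agree
        # perfectly there.
        mat = spearman_qc([s, t], min_reads=2)
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_insufficient_sites_reported_absent(self):
        s = mksample("a", {("chr1", 0): 5, ("chr1", 10): 6})
        t = mksample("b", {("chr1", 0): 5, ("chr1", 10): 6})
        mat = spearman_qc([s, t], min_reads=2)
        assert np.isnan(mat.loc["a", "b"])

    def test_single_sample_rejected(self):
        with pytest.raises(StatisticsError):
            spearman_qc([mksample("a", {("chr1", 0): 5})])

    def test_within_condition_beats_between_on_average(self, small_world, small_index):
        """Replicates of one condition correlate more than fusion-vs-control,
        averaged over >= 20 reseeded read sets (stochastic property)."""
        cfg = small_world.config
        within, between = [], []
        for seed in range(20):
            cfg_s = dataclasses.replace(cfg, seed=1000 + seed, n_reads_per_sample=4000)
            samples_reads, _ = simdata.simulate_damid_reads(
                cfg_s, small_world.genome, small_world.gatc_map,
                small_world.genes, small_world.target_ids,
            )
            samples = []
            for sid, reads in sorted(samples_reads.items()):
                trimmed = readproc.filter_and_trim(reads).kept
                counts, total = count_sites(map_read(r, small_index) for r in trimmed)
                samples.append(mksample(sid, counts, sid.split("_")[0]))
            mat = spearman_qc(samples, min_reads=2)
            for i, a in enumerate(samples):
                for j in range(i + 1, len(samples)):
                    b = samples[j]
                    rho = mat.iloc[i, j]
                    if np.isnan(rho):
                        continue
                    (within if a.condition == b.condition else between).append(rho)
        assert np.mean(within) > np.mean(between)


class TestRoundTrips:
    def test_bed6_round_trip(self, small_world, tmp_path):
        path = tmp_path / "genes.bed"
        genomap.write_genes_bed6(small_world.genes, path)
        back = genomap.read_genes_bed6(path)
        assert list(back) == list(small_world.genes)

    def test_gff3_gene_features(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsim\tgene\t101\t200\t.\t+\t.\tID=gene:g1;Name=g1\n"
            "chr1\tsim\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsim\tgene\t401\t500\t.\t-\t.\tID=g2\n"
        )
        genes = genomap.read_genes_gff3(path)
        assert [g.gene_id for g in genes] == ["g1", "g2"]
        assert genes["g1"].start == 100 and genes["g1"].end == 200  # 1-based -> 0-based
        assert genes["g2"].strand == "-"

    def test_fasta_round_trip(self, small_world, tmp_path):
        path = tmp_path / "genome.fa"
        genomap.write_fasta(small_world.genome, path)
        assert genomap.read_fasta(path) == small_world.genome

    def test_sample_counts_round_trip(self, small_world, small_index, tmp_path):
        trimmed = readproc.filter_and_trim(small_world.samples["control_2"]).kept
        sample = genomap.quantify_sample(trimmed, small_index, small_world.genes, "c2", "control", 2)
        path = tmp_path / "counts.tsv"
        genomap.write_sample_counts(sample, small_world.genes, path)
        norm = genomap.read_gene_counts(path)
        for g, v in sample.gene_counts_norm.items():
            assert norm[g] == pytest.approx(v, abs=1e-6)
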