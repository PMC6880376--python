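import numpy as np
import pandas as pd
import pytest

from conftest import random_genotype_matrix
from sweepkit import variant_io as vio


def _write_lines(path, records, samples=("s0", "s1"), contig="chr1", length=100000):
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={length}>",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="QD">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header + records) + "\n")
    return str(path)


class TestReadVcf:
    def test_header_only_empty_matrix(self, tmp_path):
        path = _write_lines(tmp_path / "empty.vcf", [])
        data = vio.read_vcf(path)
        assert data.matrices == {} or all(m.n_sites == 0 for m in data.matrices.values())

    def test_multiallelic_dropped_and_counted(self, tmp_path):
        recs = [
            "chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0|1\t1|1",
            "chr1\t200\t.\tA\tT,G\t50\tPASS\t.\tGT\t0/1\t1/2",
            "chr1\t300\t.\tAT\tA\t50\tPASS\t.\tGT\t0/1\t0/0",
        ]
        data = vio.read_vcf(_write_lines(tmp_path / "m.vcf", recs))
        gm = data.single()
        assert gm.n_sites == 1
        assert data.n_multiallelic == 1
        assert data.n_indel == 1

    def test_phase_detected_only_when_all_calls_phased(self, tmp_path):
        recs = ["chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1",
                "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t0|0\t0/1"]
        gm = vio.read_vcf(_write_lines(tmp_path / "p.vcf", recs)).single()
        assert not gm.is_phased
        recs2 = [r.replace("0/1", "0|1") for r in recs]
        gm2 = vio.read_vcf(_write_lines(tmp_path / "p2.vcf", recs2)).single()
        assert gm2.is_phased

    def test_missing_call_does_not_break_phase(self, tmp_path):
        recs = ["chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t./.",
                "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t1|1\t0|1"]
        gm = vio.read_vcf(_write_lines(tmp_path / "mp.vcf", recs)).single()
        assert gm.is_phased
        assert gm.genotypes[0, 1] == -1
        assert gm.phase[0, 2] == -1

    def test_unsorted_positions_rejected(self, tmp_path):
        recs = ["chr1\t200\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1",
                "chr1\t100\t.\tC\tG\t.\tPASS\t.\tGT\t0|0\t0|1"]
        with pytest.raises(ValueError, match="unsorted"):
            vio.read_vcf(_write_lines(tmp_path / "u.vcf", recs))

    def test_round_trip_lossless(self, tmp_path, rng):
        gm = random_genotype_matrix(rng, n_sites=25, n_samples=6,
                                    missing_rate=0.15)
        out = tmp_path / "rt.vcf"
        vio.write_vcf(gm, str(out))
        back = vio.read_vcf(str(out)).single()
        assert np.array_equal(back.positions, gm.positions)
        assert np.array_equal(back.genotypes, gm.genotypes)
        assert np.array_equal(back.ref, gm.ref)
        assert np.array_equal(back.alt, gm.alt)
        assert back.chrom_length == gm.chrom_length
        # phased matrix with masked calls keeps phase for the called entries
        assert back.is_phased
        assert np.array_equal(back.phase, gm.phase)

    def test_region_filter(self, tmp_path):
        recs = [f"chr1\t{p}\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1"
                for p in (100, 5000, 9000)]
        gm = vio.read_vcf(_write_lines(tmp_path / "r.vcf", recs),
                          region="chr1:1000-8000").single()
        assert list(gm.positions) == [5000]


class TestHardFilters:
    def _info(self, **overrides):
        base = {"QUAL": 150.0, "QD": 5.0, "MQ": 50.0, "FS": 10.0, "SOR": 1.0,
                "MQRankSum": 0.0, "ReadPosRankSum": 0.0}
        base.update(overrides)
        return base

    def _gm_with_info(self, rows, rng):
        gm = random_genotype_matrix(rng, n_sites=len(rows), n_samples=4)
        gm.site_info = pd.DataFrame(rows)
        return gm

    def test_boundary_values_retained(self, rng):
        # thresholds are strict: equality passes
        gm = self._gm_with_info([self._info(QUAL=100.0, QD=2.0, MQ=40.0,
                                            FS=60.0, SOR=3.0)], rng)
        out, log = vio.apply_hard_filters(gm)
        assert out.n_sites == 1
        assert log.empty

    def test_just_below_qual_removed(self, rng):
        gm = self._gm_with_info([self._info(QUAL=99.9)], rng)
        out, log = vio.apply_hard_filters(gm)
        assert out.n_sites == 0
        assert "QUAL" in log.iloc[0]["reasons"]

    def test_missing_annotation_passes_that_rule(self, rng):
        gm = self._gm_with_info([self._info(MQRankSum=np.nan)], rng)
        out, _ = vio.apply_hard_filters(gm)
        assert out.n_sites == 1

    def test_matches_rowwise_reevaluation(self, rng):
        rows = []
        for _ in range(200):
            rows.append({
                "QUAL": rng.uniform(0, 200),
                "QD": rng.uniform(0, 5),
                "MQ": rng.uniform(20, 60),
                "FS": rng.uniform(0, 100),
                "SOR": rng.uniform(0, 5),
                "MQRankSum": rng.uniform(-20, 5),
                "ReadPosRankSum": rng.uniform(-12, 5),
            })
        keep, _ = vio.hard_filter_mask(pd.DataFrame(rows))
        for i, row in enumerate(rows):
            expected = not (row["QUAL"] < 100.0 or row["QD"] < 2.0
                            or row["MQ"] < 40.0 or row["FS"] > 60.0
                            or row["SOR"] > 3.0 or row["MQRankSum"] < -12.5
                            or row["ReadPosRankSum"] < -8.0)
            assert keep[i] == expected

    def test_no_annotations_is_identity_with_warning(self, rng):
        gm = random_genotype_matrix(rng, n_sites=5, n_samples=4)
        with pytest.warns(UserWarning, match="no-op"):
            out, _ = vio.apply_hard_filters(gm)
        assert out.n_sites == 5

    def test_idempotent(self, rng):
        rows = [self._info(QUAL=float(q)) for q in rng.uniform(50, 150, 30)]
        gm = self._gm_with_info(rows, rng)
        once, _ = vio.apply_hard_filters(gm)
        twice, _ = vio.apply_hard_filters(once)
        assert np.array_equal(once.positions, twice.positions)


class TestFrequencyFilters:
    def _gm(self, genotypes):
        g = np.asarray(genotypes, dtype=np.int8)
        return vio.GenotypeMatrix(
            chrom="chr1", positions=np.arange(1, g.shape[0] + 1) * 100,
            ref=np.repeat("A", g.shape[0]), alt=np.repeat("T", g.shape[0]),
            genotypes=g, samples=[f"s{i}" for i in range(g.shape[1])])

    def test_maf_exactly_at_threshold_retained(self):
        # 20 samples, 2 alt alleles among 40: MAF = 0.05, "lower than" is strict
        g = np.zeros((1, 20), dtype=np.int8)
        g[0, 0] = 1
        g[0, 1] = 1
        out = vio.apply_frequency_filters(self._gm(g), maf_min=0.05)
        assert out.n_sites == 1

    def test_maf_below_threshold_removed(self):
        g = np.zeros((1, 20), dtype=np.int8)
        g[0, 0] = 1
        out = vio.apply_frequency_filters(self._gm(g), maf_min=0.05)
        assert out.n_sites == 0

    def test_missing_exactly_ten_percent_retained(self):
        g = np.ones((1, 10), dtype=np.int8)
        g[0, 0] = -1
        out = vio.apply_frequency_filters(self._gm(g), max_missing=0.10)
        assert out.n_sites == 1

    def test_all_missing_removed(self):
        g = np.full((1, 10), -1, dtype=np.int8)
        assert vio.apply_frequency_filters(self._gm(g)).n_sites == 0

    def test_matches_per_site_recomputation(self, rng):
        g = rng.choice([-1, 0, 1, 2], size=(120, 15),
                       p=[0.08, 0.45, 0.22, 0.25]).astype(np.int8)
        out = vio.apply_frequency_filters(self._gm(g))
        expected = []
        for row in g:
            called = row[row >= 0]
            if called.size == 0:
                continue
            p = called.sum() / (2 * called.size)
            maf = min(p, 1 - p)
            miss = np.mean(row < 0)
            if not (maf < 0.05 or miss > 0.10):
                expected.append(True)
            else:
                expected.append(False)
        assert out.n_sites == sum(expected)

    def test_idempotent(self, rng):
        g = rng.choice([-1, 0, 1, 2], size=(60, 12)).astype(np.int8)
        once = vio.apply_frequency_filters(self._gm(g))
        twice = vio.apply_frequency_filters(once)
        assert np.array_equal(once.positions, twice.positions)


class TestSplitPopulations:
    def test_single_population_identity(self, rng):
        gm = random_genotype_matrix(rng, n_sites=10, n_samples=4)
        pm = vio.PopulationMap({s: "TC" for s in gm.samples})
        out = vio.split_populations(gm, pm)
        assert np.array_equal(out["TC"].genotypes, gm.genotypes)

    def test_column_counts(self, rng):
        gm = random_genotype_matrix(rng, n_sites=10, n_samples=5)
        pm = vio.PopulationMap({gm.samples[i]: ("A" if i < 3 else "B")
                                for i in range(5)})
        out = vio.split_populations(gm, pm)
        assert out["A"].n_samples == 3
        assert out["B"].n_samples == 2
        assert out["A"].n_sites == gm.n_sites

    def test_allele_counts_conserved_sitewise(self, rng):
        gm = random_genotype_matrix(rng, n_sites=30, n_samples=8,
                                    missing_rate=0.1)
        pm = vio.PopulationMap({gm.samples[i]: ("A" if i % 2 else "B")
                                for i in range(8)})
        out = vio.split_populations(gm, pm)
        k_meta, n_meta = gm.allele_counts()
        k_sum = sum(out[p].allele_counts()[0] for p in ("A", "B"))
        n_sum = sum(out[p].allele_counts()[1] for p in ("A", "B"))
        assert np.array_equal(k_meta, k_sum)
        assert np.array_equal(n_meta, n_sum)

    def test_unknown_sample_rejected(self, rng):
        gm = random_genotype_matrix(rng, n_sites=5, n_samples=3)
        pm = vio.PopulationMap({**{s: "A" for s in gm.samples}, "ghost": "B"})
        with pytest.raises(ValueError, match="not present"):
            vio.split_populations(gm, pm)

    def test_uncovered_sample_rejected(self, rng):
        gm = random_genotype_matrix(rng, n_sites=5, n_samples=3)
        pm = vio.PopulationMap({gm.samples[0]: "A", gm.samples[1]: "A"})
        with pytest.raises(ValueError, match="missing from popmap"):
            vio.split_populations(gm, pm)
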