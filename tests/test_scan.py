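import numpy as np
import pandas as pd
import pytest

import oracles
from sweepkit import scan


def _window_table(values: dict, n_snps=20, start=1, chrom="chr1"):
    n = len(next(iter(values.values())))
    starts = np.arange(n) * 10_000 + start
    base = {
        "chrom": chrom,
        "start": starts,
        "end": starts + 9_999,
        "n_snps": np.full(n, n_snps),
        "partial": np.zeros(n, dtype=bool),
    }
    base.update(values)
    return pd.DataFrame(base)


class TestFilterWindows:
    def test_nine_snps_excluded_ten_retained(self):
        tab = _window_table({"fst": [0.1, 0.2]})
        tab["n_snps"] = [9, 10]
        out = scan.filter_windows(tab, min_snps=10)
        assert list(out["ranked"]) == [False, True]
        assert len(out) == 2  # retained in output, only flagged

    def test_partial_windows_never_ranked(self):
        tab = _window_table({"fst": [0.1, 0.2]})
        tab.loc[1, "partial"] = True
        out = scan.filter_windows(tab)
        assert not out.loc[1, "ranked"]

    def test_count_matches_brute_recount(self, rng):
        n_snps = rng.integers(0, 30, size=200)
        tab = _window_table({"fst": np.zeros(200)})
        tab["n_snps"] = n_snps
        out = scan.filter_windows(tab, 10)
        assert out["ranked"].sum() == int(np.sum(n_snps >= 10))


class TestEmpiricalThreshold:
    def test_uniform_grid(self):
        vals = np.arange(1, 101, dtype=float)
        thr = scan.empirical_threshold(vals, 0.95)
        assert thr == 95.0
        assert list(vals[vals > thr]) == [96, 97, 98, 99, 100]

    def test_ties_give_zero_outliers(self):
        vals = np.full(50, 3.14)
        thr = scan.empirical_threshold(vals)
        assert np.sum(vals > thr) == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            scan.empirical_threshold(np.arange(19.0))

    def test_matches_sorting_oracle(self, rng):
        for _ in range(50):
            vals = rng.normal(size=int(rng.integers(20, 200)))
            assert scan.empirical_threshold(vals) == pytest.approx(
                oracles.nearest_rank_threshold(vals), abs=1e-15)


class TestOutlierIntersection:
    def _thresholds(self):
        return {"fst": 0.5, "pi_ratio": 2.0, "ihh12": 1.0}

    def test_two_of_three_is_not_a_signal(self):
        tab = _window_table({"fst": [0.9], "pi_ratio": [5.0], "ihh12": [0.5]})
        tab["ranked"] = True
        out = scan.outlier_intersection(tab, self._thresholds())
        assert not out.loc[0, "signal"]

    def test_all_three_required_and_met(self):
        tab = _window_table({"fst": [0.9], "pi_ratio": [5.0], "ihh12": [2.0]})
        tab["ranked"] = True
        out = scan.outlier_intersection(tab, self._thresholds())
        assert out.loc[0, "signal"]

    def test_nan_comparisons_fail(self):
        tab = _window_table({"fst": [0.9], "pi_ratio": [np.nan], "ihh12": [2.0]})
        tab["ranked"] = True
        out = scan.outlier_intersection(tab, self._thresholds())
        assert not out.loc[0, "signal"]

    def test_min_pass_relaxation(self):
        tab = _window_table({"fst": [0.9], "pi_ratio": [5.0], "ihh12": [0.5]})
        tab["ranked"] = True
        out = scan.outlier_intersection(tab, self._thresholds(), min_pass=2)
        assert out.loc[0, "signal"]

    def test_matches_set_intersection_oracle(self, rng):
        n = 100
        tab = _window_table({
            "fst": rng.normal(size=n),
            "pi_ratio": rng.normal(size=n),
            "ihh12": rng.normal(size=n),
        })
        tab["ranked"] = True
        thr = {s: 0.4 for s in scan.STAT_COLUMNS}
        out = scan.outlier_intersection(tab, thr)
        sets = [set(np.flatnonzero(tab[s].to_numpy() > 0.4))
                for s in scan.STAT_COLUMNS]
        assert set(np.flatnonzero(out["signal"])) == sets[0] & sets[1] & sets[2]


class TestMergeRegions:
    def _signals(self, wins, chrom="chr1"):
        starts = np.array([w * 10_000 + 1 for w in wins])
        return pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + 9_999,
            "fst": 0.5, "pi_ratio": 2.0, "ihh12": 1.0, "signal": True,
        })

    def test_adjacent_windows_merge(self):
        regions = scan.merge_regions(self._signals([1, 2]))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (10_001, 29_999 + 1)

    def test_gap_of_one_window_splits(self):
        regions = scan.merge_regions(self._signals([1, 3]))
        assert len(regions) == 2

    def test_matches_interval_union_oracle(self, rng):
        for _ in range(30):
            wins = sorted(rng.choice(np.arange(50), size=12, replace=False))
            regions = scan.merge_regions(self._signals(wins))
            expected = oracles.merge_intervals(
                [(w * 10_000 + 1, w * 10_000 + 10_000) for w in wins])
            assert [(r.start, r.end) for r in regions] == expected

    def test_chromosomes_kept_apart(self):
        a = self._signals([1], chrom="chr1")
        b = self._signals([2], chrom="chr2")
        regions = scan.merge_regions(pd.concat([a, b], ignore_index=True))
        assert len(regions) == 2


class TestAnnotateGenes:
    def _region(self, start, end):
        return scan.SweepRegion("chr1", start, end, 1, {}, {})

    def test_one_bp_overlap_counts(self):
        genes = [scan.GeneFeature("g1", "chr1", 5000, 8000)]
        region = self._region(8000, 12_000)
        scan.annotate_genes([region], genes)
        assert region.genes == ["g1"]

    def test_adjacent_without_overlap_excluded(self):
        genes = [scan.GeneFeature("g1", "chr1", 5000, 7999)]
        region = self._region(8000, 12_000)
        scan.annotate_genes([region], genes)
        assert region.genes == []

    def test_matches_all_pairs_oracle(self, rng):
        genes = []
        raw = []
        for i in range(50):
            s = int(rng.integers(1, 100_000))
            e = s + int(rng.integers(1, 5000))
            genes.append(scan.GeneFeature(f"g{i}", "chr1", s, e))
            raw.append((f"g{i}", "chr1", s, e))
        region = self._region(40_000, 60_000)
        scan.annotate_genes([region], genes)
        assert region.genes == oracles.genes_in_region(raw, "chr1", 40_000, 60_000)

    def test_gene_order_invariance(self, rng):
        genes = [scan.GeneFeature(f"g{i}", "chr1", int(s), int(s) + 1000)
                 for i, s in enumerate(rng.integers(1, 50_000, size=20))]
        region1 = self._region(10_000, 30_000)
        region2 = self._region(10_000, 30_000)
        scan.annotate_genes([region1], genes)
        scan.annotate_genes([region2], genes[::-1])
        assert region1.genes == region2.genes

    def test_gff3_parsing(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=alpha\n"
                       "chr1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=alpha.1\n"
                       "chr2\tsrc\tgene\t300\t400\t.\t-\t.\tID=beta\n")
        genes = scan.read_gene_features(str(gff))
        assert {g.gene_id for g in genes} == {"alpha", "beta"}
        assert all(g.start <= g.end for g in genes)


class TestRunScan:
    def test_end_to_end_on_fixture(self, small_fixture_dir, tmp_path):
        cfg = {
            "vcf": small_fixture_dir["vcf"],
            "popmap": small_fixture_dir["popmap"],
            "gff": small_fixture_dir["gff"],
            "focal": "TC",
            "reference": ["BI"],
            "min_snps": 3,          # small fixture: sparse windows
        }
        out = tmp_path / "scan"
        result = scan.run_scan(cfg, str(out))
        tab = result["windows"]
        assert {"fst", "pi_ratio", "ihh12", "tajima_d", "signal"} <= set(tab.columns)
        assert (out / "windows.tsv").exists()
        assert (out / "manifest.json").exists()
        # signal windows are a subset of ranked windows
        assert (tab.loc[tab["signal"], "ranked"]).all()
        # thresholds recomputed over ranked windows only
        ranked = tab[tab["ranked"]]
        assert result["manifest"]["thresholds"]["fst"] == pytest.approx(
            scan.empirical_threshold(ranked["fst"], 0.95))

    def test_multi_chromosome_thresholds_are_genome_wide(self, tmp_path):
        from sweepkit.simulate import SimParams, simulate
        from sweepkit import variant_io as vio
        from sweepkit.calibration import _as_matrix
        mats = {}
        pm = None
        for i, chrom in enumerate(("chr1", "chr2")):
            params = SimParams(n_anc=40, pop_sizes=(40, 40), split_gens=(15, 15),
                               n_sample=8, seq_len=250_000, mu=6e-6, rec=6e-6,
                               seed=500 + i, burn_in=300, pop_names=("TC", "BI"),
                               chrom=chrom)
            gm, pm = _as_matrix(simulate(params))
            mats[chrom] = gm
        vcf = tmp_path / "two.vcf"
        vio.write_vcf(mats, str(vcf))
        popmap = tmp_path / "popmap.tsv"
        pm.to_file(str(popmap))
        cfg = {"vcf": str(vcf), "popmap": str(popmap), "focal": "TC",
               "reference": ["BI"], "min_snps": 3}
        result = scan.run_scan(cfg, str(tmp_path / "out"))
        tab = result["windows"]
        assert set(tab["chrom"]) == {"chr1", "chr2"}
        # one genome-wide threshold over the pooled ranked windows
        ranked = tab[tab["ranked"]]
        assert result["manifest"]["thresholds"]["fst"] == pytest.approx(
            scan.empirical_threshold(ranked["fst"], 0.95))
        # normalized iHH12 pooled across chromosomes: score-weighted mean ~ 0
        weighted = np.nansum(tab["ihh12"].to_numpy() * tab["n_scored"].to_numpy())
        assert abs(weighted / tab["n_scored"].sum()) < 1e-10

    def test_rerun_byte_identical(self, small_fixture_dir, tmp_path):
        cfg = {
            "vcf": small_fixture_dir["vcf"],
            "popmap": small_fixture_dir["popmap"],
            "focal": "TC",
            "reference": ["BI"],
            "min_snps": 3,
        }
        out1, out2 = tmp_path / "a", tmp_path / "b"
        scan.run_scan(cfg, str(out1))
        scan.run_scan(cfg, str(out2))
        for name in ("windows.tsv", "signal_windows.tsv", "regions.tsv",
                     "regions.bed", "manifest.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
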