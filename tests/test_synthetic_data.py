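"""Simulator: probe designs, planted truth, signal model, engineered resources."""

import math

import numpy as np
import pandas as pd
import pytest

import acghcnv as ac
from acghcnv import io as aio
from acghcnv.annotation import ReferenceDb, dgv_coverage
from acghcnv.cnv_calling import CnvRegion
from acghcnv.synthetic_data import LOG2_RATIO_FLOOR


def one_chrom(length, name="c1"):
    return ac.GenomeModel((ac.Chromosome(name, length, True),))


class TestDesignProbes:
    def test_probe_count_is_floor_of_length_over_spacing(self):
        d = ac.design_probes(one_chrom(1_000_000), 5300, seed=1, jitter_frac=0.0)
        assert d.n_probes == 1_000_000 // 5300 == 188

    def test_short_chromosome_gets_single_probe(self):
        d = ac.design_probes(one_chrom(5), 10, seed=1)
        assert d.n_probes == 1

    def test_mean_spacing_within_5pct_of_target(self):
        d = ac.design_probes(one_chrom(2_000_000), 5300, seed=3)
        assert abs(d.mean_spacing("c1") - 5300) / 5300 < 0.05

    def test_positions_sorted_unique_within_chromosome(self):
        d = ac.design_probes(ac.toy_genome(), 5300, seed=4)
        for chrom, pos in d.starts.items():
            assert np.all(np.diff(pos) > 0)
            assert pos[0] >= 0

    def test_deterministic_for_fixed_seed(self):
        a = ac.design_probes(ac.toy_genome(), 5300, seed=5)
        b = ac.design_probes(ac.toy_genome(), 5300, seed=5)
        for chrom in a.starts:
            assert np.array_equal(a.starts[chrom], b.starts[chrom])

    def test_full_array_preset_reaches_design_probe_count(self):
        d = ac.design_probes(ac.survey_array_genome(), 5300, seed=6)
        assert abs(d.n_probes - 410_739) / 410_739 < 0.01

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            ac.design_probes(one_chrom(1000), 0, seed=1)


class TestPlantTruth:
    @staticmethod
    def spec(freq, n=10, groups=None):
        groups = groups or {"G": n}
        return ac.CohortSpec(
            groups=groups,
            regions=(
                ac.PlantedRegion(
                    "r1", "c1", 1000, 9000, 3, {g: freq for g in groups}
                ),
            ),
        )

    def test_zero_frequency_gives_empty_truth(self):
        t = ac.plant_truth(self.spec(0.0), seed=1)
        assert t.rows.empty
        assert len(t.samples) == 10

    def test_unit_frequency_makes_every_sample_a_carrier(self):
        t = ac.plant_truth(self.spec(1.0, n=39), seed=1)
        assert len(t.rows) == 39

    def test_carrier_count_within_binomial_bounds(self):
        t = ac.plant_truth(self.spec(0.5, n=1000), seed=2)
        sd = math.sqrt(1000 * 0.25)
        assert abs(len(t.rows) - 500) <= 3 * sd

    def test_deterministic_for_fixed_seed(self):
        a = ac.plant_truth(self.spec(0.3, n=50), seed=3)
        b = ac.plant_truth(self.spec(0.3, n=50), seed=3)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_overlapping_regions_for_one_sample_rejected(self):
        spec = ac.CohortSpec(
            groups={"G": 5},
            regions=(
                ac.PlantedRegion("a", "c1", 1000, 9000, 3, {"G": 1.0}),
                ac.PlantedRegion("b", "c1", 5000, 12000, 1, {"G": 1.0}),
            ),
        )
        with pytest.raises(ValueError, match="overlapping"):
            ac.plant_truth(spec, seed=1)


class TestSimulateLog2:
    @staticmethod
    def build(cn, sd=0.0, freq=1.0, n=3):
        genome = one_chrom(500_000)
        spec = ac.CohortSpec(
            groups={"G": n},
            regions=(ac.PlantedRegion("r", "c1", 100_000, 200_000, cn, {"G": freq}),),
        )
        design = ac.design_probes(genome, 5000, seed=1, jitter_frac=0.0)
        truth = ac.plant_truth(spec, seed=2)
        probes = ac.simulate_log2(design, truth, ac.NoiseModel(sd, 0.0), seed=3)
        return design, truth, probes

    @pytest.mark.parametrize(
        "cn,expected",
        [(3, math.log2(1.5)), (1, -1.0), (4, 1.0), (0, LOG2_RATIO_FLOOR)],
    )
    def test_noise_free_signal_is_log2_of_copy_ratio(self, cn, expected):
        design, truth, probes = self.build(cn)
        inside = probes[(probes.start >= 100_000) & (probes.start < 200_000)]
        outside = probes[(probes.start < 100_000) | (probes.start >= 200_000)]
        for s in truth.samples:
            assert np.allclose(inside[s], expected)
            assert np.allclose(outside[s], 0.0)

    def test_null_sample_mean_within_clt_bound(self):
        genome = one_chrom(2_000_000)
        design = ac.design_probes(genome, 5000, seed=1)
        truth = ac.TruthTable(
            samples=("s1",),
            groups={"G": ("s1",)},
            rows=pd.DataFrame(
                columns=["sample", "group", "region", "chrom", "start", "end", "copy_number"]
            ),
        )
        probes = ac.simulate_log2(design, truth, ac.NoiseModel(0.1, 0.0), seed=4)
        n = len(probes)
        assert abs(probes["s1"].mean()) < 4 * 0.1 / math.sqrt(n)

    def test_truth_on_unprobed_chromosome_rejected(self):
        design = ac.design_probes(one_chrom(500_000), 5000, seed=1)
        truth = ac.plant_truth(
            ac.CohortSpec(
                groups={"G": 2},
                regions=(ac.PlantedRegion("r", "cZ", 0, 1000, 3, {"G": 1.0}),),
            ),
            seed=1,
        )
        with pytest.raises(ValueError, match="unprobed"):
            ac.simulate_log2(design, truth, ac.NoiseModel(), seed=1)


class TestReferenceDb:
    def test_engineered_coverage_matches_targets(self, toy_genome):
        regions = (
            ac.PlantedRegion("novel", "chr1", 1_000_000, 1_100_000, 3, {}, 0.0),
            ac.PlantedRegion("rare", "chr2", 2_000_000, 2_080_000, 3, {}, 30.0),
            ac.PlantedRegion("common", "chr3", 3_000_000, 3_120_000, 1, {}, 100.0),
        )
        df = ac.make_reference_db(regions, seed=5, genome_model=toy_genome)
        db = ReferenceDb.from_frame(df)
        covs = [
            dgv_coverage(
                CnvRegion(r.chrom, r.start, r.end, ("s",), 1, "Amplification"), db
            )
            for r in regions
        ]
        assert covs[0] == 0.0
        assert covs[1] == pytest.approx(30.0, abs=0.01)
        assert covs[2] == 100.0

    def test_target_above_100_rejected(self):
        r = ac.PlantedRegion("x", "chr1", 0, 1000, 3, {})
        with pytest.raises(ValueError):
            ac.make_reference_db([r], coverage_targets=[120.0])

    def test_background_records_avoid_planted_regions(self, toy_genome):
        regions = (ac.PlantedRegion("r", "chr1", 5_000_000, 5_100_000, 3, {}, 0.0),)
        df = ac.make_reference_db(regions, seed=6, genome_model=toy_genome, n_background=40)
        hits = df[(df.chrom == "chr1") & (df.start < 5_100_000) & (df.end > 5_000_000)]
        assert hits.empty


@pytest.fixture(scope="module")
def resources(toy_genome):
    spec = ac.default_cohort_spec()
    return spec, ac.make_gene_resources(spec.regions, seed=9, genome_model=toy_genome)


class TestGeneResources:
    def test_every_region_contains_requested_gene_count(self, resources, toy_genome):
        spec, res = resources
        ann = ac.GeneAnnotation.from_frame(res.genes)
        for region in spec.regions:
            found = ac.genes_in_region(
                CnvRegion(region.chrom, region.start, region.end, ("s",), 1, "Amplification"),
                ann,
            )
            assert len(found) == region.n_genes

    def test_disease_list_size_and_planted_invalid_fraction(self, resources):
        _, res = resources
        assert len(res.disease_genes) == 70
        verified = ac.verify_symbols(res.disease_genes, res.valid_symbols)
        assert len(res.disease_genes) - len(verified) == 2

    def test_planted_term_pvalue_matches_exact_enumeration(self, resources):
        spec, res = resources
        region_genes = [g for r in spec.regions for g in res.region_genes[r.name]]
        combined = ac.combined_list(region_genes, res.disease_genes)
        verified = ac.verify_symbols(combined, res.valid_symbols)
        coll = ac.GeneSetCollection.from_gmt(res.gene_sets, res.background)
        results = {r.term_id: r for r in ac.enrich(verified, coll)}
        top = results[res.planted_term_id]
        # independent exact hypergeometric tail with the EASE hit reduction
        from fractions import Fraction
        from math import comb

        n, big_n = top.list_size, top.population_size
        big_k = top.population_hits
        tail = Fraction(0)
        for x in range(top.hits - 1, min(n, big_k) + 1):
            tail += Fraction(comb(big_k, x) * comb(big_n - big_k, n - x), comb(big_n, n))
        assert top.pvalue == pytest.approx(float(tail), rel=1e-12)
        assert top.significant

    def test_single_gene_region(self, toy_genome):
        regions = (ac.PlantedRegion("r", "chr1", 100_000, 200_000, 3, {}, 0.0, n_genes=1),)
        res = ac.make_gene_resources(regions, seed=1, genome_model=toy_genome)
        ann = ac.GeneAnnotation.from_frame(res.genes)
        found = ac.genes_in_region(
            CnvRegion("chr1", 100_000, 200_000, ("s",), 1, "Amplification"), ann
        )
        assert len(found) == 1


class TestRoundTrips:
    def test_probe_matrix_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "probes.tsv"
        aio.write_probe_matrix(small_cohort.probes, path)
        back = aio.read_probe_matrix(path)
        pd.testing.assert_frame_equal(back, small_cohort.probes)

    def test_bed_and_gmt_and_symbols_roundtrip(self, small_cohort, tmp_path):
        res = small_cohort.gene_resources
        aio.write_bed(res.genes, tmp_path / "g.bed")
        back = aio.read_bed(tmp_path / "g.bed")
        pd.testing.assert_frame_equal(back, res.genes)
        aio.write_gmt(res.gene_sets, tmp_path / "s.gmt")
        gback = aio.read_gmt(tmp_path / "s.gmt")
        assert {k: (d, list(m)) for k, (d, m) in gback.items()} == {
            k: (d, list(m)) for k, (d, m) in res.gene_sets.items()
        }
        aio.write_symbol_list(res.disease_genes, tmp_path / "d.txt")
        assert aio.read_symbol_list(tmp_path / "d.txt") == res.disease_genes

    def test_write_cohort_emits_all_artifacts(self, small_cohort, tmp_path):
        paths = ac.write_cohort(small_cohort, tmp_path / "out")
        import os

        assert all(os.path.exists(p) for p in paths.values())

    def test_fixed_seed_cohorts_are_identical(self):
        a = ac.simulate_cohort(seed=33)
        b = ac.simulate_cohort(seed=33)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.reference_db, b.reference_db)
        pd.testing.assert_frame_equal(a.truth.rows, b.truth.rows)
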