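"""Coverage, distances, upstream enrichment, hotspots and density association."""

import numpy as np
import pytest

from teeco.io_formats import GeneAnnotation, GenomeLayout
from teeco.distribution import (
    HotspotWindow,
    call_hotspots,
    compare_distance_modes,
    feature_te_coverage,
    gene_erv_density_association,
    hotspot_gene_content,
    nearest_gene_distances,
    neighbor_divergence_delta,
    sd_confound_check,
    upstream_enrichment,
    upstream_regions,
)

from conftest import mk_te


def gene(gid="g1", chrom="chr1", start=10_000, end=12_000, strand="+", **kw):
    return GeneAnnotation(gene_id=gid, chrom=chrom, start=start, end=end, strand=strand, **kw)


class TestFeatureCoverage:
    def test_cds_coverage_fraction(self, small_layout):
        genes = [gene(start=1000, end=3000, biotype="coding", cds_intervals=((1000, 2000),))]
        anns = [mk_te(start=1500, end=1750)]  # 250 bp inside the 1000 bp CDS
        table, _ = feature_te_coverage(anns, genes, small_layout)
        row = table[(table.feature == "CDS") & (table.te_class == "all")].iloc[0]
        assert row["coverage"] == pytest.approx(0.25)

    def test_te_outside_features_counts_on_chromosome_only(self, small_layout):
        genes = [gene(start=1000, end=3000, biotype="coding", cds_intervals=((1000, 2000),))]
        anns = [mk_te(start=500_000, end=500_100)]
        table, _ = feature_te_coverage(anns, genes, small_layout)
        assert table[(table.feature == "CDS") & (table.te_class == "all")].iloc[0]["coverage"] == 0
        chrom_row = table[(table.feature == "chrom:chr1") & (table.te_class == "all")].iloc[0]
        assert chrom_row["covered_bp"] == 100

    def test_planted_cds_avoidance_maximal_depletion(self):
        layout = GenomeLayout(chromosomes=(("chr1", 200_000),))
        # CDS tile half the chromosome; all TEs sit in the other half
        genes = [
            gene(gid=f"g{i}", start=i * 20_000, end=i * 20_000 + 10_000, biotype="coding",
                 cds_intervals=((i * 20_000, i * 20_000 + 10_000),))
            for i in range(10)
        ]
        anns = [
            mk_te(element_id=i, start=i * 20_000 + 12_000, end=i * 20_000 + 15_000)
            for i in range(10)
        ]
        _, pvals = feature_te_coverage(anns, genes, layout, with_null=True, n_perm=99, seed=4)
        assert pvals["CDS"]["p_depleted"] == pytest.approx(1 / 100)


class TestNearestGene:
    def test_stranded_distance(self):
        genes = [gene(start=10_000, end=12_000, strand="+")]
        anns = [mk_te(start=5000, end=6000, strand="+")]
        df = nearest_gene_distances(anns, genes, mode="stranded")
        assert df.iloc[0]["distance"] == 4000

    def test_overlap_is_zero(self):
        genes = [gene(start=10_000, end=12_000)]
        anns = [mk_te(start=11_000, end=11_500)]
        assert nearest_gene_distances(anns, genes).iloc[0]["distance"] == 0

    def test_missing_when_no_same_strand_gene(self):
        genes = [gene(strand="-")]
        anns = [mk_te(start=5000, end=6000, strand="+")]
        df = nearest_gene_distances(anns, genes, mode="stranded")
        assert np.isnan(df.iloc[0]["distance"])
        # unstranded mode still finds it
        df2 = nearest_gene_distances(anns, genes, mode="unstranded")
        assert df2.iloc[0]["distance"] == 4000

    def test_compare_modes_runs(self, rodentlike_dataset, rodentlike_resolved):
        ervs = [a for a in rodentlike_resolved if a.is_erv]
        res = compare_distance_modes(ervs, rodentlike_dataset.genes)
        assert 0 < res["p"] <= 1
        assert res["median_stranded"] >= res["median_unstranded"]


class TestUpstream:
    def test_region_construction_and_clipping(self, small_layout):
        genes = [gene(start=2000, end=9000, strand="+"), gene(gid="g2", start=998_000, end=999_000, strand="-")]
        regions = upstream_regions(genes, small_layout, window_bp=5000)
        assert ("chr1", "+", 0, 2000, "g1") in regions  # clipped at chromosome start
        assert ("chr1", "-", 999_000, 1_000_000, "g2") in regions  # clipped at end

    def test_same_strand_element_counted(self, small_layout):
        genes = [gene(start=10_000, end=12_000, strand="+")]
        anns = [mk_te(start=6000, end=6500, strand="+", subfamily="E1")]
        res = upstream_enrichment(anns, genes, small_layout, n_perm=50, seed=0)
        assert res[0].observed == 1

    def test_opposite_strand_element_not_counted(self, small_layout):
        genes = [gene(start=10_000, end=12_000, strand="+")]
        anns = [mk_te(start=6000, end=6500, strand="-", subfamily="E1")]
        res = upstream_enrichment(anns, genes, small_layout, n_perm=50, seed=0)
        assert res[0].observed == 0


class TestSDConfound:
    def _setup(self):
        layout = GenomeLayout(chromosomes=(("chr1", 500_000),))
        genes = [gene(gid=f"g{i}", start=50_000 * (i + 1), end=50_000 * (i + 1) + 2000, strand="+")
                 for i in range(8)]
        # each gene has one same-strand element in its upstream window
        anns = [mk_te(element_id=i, start=50_000 * (i + 1) - 3000, end=50_000 * (i + 1) - 2500,
                      strand="+", subfamily="E1") for i in range(8)]
        return layout, genes, anns

    def test_sd_tiling_regions_flagged(self):
        layout, genes, anns = self._setup()
        sds = [("chr1", 50_000 * (i + 1) - 5000, 50_000 * (i + 1)) for i in range(8)]
        res = sd_confound_check(sds, anns, genes, layout, ["E1"], n_perm=99, seed=1)
        assert res[0].p == pytest.approx(1 / 100)
        assert res[0].extra["flagged"]

    def test_zero_sd_not_flagged(self):
        layout, genes, anns = self._setup()
        res = sd_confound_check([], anns, genes, layout, ["E1"], n_perm=99, seed=1)
        assert res[0].p == 1.0 and not res[0].extra["flagged"]


class TestHotspots:
    def test_quantile_threshold_from_known_densities(self):
        layout = GenomeLayout(chromosomes=(("chr1", 1_000_000),))
        anns = [
            mk_te(element_id=i, start=i * 100_000, end=i * 100_000 + i * 10_000)
            for i in range(1, 10)
        ]  # densities 0.0, 0.1, ..., 0.9 across the ten 100-kb windows
        windows = call_hotspots(anns, layout)
        dens = [w.erv_density for w in windows]
        assert dens == pytest.approx([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        # linear-interpolated 95th percentile of these densities is 0.855
        assert float(np.percentile(dens, 95)) == pytest.approx(0.855)
        assert [w.is_hotspot for w in windows] == [False] * 9 + [True]

    def test_uniform_densities_all_flagged(self):
        layout = GenomeLayout(chromosomes=(("chr1", 400_000),))
        anns = [mk_te(element_id=i, start=i * 100_000, end=i * 100_000 + 5000) for i in range(4)]
        windows = call_hotspots(anns, layout)
        assert all(w.is_hotspot for w in windows)  # ties at the threshold all flagged

    def test_empty_annotation_no_hotspots(self, small_layout):
        windows = call_hotspots([], small_layout)
        assert not any(w.is_hotspot for w in windows)

    def test_partial_window_normalised(self):
        layout = GenomeLayout(chromosomes=(("chr1", 250_000),))
        anns = [mk_te(start=225_000, end=250_000)]  # fills half the 50-kb tail window
        windows = call_hotspots(anns, layout)
        assert windows[-1].length == 50_000
        assert windows[-1].erv_density == pytest.approx(0.5)

    def test_density_partition_invariant(self, rodentlike_dataset, rodentlike_resolved):
        from teeco.intervals import merge

        windows = call_hotspots(rodentlike_resolved, rodentlike_dataset.layout)
        for chrom, _ in rodentlike_dataset.layout.chromosomes:
            total = sum(
                round(w.erv_density * w.length) for w in windows if w.chrom == chrom
            )
            erv_bp = sum(
                e - s
                for s, e in merge(
                    (a.start, a.end) for a in rodentlike_resolved if a.is_erv and a.chrom == chrom
                )
            )
            assert total == erv_bp


class TestNeighborDelta:
    def test_delta_values(self):
        anns = [
            mk_te(element_id=0, start=0, end=100, divergence_pct=10.0),
            mk_te(element_id=1, start=200, end=300, divergence_pct=12.0),
            mk_te(element_id=2, start=400, end=500, divergence_pct=20.0),
        ]
        hot = [HotspotWindow("chr1", (0, 1000), 0.5, is_hotspot=True)]
        res = neighbor_divergence_delta(anns, hot)
        assert res["n_inside"] == 2 and res["n_outside"] == 0
        hot_off = [HotspotWindow("chr1", (900, 1000), 0.5, is_hotspot=True)]
        res2 = neighbor_divergence_delta(anns, hot_off)
        assert res2["n_outside"] == 2

    def test_single_element_no_pairs(self):
        res = neighbor_divergence_delta([mk_te()], [])
        assert res["n_inside"] == 0 and res["n_outside"] == 0


class TestDensityAssociation:
    def test_anticorrelated_negative(self):
        windows = [
            HotspotWindow("chr1", (i * 100_000, (i + 1) * 100_000), d, gene_density=0.9 - d)
            for i, d in enumerate(np.linspace(0, 0.8, 20))
        ]
        coef, p = gene_erv_density_association(windows)
        assert coef < 0 and p < 1e-6

    def test_constant_gene_density(self):
        windows = [
            HotspotWindow("chr1", (i * 100_000, (i + 1) * 100_000), d, gene_density=0.3)
            for i, d in enumerate(np.linspace(0, 0.8, 10))
        ]
        assert gene_erv_density_association(windows) == (0.0, 1.0)


class TestHotspotGeneContent:
    def test_all_flagged_inside_small_hotspots(self):
        hot = [HotspotWindow("chr1", (0, 50_000), 0.9, is_hotspot=True)]
        genes = [
            gene(gid=f"k{i}", start=i * 3000, end=i * 3000 + 2000, is_kznf=True,
                 is_lineage_specific=True)
            for i in range(10)
        ] + [
            gene(gid=f"o{i}", start=100_000 + i * 3000, end=100_000 + i * 3000 + 2000)
            for i in range(90)
        ]
        res = hotspot_gene_content(genes, hot)
        assert res.observed == 10
        assert res.p < 1e-6

    def test_zero_flagged_errors(self):
        hot = [HotspotWindow("chr1", (0, 50_000), 0.9, is_hotspot=True)]
        with pytest.raises(ValueError):
            hotspot_gene_content([gene()], hot)
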