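import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from ramscan import (
    COMPARISONS,
    DEGene,
    SpikedWindow,
    TruthTable,
    count_reads,
    random_truth,
    simulate_expression_counts,
    simulate_genome,
    simulate_methylation_reads,
    simulate_sample_sheet,
)


class TestGenomeGenerator:
    def test_seed_determinism_byte_identical(self):
        a = simulate_genome(n_chroms=2, mean_length_bp=100_000, seed=1)
        b = simulate_genome(n_chroms=2, mean_length_bp=100_000, seed=1)
        assert a[0] == b[0]
        for chrom in a[1].cgi:
            np.testing.assert_array_equal(a[1].cgi[chrom], b[1].cgi[chrom])
        for chrom in a[1].repeats:
            np.testing.assert_array_equal(a[1].repeats[chrom], b[1].repeats[chrom])
        pd.testing.assert_frame_equal(a[1].genes, b[1].genes)

    def test_zero_repeat_fraction_empty_track(self):
        _, track = simulate_genome(n_chroms=1, mean_length_bp=50_000, repeat_fraction=0.0, seed=2)
        assert track.repeats == {}

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"mean_length_bp": 500}, "mean_length_bp"),
            ({"cgi_density": -1.0}, "cgi_density"),
            ({"gene_density": -0.1}, "gene_density"),
            ({"repeat_fraction": -0.5}, "repeat_fraction"),
        ],
    )
    def test_parameter_errors_name_the_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            simulate_genome(**kwargs)

    def test_cgi_counts_poisson_distributed(self):
        """Over 200 seeds, the total CGI count matches its Poisson law
        (intensity = density * realized chromosome length) within the
        central 99% interval."""
        density = 5e-5  # expectation 50 per Mb
        total, expected = 0, 0.0
        for seed in range(200):
            genome, track = simulate_genome(
                n_chroms=1, mean_length_bp=1_000_000, cgi_density=density,
                gene_density=0.0, repeat_fraction=0.0, seed=seed,
            )
            total += sum(len(iv) for iv in track.cgi.values())
            expected += density * genome.chrom_lengths[0]
        lo, hi = poisson.ppf([0.005, 0.995], expected)
        assert lo <= total <= hi

    def test_tracks_within_bounds_and_nonoverlapping(self):
        genome, track = simulate_genome(n_chroms=1, mean_length_bp=200_000, seed=3)
        L = genome.chrom_lengths[0]
        for iv in track.cgi.values():
            assert (iv[:, 0] < iv[:, 1]).all() and iv[0, 0] >= 0 and iv[-1, 1] <= L
            assert (iv[1:, 0] >= iv[:-1, 1]).all()  # merged, non-overlapping
        for _, g in track.genes.iterrows():
            assert 0 <= g["start"] < g["end"] <= L


class TestMethylationReads:
    @staticmethod
    def small_setup(seed, **genome_kw):
        genome, track = simulate_genome(
            n_chroms=1, mean_length_bp=30_000, cgi_density=0.0,
            gene_density=0.0, repeat_fraction=0.0, seed=seed, **genome_kw,
        )
        sheet = simulate_sample_sheet(6, seed=seed)
        return genome, track, sheet

    def test_seed_determinism(self):
        genome, track, sheet = self.small_setup(4)
        r1 = simulate_methylation_reads(genome, track, sheet, 10_000, seed=9)
        r2 = simulate_methylation_reads(genome, track, sheet, 10_000, seed=9)
        for sid in r1:
            pd.testing.assert_frame_equal(r1[sid], r2[sid])

    def test_adding_samples_does_not_perturb_existing(self):
        genome, track, _ = self.small_setup(4)
        sheet = simulate_sample_sheet(6, seed=4)
        r_all = simulate_methylation_reads(genome, track, sheet, 10_000, seed=9)
        r_sub = simulate_methylation_reads(genome, track, sheet.iloc[:4], 10_000, seed=9)
        for sid in r_sub:
            pd.testing.assert_frame_equal(r_all[sid], r_sub[sid])

    def test_poisson_at_zero_dispersion(self):
        """With dispersion 0 and a flat genome, window counts are Poisson:
        index of dispersion near 1 over >= 2000 windows."""
        genome, track = simulate_genome(
            n_chroms=1, mean_length_bp=110_000, cgi_density=0.0,
            gene_density=0.0, repeat_fraction=0.0, seed=6,
        )
        sheet = simulate_sample_sheet(1, seed=6).iloc[:1]
        n_cells = -(-genome.chrom_lengths[0] // 50)
        reads = simulate_methylation_reads(
            genome, track, sheet, depth_per_sample=25 * n_cells,
            cgi_enrichment_factor=1.0, dispersion=0.0, seed=6,
        )
        cm = count_reads(genome, reads)
        counts = cm.counts[:-1, 0]  # drop the truncated terminal window
        assert len(counts) >= 2000
        iod = counts.var(ddof=1) / counts.mean()
        assert 0.9 <= iod <= 1.1

    def test_female_y_reads_zero_by_default(self):
        genome, track, sheet = self.small_setup(7, )
        genome, track = simulate_genome(
            n_chroms=1, mean_length_bp=30_000, cgi_density=0.0,
            gene_density=0.0, repeat_fraction=0.0, seed=7, sex_chroms=True,
        )
        reads = simulate_methylation_reads(genome, track, sheet, 20_000, seed=7)
        sex = sheet.set_index("id")["sex"]
        for sid, df in reads.items():
            n_y = (df["chrom"] == "chrY").sum()
            if sex[sid] == "female":
                assert n_y == 0
            else:
                assert n_y > 0

    def test_cgi_enrichment_elevates_island_density(self):
        genome, track = simulate_genome(
            n_chroms=1, mean_length_bp=100_000, cgi_density=2e-4,
            gene_density=0.0, repeat_fraction=0.0, seed=8,
        )
        sheet = simulate_sample_sheet(1, seed=8).iloc[:1]
        reads = simulate_methylation_reads(
            genome, track, sheet, 200_000, cgi_enrichment_factor=5.0, dispersion=0.0, seed=8
        )
        df = reads[sheet["id"].iloc[0]]
        iv = track.cgi["chr1"]
        in_cgi = np.zeros(len(df), dtype=bool)
        for a, b in iv:
            in_cgi |= (df["start"] >= a) & (df["start"] < b)
        cgi_len = (iv[:, 1] - iv[:, 0]).sum()
        L = genome.chrom_lengths[0]
        density_ratio = (in_cgi.mean() / (cgi_len / L))
        assert density_ratio > 2.5  # well above uniform

    def test_spiked_fold_change_realized(self):
        """A +2 log2FC spike yields a ~4x ratio of group mean counts
        (averaged over 100 simulation replicates, 6 vs 6, mean >= 50)."""
        genome, track, sheet = self.small_setup(10)
        n_cells = -(-genome.chrom_lengths[0] // 50)
        win = SpikedWindow("chr1", 10_000, 10_100, 2.0, "nd_vs_high")
        truth = TruthTable(spiked_windows=[win])
        groups = sheet.set_index("id")["group"]
        ratios = []
        for rep in range(100):
            reads = simulate_methylation_reads(
                genome, track, sheet, depth_per_sample=25 * n_cells,
                cgi_enrichment_factor=1.0, truth=truth, dispersion=0.1, seed=1000 + rep,
            )
            cm = count_reads(genome, reads)
            row = cm.counts[(cm.windows["start"] == 10_000).to_numpy()][0]
            high = [c for c, s in zip(row, cm.samples) if groups[s] == "high"]
            nd = [c for c, s in zip(row, cm.samples) if groups[s] == "non_detect"]
            ratios.append(np.mean(high) / np.mean(nd))
        assert 3.2 <= np.mean(ratios) <= 5.0

    def test_truth_outside_genome_rejected(self):
        genome, track, sheet = self.small_setup(11)
        truth = TruthTable(
            spiked_windows=[SpikedWindow("chr1", 10**9, 10**9 + 100, 2.0, "nd_vs_high")]
        )
        with pytest.raises(ValueError, match="bounds"):
            simulate_methylation_reads(genome, track, sheet, 1000, truth=truth, seed=0)

    @pytest.mark.parametrize(
        "kwargs", [{"depth_per_sample": 0}, {"dispersion": -0.1}]
    )
    def test_parameter_errors(self, kwargs):
        genome, track, sheet = self.small_setup(12)
        with pytest.raises(ValueError):
            simulate_methylation_reads(genome, track, sheet, **{"depth_per_sample": 1000, **kwargs})


class TestExpressionCounts:
    GENES = pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(1000)]})

    def test_null_genes_have_no_group_shift(self):
        """With empty truth, large group-mean log2 ratios are rare."""
        sheet = simulate_sample_sheet(6, seed=20)
        counts = simulate_expression_counts(
            self.GENES, sheet, baseline_mean=500, dispersion=0.01, seed=20
        )
        groups = sheet.set_index("id")["group"]
        hi = counts.loc[:, [s for s in counts if groups[s] == "high"]].mean(axis=1)
        nd = counts.loc[:, [s for s in counts if groups[s] == "non_detect"]].mean(axis=1)
        ratio = np.log2(hi / nd)
        assert (np.abs(ratio) > 0.5).mean() <= 0.01

    def test_coupled_gene_moves_opposite_to_hyper_ram(self):
        sheet = simulate_sample_sheet(6, seed=21)
        truth = TruthTable(
            spiked_windows=[SpikedWindow("chr1", 0, 100, 2.0, "nd_vs_high")],
            de_genes=[DEGene("g0000", -1.5, "nd_vs_high")],
            coupling={("chr1", 0, 100): "g0000"},
        )
        counts = simulate_expression_counts(
            self.GENES, sheet, truth, baseline_mean=200, dispersion=0.05, seed=21
        )
        groups = sheet.set_index("id")["group"]
        hi = counts.loc["g0000", [s for s in counts if groups[s] == "high"]].mean()
        nd = counts.loc["g0000", [s for s in counts if groups[s] == "non_detect"]].mean()
        assert hi < nd

    def test_seed_determinism(self):
        sheet = simulate_sample_sheet(2, seed=22)
        a = simulate_expression_counts(self.GENES.iloc[:50], sheet, seed=5)
        b = simulate_expression_counts(self.GENES.iloc[:50], sheet, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_truth_gene_rejected(self):
        sheet = simulate_sample_sheet(2, seed=23)
        truth = TruthTable(de_genes=[DEGene("nope", 1.0, "nd_vs_high")])
        with pytest.raises(KeyError):
            simulate_expression_counts(self.GENES.iloc[:10], sheet, truth, seed=0)


class TestTruth:
    def test_sample_sheet_trichotomized_and_sexed(self):
        sheet = simulate_sample_sheet(6, seed=30)
        assert len(sheet) == 18 and sheet["id"].is_unique
        assert set(sheet["group"]) == {"non_detect", "low", "high"}
        assert (sheet.groupby("group")["sex"].value_counts() == 3).all()

    def test_random_truth_windows_align_to_grid_and_bounds(self):
        genome, track = simulate_genome(n_chroms=2, mean_length_bp=200_000, seed=31)
        truth = random_truth(genome, n_spikes=15, windows_per_spike=3, seed=31)
        truth.validate(genome)
        assert len(truth.spiked_windows) == 45
        for w in truth.spiked_windows:
            assert w.start % 50 == 0 and w.end - w.start == 100

    def test_spiked_regions_merge_consecutive_windows(self):
        genome, _ = simulate_genome(n_chroms=1, mean_length_bp=100_000, seed=32)
        truth = random_truth(genome, n_spikes=5, windows_per_spike=4, seed=32)
        regions = truth.spiked_regions()
        assert len(regions) == 5
        assert all(r.end - r.start == 100 + 3 * 50 for r in regions)

    def test_coupling_signs_opposed(self):
        genome, track = simulate_genome(
            n_chroms=1, mean_length_bp=300_000, gene_density=5e-5, seed=33
        )
        truth = random_truth(
            genome, n_spikes=10, annotations=track, couple_fraction=1.0, seed=33
        )
        meth = {v: k for k, v in truth.coupling.items()}
        spikes = {(w.chrom, w.start): w for w in truth.spiked_windows}
        for dg in truth.de_genes:
            chrom, s, e = meth[dg.gene_id]
            region_sign = np.sign([w.log2fc for w in truth.spiked_windows if w.chrom == chrom and s <= w.start < e][0])
            assert np.sign(dg.log2fc) == -region_sign
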