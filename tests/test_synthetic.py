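"""Generator contracts: grid geometry, planted truth, noise models,
determinism, and bit-exact file round trips."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import damidpipe as dp
from damidpipe.arrays import PROBE_TABLE_COLUMNS, read_probe_table, write_probe_table
from damidpipe.synthetic import (
    domain_probe_mask,
    read_expression,
    read_fasta,
    simulate_background_sequences,
    simulate_survival_table,
    write_expression,
    write_fasta,
)


def cfg(**kw) -> dp.SyntheticConfig:
    base = dict(seed=1, n_chromosomes=1, chromosome_length=3000, probe_spacing=300,
                probe_length=50, n_domains=0, n_peaks=0)
    base.update(kw)
    return dp.SyntheticConfig(**base)


class TestProbeGrid:
    def test_fixed_spacing_tiling(self):
        grid = dp.make_probe_grid(cfg())
        assert len(grid) == 10
        assert list(grid["start"]) == list(range(0, 3000, 300))
        assert (grid["end"] - grid["start"] == 50).all()

    def test_chromosome_shorter_than_spacing_is_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no probes"):
            grid = dp.make_probe_grid(cfg(chromosome_length=299))
        assert len(grid) == 0

    def test_same_seed_same_grid(self):
        a = dp.make_probe_grid(cfg(n_chromosomes=2, chromosome_length=100_000))
        b = dp.make_probe_grid(cfg(n_chromosomes=2, chromosome_length=100_000))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError, match="probe_spacing"):
            dp.make_probe_grid(dataclasses.replace(cfg(), probe_spacing=0))


class TestPlantDomains:
    def test_no_domains_gives_empty_truth(self):
        truth = dp.plant_domains(cfg(), dp.make_probe_grid(cfg()))
        assert truth.true_domains.empty and truth.true_peaks.empty

    def test_fifty_domains_pairwise_disjoint_by_brute_force(self):
        c = cfg(chromosome_length=10_000_000, n_domains=50,
                domain_length_range=(2000, 10000), min_domain_gap_probes=20)
        truth = dp.plant_domains(c, dp.make_probe_grid(c))
        d = truth.true_domains
        assert len(d) == 50
        rows = d.to_dict("records")
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                if a["chrom"] == b["chrom"]:
                    assert a["end"] <= b["start"] or b["end"] <= a["start"]

    def test_fixed_seed_reproducible_placement(self):
        c = cfg(chromosome_length=1_000_000, n_domains=5, domain_length_range=(2000, 5000))
        t1 = dp.plant_domains(c, dp.make_probe_grid(c))
        t2 = dp.plant_domains(c, dp.make_probe_grid(c))
        pd.testing.assert_frame_equal(t1.true_domains, t2.true_domains)

    def test_impossible_placement_reports_achieved_count(self):
        c = cfg(chromosome_length=200_000, n_domains=50, domain_length_range=(20000, 30000))
        with pytest.raises(ValueError, match=r"place \d+ of 50"):
            dp.plant_domains(c, dp.make_probe_grid(c))

    def test_domains_snap_to_probe_boundaries(self):
        c = cfg(chromosome_length=2_000_000, n_domains=10, domain_length_range=(2000, 8000))
        grid = dp.make_probe_grid(c)
        truth = dp.plant_domains(c, grid)
        assert truth.true_domains["start"].isin(grid["start"]).all()
        assert truth.true_domains["end"].isin(grid["end"]).all()


class TestDamidArrays:
    def base(self, **kw):
        defaults = dict(chromosome_length=2_000_000, n_domains=6, n_peaks=0,
                        domain_length_range=(5000, 15000), noise_sd=0.0,
                        intensity_bias_amplitude=0.0, abundance_sd=0.0)
        defaults.update(kw)
        return cfg(**defaults)

    def test_noise_free_ratio_equals_planted_effect(self):
        c = self.base(domain_effect=1.0)
        grid = dp.make_probe_grid(c)
        truth = dp.plant_domains(c, grid)
        sample = dp.simulate_damid_arrays(c, grid, truth)[0]
        track = dp.compute_log_ratio(sample, dp.NormalizationParams(pseudocount=0.0))
        mask = domain_probe_mask(grid, truth.true_domains)
        np.testing.assert_allclose(track.probes["M"][mask], 1.0, atol=1e-12)
        np.testing.assert_allclose(track.probes["M"][~mask], 0.0, atol=1e-12)

    def test_dye_swap_raw_ratio_is_negation(self):
        c = self.base()
        grid = dp.make_probe_grid(c)
        truth = dp.plant_domains(c, grid)
        samples = {s.sample_id: s for s in dp.simulate_damid_arrays(c, grid, truth)}
        raw = lambda s: np.log2(s.probes["intensity_fusion"] / s.probes["intensity_control"])
        np.testing.assert_allclose(
            raw(samples["rep1_dyeswap"]), -raw(samples["rep1"]), atol=1e-9
        )

    def test_null_track_mean_within_clt_bound(self):
        c = cfg(chromosome_length=10_000_000, noise_sd=0.2,
                intensity_bias_amplitude=0.0, abundance_sd=0.0)
        grid = dp.make_probe_grid(c)
        sample = dp.simulate_damid_arrays(c, grid, dp.TruthSet())[0]
        m = dp.compute_log_ratio(sample, dp.NormalizationParams(pseudocount=0.0)).probes["M"]
        assert abs(m.mean()) < 3 * 0.2 / np.sqrt(len(m))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            self.base(noise_sd=-0.1)

    def test_replicate_structure(self):
        c = self.base()
        samples = dp.simulate_damid_arrays(c, dp.make_probe_grid(c),
                                           dp.plant_domains(c, dp.make_probe_grid(c)))
        assert [s.dye_swapped for s in samples] == [False, False, True]

    def test_peak_probes_carry_peak_effect(self):
        c = self.base(n_peaks=4, peak_effect=2.0)
        grid = dp.make_probe_grid(c)
        truth = dp.plant_domains(c, grid)
        track = dp.compute_log_ratio(
            dp.simulate_damid_arrays(c, grid, truth)[0],
            dp.NormalizationParams(pseudocount=0.0),
        )
        peak_mask = domain_probe_mask(grid, truth.true_peaks)
        assert peak_mask.sum() > 0
        np.testing.assert_allclose(track.probes["M"][peak_mask], 2.0, atol=1e-12)


class TestExpression:
    def genes(self, c):
        grid = dp.make_probe_grid(c)
        truth = dp.plant_domains(c, grid)
        return dp.plant_genes(c, grid, truth)

    def test_zero_noise_group_difference_is_planted_fold_change(self):
        c = cfg(chromosome_length=4_000_000, n_domains=10, n_peaks=0,
                domain_length_range=(5000, 15000), n_genes=60, n_indirect_de=10,
                expr_noise_sd=0.0)
        genes, truth = self.genes(c)
        matrix, groups = dp.simulate_expression(c, truth, genes)
        diff = (
            matrix.loc[:, groups == "knockdown"].mean(axis=1)
            - matrix.loc[:, groups == "control"].mean(axis=1)
        )
        planted = dict(zip(truth.true_de_genes["gene"], truth.true_de_genes["log2fc"]))
        for gene, d in diff.items():
            assert d == pytest.approx(planted.get(gene, 0.0), abs=1e-12)

    def test_indirect_de_genes_are_unlinked_and_directions_mixed(self):
        c = cfg(chromosome_length=6_000_000, n_domains=20, n_peaks=0,
                domain_length_range=(5000, 15000), n_genes=200, n_indirect_de=40)
        _, truth = self.genes(c)
        de = truth.true_de_genes
        linked = de[de["linked_domain"].notna()]
        assert len(linked) == round(0.8 * 20)
        assert set(np.sign(de["log2fc"])) == {-1.0, 1.0}

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="n_expr_replicates"):
            cfg(n_expr_replicates=1)

    def test_fixed_seed_reproducible(self):
        c = cfg(chromosome_length=3_000_000, n_domains=5, n_peaks=0,
                domain_length_range=(5000, 15000), n_genes=50, n_indirect_de=5)
        g1, t1 = self.genes(c)
        m1, _ = dp.simulate_expression(c, t1, g1)
        g2, t2 = self.genes(c)
        m2, _ = dp.simulate_expression(c, t2, g2)
        pd.testing.assert_frame_equal(m1, m2)


class TestSequencesAndPhenotypes:
    def test_six_thousand_background_sequences_in_length_range(self):
        records = simulate_background_sequences(6000, (2000, 5000), seed=4)
        assert len(records) == 6000
        lengths = np.array([len(r.seq) for r in records])
        assert lengths.min() >= 2000 and lengths.max() <= 5000

    def test_zero_sequences_round_trip_empty_fasta(self, tmp_path):
        path = tmp_path / "empty.fasta"
        write_fasta(simulate_background_sequences(0, (2000, 5000)), path)
        assert read_fasta(path) == []

    def test_gc_zero_means_at_only(self):
        records = simulate_background_sequences(5, (100, 200), gc=0.0, seed=2)
        assert all(set(str(r.seq)) <= {"A", "T"} for r in records)

    def test_gc_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="gc"):
            simulate_background_sequences(1, (100, 200), gc=1.5)

    @pytest.mark.parametrize(
        "p,expected", [(0.0, 0), (1.0, 1000)], ids=["never", "always"]
    )
    def test_degenerate_event_probabilities(self, p, expected):
        counts = dp.simulate_phenotype_counts([("g", 1000, p)], seed=0)
        assert counts["events"].iloc[0] == expected

    def test_binomial_counts_within_clt_bound(self):
        counts = dp.simulate_phenotype_counts([("g", 10000, 0.5)], seed=5)
        assert abs(counts["events"].iloc[0] - 5000) <= 3 * np.sqrt(10000 * 0.25)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            dp.simulate_phenotype_counts([("g", -1, 0.5)])

    def test_survival_days_positive_and_reproducible(self):
        t1 = simulate_survival_table([("a", 50, 20.0, 5.0)], seed=9)
        t2 = simulate_survival_table([("a", 50, 20.0, 5.0)], seed=9)
        assert (t1["day"] >= 1).all()
        pd.testing.assert_frame_equal(t1, t2)


class TestRoundTrips:
    def test_probe_table_round_trips_bit_exactly(self, tmp_path):
        c = cfg(chromosome_length=500_000, n_domains=3, n_peaks=0,
                domain_length_range=(2000, 5000))
        grid = dp.make_probe_grid(c)
        sample = dp.simulate_damid_arrays(c, grid, dp.plant_domains(c, grid))[0]
        path = tmp_path / "probes.tsv"
        write_probe_table(sample, path)
        again = read_probe_table(path, sample_id=sample.sample_id)
        pd.testing.assert_frame_equal(again.probes[PROBE_TABLE_COLUMNS],
                                      sample.probes[PROBE_TABLE_COLUMNS])

    def test_expression_round_trips(self, tmp_path):
        c = cfg(chromosome_length=2_000_000, n_domains=4, n_peaks=0,
                domain_length_range=(5000, 10000), n_genes=30, n_indirect_de=4)
        grid = dp.make_probe_grid(c)
        genes, truth = dp.plant_genes(c, grid, dp.plant_domains(c, grid))
        matrix, groups = dp.simulate_expression(c, truth, genes)
        write_expression(matrix, groups, tmp_path / "m.csv", tmp_path / "g.csv")
        m2, g2 = read_expression(tmp_path / "m.csv", tmp_path / "g.csv")
        pd.testing.assert_frame_equal(matrix, m2)
        pd.testing.assert_series_equal(groups.rename_axis("sample"), g2)

    def test_fasta_round_trips(self, tmp_path):
        records = simulate_background_sequences(10, (50, 100), seed=1)
        write_fasta(records, tmp_path / "s.fasta")
        again = read_fasta(tmp_path / "s.fasta")
        assert [str(r.seq) for r in again] == [str(r.seq) for r in records]
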