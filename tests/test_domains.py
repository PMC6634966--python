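"""Edge filter, transition calling, domain assembly, and the peak caller."""

import numpy as np
import pandas as pd
import pytest

import damidpipe as dp
from conftest import make_track, truth_interval_set


def small_params(**kw):
    base = dict(window_probes=3, edge_threshold=0.3, min_positive_fraction=0.70,
                min_probes_per_domain=2)
    base.update(kw)
    return dp.DomainCallParams(**base)


class TestEdgeScore:
    def test_hand_computed_step_window_three(self):
        track = make_track([0, 0, 0, 1, 1, 1])
        e = dp.edge_score(track, small_params())
        # difference of flanking one-probe means, undefined at the ends
        expected = [np.nan, 0.0, 1.0, 1.0, 0.0, np.nan]
        np.testing.assert_allclose(e.to_numpy(), expected)

    def test_constant_track_scores_zero(self):
        e = dp.edge_score(make_track([0.4] * 50), small_params())
        interior = e.to_numpy()[1:-1]
        np.testing.assert_allclose(interior, 0.0)
        assert np.isnan(e.iloc[0]) and np.isnan(e.iloc[-1])

    def test_step_height_recovered_by_brute_force(self):
        rng = np.random.default_rng(0)
        delta = 0.8
        values = np.concatenate([np.zeros(250), np.full(250, delta)])
        params = dp.DomainCallParams(window_probes=21)
        track = make_track(values)
        e = dp.edge_score(track, params).to_numpy()
        h = params.half_window
        brute = np.full(500, np.nan)
        for i in range(h, 500 - h):
            brute[i] = values[i + 1 : i + h + 1].mean() - values[i - h : i].mean()
        np.testing.assert_allclose(e, brute, equal_nan=True)
        assert np.nanmax(np.abs(e)) == pytest.approx(delta)
        assert int(np.nanargmax(np.abs(e))) in (249, 250)

    def test_short_chromosome_all_undefined_with_warning(self):
        track = make_track([0.0] * 5)
        with pytest.warns(UserWarning, match="fewer than"):
            e = dp.edge_score(track, dp.DomainCallParams(window_probes=7))
        assert e.isna().all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            dp.DomainCallParams(window_probes=200)


class TestCallTransitions:
    def test_flat_track_has_no_transitions(self):
        track = make_track([0.2] * 100)
        scores = dp.edge_score(track, small_params())
        assert dp.call_transitions(track, scores, small_params()).empty

    def test_single_step_gives_one_up_transition(self):
        track = make_track([0.0] * 50 + [1.0] * 50)
        params = dp.DomainCallParams(window_probes=11)
        scores = dp.edge_score(track, params)
        trans = dp.call_transitions(track, scores, params)
        assert len(trans) == 1
        assert trans["sign"].iloc[0] == "up"
        assert trans["index"].iloc[0] == 49  # last probe before the step (leftmost tie)

    def test_subthreshold_step_ignored(self):
        track = make_track([0.0] * 50 + [0.2] * 50)
        params = dp.DomainCallParams(window_probes=11, edge_threshold=0.3)
        scores = dp.edge_score(track, params)
        assert dp.call_transitions(track, scores, params).empty

    def test_mirrored_track_swaps_transition_signs(self, small_run):
        _, _, combined, _, _ = small_run
        params = dp.DomainCallParams()
        up_down = dp.call_transitions(combined, dp.edge_score(combined, params), params)
        mirrored = dp.ProbeTrack(combined.probes.assign(M_norm=-combined.probes["M_norm"]),
                                 "mirrored")
        down_up = dp.call_transitions(mirrored, dp.edge_score(mirrored, params), params)
        assert (up_down["sign"] == "up").sum() == (down_up["sign"] == "down").sum()
        assert (up_down["sign"] == "down").sum() == (down_up["sign"] == "up").sum()
        np.testing.assert_array_equal(up_down["index"], down_up["index"])


class TestAssembleDomains:
    def test_hand_example_closes_at_chromosome_end(self):
        track = make_track([0, 0, 0, 1, 1, 1], spacing=300)
        params = small_params()
        scores = dp.edge_score(track, params)
        trans = dp.call_transitions(track, scores, params)
        domains, diag = dp.assemble_domains(trans, track, params)
        assert len(domains) == 1
        rec = domains.records.iloc[0]
        assert rec["start"] == 3 * 300 and rec["end"] == 5 * 300 + 150
        assert rec["positive_fraction"] == 1.0
        assert diag["end_closed"] == 1

    def test_sixty_percent_positive_candidate_rejected(self):
        # zero-valued probes are non-positive but do not attract boundary
        # refinement, so the 70% rule is exercised on the full span
        pattern = [1, 0, 1, 0, 1, 0, 1, 0, 1, 1]
        values = [-0.5] * 5 + pattern + [-0.5] * 5
        track = make_track(values)
        trans = pd.DataFrame(
            [{"chrom": "chr1", "index": 4, "sign": "up", "score": 1.0},
             {"chrom": "chr1", "index": 14, "sign": "down", "score": -1.0}]
        )
        domains, diag = dp.assemble_domains(trans, track, small_params(min_probes_per_domain=3))
        assert len(domains) == 0
        assert diag["dropped_positive_fraction"] == 1

    def test_seventy_percent_positive_candidate_kept(self):
        pattern = [1, 0, 1, 1, 0, 1, 0, 1, 1, 1]  # 7/10 positive
        values = [-0.5] * 5 + pattern + [-0.5] * 5
        track = make_track(values)
        trans = pd.DataFrame(
            [{"chrom": "chr1", "index": 4, "sign": "up", "score": 1.0},
             {"chrom": "chr1", "index": 14, "sign": "down", "score": -1.0}]
        )
        domains, _ = dp.assemble_domains(trans, track, small_params(min_probes_per_domain=3))
        assert len(domains) == 1
        assert domains.records["positive_fraction"].iloc[0] == pytest.approx(0.7)

    def test_leading_down_without_end_closure_dropped(self):
        track = make_track([1.0] * 5 + [-0.5] * 10)
        trans = pd.DataFrame([{"chrom": "chr1", "index": 5, "sign": "down", "score": -1.0}])
        domains, diag = dp.assemble_domains(
            trans, track, small_params(close_at_chromosome_ends=False)
        )
        assert len(domains) == 0 and diag["dropped_unpaired"] == 1
        domains, diag = dp.assemble_domains(trans, track, small_params())
        assert len(domains) == 1 and diag["end_closed"] == 1

    def test_noise_free_pipeline_recovers_planted_domains_exactly(self, noise_free_run):
        _, truth, _, domains, _ = noise_free_run
        td = truth.true_domains
        cd = domains.records
        assert len(cd) == len(td)
        np.testing.assert_array_equal(cd["start"].to_numpy(), td["start"].to_numpy())
        np.testing.assert_array_equal(cd["end"].to_numpy(), td["end"].to_numpy())

    def test_called_domains_never_overlap(self, small_run):
        _, _, _, domains, _ = small_run
        domains.assert_disjoint()

    def test_mirrored_track_yields_zero_domains(self, small_run):
        _, _, combined, _, _ = small_run
        mirrored = dp.ProbeTrack(combined.probes.assign(M_norm=-combined.probes["M_norm"]),
                                 "mirrored")
        domains, _ = dp.call_domains(mirrored)
        assert len(domains) == 0

    def test_offset_invariance_through_median_fallback(self, noise_free_run):
        """Adding a constant to raw M and re-normalizing (median fallback
        path, A constant) leaves the called domains unchanged."""
        _, _, combined, domains, _ = noise_free_run
        shifted = combined.probes.copy()
        shifted["M"] = shifted["M_norm"] + 5.0
        shifted["A"] = 10.0
        with pytest.warns(UserWarning, match="median"):
            renorm = dp.loess_normalize(dp.ProbeTrack(shifted, "shifted"))
        redomains, _ = dp.call_domains(renorm)
        pd.testing.assert_frame_equal(
            redomains.records[["chrom", "start", "end"]],
            domains.records[["chrom", "start", "end"]],
        )


class TestRecoveryUnderNoise:
    def test_f1_and_boundary_error_on_default_conditions(self):
        cfg = dp.SyntheticConfig(seed=42)
        from conftest import array_pipeline

        _, truth, _, domains, _ = array_pipeline(cfg)
        metrics = dp.recovery_metrics(domains, truth_interval_set(truth), cfg.probe_spacing)
        assert metrics["f1"] >= 0.9
        assert metrics["mean_boundary_error_probes"] <= 5


class TestCallPeaks:
    def test_constant_track_has_no_peaks(self):
        peaks = dp.call_peaks(make_track([0.5] * 100))
        assert len(peaks) == 0

    def test_three_probe_spike_called_exactly(self):
        values = np.zeros(1000)
        values[500:503] = 2.0
        peaks = dp.call_peaks(make_track(values))
        assert len(peaks) == 1
        rec = peaks.records.iloc[0]
        assert rec["start"] == 500 * 100 and rec["end"] == 502 * 100 + 50
        assert rec["n_probes"] == 3

    def test_single_probe_spike_below_min_run_ignored(self):
        values = np.zeros(1000)
        values[500] = 2.0
        peaks = dp.call_peaks(make_track(values), dp.DomainCallParams(peak_min_run=2))
        assert len(peaks) == 0

    def test_runs_inside_domains_excluded(self):
        values = np.zeros(1000)
        values[100:150] = 1.0  # a domain
        values[120:123] = 2.0  # spike inside it
        values[700:703] = 2.0  # isolated spike
        track = make_track(values)
        domains = dp.IntervalSet(
            pd.DataFrame(
                [{"chrom": "chr1", "start": 100 * 100, "end": 149 * 100 + 50,
                  "name": "d0", "score": 1.0}]
            )
        )
        peaks = dp.call_peaks(track, exclude=domains)
        assert len(peaks) == 1
        assert peaks.records["start"].iloc[0] == 700 * 100

    def test_planted_multiprobe_peaks_recovered(self, small_run):
        _, truth, combined, domains, _ = small_run
        peaks = dp.call_peaks(combined, exclude=domains)
        wide = truth.true_peaks[truth.true_peaks["i_end"] > truth.true_peaks["i_start"]]
        hits = 0
        for _, p in peaks.records.iterrows():
            ov = (
                (wide["chrom"] == p["chrom"])
                & (wide["start"] < p["end"])
                & (wide["end"] > p["start"])
            )
            hits += int(ov.any())
        assert hits == len(wide)
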