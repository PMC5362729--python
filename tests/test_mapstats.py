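"""Charge-window Z scores, probability maps, and cross-cell summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from lspsmap.trace import Trace, DegenerateMapError
from lspsmap.synthdata import (CircuitConfig, StimGrid, Population,
                               generate_hex_grid, simulate_circuit,
                               simulate_map_recording, ipsc_kernel, _doe_peak)
from lspsmap.mapstats import (ChargeWindows, CellMap, Z_CUTOFF, window_charge,
                              compute_z_scores, classify_evoked,
                              first_event_metrics, charge_150,
                              site_probability, measure_map_repetition,
                              average_within_cell, average_across_cells,
                              radial_profile, radial_bin_values,
                              peristimulus_histogram, average_evoked_trace)
from lspsmap.events import SynapticEvent
from conftest import plant_events, SAMPLE_INTERVAL


def _map_from_traces(traces, sites=None):
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    if sites is None:
        sites = np.column_stack([np.arange(n) * 100.0, np.zeros(n)])
    from lspsmap.synthdata import MapRecording
    return MapRecording(repetition_index=0, sites=sites, traces=traces,
                        sample_interval=SAMPLE_INTERVAL, t0=-0.1,
                        flash_onset_ms=0.0, flash_duration_ms=5.0,
                        power_density=42.0, stimulus_order=np.arange(n),
                        truth=pd.DataFrame())


def _constant_window_trace(current_baseline_window, current_post_window,
                           n=4000):
    """Trace with constant current in the baseline and post charge windows."""
    x = np.zeros(n)
    x[600:900] = current_baseline_window  # [-40, -10) ms
    x[1100:1400] = current_post_window  # [10, 40) ms
    return x


class TestWindowCharge:
    def test_constant_current_arithmetic(self):
        x = np.zeros(4000)
        x[1100:1400] = 1.0
        tr = Trace(x, SAMPLE_INTERVAL, t0=-0.1)
        assert window_charge(tr, 10.0, 40.0) == pytest.approx(0.03)

    def test_zero_trace(self):
        tr = Trace(np.zeros(4000), SAMPLE_INTERVAL, t0=-0.1)
        assert window_charge(tr, 10.0, 40.0) == 0.0

    def test_planted_kernel_matches_closed_form(self):
        amp, tr_, td = 40.0, 1.0, 15.0
        trace = plant_events(0.0, [60.0], amplitude=amp)
        q = window_charge(trace, 50.0, 290.0)
        expected = amp * (td - tr_) / _doe_peak(tr_, td) / 1000.0  # pC
        assert abs(q - expected) < 0.01 * expected

    def test_signed_charge_is_negative_for_inward_events(self):
        trace = plant_events(0.0, [60.0], amplitude=40.0)
        assert window_charge(trace, 50.0, 290.0, signed=True) < 0

    def test_window_outside_trace_rejected(self):
        tr = Trace(np.zeros(100), SAMPLE_INTERVAL, t0=0.0)
        with pytest.raises(ValueError):
            window_charge(tr, -50.0, -20.0)


class TestZScores:
    def test_hand_computed_z(self):
        # baseline charges -1, -2, -3 pC; spot 0 post charge -4 pC
        # => mean -2, SD 1, Z_post(0) = (-4 - (-2))/1 = -2
        traces = np.stack([
            _constant_window_trace(-100 / 3.0, -400 / 3.0),
            _constant_window_trace(-200 / 3.0, 0.0),
            _constant_window_trace(-100.0, 0.0),
        ])
        z = compute_z_scores(_map_from_traces(traces))
        assert z.q_base.to_numpy() == pytest.approx([-1.0, -2.0, -3.0])
        assert z.z_post[0] == pytest.approx(-2.0)

    def test_post_charge_equal_to_mean_baseline_gives_zero(self):
        traces = np.stack([
            _constant_window_trace(-10.0, -20.0),
            _constant_window_trace(-30.0, 0.0),
        ])
        z = compute_z_scores(_map_from_traces(traces))
        # spot 0 post charge -0.6 pC equals the across-spot baseline mean
        assert z.q_post[0] == pytest.approx(z.q_base.mean())
        assert z.z_post[0] == pytest.approx(0.0)

    def test_self_normalization_when_post_equals_baseline_window(self):
        rng = np.random.default_rng(5)
        traces = rng.normal(0, 2.0, (40, 4000))
        windows = ChargeWindows(post=(-40.0, -10.0))
        z = compute_z_scores(_map_from_traces(traces), windows)
        assert z.z_post.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.z_post.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_map_rejected(self):
        traces = np.zeros((5, 4000))
        with pytest.raises(DegenerateMapError):
            compute_z_scores(_map_from_traces(traces))


class TestClassifyEvoked:
    def test_zero_not_evoked(self):
        assert classify_evoked(0.0) is False

    def test_negative_z_counts_by_absolute_value(self):
        assert classify_evoked(-3.0) is True

    def test_cutoff_matches_two_sided_normal_quantile(self):
        assert abs(Z_CUTOFF - stats.norm.ppf(0.995)) < 0.005

    def test_monotone_in_cutoff(self):
        z = np.array([-4.0, -2.8, -1.0, 0.5, 3.1])
        n = [classify_evoked(z, cutoff=c).sum() for c in (2.0, 2.575, 3.5)]
        assert n == sorted(n, reverse=True)


class TestFirstEventMetrics:
    def test_no_event_in_window_returns_none(self):
        evs = [SynapticEvent(50.0, 10.0, 0.1, 5.0)]
        assert first_event_metrics(evs, (10.0, 40.0)) is None

    def test_earliest_event_selected(self):
        evs = [SynapticEvent(12.0, 30.0, 0.3, 5.0),
               SynapticEvent(25.0, 80.0, 0.8, 9.0)]
        assert first_event_metrics(evs, (10.0, 40.0)) == (30.0, 0.3)

    def test_pre_flash_events_never_contribute(self):
        evs = [SynapticEvent(-20.0, 99.0, 0.9, 9.0),
               SynapticEvent(15.0, 30.0, 0.3, 5.0)]
        assert first_event_metrics(evs, (10.0, 40.0)) == (30.0, 0.3)


class TestCharge150:
    def test_zero_trace(self):
        tr = Trace(np.zeros(4000), SAMPLE_INTERVAL, t0=-0.1)
        assert charge_150(tr) == 0.0

    def test_two_events_sum_to_closed_form(self):
        amp, tr_, td = 30.0, 1.0, 15.0
        trace = plant_events(0.0, [20.0, 60.0], amplitude=amp)
        expected = 2 * amp * (td - tr_) / _doe_peak(tr_, td) / 1000.0
        assert abs(charge_150(trace) - expected) < 0.02 * expected

    def test_event_outside_window_contributes_nothing(self):
        trace = plant_events(0.0, [200.0], amplitude=50.0)
        assert charge_150(trace) < 1e-6

    def test_short_trace_rejected(self):
        tr = Trace(np.zeros(1000), SAMPLE_INTERVAL, t0=-0.05)  # ends at 50 ms
        with pytest.raises(ValueError):
            charge_150(tr)


class TestSiteProbability:
    def test_always_evoked(self):
        assert site_probability([[True], [True], [True]])[0] == 1.0

    def test_quarter(self):
        p = site_probability([[True, False], [False, False],
                              [False, True], [False, True]])
        np.testing.assert_allclose(p, [0.25, 0.5])

    def test_single_repetition_is_binary_mask(self):
        flags = np.array([[True, False, True, False]])
        np.testing.assert_array_equal(site_probability(flags),
                                      flags[0].astype(float))


class TestWithinCellAveraging:
    def _measures(self, z_posts):
        return pd.DataFrame({
            "x_um": [0.0, 100.0], "y_um": [0.0, 0.0],
            "z_post": z_posts, "z_pre": [0.0, 0.0],
            "first_amp_pA": [np.nan, 50.0], "first_charge_pC": [np.nan, 0.5],
            "charge150_pC": [0.1, 0.2],
            "evoked": [abs(z) > Z_CUTOFF for z in z_posts],
        })

    def test_single_repetition_identity(self):
        m = self._measures([-3.0, 1.0])
        cm = average_within_cell([m])
        np.testing.assert_allclose(cm.sites.z_post, [-3.0, 1.0])
        np.testing.assert_allclose(cm.sites.prob, [1.0, 0.0])

    def test_mean_of_two_repetitions(self):
        cm = average_within_cell([self._measures([2.0, 0.0]),
                                  self._measures([4.0, 0.0])])
        assert cm.sites.z_post[0] == pytest.approx(3.0)

    def test_repetition_order_irrelevant(self):
        a, b = self._measures([-5.0, 2.0]), self._measures([1.0, -0.5])
        cm1 = average_within_cell([a, b])
        cm2 = average_within_cell([b, a])
        pd.testing.assert_frame_equal(cm1.sites, cm2.sites)

    def test_first_event_averaged_where_defined(self):
        a, b = self._measures([0.0, 3.0]), self._measures([0.0, 3.0])
        b.loc[1, "first_amp_pA"] = 70.0
        cm = average_within_cell([a, b])
        assert cm.sites.first_amp_pA[1] == pytest.approx(60.0)

    def test_mismatched_grids_rejected(self):
        a = self._measures([0.0, 0.0])
        b = self._measures([0.0, 0.0]).assign(x_um=[5.0, 100.0])
        with pytest.raises(ValueError):
            average_within_cell([a, b])


def _cell_map(xy, values, measure="z_post", cell_id="c"):
    sites = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], measure: values})
    return CellMap(cell_id=cell_id, genotype_label="", sites=sites,
                   n_repetitions=1)


class TestAcrossCellAveraging:
    def test_single_cell_is_binned_identity(self):
        xy = np.array([[0.0, 0.0], [100.0, 0.0]])
        gm = average_across_cells([_cell_map(xy, [1.0, 3.0])], "z_post", 50.0)
        i0 = np.flatnonzero(gm.x_centers == 0.0)[0]
        i1 = np.flatnonzero(gm.x_centers == 100.0)[0]
        j = np.flatnonzero(gm.y_centers == 0.0)[0]
        assert gm.mean[j, i0] == 1.0 and gm.mean[j, i1] == 3.0

    def test_identical_cells_average_to_themselves(self):
        xy = np.array([[0.0, 0.0], [50.0, 50.0]])
        maps = [_cell_map(xy, [2.0, -1.0], cell_id=str(i)) for i in range(2)]
        gm = average_across_cells(maps, "z_post", 50.0)
        assert np.nanmax(np.abs(gm.mean[gm.n == 2] - [2.0, -1.0])).max() < 1e-12

    def test_empty_bins_flagged_missing(self):
        xy = np.array([[0.0, 0.0], [200.0, 0.0]])
        gm = average_across_cells([_cell_map(xy, [1.0, 1.0])], "z_post", 50.0)
        assert np.isnan(gm.mean[gm.n == 0]).all()
        assert (gm.n == 0).any()


class TestRadialProfile:
    def test_all_sites_in_one_bin(self):
        xy = np.array([[25.0, 0.0], [0.0, 25.0], [-20.0, 0.0]])
        prof = radial_profile([_cell_map(xy, [1.0, 2.0, 3.0])], "z_post")
        assert prof.n[0] == 1 and np.all(prof.n[1:] == 0)
        assert prof.mean[0] == pytest.approx(2.0)

    def test_site_on_edge_goes_to_outer_bin(self):
        xy = np.array([[50.0, 0.0]])
        prof = radial_profile([_cell_map(xy, [7.0])], "z_post")
        assert prof.n[0] == 0 and prof.n[1] == 1

    def test_sem_flagged_when_single_cell(self):
        xy = np.array([[10.0, 0.0]])
        prof = radial_profile([_cell_map(xy, [1.0])], "z_post")
        assert np.isnan(prof.sem[0])
        two = radial_profile([_cell_map(xy, [1.0], cell_id="a"),
                              _cell_map(xy, [3.0], cell_id="b")], "z_post")
        assert two.mean[0] == pytest.approx(2.0)
        assert two.sem[0] == pytest.approx(1.0)  # SD sqrt(2), /sqrt(2)


class TestPeristimulusHistogram:
    def test_empty(self):
        counts, _ = peristimulus_histogram([], 10.0)
        assert counts.sum() == 0

    def test_conservation(self):
        onsets = [-50.0, 5.0, 12.0, 14.0, 200.0]
        counts, edges = peristimulus_histogram(onsets, 10.0, (-100.0, 300.0))
        assert counts.sum() == len(onsets)

    def test_modal_bin_matches_evoked_latency(self):
        cfg = CircuitConfig(field_width=300, field_depth=300, latency_mean=9.0,
                            latency_sd=2.0, spont_rate=1.0, seed=2)
        grid = generate_hex_grid(300, 300, 50)
        pop = simulate_circuit(cfg)
        rec = simulate_map_recording(pop, grid, np.arange(grid.n_sites), cfg, 1)[0]
        counts, edges = peristimulus_histogram(rec.truth.time_ms, 5.0)
        modal = edges[np.argmax(counts)]
        assert 5.0 <= modal < 15.0


class TestAverageEvokedTrace:
    def test_identical_traces_returned(self):
        traces = np.tile(np.sin(np.linspace(0, 5, 1000)), (4, 1))
        avg = average_evoked_trace(_map_from_traces(traces))
        np.testing.assert_allclose(avg.samples, traces[0])

    def test_single_event_scales_as_one_over_n(self):
        k = ipsc_kernel(150, 0.1, 60.0, 1.0, 15.0).samples
        traces = np.zeros((10, 4000))
        traces[3, 1100:1100 + k.size] = k
        avg = average_evoked_trace(_map_from_traces(traces))
        assert -avg.samples.min() == pytest.approx(6.0, rel=1e-4)

    def test_evoked_disabled_average_is_flat_within_noise(self):
        rng = np.random.default_rng(0)
        traces = rng.normal(0, 2.0, (100, 2000))
        avg = average_evoked_trace(_map_from_traces(traces))
        assert avg.samples.std() < 2.0 / np.sqrt(100) * 1.2


class TestMapPipeline:
    def test_planted_input_detected_and_measured(self):
        # one connected interneuron under one site, otherwise silent map
        cfg = CircuitConfig(connect_prob0=0.0, spont_rate=0.0, noise_sd=2.0,
                            seed=3)
        pop = Population(x=np.array([0.0]), y=np.array([0.0]),
                         connected=np.array([True]), strength=np.array([80.0]))
        sites = np.array([[0.0, 0.0], [200.0, 0.0], [0.0, 200.0],
                          [-200.0, 0.0], [0.0, -200.0], [200.0, 200.0]])
        rec = simulate_map_recording(pop, StimGrid(sites, 200, (600, 600)),
                                     np.arange(6), cfg, 1)[0]
        df = measure_map_repetition(rec)
        assert bool(df.evoked[0]) is True
        assert not df.evoked[1:].any()
        assert df.first_amp_pA[0] == pytest.approx(80.0, rel=0.10)

    def test_sensitivity_planted_sites_flagged(self):
        # connected cells well inside the activation radius of distinct sites;
        # evoked charge far above the noise-charge SD
        cfg = CircuitConfig(connect_prob0=0.0, spont_rate=0.0, noise_sd=2.0,
                            seed=8)
        rng = np.random.default_rng(1)
        hits = 0
        total = 0
        for seed in range(3):
            c = CircuitConfig(**{**cfg.to_dict(), "seed": seed})
            grid = generate_hex_grid(500, 500, 100)
            chosen = rng.choice(grid.n_sites, 5, replace=False)
            pop = Population(
                x=grid.sites[chosen, 0], y=grid.sites[chosen, 1],
                connected=np.ones(5, bool), strength=np.full(5, 60.0))
            rec = simulate_map_recording(pop, grid, np.arange(grid.n_sites), c, 1)[0]
            df = measure_map_repetition(rec)
            hits += df.evoked[chosen].sum()
            total += 5
        assert hits / total >= 0.9

    def test_connectivity_decay_length_recovered_from_z_profile(self):
        # mean |Z| vs distance should decay with roughly the connection
        # probability's length constant
        maps = []
        for seed in range(10):
            cfg = CircuitConfig(field_width=700, field_depth=700,
                                connect_lambda=110.0, seed=seed)
            grid = generate_hex_grid(700, 700, 50)
            pop = simulate_circuit(cfg)
            rec = simulate_map_recording(pop, grid, np.arange(grid.n_sites),
                                         cfg, 1)[0]
            df = measure_map_repetition(rec)
            maps.append(CellMap(cell_id=str(seed), genotype_label="",
                                sites=df, n_repetitions=1))
        vals = -radial_bin_values(maps, "z_post", 50.0, 400.0)
        r = np.arange(8) * 50.0 + 25.0
        mean_z = np.nanmean(vals, axis=0)
        popt, _ = optimize.curve_fit(lambda r, a, L: a * np.exp(-r / L),
                                     r, mean_z, p0=(mean_z[0], 100.0))
        assert 80.0 <= popt[1] <= 150.0
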