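"""Culture simulator: geometry, wiring, activity, and the on-disk format."""

import dataclasses
import math

import numpy as np
import pytest

import calcinet as cn
from calcinet.errors import (MalformedRecordingError,
                             PlacementInfeasibleError, UnknownPresetError)
from calcinet.synthetic import (REGIME_PRESETS, SimulationConfig, place_cells,
                                sample_structural_network, simulate_activity,
                                simulate_recording)


class TestPlacement:
    def test_single_cell_inside_field(self):
        cfg = SimulationConfig(n_cells=1, seed=0)
        (cell,) = place_cells(cfg)
        assert 0 <= cell.x <= cfg.field_width
        assert 0 <= cell.y <= cfg.field_height
        assert cell.radius > 0

    def test_impossible_separation_raises_with_attempt_count(self):
        diag = math.hypot(400, 400)
        cfg = SimulationConfig(n_cells=2, min_separation=diag + 1, seed=0)
        with pytest.raises(PlacementInfeasibleError) as exc:
            place_cells(cfg)
        assert exc.value.attempts > 0
        assert "attempts" in str(exc.value)

    def test_min_separation_holds_for_all_pairs(self):
        # brute-force scan of all 4950 pairs
        cfg = SimulationConfig(n_cells=100, min_separation=15.0, seed=1,
                               field_width=600, field_height=600)
        cells = place_cells(cfg)
        assert len(cells) == 100
        for i in range(100):
            for j in range(i + 1, 100):
                d = math.hypot(cells[i].x - cells[j].x,
                               cells[i].y - cells[j].y)
                assert d >= 15.0

    def test_radii_truncated_at_one_micron(self):
        cfg = SimulationConfig(n_cells=200, soma_radius_mean=1.5,
                               soma_radius_sd=2.0, min_separation=0, seed=2)
        assert min(c.radius for c in place_cells(cfg)) >= 1.0

    def test_astrocyte_fraction_respected(self):
        cfg = SimulationConfig(n_cells=60, astrocyte_fraction=0.3, seed=3)
        cells = place_cells(cfg)
        n_astro = sum(c.cell_type == "astrocyte" for c in cells)
        assert n_astro == round(0.3 * 60)


class TestStructuralNetwork:
    def test_zero_probability_gives_empty_edges(self):
        cfg = SimulationConfig(n_cells=20, connect_p0=0.0, seed=0)
        cells = place_cells(cfg)
        assert sample_structural_network(cells, cfg).edges == set()

    def test_certain_connection_gives_complete_neuron_graph(self):
        cfg = SimulationConfig(n_cells=20, connect_p0=1.0,
                               connect_lambda=1e12, seed=0)
        cells = place_cells(cfg)
        net = sample_structural_network(cells, cfg)
        neurons = [c.cell_id for c in cells if c.cell_type == "neuron"]
        assert len(net.edges) == len(neurons) * (len(neurons) - 1) // 2

    def test_astrocytes_never_wired(self):
        cfg = SimulationConfig(n_cells=30, connect_p0=1.0,
                               connect_lambda=1e12, astrocyte_fraction=0.5,
                               seed=1)
        cells = place_cells(cfg)
        net = sample_structural_network(cells, cfg)
        astro = {c.cell_id for c in cells if c.cell_type == "astrocyte"}
        for a, b in net.edges:
            assert a not in astro and b not in astro
            assert a != b

    def test_edge_count_matches_analytic_expectation(self):
        # Monte-Carlo mean over 200 wirings vs the analytic sum of pair
        # probabilities, within a 99% envelope for the mean
        cfg = SimulationConfig(n_cells=50, astrocyte_fraction=0.0,
                               connect_p0=0.6, connect_lambda=150.0, seed=5,
                               field_width=600, field_height=600)
        cells = place_cells(cfg)
        probs = []
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                d = math.hypot(cells[i].x - cells[j].x,
                               cells[i].y - cells[j].y)
                probs.append(0.6 * math.exp(-d / 150.0))
        probs = np.array(probs)
        expected = probs.sum()
        rng = np.random.default_rng(99)
        counts = []
        for _ in range(200):
            counts.append(len(sample_structural_network(cells, cfg, rng).edges))
        half_width = 2.576 * math.sqrt(probs @ (1 - probs) / 200)
        assert abs(np.mean(counts) - expected) <= half_width


class TestActivity:
    def test_fully_silent_culture_has_no_events(self):
        cfg = SimulationConfig(n_cells=20, silent_fraction=1.0,
                               astro_event_rate=0.0, seed=0)
        _, truth = simulate_recording(cfg)
        assert truth.n_events() == 0

    def test_frame_count_is_rate_times_duration(self):
        cfg = SimulationConfig(n_cells=5, frame_rate=2.0, duration=600.0,
                               seed=0)
        rec, _ = simulate_recording(cfg)
        assert rec.n_frames == 1200
        assert rec.traces.shape == (1200, 5)

    def test_traces_positive_and_finite(self, small_intact):
        _, rec, _ = small_intact
        assert np.all(np.isfinite(rec.traces))
        assert np.all(rec.traces > 0)

    def test_event_times_within_recording(self, small_intact):
        cfg, _, truth = small_intact
        for train in truth.event_trains.values():
            assert np.all((train >= 0) & (train <= cfg.duration))

    def test_planted_edges_carry_higher_correlation(self):
        cfg = cn.apply_regime("intact", seed=7)
        rec, truth = simulate_recording(cfg)
        pairs = cn.pairwise_correlation(rec)
        neuron_ids = {c.cell_id for c in rec.cells if c.cell_type == "neuron"}
        mask_n = pairs["cell_i"].isin(neuron_ids) & pairs["cell_j"].isin(neuron_ids)
        keys = list(zip(pairs["cell_i"].astype(int), pairs["cell_j"].astype(int)))
        in_edge = np.array([k in truth.edges for k in keys])
        on_edges = pairs.loc[mask_n & in_edge, "rho"]
        off_edges = pairs.loc[mask_n & ~in_edge, "rho"]
        assert on_edges.median() > off_edges.median()

    def test_no_drive_no_background_gives_near_zero_correlations(self):
        cfg = SimulationConfig(n_cells=40, participation_prob=0.0,
                               background_amplitude=0.0, silent_fraction=0.5,
                               seed=13)
        rec, _ = simulate_recording(cfg)
        pairs = cn.pairwise_correlation(rec)
        assert np.percentile(pairs["rho"], 95) < 0.3

    def test_determinism_bit_identical(self):
        cfg = cn.apply_regime("hypoxia", seed=21, n_cells=25, duration=120.0)
        rec1, t1 = simulate_recording(cfg)
        rec2, t2 = simulate_recording(cfg)
        assert np.array_equal(rec1.traces, rec2.traces)
        assert t1.edges == t2.edges
        for cid in t1.event_trains:
            assert np.array_equal(t1.event_trains[cid], t2.event_trains[cid])


class TestRegimes:
    def test_unknown_preset_raises(self):
        with pytest.raises(UnknownPresetError):
            cn.apply_regime("anoxia")

    def test_presets_differ_only_in_the_four_regime_knobs(self):
        base = dataclasses.asdict(cn.apply_regime("intact"))
        knobs = {"silent_fraction", "participation_prob", "connect_p0",
                 "background_amplitude"}
        for name in REGIME_PRESETS:
            other = dataclasses.asdict(cn.apply_regime(name))
            diff = {k for k in base if base[k] != other[k]}
            assert diff <= knobs

    def test_hypoxia_silences_more_cells_than_intact(self):
        assert (cn.apply_regime("hypoxia").silent_fraction
                > cn.apply_regime("intact").silent_fraction)


class TestRoundTrip:
    def test_write_read_identity(self, small_intact, tmp_path):
        _, rec, _ = small_intact
        cn.write_recording(rec, tmp_path / "rec")
        back = cn.read_recording(tmp_path / "rec")
        assert back.group_label == rec.group_label
        assert back.frame_rate == rec.frame_rate
        assert [c.cell_id for c in back.cells] == [c.cell_id for c in rec.cells]
        for a, b in zip(back.cells, rec.cells):
            assert (a.x, a.y, a.radius, a.cell_type) == \
                   (b.x, b.y, b.radius, b.cell_type)
        np.testing.assert_allclose(back.traces, rec.traces, atol=1e-5)

    def test_table_shapes_on_disk(self, tmp_path):
        cfg = SimulationConfig(n_cells=120, seed=4, field_width=800,
                               field_height=800)
        rec, _ = simulate_recording(cfg)
        out = cn.write_recording(rec, tmp_path / "r")
        geo = (out / "geometry.csv").read_text().strip().splitlines()
        tr = (out / "traces.csv").read_text().strip().splitlines()
        assert len(geo) == 121  # header + 120 cells
        assert len(tr) == 1201  # header + 1200 frames
        assert len(tr[0].split(",")) == 120

    def test_missing_frame_row_rejected(self, small_intact, tmp_path):
        _, rec, _ = small_intact
        out = cn.write_recording(rec, tmp_path / "rec")
        lines = (out / "traces.csv").read_text().splitlines()
        (out / "traces.csv").write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(MalformedRecordingError, match="frame rows"):
            cn.read_recording(out)

    def test_missing_trace_column_rejected(self, small_intact, tmp_path):
        _, rec, _ = small_intact
        out = cn.write_recording(rec, tmp_path / "rec")
        import pandas as pd

        tr = pd.read_csv(out / "traces.csv")
        tr.drop(columns=[tr.columns[0]]).to_csv(out / "traces.csv",
                                                index=False)
        with pytest.raises(MalformedRecordingError, match="missing column"):
            cn.read_recording(out)


def test_config_validation_rejects_bad_proportions():
    with pytest.raises(ValueError):
        SimulationConfig(silent_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(frame_rate=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(connect_lambda=-1.0)
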