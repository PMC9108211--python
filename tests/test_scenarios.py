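"""Scenario presets, configuration round-trips and the end-to-end run
behaviour on desk-scale grids (determinism, resting equilibrium, transient
shape, scenario ordering, channel-count and buffer/pump sensitivity)."""

import numpy as np
import pytest

import azsim
from azsim import (
    PRESET_NAMES,
    PRINTED_DENSITIES,
    ScenarioConfig,
    detect_peaks,
    load_config,
    make_preset,
    run_scenario,
    save_config,
    scenario_ratios,
)
from conftest import mini_preset


class TestPresets:
    def test_three_presets_geometry(self):
        t = make_preset("tbar_clustered")
        c = make_preset("no_tbar_clustered")
        d = make_preset("no_tbar_dispersed")
        assert t.geometry.has_tbar and not c.geometry.has_tbar and not d.geometry.has_tbar
        assert t.geometry.channel_zone_outer_diameter == 0.07
        assert c.geometry.channel_zone_outer_diameter == 0.07
        assert d.geometry.channel_zone_outer_diameter == 0.14
        assert not d.geometry.channels_clustered
        for cfg in (t, c, d):
            assert cfg.channel.n_channels == 6

    def test_presets_share_everything_but_geometry(self):
        dicts = {n: make_preset(n).to_dict() for n in PRESET_NAMES}
        keys = set(dicts["tbar_clustered"])
        for key in keys - {"geometry", "preset"}:
            assert dicts["tbar_clustered"][key] == dicts["no_tbar_dispersed"][key], key
        geo_t = dicts["tbar_clustered"]["geometry"]
        geo_d = dicts["no_tbar_dispersed"]["geometry"]
        differing = {k for k in geo_t if geo_t[k] != geo_d[k]}
        assert differing == {"has_tbar", "channel_zone_outer_diameter", "channels_clustered"}

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_preset("tbar_dispersed")

    def test_printed_density_presets(self):
        assert PRINTED_DENSITIES["clustered"] == 2297.1
        assert PRINTED_DENSITIES["dispersed"] == 395.8

    def test_config_roundtrip_lossless(self, tmp_path):
        cfg = make_preset("tbar_clustered").with_(t_end=1.25e-3)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        again = load_config(path)
        assert again == cfg
        assert again.to_dict() == cfg.to_dict()

    def test_waveform_csv_import_roundtrip(self, tmp_path):
        import pandas as pd

        wf = pd.DataFrame({"time": [0.0, 1e-3, 2e-3], "voltage": [-70.0, 20.0, -70.0]})
        csv = tmp_path / "wave.csv"
        wf.to_csv(csv, index=False)
        train = azsim.train_from_csv(csv, frequency=40.0)
        assert azsim.ap_voltage(1e-3, train) == pytest.approx(20.0)
        cfg = make_preset("no_tbar_clustered").with_(train=train)
        save_config(cfg, tmp_path / "cfg.yaml")
        assert load_config(tmp_path / "cfg.yaml") == cfg


class TestDerivedDensity:
    def test_same_channel_count_in_every_scenario(self, mini_first_peak_results):
        for name, res in mini_first_peak_results.items():
            assert res.rho_vgcc * res.c_area == pytest.approx(6.0, rel=1e-12), name

    def test_derived_close_to_printed(self, mini_first_peak_results):
        # the published clustered figure derives from a smaller zone area
        # (0.0026 um^2) than the analytic annulus, hence the wider margin
        assert mini_first_peak_results["tbar_clustered"].rho_vgcc == pytest.approx(
            PRINTED_DENSITIES["clustered"], rel=0.20)
        assert mini_first_peak_results["no_tbar_dispersed"].rho_vgcc == pytest.approx(
            PRINTED_DENSITIES["dispersed"], rel=0.05)

    def test_doubling_count_doubles_density(self):
        cfg = mini_preset("tbar_clustered")
        import azsim.scenarios as S
        from azsim import build_geometry, classify_faces
        faces = classify_faces(build_geometry(cfg.geometry, cfg.h), cfg.geometry)
        rho6 = S.derived_density(cfg, faces)
        cfg12 = cfg.with_(channel=cfg.channel.with_(n_channels=12))
        assert S.derived_density(cfg12, faces) == pytest.approx(2 * rho6)


class TestRunBehaviour:
    def test_transient_rises_and_decays(self, mini_first_peak_results):
        """A single 40 Hz action potential produces a calcium transient near
        the channel zone that peaks close to the depolarization and relaxes
        back toward the resting value."""
        res = mini_first_peak_results["tbar_clustered"]
        ts = res.probe_series(0.03, 0.01)
        i_peak = int(np.argmax(ts.values))
        t_peak = ts.times[i_peak]
        assert ts.values[i_peak] > 20 * 0.05          # well above rest
        assert abs(t_peak - 0.0042) <= 5e-4           # near the printed peak time
        assert ts.values[0] == pytest.approx(0.05, rel=1e-6)
        # decays substantially after the peak within the simulated window
        assert ts.values[-1] < 0.25 * ts.values[i_peak]

    def test_peak_ordering_tbar_clustered_dispersed(self, mini_first_peak_results):
        for (r, h) in [(0.02, 0.01), (0.03, 0.01), (0.04, 0.02), (0.03, 0.04)]:
            comp = scenario_ratios(mini_first_peak_results, r, h, peak_index=0)
            v = comp.values
            assert v["tbar_clustered"] > v["no_tbar_clustered"] > v["no_tbar_dispersed"]

    def test_radial_profile_decreases_outward(self, mini_first_peak_results):
        for name, res in mini_first_peak_results.items():
            ts = res.probe_series(0.03, 0.01)
            t_peak = ts.times[int(np.argmax(ts.values))]
            radii, vals = azsim.radial_profile(res, 0.01, t_peak)
            assert len(radii) >= 4
            assert vals[0] > vals[-1], name

    def test_u_average_ordering_matches_probes(self, mini_first_peak_results):
        peaks = {n: r.u_average.max() for n, r in mini_first_peak_results.items()}
        assert (peaks["tbar_clustered"] > peaks["no_tbar_clustered"]
                > peaks["no_tbar_dispersed"])

    def test_degenerate_self_comparison(self, mini_first_peak_results):
        res = mini_first_peak_results["no_tbar_clustered"]
        twin = {"tbar_clustered": res, "no_tbar_clustered": res}
        comp = scenario_ratios(twin, 0.03, 0.01)
        assert comp.percent_excess == pytest.approx(0.0, abs=1e-9)
        assert comp.fold["no_tbar_clustered"] == pytest.approx(1.0)

    def test_mass_balance_logged_and_finite(self, mini_first_peak_results):
        for res in mini_first_peak_results.values():
            assert np.isfinite(res.mass_total).all()
            assert res.mass_total[0] > 0

    def test_determinism_bit_identical(self):
        cfg = mini_preset("no_tbar_clustered", t_end=5e-4)
        r1 = run_scenario(cfg)
        r2 = run_scenario(cfg)
        for k in r1.probes:
            assert np.array_equal(r1.probes[k], r2.probes[k])
        assert np.array_equal(r1.mass_total, r2.mass_total)

    def test_config_echo_matches_input(self, mini_first_peak_results):
        res = mini_first_peak_results["tbar_clustered"]
        assert res.config_echo == mini_preset("tbar_clustered").to_dict()

    def test_save_outputs(self, tmp_path):
        cfg = mini_preset("no_tbar_dispersed", t_end=5e-4)
        res = run_scenario(cfg)
        res.save(tmp_path)
        assert (tmp_path / "probes.csv").exists()
        assert (tmp_path / "run.json").exists()
        assert (tmp_path / "config.yaml").exists()
        again = load_config(tmp_path / "config.yaml")
        assert again == cfg  # provenance: echoed config reproduces the input


class TestRestingEquilibrium:
    def test_no_stimulation_holds_50nM(self):
        """Calibrated leak with a flat (zero-amplitude) train: fields stay at
        the resting values."""
        cfg = mini_preset("tbar_clustered", t_end=5e-3)
        cfg = cfg.with_(train=cfg.train.with_(v_peak=cfg.train.v_rest))
        res = run_scenario(cfg)
        ts = res.probe_series(0.03, 0.01)
        assert np.abs(ts.values / 0.05 - 1.0).max() < 1e-3
        assert abs(res.u_average[-1] / 0.05 - 1.0) < 1e-3


class TestSweeps:
    def test_vgcc_count_proportionality_and_stable_ratios(self):
        """Peak rise above baseline scales near-proportionally with channel
        count, and cross-scenario ratios barely move (two-scenario check)."""
        rises = {}
        excesses = {}
        for count in (1, 6, 20):
            results = {}
            for name in ("tbar_clustered", "no_tbar_clustered"):
                cfg = mini_preset(name)
                cfg = cfg.with_(channel=cfg.channel.with_(n_channels=count))
                results[name] = run_scenario(cfg)
            ts = results["tbar_clustered"].probe_series(0.03, 0.01)
            rises[count] = ts.values.max() - 0.05
            excesses[count] = scenario_ratios(results, 0.03, 0.01).percent_excess
        per_channel = {c: r / c for c, r in rises.items()}
        vals = list(per_channel.values())
        assert max(vals) / min(vals) < 1.25     # near-proportional influx scaling
        exc = list(excesses.values())
        assert (max(exc) - min(exc)) < 10.0     # ratios nearly count-independent

    def test_buffer_and_pumps_off_increases_peaks_keeps_ordering(self):
        on, off = {}, {}
        for name in ("tbar_clustered", "no_tbar_clustered"):
            cfg = mini_preset(name)
            on[name] = run_scenario(cfg)
            cfg_off = cfg.with_(
                kinetics=cfg.kinetics.with_(k_on=0.0, k_off=0.0),
                pumps=cfg.pumps.with_(rho_pmca=0.0, rho_ncx=0.0),
            )
            off[name] = run_scenario(cfg_off)
        for name in on:
            v_on = on[name].probe_series(0.03, 0.01).values.max()
            v_off = off[name].probe_series(0.03, 0.01).values.max()
            assert v_off >= v_on
            # buffer field stays constant when binding is switched off
            assert np.ptp(off[name].probes[(0.03, 0.01)]) > 0  # calcium moved
        comp_on = scenario_ratios(on, 0.03, 0.01)
        comp_off = scenario_ratios(off, 0.03, 0.01)
        assert comp_on.values["tbar_clustered"] > comp_on.values["no_tbar_clustered"]
        assert comp_off.values["tbar_clustered"] > comp_off.values["no_tbar_clustered"]
        assert abs(comp_on.percent_excess - comp_off.percent_excess) < 15.0
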