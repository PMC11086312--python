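"""Synthetic e-nose generator: dosing arithmetic, kinetics, snapshots,
dataset assembly and reproducibility."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ltnet.synthetic import (DosingInputs, GasExposure, SimConfig,
                             concentration_grid, extract_snapshots,
                             generate_dataset, liquid_volume, record_seed,
                             sensor_array, simulate_exposure)


# ---------------------------------------------------------------------------
# Dosing volume
# ---------------------------------------------------------------------------

class TestLiquidVolume:
    def test_zero_concentration_gives_zero(self):
        d = DosingInputs(V_chamber_mL=500, C_target_ppm=0, M_gpermol=58.08,
                         d_fraction=0.1, r_gpercm3=0.784)
        assert liquid_volume(d) == 0.0

    def test_equal_temperatures_drop_the_ratio(self):
        base = dict(V_chamber_mL=1000, C_target_ppm=5, M_gpermol=46.07,
                    d_fraction=0.1, r_gpercm3=0.789)
        q = liquid_volume(DosingInputs(**base, T_lab_C=25, T_chamber_C=25))
        assert q == pytest.approx(1000 * 5 * 46.07 / (22.4 * 0.1 * 0.789) * 1e-9)

    def test_ethanol_worked_value(self):
        # hand evaluation (exact rational arithmetic): 4607/17673600 mL
        d = DosingInputs(V_chamber_mL=1000, C_target_ppm=10, M_gpermol=46.07,
                         d_fraction=0.1, r_gpercm3=0.789, T_lab_C=25, T_chamber_C=25)
        assert liquid_volume(d) == pytest.approx(2.6067128372261455e-4, rel=1e-12)

    @given(scale=st.floats(0.25, 8.0))
    def test_scaling_laws(self, scale):
        base = dict(V_chamber_mL=800, C_target_ppm=6, M_gpermol=58.08,
                    d_fraction=0.2, r_gpercm3=0.784, T_lab_C=22, T_chamber_C=30)
        q0 = liquid_volume(DosingInputs(**base))
        # linear in C and V, inverse in d and r
        assert liquid_volume(DosingInputs(**{**base, "C_target_ppm": base["C_target_ppm"] * scale})) == pytest.approx(q0 * scale)
        assert liquid_volume(DosingInputs(**{**base, "V_chamber_mL": base["V_chamber_mL"] * scale})) == pytest.approx(q0 * scale)
        if 0 < base["d_fraction"] * scale <= 1:
            assert liquid_volume(DosingInputs(**{**base, "d_fraction": base["d_fraction"] * scale})) == pytest.approx(q0 / scale)
        assert liquid_volume(DosingInputs(**{**base, "r_gpercm3": base["r_gpercm3"] * scale})) == pytest.approx(q0 / scale)

    @pytest.mark.parametrize("bad", [
        dict(V_chamber_mL=0), dict(M_gpermol=-1), dict(r_gpercm3=0),
        dict(d_fraction=0), dict(d_fraction=1.5), dict(C_target_ppm=-1),
    ])
    def test_domain_errors(self, bad):
        kwargs = dict(V_chamber_mL=1000, C_target_ppm=10, M_gpermol=46.07,
                      d_fraction=0.1, r_gpercm3=0.789)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            DosingInputs(**kwargs)


# ---------------------------------------------------------------------------
# Exposure simulation
# ---------------------------------------------------------------------------

def _noiseless_cfg(**kw):
    return SimConfig(seed=5, noise_sd=0.0, drift_per_s=0.0, **kw)


class TestSimulateExposure:
    def test_blank_exposure_stays_at_baseline(self):
        cfg = _noiseless_cfg()
        rec = simulate_exposure(cfg, GasExposure(0, 0, "ethanol"), seed=1)
        assert np.allclose(rec.responses, cfg.baseline[None, :])

    def test_saturated_rise_reaches_steady_state(self):
        cfg = _noiseless_cfg(tau_rise_s=np.full(16, 2.0))
        exp = GasExposure(5.0, 3.0, "mixture")
        rec = simulate_exposure(cfg, exp, seed=1)
        end = np.searchsorted(rec.times_s, cfg.exposure_s, side="right") - 1
        expected = (cfg.baseline
                    + cfg.sensitivity[:, 0] * 5.0 ** cfg.exponent
                    + cfg.sensitivity[:, 1] * 3.0 ** cfg.exponent)
        assert np.allclose(rec.responses[end], expected, rtol=0.01)

    def test_matches_independent_loop_evaluation(self):
        """Vectorized trace equals a straight-line per-tick reimplementation."""
        cfg = SimConfig(seed=9, n_sensors=4,
                        sensitivity=[[1.0, 0.5], [2.0, 0.2], [0.3, 3.0], [1.5, 1.5]],
                        exponent=[0.6, 0.8, 1.0, 0.7],
                        tau_rise_s=[5.0, 8.0, 12.0, 6.0],
                        tau_decay_s=[10.0, 9.0, 20.0, 15.0],
                        baseline=[1.0, 2.0, 0.5, 1.2],
                        noise_sd=0.0, drift_per_s=1e-3,
                        exposure_s=30.0, recovery_s=20.0, sample_rate_hz=2.0)
        exp = GasExposure(4.0, 2.0, "mixture")
        rec = simulate_exposure(cfg, exp, seed=3)
        assert rec.responses.shape == (100, 4)
        for k in range(100):
            t = k * 0.5
            for s in range(4):
                ss = (cfg.sensitivity[s, 0] * 4.0 ** cfg.exponent[s]
                      + cfg.sensitivity[s, 1] * 2.0 ** cfg.exponent[s])
                if t <= 30.0:
                    level = ss * (1.0 - np.exp(-t / cfg.tau_rise_s[s]))
                else:
                    end = ss * (1.0 - np.exp(-30.0 / cfg.tau_rise_s[s]))
                    level = end * np.exp(-(t - 30.0) / cfg.tau_decay_s[s])
                expected = cfg.baseline[s] + level + 1e-3 * t
                assert rec.responses[k, s] == pytest.approx(expected, abs=1e-12)

    def test_bit_identical_for_identical_seed(self):
        cfg = SimConfig(seed=2)
        exp = GasExposure(3.0, 0.0, "ethanol")
        a = simulate_exposure(cfg, exp, seed=42)
        b = simulate_exposure(cfg, exp, seed=42)
        assert np.array_equal(a.responses, b.responses)
        c = simulate_exposure(cfg, exp, seed=43)
        assert not np.array_equal(a.responses, c.responses)

    def test_steady_state_monotone_in_concentration(self):
        cfg = _noiseless_cfg()
        prev = None
        for ppm in (1.0, 5.0, 9.0, 15.0):
            rec = simulate_exposure(cfg, GasExposure(0.0, ppm, "acetone"), seed=1)
            end = rec.responses[np.searchsorted(rec.times_s, cfg.exposure_s) - 1]
            if prev is not None:
                assert np.all(end >= prev)
            prev = end

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            GasExposure(-1.0, 0.0, "ethanol")


# ---------------------------------------------------------------------------
# Snapshot extraction
# ---------------------------------------------------------------------------

class TestExtractSnapshots:
    @pytest.fixture
    def record(self):
        cfg = SimConfig(seed=4)
        return cfg, simulate_exposure(cfg, GasExposure(5.0, 5.0, "mixture"), seed=7)

    def test_end_policy_yields_one_snapshot(self, record):
        cfg, rec = record
        snaps = extract_snapshots(rec, policy="end", exposure_s=cfg.exposure_s)
        assert len(snaps) == 1
        assert snaps[0].class_label == "mixture"

    def test_second_half_count_at_1hz(self, record):
        cfg, rec = record
        snaps = extract_snapshots(rec, policy="second-half", exposure_s=120.0)
        # ticks 60..120 inclusive at 1 Hz
        assert len(snaps) == 61

    def test_snapshot_is_a_row_projection(self, record):
        cfg, rec = record
        snaps = extract_snapshots(rec, policy="last_k:5", exposure_s=cfg.exposure_s)
        for s in snaps:
            assert np.array_equal(s.values, rec.responses[s.meta["tick"]])

    def test_empty_selection_raises(self, record):
        cfg, rec = record
        with pytest.raises(ValueError):
            extract_snapshots(rec, policy="nonsense")


# ---------------------------------------------------------------------------
# Grid and dataset assembly
# ---------------------------------------------------------------------------

class TestGenerateDataset:
    def test_grid_structure(self):
        grid = concentration_grid()
        assert len(grid) == 32
        by_class = {c: [g for g in grid if g.class_label == c]
                    for c in ("acetone", "ethanol", "mixture")}
        assert len(by_class["acetone"]) == 8
        assert len(by_class["ethanol"]) == 8
        assert len(by_class["mixture"]) == 16
        assert all(g.ethanol_ppm == 0 for g in by_class["acetone"])
        assert all(g.acetone_ppm == 0 for g in by_class["ethanol"])
        assert all(g.ethanol_ppm > 0 and g.acetone_ppm > 0
                   for g in by_class["mixture"])
        # pure rows span 1..15 ppm odd; mixtures the 4x4 product grid
        assert sorted(g.acetone_ppm for g in by_class["acetone"]) == [1, 3, 5, 7, 9, 11, 13, 15]
        assert sorted({(g.ethanol_ppm, g.acetone_ppm) for g in by_class["mixture"]}) == \
            sorted((float(e), float(a)) for e in (1, 5, 10, 15) for a in (1, 5, 10, 15))

    def test_single_tick_dataset_counts(self):
        cfg = SimConfig(seed=1)
        snaps, manifest = generate_dataset(cfg, replicates=1, seed=1, policy="end")
        assert len(snaps) == 32
        labels = [s.class_label for s in snaps]
        assert labels.count("acetone") == 8
        assert labels.count("ethanol") == 8
        assert labels.count("mixture") == 16
        assert manifest["n_records"] == 32

    def test_replicates_scale_linearly(self):
        cfg = SimConfig(seed=1)
        for r in (1, 3):
            snaps, _ = generate_dataset(cfg, replicates=r, seed=1, policy="end")
            assert len(snaps) == 32 * r

    def test_manifest_byte_identical_for_same_seed(self):
        cfg = SimConfig(seed=6)
        _, m1 = generate_dataset(cfg, replicates=2, seed=6, policy="last_k:3")
        _, m2 = generate_dataset(cfg, replicates=2, seed=6, policy="last_k:3")
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)
        _, m3 = generate_dataset(cfg, replicates=2, seed=7, policy="last_k:3")
        assert json.dumps(m1, sort_keys=True) != json.dumps(m3, sort_keys=True)

    def test_record_seed_depends_on_index_not_order(self):
        assert record_seed(5, 3) == record_seed(5, 3)
        assert record_seed(5, 3) != record_seed(5, 4)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(SimConfig(seed=1), grid=[], replicates=1, seed=1)


def test_sensor_array_roster():
    arr = sensor_array()
    assert len(arr) == 16
    assert {s.model_name for s in arr} == {"TGS2600", "TGS2602", "TGS2610", "TGS2620"}
    assert all(s.operating_current_mA > 0 for s in arr)
    assert all(s.detection_range_ppm[0] < s.detection_range_ppm[1] for s in arr)
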