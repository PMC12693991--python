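"""Sensor model, motion protocols and stream alignment."""

import numpy as np
import pytest

from magthr.simulation import (
    CTS_RATE_HZ,
    ROBOT_RATE_HZ,
    SensorSpec,
    SensorStream,
    Trajectory,
    align_streams,
    generate_protocol_2dof,
    generate_protocol_subluxation,
    ground_truth,
    simulate_sensor,
)


class TestProtocols:
    def test_2dof_visits_twelve_tilt_levels(self, geometry):
        trajs = generate_protocol_2dof(geometry)
        assert len(trajs) == 3  # repeats
        levels = sorted(set(trajs[0].key_tilt) - {0.0})
        assert levels == [5.0 * k for k in range(1, 13)]

    def test_2dof_sweep_endpoint(self, geometry):
        traj = generate_protocol_2dof(geometry, repeats=1)[0]
        assert traj.key_azimuth.max() == 355.0
        assert traj.key_azimuth.min() == 0.0

    def test_2dof_rejects_out_of_range_tilts(self, geometry):
        with pytest.raises(ValueError):
            generate_protocol_2dof(geometry, tilts=[5.0, 80.0])

    def test_subluxation_flag_onset(self, geometry):
        traj = generate_protocol_subluxation(geometry)
        t = np.linspace(0.0, traj.duration_s, 4000)
        states = traj.sample(t)
        z, flag = traj.channels(t)
        # flag exactly tracks commanded tilt >= 64
        np.testing.assert_array_equal(
            flag, states[:, 0] >= geometry.impingement_onset - 1.0e-9)
        first = t[np.argmax(flag)]
        assert states[np.argmax(flag), 0] == pytest.approx(64.0, abs=0.1)
        assert first > 0.0

    def test_subluxation_three_ordered_events(self, geometry):
        traj = generate_protocol_subluxation(geometry)
        t = np.linspace(0.0, traj.duration_s, 8000)
        z, flag = traj.channels(t)
        # peaks: separation local maxima, one per lever-out excursion
        peaks = [z[i] for i in range(1, len(z) - 1)
                 if z[i] > 0 and z[i] >= z[i - 1] and z[i] > z[i + 1]]
        assert len(peaks) == 3
        assert peaks[0] < peaks[1] < peaks[2]
        assert peaks[2] == pytest.approx(3.14, abs=0.01)

    def test_subluxation_angles_must_exceed_onset(self, geometry):
        with pytest.raises(ValueError):
            generate_protocol_subluxation(geometry, angles=(60.0,))


class TestSensorModel:
    def test_quantisation_preserves_exact_multiples(self, geometry, magnet):
        traj = generate_protocol_2dof(geometry, repeats=1)[0]
        spec = SensorSpec(noise_sigma_uT=(0.0, 0.0, 0.0), seed=1)
        stream = simulate_sensor(traj, geometry, magnet, spec)
        step = np.asarray(spec.step_uT)
        np.testing.assert_allclose(stream.b_uT,
                                   step * np.round(stream.b_uT / step),
                                   rtol=0, atol=1.0e-9)

    def test_quantisation_error_bounded_without_noise(self, geometry, magnet):
        traj = generate_protocol_2dof(geometry, repeats=1)[0]
        spec = SensorSpec(noise_sigma_uT=(0.0, 0.0, 0.0), seed=1)
        stream = simulate_sensor(traj, geometry, magnet, spec)
        from magthr.simulation import magnet_poses
        from magthr.magnetostatics import field_poses

        rot, pos = magnet_poses(traj.sample(stream.t_s), geometry)
        truth = field_poses(magnet, rot, pos,
                            geometry.sensor_position) @ geometry.sensor_rotation
        err = np.abs(stream.b_uT - truth)
        assert np.all(err <= np.asarray(spec.step_uT) / 2.0 + 1.0e-9)

    def test_same_seed_identical_stream(self, geometry, magnet):
        traj = generate_protocol_subluxation(geometry)
        a = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=4))
        b = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=4))
        np.testing.assert_array_equal(a.b_uT, b.b_uT)
        c = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=5))
        assert not np.array_equal(a.b_uT, c.b_uT)

    def test_stream_rate_and_monotonicity(self, geometry, magnet):
        traj = generate_protocol_subluxation(geometry)
        stream = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=0))
        dt = np.diff(stream.t_s)
        np.testing.assert_allclose(dt, 1.0 / 49.0, rtol=1.0e-9)

    def test_csv_round_trip(self, tmp_path, geometry, magnet):
        traj = generate_protocol_subluxation(geometry)
        stream = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=0))
        path = tmp_path / "stream.csv"
        stream.to_csv(path)
        loaded = SensorStream.from_csv(path)
        np.testing.assert_allclose(loaded.b_uT, stream.b_uT, rtol=1e-12)
        np.testing.assert_allclose(loaded.t_s, stream.t_s, rtol=1e-12)


class TestAlignment:
    def test_identical_timestamps_identity_pairing(self, geometry, magnet):
        traj = generate_protocol_subluxation(geometry)
        stream = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=0))
        truth = ground_truth(traj, rate_hz=49.0)
        pairs = align_streams(stream, truth)
        assert len(pairs) == len(stream)
        np.testing.assert_allclose(pairs["tilt_deg"],
                                   traj.sample(stream.t_s)[:, 0], atol=1.0e-9)

    def test_sensor_keyed_length_contract(self, geometry, magnet):
        """49 Hz sensor vs 125 Hz robot truth: one row per sensor sample."""
        traj = generate_protocol_2dof(geometry, repeats=1)[0]
        stream = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=0))
        truth = ground_truth(traj, ROBOT_RATE_HZ)
        pairs = align_streams(stream, truth, key="sensor")
        assert len(pairs) == len(stream)
        # worst-case pairing error: half the truth sampling interval
        matched_t = truth.t_s[
            np.abs(truth.t_s[None, :] - stream.t_s[:, None]).argmin(axis=1)]
        assert np.max(np.abs(matched_t - stream.t_s)) <= 0.5 / ROBOT_RATE_HZ + 1e-12

    def test_truth_keyed_length_contract(self, geometry, magnet):
        """Camera-rate reference keys the subluxation pairing."""
        traj = generate_protocol_subluxation(geometry)
        stream = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=0))
        truth = ground_truth(traj, CTS_RATE_HZ)
        pairs = align_streams(stream, truth, key="truth")
        assert len(pairs) == len(truth)

    def test_disjoint_streams_rejected(self, geometry, magnet):
        traj = generate_protocol_subluxation(geometry)
        stream = simulate_sensor(traj, geometry, magnet, SensorSpec(seed=0))
        truth = ground_truth(traj, CTS_RATE_HZ)
        shifted = type(truth)(truth.t_s + stream.t_s[-1] + 10.0, truth.states,
                              truth.z_mm, truth.imp_flag)
        with pytest.raises(ValueError):
            align_streams(stream, shifted)


def test_end_to_end_noiseless_identity(geometry, magnet, grid_dataset):
    """With no noise and negligible quantisation, look-up tracking recovers
    the commanded grid states exactly at grid-aligned instants."""
    from magthr.tracking import build_lookup_model, lookup_invert

    # 1 °/s motion sampled at 1 Hz lands exactly on integer-degree states
    traj = generate_protocol_2dof(geometry, tilts=[5.0, 10.0], repeats=1,
                                  rate_deg_s=1.0)[0]
    spec = SensorSpec(step_uT=(1e-6, 1e-6, 1e-6),
                      noise_sigma_uT=(0.0, 0.0, 0.0), rate_hz=1.0, seed=0)
    stream = simulate_sensor(traj, geometry, magnet, spec)
    states = traj.sample(stream.t_s)
    on_grid = np.all(np.abs(states - np.round(states)) < 1.0e-9, axis=1)
    model = build_lookup_model(grid_dataset)
    got = lookup_invert(stream.b_uT[on_grid], model)
    expect = np.round(states[on_grid])
    expect[:, 1] %= 360.0
    nondegenerate = expect[:, 0] >= 1.0
    np.testing.assert_array_equal(got[nondegenerate], expect[nondegenerate])
    assert nondegenerate.sum() > 100
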