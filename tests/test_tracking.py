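"""Inversion methods: look-up, responsivity ratios, neural net, Z look-up."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magthr.kinematics import sensor_field, state_grid
from magthr.statespace import StateDataset
from magthr.tracking import (
    ZLookupModel,
    azimuth_atan2,
    build_lookup_model,
    build_responsivity_model,
    build_z_lookup,
    lookup_invert,
    nn_train,
    r_ratio_bmag,
    r_ratio_lutz,
    responsivity_track,
    z_invert,
)

finite_b = st.floats(-2000.0, 2000.0, allow_nan=False)


@pytest.fixture(scope="module")
def lookup(grid_dataset):
    return build_lookup_model(grid_dataset)


@pytest.fixture(scope="module")
def resp_model(geometry, magnet):
    return build_responsivity_model(geometry, magnet)


class TestLookup:
    def test_exact_hit_returns_stored_state(self, grid_dataset, lookup):
        i = 5000
        st_ = lookup_invert(grid_dataset.fields[i], lookup)
        assert tuple(st_) == tuple(grid_dataset.states[i])

    def test_matches_brute_force_on_toy_table(self, rng, geometry, magnet):
        fields = rng.normal(scale=100.0, size=(10, 3))
        states = np.column_stack([np.arange(10.0), 10.0 * np.arange(10.0)])
        model = build_lookup_model(
            StateDataset(states, fields, geometry, magnet))
        queries = rng.normal(scale=100.0, size=(40, 3))
        got = lookup_invert(queries, model)
        d = np.linalg.norm(queries[:, None, :] - fields[None, :, :], axis=2)
        expect = states[d.argmin(axis=1)]
        np.testing.assert_array_equal(got, expect)

    def test_degenerate_tie_resolves_to_lowest_index(self, grid_dataset, lookup):
        st_ = lookup_invert(grid_dataset.fields[123], lookup)  # a tilt-0 row
        assert tuple(st_) == (0.0, 0.0)

    def test_noiseless_grid_round_trip_exact_above_one_degree(
            self, grid_dataset, lookup, rng):
        """Every non-degenerate state inverts to itself without noise."""
        idx = rng.choice(np.nonzero(grid_dataset.states[:, 0] >= 1.0)[0],
                         size=2000, replace=False)
        got = lookup_invert(grid_dataset.fields[idx], lookup)
        np.testing.assert_array_equal(got, grid_dataset.states[idx])


class TestRatios:
    def test_pure_axial_field_gives_zero(self):
        b = np.array([0.0, 0.0, 500.0])
        assert r_ratio_lutz(b) == 0.0
        assert r_ratio_bmag(b) == 0.0

    def test_printed_examples(self):
        assert r_ratio_lutz(np.array([300.0, 0.0, 400.0])) == pytest.approx(0.75)
        assert r_ratio_bmag(np.array([300.0, 0.0, 400.0])) == pytest.approx(0.6)
        assert r_ratio_bmag(np.array([300.0, 400.0, 0.0])) == pytest.approx(1.0)

    def test_bz_zero_flags_infinite_lutz_ratio(self):
        with pytest.warns(UserWarning):
            assert np.isinf(r_ratio_lutz(np.array([10.0, 0.0, 0.0])))

    def test_bmag_scale_invariant(self, rng):
        b = rng.normal(size=(50, 3))
        np.testing.assert_allclose(r_ratio_bmag(7.3 * b), r_ratio_bmag(b),
                                   rtol=1.0e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(bx=finite_b, by=finite_b, bz=finite_b)
    def test_algebraic_identity_between_ratios(self, bx, by, bz):
        """r_bmag = r_lutz / sqrt(1 + r_lutz²) whenever Bz ≠ 0."""
        if abs(bz) < 1.0e-6 or (bx == 0 and by == 0 and bz == 0):
            return
        b = np.array([bx, by, bz])
        rl = r_ratio_lutz(b)
        rb = r_ratio_bmag(b)
        assert rb == pytest.approx(rl / np.sqrt(1.0 + rl * rl), rel=1.0e-9)


class TestAzimuth:
    @pytest.mark.parametrize("b,expected", [
        ((100.0, 0.0, 50.0), 0.0),
        ((0.0, 100.0, 50.0), 90.0),
        ((-100.0, 0.0, 50.0), 180.0),
        ((0.0, -1.0, 0.0), 270.0),
    ])
    def test_cardinal_directions(self, b, expected):
        assert azimuth_atan2(np.array(b)) == pytest.approx(expected)

    def test_neutral_singularity_flagged(self):
        """Zero in-plane field warns and falls back to the atan2 convention."""
        with pytest.warns(UserWarning):
            assert azimuth_atan2(np.array([0.0, 0.0, 500.0])) == 0.0


class TestResponsivity:
    def test_table_strictly_monotone(self, resp_model):
        assert np.all(np.diff(resp_model.r_table) > 0.0)
        assert resp_model.r_table[0] == 0.0
        assert resp_model.tilt_table[-1] == 66.0

    def test_non_monotone_table_rejected(self):
        from magthr.tracking import ResponsivityModel
        with pytest.raises(ValueError):
            ResponsivityModel(np.arange(3.0), np.array([0.0, 0.5, 0.4]))

    def test_round_trip_noiseless(self, geometry, magnet, resp_model):
        b = sensor_field(geometry, magnet, [(30.0, 120.0)])
        tilt, psi = responsivity_track(b, resp_model)[0]
        assert tilt == pytest.approx(30.0, abs=0.5)
        assert psi == pytest.approx(120.0, abs=0.5)

    def test_clamps_at_table_ends(self, resp_model):
        with pytest.warns(UserWarning):  # neutral reading: azimuth undefined
            lo = responsivity_track(np.array([0.0, 0.0, 700.0]), resp_model)
        assert lo[0] == 0.0
        # in-plane-only reading is beyond the table maximum
        hi = responsivity_track(np.array([500.0, 0.0, 1.0]), resp_model)
        assert hi[0] == 66.0


class TestNeuralNet:
    def test_constant_target_learned(self, rng):
        b = rng.normal(scale=300.0, size=(400, 3))
        states = np.column_stack([np.full(400, 30.0), np.full(400, 90.0)])
        model = nn_train(b, states, seed=3, max_iter=20)
        pred = model.predict(rng.normal(scale=300.0, size=(20, 3)))
        np.testing.assert_allclose(pred[:, 0], 30.0, atol=0.5)

    def test_split_sizes(self, rng):
        b = rng.normal(size=(1000, 3))
        s = np.column_stack([rng.uniform(0, 65, 1000), rng.uniform(0, 360, 1000)])
        model = nn_train(b, s, seed=1, max_iter=2)
        meta = model.metadata
        assert (meta["n_train"], meta["n_val"], meta["n_test"]) == (700, 150, 150)

    def test_same_seed_reproduces_weights(self, grid_dataset):
        sub_b = grid_dataset.fields[::97]
        sub_s = grid_dataset.states[::97]
        m1 = nn_train(sub_b, sub_s, seed=11, max_iter=8)
        m2 = nn_train(sub_b, sub_s, seed=11, max_iter=8)
        for w1, w2 in zip(m1.net.weights, m2.net.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_prediction_finite_and_wrapped(self, grid_dataset):
        model = nn_train(grid_dataset.fields[::97], grid_dataset.states[::97],
                         seed=2, max_iter=8)
        pred = model.predict(np.zeros(3))
        assert np.all(np.isfinite(pred))
        many = model.predict(grid_dataset.fields[::501])
        assert np.all((many[:, 1] >= 0.0) & (many[:, 1] < 360.0))

    def test_learns_tilt_on_grid_subsample(self, grid_dataset):
        """Noiseless grid training gives sub-degree tilt residuals."""
        model = nn_train(grid_dataset.fields[::7], grid_dataset.states[::7],
                         seed=7, max_iter=40)
        assert model.metadata["rmse_test"][0] < 1.0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            nn_train(rng.normal(size=(10, 3)), rng.normal(size=(10, 2)))


class TestZLookup:
    @pytest.fixture(scope="class")
    def zmodel(self, geometry, magnet):
        return build_z_lookup(geometry, magnet)

    def test_table_spans_onset_to_maximum(self, zmodel):
        assert len(zmodel.z_mm) == 25
        assert zmodel.z_mm[0] == 0.0
        assert zmodel.z_mm[-1] == pytest.approx(3.14, abs=5.0e-3)
        assert np.all(np.diff(zmodel.z_mm) > 0.0)

    def test_exact_table_field_returns_its_z(self, zmodel):
        for i in (0, 7, 24):
            assert z_invert(zmodel.fields[i], zmodel) == zmodel.z_mm[i]

    def test_matches_brute_force(self, zmodel, rng):
        q = zmodel.fields.mean(axis=0) + rng.normal(scale=30.0, size=(50, 3))
        got = z_invert(q, zmodel)
        d = np.linalg.norm(q[:, None, :] - zmodel.fields[None, :, :], axis=2)
        np.testing.assert_array_equal(got, zmodel.z_mm[d.argmin(axis=1)])

    def test_pure_impingement_motion_reads_zero(self, geometry, magnet, zmodel):
        """Fields from any tilt up to the onset map to zero displacement."""
        tilts = np.linspace(0.0, geometry.impingement_onset, 65)
        b = sensor_field(geometry, magnet,
                         np.column_stack([tilts, np.zeros_like(tilts)]))
        assert np.all(z_invert(b, zmodel) == 0.0)

    def test_too_short_table_rejected(self, geometry, magnet):
        with pytest.raises(ValueError):
            build_z_lookup(geometry, magnet, n=1)
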