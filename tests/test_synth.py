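"""Synthetic-cohort generator: distributions, coupling law, kinematic
consistency of generated trajectories, and the CSV dialect."""

import dataclasses

import numpy as np
import pytest

from fingercoord import synth
from fingercoord.synth import (
    CouplingLaw,
    GeneratorConfig,
    PopulationParams,
    SubjectProfile,
    TrajectoryParseError,
    TrajectorySchemaError,
)


class TestSampleSubjects:
    def test_large_sample_matches_population_means(self):
        profiles = synth.sample_subjects(10000, rng_seed=7)
        middle = np.array([p.middle_length_mm for p in profiles])
        ring = np.array([p.ring_length_mm for p in profiles])
        assert abs(middle.mean() - 84.4) < 0.2
        assert abs(ring.mean() - 79.1) < 0.2
        assert abs(middle.std() - 4.3) < 0.2
        years = np.array([p.training_years for p in profiles])
        assert years.min() >= 5.0 and years.max() <= 15.0

    def test_zero_sd_collapses_to_means(self):
        pop = PopulationParams(middle_sd_mm=0.0, ring_sd_mm=0.0)
        for p in synth.sample_subjects(5, pop, rng_seed=0):
            assert p.middle_length_mm == 84.4
            assert p.ring_length_mm == 79.1

    def test_deterministic_per_seed(self):
        a = synth.sample_subjects(6, rng_seed=3)
        b = synth.sample_subjects(6, rng_seed=3)
        assert a == b

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            synth.sample_subjects(0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"middle_length_mm": 30.0},
            {"ring_length_mm": 140.0},
            {"training_years": -1.0},
        ],
    )
    def test_profile_invariants(self, kwargs):
        base = dict(
            subject_id="x",
            middle_length_mm=84.0,
            ring_length_mm=79.0,
            training_years=10.0,
        )
        with pytest.raises(ValueError):
            SubjectProfile(**{**base, **kwargs})


class TestKeystrokePulse:
    def test_cycle_boundary_is_rest(self):
        assert synth.middle_mcp_profile(0.0, 0.75, 40.0, 10.0) == 10.0

    def test_peak_at_midcycle(self):
        assert synth.middle_mcp_profile(0.375, 0.75, 40.0, 10.0) == pytest.approx(50.0)

    def test_integral_over_cycle(self):
        # closed form: integral of rest + A sin^2(pi t/T) over [0, T)
        T, A, r = 0.75, 40.0, 10.0
        t = np.linspace(0, T, 20001, endpoint=False)
        vals = synth.middle_mcp_profile(t, T, A, r)
        integral = np.trapezoid(vals, dx=T / len(t))
        assert integral == pytest.approx(r * T + A * T / 2, rel=1e-4)

    def test_out_of_cycle_rejected(self):
        with pytest.raises(ValueError):
            synth.middle_mcp_profile(0.75, 0.75, 40.0)


class TestCouplingLaw:
    def _theta(self, n=200, dt=0.01):
        t = np.arange(n) * dt
        return synth.middle_mcp_profile(t % 0.75, 0.75, 40.0, 10.0), t

    def test_identity_coupling(self, subject):
        theta, t = self._theta()
        law = CouplingLaw(gain_base=1.0, gain_length_coeff=0.0,
                          gain_training_coeff=0.0, lag_s=0.0, offset_deg=0.0)
        np.testing.assert_allclose(
            synth.true_ring_angle(theta, t, subject, law), theta
        )

    def test_pure_scaling(self, subject):
        law = CouplingLaw(gain_base=0.8, gain_length_coeff=0.0,
                          gain_training_coeff=0.0, lag_s=0.0, offset_deg=0.0)
        theta = np.full(50, 50.0)
        t = np.arange(50) * 0.01
        np.testing.assert_allclose(
            synth.true_ring_angle(theta, t, subject, law), 40.0
        )

    def test_lag_matches_index_shift_oracle(self, subject):
        theta, t = self._theta()
        law = CouplingLaw(gain_base=1.0, gain_length_coeff=0.0,
                          gain_training_coeff=0.0, lag_s=0.02, offset_deg=0.0)
        beta = synth.true_ring_angle(theta, t, subject, law)
        # oracle: explicit 2-frame shift past the warm-up region
        np.testing.assert_allclose(beta[2:], theta[:-2])
        np.testing.assert_allclose(beta[:2], theta[0])

    def test_gain_modulated_by_covariates(self):
        law = CouplingLaw()
        short = SubjectProfile("a", 84.0, 75.0, 5.0)
        long_ = SubjectProfile("b", 84.0, 83.0, 15.0)
        assert law.gain(long_) > law.gain(short)

    def test_gain_within_unit_interval_for_population(self):
        law = CouplingLaw()
        gains = [law.gain(p) for p in synth.sample_subjects(2000, rng_seed=0)]
        assert 0.0 < min(gains) and max(gains) < 2.0

    def test_mismatched_lengths_rejected(self, subject):
        with pytest.raises(ValueError):
            synth.true_ring_angle(np.zeros(5), np.zeros(4), subject, CouplingLaw())


class TestGenerateSession:
    def test_protocol_counts(self, subject):
        cfg = GeneratorConfig(
            n_subjects=1, sets_per_subject=4, keystrokes_per_set=25
        )
        sets = synth.generate_session(subject, cfg)
        assert len(sets) == 4
        assert all(s.n_frames == cfg.frames_per_set == 1875 for s in sets)

    def test_noiseless_planarity_and_rigidity(self, subject, noiseless_set):
        assert np.all(noiseless_set.positions[..., 0] == 0.0)
        for finger, length in (
            ("middle", subject.middle_length_mm),
            ("ring", subject.ring_length_mm),
        ):
            pos = noiseless_set.finger(finger)
            seg = np.linalg.norm(np.diff(pos, axis=1), axis=-1)
            expected = length * np.asarray(synth.PHALANX_FRACTIONS)
            assert np.ptp(seg, axis=0).max() < 1e-6
            np.testing.assert_allclose(seg[0], expected, atol=1e-9)

    def test_bit_identical_for_same_seed(self, subject):
        cfg = GeneratorConfig(n_subjects=1, sets_per_subject=2,
                              keystrokes_per_set=3, seed=11)
        a = synth.generate_session(subject, cfg)
        b = synth.generate_session(subject, cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            GeneratorConfig(sets_per_subject=0)
        with pytest.raises(ValueError):
            GeneratorConfig(sample_rate_hz=10.0)  # <20 frames per cycle
        with pytest.raises(ValueError):
            GeneratorConfig(angle_noise_sd_deg=-1.0)


class TestTrajectoryIO:
    def test_round_trip(self, noiseless_set, tmp_path):
        path = tmp_path / "set.csv"
        synth.write_trajectory(path, noiseless_set)
        back = synth.read_trajectory(path)
        assert back.subject_id == noiseless_set.subject_id
        assert back.set_index == noiseless_set.set_index
        np.testing.assert_allclose(back.time_s, noiseless_set.time_s, atol=1e-6)
        np.testing.assert_allclose(
            back.positions, noiseless_set.positions, atol=1e-6
        )

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            synth.HandTrajectory(
                subject_id="x",
                set_index=0,
                time_s=np.empty(0),
                positions=np.empty((0, 2, 4, 3)),
            )

    def test_non_monotone_time_raises_parse_error(self, noiseless_set, tmp_path):
        path = tmp_path / "bad.csv"
        traj = dataclasses.replace(noiseless_set)
        synth.write_trajectory(path, traj)
        lines = path.read_text().splitlines()
        # corrupt the timestamp of the second frame (rows 9..16)
        for i in range(9, 17):
            parts = lines[i].split(",")
            parts[0] = "-1.000000"
            lines[i] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectoryParseError, match="line"):
            synth.read_trajectory(path)

    def test_missing_column_raises_schema_error(self, noiseless_set, tmp_path):
        path = tmp_path / "short.csv"
        synth.write_trajectory(path, noiseless_set)
        lines = path.read_text().splitlines()
        lines[0] = lines[0].replace("z_mm", "height")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectorySchemaError, match="z_mm"):
            synth.read_trajectory(path)
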