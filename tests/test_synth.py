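"""Generator tests: exact design bookkeeping, response-model couplings, and
recoverability of the injected oscillatory state from the raw epochs."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import hilbert

from prestim.cluster import circular_mean
from prestim.spectral import MorletSpec, band_average, morlet_transform
from prestim.synth import (
    StudyDesign,
    SubjectProfile,
    TrialLatent,
    generate_design,
    grid_layout,
    simulate_epochs,
    simulate_latent_cohort,
    simulate_responses,
)


class TestGenerateDesign:
    def test_paper_session_counts(self, paper_design):
        trials = generate_design(paper_design, seed=7)
        assert len(trials) == 900
        assert (trials.condition == "test").sum() == 600
        assert (trials.condition == "control").sum() == 300
        for d in ("inward", "outward"):
            assert ((trials.condition == "test") & (trials.direction == d)).sum() == 300

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_counts_conserved_per_cell(self, paper_design, seed):
        trials = generate_design(paper_design, seed=seed)
        cell = trials.groupby(["block", "condition", "direction"]).size()
        for (_, cond, _), n in cell.items():
            assert n == (60 if cond == "test" else 30)

    def test_minimal_design_enumeration(self):
        # 1 block, 1 trial per condition x direction cell: 2 x 2 = 4 trials
        d = StudyDesign(n_blocks=1, test_per_block_per_direction=1, control_per_block_per_direction=1)
        trials = generate_design(d, seed=0)
        assert len(trials) == 4
        assert sorted(trials.condition) == ["control", "control", "test", "test"]
        assert sorted(trials.direction) == ["inward", "inward", "outward", "outward"]

    def test_iti_within_range_and_deterministic(self, paper_design):
        a = generate_design(paper_design, seed=3)
        b = generate_design(paper_design, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert a.iti.between(*paper_design.iti_range).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_design(StudyDesign(test_per_block_per_direction=0), seed=0)


class TestSimulateResponses:
    def _latent(self, n, rng):
        return TrialLatent(phase=rng.uniform(-np.pi, np.pi, n), power=rng.standard_normal(n))

    def test_null_couplings_recover_base_rate(self, paper_design, neutral_profile):
        rng = np.random.default_rng(0)
        trials = generate_design(paper_design, seed=0)
        out = simulate_responses(trials, neutral_profile, self._latent(len(trials), rng), seed=1)
        test = out[out.condition == "test"]
        rate = (test.response == "intermediate").mean()
        # 600 trials at p=0.5: 4-sigma binomial band
        assert abs(rate - 0.5) < 4 * np.sqrt(0.25 / 600)

    def test_control_accuracy(self, paper_design, neutral_profile):
        rng = np.random.default_rng(0)
        trials = generate_design(paper_design, seed=0)
        out = simulate_responses(trials, neutral_profile, self._latent(len(trials), rng), seed=2)
        ctrl = out[out.condition == "control"]
        acc = (ctrl.response == "intermediate").mean()
        assert abs(acc - 0.81) < 4 * np.sqrt(0.81 * 0.19 / 300)

    def test_phase_coupling_opposes_condition_phases(self, paper_design):
        # strong phase coupling: ILL and no-ILL mean phases ~pi apart
        rng = np.random.default_rng(5)
        trials = generate_design(paper_design, seed=5)
        profile = SubjectProfile(base_illusion_rate=0.5, phase_coupling=3.0, preferred_phase=1.0)
        latent = self._latent(len(trials), rng)
        out = simulate_responses(trials, profile, latent, seed=6)
        test = (out.condition == "test").to_numpy()
        ill = test & (out.response == "intermediate").to_numpy()
        noill = test & (out.response == "not-intermediate").to_numpy()
        delta = circular_mean(latent.phase[ill]) - circular_mean(latent.phase[noill])
        delta = np.angle(np.exp(1j * delta))
        assert abs(abs(delta) - np.pi) < 0.35

    def test_missing_latent_errors(self, tiny_design, neutral_profile):
        trials = generate_design(tiny_design, seed=0)
        with pytest.raises(ValueError, match="latent"):
            simulate_responses(trials, neutral_profile, None, seed=0)

    def test_rts_positive(self, tiny_design, neutral_profile):
        rng = np.random.default_rng(0)
        trials = generate_design(tiny_design, seed=0)
        out = simulate_responses(trials, neutral_profile, self._latent(len(trials), rng), seed=3)
        assert (out.rt > 0).all()


class TestSimulateEpochs:
    def test_pure_alpha_band_power_scaling(self, tiny_design, layout4):
        # noiseless 10 Hz oscillator: doubling amplitude quadruples band power
        trials = generate_design(tiny_design, seed=0)
        powers = []
        for amp in (1.0, 2.0):
            profile = SubjectProfile(alpha_amplitude=amp)
            epochs, _ = simulate_epochs(
                trials, profile, layout4, tiny_design, seed=4,
                effect_sensors=[0], noise_amplitude=0.0, evoked_amplitude=0.0,
                amplitude_sigma=0.0,
            )
            tf = morlet_transform(epochs.select_trials([0]), MorletSpec.for_band("alpha"))
            i0 = np.argmin(abs(tf.times + 0.4))
            powers.append(band_average(tf.power, tf.freqs, "alpha", freq_axis=2)[0, 0, i0])
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.01)

    def test_band_power_concentrated_at_effect_sensor(self, tiny_design, layout4):
        trials = generate_design(tiny_design, seed=0)
        epochs, _ = simulate_epochs(
            trials, SubjectProfile(), layout4, tiny_design, seed=4,
            effect_sensors=[2], noise_amplitude=0.0, evoked_amplitude=0.0,
        )
        tf = morlet_transform(epochs.select_trials([0, 1]), MorletSpec.for_band("alpha"))
        p = band_average(tf.power, tf.freqs, "alpha", freq_axis=2).mean(axis=(0, 2))
        assert np.argmax(p) == 2
        assert p[2] > 100 * np.median(np.delete(p, 2))

    def test_injected_phase_recoverable(self, tiny_design, layout4):
        # wavelet phase at -400 ms vs injected latent phase, noiseless trials
        trials = generate_design(tiny_design, seed=1)
        epochs, latent = simulate_epochs(
            trials, SubjectProfile(), layout4, tiny_design, seed=9,
            effect_sensors=[0], noise_amplitude=0.0, evoked_amplitude=0.0,
        )
        tf = morlet_transform(epochs, MorletSpec([10.0]))
        i0 = np.argmin(abs(tf.times - latent.ref_time))
        ph = tf.phase[:, 0, 0, i0]
        err = np.angle(np.exp(1j * (ph - latent.phase)))
        assert np.max(np.abs(err)) < 0.2

    def test_phase_matches_analytic_signal_oracle(self, tiny_design, layout4):
        trials = generate_design(tiny_design, seed=1)
        epochs, latent = simulate_epochs(
            trials, SubjectProfile(), layout4, tiny_design, seed=9,
            effect_sensors=[0], noise_amplitude=0.0, evoked_amplitude=0.0,
        )
        x = epochs.data[0, 0]
        i0 = np.argmin(abs(epochs.times - latent.ref_time))
        oracle = np.angle(hilbert(x))[i0]
        assert abs(np.angle(np.exp(1j * (oracle - latent.phase[0])))) < 0.2

    def test_window_shorter_than_alpha_cycle_errors(self, layout4):
        d = StudyDesign(epoch_window=(-0.04, 0.05))
        trials = generate_design(d, seed=0)
        with pytest.raises(ValueError, match="alpha cycle"):
            simulate_epochs(trials, SubjectProfile(), layout4, d, seed=0)

    def test_bit_identical_given_seed(self, tiny_design, layout4, neutral_profile):
        a, la = simulate_epochs(generate_design(tiny_design, 0), neutral_profile, layout4, tiny_design, seed=5)
        b, lb = simulate_epochs(generate_design(tiny_design, 0), neutral_profile, layout4, tiny_design, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(la.phase, lb.phase)


class TestLayout:
    def test_grid_adjacency_structure(self):
        lay = grid_layout(3, 3)
        assert lay.adjacency.sum() == 2 * (2 * 3 * 2)  # 12 undirected rook edges
        assert not np.any(np.diag(lay.adjacency))
        assert np.array_equal(lay.adjacency, lay.adjacency.T)

    def test_planar_pair_channels(self):
        lay = grid_layout(2, 2, channel_kind="planar_pair")
        assert lay.n_channels == 8
        assert list(lay.site_of_channel) == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_roundtrip_json(self, tmp_path):
        lay = grid_layout(3, 2)
        lay.to_json(tmp_path / "l.json")
        back = type(lay).from_json(tmp_path / "l.json")
        np.testing.assert_array_equal(lay.adjacency, back.adjacency)


class TestLatentCohort:
    def test_base_rates_span_and_behavior_fields(self):
        c = simulate_latent_cohort(n_subjects=8, seed=3, layout=grid_layout(3, 3))
        rates = c.behavior_vector("illusion_rate")
        assert rates.min() >= 0.0 and rates.max() <= 1.0
        assert len({s.subject_id for s in c.subjects}) == 8

    def test_equalized_labels(self):
        c = simulate_latent_cohort(n_subjects=3, seed=4, layout=grid_layout(3, 3))
        for s in c.subjects:
            for d in ("inward", "outward"):
                m = s.directions == d
                assert (s.labels[m] == "ILL").sum() == (s.labels[m] == "no-ILL").sum()

    def test_deterministic(self):
        a = simulate_latent_cohort(n_subjects=2, seed=11, layout=grid_layout(3, 3))
        b = simulate_latent_cohort(n_subjects=2, seed=11, layout=grid_layout(3, 3))
        np.testing.assert_array_equal(a.subjects[0].phases, b.subjects[0].phases)
        np.testing.assert_array_equal(a.subjects[1].power, b.subjects[1].power)
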