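import numpy as np
import pytest
from scipy import signal as sps

import dfcstates as d
from dfcstates.simulate import (ConfigurationError, _structural_to_correlation,
                                bandpass_filter, make_structural_template,
                                nearest_correlation)


class TestHypnogram:
    def test_absorbing_identity_chain_stays_awake(self):
        model = d.StageModel(
            stages=("W", "N1"),
            transition_rates=(np.eye(2),),
            initial=np.array([1.0, 0.0]),
        )
        hyp = d.generate_hypnogram(model, duration=600, seed=0)
        assert set(hyp.stages) == {"W"}
        assert hyp.n_epochs == 20

    def test_same_seed_reproduces_sequence(self):
        model = d.sleep_stage_model()
        a = d.generate_hypnogram(model, seed=42)
        b = d.generate_hypnogram(model, seed=42)
        assert a.stages == b.stages

    def test_invalid_stage_label_rejected(self):
        with pytest.raises(ConfigurationError):
            d.StageModel(
                stages=("W", "S2"),
                transition_rates=(np.eye(2),),
                initial=np.array([1.0, 0.0]),
            )

    def test_row_sums_validated(self):
        bad = np.array([[0.9, 0.2], [0.1, 0.9]])
        with pytest.raises(ConfigurationError):
            d.StageModel(
                stages=("W", "N1"),
                transition_rates=(bad,),
                initial=np.array([1.0, 0.0]),
            )

    def test_cohort_prevalences_match_sleep_dataset(self):
        """48/23/19/10 W/N1/N2/N3 within +-2% over a large cohort."""
        model = d.sleep_stage_model()
        counts = {s: 0 for s in model.stages}
        total = 0
        for i in range(1000):
            hyp = d.generate_hypnogram(model, seed=i)
            for s in hyp.stages:
                counts[s] += 1
            total += hyp.n_epochs
        for stage, target in zip(model.stages, (0.48, 0.23, 0.19, 0.10)):
            assert counts[stage] / total == pytest.approx(target, abs=0.02)

    def test_wakefulness_declines_and_n1_peaks_first(self):
        """Cohort-mean W probability is non-increasing (5-min smoothing);
        N1 occurrence peaks before N2 and N3."""
        model = d.sleep_stage_model()
        hyps = [d.generate_hypnogram(model, seed=i) for i in range(400)]
        n = hyps[0].n_epochs
        occ = np.zeros((4, n))
        for hyp in hyps:
            for t, s in enumerate(hyp.stages):
                occ[model.stages.index(s), t] += 1
        occ /= len(hyps)
        width = 10  # 10 epochs = 5 minutes
        kernel = np.ones(width) / width
        smooth = np.array([np.convolve(row, kernel, mode="valid") for row in occ])
        assert np.all(np.diff(smooth[0]) <= 0.005)  # monotone up to MC jitter
        peaks = smooth.argmax(axis=1)
        assert peaks[1] < peaks[2] <= peaks[3]

    def test_stage_at_and_volume_mapping(self):
        hyp = d.Hypnogram("s", ("W", "N1"), epoch_length=30.0)
        assert hyp.stage_at(29.9) == "W"
        assert hyp.stage_at(30.0) == "N1"
        with pytest.raises(ValueError):
            hyp.stage_at(60.0)
        assert hyp.stage_per_volume(28, 2.08)[-1] == "N1"


class TestStateCovariances:
    @staticmethod
    def assert_valid_correlation(m):
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.allclose(np.diag(m), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh((m + m.T) / 2).min() > -1e-9
        assert np.abs(m).max() <= 1.0 + 1e-9

    def test_templates_are_valid_correlation_matrices(self):
        covs = d.graded_state_covariances(20, seed=3)
        for tpl in covs.templates.values():
            self.assert_valid_correlation(tpl)

    def test_inter_state_similarity_calibrated(self):
        covs = d.make_state_covariances(
            20, {"A": 0.3, "B": 0.3}, inter_state_similarity=0.7, seed=5
        )
        iu = np.triu_indices(20, 1)
        r = np.corrcoef(covs.templates["A"][iu], covs.templates["B"][iu])[0, 1]
        assert r == pytest.approx(0.7, abs=0.05)

    def test_full_sc_coupling_returns_structural_in_correlation_form(self):
        sc = make_structural_template(15, seed=2)
        covs = d.make_state_covariances(
            15, {"A": 0.2, "B": 0.2}, sc_coupling={"A": 1.0, "B": 0.1},
            structural=sc, seed=2,
        )
        np.testing.assert_allclose(
            covs.templates["A"], _structural_to_correlation(sc), atol=1e-10
        )

    def test_zero_modularity_grade_has_baseline_q(self):
        flat = d.make_state_covariances(16, {"A": 0.0}, seed=9)
        planted = d.make_state_covariances(16, {"A": 0.8}, seed=9)
        q_flat = d.louvain_maximize(flat.templates["A"], iterations=20, seed=0).q
        q_planted = d.louvain_maximize(planted.templates["A"], iterations=20, seed=0).q
        assert q_planted > q_flat + 0.05

    def test_higher_grades_give_higher_template_q_and_sc_r(self):
        covs = d.graded_state_covariances(20, seed=1)
        qs = {
            s: d.louvain_maximize(covs.templates[s], iterations=20, seed=0).q
            for s in ("W", "N1", "N2", "N3")
        }
        rs = {
            s: d.sc_fc_correlation(covs.templates[s], covs.structural)
            for s in ("W", "N1", "N2", "N3")
        }
        assert qs["W"] < qs["N1"] < qs["N2"] < qs["N3"]
        assert rs["N1"] < rs["W"] < rs["N2"] < rs["N3"]

    def test_grade_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            d.make_state_covariances(10, {"A": 1.5})

    def test_nearest_correlation_projects_to_psd(self):
        bad = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_correlation(bad)
        self.assert_valid_correlation(fixed)


class TestGenerateBold:
    def test_52_minutes_gives_1500_volumes(self):
        covs = d.two_state_covariances(6, seed=0)
        hyp = d.generate_hypnogram(d.sleep_stage_model(), 3120.0, seed=0)
        ts = d.generate_bold(hyp, covs, tr=2.08, seed=0)
        assert ts.n_volumes == 1500

    def test_empirical_correlation_converges_to_template(self):
        """Long single-stage noiseless run: empirical correlation within
        Frobenius distance 0.05 R of the template."""
        r = 10
        covs = d.make_state_covariances(r, {"W": 0.4}, seed=4)
        hyp = d.Hypnogram("s", ("W",) * 700, epoch_length=60.0)  # 42000 s
        ts = d.generate_bold(hyp, covs, tr=2.08, noise_sd=0.0, seed=4)
        assert ts.n_volumes >= 20000
        emp = np.corrcoef(ts.data, rowvar=False)
        dist = np.linalg.norm(emp - covs.templates["W"])
        assert dist < 0.05 * r

    def test_power_concentrated_in_passband(self):
        covs = d.two_state_covariances(6, seed=1)
        hyp = d.generate_hypnogram(d.sleep_stage_model(), 3120.0, seed=1)
        ts = d.generate_bold(hyp, covs, seed=1)
        f, psd = sps.welch(ts.data, fs=1 / 2.08, axis=0, nperseg=512)
        band = (f >= 0.005) & (f <= 0.12)
        assert psd[band].sum() / psd.sum() >= 0.95

    def test_missing_template_and_bad_tr_rejected(self):
        covs = d.make_state_covariances(6, {"W": 0.2}, seed=0)
        hyp = d.Hypnogram("s", ("W", "N1"), epoch_length=30.0)
        with pytest.raises(ConfigurationError):
            d.generate_bold(hyp, covs)
        hyp_w = d.Hypnogram("s", ("W",) * 40, epoch_length=30.0)
        with pytest.raises(ConfigurationError):
            d.generate_bold(hyp_w, covs, tr=-1.0)

    def test_filter_is_zero_phase_bandpass(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4096, 1))
        y = bandpass_filter(x, tr=2.08)
        f, pxx = sps.welch(y[:, 0], fs=1 / 2.08, nperseg=1024)
        stop = f > 0.15
        mid = (f > 0.02) & (f < 0.08)
        assert pxx[stop].mean() < 1e-2 * pxx[mid].mean()


class TestCohort:
    def test_cohort_reproducible_and_shaped(self):
        covs = d.two_state_covariances(8, seed=0)
        model = d.sleep_stage_model()
        a = d.generate_cohort(3, model, covs, duration=624.0, seed=11)
        b = d.generate_cohort(3, model, covs, duration=624.0, seed=11)
        assert len(a) == 3
        for (ts1, h1), (ts2, h2) in zip(a, b):
            np.testing.assert_array_equal(ts1.data, ts2.data)
            assert h1.stages == h2.stages

    def test_single_subject_delegates_to_generators(self):
        covs = d.two_state_covariances(8, seed=0)
        model = d.sleep_stage_model()
        (ts, hyp), = d.generate_cohort(1, model, covs, duration=624.0, seed=5)
        hyp_direct = d.generate_hypnogram(model, 624.0, seed=5, subject="sub-00")
        ts_direct = d.generate_bold(hyp_direct, covs, seed=5)
        assert hyp.stages == hyp_direct.stages
        np.testing.assert_array_equal(ts.data, ts_direct.data)

    def test_truncation_keeps_leading_volumes(self):
        covs = d.two_state_covariances(8, seed=0)
        cohort = d.generate_cohort(2, d.sleep_stage_model(), covs,
                                   duration=1248.0, seed=3)
        short = d.truncate_cohort(cohort, 420.0)
        assert short[0][0].n_volumes == int(420.0 // 2.08)
        np.testing.assert_array_equal(
            short[0][0].data, cohort[0][0].data[: short[0][0].n_volumes]
        )
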