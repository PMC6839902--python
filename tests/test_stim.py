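"""Trial pipeline: alignment, QC, theta selection, change measures."""

import dataclasses

import numpy as np
import pytest

import linc_ephys as le
from linc_ephys.config import AnalysisConfig

from conftest import make_trialset


@pytest.fixture(scope="module")
def aligned(short_session):
    hi, tt, events, truth = short_session
    f = events[0].frequency
    return (le.build_trials(hi, events, stim_freq=f),
            le.build_trials(tt, events, stim_freq=f),
            events, truth)


class TestBuildTrials:
    def test_window_arithmetic(self):
        rec = le.LFPRecording(np.arange(20_000, dtype=float), 1000.0,
                              "a", "opsin+", "HI")
        ts = le.build_trials(rec, [10.0], stim_freq=7.0)
        assert np.array_equal(ts.pre[0], np.arange(7000, 10000))
        assert np.array_equal(ts.during[0], np.arange(10000, 13000))

    def test_truncated_onset_dropped(self):
        rec = le.LFPRecording(np.zeros(20_000), 1000.0, "a", "opsin+", "HI")
        ts = le.build_trials(rec, [1.0, 10.0], stim_freq=7.0)
        assert ts.n_trials == 1
        assert list(ts.trial_ids) == [1]

    def test_full_synthetic_schedule_aligned(self, aligned):
        hi_trials, _, events, _ = aligned
        assert hi_trials.n_trials == len(events)

    def test_no_usable_onset_raises(self):
        rec = le.LFPRecording(np.zeros(1000), 1000.0, "a", "opsin+", "HI")
        with pytest.raises(ValueError, match="usable"):
            le.build_trials(rec, [0.5], stim_freq=7.0)


class TestArtifactQC:
    def _trials_with_ranges(self, ranges):
        """Trials whose concatenated range equals the requested values."""
        pre = np.zeros((len(ranges), 3000))
        during = np.zeros((len(ranges), 3000))
        for i, r in enumerate(ranges):
            during[i, 0] = r
        return make_trialset(pre, during)

    def test_rule_arithmetic(self):
        """Ranges {1.0 x 9, 30}: mean 3.9, threshold 7.8, one removed."""
        trials = self._trials_with_ranges([1.0] * 9 + [30.0])
        kept, report = le.reject_artifact_trials(trials)
        assert report.mean_range == pytest.approx(3.9)
        assert report.threshold == pytest.approx(7.8)
        assert list(report.removed) == [9]
        assert kept.n_trials == 9

    def test_equal_ranges_none_removed(self):
        trials = self._trials_with_ranges([5.0] * 8)
        kept, report = le.reject_artifact_trials(trials)
        assert len(report.removed) == 0
        assert kept.n_trials == 8

    def test_partition_invariant(self, aligned):
        hi_trials, *_ = aligned
        _, report = le.reject_artifact_trials(hi_trials)
        both = np.sort(np.concatenate([report.kept, report.removed]))
        assert np.array_equal(both, np.arange(hi_trials.n_trials))

    def test_injected_artifacts_removed_exactly(self):
        """10% injected 10x-amplitude artifacts: removed set = injected set."""
        proto = le.StimProtocol()
        for seed in range(3):
            p = le.LFPSimParams(session_duration=1000, seed=seed,
                                artifact_prob=0.1)
            hi, _, events, truth = le.simulate_lfp_session(p, proto)
            trials = le.build_trials(hi, events, stim_freq=events[0].frequency)
            _, report = le.reject_artifact_trials(trials)
            removed_ids = set(trials.trial_ids[report.removed].tolist())
            assert removed_ids == set(truth.artifact_trials)

    def test_all_removed_raises(self):
        pre = np.zeros((2, 3000))
        during = np.zeros((2, 3000))
        trials = make_trialset(pre, during)
        # both ranges zero -> mean 0 -> nothing exceeds threshold; craft instead
        # a config with negative multiplier to force full removal
        cfg = AnalysisConfig(artifact_multiplier=-1.0)
        during[:, 0] = 1.0
        with pytest.raises(ValueError, match="all trials"):
            le.reject_artifact_trials(make_trialset(pre, during), cfg)


class TestThetaSelection:
    def test_strict_inequality_at_criterion(self):
        """A trial whose ratio equals the criterion exactly is NOT selected."""
        rng = np.random.default_rng(0)
        t = np.arange(3000) / 1000.0
        pre = np.vstack([
            10 * np.sin(2 * np.pi * 7 * t) + rng.standard_normal(3000),
            10 * np.sin(2 * np.pi * 2 * t) + rng.standard_normal(3000),
        ])
        trials = make_trialset(pre, np.zeros_like(pre))
        ratios = le.select_theta_trials(trials).ratios
        cfg = AnalysisConfig(theta_criterion=float(ratios[0]))
        sel = le.select_theta_trials(trials, cfg)
        assert 0 not in sel.selected  # ratio == criterion -> excluded
        cfg2 = AnalysisConfig(theta_criterion=float(ratios[0]) - 1e-9)
        assert 0 in le.select_theta_trials(trials, cfg2).selected

    def test_agreement_with_ground_truth_labels(self):
        """>= 95% agreement at default simulation amplitudes."""
        proto = le.StimProtocol()
        agree = total = 0
        for seed in range(4):
            p = le.LFPSimParams(session_duration=700, seed=seed)
            hi, _, events, truth = le.simulate_lfp_session(p, proto)
            trials = le.build_trials(hi, events, stim_freq=events[0].frequency)
            sel = le.select_theta_trials(trials)
            picked = set(trials.trial_ids[sel.selected].tolist())
            gt = set(truth.theta_trials)
            for tid in trials.trial_ids:
                agree += int((tid in picked) == (tid in gt))
                total += 1
        assert agree / total >= 0.95

    def test_all_nontheta_empty_selection_warns(self, caplog):
        rng = np.random.default_rng(1)
        t = np.arange(3000) / 1000.0
        pre = np.vstack([50 * np.sin(2 * np.pi * 2 * t) + rng.standard_normal(3000)
                         for _ in range(3)])
        trials = make_trialset(pre, np.zeros_like(pre))
        with caplog.at_level("WARNING", logger="linc_ephys.stim"):
            sel = le.select_theta_trials(trials)
        assert len(sel.selected) == 0
        assert any("theta" in r.message for r in caplog.records)

    def test_selection_invariant_to_trial_order(self, aligned):
        hi_trials, *_ = aligned
        sel = le.select_theta_trials(hi_trials)
        perm = np.random.default_rng(2).permutation(hi_trials.n_trials)
        sel_p = le.select_theta_trials(hi_trials.subset(perm))
        assert set(hi_trials.trial_ids[sel.selected]) == \
            set(hi_trials.subset(perm).trial_ids[sel_p.selected])


class TestPowerChange:
    def test_identical_windows_zero_change(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 3000))
        trials = make_trialset(x, x.copy())
        res = le.power_change_at_stim(trials)
        assert res.percent_change == pytest.approx(0.0, abs=1e-9)

    def test_constructed_power_doubling(self):
        """Adding a sinusoid with band power equal to baseline gives +100%."""
        rng = np.random.default_rng(4)
        fs, f = 1000.0, 20.0 / 3.0
        t = np.arange(3000) / fs
        pre = rng.standard_normal((40, 3000))
        cfg = AnalysisConfig()
        tapers = le.compute_tapers(3000, cfg.nw, cfg.k)
        band = (f - 0.5, f + 0.5)
        p_base = le.bandpower(le.trial_psd(pre, fs, tapers), band)
        unit = le.bandpower(
            le.multitaper_psd(np.sin(2 * np.pi * f * t), fs, tapers), band)
        amp = np.sqrt(p_base / unit)
        during = pre + amp * np.sin(2 * np.pi * f * t)
        res = le.power_change_at_stim(make_trialset(pre, during))
        assert res.percent_change == pytest.approx(100.0, rel=0.10)

    def test_scale_invariance_of_percent_change(self):
        rng = np.random.default_rng(5)
        pre = rng.standard_normal((4, 3000))
        during = rng.standard_normal((4, 3000)) * 1.3
        r1 = le.power_change_at_stim(make_trialset(pre, during))
        r2 = le.power_change_at_stim(make_trialset(2 * pre, 2 * during))
        assert r1.percent_change == pytest.approx(r2.percent_change, rel=1e-9)


class TestCoherenceChange:
    def test_identical_channels_zero_change(self):
        rng = np.random.default_rng(6)
        pre = rng.standard_normal((5, 3000))
        during = rng.standard_normal((5, 3000))
        hi = make_trialset(pre, during)
        tt = make_trialset(pre.copy(), during.copy(), location="TT")
        res = le.coherence_change_at_stim(hi, tt)
        assert res.percent_change == pytest.approx(0.0, abs=1e-6)
        assert res.baseline_value == pytest.approx(1.0, abs=1e-9)

    def test_shared_entrained_component_positive_change(self, short_session):
        hi, tt, events, _ = short_session
        f = events[0].frequency
        h = le.build_trials(hi, events, stim_freq=f)
        t = le.build_trials(tt, events, stim_freq=f)
        res = le.coherence_change_at_stim(h, t)
        assert res.percent_change > 0

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(7)
        hi = make_trialset(rng.standard_normal((30, 3000)),
                           rng.standard_normal((30, 3000)))
        tt = make_trialset(rng.standard_normal((30, 3000)),
                           rng.standard_normal((30, 3000)), location="TT")
        res = le.coherence_change_at_stim(hi, tt)
        assert abs(res.light_value - res.baseline_value) < 0.05

    def test_too_few_common_trials_raises(self):
        rng = np.random.default_rng(8)
        hi = make_trialset(rng.standard_normal((3, 3000)),
                           rng.standard_normal((3, 3000)))
        tt = dataclasses.replace(
            make_trialset(rng.standard_normal((3, 3000)),
                          rng.standard_normal((3, 3000)), location="TT"),
            trial_ids=np.array([10, 11, 12]))
        with pytest.raises(ValueError, match="common"):
            le.coherence_change_at_stim(hi, tt)


class TestDominantFrequency:
    def test_pure_tone_recovered_within_half_bin(self):
        t = np.arange(3000) / 1000.0
        x = np.tile(np.sin(2 * np.pi * 7.6 * t), (3, 1))
        trials = make_trialset(x, x.copy())
        est = le.dominant_theta_frequency(trials, "pre")
        assert abs(est - 7.6) <= (1 / 3.0) / 2

    def test_entrainment_shifts_dominant_frequency_toward_stim(self):
        proto = le.StimProtocol()
        p = le.LFPSimParams(session_duration=700, seed=3, entrainment_gain=1.5)
        hi, _, events, _ = le.simulate_lfp_session(p, proto)
        f_stim = events[0].frequency
        trials = le.build_trials(hi, events, stim_freq=f_stim)
        sel = le.select_theta_trials(trials)
        theta = trials.subset(sel.selected)
        pre_f = le.dominant_theta_frequency(theta, "pre")
        dur_f = le.dominant_theta_frequency(theta, "during")
        assert abs(dur_f - f_stim) < abs(pre_f - f_stim)

    def test_tie_breaks_to_lower_frequency(self, caplog):
        t = np.arange(3000) / 1000.0
        x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 10 * t)
        trials = make_trialset(np.tile(x, (2, 1)), np.tile(x, (2, 1)))
        est = le.dominant_theta_frequency(trials, "pre")
        assert est < 8.0


class TestAverageTrace:
    def test_single_trial_identity_and_length(self):
        rng = np.random.default_rng(9)
        pre = rng.standard_normal((1, 3000))
        during = rng.standard_normal((1, 3000))
        avg = le.average_trace(make_trialset(pre, during))
        assert len(avg) == 6000
        assert np.allclose(avg, np.concatenate([pre[0], during[0]]))

    def test_phase_reset_survives_averaging(self):
        """Phase-locked entrainment adds coherently; random phases cancel."""
        p = le.LFPSimParams(session_duration=700, entrainment_gain=2.0, seed=7)
        hi, _, events, _ = le.simulate_lfp_session(p, le.StimProtocol())
        trials = le.build_trials(hi, events, stim_freq=events[0].frequency)
        avg = le.average_trace(trials, filtered=True)
        rng = np.random.default_rng(10)
        shifted = np.array([np.roll(row, rng.integers(500, 2500))
                            for row in trials.during])
        ctrl = le.average_trace(
            dataclasses.replace(trials, during=shifted), filtered=True)
        post = slice(3200, 5800)
        assert np.std(avg[post]) > 2 * np.std(ctrl[post])


class TestDifferentialSpectrogram:
    def test_identical_windows_near_zero(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((6, 3000))
        d = le.differential_spectrogram(make_trialset(x, x.copy()))
        assert d.percent_increase.shape[0] == 21
        finite = d.percent_increase[np.isfinite(d.percent_increase)]
        # identical data, but the during columns differ from the baseline
        # *time-mean*; stationarity keeps them within estimator noise
        assert np.abs(np.nanmean(finite)) < 20

    def test_entrainment_row_localizes_to_stim_frequency(self):
        proto = le.StimProtocol(frequencies=(18.0,))
        p = le.LFPSimParams(session_duration=340, seed=2, entrainment_gain=3.0)
        hi, _, events, _ = le.simulate_lfp_session(p, proto)
        trials = le.build_trials(hi, events, stim_freq=18.0)
        d = le.differential_spectrogram(trials, AnalysisConfig(nw=1, k=1))
        mask = (d.freqs >= 2) & (d.freqs <= 40)
        mean_rows = np.nanmean(d.percent_increase[:, mask], axis=0)
        best = d.freqs[mask][np.argmax(mean_rows)]
        assert abs(best - 18.0) <= 1.0


class TestGenotypeSummary:
    def _result(self, animal, genotype, change, f=7.0):
        return le.ChangeResult(animal_id=animal, genotype=genotype,
                               location="HI", stim_freq=f, measure="power",
                               baseline_value=1.0, light_value=1.0,
                               percent_change=change, n_trials=10)

    def test_single_animal_mean_is_value(self):
        table = le.genotype_summary([self._result("a", "opsin+", 42.0)])
        assert table["mean"].iloc[0] == pytest.approx(42.0)
        assert table["n"].iloc[0] == 1

    def test_balanced_cohort_rows_complete(self):
        res = [self._result(f"p{i}", "opsin+", 50.0, f)
               for i in range(12) for f in (7.0, 40.0)]
        res += [self._result(f"n{i}", "opsin-", 0.0, f)
                for i in range(6) for f in (7.0, 40.0)]
        table = le.genotype_summary(res)
        assert len(table) == 4  # 2 genotypes x 2 frequencies
        assert set(table["genotype"]) == {"opsin+", "opsin-"}

    def test_opsin_positive_exceeds_negative_in_simulation(self):
        proto = le.StimProtocol()
        results = []
        for i, gain in enumerate([1.0] * 3 + [0.0] * 3):
            p = le.LFPSimParams(session_duration=410, entrainment_gain=gain,
                                seed=20 + i)
            hi, _, events, _ = le.simulate_lfp_session(p, proto)
            trials = le.build_trials(hi, events, stim_freq=events[0].frequency)
            trials, _ = le.reject_artifact_trials(trials)
            r = le.power_change_at_stim(trials)
            results.append(dataclasses.replace(r, animal_id=f"m{i}"))
        table = le.genotype_summary(results)
        pos = table.loc[table.genotype == "opsin+", "mean"].iloc[0]
        neg = table.loc[table.genotype == "opsin-", "mean"].iloc[0]
        assert pos > neg
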