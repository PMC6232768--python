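"""Signal path: filter frequency response, referencing, sliding-window
artifact rejection against a brute-force oracle, spherical-spline CSD against
independent oracles (spherical-harmonic eigenfunctions and mne), baseline
correction, averaging, electrode validation and amplitude quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import eval_legendre

from conftest import make_epochs
from metacontrol import synthetic_data as synth
from metacontrol.epochs import EpochSet
from metacontrol.erp_pipeline import (ComponentWindow, DEFAULT_COMPONENTS,
                                      ErpStack, average_erp, bandpass_filter,
                                      baseline_correct, csd_operator,
                                      csd_transform, default_baseline,
                                      preprocess, quantify_amplitude,
                                      reject_artifacts, rereference_average,
                                      resample_epochs, validate_electrodes)
from metacontrol.montage import default_montage

SFREQ = 256.0


def _tone(freq, sfreq=SFREQ, seconds=4.0):
    t = np.arange(int(seconds * sfreq)) / sfreq
    return np.sin(2 * np.pi * freq * t)


def _mid_rms(x):
    n = len(x)
    return np.sqrt(np.mean(x[n // 4: 3 * n // 4] ** 2))


class TestBandpass:
    def test_midband_tone_preserved(self):
        x = _tone(10.0)
        y = bandpass_filter(x, SFREQ)
        assert _mid_rms(y) == pytest.approx(_mid_rms(x), rel=0.05)

    def test_40hz_attenuated_by_at_least_40db(self):
        # long tone so the 0.5 Hz edge's settling does not pollute the middle
        x = _tone(40.0, seconds=30.0)
        y = bandpass_filter(x, SFREQ)
        assert _mid_rms(y) <= _mid_rms(x) * 10 ** (-40 / 20)

    def test_dc_removed(self):
        x = np.full(2048, 7.0)
        y = bandpass_filter(x, SFREQ)
        assert np.abs(y[512:-512]).max() < 0.01 * 7.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_tone(10), SFREQ, low_hz=20, high_hz=5)
        with pytest.raises(ValueError):
            bandpass_filter(_tone(10), 30.0)  # sfreq too low for 20 Hz edge


def test_resample_preserves_band_limited_tone(montage):
    t = np.arange(2000) / 500.0
    x = np.sin(2 * np.pi * 8 * t)
    eps = make_epochs(np.tile(x, (2, 60, 1)), sfreq=500.0, montage=montage)
    out = resample_epochs(eps, 256.0)
    assert out.sfreq == 256.0
    t2 = np.arange(out.n_times) / 256.0
    expected = np.sin(2 * np.pi * 8 * t2)
    core = slice(100, out.n_times - 100)
    assert np.allclose(out.data[0, 0, core], expected[core], atol=0.02)


class TestReference:
    def test_constant_becomes_zero(self, montage):
        eps = make_epochs(np.full((3, 60, 64), 5.0), montage=montage,
                          t0_ms=0.0)
        out = rereference_average(eps)
        assert np.abs(out.data).max() < 1e-12

    def test_channel_mean_zero(self, montage):
        rng = np.random.default_rng(0)
        eps = make_epochs(rng.normal(size=(4, 60, 64)), montage=montage,
                          t0_ms=0.0)
        out = rereference_average(eps)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-9

    def test_zero_mean_input_unchanged(self):
        m = default_montage()
        data = np.zeros((1, 60, 16))
        data[0, 0] = 1.0
        data[0, 1] = -1.0
        eps = make_epochs(data, montage=m, t0_ms=0.0)
        assert np.allclose(rereference_average(eps).data, data)

    def test_csd_units_rejected(self, montage):
        eps = make_epochs(np.zeros((1, 60, 16)), montage=montage,
                          units="csd", t0_ms=0.0)
        with pytest.raises(ValueError):
            rereference_average(eps)


def _brute_force_mask(data, sfreq, max_diff=200.0, diff_ms=200.0,
                      min_act=0.5, act_ms=100.0):
    """Independent two-loop implementation of the rejection criteria."""
    wd = max(2, int(round(diff_ms * sfreq / 1000.0)))
    wa = max(2, int(round(act_ms * sfreq / 1000.0)))
    n_tr, n_ch, n_t = data.shape
    mask = np.zeros(n_tr, bool)
    for tr in range(n_tr):
        bad = False
        for ch in range(n_ch):
            x = data[tr, ch]
            for i in range(n_t - wd + 1):
                w = x[i:i + wd]
                if w.max() - w.min() > max_diff:
                    bad = True
                    break
            if bad:
                break
            for i in range(n_t - wa + 1):
                w = x[i:i + wa]
                if w.max() - w.min() < min_act:
                    bad = True
                    break
            if bad:
                break
        mask[tr] = bad
    return mask


class TestRejection:
    def _small(self, data):
        from metacontrol.montage import Montage
        m = default_montage()
        mini = Montage(names=m.names[:data.shape[1]],
                       positions=m.positions[:data.shape[1]])
        return make_epochs(data, montage=mini, t0_ms=0.0)

    def test_spike_rejected(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 5, size=(1, 3, 128))
        data[0, 1, 60] += 500.0
        eps = self._small(data)
        _, mask = reject_artifacts(eps)
        assert mask[0]

    def test_flat_epoch_rejected(self):
        eps = self._small(np.zeros((1, 3, 128)))
        _, mask = reject_artifacts(eps)
        assert mask[0]

    def test_smooth_oscillation_retained(self):
        t = np.arange(128) / SFREQ
        x = 10.0 * np.sin(2 * np.pi * 10 * t)
        eps = self._small(np.tile(x, (1, 3, 1)))
        kept, mask = reject_artifacts(eps)
        assert not mask[0] and kept.n_trials == 1

    def test_matches_brute_force_on_random_epochs(self):
        rng = np.random.default_rng(42)
        n_trials = 100
        data = rng.normal(0, 25, size=(n_trials, 3, 96))
        # plant some spikes and flats so both criteria fire
        for k in range(0, n_trials, 7):
            data[k, rng.integers(3), 40] += 300.0
        for k in range(3, n_trials, 11):
            ch = rng.integers(3)
            data[k, ch, 10:48] = data[k, ch, 10]
        # a few epochs of near-zero activity
        for k in range(5, n_trials, 23):
            data[k] = rng.normal(0, 0.05, size=(3, 96))
        eps = self._small(data)
        _, mask = reject_artifacts(eps)
        expected = _brute_force_mask(data, SFREQ)
        assert np.array_equal(mask, expected)
        assert mask.any() and not mask.all()


class TestCSD:
    def test_constant_maps_to_zero(self, montage):
        op = csd_operator(montage)
        out = op @ np.full(60, 123.4)
        assert np.abs(out).max() < 1e-6 * 123.4

    def test_linearity(self, montage):
        rng = np.random.default_rng(3)
        eps_x = make_epochs(rng.normal(size=(2, 60, 32)), montage=montage,
                            t0_ms=0.0)
        eps_y = make_epochs(rng.normal(size=(2, 60, 32)), montage=montage,
                            t0_ms=0.0)
        a, b = 2.5, -1.25
        combo = make_epochs(a * eps_x.data + b * eps_y.data, montage=montage,
                            t0_ms=0.0)
        lhs = csd_transform(combo).data
        rhs = a * csd_transform(eps_x).data + b * csd_transform(eps_y).data
        assert np.abs(lhs - rhs).max() < 1e-9 * max(1, np.abs(lhs).max())

    def test_focal_source_peaks_at_same_electrode_with_inverted_surround(
            self, montage):
        pz = montage.index("Pz")
        d = montage.geodesic_distances()[:, pz]
        v = np.exp(-d ** 2 / (2 * 0.4 ** 2))
        out = csd_operator(montage) @ v
        assert np.argmax(out) == pz
        ring = (d > 0.5) & (d < 1.2)
        assert out[ring].mean() < 0

    def test_spherical_harmonic_eigenfunction_oracle(self, montage):
        """A degree-n Legendre topography is an eigenfunction of the surface
        Laplacian with eigenvalue n(n+1); the spline estimate must reproduce
        it (closed-form oracle, no spline code involved)."""
        z = montage.positions @ montage.positions[montage.index("Cz")]
        for n in (1, 2, 3):
            v = eval_legendre(n, z)
            out = csd_operator(montage, lambda_reg=1e-9) @ v
            expected = n * (n + 1) * v
            # finite 60-electrode sampling limits the spline interpolation;
            # the relative L2 error stays well under 10%
            err = np.linalg.norm(out - expected) / np.linalg.norm(expected)
            assert err < 0.10

    def test_matches_mne_implementation(self, montage):
        """Independent cross-check against mne's spherical-spline CSD with
        identical stiffness, truncation and regularization."""
        mne = pytest.importorskip("mne")
        mne.set_log_level("ERROR")
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 20))
        radius = 0.09
        info = mne.create_info(list(montage.names), SFREQ, "eeg")
        ev = mne.EvokedArray(X.copy(), info, tmin=0)
        ev.set_montage(mne.channels.make_dig_montage(
            ch_pos={n: p * radius for n, p in
                    zip(montage.names, montage.positions)},
            coord_frame="head"))
        ref = mne.preprocessing.compute_current_source_density(
            ev, sphere=(0.0, 0.0, 0.0, radius), lambda2=1e-5, stiffness=4,
            n_legendre_terms=10).data
        mine = csd_operator(montage, 4, 10, 1e-5, head_radius_m=radius) @ X
        assert np.allclose(mine, ref, rtol=1e-6, atol=1e-9)

    def test_csd_input_units_checked(self, montage):
        eps = make_epochs(np.zeros((1, 60, 8)), montage=montage,
                          units="csd", t0_ms=0.0)
        with pytest.raises(ValueError):
            csd_transform(eps)


class TestBaseline:
    def test_constant_epoch_zeroed(self, montage):
        eps = make_epochs(np.full((2, 60, 1024), 3.3), montage=montage)
        out = baseline_correct(eps)
        assert np.abs(out.data).max() < 1e-12

    def test_baseline_window_mean_zero_random_input(self, montage):
        rng = np.random.default_rng(8)
        for locking, window in [("stimulus", (-300.0, 0.0)),
                                ("response", (300.0, 400.0))]:
            eps = make_epochs(rng.normal(size=(3, 60, 1024)), montage=montage,
                              locking=locking)
            out = baseline_correct(eps)
            sl = out.window_slice(*window)
            assert np.abs(out.data[:, :, sl].mean(axis=2)).max() < 1e-9
            assert default_baseline(locking) == window

    def test_window_outside_epoch_rejected(self, montage):
        eps = make_epochs(np.zeros((1, 60, 64)), montage=montage, t0_ms=0.0)
        with pytest.raises(ValueError):
            baseline_correct(eps, (-300.0, 0.0))


class TestAveraging:
    def test_identical_trials(self, montage):
        x = np.random.default_rng(0).normal(size=(60, 64))
        eps = make_epochs(np.tile(x, (5, 1, 1)), montage=montage, t0_ms=0.0)
        avg, n = average_erp(eps)
        assert n == 5
        assert np.allclose(avg, x)

    def test_noise_shrinks_as_sqrt_n(self, montage):
        rng = np.random.default_rng(1)
        n = 100
        eps = make_epochs(rng.normal(0, 1, size=(n, 60, 64)), montage=montage,
                          t0_ms=0.0)
        avg, _ = average_erp(eps)
        assert avg.std() == pytest.approx(1 / np.sqrt(n), rel=0.2)

    def test_only_correct_trials_enter(self, montage):
        data = np.zeros((4, 60, 16))
        data[2:] = 10.0
        eps = make_epochs(data, montage=montage, t0_ms=0.0,
                          correct=[True, True, False, False])
        avg, n = average_erp(eps)
        assert n == 2 and np.abs(avg).max() == 0

    def test_empty_cell_flagged(self, montage):
        eps = make_epochs(np.zeros((2, 60, 16)), montage=montage, t0_ms=0.0,
                          correct=[False, False])
        with pytest.raises(ValueError):
            average_erp(eps)


def _stack(data, montage, task="easy", locking="stimulus", units="csd"):
    return ErpStack(data=data, subjects=np.arange(1, data.shape[0] + 1),
                    task=task, locking=locking, sfreq=SFREQ, t0_ms=-2000.0,
                    montage=montage, units=units)


class TestElectrodeValidation:
    def test_planted_component_detected(self, montage):
        rng = np.random.default_rng(2)
        n_subj = 12
        data = rng.normal(0, 0.5, size=(n_subj, 60, 1024))
        idx = montage.indices(["P7", "P8"])
        sl = slice(540, 545)
        data[:, idx[:, None], sl] += 20.0
        tbl = validate_electrodes(_stack(data, montage), (95, 120))
        selected = set(tbl[tbl["selected"]]["electrode"])
        assert {"P7", "P8"} <= selected

    def test_false_selection_rate_calibrated(self, montage):
        """On pure-noise ERPs each electrode family false-selects at ~alpha
        in total (Bonferroni keeps the family-wise rate at alpha)."""
        rng = np.random.default_rng(3)
        n_rep, alpha = 200, 0.05
        hits = 0
        for _ in range(n_rep):
            data = rng.normal(size=(8, 60, 40))
            stack = ErpStack(data=data, subjects=np.arange(8), task="easy",
                             locking="stimulus", sfreq=SFREQ, t0_ms=0.0,
                             montage=montage, units="csd")
            tbl = validate_electrodes(stack, (0, 150), alpha=alpha)
            hits += int(tbl["selected"].any())
        rate = hits / n_rep
        assert rate < 3 * alpha  # family-wise rate bounded near alpha

    def test_single_subject_rejected(self, montage):
        with pytest.raises(ValueError):
            validate_electrodes(_stack(np.zeros((1, 60, 64)), montage),
                                (0, 100))


class TestQuantification:
    def test_constant_erp_any_window(self, montage):
        stacks = {t: _stack(np.full((3, 60, 1024), 10.0), montage, task=t)
                  for t in ("easy", "hard")}
        comp = ComponentWindow("X", "stimulus", ("Pz",), (100, 200))
        tbl = quantify_amplitude(stacks, comp)
        assert np.allclose(tbl["amplitude"], 10.0)
        assert len(tbl) == 6

    def test_n450_uses_per_task_windows(self, montage):
        comp = next(c for c in DEFAULT_COMPONENTS if c.name == "N450")
        assert comp.window_for("easy") == (380, 400)
        assert comp.window_for("hard") == (395, 415)
        data = np.zeros((2, 60, 1024))
        stack_e = _stack(data.copy(), montage, task="easy")
        stack_h = _stack(data.copy(), montage, task="hard")
        cz = montage.index("Cz")
        sl_e = stack_e.window_slice(380, 400)
        sl_h = stack_h.window_slice(395, 415)
        stack_e.data[:, cz, sl_e] = 5.0
        stack_h.data[:, cz, sl_h] = -7.0
        tbl = quantify_amplitude({"easy": stack_e, "hard": stack_h}, comp)
        by_task = tbl.groupby("task")["amplitude"].mean()
        assert by_task["easy"] == pytest.approx(5.0)
        assert by_task["hard"] == pytest.approx(-7.0)

    def test_window_convention_sample_counts(self, montage):
        stack = _stack(np.zeros((1, 60, 1024)), montage)
        sl = stack.window_slice(-300.0, 1000.0)
        assert sl.stop - sl.start == 333

    def test_potential_units_rejected(self, montage):
        stacks = {t: _stack(np.zeros((2, 60, 1024)), montage, task=t,
                            units="potential") for t in ("easy", "hard")}
        with pytest.raises(ValueError):
            quantify_amplitude(stacks, DEFAULT_COMPONENTS[0])


def test_preprocess_records_canonical_order(montage):
    rng = np.random.default_rng(0)
    eps = make_epochs(rng.normal(0, 10, size=(4, 60, 1024)), montage=montage)
    out, mask, steps = preprocess(eps)
    assert steps == ["bandpass_filter", "resample", "rereference_average",
                     "reject_artifacts", "csd_transform", "baseline_correct"]
    assert out.units == "csd"
    assert len(mask) == 4


def test_planted_task_effect_recovered_through_quantification(montage):
    """Parameter-recovery oracle: a response-locked P3 task effect planted by
    the generator is recovered by the CSD + baseline + average + quantify
    path within 2 SEM of the cohort estimate."""
    delta = 6.38
    tpl = synth.ErpTemplateSpec("P3_parietal_resp", "response", -30, 300,
                                ("Pz",), base_amplitude=17.85,
                                task_effect=delta)
    params = synth.CohortParams(n_subjects=10, n_trials_per_task=40, seed=21)
    trials = synth.generate_behavior(params)
    noise = synth.NoiseSpec(white_sd=10.0)
    comp = next(c for c in DEFAULT_COMPONENTS if c.name == "P3_parietal_resp")
    diffs = []
    for s in sorted(trials["subject"].unique()):
        eps = synth.generate_epochs_subject(params, (tpl,), noise, trials,
                                            montage, s)
        amps = {}
        for task in ("easy", "hard"):
            resp = eps[task][1]
            resp = csd_transform(resp)
            resp = baseline_correct(resp)
            avg, _ = average_erp(resp)
            stack = ErpStack(data=avg[None], subjects=np.array([s]),
                             task=task, locking="response", sfreq=SFREQ,
                             t0_ms=-2000.0, montage=montage, units="csd")
            amps[task] = quantify_amplitude({task: stack}, comp)[
                "amplitude"].iloc[0]
        diffs.append(amps["easy"] - amps["hard"])
    diffs = np.asarray(diffs)
    sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - delta) <= 2 * sem
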