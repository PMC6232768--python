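"""Synthetic two-group, two-task behavioral + EEG cohort generator.

Emulates the study conditions every downstream stage expects: a cohort of
subjects split into a (latent) low/high adaptability group, each performing an
easy and a hard task of 480 trials, with right-skewed reaction times truncated
at the 2000 ms response deadline (late responses become misses), and epoched
60-channel EEG at 256 Hz carrying the standard ERP components.  The only
planted group x task interaction sits on the response-locked parietal P3; all
other components carry task effects only, so recovering the interaction
pattern downstream is a planted-truth test.

Component amplitudes are specified on the CSD scale (µV/m²).  Because the
generator emits scalp potentials (µV) that the analysis pipeline later pushes
through the CSD transform, each template's potential-domain topography is
pre-compensated through the default CSD operator so that the planted
amplitude is what the standard quantification recovers at the peak
electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet, RESPONSE, STIMULUS
from .erp_pipeline import csd_operator
from .montage import Montage, default_montage

__all__ = [
    "CohortParams", "ErpTemplateSpec", "NoiseSpec",
    "default_templates", "generate_behavior", "generate_epochs",
    "generate_epochs_subject", "inject_artifacts",
    "write_trials", "read_trials",
]

EASY, HARD = "easy", "hard"
DEADLINE_MS = 2000.0

TRIAL_COLUMNS = ["subject", "group_true", "task", "trial", "shape", "color",
                 "size", "response", "correct", "rt_ms", "miss"]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class CohortParams:
    """Cohort-level behavioral parameters.

    Defaults reproduce the reference cohort: n = 227 subjects, 480 trials per
    task, grand-mean performance ratios near 0.212 (easy) and 0.14 (hard)
    %/ms, and a high-group advantage confined to the easy task.

    ``delta_easy_high_group`` is expressed in performance-ratio units (%/ms):
    the high group's easy-task RT mean is scaled down (and the low group's
    up) so the two groups' expected easy-task ratios differ by this amount.
    ``rt_subject_sd`` and ``acc_subject_sd`` are between-subject trait spreads
    (log-normal RT multiplier; logit-scale accuracy jitter), truncated at
    ±2.33 sd and sized so a full cohort's per-task ratio ranges stay inside
    the reference ranges (easy 0.14-0.28, hard 0.08-0.20).
    """

    n_subjects: int = 227
    n_trials_per_task: int = 480
    group_fraction_high: float = 0.5
    rt_mean_easy_ms: float = 460.0
    rt_mean_hard_ms: float = 660.0
    rt_sigma: float = 0.25
    acc_easy: float = 0.98
    acc_hard: float = 0.92
    delta_easy_high_group: float = 0.03
    rt_subject_sd: float = 0.065
    acc_subject_sd: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_trials_per_task < 1:
            raise ValueError("cohort needs >=2 subjects and >=1 trial per task")
        for p in (self.acc_easy, self.acc_hard):
            if not 0 < p <= 1:
                raise ValueError("accuracies must lie in (0, 1]")
        if not 0 <= self.group_fraction_high <= 1:
            raise ValueError("group_fraction_high must lie in [0, 1]")
        for rt in (self.rt_mean_easy_ms, self.rt_mean_hard_ms):
            if not 0 < rt <= DEADLINE_MS:
                raise ValueError("RT means must lie in (0, 2000] ms")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")


@dataclass(frozen=True)
class ErpTemplateSpec:
    """One ERP component template.

    The waveform is a Hanning bump of the given width centered at the peak
    latency (relative to the locking event); the topography falls off as a
    spatial Gaussian of ``spatial_sigma_rad`` in geodesic distance from the
    nearest peak electrode.  Amplitude per cell is

        base + s_task * task_effect/2 + s_task * s_group * group_task_effect/2

    with ``s_task`` = +1 easy / -1 hard and ``s_group`` = +1 high / -1 low,
    so ``task_effect`` is the easy-hard difference and ``group_task_effect``
    is the high-low difference of those task differences (the interaction).
    ``task_latency_shift_ms`` delays the hard-task peak (N450 latency shift).
    """

    name: str
    locking: str
    peak_latency_ms: float
    width_ms: float
    electrodes: tuple[str, ...]
    base_amplitude: float
    task_effect: float = 0.0
    group_task_effect: float = 0.0
    task_latency_shift_ms: float = 0.0
    spatial_sigma_rad: float = 0.45

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError(f"{self.name}: width must be positive")

    def amplitude(self, task: str, group: str) -> float:
        s_t = 1.0 if task == EASY else -1.0
        s_g = 1.0 if group == "high" else -1.0
        return (self.base_amplitude + s_t * self.task_effect / 2.0
                + s_t * s_g * self.group_task_effect / 2.0)

    def latency(self, task: str) -> float:
        return self.peak_latency_ms + (self.task_latency_shift_ms
                                       if task == HARD else 0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model and artifact rates.

    Noise is generated as white Gaussian noise of ``white_sd`` µV, spectrally
    shaped to a 1/f^(exponent) power profile above 1 Hz (total variance kept
    at ``white_sd``²), and spatially mixed with an exponential-decay
    covariance over geodesic electrode distance (``spatial_decay_rad``).
    """

    white_sd: float = 10.0
    one_over_f_exponent: float = 1.0
    spatial_decay_rad: float = 0.6
    spike_rate: float = 0.0
    flat_rate: float = 0.0
    drift_rate: float = 0.0
    spike_amplitude_uv: float = 500.0
    flat_duration_ms: float = 150.0

    def validate(self) -> None:
        if self.white_sd < 0:
            raise ValueError("noise sd must be non-negative")
        for r in (self.spike_rate, self.flat_rate, self.drift_rate):
            if not 0 <= r <= 1:
                raise ValueError("artifact rates must lie in [0, 1]")


def default_templates() -> tuple[ErpTemplateSpec, ...]:
    """The default component battery with reference-scale CSD amplitudes.

    Bases and task effects follow the grand-mean amplitudes of the reference
    cohort; the group x task interaction (high-low difference of easy-hard
    differences: 3.69 µV/m²) is planted only on the response-locked parietal
    P3.
    """
    return (
        ErpTemplateSpec("P1", STIMULUS, 100, 60, ("P7", "P8"),
                        base_amplitude=27.31, task_effect=1.18),
        ErpTemplateSpec("N1", STIMULUS, 175, 70, ("P7", "P8", "P9", "P10"),
                        base_amplitude=-23.30, task_effect=-3.47),
        ErpTemplateSpec("N2", STIMULUS, 240, 80, ("Cz",),
                        base_amplitude=-10.17, task_effect=1.96),
        ErpTemplateSpec("N450", STIMULUS, 390, 90, ("Cz",),
                        base_amplitude=-5.91, task_effect=13.21,
                        task_latency_shift_ms=15.0),
        ErpTemplateSpec("P3_frontocentral", STIMULUS, 600, 220, ("Cz",),
                        base_amplitude=4.06, task_effect=4.26),
        ErpTemplateSpec("P3_parietal_stim", STIMULUS, 315, 120, ("PO1", "PO2"),
                        base_amplitude=15.0, task_effect=0.0),
        ErpTemplateSpec("P3_parietal_resp", RESPONSE, -30, 300, ("Pz",),
                        base_amplitude=17.85, task_effect=6.38,
                        group_task_effect=3.69),
    )


# ---------------------------------------------------------------------------
# behavior

def _split_group_sizes(n: int, fraction_high: float) -> tuple[int, int]:
    n_high = int(np.floor(n * fraction_high))
    return n - n_high, n_high


def generate_behavior(params: CohortParams) -> pd.DataFrame:
    """Simulate the behavioral trial table for the whole cohort.

    One row per subject x task x trial.  RTs are log-normal around a
    subject-specific mean (shared log-normal trait multiplier across tasks);
    draws beyond the 2000 ms deadline become misses (no RT, coded incorrect).
    The latent ``group_true`` label receives the easy-task advantage.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xB0]))
    n = params.n_subjects
    n_low, n_high = _split_group_sizes(n, params.group_fraction_high)
    groups = np.array(["low"] * n_low + ["high"] * n_high)
    rng.shuffle(groups)

    shapes = np.array(["square", "diamond"])
    colors = np.array(["green", "red"])
    sizes = np.array(["small", "large"])

    base_ratio_easy = 100.0 * params.acc_easy / params.rt_mean_easy_ms
    rows = []
    # subject traits are truncated at +-2.33 sd (99th pct) so cohort extremes
    # stay within the reference performance-ratio bands
    z_cap = 2.33
    for si in range(n):
        subject = si + 1
        group = groups[si]
        m_rt = np.exp(params.rt_subject_sd
                      * np.clip(rng.standard_normal(), -z_cap, z_cap))
        for task in (EASY, HARD):
            acc0 = params.acc_easy if task == EASY else params.acc_hard
            rt0 = params.rt_mean_easy_ms if task == EASY else params.rt_mean_hard_ms
            if task == EASY and params.delta_easy_high_group != 0:
                half = params.delta_easy_high_group / 2.0
                shift = half if group == "high" else -half
                rt0 = rt0 * base_ratio_easy / (base_ratio_easy + shift)
            logit = np.log(acc0 / (1 - acc0)) if acc0 < 1 else np.inf
            logit = logit + params.acc_subject_sd * np.clip(
                rng.standard_normal(), -z_cap, z_cap)
            acc_s = 1.0 if np.isinf(logit) else 1.0 / (1.0 + np.exp(-logit))
            rt_mean_s = rt0 * m_rt

            nt = params.n_trials_per_task
            # mean-preserving log-normal: E[rt] = rt_mean_s
            rts = rt_mean_s * rng.lognormal(-params.rt_sigma ** 2 / 2.0,
                                            params.rt_sigma, nt)
            miss = rts > DEADLINE_MS
            correct = rng.random(nt) < acc_s
            correct &= ~miss
            shp = rng.choice(shapes, nt)
            col = rng.choice(colors, nt)
            sz = rng.choice(sizes, nt)
            # easy rule: diamond -> left, square -> right;
            # hard rule: (large,red)|(small,green) -> left, else right
            if task == EASY:
                correct_side = np.where(shp == "diamond", "left", "right")
            else:
                left = ((sz == "large") & (col == "red")) | \
                       ((sz == "small") & (col == "green"))
                correct_side = np.where(left, "left", "right")
            other = np.where(correct_side == "left", "right", "left")
            response = np.where(miss, "none",
                                np.where(correct, correct_side, other))
            for ti in range(nt):
                rows.append((subject, group, task, ti + 1, shp[ti], col[ti],
                             sz[ti], response[ti], bool(correct[ti]),
                             float(rts[ti]) if not miss[ti] else np.nan,
                             bool(miss[ti])))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return t


# ---------------------------------------------------------------------------
# EEG epochs

def _hann_bump(times_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak Hanning bump supported on |t - center| < width/2."""
    x = (times_ms - center_ms) / width_ms
    out = np.zeros_like(times_ms, dtype=float)
    inside = np.abs(x) < 0.5
    out[inside] = np.cos(np.pi * x[inside]) ** 2
    return out


def _topography(template: ErpTemplateSpec, montage: Montage) -> np.ndarray:
    """Unit-peak spatial Gaussian over geodesic distance to the nearest
    peak electrode."""
    idx = montage.indices(template.electrodes)   # raises if absent
    dists = montage.geodesic_distances()[:, idx].min(axis=1)
    return np.exp(-dists ** 2 / (2 * template.spatial_sigma_rad ** 2))


def _csd_compensated_topography(template: ErpTemplateSpec, montage: Montage,
                                csd_op: np.ndarray) -> np.ndarray:
    """Scale the potential topography so the default CSD transform returns a
    peak-electrode amplitude of exactly 1 (see module docstring)."""
    w = _topography(template, montage)
    gain = (csd_op @ w)[montage.indices(template.electrodes)].mean()
    if gain <= 0:
        raise ValueError(f"{template.name}: degenerate CSD gain")
    return w / gain


def _colored_noise(rng: np.random.Generator, shape: tuple, sfreq: float,
                   noise: NoiseSpec, mix: np.ndarray | None) -> np.ndarray:
    """(trials, channels, time) noise: 1/f-shaped in time, mixed in space."""
    n_t = shape[-1]
    white = rng.standard_normal(shape, dtype=np.float32)
    if noise.one_over_f_exponent > 0:
        freqs = np.fft.rfftfreq(n_t, 1.0 / sfreq)
        amp = np.ones_like(freqs, dtype=np.float32)
        nz = freqs >= 1.0
        amp[nz] = freqs[nz] ** (-noise.one_over_f_exponent / 2.0)
        amp[0] = amp[1]  # keep DC finite
        spec = np.fft.rfft(white, axis=-1) * amp
        out = np.fft.irfft(spec, n=n_t, axis=-1)
        # unit output variance: rfft bins carry weight 2 except DC (and
        # Nyquist when n_t is even)
        w = np.full_like(amp, 2.0)
        w[0] = 1.0
        if n_t % 2 == 0:
            w[-1] = 1.0
        out /= np.sqrt((w * amp ** 2).sum() / n_t)
        white = out
    if mix is not None:
        white = np.einsum("ij,tjk->tik", mix.astype(np.float32), white)
    return noise.white_sd * white.astype(float)


def _spatial_mixer(montage: Montage, decay_rad: float) -> np.ndarray | None:
    if decay_rad <= 0:
        return None
    d = montage.geodesic_distances()
    k = np.exp(-d / decay_rad) + 1e-9 * np.eye(len(montage))
    return np.linalg.cholesky(k)


def generate_epochs_subject(params: CohortParams, templates, noise: NoiseSpec,
                            behavior: pd.DataFrame, montage: Montage,
                            subject: int, sfreq: float = 256.0):
    """Stimulus- and response-locked EpochSets for one subject.

    Signals are synthesized on a common per-trial stimulus-clock buffer
    spanning -2000..+4000 ms; the stimulus-locked segment is the first
    2000/sfreq-aligned 4 s window and the response-locked segment is the same
    trial re-cut around the (grid-rounded) response time, so the two lockings
    share signal and noise.  Only correct-response trials yield epochs.
    """
    noise.validate()
    for t in templates:
        montage.indices(t.electrodes)  # validate electrodes early
    sub = behavior[(behavior["subject"] == subject) & behavior["correct"]]
    if len(sub) == 0:
        raise ValueError(f"subject {subject} has no correct trials")
    csd_op = csd_operator(montage)
    topo = {t.name: _csd_compensated_topography(t, montage, csd_op)
            for t in templates}
    mix = _spatial_mixer(montage, noise.spatial_decay_rad)

    n_seg = int(round(4.0 * sfreq))            # 4 s, 1024 samples at 256 Hz
    n_buf = int(round(6.0 * sfreq))
    buf_times = -2000.0 + np.arange(n_buf) * 1000.0 / sfreq
    group = str(sub["group_true"].iloc[0])

    out = {}
    for task in (EASY, HARD):
        tt = sub[sub["task"] == task]
        rts = tt["rt_ms"].to_numpy(float)
        m = len(tt)
        if m == 0:
            raise ValueError(f"subject {subject} has no correct {task} trials")
        rt_idx = np.round(rts * sfreq / 1000.0).astype(int)
        rt_grid = rt_idx * 1000.0 / sfreq

        clean = np.zeros((m, len(montage), n_buf))
        # stimulus-locked components: identical across trials of this cell
        stim_wave = np.zeros(n_buf)
        cell = np.zeros((len(montage), n_buf))
        for tpl in templates:
            amp = tpl.amplitude(task, group)
            if tpl.locking == STIMULUS:
                wave = _hann_bump(buf_times, tpl.latency(task), tpl.width_ms)
                cell += amp * np.outer(topo[tpl.name], wave)
        clean += cell[None, :, :]
        for tpl in templates:
            if tpl.locking != RESPONSE:
                continue
            amp = tpl.amplitude(task, group)
            for k in range(m):
                wave = _hann_bump(buf_times, rt_grid[k] + tpl.latency(task),
                                  tpl.width_ms)
                clean[k] += amp * np.outer(topo[tpl.name], wave)

        seed = np.random.SeedSequence(
            [params.seed, 0xEE6, int(subject), 0 if task == EASY else 1])
        rng = np.random.default_rng(seed)
        if noise.white_sd > 0:
            data = clean + _colored_noise(rng, clean.shape, sfreq, noise, mix)
        else:
            data = clean

        info = tt[["subject", "group_true", "task", "trial", "correct",
                   "rt_ms"]].reset_index(drop=True)
        stim = EpochSet(data=data[:, :, :n_seg], sfreq=sfreq, t0_ms=-2000.0,
                        locking=STIMULUS, montage=montage,
                        trial_info=info.copy(), units="potential")
        resp_data = np.empty((m, len(montage), n_seg))
        for k in range(m):
            resp_data[k] = data[k, :, rt_idx[k]:rt_idx[k] + n_seg]
        resp = EpochSet(data=resp_data, sfreq=sfreq, t0_ms=-2000.0,
                        locking=RESPONSE, montage=montage,
                        trial_info=info.copy(), units="potential")
        out[task] = (stim, resp)
    return out


def generate_epochs(params: CohortParams, templates, noise: NoiseSpec,
                    behavior: pd.DataFrame, montage: Montage,
                    subjects=None, sfreq: float = 256.0):
    """Epochs for several subjects: {subject: {task: (stimulus, response)}}.

    For large cohorts prefer :func:`generate_epochs_subject` in a streaming
    loop; this convenience materializes everything in memory.
    """
    if subjects is None:
        subjects = sorted(behavior["subject"].unique())
    return {s: generate_epochs_subject(params, templates, noise, behavior,
                                       montage, s, sfreq)
            for s in subjects}


# ---------------------------------------------------------------------------
# artifact injection

def inject_artifacts(epochs: EpochSet, noise: NoiseSpec, seed: int = 0):
    """Plant spike and flat-channel artifacts; return (epochs, labels).

    Spiked epochs receive a sharp triangular transient of
    ``spike_amplitude_uv`` (default 500 µV, violating the 200 µV / 200 ms
    criterion); flattened epochs get one channel replaced by a constant over
    ``flat_duration_ms`` (violating the 0.5 µV / 100 ms criterion).  The
    returned label table marks ground truth per trial for rejector testing.
    """
    noise.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA27]))
    data = epochs.data.copy()
    n_tr, n_ch, n_t = data.shape
    spiked = rng.random(n_tr) < noise.spike_rate
    flattened = rng.random(n_tr) < noise.flat_rate
    drifted = rng.random(n_tr) < noise.drift_rate

    spike_len = max(3, int(round(0.03 * epochs.sfreq)))
    flat_len = int(round(noise.flat_duration_ms * epochs.sfreq / 1000.0))
    pulse = 1.0 - np.abs(np.linspace(-1, 1, spike_len))
    for k in np.flatnonzero(spiked):
        ch = rng.integers(n_ch)
        t0 = rng.integers(0, n_t - spike_len)
        data[k, ch, t0:t0 + spike_len] += noise.spike_amplitude_uv * pulse
    for k in np.flatnonzero(flattened):
        ch = rng.integers(n_ch)
        t0 = rng.integers(0, n_t - flat_len)
        data[k, ch, t0:t0 + flat_len] = data[k, ch, t0]
    for k in np.flatnonzero(drifted):
        ch = rng.integers(n_ch)
        data[k, ch] += np.linspace(0, 100.0, n_t)

    labels = pd.DataFrame({"spike": spiked, "flat": flattened,
                           "drift": drifted})
    return epochs.copy_with(data=data), labels
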