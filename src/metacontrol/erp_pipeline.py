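"""ERP preprocessing and component quantification.

Implements the fixed preprocessing chain for segmented EEG:

    band-pass filter -> resample -> average reference -> artifact rejection
    -> spherical-spline CSD -> baseline correction -> per-condition averaging

followed by component amplitude quantification in fixed time windows over
fixed electrode sets, and a Bonferroni-corrected electrode-validation
procedure (each electrode's window-mean amplitude tested against the mean of
all remaining electrodes across subjects).

Analysis windows are half-open ``[start, end)`` on sample periods: the first
sample is the one at or immediately before ``start`` so a window of W ms
always covers ``ceil(W * sfreq / 1000)`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.special import eval_legendre
from scipy.stats import ttest_rel

from .epochs import EpochSet, RESPONSE, STIMULUS
from .montage import Montage

__all__ = [
    "ComponentWindow", "DEFAULT_COMPONENTS", "ErpStack",
    "bandpass_filter", "resample_epochs", "rereference_average",
    "reject_artifacts", "csd_operator", "csd_transform", "baseline_correct",
    "default_baseline", "average_erp", "validate_electrodes",
    "quantify_amplitude", "preprocess",
]


# ---------------------------------------------------------------------------
# component windows

@dataclass(frozen=True)
class ComponentWindow:
    """Named ERP component: electrode set, quantification window, locking.

    ``task_windows`` optionally overrides the window per task (the N450 is
    quantified in task-specific windows because its latency shifts with task
    difficulty).
    """

    name: str
    locking: str
    electrodes: tuple[str, ...]
    window_ms: tuple[float, float]
    task_windows: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        for w in [self.window_ms, *(self.task_windows or {}).values()]:
            if w[0] >= w[1]:
                raise ValueError(f"{self.name}: window start must precede end")

    def window_for(self, task: str) -> tuple[float, float]:
        if self.task_windows and task in self.task_windows:
            return self.task_windows[task]
        return self.window_ms


#: The standard component battery: early visual attention (P1/N1), conflict
#: monitoring (N2/N450), and the P3 family, with the response-locked parietal
#: P3 quantified just before the response.
DEFAULT_COMPONENTS: tuple[ComponentWindow, ...] = (
    ComponentWindow("P1", STIMULUS, ("P7", "P8"), (95, 105)),
    ComponentWindow("N1", STIMULUS, ("P7", "P8", "P9", "P10"), (170, 180)),
    ComponentWindow("N2", STIMULUS, ("Cz",), (230, 250)),
    ComponentWindow("N450", STIMULUS, ("Cz",), (380, 400),
                    task_windows={"easy": (380, 400), "hard": (395, 415)}),
    ComponentWindow("P3_frontocentral", STIMULUS, ("Cz",), (500, 700)),
    ComponentWindow("P3_parietal_stim", STIMULUS, ("PO1", "PO2"), (305, 325)),
    ComponentWindow("P3_parietal_resp", RESPONSE, ("Pz",), (-35, -25)),
)


# ---------------------------------------------------------------------------
# subject-average ERP container

@dataclass
class ErpStack:
    """Per-subject average ERPs for one task and locking event.

    ``data`` is ``(n_subjects, n_channels, n_times)``; rows align with
    ``subjects``.
    """

    data: np.ndarray
    subjects: np.ndarray
    task: str
    locking: str
    sfreq: float
    t0_ms: float
    montage: Montage
    units: str = "csd"
    n_trials: np.ndarray | None = field(default=None, repr=False)

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.data.shape[2]) * 1000.0 / self.sfreq

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        if start_ms >= end_ms:
            raise ValueError("window start must precede end")
        i0 = int(np.floor((start_ms - self.t0_ms) * self.sfreq / 1000.0 + 1e-9))
        i1 = int(np.floor((end_ms - self.t0_ms) * self.sfreq / 1000.0 + 1e-9))
        if i0 < 0 or i1 > self.data.shape[2]:
            raise ValueError(f"window ({start_ms}, {end_ms}) ms outside ERP span")
        return slice(i0, i1)


# ---------------------------------------------------------------------------
# filtering and resampling

def bandpass_filter(data: np.ndarray, sfreq: float, low_hz: float = 0.5,
                    high_hz: float = 20.0, order: int = 8) -> np.ndarray:
    """0.5-20 Hz band-pass, 48 dB/oct, applied zero-phase along the last axis.

    Realized as an 8th-order Butterworth high-pass cascaded with an 8th-order
    Butterworth low-pass (6 dB/oct per order -> 48 dB/oct per edge), each run
    forward-backward (``sosfiltfilt``) so the net filter is zero-phase.
    """
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if sfreq <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper edge")
    sos_hp = signal.butter(order, low_hz, btype="highpass", fs=sfreq, output="sos")
    sos_lp = signal.butter(order, high_hz, btype="lowpass", fs=sfreq, output="sos")
    # the 0.5 Hz edge has a settling time of seconds; reflect-pad as much as
    # the segment allows to keep its filtfilt transient out of the segment
    pad = min(np.asarray(data).shape[-1] - 1, int(3 * sfreq / low_hz))
    out = signal.sosfiltfilt(sos_hp, data, axis=-1, padlen=pad)
    return signal.sosfiltfilt(sos_lp, out, axis=-1, padlen=pad)


def resample_epochs(epochs: EpochSet, target_sfreq: float = 256.0) -> EpochSet:
    """Polyphase anti-aliased resampling of the time axis (e.g. 500 -> 256 Hz)."""
    if epochs.sfreq == target_sfreq:
        return epochs
    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator,
                                axis=-1)
    return epochs.copy_with(data=data, sfreq=target_sfreq)


# ---------------------------------------------------------------------------
# referencing, rejection

def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average: per-sample channel mean becomes 0."""
    if epochs.units != "potential":
        raise ValueError("re-referencing CSD-transformed data is meaningless")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def _sliding_ptp(data: np.ndarray, win: int) -> np.ndarray:
    """Max-min over every length-``win`` window along the last axis.

    Returns shape ``data.shape[:-1] + (n_windows,)`` where window ``i`` spans
    samples ``[i, i + win)``.
    """
    n = data.shape[-1]
    if win > n:
        raise ValueError("window longer than epoch")
    mx = maximum_filter1d(data, size=win, axis=-1, mode="nearest",
                          origin=-(win // 2))
    mn = minimum_filter1d(data, size=win, axis=-1, mode="nearest",
                          origin=-(win // 2))
    # with origin -(win//2) the filter window at index i spans
    # [i, i + win) for odd win and [i - 1 + ... ] for even; keep valid range
    return (mx - mn)[..., : n - win + 1]


def reject_artifacts(epochs: EpochSet, max_diff_uv: float = 200.0,
                     diff_window_ms: float = 200.0,
                     min_activity_uv: float = 0.5,
                     activity_window_ms: float = 100.0):
    """Automatic artifact rejection on sliding peak-to-peak criteria.

    An epoch is rejected if on any channel (a) any ``diff_window_ms`` window
    has a value range above ``max_diff_uv`` (transients/steps), or (b) any
    ``activity_window_ms`` window has a value range below ``min_activity_uv``
    (flat/disconnected channel).  The sliding step is one sample.

    Returns ``(retained_epochs, rejected_mask)`` where the mask is True for
    rejected trials of the input.
    """
    if epochs.units != "potential":
        raise ValueError("rejection criteria are defined on potentials (µV)")
    w_diff = max(2, int(round(diff_window_ms * epochs.sfreq / 1000.0)))
    w_act = max(2, int(round(activity_window_ms * epochs.sfreq / 1000.0)))
    ptp_diff = _sliding_ptp(epochs.data, w_diff)
    ptp_act = _sliding_ptp(epochs.data, w_act)
    bad_diff = (ptp_diff > max_diff_uv).any(axis=(1, 2))
    bad_flat = (ptp_act < min_activity_uv).any(axis=(1, 2))
    mask = bad_diff | bad_flat
    kept = epochs.copy_with(
        data=epochs.data[~mask],
        trial_info=epochs.trial_info.loc[~mask].reset_index(drop=True),
    )
    return kept, mask


# ---------------------------------------------------------------------------
# spherical-spline surface Laplacian (CSD)

def _gh_kernels(cosang: np.ndarray, m: int, n_legendre: int):
    """Perrin spherical-spline kernels g and h as Legendre series.

    ``g`` interpolates the potential; ``h`` carries the surface Laplacian of
    the spline basis.  Series truncated at degree ``n_legendre``.
    """
    g = np.zeros_like(cosang)
    h = np.zeros_like(cosang)
    for n in range(1, n_legendre + 1):
        p = eval_legendre(n, cosang)
        w = (2 * n + 1) / (n * (n + 1)) ** m
        g += w * p
        h += w * (n * (n + 1)) * p
    return g / (4 * np.pi), h / (4 * np.pi)


def csd_operator(montage: Montage, spline_order_m: int = 4,
                 legendre_max: int = 10, lambda_reg: float = 1e-5,
                 head_radius_m: float = 1.0) -> np.ndarray:
    """Linear operator L with ``csd = L @ potentials`` per time sample.

    Spherical-spline surface-Laplacian estimate (spline stiffness ``m``,
    Legendre series truncated at ``legendre_max``, Tikhonov smoothing
    ``lambda_reg`` on the interpolation system).  Output units are µV/m² for
    µV input when ``head_radius_m`` is the sphere radius in meters.  Sources
    (positive potential foci) map to positive CSD.
    """
    cosang = montage.cosine_angles()
    g, h = _gh_kernels(cosang, spline_order_m, legendre_max)
    n = len(montage)
    gi = np.linalg.inv(g + lambda_reg * np.eye(n))
    tc = gi.sum(axis=1, keepdims=True)          # G^-1 1
    sgi = tc.sum()                               # 1' G^-1 1
    # spline coefficients c = G^-1 (I - 1 1' G^-1 / (1' G^-1 1)) v
    proj = gi - (tc @ tc.T) / sgi
    if not np.isfinite(proj).all():
        raise np.linalg.LinAlgError("singular spline system (duplicate electrodes?)")
    return (h @ proj) / head_radius_m ** 2


def csd_transform(epochs: EpochSet, spline_order_m: int = 4,
                  legendre_max: int = 10, lambda_reg: float = 1e-5,
                  head_radius_m: float = 1.0) -> EpochSet:
    """Apply the spherical-spline CSD transform; units become µV/m²."""
    if epochs.units != "potential":
        raise ValueError("CSD input must be referential potentials")
    op = csd_operator(epochs.montage, spline_order_m, legendre_max,
                      lambda_reg, head_radius_m)
    data = np.einsum("ij,tjk->tik", op, epochs.data)
    out = epochs.copy_with(data=data)
    out.units = "csd"
    return out


# ---------------------------------------------------------------------------
# baseline, averaging

def default_baseline(locking: str) -> tuple[float, float]:
    """Standard baseline window: (-300, 0) ms before the stimulus for
    stimulus-locked segments, (+300, +400) ms after the response for
    response-locked segments."""
    return (-300.0, 0.0) if locking == STIMULUS else (300.0, 400.0)


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float] | None = None) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    if window_ms is None:
        window_ms = default_baseline(epochs.locking)
    sl = epochs.window_slice(*window_ms)
    if sl.start == sl.stop:
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def average_erp(epochs: EpochSet, correct_only: bool = True):
    """Trial average (the ERP) and the number of trials averaged.

    Only correct-response trials enter the average; an empty cell raises.
    """
    keep = np.ones(epochs.n_trials, bool)
    if correct_only and "correct" in epochs.trial_info.columns:
        keep = epochs.trial_info["correct"].to_numpy().astype(bool)
    n = int(keep.sum())
    if n == 0:
        raise ValueError("no retained correct trials to average")
    return epochs.data[keep].mean(axis=0), n


# ---------------------------------------------------------------------------
# electrode validation and quantification

def validate_electrodes(erps: ErpStack, search_window_ms: tuple[float, float],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Data-driven validation of electrode choices for a component.

    For each electrode, the window-mean amplitude is compared across subjects
    (paired two-sided t-test) with the mean of all other electrodes; p-values
    are Bonferroni-corrected for the number of electrodes.  Electrodes with
    corrected p < ``alpha`` are flagged ``selected``.
    """
    n_subj, n_ch, _ = erps.data.shape
    if n_subj < 2:
        raise ValueError("electrode validation requires at least 2 subjects")
    sl = erps.window_slice(*search_window_ms)
    win_mean = erps.data[:, :, sl].mean(axis=2)      # subjects x channels
    rows = []
    for ci, name in enumerate(erps.montage.names):
        others = np.delete(win_mean, ci, axis=1).mean(axis=1)
        t, p = ttest_rel(win_mean[:, ci], others)
        p_corr = min(1.0, float(p) * n_ch)
        rows.append({"electrode": name, "t": float(t), "p_raw": float(p),
                     "p_bonferroni": p_corr, "selected": p_corr < alpha})
    return pd.DataFrame(rows)


def quantify_amplitude(erps_by_task: dict[str, ErpStack],
                       component: ComponentWindow) -> pd.DataFrame:
    """Mean amplitude in the component window, averaged over its electrodes.

    Returns a table with columns subject, task, component, amplitude (µV/m²).
    """
    rows = []
    for task, stack in erps_by_task.items():
        if stack.units != "csd":
            raise ValueError("amplitude quantification expects CSD units")
        if stack.locking != component.locking:
            raise ValueError(
                f"component {component.name} is {component.locking}-locked but "
                f"ERPs are {stack.locking}-locked")
        idx = stack.montage.indices(component.electrodes)
        sl = stack.window_slice(*component.window_for(task))
        amps = stack.data[:, idx, sl].mean(axis=(1, 2))
        for subj, a in zip(stack.subjects, amps):
            rows.append({"subject": subj, "task": task,
                         "component": component.name, "amplitude": float(a)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full chain

def preprocess(epochs: EpochSet, low_hz: float = 0.5, high_hz: float = 20.0,
               target_sfreq: float = 256.0, max_diff_uv: float = 200.0,
               min_activity_uv: float = 0.5, spline_order_m: int = 4,
               legendre_max: int = 10, lambda_reg: float = 1e-5,
               baseline_ms: tuple[float, float] | None = None):
    """Run the canonical chain on one EpochSet and record the step order.

    filter -> resample -> average reference -> reject -> CSD -> baseline.
    Returns ``(epochs, rejected_mask, steps)``.
    """
    steps = []
    out = epochs.copy_with(data=bandpass_filter(epochs.data, epochs.sfreq,
                                                low_hz, high_hz))
    steps.append("bandpass_filter")
    out = resample_epochs(out, target_sfreq)
    steps.append("resample")
    out = rereference_average(out)
    steps.append("rereference_average")
    out, mask = reject_artifacts(out, max_diff_uv=max_diff_uv,
                                 min_activity_uv=min_activity_uv)
    steps.append("reject_artifacts")
    out = csd_transform(out, spline_order_m, legendre_max, lambda_reg)
    steps.append("csd_transform")
    out = baseline_correct(out, baseline_ms)
    steps.append("baseline_correct")
    return out, mask, steps
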