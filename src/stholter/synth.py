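"""Synthetic 12-lead ECG, noise synthesis, quality labels and dataset splits.

The generator renders each beat from compact-support (Hann-window) P, Q, R,
S and T bumps around an analytically known QRS onset and J point.  Between
the J point and the T-wave onset the waveform is exactly
``baseline + st_injection`` for that lead, so injected ST/J deviations are
recoverable to machine precision on noise-free records — this is what makes
the downstream measurement rules testable without clinical data.

Noise follows the three classic ambulatory-ECG contaminants: baseline
wander (sub-0.5 Hz drift), muscle artifact (20–100 Hz stochastic activity)
and electrode motion (sparse step/spike transients).  Noisy signals are
mixed as ``clean + α1·noise1 + α2·noise2`` with α ∈ [0, 0.5].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")

# class codes for the per-sample segmentation mask
NOQRS, CQRS, NQRS = 0, 1, 2
CLASS_NAMES = ("NOQRS", "CQRS", "NQRS")

NOISE_KINDS = ("baseline_wander", "muscle_artifact", "electrode_motion")

# R-wave polarity/scale per lead; ST injections are applied unscaled
_LEAD_SCALE = {
    "I": 0.7, "II": 1.0, "III": 0.5, "aVR": -0.8, "aVL": 0.4, "aVF": 0.7,
    "V1": -0.6, "V2": 0.9, "V3": 1.1, "V4": 1.2, "V5": 1.0, "V6": 0.8,
}

# beat geometry in milliseconds, relative to the QRS onset
_QRS_DUR_MS = 80.0
_ST_FLAT_MS = 100.0     # flat ST plateau; covers every HR-adjusted ST offset
_T_DUR_MS = 160.0
_P_OFF_MS = -160.0      # P bump support start
_P_DUR_MS = 100.0


class ParameterError(ValueError):
    """Invalid generator/rule parameter."""


@dataclass
class ECGRecord:
    """Multi-lead ECG signal in mV with sampling rate and demographics."""

    signal: np.ndarray            # [n_samples, n_leads]
    fs: float = 500.0
    lead_names: tuple[str, ...] = STANDARD_LEADS
    age: float | None = None
    sex: str | None = None
    subject_id: str = "synthetic"

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.signal.shape[0] < 1:
            raise ParameterError("record must contain at least one sample")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ParameterError("lead names must be unique")
        if self.signal.shape[1] != len(self.lead_names):
            raise ParameterError("signal columns must match lead names")
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("signal must be finite everywhere")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def lead(self, name: str) -> np.ndarray:
        return self.signal[:, self.lead_names.index(name)]


@dataclass
class GroundTruth:
    """Known fiducials and injected deviations of a synthetic record."""

    fs: float
    qrs_onsets: np.ndarray        # sample index per beat
    qrs_offsets: np.ndarray       # J point per beat
    st_injection: dict[str, float] = field(default_factory=dict)  # mV per lead
    baseline: dict[str, float] = field(default_factory=dict)      # mV per lead
    beat_quality: list[str] = field(default_factory=list)         # CQRS/NQRS

    def __post_init__(self):
        self.qrs_onsets = np.asarray(self.qrs_onsets, dtype=np.int64)
        self.qrs_offsets = np.asarray(self.qrs_offsets, dtype=np.int64)
        on, off = self.qrs_onsets, self.qrs_offsets
        if on.size and not np.all(np.diff(on) > 0):
            raise ParameterError("QRS onsets must be strictly increasing")
        if on.size and not np.all(off > on):
            raise ParameterError("each J point must follow its onset")
        if on.size > 1 and not np.all(off[:-1] < on[1:]):
            raise ParameterError("QRS spans must not overlap")
        if not self.beat_quality:
            self.beat_quality = ["CQRS"] * on.size

    @property
    def n_beats(self) -> int:
        return int(self.qrs_onsets.size)


@dataclass
class NoiseBank:
    kind: str
    signal: np.ndarray
    fs: float

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("noise must be finite")


@dataclass
class MixCoefficients:
    alpha1: float
    alpha2: float
    seed: int = 0

    def __post_init__(self):
        for a in (self.alpha1, self.alpha2):
            if not 0.0 <= a <= 0.5:
                raise ParameterError("mixing coefficients must lie in [0, 0.5]")

    @classmethod
    def draw(cls, rng: np.random.Generator, seed: int = 0) -> "MixCoefficients":
        """Draw α1, α2 uniform on [0, 0.5] (training-mode sampling)."""
        return cls(rng.uniform(0, 0.5), rng.uniform(0, 0.5), seed=seed)


def _hann_bump(t: np.ndarray, start: float, width: float, amp: float) -> np.ndarray:
    """Raised-cosine bump with strict support [start, start + width]."""
    out = np.zeros_like(t)
    m = (t > start) & (t < start + width)
    out[m] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - start) / width))
    return out


def generate_clean_ecg(
    n_beats: int,
    hr_mean: float = 73.54,
    hr_sd: float = 11.74,
    fs: float = 500.0,
    leads: tuple[str, ...] = STANDARD_LEADS,
    st_injection: dict[str, float] | None = None,
    baseline: dict[str, float] | float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    st_window_s: tuple[float, float] | None = None,
) -> tuple[ECGRecord, GroundTruth]:
    """Render a clean multi-lead ECG with analytically known fiducials.

    The segment between each J point and the T onset is exactly
    ``baseline + st_injection`` on every lead; the amplitude at each QRS
    onset is exactly ``baseline`` (the template bumps have strict compact
    support), so the isoelectric reference and injected deviations are
    recoverable without tolerance games.

    ``st_window_s`` restricts the injected deviation to beats whose QRS
    onset time (s) falls inside [start, end) — used to emulate transient
    ischemic episodes of known duration.
    """
    if n_beats < 2:
        raise ParameterError("need at least two beats")
    if not 30.0 < hr_mean < 200.0:
        raise ParameterError("mean heart rate must lie in (30, 200) bpm")
    if not leads:
        raise ParameterError("lead list must be non-empty")
    st_injection = dict(st_injection or {})
    if isinstance(baseline, dict):
        base = {lead: float(baseline.get(lead, 0.0)) for lead in leads}
    else:
        base = {lead: float(baseline) for lead in leads}

    rng = np.random.default_rng(seed)
    hr = np.clip(rng.normal(hr_mean, hr_sd, size=n_beats), 31.0, 199.0)
    rr = np.round(60.0 / hr * fs).astype(np.int64)

    lead_in = int(round(0.25 * fs))
    onsets = lead_in + np.concatenate(([0], np.cumsum(rr[:-1])))
    qrs_len = int(round(_QRS_DUR_MS / 1000.0 * fs))
    offsets = onsets + qrs_len
    n_samples = int(offsets[-1] + round(0.6 * fs))

    t_ms = np.arange(n_samples) / fs * 1000.0
    record = np.zeros((n_samples, len(leads)))

    for li, lead in enumerate(leads):
        scale = amplitude * _LEAD_SCALE.get(lead, 1.0)
        y = np.full(n_samples, base[lead])
        lead_inj = st_injection.get(lead, 0.0)
        for q in onsets:
            q_ms = q / fs * 1000.0
            inj = lead_inj
            if st_window_s is not None and not (
                    st_window_s[0] <= q / fs < st_window_s[1]):
                inj = 0.0
            y += _hann_bump(t_ms, q_ms + _P_OFF_MS, _P_DUR_MS, 0.12 * scale)
            y += _hann_bump(t_ms, q_ms, 20.0, -0.10 * scale)
            y += _hann_bump(t_ms, q_ms + 10.0, 60.0, 1.00 * scale)
            y += _hann_bump(t_ms, q_ms + 60.0, 20.0, -0.20 * scale)
            # flat ST plateau carrying the injected deviation, then a T wave
            # riding a linear ramp of the deviation back to baseline
            j_ms = q_ms + _QRS_DUR_MS
            st_mask = (t_ms >= j_ms) & (t_ms < j_ms + _ST_FLAT_MS)
            y[st_mask] += inj
            t_on = j_ms + _ST_FLAT_MS
            t_mask = (t_ms >= t_on) & (t_ms < t_on + _T_DUR_MS)
            ramp = 1.0 - (t_ms[t_mask] - t_on) / _T_DUR_MS
            y[t_mask] += inj * ramp
            y += _hann_bump(t_ms, t_on, _T_DUR_MS, 0.30 * scale)
        record[:, li] = y

    rec = ECGRecord(signal=record, fs=fs, lead_names=tuple(leads),
                    subject_id=f"synthetic-{seed}")
    gt = GroundTruth(fs=fs, qrs_onsets=onsets, qrs_offsets=offsets,
                     st_injection=st_injection, baseline=base)
    return rec, gt


def generate_noise(
    kind: str,
    n_samples: int,
    fs: float = 500.0,
    amplitude: float = 0.1,
    seed: int = 0,
    freqs: list[float] | None = None,
) -> NoiseBank:
    """Synthesize one of the three ambulatory noise classes.

    ``amplitude`` is the target RMS in mV (peak amplitude for electrode
    motion steps).  ``freqs`` optionally pins the baseline-wander sinusoid
    frequencies (Hz, each < 0.5).
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be positive")
    if kind not in NOISE_KINDS:
        raise ParameterError(f"unknown noise kind {kind!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs

    if amplitude == 0:
        return NoiseBank(kind=kind, signal=np.zeros(n_samples), fs=fs)

    if kind == "baseline_wander":
        if freqs is None:
            freqs = list(rng.uniform(0.05, 0.45, size=3))
        y = np.zeros(n_samples)
        for f in freqs:
            y += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        rms = np.sqrt(np.mean(y**2))
        y *= amplitude / max(rms, 1e-12)
    elif kind == "muscle_artifact":
        y = rng.standard_normal(n_samples)
        high = min(100.0, 0.45 * fs)
        low = min(20.0, 0.5 * high)
        sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        y = sps.sosfiltfilt(sos, y)
        rms = np.sqrt(np.mean(y**2))
        y *= amplitude / max(rms, 1e-12)
    else:  # electrode_motion
        y = np.zeros(n_samples)
        n_events = max(1, rng.poisson(max(1.0, n_samples / fs / 5.0)))
        for _ in range(n_events):
            start = rng.integers(0, n_samples)
            length = int(rng.uniform(0.05, 0.5) * fs)
            level = rng.uniform(-1.0, 1.0) * amplitude
            y[start:start + length] += level
    return NoiseBank(kind=kind, signal=y, fs=fs)


def resample_noise(bank: NoiseBank, fs_target: float) -> NoiseBank:
    """Polyphase resampling, e.g. 360 Hz archive noise onto a 500 Hz grid."""
    if bank.fs == fs_target:
        return bank
    g = math.gcd(int(fs_target), int(bank.fs))
    up, down = int(fs_target) // g, int(bank.fs) // g
    y = sps.resample_poly(bank.signal, up, down)
    return NoiseBank(kind=bank.kind, signal=y, fs=fs_target)


def synthesize_noisy(clean: np.ndarray, noise1: np.ndarray, noise2: np.ndarray,
                     coeffs: MixCoefficients) -> np.ndarray:
    """``clean + α1·noise1 + α2·noise2``, elementwise and exact."""
    clean = np.asarray(clean, dtype=np.float64)
    noise1 = np.asarray(noise1, dtype=np.float64)
    noise2 = np.asarray(noise2, dtype=np.float64)
    if not (clean.shape == noise1.shape == noise2.shape):
        raise ValueError("clean and noise vectors must share one shape")
    return clean + coeffs.alpha1 * noise1 + coeffs.alpha2 * noise2


def label_quality(
    ground_truth: GroundTruth,
    noise_total: np.ndarray,
    fs: float,
    rms_threshold: float = 0.1,
) -> tuple[list[str], np.ndarray]:
    """Mechanical surrogate for human beat-quality annotation.

    A beat is NQRS when the RMS of the total added noise over
    [onset − 100 ms, J + 200 ms] exceeds ``rms_threshold`` (mV); samples
    inside a QRS span inherit the beat's label, everything else is NOQRS.
    Returns (per-beat labels, per-sample mask).
    """
    if ground_truth.n_beats < 1:
        raise ParameterError("ground truth must contain at least one beat")
    noise_total = np.asarray(noise_total, dtype=np.float64)
    n = noise_total.size
    pre = int(round(0.1 * fs))
    post = int(round(0.2 * fs))
    labels: list[str] = []
    mask = np.full(n, NOQRS, dtype=np.int64)
    for onset, off in zip(ground_truth.qrs_onsets, ground_truth.qrs_offsets):
        lo = max(0, onset - pre)
        hi = min(n, off + 1 + post)
        rms = float(np.sqrt(np.mean(noise_total[lo:hi] ** 2))) if hi > lo else 0.0
        label = "NQRS" if rms > rms_threshold else "CQRS"
        labels.append(label)
        mask[onset:min(n, off + 1)] = NQRS if label == "NQRS" else CQRS
    return labels, mask


def make_splits(items, mode: str = "inter", seed: int = 0,
                ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)) -> dict[str, set]:
    """Random 7:1:2 partition of subject ids (inter) or sample ids (intra).

    Counts follow train = round(0.7·n), val = floor(0.1·n), test = remainder,
    which reproduces 107 → 75/10/22 and 276 → 193/27/56.
    """
    items = list(items)
    n = len(items)
    if n < 3:
        raise ParameterError("need at least three items to split")
    if mode not in ("inter", "intra"):
        raise ParameterError(f"unknown split mode {mode!r}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ParameterError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(math.floor(ratios[1] * n))
    train = {items[i] for i in order[:n_train]}
    val = {items[i] for i in order[n_train:n_train + n_val]}
    test = {items[i] for i in order[n_train + n_val:]}
    return {"train": train, "val": val, "test": test}


# ---------------------------------------------------------------------------
# dataset builders for model training (fixed-length single-lead patches)
# ---------------------------------------------------------------------------

def _clean_patch(patch_len: int, fs: float, seed: int,
                 lead: str = "II") -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """One clean single-lead patch, its quality mask and cropped fiducials."""
    n_beats = max(3, int(math.ceil(patch_len / fs / 0.55)))
    rec, gt = generate_clean_ecg(n_beats=n_beats, fs=fs, seed=seed,
                                 leads=(lead,))
    x = rec.lead(lead)[:patch_len]
    if x.size < patch_len:
        x = np.pad(x, (0, patch_len - x.size))
    keep = gt.qrs_offsets < patch_len
    gt_crop = GroundTruth(fs=fs, qrs_onsets=gt.qrs_onsets[keep],
                          qrs_offsets=gt.qrs_offsets[keep])
    _, mask = label_quality(gt_crop, np.zeros(patch_len), fs)
    return x, mask, gt_crop


def make_denoise_dataset(n_patches: int, patch_len: int, fs: float,
                         seed: int, noise_rms: float = 0.3,
                         fixed_alpha: bool = False,
                         return_ground_truth: bool = False):
    """(noisy, clean) pairs: clean + α1·muscle + α2·wander, α ∈ [0, 0.5].

    ``fixed_alpha`` pins both α at 0.35 (validation/test-style mixing where
    the draw is reproducible rather than re-randomized each epoch);
    ``return_ground_truth`` additionally returns the per-patch fiducials.
    """
    rng = np.random.default_rng(seed)
    X = np.empty((n_patches, patch_len))
    Y = np.empty((n_patches, patch_len))
    gts: list[GroundTruth] = []
    for i in range(n_patches):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        clean, _, gt = _clean_patch(patch_len, fs, sub_seed)
        gts.append(gt)
        n1 = generate_noise("muscle_artifact", patch_len, fs, amplitude=noise_rms,
                            seed=sub_seed + 1).signal
        n2 = generate_noise("baseline_wander", patch_len, fs, amplitude=noise_rms,
                            seed=sub_seed + 2).signal
        if fixed_alpha:
            coeffs = MixCoefficients(0.35, 0.35)
        else:
            coeffs = MixCoefficients.draw(rng)
        X[i] = synthesize_noisy(clean, n1, n2, coeffs)
        Y[i] = clean
    if return_ground_truth:
        return X, Y, gts
    return X, Y


def make_segment_dataset(n_patches: int, patch_len: int, fs: float,
                         seed: int) -> tuple[np.ndarray, np.ndarray]:
    """(signal, per-sample class mask) pairs on clean synthetic beats."""
    rng = np.random.default_rng(seed)
    X = np.empty((n_patches, patch_len))
    Y = np.empty((n_patches, patch_len), dtype=np.int64)
    for i in range(n_patches):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        x, mask, _ = _clean_patch(patch_len, fs, sub_seed)
        X[i] = x
        Y[i] = mask
    return X, Y
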