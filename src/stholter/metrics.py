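"""Denoising and segmentation evaluation metrics.

Denoising is scored against the clean reference x with the noisy input x̂
and the denoised output x̃:

    RMSE_de  = RMSE(x, x̂) − RMSE(x, x̃)          (mV; larger is better)
    SNR_imp  = SNR_out − SNR_in                   (dB; larger is better)
    PRD      = 100·sqrt(Σ(x−x̃)² / Σx²)           (%; smaller is better)

Segmentation is scored pointwise: every sampling point contributes to a
one-vs-rest confusion count per class (NOQRS/CQRS/NQRS), from which
precision, recall and F1 are reported in percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .synth import CLASS_NAMES, ParameterError


@dataclass
class DenoiseScores:
    rmse_in: float
    rmse_out: float
    rmse_de: float
    snr_in: float
    snr_out: float
    snr_imp: float
    prd: float


@dataclass
class ClassPRF:
    true_pos: int
    false_pos: int
    false_neg: int
    precision: float    # percent
    recall: float       # percent
    f1: float           # percent


@dataclass
class PointwisePRF:
    per_class: dict[str, ClassPRF]

    def __getitem__(self, name: str) -> ClassPRF:
        return self.per_class[name]


def _as_equal_arrays(*signals) -> list[np.ndarray]:
    arrays = [np.asarray(s, dtype=np.float64).ravel() for s in signals]
    n = arrays[0].size
    if n < 1 or any(a.size != n for a in arrays):
        raise ValueError("signals must be non-empty and of equal length")
    return arrays


def rmse_de(clean, noisy_in, denoised_out) -> tuple[float, float, float]:
    """(RMSE_in, RMSE_out, RMSE_de) against the clean reference."""
    x, xh, xt = _as_equal_arrays(clean, noisy_in, denoised_out)
    r_in = float(np.sqrt(np.mean((x - xh) ** 2)))
    r_out = float(np.sqrt(np.mean((x - xt) ** 2)))
    return r_in, r_out, r_in - r_out


def snr_imp(clean, noisy_in, denoised_out) -> tuple[float, float, float]:
    """(SNR_in, SNR_out, SNR_imp) in dB.

    A zero-residual (perfect) signal yields +inf with a warning rather than
    an error, so perfect-denoiser cases stay expressible.
    """
    x, xh, xt = _as_equal_arrays(clean, noisy_in, denoised_out)
    energy = float(np.sum(x**2))
    if energy == 0.0:
        raise ParameterError("clean signal must not be all-zero")

    def _snr(residual: np.ndarray) -> float:
        err = float(np.sum(residual**2))
        if err == 0.0:
            warnings.warn("zero residual energy: SNR reported as +inf",
                          stacklevel=3)
            return math.inf
        return 10.0 * math.log10(energy / err)

    s_in = _snr(x - xh)
    s_out = _snr(x - xt)
    return s_in, s_out, s_out - s_in


def prd(clean, denoised_out) -> float:
    """Percentage root-mean-square difference (%)."""
    x, xt = _as_equal_arrays(clean, denoised_out)
    energy = float(np.sum(x**2))
    if energy == 0.0:
        raise ParameterError("clean signal must not be all-zero")
    return 100.0 * math.sqrt(float(np.sum((x - xt) ** 2)) / energy)


def denoise_scores(clean, noisy_in, denoised_out) -> DenoiseScores:
    r_in, r_out, r_de = rmse_de(clean, noisy_in, denoised_out)
    s_in, s_out, s_imp = snr_imp(clean, noisy_in, denoised_out)
    return DenoiseScores(rmse_in=r_in, rmse_out=r_out, rmse_de=r_de,
                         snr_in=s_in, snr_out=s_out, snr_imp=s_imp,
                         prd=prd(clean, denoised_out))


def pointwise_prf(pred_mask, true_mask) -> PointwisePRF:
    """Per-sampling-point one-vs-rest precision/recall/F1 per class.

    Zero-denominator metrics are reported as 0 by convention (a class
    absent from both truth and prediction scores 0, not 100).
    """
    pred = np.asarray(pred_mask).ravel()
    true = np.asarray(true_mask).ravel()
    if pred.size != true.size:
        raise ValueError("masks must have equal length")
    valid = set(range(len(CLASS_NAMES)))
    if not (set(np.unique(pred)) <= valid and set(np.unique(true)) <= valid):
        raise ParameterError("mask labels must be NOQRS/CQRS/NQRS codes")
    per_class: dict[str, ClassPRF] = {}
    for code, name in enumerate(CLASS_NAMES):
        tp = int(np.sum((pred == code) & (true == code)))
        fp = int(np.sum((pred == code) & (true != code)))
        fn = int(np.sum((pred != code) & (true == code)))
        precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        per_class[name] = ClassPRF(tp, fp, fn, precision, recall, f1)
    return PointwisePRF(per_class)


def ppv(detected_count: int, confirmed_count: int) -> float:
    """Positive predictive value in percent, half-up rounded to one decimal."""
    if detected_count <= 0:
        raise ParameterError("PPV undefined without detections")
    if not 0 <= confirmed_count <= detected_count:
        raise ParameterError("confirmed count must lie in [0, detected]")
    value = 100.0 * confirmed_count / detected_count
    return math.floor(value * 10.0 + 0.5) / 10.0
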