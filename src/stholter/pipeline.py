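"""End-to-end Holter pipeline: patch → denoise → segment → measure → report.

The long record is cropped into non-overlapping 7168-sample patches (the
model's input length; 14.336 s at 500 Hz).  Each lead of each patch is
denoised, then segmented on the *denoised* signal; per-lead masks are
stitched back onto the record timeline, beats are derived from a rhythm
reference lead, ST/J deviations are measured on every lead, classified
with the demographic thresholds, and aggregated into ≥1-minute episodes.

Denoiser and segmenter are pluggable: trained checkpoints for real use,
or the identity denoiser / oracle segmenter for validation on synthetic
records with known fiducials.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ebtnet import ConfigError, EBTNet, load_checkpoint
from .rules import (DEFAULT_GAP_TOLERANCE_S, MIN_EPISODE_S, LEAD_GROUPS,
                    DeviationSeries, EpisodeReport, beats_from_mask,
                    classify_series, deviations, episodes)
from .synth import CQRS, NOQRS, NQRS, ECGRecord, GroundTruth, ParameterError

PATCH_LENGTH = 7168


@dataclass
class PatchPlan:
    patch_length: int
    offsets: list[int]
    tail_policy: str = "drop"
    tail_start: int | None = None   # set when a padded tail patch exists


@dataclass
class PipelineConfig:
    denoiser: "Denoiser"
    segmenter: "Segmenter"
    age: float | None = None
    sex: str | None = None
    rhythm_lead: str = "II"
    gap_tolerance_s: float = DEFAULT_GAP_TOLERANCE_S
    min_episode_s: float = MIN_EPISODE_S
    patch_length: int = PATCH_LENGTH
    tail_policy: str = "drop"


class Denoiser:
    def denoise(self, patch: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Segmenter:
    def segment(self, patch: np.ndarray, lead: str, start: int) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover


class IdentityDenoiser(Denoiser):
    """Pass-through stage for already-clean signals."""

    def denoise(self, patch: np.ndarray) -> np.ndarray:
        return np.asarray(patch, dtype=np.float64)


class ModelDenoiser(Denoiser):
    def __init__(self, model: EBTNet):
        if model.config.task != "denoise":
            raise ConfigError("checkpoint is not a denoising model")
        self.model = model

    @classmethod
    def from_checkpoint(cls, path) -> "ModelDenoiser":
        return cls(load_checkpoint(path))

    def denoise(self, patch: np.ndarray) -> np.ndarray:
        if patch.size != self.model.config.input_length:
            raise ConfigError(
                f"patch length {patch.size} does not match model input "
                f"{self.model.config.input_length}")
        return self.model.predict(patch)


class ModelSegmenter(Segmenter):
    def __init__(self, model: EBTNet):
        if model.config.task != "segment":
            raise ConfigError("checkpoint is not a segmentation model")
        self.model = model

    @classmethod
    def from_checkpoint(cls, path) -> "ModelSegmenter":
        return cls(load_checkpoint(path))

    def segment(self, patch: np.ndarray, lead: str, start: int) -> np.ndarray:
        if patch.size != self.model.config.input_length:
            raise ConfigError(
                f"patch length {patch.size} does not match model input "
                f"{self.model.config.input_length}")
        return self.model.predict(patch).astype(np.int64)


class OracleSegmenter(Segmenter):
    """Emit the ground-truth mask of a synthetic record (validation aid)."""

    def __init__(self, ground_truth: GroundTruth, quality: list[str] | None = None):
        self.gt = ground_truth
        self.quality = quality or list(ground_truth.beat_quality)

    def segment(self, patch: np.ndarray, lead: str, start: int) -> np.ndarray:
        mask = np.full(patch.size, NOQRS, dtype=np.int64)
        for onset, off, q in zip(self.gt.qrs_onsets, self.gt.qrs_offsets,
                                 self.quality):
            lo, hi = onset - start, off + 1 - start
            if hi <= 0 or lo >= patch.size:
                continue
            mask[max(0, lo):min(patch.size, hi)] = NQRS if q == "NQRS" else CQRS
        return mask


def crop_patches(record: ECGRecord, patch_length: int = PATCH_LENGTH,
                 tail_policy: str = "drop") -> tuple[list[np.ndarray], PatchPlan]:
    """Consecutive non-overlapping patches of the full signal matrix.

    A tail shorter than one patch is dropped by default, or zero-padded to
    full length under ``tail_policy="pad"`` (callers trim model output back
    using ``plan.tail_start``).
    """
    if record.n_samples < 1:
        raise ParameterError("empty record")
    if tail_policy not in ("drop", "pad"):
        raise ParameterError(f"unknown tail policy {tail_policy!r}")
    n_full = record.n_samples // patch_length
    offsets = [i * patch_length for i in range(n_full)]
    patches = [record.signal[o:o + patch_length] for o in offsets]
    tail_start = None
    tail = record.n_samples - n_full * patch_length
    if tail and tail_policy == "pad":
        tail_start = n_full * patch_length
        padded = np.zeros((patch_length, record.signal.shape[1]))
        padded[:tail] = record.signal[tail_start:]
        patches.append(padded)
        offsets.append(tail_start)
    plan = PatchPlan(patch_length=patch_length, offsets=offsets,
                     tail_policy=tail_policy, tail_start=tail_start)
    return patches, plan


@dataclass
class PipelineResult:
    denoised: ECGRecord
    masks: dict[str, np.ndarray]          # per lead, stitched full length
    deviations: DeviationSeries
    report: EpisodeReport


def run(record: ECGRecord, config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow on one record.

    Beats are derived from the rhythm-reference lead's stitched mask (lead
    II when present); deviations are measured on every lead at those
    fiducials.  A beat straddling a patch boundary belongs to the patch
    containing its QRS onset, which stitching by concatenation preserves.
    """
    age = config.age if config.age is not None else record.age
    sex = config.sex if config.sex is not None else record.sex
    patches, plan = crop_patches(record, config.patch_length,
                                 config.tail_policy)
    if not patches:
        raise ParameterError(
            f"record shorter than one patch ({config.patch_length} samples) "
            "with tail policy 'drop'")
    used = plan.offsets[-1] + plan.patch_length
    n_out = min(record.n_samples, used)

    denoised = np.empty((n_out, len(record.lead_names)))
    masks: dict[str, np.ndarray] = {}
    for li, lead in enumerate(record.lead_names):
        lead_mask = np.empty(n_out, dtype=np.int64)
        for patch, start in zip(patches, plan.offsets):
            den = config.denoiser.denoise(patch[:, li])
            seg = config.segmenter.segment(den, lead, start)
            stop = min(start + plan.patch_length, n_out)
            denoised[start:stop, li] = den[:stop - start]
            lead_mask[start:stop] = seg[:stop - start]
        masks[lead] = lead_mask

    den_record = ECGRecord(signal=denoised, fs=record.fs,
                           lead_names=record.lead_names, age=age, sex=sex,
                           subject_id=record.subject_id)
    rhythm = (config.rhythm_lead if config.rhythm_lead in record.lead_names
              else record.lead_names[0])
    beats = beats_from_mask(masks[rhythm], record.fs)
    series = deviations(beats, denoised, record.lead_names, record.fs)
    flagged = classify_series(series, age=age, sex=sex)
    report = episodes(flagged, gap_tolerance_s=config.gap_tolerance_s,
                      min_duration_s=config.min_episode_s)
    return PipelineResult(denoised=den_record, masks=masks,
                          deviations=series, report=report)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report(report: EpisodeReport, path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["type", "group", "start_time_s", "end_time_s",
                             "duration_s", "n_beats"])
            for ep in report.episodes:
                writer.writerow([ep.type, ep.group, ep.start_time,
                                 ep.end_time, ep.duration, ep.n_beats])
    else:
        raise ParameterError(f"unknown report format {fmt!r}")


def group_summary_csv(reports: dict[str, EpisodeReport], path) -> None:
    """Per-dataset × lead-group patient-count table (rows = dataset label)."""
    groups = list(LEAD_GROUPS)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dataset", "type"] + [",".join(LEAD_GROUPS[g])
                                               for g in groups])
        for label, report in reports.items():
            for etype in ("STD", "STE"):
                counts = [sum(1 for e in report.episodes
                              if e.type == etype and e.group == g)
                          for g in groups]
                writer.writerow([label, etype] + counts)
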