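"""Record and report I/O: CSV, minimal WFDB (format 16), JSON.

CSV records are plain text in millivolts: a header row of lead names, one
row per sample.  The WFDB support here is a deliberately small reader/
writer for single-segment format-16 records (int16 .dat, text .hea with
gain in adu/mV), enough to exchange records with standard WFDB tooling.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .synth import ECGRecord, GroundTruth


class FormatError(ValueError):
    """Malformed record file."""


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_csv(record: ECGRecord, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(record.lead_names)
        for row in record.signal:
            writer.writerow([repr(float(v)) for v in row])


def read_csv(path, fs: float = 500.0, leads: tuple[str, ...] | None = None,
             **demographics) -> ECGRecord:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if leads is not None:
            missing = [lead for lead in leads if lead not in header]
            if missing:
                raise FormatError(f"{path}: missing lead column(s) {missing}")
        rows = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{line_no}: expected {len(header)} fields, "
                    f"got {len(row)}")
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: non-numeric cell "
                                  f"({exc})") from None
    if not rows:
        raise FormatError(f"{path}: no samples")
    signal = np.array(rows)
    if leads is not None:
        signal = signal[:, [header.index(lead) for lead in leads]]
        header = list(leads)
    return ECGRecord(signal=signal, fs=fs, lead_names=tuple(header),
                     **demographics)


# ---------------------------------------------------------------------------
# minimal WFDB (single-segment, format 16)
# ---------------------------------------------------------------------------

_WFDB_FORMAT = 16
_DEFAULT_GAIN = 200.0  # adu per mV


def write_wfdb(record: ECGRecord, record_path) -> None:
    """Write ``<record_path>.hea`` + ``<record_path>.dat`` (format 16)."""
    record_path = Path(record_path)
    name = record_path.name
    n_samples, n_sig = record.signal.shape
    adu = np.clip(np.round(record.signal * _DEFAULT_GAIN), -32768, 32767)
    adu = adu.astype("<i2")
    with open(record_path.with_suffix(".dat"), "wb") as fh:
        fh.write(adu.tobytes())  # sample-major interleaving
    lines = [f"{name} {n_sig} {record.fs:g} {n_samples}"]
    for i, lead in enumerate(record.lead_names):
        first = int(adu[0, i])
        lines.append(
            f"{name}.dat {_WFDB_FORMAT} {_DEFAULT_GAIN:g}(0)/mV 16 0 "
            f"{first} 0 0 {lead}")
    with open(record_path.with_suffix(".hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_wfdb(record_path, **demographics) -> ECGRecord:
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    try:
        lines = [ln.strip() for ln in hea.read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise FormatError(f"{hea}: {exc}") from None
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}:1: malformed record line")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    gains = []
    baselines = []
    leads = []
    for i, line in enumerate(lines[1:1 + n_sig], start=2):
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"{hea}:{i}: malformed signal line")
        if int(fields[1].split("x")[0]) != _WFDB_FORMAT:
            raise FormatError(f"{hea}:{i}: only format 16 is supported")
        gain_field = fields[2] if len(fields) > 2 else f"{_DEFAULT_GAIN:g}"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain_str, base_str = gain_str.rstrip(")").split("(")
            baselines.append(float(base_str))
        else:
            baselines.append(0.0)
        gains.append(float(gain_str) or _DEFAULT_GAIN)
        leads.append(fields[-1] if len(fields) >= 9 else f"sig{i - 2}")
    raw = np.fromfile(record_path.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_samples * n_sig:
        raise FormatError(
            f"{record_path}.dat: expected {n_samples * n_sig} samples, "
            f"got {raw.size}")
    adu = raw.reshape(n_samples, n_sig).astype(np.float64)
    signal = (adu - np.array(baselines)) / np.array(gains)
    return ECGRecord(signal=signal, fs=fs, lead_names=tuple(leads),
                     **demographics)


# ---------------------------------------------------------------------------
# ground truth / report JSON
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "fs": gt.fs,
        "onsets": gt.qrs_onsets.tolist(),
        "offsets": gt.qrs_offsets.tolist(),
        "beat_quality": list(gt.beat_quality),
        "st_injection": gt.st_injection,
        "baseline": gt.baseline,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(fs=payload["fs"], qrs_onsets=payload["onsets"],
                       qrs_offsets=payload["offsets"],
                       st_injection=payload.get("st_injection", {}),
                       baseline=payload.get("baseline", {}),
                       beat_quality=payload.get("beat_quality", []))
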