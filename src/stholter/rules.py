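"""Deterministic ST-segment / J-point measurement and episode rules.

Given a per-sample QRS-quality mask and the (denoised) multi-lead signal,
this module derives beats, computes the isoelectric reference line (IRL,
the mean signal amplitude at two successive QRS onsets), places the
heart-rate-adjusted ST measurement point, measures per-beat per-lead ST
and J deviations in mV, classifies them against guideline thresholds per
anatomical lead group, and aggregates flagged beats into episodes that
must persist for at least one minute.

Beats labeled NQRS (too noisy to measure) are culled: they contribute to
no reference line, deviation or episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import CQRS, NOQRS, NQRS, ParameterError

#: anatomical lead groups; aVR stands alone and its two-contiguous-lead
#: requirement is relaxed to its single member
LEAD_GROUPS: dict[str, tuple[str, ...]] = {
    "lateral": ("I", "aVL"),
    "inferior": ("II", "III", "aVF"),
    "aVR": ("aVR",),
    "septal": ("V1", "V2"),
    "anterior": ("V3", "V4"),
    "anterolateral": ("V5", "V6"),
}

#: leads whose STE threshold depends on age and sex
_DEMOGRAPHIC_LEADS = ("V2", "V3")

STD_THRESHOLD_MV = 0.05     # depression at the ST point, ≥2 contiguous leads
STE_OTHER_MV = 0.10         # elevation at J, leads outside V2–V3
J_ELEV_MV = 0.10            # J elevation outside V2/V3 (baseline-free)
MIN_EPISODE_S = 60.0        # abnormality must persist ≥ 1 minute
DEFAULT_GAP_TOLERANCE_S = 10.0

#: ST measurement point offset after J, by instantaneous heart rate
_ST_OFFSET_TABLE_MS = ((100.0, 80.0), (110.0, 72.0), (120.0, 64.0))
_ST_OFFSET_FAST_MS = 60.0
_MIN_BEAT_MS = 20.0         # mask runs shorter than this are artifacts


@dataclass
class BeatFiducials:
    q_onset: int
    j_point: int
    quality: str                 # CQRS | NQRS
    hr: float | None             # bpm from the RR to the next beat; None at the end

    def __post_init__(self):
        if self.j_point <= self.q_onset:
            raise ParameterError("J point must follow the QRS onset")
        if self.hr is not None and self.hr <= 0:
            raise ParameterError("heart rate must be positive")


@dataclass
class DeviationSeries:
    """Per-beat × per-lead IRL, ST deviation and J deviation (mV)."""

    lead_names: tuple[str, ...]
    irl: np.ndarray              # [n_beats, n_leads]
    st_dev: np.ndarray
    j_dev: np.ndarray
    valid: np.ndarray            # [n_beats] bool
    beat_times: np.ndarray       # onset time in s per beat

    @property
    def n_beats(self) -> int:
        return int(self.valid.size)


@dataclass
class Episode:
    type: str                    # STD | STE | J_ELEV
    group: str
    start_time: float
    end_time: float
    n_beats: int

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class EpisodeReport:
    episodes: list[Episode] = field(default_factory=list)

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for ep in self.episodes:
            s = out.setdefault(ep.type, {"frequency": 0, "total_duration_s": 0.0})
            s["frequency"] += 1
            s["total_duration_s"] += ep.duration
        return out

    def to_dict(self) -> dict:
        return {
            "episodes": [
                {"type": e.type, "group": e.group, "start_time_s": e.start_time,
                 "end_time_s": e.end_time, "duration_s": e.duration,
                 "n_beats": e.n_beats}
                for e in self.episodes
            ],
            "summary": self.summary,
        }


# ---------------------------------------------------------------------------
# fiducials
# ---------------------------------------------------------------------------

def beats_from_mask(mask: np.ndarray, fs: float) -> list[BeatFiducials]:
    """Beats = maximal runs of non-NOQRS samples in a segmentation mask.

    QRS onset is the first sample of a run, the J point its last (inclusive);
    beat quality is the run's majority label (ties go to NQRS, the
    conservative choice); runs shorter than 20 ms are discarded as
    segmentation artifacts.  HR(i) comes from the onset-to-onset interval
    to the next beat; the final beat has no HR.
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        return []
    if not set(np.unique(mask)) <= {NOQRS, CQRS, NQRS}:
        raise ParameterError("mask labels must be NOQRS/CQRS/NQRS codes")
    in_qrs = mask != NOQRS
    edges = np.flatnonzero(np.diff(np.concatenate(([0], in_qrs.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2] - 1     # inclusive ends
    min_len = int(np.ceil(_MIN_BEAT_MS / 1000.0 * fs))
    fiducials: list[tuple[int, int, str]] = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_len:
            continue
        run = mask[s:e + 1]
        n_nqrs = int(np.sum(run == NQRS))
        quality = "NQRS" if n_nqrs * 2 >= run.size else "CQRS"
        fiducials.append((int(s), int(e), quality))
    beats: list[BeatFiducials] = []
    for i, (s, e, quality) in enumerate(fiducials):
        hr = None
        if i + 1 < len(fiducials):
            rr = fiducials[i + 1][0] - s
            hr = 60.0 * fs / rr
        beats.append(BeatFiducials(q_onset=s, j_point=e, quality=quality, hr=hr))
    return beats


def irl(beats: list[BeatFiducials], i: int, lead_signal: np.ndarray) -> float:
    """Isoelectric reference: mean amplitude at QRS onsets i and i+1.

    Undefined (NaN) for the last beat or when either beat is NQRS — those
    beats are culled from all downstream calculation.
    """
    lead_signal = np.asarray(lead_signal, dtype=np.float64)
    if i + 1 >= len(beats):
        return float("nan")
    if beats[i].quality != "CQRS" or beats[i + 1].quality != "CQRS":
        return float("nan")
    return 0.5 * (lead_signal[beats[i].q_onset]
                  + lead_signal[beats[i + 1].q_onset])


def st_offset_ms(hr: float) -> float:
    """HR-adjusted ST-point offset after J (ms): 80/72/64/60 as HR rises."""
    if hr <= 0:
        raise ParameterError("heart rate must be positive")
    for upper, offset in _ST_OFFSET_TABLE_MS:
        if hr < upper:
            return offset
    return _ST_OFFSET_FAST_MS


def st_point(j_point: int, hr: float, fs: float) -> int:
    """Sample index of the ST measurement point for a beat."""
    return j_point + int(round(st_offset_ms(hr) * fs / 1000.0))


def deviations(beats: list[BeatFiducials], signal: np.ndarray,
               lead_names: tuple[str, ...], fs: float) -> DeviationSeries:
    """Per-beat per-lead ST/J deviations relative to the IRL.

    A beat is valid only if it and its successor are CQRS, it has an HR,
    and its ST point lies inside the record.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_samples, n_leads = signal.shape
    if n_leads != len(lead_names):
        raise ParameterError("signal columns must match lead names")
    n = len(beats)
    irl_arr = np.full((n, n_leads), np.nan)
    st_arr = np.full((n, n_leads), np.nan)
    j_arr = np.full((n, n_leads), np.nan)
    valid = np.zeros(n, dtype=bool)
    times = np.array([b.q_onset / fs for b in beats])
    for i, beat in enumerate(beats):
        if beat.quality != "CQRS" or beat.hr is None:
            continue
        if i + 1 < n and beats[i + 1].quality != "CQRS":
            continue
        sp = st_point(beat.j_point, beat.hr, fs)
        if sp >= n_samples:
            continue
        ok = True
        for li in range(n_leads):
            ref = irl(beats, i, signal[:, li])
            if not np.isfinite(ref):
                ok = False
                break
            irl_arr[i, li] = ref
            st_arr[i, li] = signal[sp, li] - ref
            j_arr[i, li] = signal[beat.j_point, li] - ref
        valid[i] = ok
    return DeviationSeries(lead_names=tuple(lead_names), irl=irl_arr,
                           st_dev=st_arr, j_dev=j_arr, valid=valid,
                           beat_times=times)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def ste_threshold_mv(lead: str, age: float | None, sex: str | None) -> float:
    """J-point elevation threshold: demographic in V2–V3, 0.1 mV elsewhere."""
    if lead not in _DEMOGRAPHIC_LEADS:
        return STE_OTHER_MV
    if age is None or sex is None:
        raise ParameterError(
            f"age and sex are required for the {lead} STE threshold")
    sex = sex.lower()
    if sex == "female":
        return 0.15
    if sex == "male":
        return 0.25 if age < 40 else 0.20
    raise ParameterError(f"unknown sex {sex!r}")


def classify(
    st_dev: dict[str, float],
    j_dev: dict[str, float],
    age: float | None = None,
    sex: str | None = None,
    groups: dict[str, tuple[str, ...]] = LEAD_GROUPS,
) -> set[tuple[str, str]]:
    """Flag (type, group) outliers for one beat's deviation row.

    STE: ≥2 member leads (1 for aVR) with J-point elevation at or above the
    lead's threshold.  STD: ≥2 member leads (1 for aVR) with ST depression
    of at least 0.05 mV at the ST point.  J_ELEV: ≥2 member leads outside
    V2/V3 with J elevation ≥0.1 mV (baseline-free: no prior ECG is
    compared).  All thresholds are closed (≥ / ≤ boundaries included).
    """
    flags: set[tuple[str, str]] = set()
    # STE hits are evaluated per lead, then "two adjacent leads" may pair
    # across a group boundary along the precordial chain V1..V6 (V2+V3
    # elevation flags both the septal and the anterior group)
    ste_hit = {lead: j_dev[lead] >= ste_threshold_mv(lead, age, sex)
               for leads in groups.values() for lead in leads if lead in j_dev}
    chain = [f"V{i}" for i in range(1, 7)]
    chain_pairs = {
        lead
        for a, b in zip(chain, chain[1:])
        if ste_hit.get(a) and ste_hit.get(b)
        for lead in (a, b)
    }
    for gname, members in groups.items():
        need = 1 if len(members) == 1 else 2

        ste_hits = sum(1 for lead in members if ste_hit.get(lead))
        adjacent = any(lead in chain_pairs for lead in members)
        if ste_hits >= need or (ste_hits >= 1 and adjacent):
            flags.add(("STE", gname))

        std_hits = sum(1 for lead in members
                       if lead in st_dev and st_dev[lead] <= -STD_THRESHOLD_MV)
        if std_hits >= need:
            flags.add(("STD", gname))

        j_members = [m for m in members if m not in _DEMOGRAPHIC_LEADS]
        j_need = 1 if len(members) == 1 else 2
        j_hits = sum(1 for lead in j_members
                     if lead in j_dev and j_dev[lead] >= J_ELEV_MV)
        if j_members and j_hits >= j_need:
            flags.add(("J_ELEV", gname))
    return flags


def classify_series(series: DeviationSeries, age: float | None = None,
                    sex: str | None = None) -> list[tuple[float, set]]:
    """(beat time, flags) for every valid beat of a deviation series."""
    out: list[tuple[float, set]] = []
    for i in range(series.n_beats):
        if not series.valid[i]:
            continue
        st_row = {lead: series.st_dev[i, li]
                  for li, lead in enumerate(series.lead_names)}
        j_row = {lead: series.j_dev[i, li]
                 for li, lead in enumerate(series.lead_names)}
        out.append((float(series.beat_times[i]), classify(st_row, j_row, age, sex)))
    return out


# ---------------------------------------------------------------------------
# episodes
# ---------------------------------------------------------------------------

def episodes(flagged_beats: list[tuple[float, set]],
             gap_tolerance_s: float = DEFAULT_GAP_TOLERANCE_S,
             min_duration_s: float = MIN_EPISODE_S) -> EpisodeReport:
    """Merge per-beat flags into episodes and apply the 1-minute rule.

    Per (type, group), consecutively flagged beats whose gaps do not exceed
    ``gap_tolerance_s`` form one episode; episodes shorter than
    ``min_duration_s`` (from first to last flagged beat) are discarded.
    """
    by_key: dict[tuple[str, str], list[float]] = {}
    for t, flags in sorted(flagged_beats, key=lambda x: x[0]):
        for key in flags:
            by_key.setdefault(key, []).append(t)
    report = EpisodeReport()
    for (etype, group), times in sorted(by_key.items()):
        start = prev = times[0]
        count = 1
        runs: list[tuple[float, float, int]] = []
        for t in times[1:]:
            if t - prev > gap_tolerance_s:
                runs.append((start, prev, count))
                start, count = t, 0
            prev = t
            count += 1
        runs.append((start, prev, count))
        for s, e, n in runs:
            if e - s >= min_duration_s:
                report.episodes.append(Episode(type=etype, group=group,
                                               start_time=s, end_time=e,
                                               n_beats=n))
    report.episodes.sort(key=lambda e: (e.start_time, e.type, e.group))
    return report
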