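"""Signal conditioning, breath segmentation and fixed-length encoding.

The conditioning chain mirrors standard practice for ventilator waveforms:
a zero-phase Butterworth low-pass at 15 Hz removes sensor noise, the signals
are decimated to 40 Hz, breaths are segmented on the flow channel, patient
triggering is detected from the pre-insufflation Paw dip, and the inspiratory
Paw phase of each patient-triggered breath is linearly resampled to a fixed
80-sample vector — the classifier input.

Indices are 0-based; segments are half-open ``[start, end)`` so that
consecutive breaths tile the recording without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io import WaveformRecording, N_SAMPLES

DEFAULT_CUTOFF_HZ = 15.0
DEFAULT_FS_OUT = 40.0
DEFAULT_TRIGGER_SENSITIVITY = 0.5  # cmH2O below end-expiratory baseline
TRIGGER_WINDOW_S = 0.300  # look-back before insufflation onset
BASELINE_WINDOW_S = 0.250  # end-expiratory window for PEEP / baseline Pes
FLOW_END_FRACTION = 0.02  # inspiratory end: flow falls through 2% of peak


@dataclass
class BreathSegment:
    """Index bounds of one breath within a conditioned recording."""

    breath_id: str
    trigger_onset: int
    insufflation_start: int
    inspiratory_end: int
    breath_end: int
    patient_triggered: bool = False

    def __post_init__(self) -> None:
        if not (
            self.trigger_onset
            <= self.insufflation_start
            < self.inspiratory_end
            < self.breath_end
        ):
            raise ValueError(
                f"breath '{self.breath_id}': indices must satisfy "
                "trigger_onset <= insufflation_start < inspiratory_end < breath_end"
            )


@dataclass
class BreathFeatures:
    """Per-breath ventilatory features in clinical units."""

    Ti: float  # s
    Te: float  # s
    respiratory_rate: float  # breaths/min
    tidal_volume: float  # mL
    peak_insp_flow: float  # L/min
    peep: float  # cmH2O


def lowpass_filter(x, fs: float, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = 4):
    """Zero-phase Butterworth low-pass.

    Forward-backward application doubles the effective order and cancels the
    phase delay, which matters because trigger-onset timing feeds the
    classifier input window.
    """
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def decimate(x, fs_in: float, fs_out: float = DEFAULT_FS_OUT):
    """Anti-alias-filtered resampling from ``fs_in`` down to ``fs_out``.

    Output length is ``round(len(x) * fs_out / fs_in)`` (up to the rounding
    convention of polyphase resampling for non-integer ratios).
    """
    if fs_in < fs_out:
        raise ValueError(f"decimate cannot upsample ({fs_in} -> {fs_out} Hz)")
    x = np.asarray(x, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator, padtype="line")


def condition_recording(
    recording: WaveformRecording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    fs_out: float = DEFAULT_FS_OUT,
    apply_filter: bool = True,
) -> WaveformRecording:
    """Low-pass filter (optional) and decimate all channels of a recording."""
    fs = recording.sampling_rate

    def chain(ch):
        y = lowpass_filter(ch, fs, cutoff) if apply_filter and cutoff < fs / 2 else ch
        return decimate(y, fs, fs_out)

    flow = chain(recording.flow)
    n = len(flow)
    time = recording.time[0] + np.arange(n) / fs_out
    return WaveformRecording(
        patient_id=recording.patient_id,
        sampling_rate=fs_out,
        time=time,
        flow=flow,
        paw=chain(recording.paw),
        pes=chain(recording.pes) if recording.pes is not None else None,
        site_tag=recording.site_tag,
        mode_tag=recording.mode_tag,
    )


def _insufflation_onsets(flow: np.ndarray, fs: float) -> list[tuple[int, int]]:
    """Find (insufflation_start, inspiratory_end) pairs on the flow channel.

    An insufflation is a run of flow above an absolute onset threshold
    sustained for at least 100 ms; it ends where flow falls back through
    ``FLOW_END_FRACTION`` of that breath's peak inspiratory flow.
    """
    onset_thresh = max(2.0, 0.05 * float(np.max(flow, initial=0.0)))  # L/min
    above = flow > onset_thresh
    min_run = max(1, int(round(0.100 * fs)))
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    pairs = []
    last_end = 0
    for start in edges:
        if start < last_end:
            continue
        run_end = start
        while run_end < len(flow) and above[run_end]:
            run_end += 1
        if run_end - start < min_run:
            continue
        peak = float(np.max(flow[start:run_end]))
        thresh = FLOW_END_FRACTION * peak
        end = run_end
        while end < len(flow) and flow[end] > thresh:
            end += 1
        pairs.append((int(start), int(end)))
        last_end = end
    return pairs


def segment_breaths(recording: WaveformRecording) -> list[BreathSegment]:
    """Segment a conditioned recording into ordered, non-overlapping breaths.

    ``breath_end`` is the next breath's ``insufflation_start`` (or the end of
    the recording), so segments tile the tracing. Patient triggering is
    detected afterwards via :func:`detect_patient_trigger`.
    """
    pairs = _insufflation_onsets(recording.flow, recording.sampling_rate)
    segments: list[BreathSegment] = []
    for k, (start, insp_end) in enumerate(pairs):
        breath_end = (
            pairs[k + 1][0] if k + 1 < len(pairs) else recording.n_samples - 1
        )
        if insp_end >= breath_end:
            continue  # truncated final breath
        seg = BreathSegment(
            breath_id=f"{recording.patient_id}_b{k:04d}",
            trigger_onset=start,
            insufflation_start=start,
            inspiratory_end=insp_end,
            breath_end=breath_end,
            patient_triggered=False,
        )
        seg.patient_triggered = detect_patient_trigger(seg, recording)
        segments.append(seg)
    return segments


def detect_patient_trigger(
    segment: BreathSegment,
    recording: WaveformRecording,
    sensitivity: float = DEFAULT_TRIGGER_SENSITIVITY,
) -> bool:
    """Detect the pre-insufflation Paw dip of a patient-triggered breath.

    The breath is patient-triggered when Paw drops at least ``sensitivity``
    cmH2O below the end-expiratory baseline (median Paw over the final 250 ms
    of the preceding expiration) within the 300 ms before insufflation onset.
    On success ``segment.trigger_onset`` is moved back to the dip onset —
    the last sample before the window at which Paw was still at baseline
    level.
    """
    fs = recording.sampling_rate
    start = segment.insufflation_start
    win = int(round(TRIGGER_WINDOW_S * fs))
    base_win = int(round(BASELINE_WINDOW_S * fs))
    win_start = max(0, start - win)
    base_stop = win_start
    base_start = max(0, base_stop - base_win)
    if base_stop - base_start < 2:
        return False
    baseline = float(np.median(recording.paw[base_start:base_stop]))
    window = recording.paw[win_start:start]
    if len(window) == 0:
        return False
    dips = baseline - window
    if float(np.max(dips)) < sensitivity:
        return False
    # dip onset: first sample in the window where Paw departs from baseline
    # by more than a small fraction of the trigger sensitivity
    departed = dips > 0.2 * sensitivity
    onset = win_start + int(np.argmax(departed)) if departed.any() else win_start
    segment.trigger_onset = onset
    return True


def extract_inspiratory_phase(
    segment: BreathSegment, recording: WaveformRecording,
    include_trigger_dip: bool = True,
) -> np.ndarray:
    """Paw samples of the inspiratory phase of a patient-triggered breath.

    The window runs from the trigger-dip onset (or from valve opening, when
    ``include_trigger_dip`` is false) through the end of insufflation. Breaths
    that are not patient-triggered are excluded from classifier input by
    contract and raise.
    """
    if not segment.patient_triggered:
        raise ValueError(
            f"breath '{segment.breath_id}' is not patient-triggered; "
            "only patient-triggered breaths enter the classifier"
        )
    start = segment.trigger_onset if include_trigger_dip else segment.insufflation_start
    return recording.paw[start : segment.inspiratory_end + 1].copy()


def resample_to_fixed_length(samples, n: int = N_SAMPLES) -> np.ndarray:
    """Linear interpolation onto ``n`` equally spaced points.

    Endpoints are preserved exactly; an input already on the target grid is
    returned unchanged (linear interpolation is the identity on its own grid).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or len(samples) < 2:
        raise ValueError("resampling requires at least 2 samples")
    src = np.linspace(0.0, 1.0, len(samples))
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, samples)


def compute_breath_features(
    segment: BreathSegment, recording: WaveformRecording
) -> BreathFeatures:
    """Ventilatory features of one segmented breath.

    Tidal volume is the trapezoidal integral of inspiratory flow (L/min
    converted to L/s, reported in mL); PEEP is the median Paw over the final
    250 ms of the breath's expiration.
    """
    fs = recording.sampling_rate
    i0, i1, i2 = segment.insufflation_start, segment.inspiratory_end, segment.breath_end
    Ti = (i1 - i0) / fs
    Te = (i2 - i1) / fs
    flow_lps = recording.flow[i0 : i1 + 1] / 60.0
    vt_ml = float(np.trapezoid(flow_lps, dx=1.0 / fs)) * 1000.0
    peak = float(np.max(recording.flow[i0 : i1 + 1]))
    base_win = int(round(BASELINE_WINDOW_S * fs))
    peep = float(np.median(recording.paw[max(i1, i2 - base_win) : i2]))
    duration = (i2 - i0) / fs
    return BreathFeatures(
        Ti=Ti,
        Te=Te,
        respiratory_rate=60.0 / duration,
        tidal_volume=max(vt_ml, 0.0),
        peak_insp_flow=peak,
        peep=peep,
    )


def preprocess_recording(
    recording: WaveformRecording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    fs_out: float = DEFAULT_FS_OUT,
    trigger_sensitivity: float = DEFAULT_TRIGGER_SENSITIVITY,
    include_trigger_dip: bool = True,
    standardize: bool = False,
):
    """Full conditioning chain: filter, decimate, segment, encode.

    Returns ``(conditioned_recording, segments, x, features)`` where ``x`` is
    the ``(n_patient_triggered, 80)`` matrix of fixed-length inspiratory Paw
    vectors (optionally per-breath standardized) and ``features`` the list of
    :class:`BreathFeatures` for the same breaths, in order.
    """
    cond = condition_recording(recording, cutoff=cutoff, fs_out=fs_out)
    segments = segment_breaths(cond)
    vectors, feats, kept = [], [], []
    for seg in segments:
        if not seg.patient_triggered:
            continue
        if detect_patient_trigger(seg, cond, sensitivity=trigger_sensitivity):
            phase = extract_inspiratory_phase(
                seg, cond, include_trigger_dip=include_trigger_dip
            )
            if len(phase) < 2:
                continue
            v = resample_to_fixed_length(phase)
            if standardize:
                sd = v.std()
                v = (v - v.mean()) / (sd if sd > 0 else 1.0)
            vectors.append(v)
            feats.append(compute_breath_features(seg, cond))
            kept.append(seg)
    x = np.array(vectors) if vectors else np.empty((0, N_SAMPLES))
    return cond, kept, x, feats
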