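"""Esophageal-pressure effort analysis and double-trigger detection.

The esophageal pressure (Pes) swing ΔPes — the drop from the end-expiratory
baseline to the inspiratory nadir — is the bedside proxy for inspiratory
muscle effort. This module measures ΔPes per breath, tabulates how often it
exceeds clinically meaningful thresholds (8, 10, 15 cmH2O) within each
Paw-deformation severity class, detects double triggering (breath stacking)
from the expiratory-time rule, and compares ventilatory features across
severity classes with rank-based tests under Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SEVERITY_CLASSES, WaveformRecording
from .preprocessing import BASELINE_WINDOW_S, BreathSegment

DEFAULT_THRESHOLDS = (8.0, 10.0, 15.0)  # cmH2O
BONFERRONI_DEFAULT = 0.05 / 6  # two features x three class pairs


@dataclass
class EffortMeasurement:
    breath_id: str
    delta_pes: float  # cmH2O, >= 0
    baseline_pes: float
    nadir_pes: float


@dataclass
class DoubleTriggerEvent:
    first_breath_id: str
    second_breath_id: str
    separating_expiratory_time: float  # s


def compute_pes_swing(
    segment: BreathSegment, recording: WaveformRecording
) -> EffortMeasurement:
    """ΔPes of one breath.

    Baseline is the median Pes over the final 250 ms of the preceding
    expiration (just before the trigger dip); the nadir is the minimum Pes
    between trigger onset and the end of insufflation. ΔPes is floored at 0
    and, being a difference, is invariant to any constant Pes offset.
    """
    if recording.pes is None:
        raise ValueError("recording has no Pes channel")
    fs = recording.sampling_rate
    base_n = max(2, int(round(BASELINE_WINDOW_S * fs)))
    b1 = segment.trigger_onset
    b0 = max(0, b1 - base_n)
    if b1 - b0 < 2:
        b1 = min(segment.trigger_onset + 2, segment.inspiratory_end)
        b0 = 0
    baseline = float(np.median(recording.pes[b0:b1]))
    nadir = float(
        np.min(recording.pes[segment.trigger_onset : segment.inspiratory_end + 1])
    )
    return EffortMeasurement(
        breath_id=segment.breath_id,
        delta_pes=max(baseline - nadir, 0.0),
        baseline_pes=baseline,
        nadir_pes=nadir,
    )


def effort_threshold_table(
    measurements: Sequence[EffortMeasurement],
    labels: dict,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Percent of breaths with ΔPes strictly above each threshold, per class.

    ``labels`` maps breath_id to a severity class; every measured breath
    must be labeled. Rows are the three severity classes, columns the
    thresholds.
    """
    values: dict[str, list[float]] = {c: [] for c in SEVERITY_CLASSES}
    for m in measurements:
        if m.breath_id not in labels or labels[m.breath_id] is None:
            raise ValueError(f"no severity label for measured breath '{m.breath_id}'")
        values[labels[m.breath_id]].append(m.delta_pes)
    out = np.full((len(SEVERITY_CLASSES), len(thresholds)), np.nan)
    for i, cls in enumerate(SEVERITY_CLASSES):
        v = np.asarray(values[cls])
        if len(v):
            out[i] = [100.0 * float(np.mean(v > th)) for th in thresholds]
    return pd.DataFrame(
        out,
        index=list(SEVERITY_CLASSES),
        columns=[f">{th:g} cmH2O" for th in thresholds],
    )


def detect_double_triggering(
    segments: Sequence[BreathSegment],
    recording: WaveformRecording,
    te_fraction: float = 0.5,
) -> list[DoubleTriggerEvent]:
    """Flag stacked breath pairs by the short-expiratory-time rule.

    Consecutive insufflations i, i+1 form a double-trigger event when the
    expiratory time separating them is shorter than ``te_fraction`` times the
    running mean inspiratory time and breath i is patient-triggered.
    """
    fs = recording.sampling_rate
    events = []
    ti_sum = 0.0
    for k, seg in enumerate(segments):
        ti_sum += (seg.inspiratory_end - seg.insufflation_start) / fs
        if k + 1 >= len(segments):
            break
        nxt = segments[k + 1]
        te = (nxt.insufflation_start - seg.inspiratory_end) / fs
        mean_ti = ti_sum / (k + 1)
        if seg.patient_triggered and te < te_fraction * mean_ti:
            events.append(
                DoubleTriggerEvent(
                    first_breath_id=seg.breath_id,
                    second_breath_id=nxt.breath_id,
                    separating_expiratory_time=te,
                )
            )
    return events


def compare_features_across_classes(
    features: pd.DataFrame,
    feature_names: Sequence[str] = ("Ti", "peak_insp_flow"),
    alpha: float = 0.05,
    n_comparisons: int = 6,
    method: str = "signed_rank",
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise rank-based comparison of features across severity classes.

    ``features`` must hold one row per breath with the feature columns and a
    ``label`` column. For each feature and class pair, the two groups are
    size-matched by seeded random subsampling and compared with the Wilcoxon
    signed-rank test on random pairings (``method="rank_sum"`` switches to
    the unpaired Mann-Whitney test). Significance is declared at the
    Bonferroni-corrected level ``alpha / n_comparisons``.
    """
    if method not in ("signed_rank", "rank_sum"):
        raise ValueError(f"unknown test method '{method}'")
    corrected = alpha / n_comparisons
    rng = np.random.default_rng(seed)
    rows = []
    for feat in feature_names:
        if feat not in features.columns:
            raise ValueError(f"feature '{feat}' not in table")
        for a, b in combinations(SEVERITY_CLASSES, 2):
            xa = features.loc[features["label"] == a, feat].to_numpy(dtype=float)
            xb = features.loc[features["label"] == b, feat].to_numpy(dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"skipping {feat} {a} vs {b}: fewer than 2 breaths in a class"
                )
                continue
            n = min(len(xa), len(xb))
            sa = rng.permutation(xa)[:n]
            sb = rng.permutation(xb)[:n]
            if method == "signed_rank":
                diffs = sa - sb
                if np.allclose(diffs, 0):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = stats.wilcoxon(sa, sb)
            else:
                stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            q25a, q75a = np.percentile(xa, [25, 75])
            q25b, q75b = np.percentile(xb, [25, 75])
            rows.append(
                {
                    "feature": feat,
                    "class_a": a,
                    "class_b": b,
                    "n_matched": n,
                    "statistic": float(stat),
                    "p_value": float(p),
                    "significant": bool(p < corrected),
                    "alpha_corrected": corrected,
                    "median_a": float(np.median(xa)),
                    "iqr_a": (float(q25a), float(q75a)),
                    "median_b": float(np.median(xb)),
                    "iqr_b": (float(q25b), float(q75b)),
                }
            )
    return pd.DataFrame(rows)
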