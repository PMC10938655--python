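"""Single-compartment respiratory-mechanics simulator.

Generates labeled square-flow volume assist-control tracings: the ventilator
delivers a constant inspiratory flow for a set time, so any inspiratory
muscle pressure (Pmus) subtracts directly from the passive airway-pressure
profile — precisely the flow-starvation deformation being graded. The model
is the linear equation of motion

    Paw(t) = PEEP + R·F + V(t)/C − Pmus(t)        (insufflation, F fixed)

with resistance R (cmH2O·s/L), compliance C (here mL/cmH2O at the interface,
L/cmH2O internally) and passive single-exponential expiration with time
constant R·C. Esophageal pressure is synthesized as

    Pes(t) = baseline + w·V(t)/C − Pmus(t)

where w is the chest-wall share of elastance, so the Pes swing tracks the
configured effort amplitude.

Breath anatomy: an end-expiratory pre-phase at PEEP; a trigger phase in which
effort lowers Paw against the closed valve until the trigger sensitivity is
crossed; the square-flow insufflation; passive expiration. When effort
outlasts the insufflation and double-trigger coupling is enabled, a second
insufflation is appended after a short expiratory gap (breath stacking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import (
    IMV_STAGES,
    SEVERITY_CLASSES,
    WaveformRecording,
    make_breath_table,
)
from .preprocessing import resample_to_fixed_length

#: effort-amplitude bands (cmH2O of peak Pmus) defining ground-truth severity;
#: left-closed, right-open, partitioning [0, inf)
DEFAULT_SEVERITY_BANDS = ((0.0, 5.0), (5.0, 10.0), (10.0, float("inf")))

#: per-class amplitude sampling ranges used by simulate_recording; they sit
#: inside the bands with a margin so the three deformation grades are the
#: well-separated patterns experts can grade visually
DEFAULT_AMPLITUDE_RANGES = ((1.5, 4.0), (5.5, 9.5), (11.0, 20.0))

DEFAULT_NOISE_SD = 0.5  # cmH2O additive white noise on Paw and Pes


@dataclass
class PatientMechanics:
    """Linear single-compartment mechanics."""

    resistance: float = 10.0  # cmH2O·s/L
    compliance: float = 50.0  # mL/cmH2O
    chest_wall_fraction: float = 0.4  # share of elastance from the chest wall
    pes_baseline: float = 5.0  # cmH2O, end-expiratory Pes

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.compliance <= 0:
            raise ValueError("resistance and compliance must be positive")
        if not 0 < self.chest_wall_fraction < 1:
            raise ValueError("chest_wall_fraction must be in (0, 1)")

    @property
    def compliance_l(self) -> float:
        return self.compliance / 1000.0  # L/cmH2O

    @property
    def time_constant(self) -> float:
        return self.resistance * self.compliance_l  # s


@dataclass
class VentilatorSettings:
    set_flow: float = 45.0  # L/min, square profile
    Ti: float = 1.0  # s
    peep: float = 5.0  # cmH2O
    trigger_sensitivity: float = 0.5  # cmH2O
    backup_rate: float = 15.0  # breaths/min
    #: valve-opening latency after the sensitivity is crossed; effort keeps
    #: deepening the Paw dip during this interval, as on real ventilators
    trigger_delay: float = 0.12  # s

    def __post_init__(self) -> None:
        if self.set_flow <= 0 or self.Ti <= 0:
            raise ValueError("set_flow and Ti must be positive")

    @property
    def flow_lps(self) -> float:
        return self.set_flow / 60.0


@dataclass
class EffortProfile:
    """Inspiratory muscle-pressure time course."""

    amplitude: float = 0.0  # cmH2O, peak Pmus
    onset: float = 0.9  # s from breath start
    rise_time: float = 0.3  # s
    hold_time: float = 0.4  # s
    release_time: float = 0.3  # s
    shape: str = "half_sine"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("effort amplitude must be >= 0")
        if min(self.rise_time, self.hold_time, self.release_time) < 0:
            raise ValueError("effort durations must be >= 0")
        if self.shape not in ("half_sine", "trapezoid"):
            raise ValueError(f"unknown effort shape '{self.shape}'")

    @property
    def duration(self) -> float:
        return self.rise_time + self.hold_time + self.release_time

    def pmus(self, t: np.ndarray) -> np.ndarray:
        """Pmus at absolute times ``t`` (array, seconds)."""
        tt = np.asarray(t, dtype=float) - self.onset
        out = np.zeros_like(tt)
        d = self.duration
        if self.amplitude == 0 or d == 0:
            return out
        inside = (tt >= 0) & (tt <= d)
        if self.shape == "half_sine":
            out[inside] = self.amplitude * np.sin(np.pi * tt[inside] / d)
        else:
            up = inside & (tt < self.rise_time)
            hold = inside & (tt >= self.rise_time) & (tt < self.rise_time + self.hold_time)
            down = inside & ~up & ~hold
            if self.rise_time > 0:
                out[up] = self.amplitude * tt[up] / self.rise_time
            out[hold] = self.amplitude
            if self.release_time > 0:
                out[down] = self.amplitude * (d - tt[down]) / self.release_time
        return out


@dataclass
class SimulatedBreath:
    """One synthetic breath with its noiseless ground truth."""

    time: np.ndarray
    flow: np.ndarray  # L/min
    paw: np.ndarray  # cmH2O, noisy
    pes: np.ndarray  # cmH2O, noisy
    severity: str
    pmus_max: float
    delta_pes_true: float
    double_trigger: bool
    patient_triggered: bool
    trigger_onset: int  # sample indices into this breath's arrays
    insufflation_start: int
    inspiratory_end: int

    def inspiratory_vector(self, n: int = 80) -> np.ndarray:
        """Fixed-length encoding of this breath's inspiratory Paw phase."""
        return resample_to_fixed_length(
            self.paw[self.trigger_onset : self.inspiratory_end + 1], n
        )


def severity_from_amplitude(
    pmus_max: float, bands: Sequence[tuple] = DEFAULT_SEVERITY_BANDS
) -> str:
    """Map a peak-Pmus amplitude to its severity class (left-closed bands)."""
    if len(bands) != len(SEVERITY_CLASSES):
        raise ValueError("need one amplitude band per severity class")
    lo0 = bands[0][0]
    if lo0 != 0.0 or bands[-1][1] != float("inf"):
        raise ValueError("bands must cover [0, inf)")
    for (a, b), (c, d) in zip(bands, bands[1:]):
        if b != c or a >= b:
            raise ValueError("bands must be disjoint, ordered and contiguous")
    if pmus_max < 0:
        raise ValueError("amplitude must be >= 0")
    for cls, (a, b) in zip(SEVERITY_CLASSES, bands):
        if a <= pmus_max < b:
            return cls
    return SEVERITY_CLASSES[-1]


def _passive_paw(mech, vent, t_rel, v0=0.0):
    """Passive insufflation Paw at times ``t_rel`` from valve opening."""
    f = vent.flow_lps
    return vent.peep + mech.resistance * f + (v0 + f * t_rel) / mech.compliance_l


def simulate_passive_breath(
    mech: PatientMechanics,
    vent: VentilatorSettings,
    fs: float = 100.0,
    pre_s: float = 1.0,
    te: Optional[float] = None,
) -> dict:
    """Zero-effort (controlled) breath from the closed-form equation of motion.

    Returns a dict of ``time, flow, paw, pes, insufflation_start,
    inspiratory_end`` arrays/indices. Flow is in L/min at the interface.
    """
    if fs < 40:
        raise ValueError("simulator requires fs >= 40 Hz")
    if te is None:
        te = max(60.0 / vent.backup_rate - vent.Ti - pre_s, 3 * mech.time_constant)
    dt = 1.0 / fs
    n_pre = int(round(pre_s * fs))
    n_ti = int(round(vent.Ti * fs))
    n_te = int(round(te * fs))
    n = n_pre + n_ti + 1 + n_te
    t = np.arange(n) * dt
    flow = np.zeros(n)
    paw = np.full(n, float(vent.peep))
    vol = np.zeros(n)  # L above FRC
    # insufflation spans [i0, i1] inclusive: t_rel = 0 (valve opening, V = 0)
    # through t_rel = Ti (end-inspiratory volume on the grid)
    i0, i1 = n_pre, n_pre + n_ti
    t_rel = t[i0 : i1 + 1] - t[i0]
    flow[i0 : i1 + 1] = vent.set_flow
    vol[i0 : i1 + 1] = vent.flow_lps * t_rel
    paw[i0 : i1 + 1] = _passive_paw(mech, vent, t_rel)
    vt = vent.flow_lps * (n_ti * dt)
    tau = mech.time_constant
    t_exp = t[i1 + 1 :] - t[i1]
    vol[i1 + 1 :] = vt * np.exp(-t_exp / tau)
    flow[i1 + 1 :] = -(vt / tau) * np.exp(-t_exp / tau) * 60.0
    pes = mech.pes_baseline + mech.chest_wall_fraction * vol / mech.compliance_l
    return {
        "time": t,
        "flow": flow,
        "paw": paw,
        "pes": pes,
        "insufflation_start": i0,
        "inspiratory_end": i1,
    }


def simulate_assisted_breath(
    mech: PatientMechanics,
    vent: VentilatorSettings,
    effort: EffortProfile,
    fs: float = 100.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: Optional[int] = None,
    pre_s: float = 1.0,
    te: Optional[float] = None,
    dt_coupling: bool = False,
    dt_gap_fraction: float = 0.3,
    severity_bands: Sequence[tuple] = DEFAULT_SEVERITY_BANDS,
) -> SimulatedBreath:
    """Patient-triggered breath with graded Paw deformation.

    During the (flow-controlled) insufflation the entire effort appears as a
    Paw deficit: ``Paw = passive − Pmus``. Before valve opening, effort lowers
    Paw below PEEP until ``trigger_sensitivity`` is crossed. With
    ``dt_coupling`` and an effort still above the trigger threshold at the
    end of the expiratory gap, a second stacked insufflation is appended
    (double triggering); the gap is ``dt_gap_fraction·Ti`` (< 0.5·Ti).
    """
    if fs < 40:
        raise ValueError("simulator requires fs >= 40 Hz")
    if te is None:
        te = max(60.0 / vent.backup_rate - vent.Ti - pre_s, 3 * mech.time_constant)
    dt = 1.0 / fs
    rng = np.random.default_rng(seed)

    # --- trigger phase: valve closed, Paw = peep - Pmus ------------------
    n_pre_max = int(round((pre_s + effort.duration) * fs))
    t_grid = np.arange(n_pre_max) * dt
    pmus_pre = effort.pmus(t_grid)
    crossed = pmus_pre >= vent.trigger_sensitivity
    sched = int(round(pre_s * fs))
    n_delay = int(round(vent.trigger_delay * fs))
    if effort.amplitude > 0 and crossed.any() and int(np.argmax(crossed)) < sched:
        i0 = int(np.argmax(crossed)) + n_delay
        patient_triggered = True
    else:
        i0 = sched  # machine (backup) triggered
        patient_triggered = False

    n_ti = int(round(vent.Ti * fs))
    tau = mech.time_constant
    f_lps = vent.flow_lps

    # decide double triggering: effort must still exceed the trigger
    # threshold at the end of the expiratory gap after the first insufflation
    gap_s = dt_gap_fraction * vent.Ti
    n_gap = int(round(gap_s * fs))
    t_end_gap = (i0 + n_ti + n_gap) * dt
    double_trigger = bool(
        dt_coupling
        and patient_triggered
        and effort.pmus(np.array([t_end_gap]))[0] >= vent.trigger_sensitivity
    )

    n_te = int(round(te * fs))
    n = i0 + n_ti + 1 + (n_gap + n_ti + 1 if double_trigger else 0) + n_te
    t = np.arange(n) * dt
    pmus = effort.pmus(t)
    flow = np.zeros(n)
    vol = np.zeros(n)
    paw = np.full(n, float(vent.peep)) - pmus  # valve-closed / expiratory default

    # first insufflation, inclusive span [i0, i1]: t_rel = 0 .. Ti
    i1 = i0 + n_ti
    t_rel = t[i0 : i1 + 1] - t[i0]
    flow[i0 : i1 + 1] = vent.set_flow
    vol[i0 : i1 + 1] = f_lps * t_rel
    paw[i0 : i1 + 1] = _passive_paw(mech, vent, t_rel) - pmus[i0 : i1 + 1]
    vt1 = f_lps * (n_ti * dt)

    if double_trigger:
        g = slice(i1 + 1, i1 + 1 + n_gap)
        t_exp = t[g] - t[i1]
        vol[g] = vt1 * np.exp(-t_exp / tau)
        flow[g] = -(vt1 / tau) * np.exp(-t_exp / tau) * 60.0
        # paw stays peep - pmus during the gap (the re-trigger dip)
        j0 = i1 + 1 + n_gap
        j1 = j0 + n_ti
        v0 = vt1 * np.exp(-(t[j0] - t[i1]) / tau)
        t_rel2 = t[j0 : j1 + 1] - t[j0]
        flow[j0 : j1 + 1] = vent.set_flow
        vol[j0 : j1 + 1] = v0 + f_lps * t_rel2
        paw[j0 : j1 + 1] = _passive_paw(mech, vent, t_rel2, v0=v0) - pmus[j0 : j1 + 1]
        exp_start, v_end = j1, v0 + vt1
    else:
        exp_start, v_end = i1, vt1

    t_exp = t[exp_start + 1 :] - t[exp_start]
    vol[exp_start + 1 :] = v_end * np.exp(-t_exp / tau)
    flow[exp_start + 1 :] = -(v_end / tau) * np.exp(-t_exp / tau) * 60.0

    pes_clean = (
        mech.pes_baseline + mech.chest_wall_fraction * vol / mech.compliance_l - pmus
    )

    # ground-truth trigger onset: where the pre-insufflation dip departs from
    # baseline by a fifth of the sensitivity — the same onset convention the
    # trigger detector uses, so simulator-encoded and pipeline-encoded
    # inspiratory windows agree
    active = (pmus > 0.2 * vent.trigger_sensitivity) & (np.arange(n) < i0)
    trig = int(np.argmax(active)) if active.any() else i0

    base_n = max(1, int(round(0.25 * fs)))
    baseline_pes = float(np.median(pes_clean[max(0, trig - base_n) : max(trig, 1)]))
    nadir = float(np.min(pes_clean[trig : i1 + 1]))
    delta_pes_true = max(baseline_pes - nadir, 0.0)

    if noise_sd > 0:
        paw = paw + rng.normal(0.0, noise_sd, n)
        pes = pes_clean + rng.normal(0.0, noise_sd, n)
    else:
        pes = pes_clean.copy()

    return SimulatedBreath(
        time=t,
        flow=flow,
        paw=paw,
        pes=pes,
        severity=severity_from_amplitude(effort.amplitude, severity_bands),
        pmus_max=effort.amplitude,
        delta_pes_true=delta_pes_true,
        double_trigger=double_trigger,
        patient_triggered=patient_triggered,
        trigger_onset=trig,
        insufflation_start=i0,
        inspiratory_end=i1,
    )


def _stage_for(index: int, total: int) -> str:
    third = max(total / 3.0, 1e-9)
    return IMV_STAGES[min(int(index / third), 2)]


def simulate_recording(
    n_patients: int = 20,
    breaths_per_patient: int = 150,
    class_mix: Sequence[float] = (0.42, 0.24, 0.34),
    mech_ranges: Optional[dict] = None,
    vent_ranges: Optional[dict] = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    dt_rate: float = 0.0,
    fs: float = 100.0,
    seed: int = 0,
    amplitude_ranges: Sequence[tuple] = DEFAULT_AMPLITUDE_RANGES,
):
    """Generate a labeled multi-patient synthetic cohort.

    Per patient, mechanics and ventilator settings are drawn once from the
    stated ranges; per breath, a severity class is drawn from ``class_mix``
    and the effort amplitude from that class's range. ``dt_rate`` is the
    probability that a *severe* breath develops double triggering (effort
    prolonged beyond the insufflation, coupling enabled); the stacked second
    insufflation appears in the tracing and in the ground-truth table as its
    own row. Returns ``(recordings, table)`` where ``table`` is a breath
    dataset with ground-truth columns ``pmus_max`` and ``delta_pes_true``.
    """
    mix = np.asarray(class_mix, dtype=float)
    if len(mix) != 3 or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("class_mix must be 3 nonnegative proportions summing to 1")
    mech_ranges = mech_ranges or {
        "resistance": (8.0, 15.0),
        "compliance": (40.0, 60.0),
        # modest chest-wall share keeps the Pes swing tracking Pmus closely,
        # so the class-conditional threshold pattern stays ordinal
        "chest_wall_fraction": (0.15, 0.30),
        "pes_baseline": (3.0, 8.0),
    }
    vent_ranges = vent_ranges or {
        "set_flow": (35.0, 55.0),
        "Ti": (0.8, 1.1),
        "peep": (5.0, 10.0),
    }
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 27644437]))
    recordings = []
    rows = {
        "breath_id": [], "patient_id": [], "imv_stage": [], "label": [],
        "double_trigger": [], "pmus_max": [], "delta_pes_true": [],
        "patient_triggered": [],
    }
    vectors = []
    for p in range(n_patients):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        pid = f"sim{p:03d}"
        mech = PatientMechanics(
            resistance=rng.uniform(*mech_ranges["resistance"]),
            compliance=rng.uniform(*mech_ranges["compliance"]),
            chest_wall_fraction=rng.uniform(*mech_ranges["chest_wall_fraction"]),
            pes_baseline=rng.uniform(*mech_ranges["pes_baseline"]),
        )
        vent = VentilatorSettings(
            set_flow=rng.uniform(*vent_ranges["set_flow"]),
            Ti=rng.uniform(*vent_ranges["Ti"]),
            peep=rng.uniform(*vent_ranges["peep"]),
        )
        chunks_t, chunks_f, chunks_p, chunks_e = [], [], [], []
        offset = 0.0
        for b in range(breaths_per_patient):
            cls_idx = int(rng.choice(3, p=mix))
            amp = float(rng.uniform(*amplitude_ranges[cls_idx]))
            is_dt = bool(
                cls_idx == 2 and dt_rate > 0 and rng.random() < dt_rate
            )
            pre = float(rng.uniform(0.5, 0.8))
            gap_frac = 0.3
            if is_dt:
                dur = 1.3 * (vent.Ti * (1 + gap_frac)) + 0.25
            else:
                dur = float(rng.uniform(0.7, 1.0)) * vent.Ti + 0.25
            # effort leads the scheduled backup insufflation by 250 ms so the
            # sensitivity is always crossed first: every breath is
            # patient-triggered, as in tracings selected for assisted breaths
            effort = EffortProfile(
                amplitude=amp,
                onset=pre - 0.25,
                rise_time=0.35 * dur,
                hold_time=0.30 * dur,
                release_time=0.35 * dur,
                shape="half_sine",
            )
            breath = simulate_assisted_breath(
                mech, vent, effort, fs=fs, noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)), pre_s=pre,
                te=float(rng.uniform(1.5, 2.5)),
                dt_coupling=is_dt, dt_gap_fraction=gap_frac,
            )
            chunks_t.append(breath.time + offset)
            offset += len(breath.time) / fs
            chunks_f.append(breath.flow)
            chunks_p.append(breath.paw)
            chunks_e.append(breath.pes)
            stage = _stage_for(b, breaths_per_patient)

            def add_row(suffix, trig, i_end, dpes):
                rows["breath_id"].append(f"{pid}_b{b:04d}{suffix}")
                rows["patient_id"].append(pid)
                rows["imv_stage"].append(stage)
                rows["label"].append(breath.severity)
                rows["double_trigger"].append(breath.double_trigger)
                rows["pmus_max"].append(breath.pmus_max)
                rows["delta_pes_true"].append(dpes)
                rows["patient_triggered"].append(breath.patient_triggered)
                vectors.append(
                    resample_to_fixed_length(breath.paw[trig : i_end + 1])
                )

            add_row("", breath.trigger_onset, breath.inspiratory_end,
                    breath.delta_pes_true)
            if breath.double_trigger:
                # the stacked second insufflation is its own table row; its
                # "trigger dip" is the short expiratory gap, mirroring how
                # the segmenter slices the stacked pair
                n_ti = breath.inspiratory_end - breath.insufflation_start
                n_gap = int(round(gap_frac * vent.Ti * fs))
                j1 = breath.inspiratory_end + 1 + n_gap + n_ti
                add_row("s", breath.inspiratory_end + 1, j1,
                        breath.delta_pes_true)
        time = np.concatenate(chunks_t)
        time = time[0] + np.arange(len(time)) / fs  # exact uniform grid
        recordings.append(
            WaveformRecording(
                patient_id=pid,
                sampling_rate=fs,
                time=time,
                flow=np.concatenate(chunks_f),
                paw=np.concatenate(chunks_p),
                pes=np.concatenate(chunks_e),
                site_tag="synthetic",
            )
        )
    table = make_breath_table(
        rows["breath_id"], rows["patient_id"], np.asarray(vectors),
        imv_stage=rows["imv_stage"], label=rows["label"],
        double_trigger=rows["double_trigger"],
    )
    table["pmus_max"] = rows["pmus_max"]
    table["delta_pes_true"] = rows["delta_pes_true"]
    table["patient_triggered"] = rows["patient_triggered"]
    return recordings, table
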