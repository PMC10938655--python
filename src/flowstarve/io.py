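"""Reading, validating and writing ventilator recordings and breath datasets.

Two plain-text formats are used throughout the package:

* **Recording CSV** — one multichannel tracing per file, columns
  ``time_s, flow_lpm, paw_cmh2o`` and optionally ``pes_cmh2o``, preceded by
  ``#``-prefixed metadata lines carrying at least ``sampling_rate_hz`` and
  ``patient_id``.
* **Breath dataset CSV** — one row per breath with metadata columns
  ``breath_id, patient_id, imv_stage, label, double_trigger`` followed by the
  80 airway-pressure samples ``x0 .. x79``.

Both formats are comma-separated with ``.`` decimal marks so that
write-then-read round-trips are exact to printing precision.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

N_SAMPLES = 80
SEVERITY_CLASSES = ("normal_mild", "moderate", "severe")
IMV_STAGES = ("early", "intermediate", "late")

X_COLUMNS = [f"x{i}" for i in range(N_SAMPLES)]
META_COLUMNS = ["breath_id", "patient_id", "imv_stage", "label", "double_trigger"]


class WaveformIOError(ValueError):
    """Raised on malformed recording or breath-dataset files."""


@dataclass
class WaveformRecording:
    """A multichannel ventilator tracing.

    Channels are stored in canonical units: time in seconds, flow in L/min,
    airway pressure (Paw) and optional esophageal pressure (Pes) in cmH2O.
    ``sampling_rate`` is authoritative metadata; the time axis is validated
    against it rather than the other way round, because downstream decimation
    needs an exact rate.
    """

    patient_id: str
    sampling_rate: float
    time: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    pes: Optional[np.ndarray] = None
    site_tag: str = ""
    mode_tag: str = "square-flow VACV"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        if self.pes is not None:
            self.pes = np.asarray(self.pes, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise WaveformIOError("sampling_rate must be positive")
        n = len(self.time)
        if n < 2:
            raise WaveformIOError("recording must contain at least 2 samples")
        for name in ("flow", "paw"):
            if len(getattr(self, name)) != n:
                raise WaveformIOError(
                    f"channel '{name}' has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if self.pes is not None and len(self.pes) != n:
            raise WaveformIOError(
                f"channel 'pes' has length {len(self.pes)}, expected {n}"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise WaveformIOError(
                f"time column is not strictly increasing at row {row}"
            )
        expected = 1.0 / self.sampling_rate
        if np.any(np.abs(dt - expected) > 0.01 * expected):
            row = int(np.argmax(np.abs(dt - expected) > 0.01 * expected)) + 1
            raise WaveformIOError(
                f"time spacing at row {row} deviates more than 1% from the "
                f"declared sampling rate {self.sampling_rate} Hz"
            )

    def channel_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time, "flow_lpm": self.flow, "paw_cmh2o": self.paw}
        if self.pes is not None:
            data["pes_cmh2o"] = self.pes
        return pd.DataFrame(data)


def read_recording(
    path,
    column_map: Optional[dict] = None,
    sampling_rate: Optional[float] = None,
) -> WaveformRecording:
    """Read a recording CSV into a validated :class:`WaveformRecording`.

    Parameters
    ----------
    path
        CSV file with ``#``-prefixed metadata lines and a header row.
    column_map
        Optional mapping from canonical names (``time``, ``flow``, ``paw``,
        ``pes``) to the column names present in the file; defaults to the
        package's native column names.
    sampling_rate
        Overrides the ``# sampling_rate_hz=`` metadata line when given.
    """
    path = Path(path)
    if not path.exists():
        raise WaveformIOError(f"no such recording file: {path}")
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    if not lines:
        raise WaveformIOError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("".join(lines)))
    cmap = {
        "time": "time_s",
        "flow": "flow_lpm",
        "paw": "paw_cmh2o",
        "pes": "pes_cmh2o",
    }
    if column_map:
        cmap.update(column_map)
    for key in ("time", "flow", "paw"):
        if cmap[key] not in df.columns:
            raise WaveformIOError(f"{path}: missing required column '{cmap[key]}'")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) + 1 if len(bad) else 0
            raise WaveformIOError(f"{path}: non-numeric value in '{col}' at row {row}")
    if sampling_rate is None:
        if "sampling_rate_hz" not in meta:
            raise WaveformIOError(
                f"{path}: no '# sampling_rate_hz=' metadata and no rate given"
            )
        sampling_rate = float(meta["sampling_rate_hz"])
    pes = df[cmap["pes"]].to_numpy() if cmap["pes"] in df.columns else None
    return WaveformRecording(
        patient_id=meta.get("patient_id", path.stem),
        sampling_rate=sampling_rate,
        time=df[cmap["time"]].to_numpy(),
        flow=df[cmap["flow"]].to_numpy(),
        paw=df[cmap["paw"]].to_numpy(),
        pes=pes,
        site_tag=meta.get("site_tag", ""),
        mode_tag=meta.get("mode_tag", "square-flow VACV"),
    )


def write_recording(recording: WaveformRecording, path) -> None:
    """Write a recording as CSV with metadata comment lines."""
    recording.validate()
    path = Path(path)
    df = recording.channel_frame()
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={recording.sampling_rate!r}\n")
        fh.write(f"# patient_id={recording.patient_id}\n")
        if recording.site_tag:
            fh.write(f"# site_tag={recording.site_tag}\n")
        fh.write(f"# mode_tag={recording.mode_tag}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def validate_breath_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a breath dataset table in place and return it.

    A valid table has the metadata columns, exactly 80 finite pressure
    samples per row, unique breath ids, and labels drawn from the three
    severity classes (missing labels are permitted: unlabeled datasets are
    what a deployed classifier consumes).
    """
    for col in META_COLUMNS:
        if col not in table.columns:
            raise WaveformIOError(f"breath table missing column '{col}'")
    missing = [c for c in X_COLUMNS if c not in table.columns]
    if missing:
        raise WaveformIOError(
            f"breath table missing {len(missing)} sample columns (x0..x79 required)"
        )
    x = table[X_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        bad = table.index[~np.isfinite(x).all(axis=1)][0]
        bid = table.loc[bad, "breath_id"]
        raise WaveformIOError(f"breath '{bid}' has non-finite or missing samples")
    if table["breath_id"].duplicated().any():
        dup = table.loc[table["breath_id"].duplicated(), "breath_id"].iloc[0]
        raise WaveformIOError(f"duplicate breath_id '{dup}'")
    labels = table["label"].dropna()
    bad_labels = set(labels.unique()) - set(SEVERITY_CLASSES)
    if bad_labels:
        raise WaveformIOError(f"unknown severity labels: {sorted(bad_labels)}")
    bad_stages = set(table["imv_stage"].dropna().unique()) - set(IMV_STAGES)
    if bad_stages:
        raise WaveformIOError(f"unknown imv_stage values: {sorted(bad_stages)}")
    return table


def make_breath_table(
    breath_ids,
    patient_ids,
    x: np.ndarray,
    imv_stage=None,
    label=None,
    double_trigger=None,
) -> pd.DataFrame:
    """Assemble a validated breath dataset table from arrays."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_SAMPLES:
        raise WaveformIOError(f"x must be (n, {N_SAMPLES}), got {x.shape}")
    n = x.shape[0]
    table = pd.DataFrame(
        {
            "breath_id": list(breath_ids),
            "patient_id": list(patient_ids),
            "imv_stage": imv_stage if imv_stage is not None else ["early"] * n,
            "label": label if label is not None else [None] * n,
            "double_trigger": (
                double_trigger if double_trigger is not None else [False] * n
            ),
        }
    )
    for i, col in enumerate(X_COLUMNS):
        table[col] = x[:, i]
    return validate_breath_table(table)


def read_breath_dataset(path) -> pd.DataFrame:
    """Read and validate a breath dataset CSV."""
    path = Path(path)
    if not path.exists():
        raise WaveformIOError(f"no such breath dataset: {path}")
    df = pd.read_csv(path, comment="#")
    sample_cols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    if len(sample_cols) != N_SAMPLES:
        # locate the offending rows for a useful message when the file was
        # written with a ragged sample block
        raise WaveformIOError(
            f"{path}: expected {N_SAMPLES} sample columns, found {len(sample_cols)}"
        )
    x = df[X_COLUMNS]
    if x.isna().any(axis=None):
        bid = df.loc[x.isna().any(axis=1), "breath_id"].iloc[0]
        raise WaveformIOError(
            f"{path}: breath '{bid}' does not provide all {N_SAMPLES} samples"
        )
    if "double_trigger" in df.columns:
        df["double_trigger"] = df["double_trigger"].fillna(False).astype(bool)
    if "label" in df.columns:
        df["label"] = df["label"].where(df["label"].notna(), None)
    return validate_breath_table(df)


def write_breath_dataset(table: pd.DataFrame, path) -> None:
    """Write a validated breath dataset table as CSV."""
    validate_breath_table(table)
    cols = META_COLUMNS + X_COLUMNS
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.17g")
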