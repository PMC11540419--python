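"""On-disk formats: CSV signals, WESAD-style archives, checkpoints, results.

The package's native interchange format is plain text: a two-column signal CSV
``(time_s, eda_uS)`` plus a sidecar annotation CSV
``(start_s, end_s, arousal, q1..q6)`` with one row per segment. The writer and
reader round-trip sample values bit-exactly.

A loader for per-subject archives in the layout published with the WESAD
dataset (a pickled dict with ``signal/chest/EDA`` at 700 Hz and a per-sample
condition ``label`` vector) is provided for users who download that dataset;
it is optional and nothing else in the package depends on it.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EDARecording, SegmentSpec, ValidationError

__all__ = [
    "StressReport",
    "SubjectDataset",
    "Source",
    "FormatError",
    "write_csv_signal",
    "read_csv_signal",
    "read_wesad_subject",
    "WESAD_CONDITIONS",
    "save_checkpoint",
    "load_checkpoint",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """A file did not match its documented layout."""


class Source(str, Enum):
    synthetic = "synthetic"
    wesad = "wesad"
    csv = "csv"


@dataclass(frozen=True)
class StressReport:
    """One Likert answer to one questionnaire item for one segment."""

    segment_id: int
    question_id: int
    likert: int

    def __post_init__(self) -> None:
        if not 1 <= self.question_id <= 6:
            raise ValidationError(f"question_id must be in [1, 6], got {self.question_id}")
        if self.likert not in (1, 2, 3, 4):
            raise ValidationError(f"likert must be in [1, 4], got {self.likert}")


@dataclass
class SubjectDataset:
    """A recording plus its stress self-reports."""

    recording: EDARecording
    reports: list[StressReport]
    source: Source = Source.synthetic

    def __post_init__(self) -> None:
        n_segments = len(self.recording.segment_boundaries)
        for r in self.reports:
            if not 0 <= r.segment_id < n_segments:
                raise ValidationError(
                    f"report references segment {r.segment_id}, "
                    f"but the recording has {n_segments} segments"
                )


def dataset_from_recording(recording: EDARecording, source: Source = Source.synthetic) -> SubjectDataset:
    """Build a SubjectDataset whose reports come from the segment annotations."""
    reports = [
        StressReport(segment_id=i, question_id=q + 1, likert=spec.likert_answers[q])
        for i, (_s, _e, spec) in enumerate(recording.segment_boundaries)
        for q in range(6)
    ]
    return SubjectDataset(recording=recording, reports=reports, source=source)


# ---------------------------------------------------------------------------
# CSV signal dialect
# ---------------------------------------------------------------------------

def write_csv_signal(recording: EDARecording, signal_path, annotation_path) -> None:
    """Write the two-column signal CSV and its segment-annotation sidecar."""
    fs = recording.sampling_rate
    n = len(recording.samples)
    pd.DataFrame(
        {"time_s": np.arange(n) / fs, "eda_uS": recording.samples}
    ).to_csv(signal_path, index=False)
    rows = []
    for start, end, spec in recording.segment_boundaries:
        row = {"start_s": start / fs, "end_s": end / fs, "arousal": spec.arousal}
        row.update({f"q{i+1}": a for i, a in enumerate(spec.likert_answers)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(annotation_path, index=False)


def read_csv_signal(signal_path, annotation_path=None, subject_id: str | None = None) -> SubjectDataset:
    """Read a signal CSV (+ optional annotations) back into a SubjectDataset.

    The sampling rate is inferred from the time column; segment boundaries are
    reconstructed as ``floor(start_s*fs) .. floor(end_s*fs)`` (0-based,
    half-open). Raises :class:`FormatError` on missing columns, a
    non-monotone time axis, or annotations extending past the signal.
    """
    sig = pd.read_csv(signal_path, float_precision="round_trip")
    for col in ("time_s", "eda_uS"):
        if col not in sig.columns:
            raise FormatError(f"signal CSV is missing column {col!r}")
    t = sig["time_s"].to_numpy(dtype=np.float64)
    if len(t) < 2:
        raise FormatError("signal CSV must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("time column must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    if abs(fs - round(fs)) < 1e-3:
        fs = float(round(fs))
    samples = sig["eda_uS"].to_numpy(dtype=np.float64)

    boundaries: list[tuple[int, int, SegmentSpec]] = []
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path)
        needed = ["start_s", "end_s", "arousal"] + [f"q{i}" for i in range(1, 7)]
        for col in needed:
            if col not in ann.columns:
                raise FormatError(f"annotation CSV is missing column {col!r}")
        for _, row in ann.iterrows():
            start = int(np.floor(row["start_s"] * fs))
            end = int(np.floor(row["end_s"] * fs))
            if end > len(samples):
                raise FormatError(
                    f"annotation [{row['start_s']}, {row['end_s']}] s extends past "
                    f"the signal end ({len(samples) / fs:.3f} s)"
                )
            spec = SegmentSpec(
                duration=(end - start) / fs,
                arousal=float(row["arousal"]),
                likert_answers=tuple(int(row[f"q{i}"]) for i in range(1, 7)),
            )
            boundaries.append((start, end, spec))

    recording = EDARecording(
        samples=samples,
        sampling_rate=fs,
        subject_id=subject_id or Path(signal_path).stem,
        segment_boundaries=boundaries,
    )
    ds = dataset_from_recording(recording, source=Source.csv)
    if not boundaries:
        ds.reports = []
    return ds


# ---------------------------------------------------------------------------
# WESAD-style archives (optional)
# ---------------------------------------------------------------------------

#: condition codes used in the published per-sample label vector
WESAD_CONDITIONS = {"baseline": 1, "stress": 2, "amusement": 3, "meditation": 4}


def read_wesad_subject(
    archive_path,
    conditions: list[str],
    stai_answers: dict[str, tuple[int, ...]],
    device: str = "chest",
    channel: str = "EDA",
) -> SubjectDataset:
    """Load the 700 Hz chest EDA channel of a WESAD-layout subject archive.

    ``conditions`` selects which study conditions become segments (the
    published protocol narrative is ambiguous about which condition carries
    the stress self-reports, so the caller must choose explicitly — this
    loader never guesses). ``stai_answers`` maps each selected condition name
    to its six Likert answers. Each maximal contiguous run of a selected
    condition code becomes one segment.

    Only ``device='chest'`` and ``channel='EDA'`` are supported.
    """
    if device != "chest":
        raise ValidationError(f"unsupported device {device!r}; only 'chest' is supported")
    if channel != "EDA":
        raise ValidationError(f"unsupported channel {channel!r}; only 'EDA' is supported")
    path = Path(archive_path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found; the WESAD dataset must be downloaded separately "
            "(https://ubicomp.eti.uni-siegen.de/home/datasets/icmi18/)"
        )
    with open(path, "rb") as fh:
        record = pickle.load(fh, encoding="latin1")
    try:
        eda = np.asarray(record["signal"]["chest"]["EDA"], dtype=np.float64).ravel()
        labels = np.asarray(record["label"]).ravel()
        subject = str(record.get("subject", path.stem))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"unexpected archive layout: missing key {exc}") from exc
    if len(labels) != len(eda):
        raise FormatError(
            f"label vector length {len(labels)} does not match EDA length {len(eda)}"
        )

    unknown = [c for c in conditions if c not in WESAD_CONDITIONS]
    if unknown:
        raise ValidationError(f"unknown condition(s) {unknown}; know {sorted(WESAD_CONDITIONS)}")
    missing = [c for c in conditions if c not in stai_answers]
    if missing:
        raise ValidationError(f"no STAI answers supplied for condition(s) {missing}")

    keep = np.isin(labels, [WESAD_CONDITIONS[c] for c in conditions])
    if not keep.any():
        raise FormatError(f"archive contains no samples for conditions {conditions}")

    # concatenate maximal runs of selected conditions, one segment per run
    pieces: list[np.ndarray] = []
    boundaries: list[tuple[int, int, SegmentSpec]] = []
    code_to_name = {v: k for k, v in WESAD_CONDITIONS.items()}
    fs = 700.0
    cursor = 0
    edges = np.flatnonzero(np.diff(labels) != 0) + 1
    for start, end in zip(np.r_[0, edges], np.r_[edges, len(labels)]):
        code = int(labels[start])
        name = code_to_name.get(code)
        if name not in conditions:
            continue
        run = eda[start:end]
        spec = SegmentSpec(
            duration=len(run) / fs,
            arousal=1.0 if name == "stress" else 0.0,
            likert_answers=tuple(int(a) for a in stai_answers[name]),
        )
        pieces.append(run)
        boundaries.append((cursor, cursor + len(run), spec))
        cursor += len(run)

    recording = EDARecording(
        samples=np.clip(np.concatenate(pieces), 0.0, None),
        sampling_rate=fs,
        subject_id=subject,
        segment_boundaries=boundaries,
    )
    return dataset_from_recording(recording, source=Source.wesad)


# ---------------------------------------------------------------------------
# Checkpoints and results tables
# ---------------------------------------------------------------------------

def save_checkpoint(path, weights: list[np.ndarray], manifest: dict) -> None:
    """Store model weights in a single ``.npz`` with a JSON manifest entry."""
    arrays = {f"param_{i:03d}": w for i, w in enumerate(weights)}
    arrays["manifest"] = np.frombuffer(
        json.dumps(manifest, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[list[np.ndarray], dict]:
    """Inverse of :func:`save_checkpoint`."""
    with np.load(path) as data:
        try:
            manifest = json.loads(bytes(data["manifest"].tobytes()).decode())
        except KeyError as exc:
            raise FormatError("checkpoint has no manifest") from exc
        keys = sorted(k for k in data.files if k.startswith("param_"))
        weights = [data[k] for k in keys]
    return weights, manifest


RESULT_COLUMNS = ["subject_id", "question_id", "method", "budget", "resample", "rmse"]


def write_results(rows: pd.DataFrame, path) -> None:
    """Write a tidy comparison table (one row per subject × question ×
    method × budget × resample)."""
    missing = [c for c in RESULT_COLUMNS if c not in rows.columns]
    if missing:
        raise ValidationError(f"results table is missing columns {missing}")
    rows[RESULT_COLUMNS].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results CSV is missing columns {missing}")
    return df
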