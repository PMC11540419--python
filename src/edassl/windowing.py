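"""Window construction, ordinal label conversion, and train/test splitting.

The pretext (self-supervised) unit is a pair *(7000-sample window, next 40
samples)*; consecutive windows overlap, advancing by a 100-sample stride, so a
recording of length L yields ``floor((L - 7000 - 40)/100) + 1`` pairs. The
downstream unit is a 7000-sample window lying entirely inside one annotated
segment, labelled with that segment's Likert answer mapped onto the ordinal
targets {0.25, 0.5, 0.75, 1.0}.

All indices are 0-based and half-open. Window arrays are views into the
recording's sample buffer — a pair's target is literally the slice it indexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import EDARecording, ValidationError

__all__ = [
    "WindowingParams",
    "PretextPair",
    "LabeledWindow",
    "MinMaxNormalizer",
    "convert_label",
    "make_pretext_pairs",
    "make_labeled_windows",
    "split_train_test",
    "normalize_recording",
]


@dataclass(frozen=True)
class WindowingParams:
    """Sliding-window geometry: input length, forecast horizon, stride."""

    window_len: int = 7000
    horizon: int = 40
    stride: int = 100

    def __post_init__(self) -> None:
        for name in ("window_len", "horizon", "stride"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.window_len < self.horizon:
            raise ValidationError("window_len must be >= horizon")


@dataclass(frozen=True)
class PretextPair:
    """(input window, forecast target) — the self-supervised training unit."""

    input: np.ndarray
    target: np.ndarray
    start_index: int


@dataclass(frozen=True)
class LabeledWindow:
    """A window with an ordinal stress target — the downstream training unit."""

    input: np.ndarray
    target: float
    question_id: int
    segment_id: int
    start_index: int


def convert_label(likert: int) -> float:
    """Map a 4-point Likert answer onto an equally spaced ordinal target.

    1 → 0.25, 2 → 0.5, 3 → 0.75, 4 → 1.0 (i.e. ``likert / 4``), preserving
    both the categorical and the ordinal character of the self-report.
    """
    if isinstance(likert, bool) or not isinstance(likert, (int, np.integer)):
        raise ValidationError(f"likert must be an integer, got {likert!r}")
    if likert not in (1, 2, 3, 4):
        raise ValidationError(f"likert must be in {{1, 2, 3, 4}}, got {likert}")
    return likert / 4.0


def make_pretext_pairs(
    recording: EDARecording, params: WindowingParams = WindowingParams()
) -> list[PretextPair]:
    """Slice a recording into overlapping forecast pairs.

    Pair *i* starts at ``i × stride``; its input is the next ``window_len``
    samples and its target the ``horizon`` samples after those. Signals too
    short for a single pair yield an empty list.
    """
    x = recording.samples
    span = params.window_len + params.horizon
    n = len(x)
    if n < span:
        return []
    n_pairs = (n - span) // params.stride + 1
    pairs = []
    for i in range(n_pairs):
        s = i * params.stride
        pairs.append(
            PretextPair(
                input=x[s : s + params.window_len],
                target=x[s + params.window_len : s + span],
                start_index=s,
            )
        )
    return pairs


def make_labeled_windows(
    dataset,
    question_id: int,
    params: WindowingParams = WindowingParams(),
    stride: int | None = None,
) -> list[LabeledWindow]:
    """Tile each labelled segment with windows carrying its ordinal target.

    ``stride`` defaults to ``window_len`` (non-overlapping tiles, the
    leakage-conservative choice); pass a smaller stride to reproduce denser
    overlapped sampling. Windows never cross a segment boundary; segments
    shorter than one window contribute nothing.
    """
    stride = params.window_len if stride is None else int(stride)
    if stride <= 0:
        raise ValidationError(f"stride must be > 0, got {stride}")
    answers = {
        r.segment_id: r.likert for r in dataset.reports if r.question_id == question_id
    }
    if not answers:
        raise ValidationError(f"no stress reports for question {question_id}")
    rec = dataset.recording
    x = rec.samples
    windows = []
    for seg_id, (start, end, _spec) in enumerate(rec.segment_boundaries):
        if seg_id not in answers:
            continue
        target = convert_label(answers[seg_id])
        seg_len = end - start
        if seg_len < params.window_len:
            continue
        for i in range((seg_len - params.window_len) // stride + 1):
            s = start + i * stride
            windows.append(
                LabeledWindow(
                    input=x[s : s + params.window_len],
                    target=target,
                    question_id=question_id,
                    segment_id=seg_id,
                    start_index=s,
                )
            )
    return windows


def split_train_test(
    windows: list[LabeledWindow],
    test_fraction: float,
    mode: str = "random",
    seed: int = 0,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Deterministic train/test split of labelled windows.

    ``random`` draws ``floor(n × test_fraction)`` windows uniformly — this
    mirrors protocols that sample test points at random, and with overlapping
    windows it permits sample-level leakage. ``block`` instead reserves a
    contiguous tail of each segment for testing and drops any training window
    sharing raw samples with it, guaranteeing disjoint signal coverage.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = len(windows)
    n_test = int(n * test_fraction)
    if n_test < 1 or n - n_test < 1:
        raise ValidationError(
            f"{n} windows at test_fraction {test_fraction} cannot populate both sides"
        )
    if mode == "random":
        order = np.random.default_rng(seed).permutation(n)
        test_idx = set(order[:n_test].tolist())
        train = [w for i, w in enumerate(windows) if i not in test_idx]
        test = [w for i, w in enumerate(windows) if i in test_idx]
        return train, test
    if mode == "block":
        by_segment: dict[int, list[LabeledWindow]] = {}
        for w in windows:
            by_segment.setdefault(w.segment_id, []).append(w)
        train, test = [], []
        for seg_windows in by_segment.values():
            seg_windows = sorted(seg_windows, key=lambda w: w.start_index)
            k = max(1, int(round(len(seg_windows) * test_fraction)))
            seg_test = seg_windows[-k:]
            cut = min(w.start_index for w in seg_test)
            window_len = len(seg_test[0].input)
            test.extend(seg_test)
            train.extend(
                w for w in seg_windows[:-k] if w.start_index + window_len <= cut
            )
        if not train or not test:
            raise ValidationError("block split left one side empty")
        return train, test
    raise ValidationError(f"unknown split mode {mode!r}")


@dataclass(frozen=True)
class MinMaxNormalizer:
    """Affine map sending the fitted range [lo, hi] onto [0, 1].

    A flat signal (hi == lo) maps to the constant 0 — the degenerate case is
    well-defined rather than an error.
    """

    lo: float
    hi: float

    @classmethod
    def fit(cls, samples: np.ndarray) -> "MinMaxNormalizer":
        samples = np.asarray(samples)
        if samples.size == 0:
            raise ValidationError("cannot fit a normalizer on an empty signal")
        return cls(lo=float(samples.min()), hi=float(samples.max()))

    @property
    def scale(self) -> float:
        span = self.hi - self.lo
        return 1.0 / span if span > 0 else 1.0

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.lo) * self.scale

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=np.float64) / self.scale + self.lo


def normalize_recording(
    recording: EDARecording, normalizer: MinMaxNormalizer | None = None
) -> tuple[EDARecording, MinMaxNormalizer]:
    """Return a unit-scaled copy of a recording plus the fitted normalizer.

    Per-subject min–max scaling to [0, 1], fitted by default on the full trace
    (the pre-training corpus is the entire signal). Segment annotations are
    carried through unchanged.
    """
    if normalizer is None:
        normalizer = MinMaxNormalizer.fit(recording.samples)
    scaled = np.clip(normalizer.transform(recording.samples), 0.0, None)
    return (
        EDARecording(
            samples=scaled,
            sampling_rate=recording.sampling_rate,
            subject_id=recording.subject_id,
            segment_boundaries=list(recording.segment_boundaries),
            scr_event_times=recording.scr_event_times,
        ),
        normalizer,
    )
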