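"""Synthetic per-subject electrodermal activity (EDA) with known stress structure.

A skin-conductance trace is modelled as the sum of three standard components:

* a **tonic** skin-conductance level — a slowly wandering baseline, here a
  Gaussian random walk around a resting level;
* a **phasic** train of skin-conductance responses (SCRs) — brief peaks with a
  fast rise and a slow decay, modelled with the canonical biexponential kernel
  and event times drawn from a homogeneous Poisson process whose rate rises
  linearly with the segment's arousal level;
* additive white Gaussian measurement noise.

Each recording is divided into contiguous *segments*, each with an arousal
level in [0, 1] and six 4-point Likert answers to anxiety-inventory questions.
Arousal drives the SCR event rate, so the downstream ordinal stress targets
are (noisily) recoverable from the signal — which is exactly what makes the
simulator a meaningful test surface for the transfer-learning pipeline.

Conductance is in microsiemens (µS) throughout and is clipped at zero: real
skin conductance is nonnegative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentSpec",
    "SimConfig",
    "EDARecording",
    "scr_kernel",
    "scr_peak_time",
    "simulate_subject",
    "default_segments",
    "default_sim_config",
]


class ValidationError(ValueError):
    """A configuration or argument violated a documented invariant."""


@dataclass(frozen=True)
class SegmentSpec:
    """One experimental condition block.

    Parameters
    ----------
    duration : float
        Segment length in seconds, strictly positive.
    arousal : float
        Physiological arousal in [0, 1]; scales the SCR event rate.
    likert_answers : tuple of six ints
        Answers (1..4) to the six anxiety-inventory items for this segment.
        They need not be a deterministic function of arousal — self-reports
        are subjective.
    """

    duration: float
    arousal: float
    likert_answers: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if not 0.0 <= self.arousal <= 1.0:
            raise ValidationError(f"arousal must be in [0, 1], got {self.arousal}")
        answers = tuple(int(a) for a in self.likert_answers)
        if len(answers) != 6 or any(a not in (1, 2, 3, 4) for a in answers):
            raise ValidationError(
                f"likert_answers must be six integers in {{1..4}}, got {self.likert_answers!r}"
            )
        object.__setattr__(self, "likert_answers", answers)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic subject.

    Defaults describe a calm laboratory recording: a 2 µS baseline with a
    gentle random walk, a spontaneous SCR rate of 0.03 events/s rising to
    0.23 events/s at maximal arousal, SCR amplitudes of 0.3 ± 0.1 µS with
    0.75 s rise and 4 s decay time constants, and 5 nS sensor noise.
    """

    subject_seed: int
    segments: tuple[SegmentSpec, ...]
    sampling_rate: float = 700.0
    tonic_level: float = 2.0
    tonic_drift_sd: float = 0.01
    scr_base_rate: float = 0.03
    scr_rate_gain: float = 0.20
    scr_amp_mean: float = 0.3
    scr_amp_sd: float = 0.1
    scr_rise_tau: float = 0.75
    scr_decay_tau: float = 4.0
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValidationError("segments must be non-empty")
        for name in ("sampling_rate", "scr_rise_tau", "scr_decay_tau"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in (
            "tonic_level",
            "tonic_drift_sd",
            "scr_base_rate",
            "scr_rate_gain",
            "scr_amp_mean",
            "scr_amp_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class EDARecording:
    """A subject's raw conductance trace with segment annotations.

    ``segment_boundaries`` holds ``(start, end, SegmentSpec)`` index triples,
    0-based and half-open, tiling ``[0, len(samples))`` without overlap.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str
    segment_boundaries: list[tuple[int, int, SegmentSpec]] = field(default_factory=list)
    #: SCR event onsets in seconds (simulator metadata; None for loaded data)
    scr_event_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D array")
        if np.any(self.samples < 0):
            raise ValidationError("conductance samples must be nonnegative")
        cursor = 0
        for start, end, _ in self.segment_boundaries:
            if start != cursor or end <= start:
                raise ValidationError(
                    "segment boundaries must tile [0, n) contiguously without overlap"
                )
            cursor = end
        if self.segment_boundaries and cursor != len(self.samples):
            raise ValidationError("segment boundaries must cover the full trace")

    @property
    def duration(self) -> float:
        """Total length in seconds."""
        return len(self.samples) / self.sampling_rate

    def segment_slice(self, segment_id: int) -> slice:
        start, end, _ = self.segment_boundaries[segment_id]
        return slice(start, end)


def scr_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the biexponential kernel's maximum (closed form)."""
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValidationError("time constants must be > 0")
    if rise_tau == decay_tau:
        # degenerate limit: (t/tau) * exp(1 - t/tau) peaks at t = tau
        return rise_tau
    return math.log(decay_tau / rise_tau) / (1.0 / rise_tau - 1.0 / decay_tau)


def scr_kernel(t, rise_tau: float = 0.75, decay_tau: float = 4.0):
    """Peak-normalized biexponential skin-conductance-response shape.

    ``k(t) = (exp(-t/decay_tau) - exp(-t/rise_tau)) / k_max`` so that the
    maximum equals 1; ``k(0) = 0`` and ``k -> 0`` as ``t -> inf``. Accepts a
    scalar or array of nonnegative times (seconds).
    """
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValidationError("time constants must be > 0")
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValidationError("t must be >= 0")
    if rise_tau == decay_tau:
        tau = rise_tau
        out = (t_arr / tau) * np.exp(1.0 - t_arr / tau)
    else:
        t_star = scr_peak_time(rise_tau, decay_tau)
        peak = math.exp(-t_star / decay_tau) - math.exp(-t_star / rise_tau)
        out = (np.exp(-t_arr / decay_tau) - np.exp(-t_arr / rise_tau)) / peak
    return float(out) if np.isscalar(t) else out


def _kernel_support_samples(config: SimConfig) -> int:
    # length after which the decaying tail is < 1e-4 of the peak
    t_max = config.scr_decay_tau * math.log(1e4) + scr_peak_time(
        config.scr_rise_tau, config.scr_decay_tau
    )
    return int(math.ceil(t_max * config.sampling_rate))


def simulate_subject(config: SimConfig, subject_id: str | None = None) -> EDARecording:
    """Generate one subject's EDA recording, deterministically from the seed.

    The trace is ``tonic random walk + Σ amplitude·kernel(t - t_event) +
    noise``, clipped at zero. Event times follow a per-segment homogeneous
    Poisson process with rate ``scr_base_rate + scr_rate_gain × arousal``;
    kernels spill freely across segment boundaries (sweat-gland activity does
    not reset at condition changes).
    """
    fs = config.sampling_rate
    rng = np.random.default_rng(config.subject_seed)

    seg_samples = [int(seg.duration * fs) for seg in config.segments]
    n = int(sum(seg_samples))
    if n == 0:
        raise ValidationError("total duration too short for one sample")

    # tonic: level + Brownian drift with per-step sd tonic_drift_sd * sqrt(dt)
    steps = rng.normal(0.0, config.tonic_drift_sd / math.sqrt(fs), size=n)
    steps[0] = 0.0
    trace = config.tonic_level + np.cumsum(steps)

    # phasic: per-segment Poisson event times, shared biexponential kernel
    support = _kernel_support_samples(config)
    kernel = scr_kernel(
        np.arange(support) / fs, config.scr_rise_tau, config.scr_decay_tau
    )
    boundaries: list[tuple[int, int, SegmentSpec]] = []
    event_indices: list[int] = []
    start = 0
    for seg, n_seg in zip(config.segments, seg_samples):
        rate = config.scr_base_rate + config.scr_rate_gain * seg.arousal
        count = rng.poisson(rate * n_seg / fs)
        offsets = np.sort(rng.uniform(0.0, n_seg, size=count)).astype(np.int64)
        amps = np.maximum(
            rng.normal(config.scr_amp_mean, config.scr_amp_sd, size=count), 0.0
        )
        for off, amp in zip(offsets, amps):
            i0 = start + int(off)
            i1 = min(i0 + support, n)
            trace[i0:i1] += amp * kernel[: i1 - i0]
            event_indices.append(i0)
        boundaries.append((start, start + n_seg, seg))
        start += n_seg

    if config.noise_sd > 0:
        trace += rng.normal(0.0, config.noise_sd, size=n)
    np.clip(trace, 0.0, None, out=trace)

    return EDARecording(
        samples=trace,
        sampling_rate=fs,
        subject_id=subject_id if subject_id is not None else f"sim{config.subject_seed}",
        segment_boundaries=boundaries,
        scr_event_times=np.asarray(event_indices, dtype=np.float64) / fs,
    )


_DEFAULT_AROUSALS = (0.05, 0.8, 0.3, 0.95, 0.0, 0.6, 0.15, 1.0)


def default_segments(
    subject_seed: int,
    n_segments: int = 8,
    segment_duration: float = 150.0,
) -> tuple[SegmentSpec, ...]:
    """Default condition schedule: alternating low/high-arousal blocks.

    Likert answers track arousal (answer ≈ 1 + 3·arousal) with subject-specific
    ±1 jitter on a third of the items, emulating the subjectivity of
    self-reports without severing the signal–label link.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(subject_seed), 0x5E9]))
    segments = []
    for i in range(n_segments):
        arousal = _DEFAULT_AROUSALS[i % len(_DEFAULT_AROUSALS)]
        base = 1 + int(round(3 * arousal))
        answers = []
        for _ in range(6):
            a = base
            if rng.random() < 1 / 3:
                a += rng.choice((-1, 1))
            answers.append(int(np.clip(a, 1, 4)))
        segments.append(
            SegmentSpec(duration=segment_duration, arousal=arousal, likert_answers=tuple(answers))
        )
    return tuple(segments)


def default_sim_config(subject_seed: int, **overrides) -> SimConfig:
    """A ready-to-run subject configuration (~1200 s across 8 segments).

    ``n_segments`` / ``segment_duration`` shape the default schedule; any
    other keyword overrides the corresponding :class:`SimConfig` field.
    """
    segments = overrides.pop("segments", None)
    if segments is None:
        seg_kwargs = {
            k: overrides.pop(k)
            for k in ("n_segments", "segment_duration")
            if k in overrides
        }
        segments = default_segments(subject_seed, **seg_kwargs)
    return SimConfig(subject_seed=subject_seed, segments=segments, **overrides)
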