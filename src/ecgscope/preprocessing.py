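"""Raw ECG to standardized 384-sample segments.

The model consumes 3-second windows of single-lead ECG at 128 Hz (384
samples).  A recording is prepared in a fixed order:

1. resample to 128 Hz (anti-aliased polyphase resampling);
2. blind segmentation — cut a 384-sample window at an arbitrary offset,
   with no R-peak or fiducial-point detection of any kind;
3. fifth-order Butterworth band-pass (0.01 fN to 0.7 fN with fN = 64 Hz,
   i.e. 0.64–44.8 Hz), applied per segment so end-of-window filter
   distortion is part of what the classifier sees;
4. standard-score normalization of the segment, g' = (g - mu) / sigma.

Segmentation must precede filtering, and standardization is applied to
every enrolled and every query segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "TARGET_RATE_HZ", "SEGMENT_SECONDS", "SEGMENT_SAMPLES",
    "ECGRecording", "ECGSegment", "FilterSpec",
    "resample", "blind_segment", "bandpass_filter", "standardize",
    "preprocess_pipeline", "segment_windows", "finalize_windows",
    "DegenerateSegmentError",
]

TARGET_RATE_HZ = 128.0
SEGMENT_SECONDS = 3.0
#: samples per segment: 3 s x 128 Hz
SEGMENT_SAMPLES = int(SEGMENT_SECONDS * TARGET_RATE_HZ)


class DegenerateSegmentError(ValueError):
    """Raised when a segment is flat (zero standard deviation)."""


@dataclass
class ECGRecording:
    """A labeled raw single-lead ECG trace.

    session_start is seconds since an arbitrary epoch and only feeds
    time-separation bookkeeping; it does not affect preprocessing.
    """

    samples: np.ndarray
    sampling_rate: float
    identity_id: str
    database_id: str = ""
    session_start: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.identity_id:
            raise ValueError("identity_id must be non-empty")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class ECGSegment:
    """One 384-sample window; the model's atomic input."""

    values: np.ndarray
    source_identity: str
    source_offset: int = 0
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (SEGMENT_SAMPLES,):
            raise ValueError(
                f"segment must have exactly {SEGMENT_SAMPLES} samples, "
                f"got shape {self.values.shape}")
        if self.standardized:
            if abs(self.values.mean()) > 1e-6 or abs(self.values.std() - 1.0) > 1e-6:
                raise ValueError("standardized segment must have mean 0, std 1")


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: cutoffs as fractions of the Nyquist rate fN."""

    order: int = 5
    low_frac: float = 0.01
    high_frac: float = 0.7
    nyquist_hz: float = TARGET_RATE_HZ / 2.0
    zero_phase: bool = True

    def __post_init__(self):
        if not 0 < self.low_frac < self.high_frac < 1:
            raise ValueError("need 0 < low_frac < high_frac < 1")

    @property
    def band_hz(self) -> tuple[float, float]:
        return (self.low_frac * self.nyquist_hz, self.high_frac * self.nyquist_hz)

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return signal.butter(self.order, [self.low_frac, self.high_frac],
                             btype="bandpass")


def resample(recording: ECGRecording, target_rate: float = TARGET_RATE_HZ) -> ECGRecording:
    """Resample to `target_rate` with an anti-aliased polyphase filter.

    A recording already at the target rate is returned unchanged
    (sample-identical).  The rational rate ratio is approximated to a
    denominator of at most 1000, which is exact for all common ECG
    sampling rates.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if recording.sampling_rate == target_rate:
        return recording
    ratio = Fraction(target_rate / recording.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(recording.samples, ratio.numerator, ratio.denominator)
    return replace(recording, samples=out, sampling_rate=target_rate)


def blind_segment(recording: ECGRecording, start_offset: int) -> ECGSegment:
    """Cut the 384 samples at [start_offset, start_offset+384).

    Purely positional: the signal content is never inspected, so any two
    equal-length recordings yield identically placed windows.
    """
    if recording.sampling_rate != TARGET_RATE_HZ:
        raise ValueError(
            f"blind segmentation operates at {TARGET_RATE_HZ} Hz; "
            f"recording is at {recording.sampling_rate} Hz (resample first)")
    if start_offset < 0:
        raise IndexError(f"start_offset must be >= 0, got {start_offset}")
    if start_offset + SEGMENT_SAMPLES > recording.samples.size:
        raise IndexError(
            f"window [{start_offset}, {start_offset + SEGMENT_SAMPLES}) exceeds "
            f"recording of {recording.samples.size} samples")
    values = recording.samples[start_offset:start_offset + SEGMENT_SAMPLES].copy()
    return ECGSegment(values, recording.identity_id, int(start_offset))


def bandpass_filter(segment: ECGSegment, spec: FilterSpec = FilterSpec()) -> ECGSegment:
    """Apply the Butterworth band-pass to one raw segment.

    Zero-phase forward-backward filtering by default (end-of-segment
    distortion without phase shift); set spec.zero_phase=False for a
    causal single pass.
    """
    if segment.standardized:
        raise ValueError("filter is applied before standardization")
    b, a = spec.coefficients()
    if spec.zero_phase:
        out = signal.filtfilt(b, a, segment.values)
    else:
        out = signal.lfilter(b, a, segment.values)
    return replace(segment, values=out)


def standardize(segment: ECGSegment) -> ECGSegment:
    """Standard-score normalization: g' = (g - mu) / sigma.

    sigma is the population (1/N) standard deviation.  A flat segment
    (sigma = 0) raises DegenerateSegmentError rather than silently
    emitting zeros.
    """
    if segment.standardized:
        return segment
    mu = segment.values.mean()
    sigma = segment.values.std()
    # relative threshold: a constant trace has sigma at rounding-noise level
    if sigma <= 1e-12 * max(abs(mu), 1.0):
        raise DegenerateSegmentError(
            f"flat segment (identity={segment.source_identity}, "
            f"offset={segment.source_offset}): sigma is 0")
    return replace(segment, values=(segment.values - mu) / sigma, standardized=True)


def preprocess_pipeline(recording: ECGRecording, offsets,
                        spec: FilterSpec = FilterSpec()) -> list[ECGSegment]:
    """resample -> blind segment at each offset -> filter -> standardize.

    Offsets are 0-based sample indices at 128 Hz; windows are half-open
    [offset, offset+384).
    """
    rec = resample(recording)
    out = []
    for off in offsets:
        seg = blind_segment(rec, off)
        seg = bandpass_filter(seg, spec)
        out.append(standardize(seg))
    return out


def finalize_windows(windows: np.ndarray,
                     spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Vectorized filter + standardize of raw (N, 384) windows.

    Equivalent to bandpass_filter followed by standardize on each row;
    both act strictly per segment, so batching is exact, not an
    approximation.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    if windows.shape[1] != SEGMENT_SAMPLES:
        raise ValueError(f"windows must have {SEGMENT_SAMPLES} columns")
    b, a = spec.coefficients()
    if spec.zero_phase:
        filtered = signal.filtfilt(b, a, windows, axis=1)
    else:
        filtered = signal.lfilter(b, a, windows, axis=1)
    mu = filtered.mean(axis=1, keepdims=True)
    sigma = filtered.std(axis=1, keepdims=True)
    if np.any(sigma <= 1e-12 * np.maximum(np.abs(mu), 1.0)):
        raise DegenerateSegmentError("flat segment in batch")
    return (filtered - mu) / sigma


def segment_windows(samples_128hz: np.ndarray, offsets: np.ndarray,
                    spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Filter+standardize the windows of one 128 Hz signal at `offsets`.

    Fast path used by the dataset builder and the evaluation protocol;
    per-window equivalent of preprocess_pipeline.  Returns an array of
    shape (len(offsets), 384).
    """
    offsets = np.asarray(offsets, dtype=np.intp)
    if offsets.size == 0:
        return np.empty((0, SEGMENT_SAMPLES))
    if offsets.min() < 0 or offsets.max() + SEGMENT_SAMPLES > samples_128hz.size:
        raise IndexError("window exceeds the recording")
    windows = samples_128hz[offsets[:, None] + np.arange(SEGMENT_SAMPLES)[None, :]]
    return finalize_windows(windows, spec)
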