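"""Audio ingestion and time-frequency feature extraction.

The analysis front end mirrors a conventional speech pipeline: recordings are
downsampled to 16 kHz / 16-bit, same-state training audio is concatenated and
cut into non-overlapping 10-s segments, and each segment is represented by the
magnitude of a short-time Fourier transform (25 ms window, 7.5 ms overlap,
201 one-sided frequency bins), z-scored per frequency channel with statistics
estimated on training data only.

Phone-attribute posterior streams (frames x 21 probabilities, one column per
phonological class) are carried as :class:`PosteriorStream` and serialized as
headered CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

from .errors import ContractError, FormatError, UnsupportedRateError

TARGET_RATE = 16_000
SEGMENT_SECONDS = 10.0
WINDOW_MS = 25.0
OVERLAP_MS = 7.5
N_FFT = 400  # 25 ms at 16 kHz
N_FREQ_BINS = N_FFT // 2 + 1  # 201
HOP_SAMPLES = int(round((WINDOW_MS - OVERLAP_MS) / 1000.0 * TARGET_RATE))  # 280
STD_FLOOR = 1e-8

N_ATTRIBUTES = 21


@dataclass
class Waveform:
    """Mono audio buffer with float samples in [-1, 1]."""

    samples: np.ndarray
    rate: int
    bit_depth: str = "float32"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ContractError("waveform must be mono (1-D)")
        if self.rate <= 0:
            raise ContractError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class Spectrogram:
    """One-sided STFT magnitude, shape (freq_bins, frames)."""

    magnitude: np.ndarray
    rate: int = TARGET_RATE
    window_ms: float = WINDOW_MS
    overlap_ms: float = OVERLAP_MS
    normalized: bool = False
    nonstandard_length: bool = False


@dataclass
class NormStats:
    """Per-frequency-channel mean/std fitted on training spectrograms."""

    mean: np.ndarray
    std: np.ndarray
    provenance: str = "train"
    n_frames: int = 0


@dataclass
class PosteriorStream:
    """Frames x 21 matrix of phone-attribute posterior probabilities."""

    posteriors: np.ndarray
    attribute_names: Sequence[str]
    frame_period: float = 0.01
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=np.float64)
        names = list(self.attribute_names)
        if self.posteriors.ndim != 2 or self.posteriors.shape[1] != N_ATTRIBUTES:
            raise FormatError(
                f"posterior matrix must have {N_ATTRIBUTES} columns, "
                f"got shape {self.posteriors.shape}"
            )
        if len(names) != N_ATTRIBUTES or len(set(names)) != N_ATTRIBUTES:
            raise FormatError("attribute names must be 21 unique labels")
        if "silence" not in names:
            raise FormatError("attribute names must include 'silence'")
        if self.posteriors.size and (
            self.posteriors.min() < 0.0 or self.posteriors.max() > 1.0
        ):
            bad = np.argwhere((self.posteriors < 0) | (self.posteriors > 1))[0]
            raise FormatError(
                f"posterior value out of [0, 1] at row {bad[0]}, "
                f"column '{names[bad[1]]}'"
            )
        self.attribute_names = names

    @property
    def n_frames(self) -> int:
        return self.posteriors.shape[0]


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    return Waveform(np.asarray(data, dtype=np.float64), int(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    wavfile.write(path, w.rate, np.clip(w.samples, -1.0, 1.0).astype(np.float32))


# ---------------------------------------------------------------------------
# Resampling and segmentation
# ---------------------------------------------------------------------------

def resample_and_quantize(w: Waveform, target_rate: int = TARGET_RATE) -> Waveform:
    """Downsample to 16 kHz and round-trip through 16-bit quantization.

    ``resample_poly`` applies a Kaiser-windowed anti-aliasing low-pass before
    decimation, so energy above the 8 kHz Nyquist is strongly suppressed.
    """
    if w.rate < target_rate:
        raise UnsupportedRateError(
            f"input rate {w.rate} Hz below the {target_rate} Hz target"
        )
    if w.rate == target_rate:
        y = w.samples
    else:
        g = np.gcd(int(w.rate), target_rate)
        y = resample_poly(w.samples, target_rate // g, int(w.rate) // g)
    q = np.clip(np.round(y * 32767.0), -32768, 32767).astype(np.int16)
    return Waveform(q.astype(np.float64) / 32767.0, target_rate, bit_depth="int16")


def chunk_training_audio(
    recordings: Iterable[tuple[str, np.ndarray]],
    rate: int = TARGET_RATE,
    segment_seconds: float = SEGMENT_SECONDS,
) -> list[tuple[np.ndarray, str]]:
    """Concatenate same-state recordings (in given order) and cut 10-s segments.

    ``recordings`` yields ``(state, samples)`` pairs at 16 kHz. Segments never
    mix states; a trailing remainder shorter than ``segment_seconds`` is
    dropped.
    """
    seg_len = int(round(segment_seconds * rate))
    pooled: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    for state, samples in recordings:
        if state not in pooled:
            pooled[state] = []
            order.append(state)
        pooled[state].append(np.asarray(samples))
    segments: list[tuple[np.ndarray, str]] = []
    for state in order:
        cat = np.concatenate(pooled[state]) if pooled[state] else np.empty(0)
        n_seg = cat.size // seg_len
        for i in range(n_seg):
            segments.append((cat[i * seg_len : (i + 1) * seg_len], state))
    return segments


def split_test_segment(segment: np.ndarray, rate: int = TARGET_RATE) -> tuple[np.ndarray, np.ndarray]:
    """Split a 10-s segment into a 5-s validation half and a 5-s test half."""
    segment = np.asarray(segment)
    expected = int(round(SEGMENT_SECONDS * rate))
    if segment.size != expected:
        raise ContractError(
            f"segment must be exactly {expected} samples, got {segment.size}"
        )
    half = expected // 2
    return segment[:half], segment[half:]


def extend_by_repetition(samples: np.ndarray, target_len: int) -> np.ndarray:
    """Tile a short signal until it reaches ``target_len`` samples."""
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ContractError("cannot extend an empty signal")
    reps = int(np.ceil(target_len / samples.size))
    return np.tile(samples, reps)[:target_len]


# ---------------------------------------------------------------------------
# Spectrogram
# ---------------------------------------------------------------------------

def compute_spectrogram(
    samples: np.ndarray,
    rate: int = TARGET_RATE,
    window: str = "hamming",
    n_fft: int = N_FFT,
    hop: int = HOP_SAMPLES,
) -> Spectrogram:
    """Magnitude STFT without padding: frames = floor((N - win)/hop) + 1.

    A 10-s segment at 16 kHz yields exactly (201, 571); the 5-s halves yield
    (201, 284) and are flagged ``nonstandard_length``.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < n_fft:
        raise ContractError("signal shorter than one analysis window")
    win = get_window(window, n_fft, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(x, n_fft)[::hop]
    mag = np.abs(np.fft.rfft(frames * win, n=n_fft, axis=1)).T
    std_frames = int((round(SEGMENT_SECONDS * rate) - n_fft) // hop) + 1
    return Spectrogram(
        magnitude=mag,
        rate=rate,
        nonstandard_length=(mag.shape[1] != std_frames),
    )


def fit_normalizer(train_spectrograms: Sequence[Spectrogram], provenance: str = "train") -> NormStats:
    """Per-frequency-channel mean/std over all frames of the training pool."""
    if not train_spectrograms:
        raise ContractError("need at least one training spectrogram")
    stacked = np.concatenate([s.magnitude for s in train_spectrograms], axis=1)
    mean = stacked.mean(axis=1)
    std = stacked.std(axis=1)
    floored = std < STD_FLOOR
    if floored.any():
        std = np.where(floored, STD_FLOOR, std)
    return NormStats(mean=mean, std=std, provenance=provenance, n_frames=stacked.shape[1])


def apply_normalizer(s: Spectrogram, stats: NormStats) -> Spectrogram:
    norm = (s.magnitude - stats.mean[:, None]) / stats.std[:, None]
    # channels whose training std hit the floor carry no information: zero them
    norm = np.where(stats.std[:, None] <= STD_FLOOR, 0.0, norm)
    return Spectrogram(
        magnitude=norm,
        rate=s.rate,
        window_ms=s.window_ms,
        overlap_ms=s.overlap_ms,
        normalized=True,
        nonstandard_length=s.nonstandard_length,
    )


# ---------------------------------------------------------------------------
# Posterior stream I/O
# ---------------------------------------------------------------------------

def write_posteriors(stream: PosteriorStream, path: str | Path, sidecar: bool = False) -> None:
    """Write a posterior stream as headered CSV (optionally a .npy sidecar)."""
    df = pd.DataFrame(stream.posteriors, columns=list(stream.attribute_names))
    df.to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        np.save(Path(path).with_suffix(".npy"), stream.posteriors.astype(np.float32))


def read_posteriors(
    path: str | Path,
    expected_attributes: Sequence[str] | None = None,
    frame_period: float = 0.01,
) -> PosteriorStream:
    """Read a posterior CSV, validating schema and value range."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if expected_attributes is not None:
        missing = [a for a in expected_attributes if a not in cols]
        extra = [c for c in cols if c not in expected_attributes]
        if missing or extra:
            raise FormatError(
                f"{path}: attribute columns mismatch; missing {missing}, extra {extra}"
            )
        df = df[list(expected_attributes)]
        cols = list(expected_attributes)
    elif len(cols) != N_ATTRIBUTES:
        raise FormatError(
            f"{path}: expected {N_ATTRIBUTES} attribute columns, found {len(cols)}"
        )
    values = df.to_numpy(dtype=np.float64)
    bad = np.argwhere((values < 0.0) | (values > 1.0) | ~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{path}: value {values[r, c]} outside [0, 1] at row {r}, column '{cols[c]}'"
        )
    return PosteriorStream(values, cols, frame_period=frame_period, provenance="external")
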