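"""Timbre feature extraction from short-time audio spectra.

Audio is cut into 1-second windows with 50% overlap and five spectral-shape
(timbre) descriptors are computed per window: spectral centroid, centroid
spread, centroid skewness, spectral entropy and spectral flux.  Timbre is the
aspect of sound quality that is independent of pitch and loudness, and these
descriptors summarise it as moments and information content of the magnitude
spectrum, plus the frame-to-frame rate of spectral change.

Conventions
-----------
* A window is emitted iff its *end* falls strictly before the track end, so a
  60 s track under 1 s / 50% overlap yields exactly 118 windows.
* Each frame is Hann-tapered before the FFT to limit spectral leakage.
* The first three descriptors are moments of the L1-normalised magnitude
  distribution p_k = |S_k| / Σ|S_k| over frequency; entropy is Shannon entropy
  normalised to [0, 1] by log(K); flux is the Euclidean distance between
  consecutive L1-normalised spectra (0 for the first window).
* An all-zero (silent) spectrum maps every descriptor to 0 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidInputError, ShapeError

#: fixed descriptor column order of the per-track feature matrix
TIMBRE_COLUMNS = ("centroid", "spread", "skewness", "entropy", "flux")

#: default analysis sample rate (Hz) audio is resampled to before framing
DEFAULT_ANALYSIS_RATE = 22050


@dataclass
class AudioTrack:
    """A mono waveform with its sample rate.

    Amplitudes are dimensionless, nominally in [-1, 1].
    """

    samples: np.ndarray
    sample_rate: int
    track_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidInputError(
                f"AudioTrack '{self.track_id}': samples must be a non-empty 1-D "
                f"vector, got shape {self.samples.shape}"
            )
        if not int(self.sample_rate) > 0:
            raise InvalidInputError(
                f"AudioTrack '{self.track_id}': sample_rate must be positive, "
                f"got {self.sample_rate}"
            )
        self.sample_rate = int(self.sample_rate)
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError(
                f"AudioTrack '{self.track_id}': samples contain non-finite values"
            )

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class SpectralFrame:
    """Magnitude spectrum of one analysis window over the non-negative bins."""

    magnitudes: np.ndarray
    bin_freqs: np.ndarray
    frame_start: float = 0.0

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=np.float64)
        if self.magnitudes.shape != self.bin_freqs.shape:
            raise ShapeError(
                f"SpectralFrame: magnitudes {self.magnitudes.shape} and bin_freqs "
                f"{self.bin_freqs.shape} differ in length"
            )
        if self.magnitudes.size and np.any(self.magnitudes < 0):
            raise InvalidInputError("SpectralFrame: magnitudes must be >= 0")
        if self.bin_freqs.size and (
            self.bin_freqs[0] < 0 or np.any(np.diff(self.bin_freqs) <= 0)
        ):
            raise InvalidInputError(
                "SpectralFrame: bin_freqs must be non-negative and strictly increasing"
            )

    def normalized(self) -> np.ndarray:
        """L1-normalised magnitude distribution p_k (all-zero for silence)."""
        total = self.magnitudes.sum()
        if total <= 0:
            return np.zeros_like(self.magnitudes)
        return self.magnitudes / total


@dataclass
class TimbreFeatureMatrix:
    """Per-window timbre descriptors of one track, columns = TIMBRE_COLUMNS."""

    values: np.ndarray
    window_starts: np.ndarray
    track_id: str = ""
    columns: tuple = field(default=TIMBRE_COLUMNS, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.window_starts = np.asarray(self.window_starts, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(TIMBRE_COLUMNS):
            raise ShapeError(
                f"TimbreFeatureMatrix: expected (n_windows, {len(TIMBRE_COLUMNS)}), "
                f"got {self.values.shape}"
            )
        if self.values.shape[0] != self.window_starts.size:
            raise ShapeError("TimbreFeatureMatrix: window_starts length mismatch")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major flattened feature vector (n_windows * 5,)."""
        return self.values.ravel()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(TIMBRE_COLUMNS))
        df.insert(0, "window_start", self.window_starts)
        df.insert(0, "track_id", self.track_id)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def extract_windows(
    track: AudioTrack, window_s: float = 1.0, overlap: float = 0.5
):
    """Cut a track into fixed-length overlapping windows.

    Window k covers [k*hop, k*hop + window_s) with hop = window_s * (1 - overlap);
    a window is emitted iff its end lies strictly before the track duration.
    A 60 s track at 1 s / 50% therefore yields 118 windows.

    Returns a list of ``(samples, start_seconds)`` pairs in time order.  A track
    shorter than one window yields an empty list.
    """
    if not isinstance(track, AudioTrack):
        track = AudioTrack(np.asarray(track), DEFAULT_ANALYSIS_RATE)
    if window_s <= 0:
        raise InvalidInputError(f"window_s must be > 0, got {window_s}")
    if not 0 <= overlap < 1:
        raise InvalidInputError(f"overlap must be in [0, 1), got {overlap}")

    hop_s = window_s * (1.0 - overlap)
    duration = track.duration
    win_n = int(round(window_s * track.sample_rate))
    frames = []
    k = 0
    while k * hop_s + window_s < duration:
        start_idx = int(round(k * hop_s * track.sample_rate))
        frames.append((track.samples[start_idx : start_idx + win_n], k * hop_s))
        k += 1
    return frames


def count_windows(duration: float, window_s: float, hop_s: float) -> int:
    """Number of windows under the strict-end rule, |{k >= 0 : k*hop + w < D}|."""
    if window_s >= duration:
        return 0
    # largest k with k*hop < D - w; guard float edge by direct check
    k = int(np.floor((duration - window_s) / hop_s)) + 1
    while k * hop_s + window_s < duration:
        k += 1
    while k > 0 and (k - 1) * hop_s + window_s >= duration:
        k -= 1
    return k


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

def frame_spectrum(frame: np.ndarray, sample_rate: int, frame_start: float = 0.0) -> SpectralFrame:
    """Magnitude spectrum of a Hann-tapered frame over the non-negative bins.

    bin_freqs[k] = k * sample_rate / N for an N-sample frame.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1 or frame.size == 0:
        raise InvalidInputError("frame_spectrum: frame must be a non-empty 1-D vector")
    n = frame.size
    taper = sps.get_window("hann", n, fftbins=True)
    mags = np.abs(np.fft.rfft(frame * taper))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return SpectralFrame(mags, freqs, frame_start)


# ---------------------------------------------------------------------------
# The five descriptors
# ---------------------------------------------------------------------------

def spectral_centroid(s: SpectralFrame) -> float:
    """Center of mass of the spectrum, C = sum f_k p_k  [Hz]; 0 for silence."""
    p = s.normalized()
    return float(np.dot(s.bin_freqs, p))


def spectral_spread(s: SpectralFrame) -> float:
    """Width around the centroid, sqrt(sum (f_k - C)^2 p_k)  [Hz]; 0 for silence."""
    p = s.normalized()
    if p.sum() == 0:
        return 0.0
    c = float(np.dot(s.bin_freqs, p))
    return float(np.sqrt(np.dot((s.bin_freqs - c) ** 2, p)))


def spectral_skewness(s: SpectralFrame) -> float:
    """Standardised third moment of the spectral distribution; 0 when spread = 0."""
    p = s.normalized()
    if p.sum() == 0:
        return 0.0
    c = float(np.dot(s.bin_freqs, p))
    var = float(np.dot((s.bin_freqs - c) ** 2, p))
    if var <= 0:
        return 0.0
    m3 = float(np.dot((s.bin_freqs - c) ** 3, p))
    return m3 / var**1.5


def spectral_entropy(s: SpectralFrame) -> float:
    """Shannon entropy of p_k normalised by log(K) into [0, 1]; 0 for silence."""
    p = s.normalized()
    k = p.size
    if k <= 1:
        return 0.0
    nz = p[p > 0]
    if nz.size <= 1:
        return 0.0
    h = -float(np.sum(nz * np.log(nz)))
    return h / np.log(k)


def spectral_flux(current: SpectralFrame, previous: SpectralFrame | None) -> float:
    """Euclidean distance between consecutive L1-normalised spectra; 0 at frame 0."""
    if previous is None:
        return 0.0
    if current.magnitudes.size != previous.magnitudes.size:
        raise ShapeError(
            f"spectral_flux: bin counts differ "
            f"({current.magnitudes.size} vs {previous.magnitudes.size})"
        )
    return float(np.linalg.norm(current.normalized() - previous.normalized()))


# ---------------------------------------------------------------------------
# Per-track pipeline
# ---------------------------------------------------------------------------

def resample_track(track: AudioTrack, rate: int) -> AudioTrack:
    """Polyphase-resample a track to ``rate`` Hz (no-op if already there)."""
    if track.sample_rate == rate:
        return track
    frac = Fraction(int(rate), int(track.sample_rate))
    out = sps.resample_poly(track.samples, frac.numerator, frac.denominator)
    return AudioTrack(out, rate, track.track_id)


def track_features(
    track: AudioTrack,
    window_s: float = 1.0,
    overlap: float = 0.5,
    analysis_rate: int = DEFAULT_ANALYSIS_RATE,
) -> TimbreFeatureMatrix:
    """Full timbre matrix of a track: (n_windows, 5) in TIMBRE_COLUMNS order.

    The track is resampled to ``analysis_rate`` before framing.  Raises a
    structured error (naming the minimum duration) for tracks shorter than one
    window under the strict-end rule.
    """
    track = resample_track(track, analysis_rate)
    frames = extract_windows(track, window_s, overlap)
    if not frames:
        raise InvalidInputError(
            f"track '{track.track_id}' is too short for feature extraction: "
            f"duration must exceed one window ({window_s} s), got {track.duration:.3f} s"
        )
    rows = np.empty((len(frames), len(TIMBRE_COLUMNS)))
    starts = np.empty(len(frames))
    prev: SpectralFrame | None = None
    for i, (samples, start) in enumerate(frames):
        s = frame_spectrum(samples, track.sample_rate, start)
        rows[i] = (
            spectral_centroid(s),
            spectral_spread(s),
            spectral_skewness(s),
            spectral_entropy(s),
            spectral_flux(s, prev),
        )
        starts[i] = start
        prev = s
    return TimbreFeatureMatrix(rows, starts, track.track_id)
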