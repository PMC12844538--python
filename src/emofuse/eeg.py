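"""EEG band-power feature extraction.

Trials are 32-channel recordings at 128 Hz (the DEAP preprocessed layout:
60 s = 7680 samples per channel).  The pipeline is: zero-phase Butterworth
bandpass 0.5-45 Hz -> per-channel power spectral density (Welch by default)
-> per-band peak features.  For each channel and each of the five canonical
bands (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, low gamma 30-45 Hz)
the features are the frequency of the highest PSD value within the band and
that PSD value itself — the dominant oscillatory activity.  With 32 channels
and 5 bands this flattens to 320 numbers per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidInputError, ShapeError

#: electrode order of the 32-channel DEAP preprocessed release (10-20 labels)
DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "C4",
    "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
)


@dataclass(frozen=True)
class BandSpec:
    """One named frequency band, [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise InvalidInputError(
                f"BandSpec {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )


#: the five canonical EEG bands tiling [0.5, 45] Hz
DEFAULT_BANDS = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),  # "low" gamma
)


@dataclass
class EEGTrial:
    """One trial: (n_channels, n_samples) at ``sample_rate`` Hz."""

    data: np.ndarray
    sample_rate: float = 128.0
    channel_names: tuple = DEAP_CHANNELS
    trial_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError(
                f"EEGTrial '{self.trial_id}': data must be (n_channels, n_samples), "
                f"got shape {self.data.shape}"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ShapeError(
                f"EEGTrial '{self.trial_id}': {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError(f"EEGTrial '{self.trial_id}': non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise InvalidInputError(
                f"EEGTrial '{self.trial_id}': no channel named {name!r}"
            ) from None


@dataclass
class PSDSpectrum:
    """Per-channel power spectral density on a shared frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs), power per Hz
    channel_names: tuple = ()

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2 or self.power.shape[1] != self.freqs.size:
            raise ShapeError(
                f"PSDSpectrum: power {self.power.shape} does not match "
                f"{self.freqs.size} frequencies"
            )
        if np.any(self.power < -1e-12):
            raise InvalidInputError("PSDSpectrum: power must be non-negative")
        self.power = np.maximum(self.power, 0.0)

    def band_slice(self, band: BandSpec) -> np.ndarray:
        """Boolean mask of grid points inside [lo, hi]."""
        return (self.freqs >= band.lo) & (self.freqs <= band.hi)

    def to_frame(self) -> pd.DataFrame:
        """Channels x frequencies matrix with a frequency header row."""
        names = self.channel_names or tuple(
            f"ch{i}" for i in range(self.power.shape[0])
        )
        return pd.DataFrame(
            self.power, index=list(names),
            columns=[f"{f:g}Hz" for f in self.freqs],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="channel")


@dataclass
class BandPeakFeatures:
    """(n_channels, n_bands, 2) array; last axis = (peak_freq Hz, peak_power)."""

    values: np.ndarray
    channel_names: tuple
    band_names: tuple
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ShapeError(
                f"BandPeakFeatures: expected (n_channels, n_bands, 2), "
                f"got {self.values.shape}"
            )

    def flatten(self) -> np.ndarray:
        """Channel-major flattened vector of length n_channels * n_bands * 2."""
        return self.values.ravel()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channel_names):
            for bi, band in enumerate(self.band_names):
                rows.append(
                    {
                        "subject_id": self.subject_id,
                        "trial_id": self.trial_id,
                        "channel": ch,
                        "band": band,
                        "peak_freq": self.values[ci, bi, 0],
                        "peak_power": self.values[ci, bi, 1],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def bandpass_filter(
    trial: EEGTrial, lo: float = 0.5, hi: float = 45.0, order: int = 4
) -> EEGTrial:
    """Zero-phase Butterworth bandpass; shape and metadata preserved.

    Applied forward-backward (``sosfiltfilt``) so the passband is phase-neutral.
    """
    nyq = trial.sample_rate / 2.0
    if not 0 < lo < hi:
        raise InvalidInputError(f"bandpass_filter: need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise InvalidInputError(
            f"bandpass_filter: upper edge {hi} Hz must lie below the Nyquist "
            f"frequency {nyq} Hz"
        )
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=trial.sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trial.data, axis=1)
    return EEGTrial(
        filtered, trial.sample_rate, trial.channel_names, trial.trial_id, trial.subject_id
    )


def compute_psd(
    trial: EEGTrial,
    mode: str = "welch",
    nperseg: int = 256,
    overlap: float = 0.5,
) -> PSDSpectrum:
    """Per-channel PSD via FFT.

    ``welch`` (default) averages Hann-tapered 256-sample (2 s at 128 Hz)
    segments with 50% overlap, trading frequency resolution for variance so
    band peaks are stable; ``periodogram`` uses the full-length FFT.
    """
    if mode == "welch":
        if trial.n_samples < nperseg:
            raise InvalidInputError(
                f"compute_psd: trial has {trial.n_samples} samples but one Welch "
                f"segment needs {nperseg}"
            )
        freqs, power = sps.welch(
            trial.data,
            fs=trial.sample_rate,
            window="hann",
            nperseg=nperseg,
            noverlap=int(nperseg * overlap),
            axis=1,
        )
    elif mode == "periodogram":
        if trial.n_samples < 2:
            raise InvalidInputError("compute_psd: trial too short for a periodogram")
        freqs, power = sps.periodogram(trial.data, fs=trial.sample_rate, axis=1)
    else:
        raise InvalidInputError(f"compute_psd: unknown mode {mode!r}")
    return PSDSpectrum(freqs, power, trial.channel_names)


def band_peak_features(
    psd: PSDSpectrum, bands=DEFAULT_BANDS, subject_id: str = "", trial_id: str = ""
) -> BandPeakFeatures:
    """Per channel x band: (argmax frequency, max power) within the band.

    Ties break toward the lower frequency.  A band with no grid point raises.
    """
    n_ch = psd.power.shape[0]
    out = np.empty((n_ch, len(bands), 2))
    for bi, band in enumerate(bands):
        mask = psd.band_slice(band)
        if not mask.any():
            raise InvalidInputError(
                f"band_peak_features: band {band.name!r} [{band.lo}, {band.hi}] Hz "
                f"contains no frequency-grid point"
            )
        sub_f = psd.freqs[mask]
        sub_p = psd.power[:, mask]
        idx = np.argmax(sub_p, axis=1)  # first max = lowest frequency on ties
        out[:, bi, 0] = sub_f[idx]
        out[:, bi, 1] = sub_p[np.arange(n_ch), idx]
    names = psd.channel_names or tuple(f"ch{i}" for i in range(n_ch))
    return BandPeakFeatures(out, names, tuple(b.name for b in bands), subject_id, trial_id)


def band_power_summary(trial: EEGTrial, lo: float = 0.5, hi: float = 45.0) -> np.ndarray:
    """Total band-limited power per channel (the default per-trial summary)."""
    psd = compute_psd(trial)
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    df = np.diff(psd.freqs).mean() if psd.freqs.size > 1 else 1.0
    return psd.power[:, mask].sum(axis=1) * df


@dataclass
class ChannelCorrelation:
    """Pairwise Pearson correlation of per-trial channel summaries."""

    matrix: np.ndarray
    channels: tuple
    degenerate: tuple = field(default=())  # zero-variance channels, flagged not NaN

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.channels), columns=list(self.channels))


def channel_correlation(trials, channels, summary=band_power_summary) -> ChannelCorrelation:
    """Pearson correlation between channels across trials.

    Each trial is reduced to one number per requested channel (default: total
    0.5-45 Hz band power); the correlation is computed across trials.  The
    matrix is symmetric with unit diagonal.  A channel whose summary has zero
    variance is flagged in ``degenerate`` and its off-diagonal entries set to 0
    instead of propagating NaN.
    """
    trials = list(trials)
    if len(channels) < 2:
        raise InvalidInputError("channel_correlation: need at least 2 channels")
    if len(trials) < 2:
        raise InvalidInputError("channel_correlation: need at least 2 trials")
    idx = [trials[0].channel_index(c) for c in channels]
    table = np.stack([summary(t)[idx] for t in trials])  # (n_trials, n_channels)
    sd = table.std(axis=0)
    degenerate = tuple(c for c, s in zip(channels, sd) if s == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(table, rowvar=False)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ChannelCorrelation(r, tuple(channels), degenerate)
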