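"""DEAP-shaped synthetic multimodal datasets with planted emotion signal.

The generator emulates the layout of the DEAP preprocessed release — 32
subjects x 40 one-minute trials, 32-channel EEG at 128 Hz (7680 samples),
one paired mono audio track per trial, and (valence, arousal) ratings on a
1-9 scale — with a *known* generative link between signal properties and
labels so that every downstream module can be tested without the
registration-gated download:

* latent valence and arousal are drawn uniformly on [1, 9] per trial;
* the audio track is a harmonic complex (random fundamental near 220 Hz)
  whose harmonic decay flattens as valence grows, so the spectral-centroid
  level increases monotonically with valence, plus a little broadband noise;
* each EEG channel is a sum of five band-limited oscillations (one random
  frequency inside each canonical band, random phase) over 1/f background
  noise; on the designated signal channels the beta amplitude rises and the
  alpha amplitude falls with arousal, so the beta/alpha power ratio increases
  monotonically with arousal.  Off-signal channels carry no label
  information.  Valence lives (almost) exclusively in audio and arousal
  exclusively in EEG, which gives the EEG-off ablation a guaranteed
  direction;
* recorded labels are the latents plus Gaussian rating noise, clipped to
  [1, 9].

Datasets are lazy sequences: every trial is synthesised on demand from seed
streams spawned per (subject, trial), so items are bit-identical across
instances with the same config and independent of access order, and the
default 1280-trial dataset never needs ~7 GB of audio in memory at once.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .audio import AudioTrack
from .eeg import DEAP_CHANNELS, EEGTrial
from .errors import FormatError, InvalidInputError

#: per-band synthesis ranges (Hz) and baseline amplitudes (1/f-like profile)
_BAND_FREQ_RANGES = (
    (1.0, 3.5),    # delta
    (4.5, 7.5),    # theta
    (8.5, 12.5),   # alpha
    (14.0, 28.0),  # beta
    (31.0, 44.0),  # gamma
)
_BAND_BASE_AMPS = np.array([2.0, 1.2, 1.0, 0.8, 0.4])
_ALPHA_IDX, _BETA_IDX = 2, 3

#: DEAP preprocessed release constants
DEAP_BASELINE_SECONDS = 3.0
DEAP_TOTAL_ROWS = 40  # 32 EEG + 8 peripheral channels


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_subjects: int = 32
    n_trials: int = 40              # per subject
    trial_seconds: float = 60.0
    eeg_rate: float = 128.0
    n_channels: int = 32
    audio_rate: int = 22050
    seed: int = 0
    valence_link: float = 1.0       # audio brightness <- valence coupling
    arousal_link: float = 1.0       # EEG beta/alpha ratio <- arousal coupling
    noise_sd: float = 0.25          # rating noise, 1-9 scale units
    signal_channels: tuple = ("Fp1", "Fp2", "P3", "P4")

    def __post_init__(self):
        self.signal_channels = tuple(self.signal_channels)
        if min(self.n_subjects, self.n_trials, self.n_channels) < 1:
            raise InvalidInputError("SyntheticConfig: counts must be positive")
        if self.trial_seconds <= 0 or self.eeg_rate <= 0 or self.audio_rate <= 0:
            raise InvalidInputError("SyntheticConfig: durations/rates must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("SyntheticConfig: noise_sd must be >= 0")
        names = DEAP_CHANNELS[: self.n_channels]
        unknown = set(self.signal_channels) - set(names)
        if unknown:
            raise InvalidInputError(
                f"SyntheticConfig: signal channels {sorted(unknown)} not among the "
                f"first {self.n_channels} electrode labels"
            )

    @property
    def channel_names(self) -> tuple:
        return DEAP_CHANNELS[: self.n_channels]

    @property
    def n_examples(self) -> int:
        return self.n_subjects * self.n_trials

    @property
    def eeg_samples(self) -> int:
        return int(round(self.trial_seconds * self.eeg_rate))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialExample:
    """One training record: paired audio + EEG with its ratings."""

    audio: AudioTrack
    eeg: EEGTrial
    valence: float
    arousal: float
    subject_id: str = ""
    trial_id: str = ""
    latent_valence: float = float("nan")
    latent_arousal: float = float("nan")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float = 1.0) -> np.ndarray:
    """Gaussian 1/f^exponent noise of length n, unit RMS."""
    n_freq = n // 2 + 1
    coeffs = rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    f = np.arange(n_freq, dtype=np.float64)
    f[0] = 1.0
    coeffs *= f ** (-exponent / 2.0)
    coeffs[0] = 0.0
    x = np.fft.irfft(coeffs, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _synth_audio(rng: np.random.Generator, cfg: SyntheticConfig, valence: float) -> np.ndarray:
    """Harmonic complex + filtered noise whose brightness grows with valence.

    Synthesised in the frequency domain (one inverse FFT): twelve harmonics of
    a random fundamental near 220 Hz whose amplitude decay flattens as valence
    rises, a faint 1/f background, and a 2-8 kHz noise band whose level scales
    with valence.  Both the harmonic tilt and the high band push the
    spectral-centroid level up monotonically with valence.
    """
    n = int(round(cfg.trial_seconds * cfg.audio_rate))
    f0 = rng.uniform(190.0, 260.0)
    g = np.clip(cfg.valence_link * (valence - 1.0) / 8.0, 0.0, 1.0)
    slope = 2.4 - 2.0 * g  # harmonic amplitude decay rate; flatter = brighter
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.audio_rate)
    n_freq = freqs.size
    # background: 1/f floor everywhere + valence-scaled 2-8 kHz band
    env = 1.5e-4 / (1.0 + freqs / 300.0)
    hf = (freqs >= 2000.0) & (freqs <= 8000.0)
    env[hf] += 4.2e-4 * (0.05 + 0.95 * g)
    noise = rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    coeff = (n / 2.0) * env * noise / np.sqrt(2.0)
    coeff[0] = 0.0
    # harmonic lines at the nearest grid frequencies, random phases; amplitudes
    # sum to 1 so total harmonic mass is valence-independent and only the
    # tilt (and the high band) moves the centroid
    phases = rng.uniform(0, 2 * np.pi, 12)
    amps = np.exp(-slope * np.arange(12))
    amps /= amps.sum()
    df = cfg.audio_rate / n
    for h in range(1, 13):
        fh = h * f0
        if fh >= 0.45 * cfg.audio_rate:
            break
        k = int(round(fh / df))
        if 0 < k < n_freq:
            coeff[k] += (n / 2.0) * amps[h - 1] * np.exp(1j * phases[h - 1])
    x = np.fft.irfft(coeff, n)
    peak = np.abs(x).max()
    if peak > 0:
        x *= 0.9 / peak
    return x


def _synth_eeg(rng: np.random.Generator, cfg: SyntheticConfig, arousal: float) -> np.ndarray:
    """(n_channels, n_samples) band-limited oscillations + 1/f background."""
    n = cfg.eeg_samples
    n_ch = cfg.n_channels
    t = np.arange(n) / cfg.eeg_rate
    n_bands = len(_BAND_FREQ_RANGES)
    lo = np.array([r[0] for r in _BAND_FREQ_RANGES])
    hi = np.array([r[1] for r in _BAND_FREQ_RANGES])
    freqs = rng.uniform(lo, hi, size=(n_ch, n_bands))
    phases = rng.uniform(0, 2 * np.pi, size=(n_ch, n_bands))
    amps = _BAND_BASE_AMPS * np.exp(rng.normal(0.0, 0.15, size=(n_ch, n_bands)))
    g = np.clip(cfg.arousal_link * (arousal - 1.0) / 8.0, 0.0, None)
    sig_idx = [cfg.channel_names.index(c) for c in cfg.signal_channels]
    amps[sig_idx, _BETA_IDX] *= np.exp(0.9 * (g - 0.5))
    amps[sig_idx, _ALPHA_IDX] *= np.exp(-0.9 * (g - 0.5))
    x = np.einsum(
        "cb,cbt->ct",
        amps,
        np.sin(2 * np.pi * freqs[:, :, None] * t[None, None, :] + phases[:, :, None]),
        optimize=True,
    )
    for c in range(n_ch):
        x[c] += 0.3 * _pink_noise(rng, n)
    return x


class SyntheticDataset(Sequence):
    """Lazy, index-deterministic sequence of TrialExample."""

    def __init__(self, config: SyntheticConfig):
        self.config = config

    def __len__(self) -> int:
        return self.config.n_examples

    def _streams(self, index: int):
        subject, trial = divmod(index, self.config.n_trials)
        ss = np.random.SeedSequence(entropy=(self.config.seed, subject, trial))
        label_ss, audio_ss, eeg_ss = ss.spawn(3)
        return subject, trial, label_ss, audio_ss, eeg_ss

    def _labels(self, index: int):
        """(latent_v, latent_a, rated_v, rated_a) without synthesising signals."""
        _, _, label_ss, _, _ = self._streams(index)
        rng = np.random.default_rng(label_ss)
        v, a = rng.uniform(1.0, 9.0, 2)
        noise = rng.normal(0.0, 1.0, 2) * self.config.noise_sd
        rv, ra = np.clip([v + noise[0], a + noise[1]], 1.0, 9.0)
        return float(v), float(a), float(rv), float(ra)

    def labels_array(self) -> np.ndarray:
        """(n, 2) rated (valence, arousal) for the whole dataset (fast path)."""
        return np.array([self._labels(i)[2:] for i in range(len(self))])

    def eeg_only(self, index: int) -> EEGTrial:
        """Synthesise just the EEG of one trial (fast path for EEG tests)."""
        cfg = self.config
        subject, trial, _, _, eeg_ss = self._streams(index)
        _, a, _, _ = self._labels(index)
        data = _synth_eeg(np.random.default_rng(eeg_ss), cfg, a)
        return EEGTrial(
            data, cfg.eeg_rate, cfg.channel_names,
            trial_id=f"s{subject + 1:02d}_t{trial + 1:02d}",
            subject_id=f"s{subject + 1:02d}",
        )

    def audio_only(self, index: int) -> AudioTrack:
        """Synthesise just the audio of one trial (fast path for audio tests)."""
        cfg = self.config
        subject, trial, _, audio_ss, _ = self._streams(index)
        v, _, _, _ = self._labels(index)
        samples = _synth_audio(np.random.default_rng(audio_ss), cfg, v)
        return AudioTrack(samples, cfg.audio_rate, f"s{subject + 1:02d}_t{trial + 1:02d}")

    def latents_array(self) -> np.ndarray:
        """(n, 2) latent (valence, arousal) before rating noise."""
        return np.array([self._labels(i)[:2] for i in range(len(self))])

    def __getitem__(self, index: int) -> TrialExample:
        n = len(self)
        if index < 0:
            index += n
        if not 0 <= index < n:
            raise IndexError(index)
        v, a, rv, ra = self._labels(index)
        audio = self.audio_only(index)
        eeg = self.eeg_only(index)
        return TrialExample(
            audio=audio,
            eeg=eeg,
            valence=rv,
            arousal=ra,
            subject_id=eeg.subject_id,
            trial_id=eeg.trial_id,
            latent_valence=v,
            latent_arousal=a,
        )

    def trial_ids(self) -> list:
        cfg = self.config
        return [
            f"s{s + 1:02d}_t{t + 1:02d}"
            for s in range(cfg.n_subjects)
            for t in range(cfg.n_trials)
        ]


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Build the lazy synthetic dataset for ``config`` (defaults = DEAP shape)."""
    return SyntheticDataset(config or SyntheticConfig())


def generate_deap_format_fixture(config: SyntheticConfig, out_dir) -> list:
    """Write per-subject files in the DEAP preprocessed layout.

    Each subject file is a pickled dict with 'data' of shape
    (n_trials, 40, (3 s + trial) * rate) — the first ``n_channels`` rows are
    the generated EEG with a 3 s synthetic baseline prefix, remaining rows are
    white-noise placeholder peripheral channels — and 'labels' of shape
    (n_trials, 4) = (valence, arousal, dominance, liking).  Returns the list
    of written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create fixture directory {out_dir}: {exc}") from exc
    ds = SyntheticDataset(config)
    baseline_n = int(round(DEAP_BASELINE_SECONDS * config.eeg_rate))
    total_n = baseline_n + config.eeg_samples
    paths = []
    for s in range(config.n_subjects):
        data = np.empty((config.n_trials, DEAP_TOTAL_ROWS, total_n))
        labels = np.empty((config.n_trials, 4))
        side_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(config.seed, s, 10**6))
        )
        for t in range(config.n_trials):
            i = s * config.n_trials + t
            ex_eeg = ds.eeg_only(i)
            _, _, rv, ra = ds._labels(i)
            nc = config.n_channels
            data[t, :nc, :baseline_n] = 0.3 * side_rng.standard_normal((nc, baseline_n))
            data[t, :nc, baseline_n:] = ex_eeg.data
            data[t, nc:, :] = side_rng.standard_normal((DEAP_TOTAL_ROWS - nc, total_n))
            labels[t] = (rv, ra, *side_rng.uniform(1.0, 9.0, 2))
        path = out_dir / f"s{s + 1:02d}.dat"
        try:
            with open(path, "wb") as fh:
                pickle.dump({"data": data, "labels": labels}, fh, protocol=2)
        except OSError as exc:
            raise FormatError(f"cannot write fixture file {path}: {exc}") from exc
        paths.append(path)
    return paths
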