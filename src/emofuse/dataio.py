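"""File formats and run configuration.

Reads WAV audio (PCM 16/24/32-bit and float), the DEAP preprocessed release
layout (one pickled dict per subject: 'data' (40 trials x 40 rows x 8064
samples, 32 EEG rows + 8 peripheral, 3 s baseline + 60 s trial at 128 Hz)
and 'labels' (40 x 4)), and YAML run configurations with strict
unknown-key rejection.
"""

from __future__ import annotations

import dataclasses
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .audio import AudioTrack
from .eeg import DEAP_CHANNELS, EEGTrial
from .errors import FormatError, InvalidInputError
from .model import FusionModelConfig
from .synth import DEAP_BASELINE_SECONDS, SyntheticConfig
from .train import TrainParams

_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): 2**7}


def read_wav(path) -> AudioTrack:
    """Read a WAV file as a mono AudioTrack at its native rate.

    Integer PCM is scaled to [-1, 1]; stereo/multichannel audio is averaged
    across channels.  Resampling is the caller's explicit step.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype in _INT_SCALE:
        offset = 128 if data.dtype == np.uint8 else 0
        data = (data.astype(np.float64) - offset) / _INT_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample encoding {data.dtype} in {path}")
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioTrack(data, int(rate), track_id=path.stem)


def write_wav(path, track: AudioTrack) -> None:
    """Write a track as 32-bit float WAV."""
    wavfile.write(path, track.sample_rate, track.samples.astype(np.float32))


def read_deap_subject(path, eeg_rate: float = 128.0, n_eeg_channels: int = 32):
    """Read one DEAP-preprocessed-release subject file.

    Returns a list of ``(EEGTrial, (valence, arousal))`` pairs: the first 32
    rows per trial with the 3 s baseline prefix removed (7680 samples at
    128 Hz) and the first two label columns.  Fails closed on truncated or
    malformed files.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
    except (OSError, pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise FormatError(f"cannot parse DEAP subject file {path}: {exc}") from exc
    if not isinstance(payload, dict) or not {"data", "labels"} <= set(payload):
        raise FormatError(
            f"DEAP subject file {path} must be a dict with keys 'data' and 'labels'"
        )
    data = np.asarray(payload["data"])
    labels = np.asarray(payload["labels"])
    if data.ndim != 3:
        raise FormatError(
            f"DEAP 'data' must be (n_trials, n_rows, n_samples), got shape {data.shape}"
        )
    if labels.ndim != 2 or labels.shape[0] != data.shape[0] or labels.shape[1] < 2:
        raise FormatError(
            f"DEAP 'labels' must be (n_trials, >=2), got shape {labels.shape} "
            f"for {data.shape[0]} trials"
        )
    if data.shape[1] < n_eeg_channels:
        raise FormatError(
            f"DEAP 'data' has {data.shape[1]} rows; expected at least "
            f"{n_eeg_channels} EEG channels"
        )
    baseline_n = int(round(DEAP_BASELINE_SECONDS * eeg_rate))
    if data.shape[2] <= baseline_n:
        raise FormatError(
            f"DEAP 'data' trials have {data.shape[2]} samples, not longer than "
            f"the {baseline_n}-sample baseline prefix"
        )
    subject_id = path.stem
    out = []
    names = DEAP_CHANNELS[:n_eeg_channels]
    for t in range(data.shape[0]):
        trial = EEGTrial(
            data[t, :n_eeg_channels, baseline_n:],
            sample_rate=eeg_rate,
            channel_names=names,
            trial_id=f"{subject_id}_t{t + 1:02d}",
            subject_id=subject_id,
        )
        out.append((trial, (float(labels[t, 0]), float(labels[t, 1]))))
    return out


# ---------------------------------------------------------------------------
# Native dataset layout: one WAV + one compressed array container per trial,
# plus a labels.csv manifest
# ---------------------------------------------------------------------------


def write_native_dataset(dataset, out_dir) -> Path:
    """Write trials as ``<id>.wav`` + ``<id>_eeg.npz`` with a labels manifest."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(dataset)):
        ex = dataset[i]
        tid = ex.trial_id or f"trial{i:04d}"
        wav_name, eeg_name = f"{tid}.wav", f"{tid}_eeg.npz"
        write_wav(out_dir / wav_name, ex.audio)
        np.savez_compressed(
            out_dir / eeg_name,
            data=ex.eeg.data,
            sample_rate=ex.eeg.sample_rate,
            channel_names=np.array(ex.eeg.channel_names),
        )
        rows.append(
            {
                "trial_id": tid,
                "subject_id": ex.subject_id,
                "valence": ex.valence,
                "arousal": ex.arousal,
                "audio_file": wav_name,
                "eeg_file": eeg_name,
            }
        )
    manifest = out_dir / "labels.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_eeg_container(path) -> EEGTrial:
    """Read one ``*_eeg.npz`` trial container."""
    path = Path(path)
    try:
        with np.load(path) as z:
            return EEGTrial(
                z["data"],
                float(z["sample_rate"]),
                tuple(str(c) for c in z["channel_names"]),
                trial_id=path.stem.removesuffix("_eeg"),
            )
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"cannot read EEG container {path}: {exc}") from exc


def load_native_dataset(data_dir) -> list:
    """Load a native-layout directory back into TrialExample records."""
    import pandas as pd

    from .synth import TrialExample

    data_dir = Path(data_dir)
    manifest = data_dir / "labels.csv"
    if not manifest.exists():
        raise FormatError(f"no labels.csv manifest in {data_dir}")
    table = pd.read_csv(manifest)
    required = {"trial_id", "subject_id", "valence", "arousal", "audio_file", "eeg_file"}
    if not required <= set(table.columns):
        raise FormatError(
            f"labels.csv is missing columns {sorted(required - set(table.columns))}"
        )
    out = []
    for row in table.itertuples(index=False):
        audio = read_wav(data_dir / row.audio_file)
        audio.track_id = str(row.trial_id)
        eeg = read_eeg_container(data_dir / row.eeg_file)
        eeg.trial_id = str(row.trial_id)
        eeg.subject_id = str(row.subject_id)
        out.append(
            TrialExample(
                audio=audio,
                eeg=eeg,
                valence=float(row.valence),
                arousal=float(row.arousal),
                subject_id=str(row.subject_id),
                trial_id=str(row.trial_id),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one run needs; snapshot-serialised into each run directory."""

    data_dir: str = "data"
    out_dir: str = "runs"
    seed: int = 0
    psd_mode: str = "welch"
    attribution_method: str = "gradient_x_input"
    model: FusionModelConfig = field(default_factory=FusionModelConfig)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    training: TrainParams = field(default_factory=TrainParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"]["mlp_hidden"] = list(self.model.mlp_hidden)
        d["synth"]["signal_channels"] = list(self.synth.signal_channels)
        return d


def _build_section(cls, raw: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(
            f"config section '{section}': unknown keys {sorted(unknown)}"
        )
    return cls(**raw)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"config: unknown top-level keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in (("model", FusionModelConfig), ("synth", SyntheticConfig),
                      ("training", TrainParams)):
        if name in raw:
            section = raw.pop(name) or {}
            kwargs[name] = _build_section(cls, section, name)
    kwargs.update(raw)
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
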