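"""Three-branch fusion regressor for valence/arousal prediction.

The model sums the outputs of three branches, each ending in 2 neurons:

* an MLP (d -> 1000 -> 1000 -> 2) on the tabular feature vector (flattened
  per-window timbre descriptors, optionally concatenated with the per-channel
  EEG band-peak features);
* a compact CNN on the raw mono audio waveform (1 input channel);
* the same CNN architecture on the per-channel EEG power spectral density
  matrix (32 input channels over the frequency axis).

Each CNN has three blocks: conv(8 filters, k=9) -> depthwise conv(x2 -> 16
channels, k=32) -> ELU -> average pool(4) -> dropout(0.5); depthwise
conv(16, k=26) -> pointwise conv -> ELU; flatten -> dense(200) -> dense(2).
The "16 depthwise filters" after an 8-channel layer are realised as a depth
multiplier of 2.  Predicted valence and arousal are the elementwise sum of
the branch outputs, nominally on the 1-9 rating scale.

The audio-only ablation variant drops the EEG CNN branch and the EEG part of
the MLP input entirely, so its forward pass never touches EEG data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import InvalidInputError, ShapeError

N_TIMBRE_FEATURES = 5
DEFAULT_N_WINDOWS = 118
DEFAULT_EEG_CHANNELS = 32
DEFAULT_N_BANDS = 5


@dataclass
class CNNBlock1:
    conv_filters: int = 8
    conv_kernel: int = 9
    dw_filters: int = 16
    dw_kernel: int = 32
    pool_factor: int = 4
    dropout: float = 0.5


@dataclass
class CNNBlock2:
    dw_filters: int = 16
    dw_kernel: int = 26
    pointwise: bool = True


@dataclass
class FusionModelConfig:
    """Every architectural hyperparameter of the fusion regressor.

    ``mlp_input_dim=None`` means "compute from the feature composition"
    (n_windows*5 timbre values plus, when the MLP consumes EEG features,
    channels*bands*2 band-peak values — 590 + 320 = 910 at the default
    layout).  An explicit integer overrides the computation.
    """

    mlp_input_dim: int | None = None
    mlp_hidden: tuple = (1000, 1000)
    cnn_block1: CNNBlock1 = field(default_factory=CNNBlock1)
    cnn_block2: CNNBlock2 = field(default_factory=CNNBlock2)
    fc_intermediate: int = 200
    output_dim: int = 2
    audio_branch_rate: float = 250.0
    eeg_channels: int = DEFAULT_EEG_CHANNELS
    n_bands: int = DEFAULT_N_BANDS
    n_windows: int = DEFAULT_N_WINDOWS
    mlp_uses_eeg_features: bool = True
    clip_outputs: bool = False

    def __post_init__(self):
        if isinstance(self.cnn_block1, dict):
            self.cnn_block1 = CNNBlock1(**self.cnn_block1)
        if isinstance(self.cnn_block2, dict):
            self.cnn_block2 = CNNBlock2(**self.cnn_block2)
        self.mlp_hidden = tuple(self.mlp_hidden)
        self.validate()

    def validate(self) -> None:
        b1, b2 = self.cnn_block1, self.cnn_block2
        if self.output_dim != 2:
            raise InvalidInputError("FusionModelConfig: output_dim must be 2")
        for label, v in (
            ("conv_filters", b1.conv_filters), ("conv_kernel", b1.conv_kernel),
            ("dw_filters", b1.dw_filters), ("dw_kernel", b1.dw_kernel),
            ("pool_factor", b1.pool_factor), ("block2 dw_filters", b2.dw_filters),
            ("block2 dw_kernel", b2.dw_kernel), ("fc_intermediate", self.fc_intermediate),
        ):
            if v < 1:
                raise InvalidInputError(f"FusionModelConfig: {label} must be positive, got {v}")
        if not 0 <= b1.dropout < 1:
            raise InvalidInputError(f"FusionModelConfig: dropout must be in [0,1), got {b1.dropout}")
        if b1.dw_filters % b1.conv_filters != 0:
            raise InvalidInputError(
                "FusionModelConfig: block-1 depthwise filters must be a multiple "
                f"of conv filters ({b1.dw_filters} vs {b1.conv_filters})"
            )
        if b2.dw_filters != b1.dw_filters:
            raise InvalidInputError(
                "FusionModelConfig: block-2 depthwise width must match block-1 output"
            )

    def audio_feature_dim(self) -> int:
        return self.n_windows * N_TIMBRE_FEATURES

    def eeg_feature_dim(self) -> int:
        return self.eeg_channels * self.n_bands * 2

    def resolved_mlp_input_dim(self, with_eeg: bool = True) -> int:
        if self.mlp_input_dim is not None:
            return self.mlp_input_dim
        dim = self.audio_feature_dim()
        if with_eeg and self.mlp_uses_eeg_features:
            dim += self.eeg_feature_dim()
        return dim

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PredictionPair:
    """One (valence, arousal) prediction on the nominal 1-9 scale."""

    valence: float
    arousal: float

    def __post_init__(self):
        if not (np.isfinite(self.valence) and np.isfinite(self.arousal)):
            raise InvalidInputError("PredictionPair: values must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.valence, self.arousal])


def cnn_min_length(config: FusionModelConfig) -> int:
    """Shortest input length the CNN branch accepts (largest kernel / pooling)."""
    b1 = config.cnn_block1
    return max(b1.dw_kernel, b1.conv_kernel, b1.pool_factor, config.cnn_block2.dw_kernel)


def build_cnn_branch(
    config: FusionModelConfig,
    in_channels: int,
    in_length: int,
    rng: np.random.Generator,
    dtype=np.float32,
) -> nn.Sequential:
    """The compact three-block CNN mapping (in_channels, in_length) -> 2 reals."""
    if in_length < cnn_min_length(config):
        raise InvalidInputError(
            f"build_cnn_branch: input length {in_length} is too short; the "
            f"architecture needs at least {cnn_min_length(config)} samples"
        )
    b1, b2 = config.cnn_block1, config.cnn_block2
    mult = b1.dw_filters // b1.conv_filters
    pooled = nn.AvgPool1d.out_len(in_length, b1.pool_factor)
    flat = b2.dw_filters * pooled
    return nn.Sequential([
        nn.Conv1d(in_channels, b1.conv_filters, b1.conv_kernel, rng, dtype),
        nn.DepthwiseConv1d(b1.conv_filters, mult, b1.dw_kernel, rng, dtype),
        nn.ELU(),
        nn.AvgPool1d(b1.pool_factor),
        nn.Dropout(b1.dropout),
        nn.DepthwiseConv1d(b1.dw_filters, 1, b2.dw_kernel, rng, dtype),
        nn.Conv1d(b2.dw_filters, b2.dw_filters, 1, rng, dtype),  # pointwise
        nn.ELU(),
        nn.Flatten(),
        nn.Dense(flat, config.fc_intermediate, rng, dtype),
        nn.Dense(config.fc_intermediate, config.output_dim, rng, dtype),
    ])


def build_mlp_branch(
    config: FusionModelConfig,
    rng: np.random.Generator,
    input_dim: int | None = None,
    dtype=np.float32,
) -> nn.Sequential:
    """The tabular branch: dense(d->1000) -> ELU -> dense(1000->1000) -> ELU -> dense(1000->2)."""
    d = input_dim if input_dim is not None else config.resolved_mlp_input_dim()
    if d < 1:
        raise InvalidInputError(f"build_mlp_branch: input dim must be >= 1, got {d}")
    h1, h2 = config.mlp_hidden
    return nn.Sequential([
        nn.Dense(d, h1, rng, dtype),
        nn.ELU(),
        nn.Dense(h1, h2, rng, dtype),
        nn.ELU(),
        nn.Dense(h2, config.output_dim, rng, dtype),
    ])


def fuse(mlp_out, cnn_audio_out, cnn_eeg_out, clip: bool = False) -> PredictionPair:
    """Elementwise sum of the three branch outputs -> (valence, arousal).

    ``cnn_eeg_out`` may be None (ablation model).  With ``clip`` the sum is
    clamped to the [1, 9] rating scale.
    """
    parts = {"mlp": mlp_out, "cnn_audio": cnn_audio_out, "cnn_eeg": cnn_eeg_out}
    total = np.zeros(2)
    for name, part in parts.items():
        if part is None:
            continue
        arr = np.asarray(part, dtype=np.float64).reshape(-1)
        if arr.size != 2:
            raise ShapeError(f"fuse: branch '{name}' output must have length 2, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"fuse: branch '{name}' produced a non-finite output")
        total += arr
    if clip:
        total = np.clip(total, 1.0, 9.0)
    return PredictionPair(float(total[0]), float(total[1]))


class FusionModel:
    """The trainable multimodal regressor (MLP + audio CNN [+ EEG CNN]).

    Parameters
    ----------
    config : FusionModelConfig
    audio_len : waveform samples fed to the audio CNN branch
    eeg_len : frequency bins fed to the EEG CNN branch (ignored when
        ``with_eeg`` is false)
    seed : initialisation seed; identical seeds give identical weights
    with_eeg : False builds the audio-only ablation variant — no
        EEG-consuming parameters exist and forward never reads EEG input
    """

    def __init__(
        self,
        config: FusionModelConfig,
        audio_len: int,
        eeg_len: int | None = None,
        seed: int = 0,
        with_eeg: bool = True,
        dtype=np.float32,
    ):
        self.config = config
        self.with_eeg = bool(with_eeg)
        self.audio_len = int(audio_len)
        self.eeg_len = int(eeg_len) if eeg_len is not None else None
        self.seed = int(seed)
        self.dtype = dtype
        ss = np.random.SeedSequence(self.seed)
        r_mlp, r_audio, r_eeg = (np.random.default_rng(s) for s in ss.spawn(3))
        self.mlp_input_dim = config.resolved_mlp_input_dim(with_eeg=self.with_eeg)
        self.mlp = build_mlp_branch(config, r_mlp, self.mlp_input_dim, dtype)
        self.audio_cnn = build_cnn_branch(config, 1, self.audio_len, r_audio, dtype)
        if self.with_eeg:
            if self.eeg_len is None:
                raise InvalidInputError("FusionModel: eeg_len required when with_eeg=True")
            self.eeg_cnn = build_cnn_branch(
                config, config.eeg_channels, self.eeg_len, r_eeg, dtype
            )
        else:
            self.eeg_cnn = None
        # CNN output layers start at zero so the fused prediction begins at
        # the feature branch and the convolutional branches fade in as their
        # own output weights grow; stabilises summed fusion heads on small
        # training sets
        for _name, _branch in self.branches():
            if _name != "mlp":
                _branch.layers[-1].W[...] = 0.0

    # -- plumbing -----------------------------------------------------------

    def branches(self):
        out = [("mlp", self.mlp), ("cnn_audio", self.audio_cnn)]
        if self.eeg_cnn is not None:
            out.append(("cnn_eeg", self.eeg_cnn))
        return out

    def modules(self):
        return [m for _, m in self.branches()]

    def n_parameters(self) -> int:
        return sum(m.n_parameters() for m in self.modules())

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for m in self.modules():
            m.set_dropout_rng(rng)

    def state_dict(self) -> dict:
        return {
            f"{bname}/{k}": v
            for bname, m in self.branches()
            for k, v in m.state_dict().items()
        }

    def load_state_dict(self, state: dict) -> None:
        for bname, m in self.branches():
            m.load_state_dict(
                {k.split("/", 1)[1]: v for k, v in state.items() if k.startswith(bname + "/")}
            )

    # -- forward / backward -------------------------------------------------

    def forward(self, feats, audio, eeg_psd=None, train: bool = False) -> np.ndarray:
        """Batched forward pass; returns (batch, 2) raw branch sums.

        ``audio`` is (batch, audio_len) or (batch, 1, audio_len); ``eeg_psd``
        is (batch, eeg_channels, eeg_len) and is ignored by the ablation model.
        """
        feats = np.asarray(feats, dtype=self.dtype)
        audio = np.asarray(audio, dtype=self.dtype)
        if audio.ndim == 2:
            audio = audio[:, None, :]
        out = self.mlp.forward(feats, train=train)
        out = out + self.audio_cnn.forward(audio, train=train)
        if self.eeg_cnn is not None:
            if eeg_psd is None:
                raise InvalidInputError("FusionModel.forward: EEG input required")
            eeg_psd = np.asarray(eeg_psd, dtype=self.dtype)
            out = out + self.eeg_cnn.forward(eeg_psd, train=train)
        if not np.all(np.isfinite(out)):
            raise InvalidInputError("FusionModel.forward: non-finite branch output")
        return out

    def backward(self, dy: np.ndarray) -> None:
        """Distribute the output gradient into every active branch."""
        dy = np.asarray(dy, dtype=self.dtype)
        for _, m in self.branches():
            m.backward(dy)

    def predict(self, feats, audio, eeg_psd=None) -> np.ndarray:
        """Evaluation-mode predictions, clipped to [1, 9] iff configured."""
        out = self.forward(feats, audio, eeg_psd, train=False)
        if self.config.clip_outputs:
            out = np.clip(out, 1.0, 9.0)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": self.config.to_dict(),
            "audio_len": self.audio_len,
            "eeg_len": self.eeg_len,
            "seed": self.seed,
            "with_eeg": self.with_eeg,
        }
        arrays = {k.replace("/", "__"): v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "FusionModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {
                k.replace("__", "/"): data[k] for k in data.files if k != "__meta__"
            }
        cfg = meta["config"]
        cfg["mlp_hidden"] = tuple(cfg["mlp_hidden"])
        model = cls(
            FusionModelConfig(**cfg),
            audio_len=meta["audio_len"],
            eeg_len=meta["eeg_len"],
            seed=meta["seed"],
            with_eeg=meta["with_eeg"],
        )
        model.load_state_dict(state)
        return model


def build_ablation_model(
    config: FusionModelConfig, audio_len: int, seed: int = 0, dtype=np.float32
) -> FusionModel:
    """Audio-only variant: MLP on timbre features + CNN on the waveform.

    No EEG-consuming parameters exist, so replacing the EEG input with
    anything leaves the output bit-for-bit unchanged.
    """
    return FusionModel(config, audio_len, eeg_len=None, seed=seed, with_eeg=False, dtype=dtype)
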