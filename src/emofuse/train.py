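"""Dataset splitting, training with early stopping, metrics, ablation and
channel attribution.

The experiment protocol: trials are split 8:1:1 into train/validation/test;
the network minimises mean absolute error with Adam; the validation set
drives early stopping (the best-validation epoch's weights are returned);
the held-out test set yields MAE, MAPE and R² pooled over valence and
arousal and per target.  The EEG-off ablation retrains an audio-only model
on the identical split and seed, and channel attribution scores each EEG
electrode by mean |gradient x input| over every EEG-derived model input
(with channel occlusion as a cross-check).
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .audio import resample_track, track_features
from .eeg import DEFAULT_BANDS, band_peak_features, bandpass_filter, compute_psd
from .errors import InvalidInputError, TrainingError
from .model import (
    FusionModel,
    FusionModelConfig,
    N_TIMBRE_FEATURES,
    build_ablation_model,
)
from .nn import Adam, Dense

# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test identifier lists (8:1:1 by default)."""

    train_ids: list
    val_ids: list
    test_ids: list
    seed: int

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise InvalidInputError("DatasetSplit: partitions overlap")


def split_dataset(ids, ratios=(8, 1, 1), seed: int = 0) -> DatasetSplit:
    """Randomly partition ids by ``ratios``; remainder goes to train.

    Deterministic given the seed: the same seed always yields the same
    partition.  1280 ids under 8:1:1 give sizes (1024, 128, 128).
    """
    ids = list(ids)
    if len(ids) < len(ratios):
        raise InvalidInputError(
            f"split_dataset: need at least {len(ratios)} ids, got {len(ids)}"
        )
    total = sum(ratios)
    n = len(ids)
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    n_train = n - n_val - n_test
    return DatasetSplit(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train : n_train + n_val],
        test_ids=shuffled[n_train + n_val :],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureLayout:
    """Index map of the composed MLP feature vector."""

    n_windows: int
    n_channels: int
    n_bands: int
    uses_eeg: bool

    @property
    def audio_dim(self) -> int:
        return self.n_windows * N_TIMBRE_FEATURES

    @property
    def eeg_dim(self) -> int:
        return self.n_channels * self.n_bands * 2 if self.uses_eeg else 0

    @property
    def total_dim(self) -> int:
        return self.audio_dim + self.eeg_dim

    def channel_slice(self, channel_index: int) -> slice:
        """Columns of the full feature vector holding one channel's band peaks."""
        if not self.uses_eeg:
            return slice(0, 0)
        w = self.n_bands * 2
        start = self.audio_dim + channel_index * w
        return slice(start, start + w)


@dataclass
class DatasetArrays:
    """Model-ready tensors for a set of trials."""

    ids: list
    feats: np.ndarray          # (n, audio_dim [+ eeg_dim]) tabular features
    audio_wave: np.ndarray     # (n, audio_len) resampled waveform
    eeg_psd: np.ndarray        # (n, n_channels, n_freqs) log-PSD
    y: np.ndarray              # (n, 2) = (valence, arousal)
    layout: FeatureLayout
    channel_names: tuple
    psd_freqs: np.ndarray

    def subset(self, indices) -> "DatasetArrays":
        idx = np.asarray(indices, dtype=int)
        return DatasetArrays(
            ids=[self.ids[i] for i in idx],
            feats=self.feats[idx],
            audio_wave=self.audio_wave[idx],
            eeg_psd=self.eeg_psd[idx],
            y=self.y[idx],
            layout=self.layout,
            channel_names=self.channel_names,
            psd_freqs=self.psd_freqs,
        )

    def __len__(self) -> int:
        return len(self.ids)


def prepare_inputs(
    dataset,
    config: FusionModelConfig,
    bands=DEFAULT_BANDS,
    psd_mode: str = "welch",
    filter_lo: float = 0.5,
    filter_hi: float = 45.0,
) -> DatasetArrays:
    """Run the full feature pipeline over a sequence of TrialExample.

    Per trial: timbre matrix (flattened), EEG bandpass -> PSD -> band-peak
    features (flattened, channel-major) appended when the MLP consumes them,
    the waveform resampled to ``config.audio_branch_rate`` for the audio CNN,
    and log10 PSD restricted to the filter band for the EEG CNN.
    """
    n = len(dataset)
    if n == 0:
        raise InvalidInputError("prepare_inputs: empty dataset")
    feats_list, wave_list, psd_list, y_list, ids = [], [], [], [], []
    psd_freqs = None
    channel_names = None
    rate = int(round(config.audio_branch_rate))
    for i in range(n):
        ex = dataset[i]
        timbre = track_features(ex.audio, analysis_rate=ex.audio.sample_rate)
        filtered = bandpass_filter(ex.eeg, filter_lo, filter_hi)
        psd = compute_psd(filtered, mode=psd_mode)
        peaks = band_peak_features(psd, bands, ex.eeg.subject_id, ex.eeg.trial_id)
        vec = timbre.flatten()
        if config.mlp_uses_eeg_features:
            # PSD peak powers span orders of magnitude; feed the MLP their
            # log so band-power ratios become linear in the features
            pv = peaks.values.copy()
            pv[:, :, 1] = np.log10(pv[:, :, 1] + 1e-12)
            vec = np.concatenate([vec, pv.ravel()])
        feats_list.append(vec)
        wave_list.append(resample_track(ex.audio, rate).samples.astype(np.float32))
        mask = (psd.freqs >= filter_lo) & (psd.freqs <= filter_hi)
        psd_list.append(np.log10(psd.power[:, mask] + 1e-12).astype(np.float32))
        if psd_freqs is None:
            psd_freqs = psd.freqs[mask]
            channel_names = tuple(ex.eeg.channel_names)
        y_list.append([ex.valence, ex.arousal])
        ids.append(ex.trial_id or str(i))
    n_windows = feats_list[0].size
    layout = FeatureLayout(
        n_windows=(n_windows - (len(channel_names) * len(bands) * 2
                                if config.mlp_uses_eeg_features else 0))
        // N_TIMBRE_FEATURES,
        n_channels=len(channel_names),
        n_bands=len(bands),
        uses_eeg=config.mlp_uses_eeg_features,
    )
    return DatasetArrays(
        ids=ids,
        feats=np.stack(feats_list),
        audio_wave=np.stack(wave_list),
        eeg_psd=np.stack(psd_list),
        y=np.asarray(y_list, dtype=np.float64),
        layout=layout,
        channel_names=channel_names,
        psd_freqs=psd_freqs,
    )


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on the training portion only."""

    mean: np.ndarray = None
    std: np.ndarray = None

    def fit(self, x: np.ndarray) -> "Standardizer":
        self.mean = x.mean(axis=0)
        std = x.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.mean) / self.std).astype(np.float32)


def standardize_arrays(train: DatasetArrays, *others):
    """Fit feature and PSD scalers on ``train`` and apply to every set."""
    feat_sc = Standardizer().fit(train.feats)
    psd_sc = Standardizer().fit(train.eeg_psd.reshape(len(train), -1))

    def apply(d: DatasetArrays) -> DatasetArrays:
        out = copy.copy(d)
        out.feats = feat_sc.transform(d.feats)
        out.eeg_psd = psd_sc.transform(d.eeg_psd.reshape(len(d), -1)).reshape(
            d.eeg_psd.shape
        )
        return out

    return tuple(apply(d) for d in (train, *others))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _series_metrics(y: np.ndarray, x: np.ndarray):
    """Standard MAE, MAPE (%), R² of one series of truths y and predictions x."""
    err = y - x
    mae = float(np.mean(np.abs(err)))
    n_zero = int(np.sum(y == 0))
    if n_zero:
        mape = float("nan")
    else:
        mape = float(100.0 * np.mean(np.abs(err / y)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return mae, mape, r2, n_zero


@dataclass
class TargetMetrics:
    mae: float
    mape: float
    r2: float


@dataclass
class MetricsReport:
    """MAE (rating units), MAPE (%), R² — pooled over both targets and per target."""

    mae: float
    mape: float
    r2: float
    per_target: dict = field(default_factory=dict)
    n: int = 0
    n_zero_truth: int = 0  # flagged: labels live in [1,9], zeros mean misuse

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mape": self.mape,
            "r2": self.r2,
            "per_target": {k: vars(v) for k, v in self.per_target.items()},
            "n": self.n,
            "n_zero_truth": self.n_zero_truth,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(predictions, truths) -> MetricsReport:
    """Score predictions against truths.

    Inputs are either 1-D series or (n, 2) pairs ordered (valence, arousal).
    Pooled metrics concatenate the two targets; per-target metrics are
    computed separately for pairs.  Zero truths are flagged (MAPE undefined)
    rather than raising.
    """
    x = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(truths, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidInputError(
            f"evaluate: shape mismatch, predictions {x.shape} vs truths {y.shape}"
        )
    if x.shape[0] < 2:
        raise InvalidInputError("evaluate: need at least 2 prediction/truth pairs")
    per_target = {}
    if y.ndim == 2:
        if y.shape[1] != 2:
            raise InvalidInputError("evaluate: paired input must have 2 columns")
        for j, name in enumerate(("valence", "arousal")):
            m, p, r, _ = _series_metrics(y[:, j], x[:, j])
            per_target[name] = TargetMetrics(m, p, r)
        y_flat, x_flat = y.ravel(), x.ravel()
    else:
        y_flat, x_flat = y, x
    mae, mape, r2, n_zero = _series_metrics(y_flat, x_flat)
    return MetricsReport(
        mae=mae, mape=mape, r2=r2, per_target=per_target,
        n=x.shape[0], n_zero_truth=n_zero,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainParams:
    """Optimisation hyperparameters (none stated by the reference protocol
    beyond the loss and early stopping; values chosen for desk-scale CPU runs)."""

    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 20
    weight_decay: float = 1e-3
    seed: int = 0
    init_output_bias: bool = True  # start each branch at mean(y)/n_branches
    verbose: bool = False


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1  # 0-based index into the history lists
    best_val_loss: float = float("inf")

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _forward_in_batches(model: FusionModel, data: DatasetArrays, batch_size: int):
    outs = []
    for start in range(0, len(data), batch_size):
        sl = slice(start, start + batch_size)
        outs.append(
            model.forward(data.feats[sl], data.audio_wave[sl], data.eeg_psd[sl])
        )
    return np.concatenate(outs, axis=0)


def train(
    model: FusionModel,
    train_data: DatasetArrays,
    val_data: DatasetArrays,
    params: TrainParams | None = None,
) -> TrainingHistory:
    """Fit the model with Adam on MAE loss; early-stop on validation loss.

    Restores and returns the weights of the epoch with the lowest validation
    loss.  Fully reproducible given ``params.seed`` (shuffling and dropout
    both flow from it).  Aborts with diagnostics on a non-finite loss.
    """
    params = params or TrainParams()
    if len(train_data) == 0 or len(val_data) == 0:
        raise InvalidInputError("train: train and validation sets must be non-empty")
    ss = np.random.SeedSequence(params.seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    model.set_dropout_rng(dropout_rng)

    if params.init_output_bias:
        mean_y = train_data.y.mean(axis=0)
        n_branches = len(model.modules())
        for module in model.modules():
            last = module.layers[-1]
            assert isinstance(last, Dense)
            last.b[...] = (mean_y / n_branches).astype(last.b.dtype)

    optimizer = Adam(model.modules(), lr=params.lr, weight_decay=params.weight_decay)
    history = TrainingHistory()
    best_state = None
    n = len(train_data)
    y_train = train_data.y
    no_improve = 0
    for epoch in range(params.max_epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, params.batch_size):
            idx = order[start : start + params.batch_size]
            pred = model.forward(
                train_data.feats[idx],
                train_data.audio_wave[idx],
                train_data.eeg_psd[idx],
                train=True,
            )
            err = pred - y_train[idx]
            loss = float(np.mean(np.abs(err)))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"train: non-finite training loss at epoch {epoch + 1} "
                    f"(lr={params.lr}, batch={params.batch_size})"
                )
            losses.append(loss)
            dy = np.sign(err) / err.size
            model.backward(dy)
            optimizer.step()
        val_pred = _forward_in_batches(model, val_data, params.batch_size)
        val_loss = float(np.mean(np.abs(val_pred - val_data.y)))
        if not np.isfinite(val_loss):
            raise TrainingError(f"train: non-finite validation loss at epoch {epoch + 1}")
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            no_improve = 0
        else:
            no_improve += 1
        if params.verbose:
            print(
                f"epoch {epoch + 1:3d}  train MAE {history.train_loss[-1]:.4f}  "
                f"val MAE {val_loss:.4f}"
            )
        if no_improve >= params.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


# ---------------------------------------------------------------------------
# Experiments: end-to-end run and EEG-off ablation
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    model: FusionModel
    history: TrainingHistory
    report: MetricsReport
    split: DatasetSplit
    test_data: DatasetArrays
    predictions: np.ndarray


def run_experiment(
    data: DatasetArrays,
    config: FusionModelConfig,
    seed: int = 0,
    with_eeg: bool = True,
    params: TrainParams | None = None,
    split: DatasetSplit | None = None,
) -> ExperimentResult:
    """Split, standardise, train and evaluate one model on prepared arrays."""
    params = params or TrainParams(seed=seed)
    # the composed feature dimensions follow the data actually prepared
    # (an explicit mlp_input_dim override is left untouched)
    config = dataclasses.replace(
        config,
        n_windows=data.layout.n_windows,
        eeg_channels=data.layout.n_channels,
        n_bands=data.layout.n_bands,
    )
    if split is None:
        split = split_dataset(data.ids, seed=seed)
    pos = {tid: i for i, tid in enumerate(data.ids)}
    tr = data.subset([pos[t] for t in split.train_ids])
    va = data.subset([pos[t] for t in split.val_ids])
    te = data.subset([pos[t] for t in split.test_ids])
    if not with_eeg:
        # strip the EEG block from the tabular features for the ablation model
        audio_dim = data.layout.audio_dim
        for d in (tr, va, te):
            d.feats = d.feats[:, :audio_dim]
    tr, va, te = standardize_arrays(tr, va, te)
    audio_len = data.audio_wave.shape[1]
    if with_eeg:
        model = FusionModel(
            config, audio_len=audio_len, eeg_len=data.eeg_psd.shape[2], seed=seed
        )
    else:
        model = build_ablation_model(config, audio_len=audio_len, seed=seed)
    history = train(model, tr, va, params)
    preds = _forward_in_batches(model, te, params.batch_size)
    if config.clip_outputs:
        preds = np.clip(preds, 1.0, 9.0)
    report = evaluate(preds, te.y)
    return ExperimentResult(model, history, report, split, te, preds)


@dataclass
class AblationResult:
    full: ExperimentResult
    audio_only: ExperimentResult

    @property
    def delta_r2(self) -> float:
        return self.full.report.r2 - self.audio_only.report.r2

    def summary(self) -> dict:
        return {
            "full": self.full.report.to_dict(),
            "audio_only": self.audio_only.report.to_dict(),
            "delta_r2": self.delta_r2,
            "delta_mae": self.full.report.mae - self.audio_only.report.mae,
        }


def run_ablation(
    data: DatasetArrays,
    config: FusionModelConfig,
    seed: int = 0,
    params: TrainParams | None = None,
) -> AblationResult:
    """Train the full multimodal model and the audio-only ablation on an
    identical split and seed; reproducible given the seed."""
    split = split_dataset(data.ids, seed=seed)
    full = run_experiment(data, config, seed=seed, with_eeg=True, params=params, split=split)
    audio_only = run_experiment(
        data, config, seed=seed, with_eeg=False, params=params, split=split
    )
    return AblationResult(full=full, audio_only=audio_only)


# ---------------------------------------------------------------------------
# Channel attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributionReport:
    """Per-EEG-channel importance scores, descending ranking."""

    channel_scores: dict
    ranking: list
    method: str

    def to_dict(self) -> dict:
        return {
            "channel_scores": self.channel_scores,
            "ranking": self.ranking,
            "method": self.method,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def attribute_channels(
    model: FusionModel,
    data: DatasetArrays,
    method: str = "gradient_x_input",
    batch_size: int = 32,
) -> AttributionReport:
    """Score each EEG channel's contribution to the fused prediction.

    ``gradient_x_input`` (default): mean |d(valence+arousal)/d(input) * input|
    over the evaluation set, summed over the channel's PSD row fed to the EEG
    CNN and, when present, the channel's band-peak columns fed to the MLP.
    ``occlusion``: mean |prediction shift| when the channel's inputs are
    zeroed out.  The audio-only ablation model has no EEG path and raises.
    """
    if model.eeg_cnn is None:
        raise InvalidInputError(
            "attribute_channels: model has no EEG branch (audio-only ablation)"
        )
    channels = data.channel_names
    n_ch = len(channels)
    scores = np.zeros(n_ch)
    n_total = 0
    if method == "gradient_x_input":
        dy_unit = 1.0
        for start in range(0, len(data), batch_size):
            sl = slice(start, start + batch_size)
            psd = np.asarray(data.eeg_psd[sl], dtype=model.dtype)
            feats = np.asarray(data.feats[sl], dtype=model.dtype)
            b = psd.shape[0]
            dy = np.full((b, 2), dy_unit, dtype=model.dtype)
            model.eeg_cnn.forward(psd)
            g_psd = model.eeg_cnn.backward(dy)
            contrib = np.abs(g_psd * psd).sum(axis=2)  # (b, n_ch)
            if model.config.mlp_uses_eeg_features and data.layout.uses_eeg:
                model.mlp.forward(feats)
                g_feat = model.mlp.backward(dy)
                gx = np.abs(g_feat * feats)
                for c in range(n_ch):
                    contrib[:, c] += gx[:, data.layout.channel_slice(c)].sum(axis=1)
            scores += contrib.sum(axis=0)
            n_total += b
        scores /= max(n_total, 1)
    elif method == "occlusion":
        base = _forward_in_batches(model, data, batch_size)
        for c in range(n_ch):
            masked = copy.copy(data)
            masked.eeg_psd = data.eeg_psd.copy()
            masked.eeg_psd[:, c, :] = 0.0
            if model.config.mlp_uses_eeg_features and data.layout.uses_eeg:
                masked.feats = data.feats.copy()
                masked.feats[:, data.layout.channel_slice(c)] = 0.0
            pred = _forward_in_batches(model, masked, batch_size)
            scores[c] = float(np.mean(np.abs(pred - base)))
    else:
        raise InvalidInputError(f"attribute_channels: unknown method {method!r}")
    order = np.argsort(-scores, kind="stable")
    return AttributionReport(
        channel_scores={channels[i]: float(scores[i]) for i in range(n_ch)},
        ranking=[channels[i] for i in order],
        method=method,
    )
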