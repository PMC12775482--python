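"""Multi-output cleavage-score regression with ensemble uncertainty.

A peptide is mapped to one predicted cleavage Z-score per panel protease.
Two backbones are provided: a 2-layer encoder-only transformer (model dim 32,
6 attention heads, CLS pooling, warmup/inverse-sqrt learning-rate schedule)
and a 2-layer bidirectional LSTM (model dim 32, dropout 0.25, constant lr
5e-3). Uncertainty is the standard deviation of predictions across an
ensemble of K members, each trained on an independent 80/20
train/validation resplit with per-epoch checkpointing on validation loss.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as scipy_stats
from sklearn.metrics import roc_auc_score

from . import nn
from .nn import Tensor, lr_at_step  # re-exported: lr_at_step
from .peptides_io import Peptide, SubstrateLibrary, TokenScheme, tokenize

__all__ = [
    "PredictorConfig", "PredictionResult", "PredictorEnsemble",
    "train_predictor_ensemble", "predict", "evaluate", "lr_at_step",
]

logger = logging.getLogger("cleavekit")

DEFAULT_THRESHOLDS = (0.0, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class PredictorConfig:
    backbone: str = "transformer"          # {"transformer", "lstm"}
    n_layers: int = 2
    model_dim: int = 32
    n_heads: int = 6                       # transformer only
    head_dim: int = 5                      # 6 heads x width 5 -> inner 30, projected to 32
    dropout: float = 0.25                  # lstm only
    transformer_dropout: float = 0.1       # sublayer dropout, training only
    embedding_dim: int = 32
    ff_dim: int = 128                      # 4 x model_dim
    batch_size: int | None = None          # default: 64 transformer / 32 lstm
    epochs: int = 70
    warmup_steps: int = 4000
    constant_lr: float = 5e-3              # lstm schedule
    seed: int = 0

    @property
    def effective_batch_size(self) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 64 if self.backbone == "transformer" else 32


@dataclass(frozen=True)
class PredictionResult:
    """Per-protease predicted Z-score and ensemble uncertainty for one peptide."""

    peptide: Peptide
    zhat: np.ndarray      #: (M,) ensemble-mean prediction
    sigma: np.ndarray     #: (M,) std across the K members (0 when K = 1)
    ensemble_size: int


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------


class TransformerRegressor(nn.Module):
    def __init__(self, config: PredictorConfig, n_outputs: int,
                 scheme: TokenScheme, rng: np.random.Generator):
        self.config = config
        self.scheme = scheme
        D = config.model_dim
        self.embed = Tensor(
            rng.normal(0, 1.0 / math.sqrt(D), size=(scheme.vocab_size, D)),
            requires_grad=True,
        )
        self.blocks = [
            nn.TransformerBlock(D, config.n_heads, config.ff_dim, rng,
                                causal=False, head_dim=config.head_dim)
            for _ in range(config.n_layers)
        ]
        self.head = nn.Linear(D, n_outputs, rng)
        self.pe = nn.sinusoidal_positions(scheme.max_length, D)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    def __call__(self, tokens: np.ndarray, train: bool = False) -> Tensor:
        valid = tokens != self.scheme.PAD
        x = nn.embedding(self.embed, tokens) + Tensor(self.pe[: tokens.shape[1]])
        for block in self.blocks:
            x = block(x, key_valid=valid,
                      dropout_p=self.config.transformer_dropout,
                      rng=self._dropout_rng, train=train)
        return self.head(x[:, 0, :])  # CLS pooling


class LSTMRegressor(nn.Module):
    def __init__(self, config: PredictorConfig, n_outputs: int,
                 scheme: TokenScheme, rng: np.random.Generator):
        self.config = config
        self.scheme = scheme
        E, H = config.embedding_dim, config.model_dim
        self.embed = Tensor(
            rng.normal(0, 1.0 / math.sqrt(E), size=(scheme.vocab_size, E)),
            requires_grad=True,
        )
        self.layers = []
        n_in = E
        for _ in range(config.n_layers):
            self.layers.append((nn.LSTM(n_in, H, rng), nn.LSTM(n_in, H, rng, reverse=True)))
            n_in = 2 * H
        self.lstm_params = [lstm for pair in self.layers for lstm in pair]
        self.head = nn.Linear(n_in, n_outputs, rng)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    def __call__(self, tokens: np.ndarray, train: bool = False) -> Tensor:
        valid = (tokens != self.scheme.PAD).astype(float)  # (B,T)
        x = nn.embedding(self.embed, tokens)
        for fwd, bwd in self.layers:
            x = nn.concat([fwd(x), bwd(x)], axis=2)
            x = nn.dropout(x, self.config.dropout, self._dropout_rng, train)
        # mean-pool over non-pad positions
        w = valid / valid.sum(axis=1, keepdims=True)
        pooled = (x * Tensor(w[:, :, None])).sum(axis=1)
        return self.head(pooled)


def _encode_batch(sequences: list[str], scheme: TokenScheme, backbone: str) -> np.ndarray:
    """Token matrix for a batch. The transformer prepends CLS; the LSTM takes
    the bare residue tokens."""
    rows = []
    for s in sequences:
        toks = tokenize(s, scheme, mode="predictor", pad=True)
        if backbone == "lstm":
            toks = toks[1:] + [scheme.PAD]
        rows.append(toks)
    return np.array(rows, dtype=np.int64)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def _train_member(
    library: SubstrateLibrary,
    config: PredictorConfig,
    scheme: TokenScheme,
    member_seed: int,
) -> tuple[nn.Module, dict]:
    """Train one ensemble member on its own 80/20 train/validation resplit;
    return the checkpoint with the lowest validation loss."""
    rng = np.random.default_rng(member_seed)
    n = len(library)
    perm = rng.permutation(n)
    n_val = math.ceil(0.2 * n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X = _encode_batch(library.sequences, scheme, config.backbone)
    Y = library.Z
    Xtr, Ytr, Xval, Yval = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]

    model_cls = TransformerRegressor if config.backbone == "transformer" else LSTMRegressor
    model = model_cls(config, Y.shape[1], scheme, rng)
    opt = nn.Adam(model.parameters(), lr=config.constant_lr)
    batch = config.effective_batch_size
    step = 0
    best = {"val_loss": np.inf, "epoch": -1, "state": None}
    history = {"train_loss": [], "val_loss": []}

    def forward(tokens, train):
        return model(tokens, train=train)

    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(Xtr), batch):
            idx = order[start:start + batch]
            step += 1
            if config.backbone == "transformer":
                opt.lr = lr_at_step(config.model_dim, step, config.warmup_steps)
            loss = _mse(forward(Xtr[idx], train=True), Ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        with nn.no_grad():
            val_loss = float(_mse(forward(Xval, train=False), Yval).data)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "epoch": epoch,
                    "state": [a.copy() for a in model.state_arrays()]}
    model.load_state_arrays(best["state"])
    logger.info(
        "member seed=%d: best val loss %.4f at epoch %d/%d",
        member_seed, best["val_loss"], best["epoch"] + 1, config.epochs,
    )
    return model, history


@dataclass
class PredictorEnsemble:
    members: list
    panel: list[str]
    scheme: TokenScheme
    config: PredictorConfig
    histories: list[dict] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.members)

    def member_predictions(self, sequences: list[str]) -> np.ndarray:
        """Raw per-member predictions, shape (K, n, M). Deterministic (no
        dropout at inference)."""
        X = _encode_batch(list(sequences), self.scheme, self.config.backbone)
        outs = []
        with nn.no_grad():
            for model in self.members:
                outs.append(model(X, train=False).data)
        return np.stack(outs, axis=0)

    def save(self, path) -> None:
        """Checkpoint: config + panel + vocabulary + member weights (npz)."""
        meta = {
            "config": self.config.__dict__,
            "panel": self.panel,
            "max_length": self.scheme.max_length,
            "K": self.K,
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for k, model in enumerate(self.members):
            for i, arr in enumerate(model.state_arrays()):
                arrays[f"m{k}_p{i}"] = arr
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "PredictorEnsemble":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        config = PredictorConfig(**meta["config"])
        scheme = TokenScheme(max_length=meta["max_length"])
        rng = np.random.default_rng(0)
        members = []
        model_cls = TransformerRegressor if config.backbone == "transformer" else LSTMRegressor
        for k in range(meta["K"]):
            model = model_cls(config, len(meta["panel"]), scheme, rng)
            arrays = []
            i = 0
            while f"m{k}_p{i}" in data:
                arrays.append(data[f"m{k}_p{i}"])
                i += 1
            model.load_state_arrays(arrays)
            members.append(model)
        return cls(members=members, panel=meta["panel"], scheme=scheme, config=config)


def train_predictor_ensemble(
    train: SubstrateLibrary,
    config: PredictorConfig = PredictorConfig(),
    K: int = 5,
    scheme: TokenScheme | None = None,
) -> PredictorEnsemble:
    """Train K members over independent 80/20 train/validation resplits
    (member seeds derived as ``config.seed + member index``)."""
    if len(train) < 2:
        raise ValueError("need at least 2 training peptides")
    if len(train.panel) < 1:
        raise ValueError("training library has an empty protease panel")
    if not np.isfinite(train.Z).all():
        raise ValueError("training Z contains non-finite values")
    if scheme is None:
        max_len = max(len(p) for p in train.peptides) + 1  # room for CLS
        scheme = TokenScheme(max_length=max_len)
    members, histories = [], []
    for k in range(K):
        model, history = _train_member(train, config, scheme, config.seed + k)
        members.append(model)
        histories.append(history)
    return PredictorEnsemble(
        members=members, panel=list(train.panel), scheme=scheme,
        config=config, histories=histories,
    )


def predict(ensemble: PredictorEnsemble, peptides) -> list[PredictionResult]:
    """Ensemble-mean prediction and member-spread uncertainty per peptide."""
    peps = [p if isinstance(p, Peptide) else Peptide(p) for p in peptides]
    member_preds = ensemble.member_predictions([p.sequence for p in peps])
    zhat = member_preds.mean(axis=0)
    sigma = member_preds.std(axis=0, ddof=0) if ensemble.K > 1 \
        else np.zeros_like(zhat)
    return [
        PredictionResult(peptide=p, zhat=zhat[i], sigma=sigma[i],
                         ensemble_size=ensemble.K)
        for i, p in enumerate(peps)
    ]


def predictions_to_arrays(results: list[PredictionResult]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a list of results into (zhat, sigma) matrices of shape (n, M)."""
    return (np.stack([r.zhat for r in results]),
            np.stack([r.sigma for r in results]))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(
    zhat: np.ndarray,
    truth: np.ndarray,
    panel: list[str] | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> dict:
    """Per-protease MAE, Pearson r, and ROC-AUC at each Z threshold.

    True labels at threshold t are ``truth >= t``; AUC ranks ``zhat``. A
    threshold that leaves one class empty yields NaN with a warning.
    """
    zhat = np.asarray(zhat, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if zhat.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    if zhat.ndim == 1:
        zhat, truth = zhat[:, None], truth[:, None]
    M = zhat.shape[1]
    panel = panel or [f"protease{j}" for j in range(M)]
    out = {"mae": {}, "pearson_r": {}, "auc": {}}
    for j, name in enumerate(panel):
        out["mae"][name] = float(np.abs(zhat[:, j] - truth[:, j]).mean())
        out["pearson_r"][name] = float(scipy_stats.pearsonr(zhat[:, j], truth[:, j])[0])
        aucs = {}
        for t in thresholds:
            labels = truth[:, j] >= t
            if labels.all() or not labels.any():
                warnings.warn(
                    f"AUC undefined for {name} at Z_t={t}: single-class labels"
                )
                aucs[t] = float("nan")
            else:
                aucs[t] = float(roc_auc_score(labels, zhat[:, j]))
        out["auc"][name] = aucs
    return out
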