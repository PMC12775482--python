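"""Decoder-only autoregressive peptide generator with cleavage-profile
conditioning.

The model factorizes sequence probability autoregressively over residues
(plus a STOP term) and is trained with next-token cross-entropy. Each
training sample is conditioned with probability ``conditional_fraction`` on
its own panel Z-score vector rounded to the nearest tenth: the tag passes
through a learned linear map to the model dimension and occupies the first
sequence position in place of the START embedding. Sampling is temperature-
scaled with a sign-aware repeat penalty on the immediately preceding token,
halting at STOP or at ``max_generated_length`` residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, lr_at_step
from .peptides_io import Peptide, SubstrateLibrary, TokenScheme, tokenize

logger = logging.getLogger("cleavekit")


@dataclass(frozen=True)
class GeneratorConfig:
    n_layers: int = 3
    model_dim: int = 64
    n_heads: int = 6
    head_dim: int = 10          # 6 heads x width 10 -> inner 60, projected to 64
    ff_dim: int = 256
    batch_size: int = 128
    epochs: int = 50
    warmup_steps: int = 4000
    conditional_fraction: float = 0.5
    max_generated_length: int = 20
    holdout_fraction: float = 0.1   # carved from training data for checkpointing
    seed: int = 0


def round_tag(profile: np.ndarray) -> np.ndarray:
    """A conditioning tag: panel Z-scores rounded to the nearest tenth."""
    return np.round(np.asarray(profile, dtype=float), 1)


class GeneratorModel(nn.Module):
    def __init__(self, config: GeneratorConfig, n_proteases: int,
                 scheme: TokenScheme, rng: np.random.Generator):
        self.config = config
        self.scheme = scheme
        self.n_proteases = n_proteases
        D = config.model_dim
        self.embed = Tensor(
            rng.normal(0, 1.0 / math.sqrt(D), size=(scheme.vocab_size, D)),
            requires_grad=True,
        )
        self.tag_proj = nn.Linear(n_proteases, D, rng)
        self.blocks = [
            nn.TransformerBlock(D, config.n_heads, config.ff_dim, rng,
                                causal=True, head_dim=config.head_dim)
            for _ in range(config.n_layers)
        ]
        self.head = nn.Linear(D, scheme.vocab_size, rng)
        self.pe = nn.sinusoidal_positions(config.max_generated_length + 2, D)
        #: instrumentation: how many samples took the conditional pathway
        self.n_conditional_samples = 0
        self.n_unconditional_samples = 0

    def __call__(self, tokens: np.ndarray,
                 tags: np.ndarray | None = None,
                 cond_mask: np.ndarray | None = None) -> Tensor:
        """Logits over the vocabulary at every position.

        ``tokens`` is (B, T) and starts with START. Rows flagged in
        ``cond_mask`` have the position-0 embedding replaced by the projected
        conditioning tag from ``tags`` (B, M).
        """
        B, T = tokens.shape
        x = nn.embedding(self.embed, tokens)
        if tags is not None and cond_mask is not None and cond_mask.any():
            tag_emb = self.tag_proj(Tensor(np.asarray(tags, dtype=float)))  # (B, D)
            m = Tensor(cond_mask.astype(float)[:, None])
            x0 = x[:, 0, :] * (1.0 - m) + tag_emb * m
            x = nn.concat([x0.reshape(B, 1, -1), x[:, 1:, :]], axis=1)
        x = x + Tensor(self.pe[:T])
        valid = tokens != self.scheme.PAD
        for block in self.blocks:
            x = block(x, key_valid=valid)
        return self.head(x)


def _cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over positions where ``mask`` is true."""
    lp = nn.log_softmax(logits, axis=-1)
    B, T = targets.shape
    bi, ti = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
    picked = lp[(bi, ti, targets)]          # (B, T)
    w = mask.astype(float)
    return -(picked * Tensor(w)).sum() / w.sum()


def _encode_generator_batch(sequences: list[str], scheme: TokenScheme) -> np.ndarray:
    return np.array(
        [tokenize(s, scheme, mode="generator", pad=True) for s in sequences],
        dtype=np.int64,
    )


def train_generator(
    train: SubstrateLibrary,
    config: GeneratorConfig = GeneratorConfig(),
    scheme: TokenScheme | None = None,
) -> GeneratorModel:
    """Next-token cross-entropy training with per-sample 50/50 conditioning.

    A ``holdout_fraction`` slice of the input is carved off to monitor
    held-out loss per epoch; the checkpoint with the lowest held-out loss is
    returned. Conditioning tags are each sample's own Z row rounded to
    tenths.
    """
    if config.conditional_fraction > 0 and len(train.panel) == 0:
        raise ValueError("conditional training requires Z columns in the library")
    if scheme is None:
        max_len = max(len(p) for p in train.peptides) + 2  # START + STOP
        scheme = TokenScheme(max_length=max_len)
    rng = np.random.default_rng(config.seed)
    n = len(train)
    perm = rng.permutation(n)
    n_hold = max(1, math.ceil(config.holdout_fraction * n)) if n > 10 else 0
    hold_idx, tr_idx = perm[:n_hold], perm[n_hold:]

    toks = _encode_generator_batch(train.sequences, scheme)
    tags = round_tag(train.Z) if len(train.panel) else np.zeros((n, 0))
    inputs, targets = toks[:, :-1], toks[:, 1:]
    tgt_mask = targets != scheme.PAD

    model = GeneratorModel(config, len(train.panel), scheme, rng)
    opt = nn.Adam(model.parameters())
    step = 0
    best = {"loss": np.inf, "state": None, "epoch": -1}

    def heldout_loss() -> float:
        if n_hold == 0:
            return np.nan
        with nn.no_grad():
            cm = np.zeros(n_hold, dtype=bool)  # unconditional held-out loss
            logits = model(inputs[hold_idx], tags[hold_idx], cm)
            return float(_cross_entropy(logits, targets[hold_idx], tgt_mask[hold_idx]).data)

    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        for start in range(0, len(tr_idx), config.batch_size):
            idx = tr_idx[order[start:start + config.batch_size]]
            step += 1
            opt.lr = lr_at_step(config.model_dim, step, config.warmup_steps)
            cond = rng.random(len(idx)) < config.conditional_fraction
            model.n_conditional_samples += int(cond.sum())
            model.n_unconditional_samples += int((~cond).sum())
            logits = model(inputs[idx], tags[idx], cond)
            loss = _cross_entropy(logits, targets[idx], tgt_mask[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        hl = heldout_loss()
        logger.info("generator epoch %d/%d: held-out loss %.4f", epoch + 1, config.epochs, hl)
        if n_hold == 0 or hl < best["loss"]:
            best = {"loss": hl, "epoch": epoch,
                    "state": [a.copy() for a in model.state_arrays()]}
    if best["state"] is not None:
        model.load_state_arrays(best["state"])
    return model


def heldout_losses_by_pathway(
    model: GeneratorModel, lib: SubstrateLibrary
) -> dict[str, float]:
    """Held-out cross-entropy with and without conditioning, for the same
    sequences (conditioning should be informative: conditional < unconditional)."""
    scheme = model.scheme
    toks = _encode_generator_batch(lib.sequences, scheme)
    tags = round_tag(lib.Z)
    inputs, targets = toks[:, :-1], toks[:, 1:]
    mask = targets != scheme.PAD
    out = {}
    with nn.no_grad():
        for label, cm in (("unconditional", np.zeros(len(lib), dtype=bool)),
                          ("conditional", np.ones(len(lib), dtype=bool))):
            logits = model(inputs, tags, cm)
            out[label] = float(_cross_entropy(logits, targets, mask).data)
    return out


# ---------------------------------------------------------------------------
# Scoring and sampling
# ---------------------------------------------------------------------------


def sequence_log_probability(
    model: GeneratorModel, peptide: Peptide | str, tag: np.ndarray | None = None
) -> float:
    """Sum of per-position log-probabilities, including the STOP term."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else Peptide(peptide).sequence
    scheme = model.scheme
    toks = np.array([tokenize(seq, scheme, mode="generator")], dtype=np.int64)
    inputs, targets = toks[:, :-1], toks[:, 1:]
    cond = np.array([tag is not None])
    tags = round_tag(tag)[None, :] if tag is not None else None
    with nn.no_grad():
        logits = model(inputs, tags, cond if tag is not None else None)
        lp = nn.log_softmax(logits, axis=-1).data[0]
    return float(lp[np.arange(targets.shape[1]), targets[0]].sum())


def apply_repeat_penalty(
    logits: np.ndarray, previous_token: int | None, penalty: float = 1.2
) -> np.ndarray:
    """Sign-aware scaling of the previous token's logit only: positive logits
    are divided by the penalty, negative multiplied (penalty 1 is identity)."""
    if penalty < 1:
        raise ValueError("penalty must be >= 1")
    out = np.array(logits, dtype=float)
    if previous_token is None or penalty == 1.0:
        return out
    v = out[..., previous_token]
    out[..., previous_token] = np.where(v > 0, v / penalty, v * penalty)
    return out


def sample(
    model: GeneratorModel,
    n: int,
    temperature: float = 1.0,
    repeat_penalty: float = 1.2,
    tag: np.ndarray | None = None,
    seed: int = 0,
) -> list[str]:
    """Autoregressive batched sampling; returns raw variable-length peptides.

    ``tag`` may be a single (M,) profile applied to every sample or an
    (n, M) matrix of per-sample profiles. Generation halts at STOP or at
    ``max_generated_length`` residues (then STOP is forced).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    scheme = model.scheme
    rng = np.random.default_rng(seed)
    max_len = model.config.max_generated_length
    if tag is not None:
        tags = round_tag(tag)
        if tags.ndim == 1:
            tags = np.broadcast_to(tags, (n, tags.shape[0])).copy()
        cond = np.ones(n, dtype=bool)
    else:
        tags, cond = None, None

    tokens = np.full((n, 1), scheme.START, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    prev = np.full(n, -1, dtype=np.int64)   # previously emitted amino acid
    with nn.no_grad():
        for _ in range(max_len):
            logits = model(tokens, tags, cond).data[:, -1, :]  # (n, V)
            # never emit PAD/CLS/START
            logits[:, scheme.PAD] = -np.inf
            logits[:, scheme.CLS] = -np.inf
            logits[:, scheme.START] = -np.inf
            has_prev = prev >= 0
            if repeat_penalty != 1.0 and has_prev.any():
                rows = np.flatnonzero(has_prev)
                v = logits[rows, prev[rows]]
                logits[rows, prev[rows]] = np.where(v > 0, v / repeat_penalty,
                                                    v * repeat_penalty)
            scaled = logits / temperature
            scaled -= scaled.max(axis=1, keepdims=True)
            probs = np.exp(scaled)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            nxt = (probs.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)
            nxt[done] = scheme.PAD
            newly_done = (~done) & (nxt == scheme.STOP)
            done |= newly_done
            alive = ~done & (nxt != scheme.PAD)
            prev = np.where(alive, nxt, np.where(done, -1, prev))
            tokens = np.concatenate([tokens, nxt[:, None]], axis=1)
            if done.all():
                break

    out = []
    for row in tokens:
        seq = []
        for t in row[1:]:
            if t in (scheme.STOP, scheme.PAD):
                break
            seq.append(scheme.residue_of(int(t)))
        out.append("".join(seq))
    return out


def filter_generations(
    peptides: list[str], length: int, train: SubstrateLibrary | list[str]
) -> tuple[list[str], dict]:
    """Drop off-length generations and exact matches to the training set;
    report the count removed by each rule."""
    train_seqs = set(train.sequences if isinstance(train, SubstrateLibrary) else train)
    kept, n_length, n_exact = [], 0, 0
    for s in peptides:
        if len(s) != length:
            n_length += 1
        elif s in train_seqs:
            n_exact += 1
        else:
            kept.append(s)
    report = {
        "n_in": len(peptides),
        "n_out": len(kept),
        "n_length_filtered": n_length,
        "n_exact_filtered": n_exact,
    }
    logger.info("generation filter: %s", report)
    return kept, report


def conditional_seed_profiles(
    zhat: np.ndarray,
    panel: list[str],
    target: str | int,
    objective: str = "selectivity",
    k: int = 50,
) -> np.ndarray:
    """Top-k predicted profiles to seed conditional generation, rounded to
    tenths: ranked by the target's predicted Z (efficiency) or by the
    predicted selectivity score (selectivity)."""
    zhat = np.asarray(zhat, dtype=float)
    if k > zhat.shape[0]:
        raise ValueError(f"k={k} exceeds library size {zhat.shape[0]}")
    m = panel.index(target) if isinstance(target, str) else int(target)
    if objective == "efficiency":
        scores = zhat[:, m]
    elif objective == "selectivity":
        others = np.delete(zhat, m, axis=1)
        scores = zhat[:, m] - others.mean(axis=1)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    top = np.argsort(-scores, kind="stable")[:k]
    return round_tag(zhat[top])
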