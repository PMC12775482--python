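"""Substrate nomination: ranking, k-mer diversity filtering, and baselines.

Efficiency-oriented design ranks candidates by the uncertainty-aware score
Ẑ - σ for the target protease; selectivity-oriented design ranks by the
predicted selectivity score without uncertainty adjustment. A greedy k-mer
diversity filter (default 5-mers) keeps only the top-scoring sequence
claiming each k-mer, so the nominated panel has globally unique k-mers. The
site-independent baseline samples each position independently from the
empirical residue frequencies of a source set — the null model against which
learned generation is judged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptides_io import AMINO_ACIDS, SubstrateLibrary
from .scoring import selectivity_score

logger = logging.getLogger("cleavekit")


@dataclass(frozen=True)
class DesignObjective:
    target: str | int
    mode: str = "efficiency"            # {"efficiency", "selectivity"}
    n_nominees: int = 24
    diversity_k: int = 5
    uncertainty_aware: bool | None = None   # default: True for efficiency only

    @property
    def use_uncertainty(self) -> bool:
        if self.uncertainty_aware is None:
            return self.mode == "efficiency"
        return self.uncertainty_aware


def uncertainty_aware_score(zhat, sigma) -> np.ndarray:
    """Ẑ - σ (pessimistic cleavage score for ranking)."""
    return np.asarray(zhat, dtype=float) - np.asarray(sigma, dtype=float)


def kmer_set(sequence: str, k: int) -> set[str]:
    if len(sequence) < k:
        raise ValueError(f"sequence {sequence!r} shorter than k={k}")
    return {sequence[i:i + k] for i in range(len(sequence) - k + 1)}


def kmer_diversity_filter(
    peptides: list[str], scores: np.ndarray, k: int = 5
) -> list[int]:
    """Greedy pass in descending score order (ties broken lexicographically by
    sequence): keep a peptide iff none of its k-mers was claimed by an
    already-kept peptide. Returns kept indices into ``peptides``."""
    scores = np.asarray(scores, dtype=float)
    order = sorted(range(len(peptides)), key=lambda i: (-scores[i], peptides[i]))
    claimed: set[str] = set()
    kept = []
    for i in order:
        kmers = kmer_set(peptides[i], k)
        if claimed.isdisjoint(kmers):
            kept.append(i)
            claimed.update(kmers)
    kept.sort(key=lambda i: (-scores[i], peptides[i]))
    return kept


def site_independent_sample(
    source: SubstrateLibrary | list[str], n: int, seed: int = 0
) -> list[str]:
    """Sample each position independently from the source's empirical residue
    frequencies at that position."""
    seqs = source.sequences if isinstance(source, SubstrateLibrary) else list(source)
    if not seqs:
        raise ValueError("source set is empty")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"source lengths are ragged: {sorted(lengths)}")
    L = lengths.pop()
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    freqs = np.zeros((L, 20))
    for s in seqs:
        for i, ch in enumerate(s):
            freqs[i, index[ch]] += 1
    freqs /= freqs.sum(axis=1, keepdims=True)
    cols = [rng.choice(aa, size=n, p=freqs[i]) for i in range(L)]
    return ["".join(col[j] for col in cols) for j in range(n)]


def nominate(
    generations: list[str],
    zhat: np.ndarray,
    sigma: np.ndarray,
    panel: list[str],
    objective: DesignObjective,
) -> pd.DataFrame:
    """Rank -> k-mer diversity filter -> top ``n_nominees``.

    Returns a tidy frame (sequence, score, zhat_target, sigma_target,
    selectivity, rank) sorted by descending objective score.
    """
    zhat = np.asarray(zhat, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if len(generations) != zhat.shape[0]:
        raise ValueError("predictions do not cover all generations")
    m = panel.index(objective.target) if isinstance(objective.target, str) \
        else int(objective.target)
    if objective.mode == "efficiency":
        scores = zhat[:, m]
    elif objective.mode == "selectivity":
        scores = selectivity_score(zhat, m)
    else:
        raise ValueError(f"unknown design mode {objective.mode!r}")
    if objective.use_uncertainty:
        scores = scores - sigma[:, m]

    kept = kmer_diversity_filter(list(generations), scores, k=objective.diversity_k)
    if len(kept) < objective.n_nominees:
        logger.warning(
            "only %d diverse candidates survive (requested %d)",
            len(kept), objective.n_nominees,
        )
    top = kept[: objective.n_nominees]
    return pd.DataFrame({
        "sequence": [generations[i] for i in top],
        "score": scores[np.array(top, dtype=int)],
        "zhat_target": zhat[np.array(top, dtype=int), m],
        "sigma_target": sigma[np.array(top, dtype=int), m],
        "selectivity": selectivity_score(zhat, m)[np.array(top, dtype=int)]
        if len(panel) >= 2 else np.nan,
        "rank": np.arange(1, len(top) + 1),
    })
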