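"""Peptide domain types, tokenization, library I/O, and dataset splitting.

Substrate libraries pair short peptides (10-mers in the P5...P5' register for
the matrix-metalloproteinase screen this package models) with per-protease
normalized cleavage Z-scores. This module owns the canonical alphabet and
token scheme shared by the predictor and generator, CSV/FASTA round-tripping,
Levenshtein distances for homology control, and the train/test split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("cleavekit")

#: Canonical amino acids, alphabetical by one-letter code. Index i+1 in the
#: token scheme (0 is PAD).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class InvalidResidueError(ValueError):
    """Raised when a sequence contains a non-canonical residue."""

    def __init__(self, sequence: str, position: int):
        self.position = position
        self.character = sequence[position]
        super().__init__(
            f"invalid residue {self.character!r} at position {position + 1} "
            f"in sequence {sequence!r}"
        )


@dataclass(frozen=True)
class Peptide:
    """A peptide over the 20 canonical residues (uppercase one-letter codes)."""

    sequence: str
    id: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError("peptide sequence must be non-empty")
        for i, ch in enumerate(seq):
            if ch not in _AA_SET:
                raise InvalidResidueError(seq, i)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TokenScheme:
    """Shared vocabulary: PAD=0, amino acids 1..20 (alphabetical), specials after.

    The predictor prepends CLS; the generator wraps sequences in START/STOP.
    ``max_length`` is the padded length used when batching (it counts the
    special tokens).
    """

    max_length: int = 12

    PAD: int = 0
    CLS: int = 21
    START: int = 22
    STOP: int = 23

    #: vocabulary size including all specials
    vocab_size: int = 24

    def index_of(self, residue: str) -> int:
        return AMINO_ACIDS.index(residue) + 1

    def residue_of(self, index: int) -> str:
        if not 1 <= index <= 20:
            raise ValueError(f"token index {index} is not an amino acid")
        return AMINO_ACIDS[index - 1]


def tokenize(
    peptide: Peptide | str,
    scheme: TokenScheme = TokenScheme(),
    mode: str = "predictor",
    pad: bool = False,
) -> list[int]:
    """Tokenize a peptide for the predictor (CLS + residues) or generator
    (START + residues + STOP). With ``pad=True`` the list is right-padded with
    PAD to ``scheme.max_length``."""
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    body = [scheme.index_of(ch) for ch in peptide.sequence]
    if mode == "predictor":
        toks = [scheme.CLS] + body
    elif mode == "generator":
        toks = [scheme.START] + body + [scheme.STOP]
    else:
        raise ValueError(f"unknown tokenize mode {mode!r}")
    if pad:
        if len(toks) > scheme.max_length:
            raise ValueError(
                f"tokenized length {len(toks)} exceeds max_length {scheme.max_length}"
            )
        toks = toks + [scheme.PAD] * (scheme.max_length - len(toks))
    return toks


def detokenize(tokens, scheme: TokenScheme = TokenScheme()) -> str:
    """Inverse of :func:`tokenize`: strips specials/padding, returns the sequence."""
    specials = {scheme.PAD, scheme.CLS, scheme.START, scheme.STOP}
    return "".join(scheme.residue_of(t) for t in tokens if t not in specials)


# ---------------------------------------------------------------------------
# SubstrateLibrary
# ---------------------------------------------------------------------------


@dataclass
class SubstrateLibrary:
    """Peptides with per-protease normalized cleavage Z-scores.

    ``Z`` has shape (n_peptides, len(panel)); ``panel`` orders the protease
    names; ``group`` optionally labels provenance per peptide.
    """

    peptides: list[Peptide]
    panel: list[str] = field(default_factory=list)
    Z: np.ndarray | None = None
    group: list[str] | None = None

    def __post_init__(self):
        if self.Z is None:
            self.Z = np.zeros((len(self.peptides), len(self.panel)))
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (len(self.peptides), len(self.panel)):
            raise ValueError(
                f"Z shape {self.Z.shape} does not match "
                f"({len(self.peptides)} peptides, {len(self.panel)} proteases)"
            )
        ids = [p.id for p in self.peptides if p.id is not None]
        if len(ids) != len(set(ids)):
            raise ValueError("peptide ids must be unique")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def subset(self, indices) -> "SubstrateLibrary":
        indices = np.asarray(indices, dtype=np.intp)
        return SubstrateLibrary(
            peptides=[self.peptides[i] for i in indices],
            panel=list(self.panel),
            Z=self.Z[indices],
            group=[self.group[i] for i in indices] if self.group else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sequence": self.sequences})
        ids = [p.id for p in self.peptides]
        if any(i is not None for i in ids):
            df.insert(0, "id", ids)
        for j, name in enumerate(self.panel):
            df[name] = self.Z[:, j]
        if self.group is not None:
            df["group"] = self.group
        return df


def read_library(path, format: str = "csv") -> SubstrateLibrary:
    """Read a substrate library from CSV (``sequence`` column + one Z column
    per protease) or plain FASTA (empty panel)."""
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        peptides = [Peptide(str(r.seq), id=r.id) for r in records]
        logger.info("read %d peptides from FASTA %s", len(peptides), path)
        return SubstrateLibrary(peptides=peptides)
    if format != "csv":
        raise ValueError(f"unknown library format {format!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing required 'sequence' column")
    reserved = {"sequence", "id", "group"}
    panel = [c for c in df.columns if c not in reserved]
    Z = np.empty((len(df), len(panel)))
    for j, name in enumerate(panel):
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.isna() & df[name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[name].iloc[row]!r} in column "
                f"{name!r} at data row {row + 1}"
            )
        Z[:, j] = col.to_numpy()
    ids = df["id"].astype(str).tolist() if "id" in df.columns else [None] * len(df)
    peptides = [Peptide(s, id=i) for s, i in zip(df["sequence"], ids)]
    group = df["group"].astype(str).tolist() if "group" in df.columns else None
    logger.info("read %d peptides x %d proteases from %s", len(df), len(panel), path)
    return SubstrateLibrary(peptides=peptides, panel=panel, Z=Z, group=group)


def write_library(lib: SubstrateLibrary, path, format: str = "csv") -> None:
    if format == "csv":
        # %.17g guarantees float64 round-trip to full precision
        lib.to_frame().to_csv(path, index=False, float_format="%.17g")
    elif format == "fasta":
        records = [
            SeqRecord(Seq(p.sequence), id=p.id or f"pep{i}", description="")
            for i, p in enumerate(lib.peptides)
        ]
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown library format {format!r}")
    logger.info("wrote %d peptides to %s (%s)", len(lib), path, format)


# ---------------------------------------------------------------------------
# Distances, splitting, homology filtering
# ---------------------------------------------------------------------------


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute)."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def split_train_test(
    lib: SubstrateLibrary, test_fraction: float, seed: int
) -> tuple[SubstrateLibrary, SubstrateLibrary]:
    """Random disjoint/exhaustive partition with ``ceil(test_fraction * n)``
    test items; deterministic under ``seed``."""
    n = len(lib)
    if n < 2:
        raise ValueError("need at least 2 peptides to split")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = math.ceil(test_fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    logger.info("split: %d train / %d test (fraction %.3f)", n - n_test, n_test, test_fraction)
    return lib.subset(train_idx), lib.subset(test_idx)


def min_distance_to_set(sequence: str, pool: list[str]) -> int:
    """Minimum Levenshtein distance from ``sequence`` to any sequence in ``pool``."""
    return min(levenshtein(sequence, t) for t in pool)


def homology_filter(
    test: SubstrateLibrary, train: SubstrateLibrary, min_distance: int = 3
) -> SubstrateLibrary:
    """Drop test peptides whose minimum edit distance to the training set is
    below ``min_distance`` (homology control for held-out evaluation)."""
    if len(train) == 0:
        raise ValueError("train set is empty")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    train_seqs = train.sequences
    keep = [
        i
        for i, s in enumerate(test.sequences)
        if min_distance_to_set(s, train_seqs) >= min_distance
    ]
    logger.info(
        "homology filter: kept %d/%d test peptides (min_distance=%d)",
        len(keep), len(test), min_distance,
    )
    return test.subset(keep)
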