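"""Motif and library analytics.

Position-wise amino-acid composition matrices (raw frequencies or fold
change against a reference composition — the IceLogo representation),
position-wise Kullback-Leibler divergence between peptide sets, overlapping
k-mer censuses with cumulative-coverage curves and shared/unique breakdowns,
sequence biophysical properties, and hierarchical clustering of protease
activity profiles.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .peptides_io import AMINO_ACIDS, Peptide

logger = logging.getLogger("cleavekit")

#: Swiss-Prot average amino-acid composition (fractions), used as the
#: "natural" reference for fold-change normalization.
NATURAL_FREQUENCIES = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

#: residue color classes (side-chain chemistry) exported as IceLogo metadata
RESIDUE_CLASSES = {
    "hydrophobic_aromatic": "FWY",
    "hydrophobic": "AILMPVG",
    "hydrophilic": "CNQST",
    "acidic": "DEH",
    "basic": "KR",
}

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _check_uniform(peptides: list[str]) -> int:
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError(f"peptide lengths are ragged: {sorted(lengths)}")
    return lengths.pop()


def position_frequencies(peptides: list[str], pseudocount: float = 0.0) -> np.ndarray:
    """(L, 20) per-position residue frequencies with optional additive
    pseudocount on counts."""
    if not peptides:
        raise ValueError("empty peptide set")
    L = _check_uniform(peptides)
    counts = np.full((L, 20), pseudocount, dtype=float)
    for s in peptides:
        for i, ch in enumerate(s):
            counts[i, _AA_INDEX[ch]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


@dataclass
class IceLogoMatrix:
    """Positions x 20 residues; raw frequencies or fold change vs a reference."""

    values: np.ndarray
    normalization: str                    # {"raw", "natural", "background"}
    reference: np.ndarray | None          # the reference frequencies used
    residues: str = AMINO_ACIDS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            columns=list(self.residues),
            index=[f"pos{i + 1}" for i in range(self.values.shape[0])],
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# normalization={self.normalization}\n")
            for cls, members in RESIDUE_CLASSES.items():
                fh.write(f"# class:{cls}={members}\n")
            self.to_frame().to_csv(fh, sep="\t")


def icelogo(
    peptides: list[str],
    normalization: str = "raw",
    reference: dict[str, float] | np.ndarray | None = None,
    pseudocount: float = 0.0,
) -> IceLogoMatrix:
    """Position-wise composition matrix.

    ``raw``: frequencies summing to 1 per position. ``natural``: fold change
    against the built-in natural composition. ``background``: fold change
    against a supplied reference frequency table (per-residue, or per
    position x residue).
    """
    freq = position_frequencies(peptides, pseudocount)
    if normalization == "raw":
        return IceLogoMatrix(values=freq, normalization="raw", reference=None)
    if normalization == "natural":
        ref = np.array([NATURAL_FREQUENCIES[a] for a in AMINO_ACIDS])
    elif normalization == "background":
        if reference is None:
            raise ValueError("background normalization requires a reference")
        if isinstance(reference, dict):
            ref = np.array([reference[a] for a in AMINO_ACIDS])
        else:
            ref = np.asarray(reference, dtype=float)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if np.any(ref <= 0):
        raise ValueError("reference frequencies must be strictly positive "
                         "(apply a pseudocount)")
    return IceLogoMatrix(values=freq / ref, normalization=normalization, reference=ref)


def position_kl(
    p_set: list[str],
    q_set: list[str],
    positions: list[int] | None = None,
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Per-position KL(P_pos || Q_pos) in nats with additive pseudocount on
    counts, plus the mean over the requested positions (0-based; default all)."""
    if not p_set or not q_set:
        raise ValueError("empty peptide set")
    P = position_frequencies(p_set, pseudocount)
    Q = position_frequencies(q_set, pseudocount)
    if P.shape != Q.shape:
        raise ValueError("peptide sets have different lengths")
    kl = (P * np.log(P / Q)).sum(axis=1)
    if positions is None:
        positions = list(range(P.shape[0]))
    return kl, float(kl[list(positions)].mean())


# ---------------------------------------------------------------------------
# k-mer analytics
# ---------------------------------------------------------------------------


def kmer_census(peptides: list[str], k: int) -> Counter:
    """Position-independent overlapping k-mer counts."""
    census: Counter = Counter()
    for s in peptides:
        if len(s) < k:
            raise ValueError(f"peptide {s!r} shorter than k={k}")
        for i in range(len(s) - k + 1):
            census[s[i:i + k]] += 1
    return census


def kmer_cdf(census: Counter) -> pd.DataFrame:
    """Unique k-mers sorted by descending count; cumulative frequency mass.

    The curve is non-decreasing and ends at 1.
    """
    items = sorted(census.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = np.array([c for _, c in items], dtype=float)
    cum = counts.cumsum() / counts.sum()
    return pd.DataFrame({
        "kmer": [k for k, _ in items],
        "count": counts.astype(int),
        "rank": np.arange(1, len(items) + 1),
        "cumulative_frequency": cum,
    })


def shared_breakdown(census_a: Counter, census_b: Counter, top: int = 3) -> dict:
    """Partition the union of two k-mer sets into shared / A-only / B-only;
    fractions (of the union) sum to 1; top occurring k-mers listed per class."""
    a_set, b_set = set(census_a), set(census_b)
    union = a_set | b_set
    shared = a_set & b_set
    a_only = a_set - b_set
    b_only = b_set - a_set
    n = len(union)

    def top_of(kmers, census):
        return [k for k, _ in sorted(
            ((k, census[k]) for k in kmers), key=lambda kv: (-kv[1], kv[0])
        )[:top]]

    combined = census_a + census_b
    return {
        "shared_fraction": len(shared) / n if n else 0.0,
        "a_only_fraction": len(a_only) / n if n else 0.0,
        "b_only_fraction": len(b_only) / n if n else 0.0,
        "top_shared": top_of(shared, combined),
        "top_a_only": top_of(a_only, census_a),
        "top_b_only": top_of(b_only, census_b),
    }


# ---------------------------------------------------------------------------
# Biophysical properties
# ---------------------------------------------------------------------------

KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Boman residue solubility scale (kcal/mol, protein-binding potential)
BOMAN = {
    "A": -0.5, "C": 0.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0, "H": 0.5,
    "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2,
    "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

#: EMBOSS-style side-chain pKa values
PKA_SIDECHAIN = {"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}
PKA_NTERM = 8.6
PKA_CTERM = 3.6
_POSITIVE = {"H", "K", "R"}


def net_charge(sequence: str, ph: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge including termini."""
    pos = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    neg = -1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for ch in sequence:
        pka = PKA_SIDECHAIN.get(ch)
        if pka is None:
            continue
        if ch in _POSITIVE:
            pos += 1.0 / (1.0 + 10 ** (ph - pka))
        else:
            neg -= 1.0 / (1.0 + 10 ** (pka - ph))
    return pos + neg


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """Bisection root of net_charge over pH (charge(pI) ~ 0)."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def biophysical_properties(peptide: Peptide | str) -> dict[str, float]:
    """Aliphatic index, mean Kyte-Doolittle hydrophobicity, Boman index, net
    charge at pH 7, and isoelectric point."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else Peptide(peptide).sequence
    n = len(seq)
    fa = seq.count("A") / n
    fv = seq.count("V") / n
    fil = (seq.count("I") + seq.count("L")) / n
    return {
        "aliphatic_index": 100.0 * (fa + 2.9 * fv + 3.9 * fil),
        "hydrophobicity": sum(KYTE_DOOLITTLE[c] for c in seq) / n,
        "boman_index": sum(BOMAN[c] for c in seq) / n,
        "net_charge": net_charge(seq, 7.0),
        "isoelectric_point": isoelectric_point(seq),
    }


# ---------------------------------------------------------------------------
# Activity clustering
# ---------------------------------------------------------------------------


def activity_clustering(
    profiles: np.ndarray,
    panel: list[str],
    cutoff: float = 0.5,
) -> dict:
    """Agglomerative clustering of protease activity columns.

    ``profiles`` is (n_substrates, M) — e.g., the stacked top-n predicted
    profiles per protease. Distance is 1 - Pearson correlation between
    columns, average linkage; ``cutoff`` gives the flat groups. Returns the
    linkage matrix, group labels per protease, and a Newick rendering.
    """
    profiles = np.asarray(profiles, dtype=float)
    M = profiles.shape[1]
    if M < 2:
        raise ValueError("need at least 2 proteases to cluster")
    sds = profiles.std(axis=0)
    if (sds < 1e-12).any():
        bad = [panel[j] for j in np.flatnonzero(sds < 1e-12)]
        raise ValueError(f"constant activity column(s), correlation undefined: {bad}")
    corr = np.corrcoef(profiles.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    groups = fcluster(Z, t=cutoff, criterion="distance")

    def newick(node) -> str:
        if node.is_leaf():
            return panel[node.id]
        return f"({newick(node.left)},{newick(node.right)}):{node.dist:.4f}"

    tree = to_tree(Z)
    return {
        "linkage": Z,
        "groups": {name: int(g) for name, g in zip(panel, groups)},
        "n_groups": int(groups.max()),
        "newick": newick(tree) + ";",
    }
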