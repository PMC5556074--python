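"""Sequence-derived descriptors.

Protein-level descriptors (computed per chain group and attached to every
residue observation of that group):

* amino-acid composition (AAC, 20 fractions);
* Chou's pseudo amino-acid composition (PAAC, 20 + lambda values) built
  from standardized hydrophobicity / hydrophilicity / side-chain-mass
  scales;
* amphiphilic pseudo amino-acid composition (APAAC, 20 + 2*lambda) with
  separate hydrophobicity and hydrophilicity correlation channels;
* substitution-matrix scale descriptors: each residue projected onto the
  top-k principal components of BLOSUM62 (or any user scale matrix),
  summarised by auto/cross-covariances up to a maximum lag.

Residue-level evolutionary features (40 per position) come from an
externally produced ASCII PSSM profile; when no profile is supplied the
40 features are imputed as zero and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from ._aa import AA1, HYDROPHOBICITY, HYDROPHILICITY, SIDECHAIN_MASS

DEFAULT_LAMBDA = 30
DEFAULT_WEIGHT = 0.05
DEFAULT_K_COMPONENTS = 5
DEFAULT_MAX_LAG = 7
DEFAULT_MIN_HOMOLOGS = 10


class SequenceError(ValueError):
    pass


class InsufficientHomologsError(ValueError):
    """The profile search found too few homologs for reliable PSSM features."""


def _validate(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in AA1:
            raise SequenceError(
                f"invalid amino-acid letter {ch!r} at position {i}"
            )
    if not seq:
        raise SequenceError("empty sequence")
    return seq


def aac(seq: str) -> dict[str, float]:
    """Amino-acid composition: fraction of each residue type."""
    seq = _validate(seq)
    n = len(seq)
    return {f"aac_{a}": seq.count(a) / n for a in AA1}


def _standardize_scale(scale: Mapping[str, float]) -> dict[str, float]:
    # Chou's convention: centre over the 20 amino acids, divide by the
    # population (ddof=0) standard deviation over the 20 values.
    vals = np.array([scale[a] for a in AA1], dtype=float)
    mu = vals.mean()
    sd = math.sqrt(float(np.mean((vals - mu) ** 2)))
    return {a: (scale[a] - mu) / sd for a in AA1}


@lru_cache(maxsize=None)
def _paac_scales() -> tuple[dict, dict, dict]:
    return (
        _standardize_scale(HYDROPHOBICITY),
        _standardize_scale(HYDROPHILICITY),
        _standardize_scale(SIDECHAIN_MASS),
    )


def paac(seq: str, lam: int = DEFAULT_LAMBDA, w: float = DEFAULT_WEIGHT) -> dict[str, float]:
    """Chou's pseudo amino-acid composition (20 + lam values, sums to 1).

    The lam sequence-order correlation factors average, over residue
    pairs at distance l, the mean squared difference of the three
    standardized physicochemical scales.
    """
    seq = _validate(seq)
    if w <= 0:
        raise SequenceError("weight w must be positive")
    if len(seq) <= lam:
        raise SequenceError(
            f"sequence length {len(seq)} must exceed lambda={lam}"
        )
    h1, h2, m = _paac_scales()
    theta = []
    for l in range(1, lam + 1):
        acc = 0.0
        for i in range(len(seq) - l):
            a, b = seq[i], seq[i + l]
            acc += (
                (h1[b] - h1[a]) ** 2 + (h2[b] - h2[a]) ** 2 + (m[b] - m[a]) ** 2
            ) / 3.0
        theta.append(acc / (len(seq) - l))
    freqs = {a: seq.count(a) / len(seq) for a in AA1}
    denom = 1.0 + w * sum(theta)
    out = {f"paac_{a}": freqs[a] / denom for a in AA1}
    for l, th in enumerate(theta, start=1):
        out[f"paac_lambda{l}"] = w * th / denom
    return out


def apaac(seq: str, lam: int = DEFAULT_LAMBDA, w: float = DEFAULT_WEIGHT) -> dict[str, float]:
    """Amphiphilic pseudo amino-acid composition (20 + 2*lam values).

    Correlation terms are products of standardized hydrophobicity values
    (odd channels) and hydrophilicity values (even channels) at each lag;
    all 20 + 2*lam entries sum to 1 under the shared normalisation.
    """
    seq = _validate(seq)
    if w <= 0:
        raise SequenceError("weight w must be positive")
    if len(seq) <= lam:
        raise SequenceError(
            f"sequence length {len(seq)} must exceed lambda={lam}"
        )
    h1, h2, _ = _paac_scales()
    tau = []
    for l in range(1, lam + 1):
        n = len(seq) - l
        tau.append(sum(h1[seq[i]] * h1[seq[i + l]] for i in range(n)) / n)
        tau.append(sum(h2[seq[i]] * h2[seq[i + l]] for i in range(n)) / n)
    freqs = {a: seq.count(a) / len(seq) for a in AA1}
    denom = 1.0 + w * sum(tau)
    out = {f"apaac_{a}": freqs[a] / denom for a in AA1}
    for k, t in enumerate(tau, start=1):
        lag = (k + 1) // 2
        channel = "hb" if k % 2 == 1 else "hl"
        out[f"apaac_{channel}_lambda{lag}"] = w * t / denom
    return out


@lru_cache(maxsize=None)
def blosum62_components(k: int = DEFAULT_K_COMPONENTS) -> tuple[tuple[str, ...], np.ndarray]:
    """Top-k principal components of the BLOSUM62 substitution matrix.

    Returns (feature names, 20 x k loading matrix indexed by ``AA1``).
    """
    from sklearn.decomposition import PCA
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    letters = [a for a in blosum.alphabet if a in AA1]
    mat = np.array(
        [[float(blosum[a, b]) for b in letters] for a in letters]
    )
    proj = PCA(n_components=k, random_state=0).fit_transform(mat)
    order = [letters.index(a) for a in AA1]
    names = tuple(f"blosum_pc{i + 1}" for i in range(k))
    return names, proj[order]


def scales_descriptor(
    seq: str,
    scales: np.ndarray | None = None,
    lag: int = DEFAULT_MAX_LAG,
    prefix: str = "blosum",
) -> dict[str, float]:
    """Auto/cross-covariance descriptor over per-residue scale projections.

    ``scales`` is a 20 x k matrix (rows ordered as ``AA1``); by default the
    top-5 principal components of BLOSUM62.  Each residue is projected
    onto the k components; for every ordered component pair (c, d) and
    lag l in 1..lag the descriptor holds the covariance of the centred
    projections at sequence separation l — k^2 * lag values.
    """
    seq = _validate(seq)
    if scales is None:
        _, scales = blosum62_components()
    scales = np.asarray(scales, dtype=float)
    if scales.shape[0] != 20:
        raise SequenceError("scale matrix must have one row per amino-acid type")
    if lag >= len(seq):
        raise SequenceError(f"lag {lag} must be smaller than sequence length {len(seq)}")
    idx = np.array([AA1.index(ch) for ch in seq])
    z = scales[idx]  # n x k projections
    z = z - z.mean(axis=0, keepdims=True)
    n, k = z.shape
    out = {}
    for l in range(1, lag + 1):
        cov = z[:-l].T @ z[l:] / (n - l)
        for c in range(k):
            for d in range(k):
                out[f"{prefix}_acc_c{c + 1}_d{d + 1}_lag{l}"] = float(cov[c, d])
    return out


@dataclass
class PssmProfile:
    """Positional profile for one chain: log-odds + observed percentages."""

    sequence: str
    log_odds: np.ndarray  # n x 20
    percentages: np.ndarray  # n x 20
    n_homologs: int = 0

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.percentages = np.asarray(self.percentages, dtype=float)
        n = len(self.sequence)
        if self.log_odds.shape != (n, 20) or self.percentages.shape != (n, 20):
            raise ValueError(
                "profile rows must carry 20 log-odds and 20 percentages "
                "aligned to the sequence"
            )


# Column order used by ASCII PSSM profile files.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def read_pssm(path_or_text) -> PssmProfile:
    """Read an ASCII PSSM profile (the standard profile-search output).

    Expects the tabular section whose rows are
    ``pos aa  <20 log-odds>  <20 weighted observed percentages> ...``.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    elif "\n" in str(path_or_text):
        text = str(path_or_text)
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    seq, lo, pct = [], [], []
    n_homologs = 0
    for line in text.splitlines():
        parts = line.split()
        if len(parts) >= 42 and parts[0].isdigit() and len(parts[1]) == 1:
            seq.append(parts[1])
            lo.append([float(v) for v in parts[2:22]])
            pct.append([float(v) for v in parts[22:42]])
        elif line.strip().lower().startswith("# homologs"):
            n_homologs = int(parts[-1])
    if not seq:
        raise ValueError("no PSSM rows found in profile input")
    return PssmProfile(
        sequence="".join(seq),
        log_odds=np.array(lo),
        percentages=np.array(pct),
        n_homologs=n_homologs,
    )


def write_pssm(profile: PssmProfile) -> str:
    """Serialize a profile in the ASCII layout accepted by :func:`read_pssm`."""
    lines = [
        "",
        "Last position-specific scoring matrix computed",
        "# homologs " + str(profile.n_homologs),
        "    " + "  ".join(PSSM_ALPHABET) + "   " + "  ".join(PSSM_ALPHABET),
    ]
    for i, aa in enumerate(profile.sequence):
        row = (
            f"{i + 1:5d} {aa} "
            + " ".join(f"{v:6.2f}" for v in profile.log_odds[i])
            + "  "
            + " ".join(f"{v:6.2f}" for v in profile.percentages[i])
        )
        lines.append(row)
    return "\n".join(lines) + "\n"


def pssm_features(
    profile: PssmProfile,
    position: int,
    min_homologs: int = DEFAULT_MIN_HOMOLOGS,
) -> dict[str, float]:
    """The 40 evolutionary features at one 0-based sequence position."""
    if profile.n_homologs < min_homologs:
        raise InsufficientHomologsError(
            f"profile built from {profile.n_homologs} homologs; "
            f"at least {min_homologs} required"
        )
    if not 0 <= position < len(profile.sequence):
        raise IndexError(
            f"position {position} outside profile of length {len(profile.sequence)}"
        )
    out = {
        f"pssm_lo_{a}": float(v)
        for a, v in zip(PSSM_ALPHABET, profile.log_odds[position])
    }
    out.update(
        {
            f"pssm_pct_{a}": float(v)
            for a, v in zip(PSSM_ALPHABET, profile.percentages[position])
        }
    )
    return out


def zero_pssm_features() -> dict[str, float]:
    """Zero-imputed PSSM block used when no profile is available."""
    out = {f"pssm_lo_{a}": 0.0 for a in PSSM_ALPHABET}
    out.update({f"pssm_pct_{a}": 0.0 for a in PSSM_ALPHABET})
    return out


def chain_descriptors(
    seq: str,
    lam: int = DEFAULT_LAMBDA,
    w: float = DEFAULT_WEIGHT,
    lag: int = DEFAULT_MAX_LAG,
) -> dict[str, float]:
    """All protein-level sequence descriptors for one chain group."""
    out = {}
    out.update(aac(seq))
    out.update(paac(seq, lam, w))
    out.update(apaac(seq, lam, w))
    out.update(scales_descriptor(seq, lag=lag))
    return out
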