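"""Fixed-length single representations of a protein.

Three encoders, each mapping one protein to a length-independent vector:

* **DipC** (420D): 20 residue frequencies ``aa_i / L`` followed by the 400
  ordered-dipeptide frequencies ``cr_i / (L-1)``.  The dipeptide (a, b)
  occupies position ``20 + 20*(index(a)-1) + index(b)`` (1-based, row-major
  over ordered residue pairs).
* **PseAAC** (20+2λ D): residue frequencies plus λ tiers of sequence-order
  correlation factors.  Tier k holds two factors — the mean over all
  residue pairs k apart of the product of standardized hydrophobicity
  values, and the same with hydrophilicity — interleaved (hydrophobicity at
  odd, hydrophilicity at even positions).  All 20+2λ components share one
  normalizing denominator and sum to 1.
* **compressed PSSM** (210D): the lower triangle, row-major, of the
  symmetric 20x20 matrix M = PᵀP built from the L x 20 score matrix P.  M
  is length-free, so proteins of any length compare in the same space.

Each encoder is exposed both as a plain function and as a scikit-learn
transformer operating on lists of records/matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import CANONICAL_ALPHABET, LabeledDataset, PSSMMatrix, SequenceRecord

DIPC_DIM = 420
PSSM_DIM = 210

# Hydrophobicity (Tanford-style, as used in the classical pseudo-amino-acid
# composition) and hydrophilicity (Hopp-Woods), both listed in canonical
# alphabetical residue order and standardized before use.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}


def _standardize(table: dict[str, float]) -> np.ndarray:
    v = np.array([table[aa] for aa in CANONICAL_ALPHABET], dtype=float)
    return (v - v.mean()) / v.std()  # population SD over the 20 residues


DEFAULT_HYDROPHOBICITY: np.ndarray = _standardize(_HYDROPHOBICITY)
DEFAULT_HYDROPHILICITY: np.ndarray = _standardize(_HYDROPHILICITY)


class EncodingError(ValueError):
    """A record fails an encoder's precondition."""


@dataclass(frozen=True)
class PseAACParams:
    """Parameters of the pseudo-amino-acid composition encoder.

    lam is the highest rank of sequence-order correlation (tiers 1..lam);
    w weights the correlation block against the composition block.  h1/h2
    are the 20-residue hydrophobicity and hydrophilicity scales in canonical
    order, standardized to zero mean and unit SD.
    """

    lam: int = 10
    w: float = 0.05
    h1: np.ndarray = field(default_factory=lambda: DEFAULT_HYDROPHOBICITY.copy())
    h2: np.ndarray = field(default_factory=lambda: DEFAULT_HYDROPHILICITY.copy())

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if self.w <= 0:
            raise ValueError(f"w must be positive, got {self.w}")
        for name, scale in (("h1", self.h1), ("h2", self.h2)):
            s = np.asarray(scale, dtype=float)
            if s.shape != (20,):
                raise ValueError(f"{name} must have 20 entries")
            if abs(s.mean()) > 1e-9 or abs(s.std() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be standardized (mean 0, SD 1)")

    @property
    def dim(self) -> int:
        return 20 + 2 * self.lam


def encode_dipc(record: SequenceRecord) -> np.ndarray:
    """420D dipeptide-composition vector of one protein.

    Requires L >= 2 (the dipeptide denominator is L-1).
    """
    L = record.L
    if L < 2:
        raise EncodingError(
            f"record {record.id!r}: DipC needs L >= 2, got L={L}"
        )
    idx = record.indices()
    out = np.zeros(DIPC_DIM)
    counts = np.bincount(idx, minlength=20).astype(float)
    out[:20] = counts / L
    pair = 20 * idx[:-1] + idx[1:]
    out[20:] = np.bincount(pair, minlength=400).astype(float) / (L - 1)
    return out


def encode_pseaac(
    record: SequenceRecord, params: PseAACParams | None = None
) -> np.ndarray:
    """(20+2λ)D pseudo-amino-acid composition vector of one protein.

    Requires L >= λ+1 so every correlation tier has at least one pair.
    """
    p = params if params is not None else PseAACParams()
    L = record.L
    if L <= p.lam:
        raise EncodingError(
            f"record {record.id!r}: PseAAC needs L >= lam+1 (L={L}, lam={p.lam})"
        )
    idx = record.indices()
    f = np.bincount(idx, minlength=20).astype(float) / L
    s1 = np.asarray(p.h1, dtype=float)[idx]
    s2 = np.asarray(p.h2, dtype=float)[idx]
    tau = np.empty(2 * p.lam)
    for k in range(1, p.lam + 1):
        tau[2 * k - 2] = np.mean(s1[:-k] * s1[k:])
        tau[2 * k - 1] = np.mean(s2[:-k] * s2[k:])
    denom = f.sum() + p.w * tau.sum()
    return np.concatenate([f, p.w * tau]) / denom


def compress_pssm(pssm: PSSMMatrix) -> np.ndarray:
    """210D compression of an L x 20 PSSM: lower triangle of M = PᵀP.

    Row-major over the triangle, so element (i, j) with i >= j (1-based)
    lands at position i(i-1)/2 + j.  Invariant under any reordering of the
    PSSM rows, since PᵀP sums over positions.
    """
    P = pssm.scores
    M = P.T @ P
    tri = np.tril_indices(20)
    return M[tri]


def pssm_from_compressed(values: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric 20x20 matrix M from its 210-element triangle."""
    values = np.asarray(values, dtype=float)
    if values.shape != (PSSM_DIM,):
        raise ValueError(f"expected {PSSM_DIM} values, got {values.shape}")
    M = np.zeros((20, 20))
    M[np.tril_indices(20)] = values
    return M + np.tril(M, -1).T


def encode_all(
    dataset: LabeledDataset,
    which: str,
    params: PseAACParams | None = None,
    strict: bool = True,
) -> dict[str, np.ndarray]:
    """Encode every record in a dataset; failures are aggregated.

    which is one of ``dipc``, ``pseaac``, ``pssm``.  In strict mode a single
    aggregate error lists every failing id; otherwise failing ids are
    silently excluded from the returned mapping.
    """
    out: dict[str, np.ndarray] = {}
    failures: list[str] = []
    for rec in dataset.records:
        try:
            if which == "dipc":
                out[rec.id] = encode_dipc(rec)
            elif which == "pseaac":
                out[rec.id] = encode_pseaac(rec, params)
            elif which == "pssm":
                if rec.id not in dataset.pssms:
                    raise EncodingError(f"record {rec.id!r}: no PSSM")
                out[rec.id] = compress_pssm(dataset.pssms[rec.id])
            else:
                raise ValueError(f"unknown representation {which!r}")
        except EncodingError:
            failures.append(rec.id)
    if failures and strict:
        raise EncodingError(
            f"{len(failures)} record(s) failed {which} encoding: {sorted(failures)}"
        )
    return out


class _RecordEncoder(BaseEstimator, TransformerMixin):
    """Stateless transformer base: fit is a no-op, transform maps records."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.vstack([self._encode_one(x) for x in X])


class DipCEncoder(_RecordEncoder):
    """Transformer: list of SequenceRecord -> (N, 420) DipC matrix."""

    def _encode_one(self, rec: SequenceRecord) -> np.ndarray:
        return encode_dipc(rec)


class PseAACEncoder(_RecordEncoder):
    """Transformer: list of SequenceRecord -> (N, 20+2λ) PseAAC matrix."""

    def __init__(self, lam: int = 10, w: float = 0.05):
        self.lam = lam
        self.w = w

    def _encode_one(self, rec: SequenceRecord) -> np.ndarray:
        return encode_pseaac(rec, PseAACParams(lam=self.lam, w=self.w))


class PSSMCompressor(_RecordEncoder):
    """Transformer: list of PSSMMatrix -> (N, 210) compressed matrix."""

    def _encode_one(self, pssm: PSSMMatrix) -> np.ndarray:
        return compress_pssm(pssm)
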