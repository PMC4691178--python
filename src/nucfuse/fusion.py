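"""Balance-factor fusion of a composition-type block with the PSSM block.

A fused vector for a protein of sub-nuclear location i is the weighted
concatenation V_i = [r_i * A_i, (1 - r_i) * B_i], where A is the DipC or
PseAAC block, B the compressed-PSSM block, and r_i in (0, 1) is the
location's balance factor.  With DipC the fused vector has 420+210 = 630
dimensions; with PseAAC (λ=10), 40+210 = 250.

A test protein's location — hence its balance factor — is unknown, so two
weighting modes are provided: ``true-label`` (each sample fused with its
own class's factor; only usable with known labels, i.e. for training and
optimization-time fitness) and ``candidate-class`` (each sample yields one
fused variant per candidate class; the classifier compares a query's
variant c against training neighbours of class c, keeping prediction
label-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

FusionMode = Literal["true-label", "candidate-class"]

_EPS = 1e-6


@dataclass
class BalanceVector:
    """Per-location balance factors r_i in the open interval (0, 1)."""

    r: np.ndarray
    provenance: Literal["fixed", "greedy-init", "ga-optimized"] = "fixed"
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1 or self.r.size < 2:
            raise ValueError("balance vector needs one factor per class, n >= 2")
        if np.any(self.r <= 0.0) or np.any(self.r >= 1.0):
            raise ValueError(
                f"balance factors must lie strictly in (0,1), got {self.r}"
            )

    @property
    def n(self) -> int:
        return int(self.r.size)

    @classmethod
    def equal(cls, n: int) -> "BalanceVector":
        """The equal-importance baseline: every r_i = 0.5."""
        return cls(r=np.full(n, 0.5), provenance="fixed")

    def save(self, path: str | Path, seed: int | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance\t{self.provenance}\n")
            if seed is not None:
                fh.write(f"# seed\t{seed}\n")
            for i, ri in enumerate(self.r, start=1):
                fh.write(f"{i}\t{float(ri)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "BalanceVector":
        prov = "fixed"
        vals: dict[int, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split("\t")
                    if len(parts) == 2 and parts[0].strip() == "provenance":
                        prov = parts[1].strip()
                    continue
                code, v = line.split("\t")
                vals[int(code)] = float(v)
        r = np.array([vals[c] for c in sorted(vals)])
        return cls(r=r, provenance=prov)  # type: ignore[arg-type]


@dataclass(frozen=True)
class FusedVector:
    """One weighted concatenation [r*A, (1-r)*B] and its bookkeeping."""

    values: np.ndarray
    block_lengths: tuple[int, int]
    weight_used: float


def fuse_one(A: np.ndarray, B: np.ndarray, r: float) -> FusedVector:
    """Fuse two feature blocks with balance factor r in (0, 1)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.size == 0 or B.size == 0:
        raise ValueError("feature blocks must be non-empty")
    if not (0.0 < r < 1.0):
        raise ValueError(f"balance factor must lie in (0,1), got {r}")
    values = np.concatenate([r * A, (1.0 - r) * B])
    return FusedVector(values=values, block_lengths=(A.size, B.size), weight_used=r)


def fuse_dataset(
    blocksA: Mapping[str, np.ndarray],
    blocksB: Mapping[str, np.ndarray],
    labels: Mapping[str, int],
    R: BalanceVector,
    mode: FusionMode = "true-label",
) -> dict[str, np.ndarray]:
    """Fuse every sample of a dataset under one of the two weighting modes.

    true-label: returns id -> fused vector using r_{label(id)}.
    candidate-class: returns id -> (n, dA+dB) array of fused variants, row
    c-1 fused with candidate class c's factor.
    """
    if set(blocksA) != set(blocksB):
        raise ValueError("blocksA and blocksB must cover identical id sets")
    out: dict[str, np.ndarray] = {}
    if mode == "true-label":
        for sid in blocksA:
            if sid not in labels:
                raise ValueError(f"id {sid!r} has no label (true-label mode)")
            c = labels[sid]
            if not (1 <= c <= R.n):
                raise ValueError(f"id {sid!r}: label {c} outside 1..{R.n}")
            out[sid] = fuse_one(blocksA[sid], blocksB[sid], float(R.r[c - 1])).values
    elif mode == "candidate-class":
        for sid in blocksA:
            out[sid] = np.vstack(
                [
                    fuse_one(blocksA[sid], blocksB[sid], float(ri)).values
                    for ri in R.r
                ]
            )
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    return out


def clamp_open_unit(x: np.ndarray | float, eps: float = _EPS):
    """Clamp into the open interval (eps, 1-eps) required of balance factors."""
    return np.clip(x, eps, 1.0 - eps)
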