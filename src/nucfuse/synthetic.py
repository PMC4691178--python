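"""Seeded synthetic datasets of labeled sequences and score matrices.

The generator emulates the statistical structure the fusion model assumes:
every sub-nuclear location class may carry discriminative signal in its
residue composition (hence in DipC/PseAAC space), in its PSSM column
profile, or in any mixture of the two.  ``signal_split[c]`` sets that
mixture per class — 1.0 puts all of class c's signal in the
composition/sequence block, 0.0 puts it all in the PSSM block — which is
what makes balance-factor recovery testable: an optimizer should push r_c
up for composition-heavy classes and down for PSSM-heavy ones.

Sequences are drawn i.i.d. from a class-specific residue-frequency profile
whose deviation from uniform scales with signal_split·concentration.  Each
PSSM row is a shared base column profile plus a class-specific shift scaled
by (1−signal_split)·shift plus Gaussian noise, rounded and clipped to
[−16, 13], the range typical of log-odds substitution scores.  Everything
is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    CANONICAL_ALPHABET,
    LabeledDataset,
    PSSMMatrix,
    SequenceRecord,
    write_pssm_tsv,
)

SCORE_MIN, SCORE_MAX = -16, 13


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw."""

    n_classes: int = 3
    per_class: int = 10
    length_range: tuple[int, int] = (30, 80)
    composition_concentration: float = 1.0
    pssm_profile_shift: float = 3.0
    pssm_noise_sd: float = 1.0
    signal_split: tuple[float, ...] | None = None  # None -> 0.5 everywhere
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.per_class < 3:
            raise ValueError("per_class must be >= 3 for CV viability")
        lo, hi = self.length_range
        if lo < 12:
            raise ValueError(
                "length_range minimum must be >= 12 (PseAAC at lam=10 needs "
                "L >= 11, DipC needs L >= 2)"
            )
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        if self.signal_split is not None:
            if len(self.signal_split) != self.n_classes:
                raise ValueError("signal_split needs one entry per class")
            if any(not (0.0 <= s <= 1.0) for s in self.signal_split):
                raise ValueError("signal_split entries must lie in [0,1]")

    @property
    def splits(self) -> np.ndarray:
        if self.signal_split is None:
            return np.full(self.n_classes, 0.5)
        return np.asarray(self.signal_split, dtype=float)


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw one labeled dataset (sequences, PSSMs, class codes 1..n)."""
    rng = np.random.default_rng(spec.seed)
    splits = spec.splits
    lo, hi = spec.length_range
    alphabet = np.array(list(CANONICAL_ALPHABET))

    base_profile = rng.normal(0.0, 2.0, 20)  # shared PSSM column profile
    # class effects, ANOVA-style: deviations are centered across the classes
    # that carry them, so the shared base is the grand mean and "no
    # deviation" is the centroid of the class cloud, never a signature of
    # its own.  Centering is skipped when fewer than two classes carry a
    # deviation (it would erase the only signal).
    comp_logits = np.vstack(
        [
            splits[c] * spec.composition_concentration * rng.normal(0.0, 1.0, 20)
            for c in range(spec.n_classes)
        ]
    )
    pssm_shifts = np.vstack(
        [
            (1.0 - splits[c]) * spec.pssm_profile_shift * rng.normal(0.0, 1.0, 20)
            for c in range(spec.n_classes)
        ]
    )
    for effects, active in (
        (comp_logits, splits > 0.0),
        (pssm_shifts, splits < 1.0),
    ):
        if active.sum() >= 2:
            effects[active] -= effects[active].mean(axis=0)

    records: list[SequenceRecord] = []
    pssms: dict[str, PSSMMatrix] = {}
    labels: dict[str, int] = {}
    for c in range(spec.n_classes):
        comp = np.exp(comp_logits[c])
        comp /= comp.sum()
        pssm_shift = pssm_shifts[c]
        for j in range(spec.per_class):
            sid = f"c{c + 1}s{j + 1:03d}"
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(alphabet[rng.choice(20, size=L, p=comp)])
            scores = (
                base_profile
                + pssm_shift
                + rng.normal(0.0, spec.pssm_noise_sd, (L, 20))
            )
            scores = np.clip(np.rint(scores), SCORE_MIN, SCORE_MAX)
            records.append(SequenceRecord(id=sid, sequence=seq))
            pssms[sid] = PSSMMatrix(id=sid, scores=scores, provenance="synthetic")
            labels[sid] = c + 1
    return LabeledDataset(
        records=records,
        pssms=pssms,
        labels=labels,
        label_names={c + 1: str(c + 1) for c in range(spec.n_classes)},
    )


def write_fixture(
    dataset: LabeledDataset, directory: str | Path, overwrite: bool = False
) -> None:
    """Write a dataset as FASTA + tsv-matrix PSSMs + label TSV.

    The layout is exactly what :func:`nucfuse.io_formats.load_dataset`
    expects, and the round trip is lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace it"
        )
    with open(directory / "sequences.fasta", "w") as fh:
        for rec in dataset.records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    with open(directory / "labels.tsv", "w") as fh:
        for rec in dataset.records:
            fh.write(f"{rec.id}\t{dataset.labels[rec.id]}\n")
    pssm_dir = directory / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for sid, pssm in dataset.pssms.items():
        write_pssm_tsv(pssm, pssm_dir / f"{sid}.pssm")
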