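"""Readers, writers and domain containers for sequences, PSSMs and labels.

Residue indexing convention: the 20 native amino acids are numbered 1..20 by
the alphabetical order of their one-letter codes (A=1, C=2, ..., Y=20).
Every PSSM is remapped into this canonical column order on read, whatever
the source dialect.  All positions reported in error messages are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

#: One-letter codes of the 20 native amino acids, alphabetical.
CANONICAL_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the log-odds block in PSI-BLAST ASCII PSSM output.
PSIBLAST_ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

#: index into a canonical-order vector for each residue letter (0-based).
RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}

# permutation p such that canonical_column[j] = source_column[p[j]]
_PSIBLAST_TO_CANONICAL = np.array(
    [PSIBLAST_ALPHABET.index(aa) for aa in CANONICAL_ALPHABET]
)

ResiduePolicy = Literal["strict", "skip-unknown"]
PSSMDialect = Literal["psiblast-ascii", "tsv-matrix"]


class ParseError(ValueError):
    """A file did not match its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein identifier plus its validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = [
            (i + 1, ch)
            for i, ch in enumerate(self.sequence)
            if ch not in RESIDUE_INDEX
        ]
        if bad:
            pos, ch = bad[0]
            raise ValueError(
                f"record {self.id!r}: non-canonical residue {ch!r} at position {pos}"
            )

    @property
    def L(self) -> int:
        return len(self.sequence)

    def indices(self) -> np.ndarray:
        """Sequence as 0-based canonical residue indices."""
        return np.fromiter(
            (RESIDUE_INDEX[ch] for ch in self.sequence), dtype=np.intp, count=self.L
        )


@dataclass
class PSSMMatrix:
    """An L x 20 substitution-score matrix, columns in canonical order.

    ``scores[i, j]`` is the score that the residue at (1-based) position
    i+1 is substituted by amino-acid type ``CANONICAL_ALPHABET[j]``.
    """

    id: str
    scores: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.id!r}: expected an Lx20 matrix, got shape "
                f"{self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM {self.id!r}: matrix has no rows")

    @property
    def L(self) -> int:
        return int(self.scores.shape[0])


@dataclass
class LabeledDataset:
    """Sequences, their PSSMs and integer location codes 1..n."""

    records: list[SequenceRecord]
    pssms: dict[str, PSSMMatrix]
    labels: dict[str, int]
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        missing = [i for i in self.labels if i not in set(ids)]
        if missing:
            raise ValueError(f"labels reference unknown ids: {sorted(missing)}")
        codes = sorted(set(self.labels.values()))
        if len(codes) < 2:
            raise ValueError(f"need at least 2 location classes, got {len(codes)}")
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError(f"location codes must be 1..n, got {codes}")

    @property
    def n(self) -> int:
        return len(set(self.labels.values()))

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def class_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return dict(sorted(sizes.items()))

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def y(self) -> np.ndarray:
        """Label vector aligned with ``records`` order."""
        return np.array([self.labels[r.id] for r in self.records], dtype=int)


def read_fasta(path: str | Path, policy: ResiduePolicy = "strict") -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Under ``strict`` any character outside the 20-letter alphabet (including
    B, Z, X, U, O and ``*``) raises; under ``skip-unknown`` such characters
    are removed and a warning reports how many were dropped per record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if policy == "skip-unknown":
            kept = "".join(ch for ch in seq if ch in RESIDUE_INDEX)
            dropped = len(seq) - len(kept)
            if dropped:
                warnings.warn(
                    f"record {entry.id!r}: removed {dropped} non-canonical "
                    f"residue(s)",
                    stacklevel=2,
                )
            seq = kept
        elif policy != "strict":
            raise ValueError(f"unknown residue policy {policy!r}")
        if not seq:
            raise ParseError(f"record {entry.id!r}: empty sequence after policy")
        records.append(SequenceRecord(id=entry.id, sequence=seq))
    if not records and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records found (missing '>' header?)")
    return records


def _parse_psiblast_ascii(lines: Iterable[str], name: str) -> np.ndarray:
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        # data rows: position index, residue letter, >= 40 integers
        if len(fields) < 42:
            continue
        if not fields[0].isdigit() or fields[1].upper() not in RESIDUE_INDEX:
            continue
        try:
            ints = [int(x) for x in fields[2:42]]
        except ValueError as exc:
            raise ParseError(
                f"{name}: row {lineno}: expected 40 integer score fields"
            ) from exc
        rows.append(ints[:20])  # log-odds block only
    if not rows:
        raise ParseError(f"{name}: no PSSM data rows found")
    return np.array(rows, dtype=float)


def read_pssm(
    path: str | Path, dialect: PSSMDialect = "psiblast-ascii", id: str | None = None
) -> PSSMMatrix:
    """Read one PSSM, permuting columns into canonical alphabetical order.

    ``psiblast-ascii`` is the standard PSI-BLAST text layout; only the first
    20 integer columns per row (the log-odds block) are consumed.
    ``tsv-matrix`` is a header-less file of L rows x 20 tab-separated numbers
    already in canonical order.
    """
    path = Path(path)
    pid = id if id is not None else path.stem
    if dialect == "psiblast-ascii":
        with open(path) as fh:
            raw = _parse_psiblast_ascii(fh, str(path))
        scores = raw[:, _PSIBLAST_TO_CANONICAL]
        prov = "psiblast-ascii"
    elif dialect == "tsv-matrix":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 20:
                    raise ParseError(
                        f"{path}: row {lineno}: expected 20 tab-separated "
                        f"fields, got {len(fields)}"
                    )
                rows.append([float(x) for x in fields])
        if not rows:
            raise ParseError(f"{path}: empty tsv-matrix file")
        scores = np.array(rows)
        prov = "tsv-matrix"
    else:
        raise ValueError(f"unknown PSSM dialect {dialect!r}")
    return PSSMMatrix(id=pid, scores=scores, provenance=prov)


def write_pssm_tsv(pssm: PSSMMatrix, path: str | Path) -> None:
    """Write a PSSM in the tsv-matrix dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        for row in pssm.scores:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (sequence id, location label)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: row {lineno}: expected 2 tab-separated columns"
                )
            sid, label = fields
            if sid in out:
                raise ParseError(f"{path}: duplicate id {sid!r} at row {lineno}")
            out[sid] = label
    return out


def load_dataset(
    fasta: str | Path,
    pssm_dir: str | Path,
    labels: str | Path,
    policy: ResiduePolicy = "strict",
    dialect: PSSMDialect = "tsv-matrix",
    strict: bool = True,
) -> LabeledDataset:
    """Assemble and cross-validate a full labeled dataset.

    PSSM files are looked up in ``pssm_dir`` as ``<id>.pssm``.  Labels may
    be arbitrary strings; they are mapped to integer codes 1..n by sorted
    order (numeric strings sort numerically).  Ids labeled but missing a
    sequence or PSSM raise in strict mode, otherwise are dropped with a
    warning.
    """
    records = read_fasta(fasta, policy=policy)
    by_id = {r.id: r for r in records}
    raw_labels = read_labels(labels)
    pssm_dir = Path(pssm_dir)

    missing_seq = sorted(set(raw_labels) - set(by_id))
    if missing_seq:
        if strict:
            raise ValueError(f"labels reference ids with no sequence: {missing_seq}")
        warnings.warn(f"dropping {len(missing_seq)} label(s) with no sequence")
        raw_labels = {k: v for k, v in raw_labels.items() if k not in missing_seq}

    pssms: dict[str, PSSMMatrix] = {}
    missing_pssm: list[str] = []
    ext = ".pssm"
    for sid in raw_labels:
        p = pssm_dir / f"{sid}{ext}"
        if p.exists():
            pssms[sid] = read_pssm(p, dialect=dialect, id=sid)
        else:
            missing_pssm.append(sid)
    if missing_pssm:
        if strict:
            raise ValueError(f"ids missing a PSSM file: {sorted(missing_pssm)}")
        warnings.warn(f"dropping {len(missing_pssm)} id(s) with no PSSM")
        raw_labels = {k: v for k, v in raw_labels.items() if k not in missing_pssm}

    def _key(v: str):
        try:
            return (0, float(v), "")
        except ValueError:
            return (1, 0.0, v)

    uniq = sorted(set(raw_labels.values()), key=_key)
    code_of = {name: i + 1 for i, name in enumerate(uniq)}
    labeled_ids = set(raw_labels)
    kept = [r for r in records if r.id in labeled_ids]
    unlabeled = len(records) - len(kept)
    if unlabeled:
        warnings.warn(f"ignoring {unlabeled} sequence(s) with no label")
    return LabeledDataset(
        records=kept,
        pssms=pssms,
        labels={sid: code_of[v] for sid, v in raw_labels.items()},
        label_names={c: name for name, c in code_of.items()},
    )
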