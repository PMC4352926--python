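"""Sequence I/O, Voss indicator-sequence encoding, and mutation operators.

A DNA string over {A, C, G, T} is mapped to four binary indicator series
x_A(k), x_C(k), x_G(k), x_T(k) — a 1 at position k marks the presence of that
base.  Stacked in the fixed row order A, C, G, T they form a 4 x N binary
image on which image descriptors (HOG, LBP) are computed downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
ROW_ORDER = {base: i for i, base in enumerate(ALPHABET)}

#: Six-class label scheme: index i is the one-hot position of the ANN target
#: vector and i + 1 is the integer SVM target.
CLASS_NAMES = (
    "normal",
    "EGFR_deletion",
    "EGFR_substitution",
    "KRAS_substitution",
    "TP53_deletion",
    "TP53_substitution",
)
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


class SequenceError(ValueError):
    """Invalid sequence content or malformed sequence file."""


class MutationSpecError(ValueError):
    """Mutation specification inconsistent with its reference."""


class VossMatrixError(ValueError):
    """Matrix violating the Voss indicator invariants."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence with a record identifier."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, b in enumerate(self.bases):
            if b not in ROW_ORDER:
                raise SequenceError(
                    f"record {self.id!r}: invalid base {b!r} at position "
                    f"{pos + 1} (alphabet is A/C/G/T)"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MutationSpec:
    """A single substitution or contiguous deletion, 0-based coordinates."""

    kind: str  # "substitution" | "deletion"
    position: int
    alt_base: str | None = None
    del_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion"):
            raise MutationSpecError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "substitution":
            if self.alt_base not in ROW_ORDER:
                raise MutationSpecError(
                    f"substitution needs alt_base in A/C/G/T, got {self.alt_base!r}"
                )
        else:
            if self.del_length is None or self.del_length < 1:
                raise MutationSpecError("deletion needs del_length >= 1")

    def validate_against(self, ref: NucleotideSequence) -> None:
        n = len(ref)
        if not 0 <= self.position < n:
            raise MutationSpecError(
                f"position {self.position} outside reference of length {n}"
            )
        if self.kind == "substitution":
            if ref.bases[self.position] == self.alt_base:
                raise MutationSpecError(
                    f"substitution at {self.position} to {self.alt_base!r} "
                    "equals the reference base (no-op forbidden)"
                )
        else:
            if self.position + self.del_length > n:
                raise MutationSpecError(
                    f"deletion of {self.del_length} at {self.position} runs "
                    f"past the reference end ({n})"
                )


@dataclass(frozen=True)
class ClassLabel:
    """One of the six mutation classes with its target encodings."""

    name: str
    index: int = field(init=False)

    def __post_init__(self) -> None:
        if self.name not in CLASS_INDEX:
            raise ValueError(f"unknown class {self.name!r}")
        object.__setattr__(self, "index", CLASS_INDEX[self.name])

    @property
    def ann_target(self) -> np.ndarray:
        v = np.zeros(len(CLASS_NAMES))
        v[self.index] = 1.0
        return v

    @property
    def svm_target(self) -> int:
        return self.index + 1


def one_hot_targets(labels, class_order=CLASS_NAMES) -> np.ndarray:
    """Target matrix of one-hot rows for integer indices or class names."""
    order = list(class_order)
    out = np.zeros((len(labels), len(order)))
    for i, lab in enumerate(labels):
        j = lab if isinstance(lab, (int, np.integer)) else order.index(lab)
        out[i, j] = 1.0
    return out


# ---------------------------------------------------------------------------
# FASTA / label-table I/O


def read_fasta(path) -> list[NucleotideSequence]:
    """Read FASTA records in file order, upper-casing and validating bases."""
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise SequenceError(
                f"{path}: line 1 is not a FASTA header (expected '>')"
            )
        fh.seek(0)
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return [NucleotideSequence(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), 70):
                fh.write(s.bases[i : i + 70] + "\n")


def read_label_table(path) -> dict[str, str]:
    """Tab-separated (record id, class name) table -> id -> class name."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rec_id, cls = parts[0], parts[1]
            if cls not in CLASS_INDEX:
                raise SequenceError(f"{path}:{lineno}: unknown class {cls!r}")
            labels[rec_id] = cls
    return labels


# ---------------------------------------------------------------------------
# Voss encoding


def voss_encode(seq: NucleotideSequence | str) -> np.ndarray:
    """Encode a sequence as the 4 x N binary indicator matrix (rows A,C,G,T)."""
    if isinstance(seq, str):
        seq = NucleotideSequence("_", seq)
    idx = np.fromiter((ROW_ORDER[b] for b in seq.bases), dtype=np.intp, count=len(seq))
    m = np.zeros((4, len(seq)), dtype=np.uint8)
    m[idx, np.arange(len(seq))] = 1
    return m


def voss_decode(matrix: np.ndarray, id: str = "decoded") -> NucleotideSequence:
    """Invert :func:`voss_encode`; raises on any column not summing to 1."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != 4:
        raise VossMatrixError(f"expected a 4 x N matrix, got shape {m.shape}")
    col_sums = m.sum(axis=0)
    bad = np.nonzero(col_sums != 1)[0]
    if bad.size:
        raise VossMatrixError(
            f"column {int(bad[0])} sums to {int(col_sums[bad[0]])}, expected 1"
        )
    bases = "".join(ALPHABET[i] for i in np.argmax(m, axis=0))
    return NucleotideSequence(id, bases)


def write_matrix_text(matrix: np.ndarray, path) -> None:
    """Debug dump: one 0/1 row per nucleotide indicator (A, C, G, T)."""
    np.savetxt(path, np.asarray(matrix), fmt="%d")


# ---------------------------------------------------------------------------
# Mutation operators


def apply_mutation(ref: NucleotideSequence, spec: MutationSpec,
                   id: str | None = None) -> NucleotideSequence:
    """Apply a substitution or deletion to a reference; pure (ref untouched)."""
    spec.validate_against(ref)
    b = ref.bases
    if spec.kind == "substitution":
        bases = b[: spec.position] + spec.alt_base + b[spec.position + 1 :]
    else:
        bases = b[: spec.position] + b[spec.position + spec.del_length :]
    return NucleotideSequence(id or f"{ref.id}_mut", bases)
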