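"""Seeded six-class synthetic corpus emulating a real mutation database's structure.

Three uniform-random reference "genes" stand in for the EGFR/KRAS/TP53
coding sequences (lengths 3633, 567, and 1182); the five mutation classes
are generated by applying seeded single-event substitutions or contiguous
deletions to the matching reference, and the normal class pools unmutated
copies of all three genes under one label.  The whole corpus is a pure
function of its configuration (including the seed), so every downstream
module is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import (ALPHABET, CLASS_NAMES, MutationSpec, NucleotideSequence,
                       apply_mutation, read_fasta, read_label_table, write_fasta)

#: Reference coding-sequence lengths emulated by the generator.
GENE_LENGTHS = {"EGFR": 3633, "KRAS": 567, "TP53": 1182}

#: Acquired mutation-sample counts per class in the emulated database.
ACQUIRED_COUNTS = {
    "EGFR_deletion": 2640,
    "EGFR_substitution": 975,
    "KRAS_substitution": 2472,
    "TP53_deletion": 42,
    "TP53_substitution": 277,
}

#: Unique-sample subset sizes per class in the emulated database.
UNIQUE_COUNTS = {
    "EGFR_deletion": 35,
    "EGFR_substitution": 27,
    "KRAS_substitution": 28,
    "TP53_deletion": 32,
    "TP53_substitution": 35,
}

MUTATION_CLASSES = tuple(ACQUIRED_COUNTS)


class CorpusConfigError(ValueError):
    """Invalid corpus configuration."""


class CapacityError(ValueError):
    """Requested more unique samples than distinct mutants exist."""


def scaled_class_counts(scale: float) -> dict[str, int]:
    """Acquired-count proportions scaled by ``scale``, nearest integer."""
    if scale <= 0:
        raise CorpusConfigError("scale must be > 0")
    return {cls: int(round(n * scale)) for cls, n in ACQUIRED_COUNTS.items()}


def default_class_counts() -> dict[str, int]:
    """Desk-scale defaults: acquired proportions at scale 0.047 (~300
    mutation samples) plus 21 normal samples (7 per gene)."""
    return {"normal": 21, **scaled_class_counts(0.047)}


@dataclass
class CorpusConfig:
    """Generator settings; the corpus is a pure function of this object."""

    gene_lengths: dict = field(default_factory=lambda: dict(GENE_LENGTHS))
    class_counts: dict = field(default_factory=default_class_counts)
    unique_only: bool = False
    deletion_length_range: tuple = (3, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, length in self.gene_lengths.items():
            if length < 10:
                raise CorpusConfigError(
                    f"gene {gene}: length {length} is below the descriptor minimum")
        for cls, count in self.class_counts.items():
            if cls not in CLASS_NAMES:
                raise CorpusConfigError(f"unknown class {cls!r}")
            if count < 1:
                raise CorpusConfigError(f"class {cls}: count must be >= 1")
        lo, hi = self.deletion_length_range
        if not 1 <= lo <= hi:
            raise CorpusConfigError("deletion_length_range must satisfy 1 <= lo <= hi")
        if hi >= min(self.gene_lengths.values()):
            raise CorpusConfigError(
                "maximum deletion length must be shorter than the shortest gene")


@dataclass
class SyntheticCorpus:
    """References, labeled samples, and per-sample mutation provenance."""

    references: dict  # gene name -> NucleotideSequence
    samples: list  # list of NucleotideSequence
    labels: list  # parallel list of class names
    manifest: pd.DataFrame
    config: CorpusConfig


def _gene_of(class_name: str) -> str:
    return class_name.split("_")[0]


def generate_references(cfg: CorpusConfig) -> dict[str, NucleotideSequence]:
    """Seeded uniform-random references at the configured lengths."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    refs = {}
    for gene, length in cfg.gene_lengths.items():
        bases = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
        refs[gene] = NucleotideSequence(gene, bases)
    return refs


def _mutation_capacity(n: int, kind: str, del_range: tuple[int, int]) -> int:
    if kind == "substitution":
        return 3 * n
    lo, hi = del_range
    hi = min(hi, n)
    return sum(n - ln + 1 for ln in range(lo, hi + 1))


def _draw_spec(rng, ref: NucleotideSequence, kind: str,
               del_range: tuple[int, int]) -> MutationSpec:
    n = len(ref)
    if kind == "substitution":
        pos = int(rng.integers(0, n))
        choices = [b for b in ALPHABET if b != ref.bases[pos]]
        return MutationSpec("substitution", pos,
                            alt_base=choices[int(rng.integers(0, 3))])
    lo, hi = del_range
    length = int(rng.integers(lo, min(hi, n) + 1))
    pos = int(rng.integers(0, n - length + 1))
    return MutationSpec("deletion", pos, del_length=length)


def generate_corpus(cfg: CorpusConfig | None = None) -> SyntheticCorpus:
    """Draw the full labeled corpus: one mutation event per mutated sample."""
    cfg = cfg or CorpusConfig()
    refs = generate_references(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    samples, labels, rows = [], [], []

    for cls in CLASS_NAMES:
        count = cfg.class_counts.get(cls, 0)
        if count == 0:
            continue
        if cls == "normal":
            genes = list(refs)
            if cfg.unique_only and count > len(genes):
                raise CapacityError(
                    f"normal: {count} unique samples requested but only "
                    f"{len(genes)} distinct references exist")
            for i in range(count):
                gene = genes[i % len(genes)]
                seq = NucleotideSequence(f"normal_{gene}_{i:04d}", refs[gene].bases)
                samples.append(seq)
                labels.append(cls)
                rows.append({"id": seq.id, "gene": gene, "class": cls,
                             "kind": "none", "position": -1, "alt_base": "",
                             "del_length": 0})
            continue
        gene = _gene_of(cls)
        ref = refs[gene]
        kind = "deletion" if cls.endswith("deletion") else "substitution"
        if cfg.unique_only:
            capacity = _mutation_capacity(len(ref), kind, cfg.deletion_length_range)
            if count > capacity:
                raise CapacityError(
                    f"{cls}: {count} unique samples requested but only "
                    f"{capacity} distinct mutants exist")
        seen: set[str] = set()
        i = 0
        while i < count:
            spec = _draw_spec(rng, ref, kind, cfg.deletion_length_range)
            seq = apply_mutation(ref, spec, id=f"{cls}_{i:04d}")
            if cfg.unique_only:
                if seq.bases in seen:
                    continue
                seen.add(seq.bases)
            samples.append(seq)
            labels.append(cls)
            rows.append({"id": seq.id, "gene": gene, "class": cls,
                         "kind": spec.kind, "position": spec.position,
                         "alt_base": spec.alt_base or "",
                         "del_length": spec.del_length or 0})
            i += 1

    manifest = pd.DataFrame(rows)
    return SyntheticCorpus(references=refs, samples=samples, labels=labels,
                           manifest=manifest, config=cfg)


def write_fixture(corpus: SyntheticCorpus, directory) -> dict:
    """Write FASTA + TSV label table + TSV manifest; round-trips via
    :func:`vosshog.encoding.read_fasta`."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "references": directory / "references.fasta",
        "samples": directory / "samples.fasta",
        "labels": directory / "labels.tsv",
        "manifest": directory / "manifest.tsv",
    }
    write_fasta(corpus.references.values(), paths["references"])
    write_fasta(corpus.samples, paths["samples"])
    with open(paths["labels"], "w") as fh:
        for seq, label in zip(corpus.samples, corpus.labels):
            fh.write(f"{seq.id}\t{label}\n")
    manifest = corpus.manifest.copy()
    manifest["seed"] = corpus.config.seed
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths


def load_fixture(directory) -> tuple[list[NucleotideSequence], list[str]]:
    """Read back a written fixture as (samples, labels)."""
    from pathlib import Path

    directory = Path(directory)
    samples = read_fasta(directory / "samples.fasta")
    table = read_label_table(directory / "labels.tsv")
    return samples, [table[s.id] for s in samples]
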