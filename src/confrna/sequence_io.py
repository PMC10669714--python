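"""Labeled RNA sequence I/O and stratified cross-validation fold plans.

Sequences live in FASTA; family labels come either from the header
(``>id|family``) or from a two-column TSV (id, family).  On ingest,
DNA-style ``T`` is normalized to ``U`` and lowercase is folded; anything
outside {A, C, G, U} after normalization is rejected — IUPAC ambiguity
codes are not accepted because the model's alphabet is the four
nucleotides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "SequenceRecord",
    "LabeledDataset",
    "FoldPlan",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "write_label_table",
    "make_folds",
    "write_fold_plan",
    "read_fold_plan",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled RNA sequence over the alphabet {A, C, G, U}."""

    id: str
    family: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in RNA_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """An ordered collection of records plus the family label vocabulary."""

    records: list[SequenceRecord]
    families: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.families:
            seen: dict[str, None] = {}
            for rec in self.records:
                seen.setdefault(rec.family, None)
            self.families = list(seen)
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate family labels in vocabulary")
        known = set(self.families)
        ids: set[str] = set()
        for rec in self.records:
            if rec.family not in known:
                raise ValueError(f"record {rec.id!r}: family {rec.family!r} not in vocabulary")
            if rec.id in ids:
                raise ValueError(f"duplicate record id {rec.id!r}")
            ids.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_family(self) -> dict[str, list[SequenceRecord]]:
        groups: dict[str, list[SequenceRecord]] = {f: [] for f in self.families}
        for rec in self.records:
            groups[rec.family].append(rec)
        return groups

    def subset(self, ids) -> "LabeledDataset":
        wanted = set(ids)
        return LabeledDataset(
            [r for r in self.records if r.id in wanted], list(self.families)
        )

    def labels_as_indices(self) -> np.ndarray:
        index = {f: i for i, f in enumerate(self.families)}
        return np.array([index[r.family] for r in self.records], dtype=np.intp)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every record id to one of ``n_folds`` folds."""

    n_folds: int
    assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold_index: int) -> list[str]:
        return [rid for rid, f in self.assignments.items() if f == fold_index]

    def split(self, fold_index: int) -> tuple[list[str], list[str]]:
        """(train ids, test ids) for one CV rotation."""
        if not 0 <= fold_index < self.n_folds:
            raise ValueError(f"fold index {fold_index} outside [0, {self.n_folds})")
        train, test = [], []
        for rid, f in self.assignments.items():
            (test if f == fold_index else train).append(rid)
        return train, test


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase, map T->U, and validate against {A,C,G,U}."""
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"record {record_id!r}: invalid character {ch!r} at position {pos} "
                "after T->U normalization"
            )
    return seq


def read_label_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, family) -> mapping."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"label table row {row!r}: expected two columns")
            labels[row[0]] = row[1]
    return labels


def write_label_table(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rec in dataset:
            writer.writerow([rec.id, rec.family])


def read_fasta(path: str | Path, label_source: str | Path = "header") -> LabeledDataset:
    """Read a labeled dataset from FASTA.

    ``label_source`` is either the string ``"header"`` (family taken from
    a ``>id|family`` header) or a path to a two-column TSV mapping id to
    family.
    """
    table = None if label_source == "header" else read_label_table(label_source)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        name = entry.id
        if table is None:
            if "|" not in name:
                raise ValueError(
                    f"record {name!r}: header carries no '|family' label and no "
                    "label table was given"
                )
            rid, family = name.split("|", 1)
        else:
            rid = name
            if rid not in table:
                raise ValueError(f"record {rid!r}: missing from the label table")
            family = table[rid]
        records.append(SequenceRecord(rid, family, normalize_residues(str(entry.seq), rid)))
    if not records:
        raise ValueError(f"no records in {path}")
    return LabeledDataset(records)


def write_fasta(dataset: LabeledDataset, path: str | Path, label_in_header: bool = True) -> None:
    entries = [
        _BioRecord(
            Seq(rec.residues),
            id=f"{rec.id}|{rec.family}" if label_in_header else rec.id,
            description="",
        )
        for rec in dataset
    ]
    SeqIO.write(entries, str(path), "fasta")


def make_folds(dataset: LabeledDataset, n_folds: int, seed: int) -> FoldPlan:
    """Stratified fold assignment: shuffle within family, deal round-robin.

    Per-family fold counts differ by at most one, so the smallest family
    (IRES-sized, in the emulated composition) contributes evenly to every
    rotation.  Deterministic given (dataset order, n_folds, seed).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for family, members in dataset.by_family().items():
        if len(members) < n_folds:
            raise ValueError(
                f"family {family!r} has {len(members)} members, fewer than {n_folds} folds"
            )
        order = rng.permutation(len(members))
        for deal, idx in enumerate(order):
            assignments[members[idx].id] = deal % n_folds
    # restore dataset order for a stable serialization
    assignments = {rec.id: assignments[rec.id] for rec in dataset}
    return FoldPlan(n_folds=n_folds, assignments=assignments, seed=seed)


def write_fold_plan(plan: FoldPlan, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["#n_folds", plan.n_folds, "seed", plan.seed])
        for rid, fold in plan.assignments.items():
            writer.writerow([rid, fold])


def read_fold_plan(path: str | Path) -> FoldPlan:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header = rows[0]
    return FoldPlan(
        n_folds=int(header[1]),
        assignments={rid: int(f) for rid, f in rows[1:]},
        seed=int(header[3]),
    )
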