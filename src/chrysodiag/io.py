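"""Readers and writers for the formats the pipeline touches.

Everything is validated on ingest and nothing is silently altered beyond the
two documented normalisations: residues are uppercased and U is mapped to T
(DNA-only pipeline).  Gaps (``-``) and IUPAC ambiguity codes are kept;
downstream operations decide their semantics.  All alignment coordinates in
this package are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "SequenceRecord",
    "MultiLocusAlignment",
    "PrimerTableRow",
    "CountTable",
    "read_fasta",
    "write_fasta",
    "read_primer_table",
    "write_primer_table",
    "read_count_table",
    "write_count_table",
]

#: IUPAC nucleotide one-letter codes mapped to the set of bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_ALIGNMENT_ALPHABET = frozenset(IUPAC_CODES) | {"-"}


def _normalise_residues(raw: str, *, where: str, allow_gaps: bool = True) -> str:
    residues = raw.upper().replace("U", "T")
    allowed = _ALIGNMENT_ALPHABET if allow_gaps else frozenset(IUPAC_CODES)
    for pos, ch in enumerate(residues):
        if ch not in allowed:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {pos} in {where}"
            )
    return residues


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence: an isolate at one locus.

    ``residues`` is an uppercase IUPAC DNA string; ``-`` is permitted only in
    alignments.  ``species_label`` is optional — panels may contain
    unassigned isolates.
    """

    id: str
    residues: str
    locus: str = ""
    species_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        object.__setattr__(
            self,
            "residues",
            _normalise_residues(self.residues, where=f"record {self.id!r}"),
        )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class MultiLocusAlignment:
    """Per-locus aligned sequences for a panel of isolates with a species map.

    ``partition`` maps isolate id to species name; isolates present in
    ``records`` but absent from the partition are reported by
    :meth:`unassigned_ids` rather than rejected.
    """

    loci: list[str]
    records: dict[str, list[SequenceRecord]]
    partition: dict[str, str]

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus not in self.records:
                raise ValueError(f"locus {locus!r} listed but has no records")
        for locus, recs in self.records.items():
            if not recs:
                raise ValueError(f"locus {locus!r} has no sequences")
            lengths = {len(r) for r in recs}
            if len(lengths) != 1:
                raise ValueError(
                    f"locus {locus!r}: unequal aligned lengths {sorted(lengths)}"
                )
            ids = [r.id for r in recs]
            if len(set(ids)) != len(ids):
                dup = next(i for i in ids if ids.count(i) > 1)
                raise ValueError(f"locus {locus!r}: duplicate isolate id {dup!r}")

    @property
    def species(self) -> list[str]:
        return sorted(set(self.partition.values()))

    def alignment_length(self, locus: str) -> int:
        return len(self.records[locus][0])

    def isolate_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for locus in self.loci:
            for rec in self.records[locus]:
                seen.setdefault(rec.id, None)
        return list(seen)

    def unassigned_ids(self) -> list[str]:
        return [i for i in self.isolate_ids() if i not in self.partition]

    def records_for_species(self, locus: str, species: str) -> list[SequenceRecord]:
        return [
            r for r in self.records[locus] if self.partition.get(r.id) == species
        ]

    def subset_species(self, keep: Iterable[str]) -> "MultiLocusAlignment":
        keep = set(keep)
        records = {
            locus: [r for r in recs if self.partition.get(r.id) in keep]
            for locus, recs in self.records.items()
        }
        partition = {k: v for k, v in self.partition.items() if v in keep}
        return MultiLocusAlignment(list(self.loci), records, partition)


@dataclass(frozen=True)
class PrimerTableRow:
    """One species-specific assay: primer pair, expected product, cycles."""

    set_name: str
    target_species: str
    forward_5to3: str
    reverse_5to3: str
    amplicon_length: int
    cycles: int

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward_5to3), ("reverse", self.reverse_5to3)):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(
                    f"assay {self.set_name!r}: {name} primer {seq!r} is not pure A/C/G/T"
                )
        if self.amplicon_length <= 0:
            raise ValueError(f"assay {self.set_name!r}: amplicon_length must be > 0")
        if self.cycles <= 0:
            raise ValueError(f"assay {self.set_name!r}: cycles must be > 0")

    @property
    def locus(self) -> str:
        """Locus targeted by the assay, taken from the ``locus_Species`` set name."""
        return self.set_name.split("_", 1)[0]


@dataclass
class CountTable:
    """Location x category integer counts feeding all statistics."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.row_labels)} rows x {len(self.col_labels)} cols"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValueError(
                    f"non-integer count at ({self.row_labels[bad[0]]!r}, "
                    f"{self.col_labels[bad[1]]!r})"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at ({self.row_labels[bad[0]]!r}, "
                f"{self.col_labels[bad[1]]!r})"
            )

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    def aggregate_rows(self, groups: Mapping[str, str]) -> "CountTable":
        """Sum rows into groups (e.g. stations into Underground lines).

        ``groups`` maps row label -> group label; group order follows first
        appearance in the existing row order.
        """
        missing = [r for r in self.row_labels if r not in groups]
        if missing:
            raise ValueError(f"rows without a group: {missing}")
        order: list[str] = []
        for r in self.row_labels:
            g = groups[r]
            if g not in order:
                order.append(g)
        mat = np.zeros((len(order), len(self.col_labels)), dtype=np.int64)
        for i, r in enumerate(self.row_labels):
            mat[order.index(groups[r])] += self.counts[i]
        return CountTable(order, list(self.col_labels), mat)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, locus: str = "") -> list[SequenceRecord]:
    """Read a (possibly aligned) FASTA file into validated records.

    Residues are uppercased and U is mapped to T; duplicate ids and
    non-IUPAC characters are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), locus=locus))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    out = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(out, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Primer tables (schema of the published assay table)

_PRIMER_COLUMNS = [
    "set_name",
    "target_species",
    "forward",
    "reverse",
    "amplicon_length",
    "cycles",
]


def read_primer_table(path: str | Path) -> list[PrimerTableRow]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PRIMER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing primer-table column(s) {missing}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            PrimerTableRow(
                set_name=r["set_name"],
                target_species=r["target_species"],
                forward_5to3=r["forward"].strip().upper(),
                reverse_5to3=r["reverse"].strip().upper(),
                amplicon_length=int(r["amplicon_length"]),
                cycles=int(r["cycles"]),
            )
        )
    return rows


def write_primer_table(rows: Sequence[PrimerTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "target_species": r.target_species,
                "forward": r.forward_5to3,
                "reverse": r.reverse_5to3,
                "amplicon_length": r.amplicon_length,
                "cycles": r.cycles,
            }
            for r in rows
        ],
        columns=_PRIMER_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count tables


def read_count_table(path: str | Path) -> CountTable:
    """Read a CSV count table: first column row labels, the rest integer counts.

    Rows or columns labelled ``total`` (case-insensitive) are stripped; they
    are re-derivable from the marginals.
    """
    df = pd.read_csv(path, index_col=0)
    keep_rows = [r for r in df.index if str(r).strip().lower() != "total"]
    keep_cols = [c for c in df.columns if str(c).strip().lower() != "total"]
    df = df.loc[keep_rows, keep_cols]
    for i, r in enumerate(df.index):
        for j, c in enumerate(df.columns):
            v = df.iat[i, j]
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise ValueError(f"{path}: non-numeric count {v!r} at ({r!r}, {c!r})")
            if fv != int(fv):
                raise ValueError(f"{path}: non-integer count {v!r} at ({r!r}, {c!r})")
            if fv < 0:
                raise ValueError(f"{path}: negative count {v!r} at ({r!r}, {c!r})")
    return CountTable(
        [str(r) for r in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=np.int64),
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index_label="location")
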