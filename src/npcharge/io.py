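"""Sequence and table input/output.

Protein sequences travel as :class:`ProteinRecord` objects (id, class label,
validated sequence over the 20-residue alphabet). Receptor-cargo complexes are
described by :class:`ComplexManifest` tables mapping a complex name to member
record ids with copy counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter residue codes, in alphabetical order.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes that may legally appear in real databases
#: but have no defined composition contribution.
AMBIGUOUS_RESIDUES: str = "BZXUO"

#: Class labels recognised downstream (free-form labels are tolerated but
#: these drive regime classification and plotting).
KNOWN_LABELS = (
    "importin",
    "exportin",
    "cargo",
    "complex_member",
    "nucleoporin_scaffold",
    "nucleoporin_fg",
    "fg_domain",
    "signaling",
    "background",
    "receptor_like",
    "cargo_like",
    "fg_nup_like",
    "unknown",
)


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with an optional class label.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header token before the first whitespace).
    sequence : str
        Upper-case sequence over the 20 standard residues.
    label : str
        Class tag used by the regime classifier and plots; ``"unknown"`` when
        no annotation is available.
    """

    id: str
    sequence: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        validate_sequence(self.sequence, record_id=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str, record_id: str = "?") -> None:
    """Raise ``ValueError`` unless *sequence* is non-empty standard residues."""
    if not sequence:
        raise ValueError(f"record '{record_id}': sequence is empty")
    bad = sorted(set(sequence) - set(STANDARD_RESIDUES))
    if bad:
        raise ValueError(
            f"record '{record_id}': invalid residue symbol(s) "
            + ", ".join(repr(b) for b in bad)
        )


def normalize_sequence(
    raw: str, record_id: str = "?", drop_ambiguous: bool = False
) -> str:
    """Upper-case *raw*, strip whitespace, and police the alphabet.

    Ambiguity codes (B, Z, X, U, O) are rejected by default because
    composition sums are ill-defined for them; with ``drop_ambiguous=True``
    they are removed with a warning instead. Any other non-residue symbol is
    always an error naming the offending character.
    """
    seq = "".join(raw.split()).upper()
    present_ambiguous = sorted(set(seq) & set(AMBIGUOUS_RESIDUES))
    if present_ambiguous and drop_ambiguous:
        warnings.warn(
            f"record '{record_id}': dropping ambiguous residue(s) "
            + ", ".join(present_ambiguous),
            stacklevel=2,
        )
        seq = "".join(c for c in seq if c not in AMBIGUOUS_RESIDUES)
    validate_sequence(seq, record_id=record_id)
    return seq


def read_fasta(
    path: str | Path,
    labels: Mapping[str, str] | None = None,
    drop_ambiguous: bool = False,
) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    The header token before the first whitespace becomes the record id;
    sequences are upper-cased and internal whitespace is removed. Duplicate
    ids and out-of-alphabet symbols raise ``ValueError``.

    Parameters
    ----------
    labels : mapping, optional
        id -> class label; records absent from the mapping get ``"unknown"``.
    drop_ambiguous : bool
        Drop B/Z/X/U/O with a warning instead of rejecting the record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate record id '{rid}' in {path}")
        seen.add(rid)
        seq = normalize_sequence(str(entry.seq), record_id=rid, drop_ambiguous=drop_ambiguous)
        label = labels.get(rid, "unknown") if labels else "unknown"
        records.append(ProteinRecord(id=rid, sequence=seq, label=label))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA (fixed line width so output is reproducible)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        for sr in seq_records:
            fh.write(f">{sr.id}\n")
            s = str(sr.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, label) tab-separated table into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} needs at least two columns")
    id_col, label_col = df.columns[0], df.columns[1]
    return dict(zip(df[id_col], df[label_col]))


@dataclass(frozen=True)
class ComplexManifest:
    """A named receptor-cargo complex: member records with copy counts."""

    name: str
    members: tuple[tuple[ProteinRecord, int], ...] = field(default_factory=tuple)
    label: str = "complex_member"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("complex name must be non-empty")
        if not self.members:
            raise ValueError(f"complex '{self.name}' has no members")
        for record, count in self.members:
            if count < 1:
                raise ValueError(
                    f"complex '{self.name}': copy count for '{record.id}' "
                    f"must be >= 1, got {count}"
                )

    @property
    def total_length(self) -> int:
        return sum(count * len(record) for record, count in self.members)


def load_complex_manifest(
    path: str | Path, records: Sequence[ProteinRecord]
) -> list[ComplexManifest]:
    """Parse a tab-separated manifest (complex, member id, copies).

    Every member id must resolve to a loaded record; unknown ids raise
    ``ValueError``. A header row is expected.
    """
    by_id = {r.id: r for r in records}
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"manifest {path} needs columns: complex, member, copies")
    name_col, member_col, copy_col = df.columns[:3]
    manifests: list[ComplexManifest] = []
    for name, group in df.groupby(name_col, sort=False):
        members = []
        for _, row in group.iterrows():
            mid = row[member_col]
            if mid not in by_id:
                raise ValueError(
                    f"complex '{name}': member id '{mid}' does not resolve "
                    "to a loaded record"
                )
            members.append((by_id[mid], int(row[copy_col])))
        manifests.append(ComplexManifest(name=str(name), members=tuple(members)))
    return manifests


def write_complex_manifest(manifests: Iterable[ComplexManifest], path: str | Path) -> None:
    rows = [
        {"complex": m.name, "member": rec.id, "copies": count}
        for m in manifests
        for rec, count in m.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
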