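"""Proteome ingestion: FASTA reading/writing, validation and cysteine indexing.

All internal residue coordinates are 0-based; report writers convert to
1-based numbering at the output boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids plus the ambiguity codes X/B/Z and
#: selenocysteine U.  'U' is deliberately *not* treated as cysteine
#: (see :func:`index_cysteines`).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")

_OS_RE = re.compile(r"\bOS=(.+?)(?:\s+[A-Z]{2}=|$)")


class ProteomeError(ValueError):
    """Raised for malformed proteome input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry.

    Parameters
    ----------
    id:
        Unique accession (text up to the first whitespace of the header).
    organism:
        Free-text organism label, parsed from a UniProt-style ``OS=`` token
        when present, otherwise supplied by the caller (may be empty).
    sequence:
        Upper-case amino-acid string over :data:`VALID_RESIDUES`.
    cys_positions:
        Strictly increasing 0-based indices of 'C' in ``sequence``.
    """

    id: str
    sequence: str
    organism: str = ""
    cys_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.id:
            raise ProteomeError("protein record has an empty id")
        if self.cys_positions is None:
            object.__setattr__(
                self, "cys_positions", tuple(index_cysteines(self.sequence))
            )
        for p in self.cys_positions:
            if self.sequence[p] != "C":
                raise ProteomeError(
                    f"record {self.id!r}: cys_positions index {p} is not 'C'"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)


@dataclass
class ProteomeSet:
    """An ordered collection of :class:`ProteinRecord` with unique ids."""

    label: str
    records: list[ProteinRecord]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ProteomeError(f"duplicate record id {r.id!r}")
            seen.add(r.id)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, keep: Iterable[str]) -> "ProteomeSet":
        keep = set(keep)
        return ProteomeSet(
            label=self.label,
            records=[r for r in self.records if r.id in keep],
            source=self.source,
        )


def index_cysteines(record_or_sequence: ProteinRecord | str) -> list[int]:
    """Return the ordered 0-based positions of 'C' residues.

    Ambiguity codes (X/B/Z) and selenocysteine (U) are not counted.
    """
    seq = (
        record_or_sequence.sequence
        if isinstance(record_or_sequence, ProteinRecord)
        else record_or_sequence
    )
    return [i for i, aa in enumerate(seq) if aa == "C"]


def _clean_sequence(rec_id: str, raw: str) -> str:
    seq = raw.upper()
    while seq.endswith("*"):  # terminal stop codon markers
        seq = seq[:-1]
    bad = set(seq) - VALID_RESIDUES
    if bad:
        ch = sorted(bad)[0]
        raise ProteomeError(
            f"record {rec_id!r} contains invalid residue character {ch!r}"
        )
    return seq


def _parse_organism(description: str) -> str:
    m = _OS_RE.search(description)
    return m.group(1).strip() if m else ""


def read_fasta(
    path: str | Path, label: str | None = None, organism: str = ""
) -> ProteomeSet:
    """Read a proteome from FASTA.

    Sequences are upper-cased, terminal '*' stop characters are stripped and
    file order is preserved.  Raises :class:`ProteomeError` on an empty file,
    a duplicate id, or residue characters outside the accepted alphabet.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(rec.id, str(rec.seq))
        org = _parse_organism(rec.description) or organism
        records.append(ProteinRecord(id=rec.id, sequence=seq, organism=org))
    if not records:
        raise ProteomeError(f"no sequences in {path}")
    return ProteomeSet(label=label or path.stem, records=records, source=str(path))


def write_fasta(proteome: ProteomeSet, path: str | Path, width: int = 60) -> None:
    """Write a proteome to FASTA with sequences wrapped at ``width`` columns."""
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in proteome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
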