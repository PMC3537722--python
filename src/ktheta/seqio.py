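"""Reading, validating, trimming, and writing DNA sequence alignments.

An :class:`Alignment` is a rectangular matrix of uppercase residues over the
DNA alphabet plus gap/ambiguity characters, with unique sequence identifiers.
It is the substrate for every distance and diversity computation in this
package.  FASTA parsing and writing go through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError

__all__ = [
    "Alignment",
    "TrimReport",
    "read_alignment",
    "write_alignment",
    "trim_to_shared_window",
]

#: characters treated as "no data" when locating the shared sequence window
EDGE_MISSING = frozenset(b"-.?N")

# base -> small integer code used by the distance machinery; anything that is
# not an unambiguous A/C/G/T maps to -1 and is excluded pairwise.
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase, defensive: residues are stored uppercase


@dataclass
class Alignment:
    """A rectangular DNA alignment.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, in input order.
    residues:
        ``(n, L)`` byte matrix (dtype ``S1``), stored uppercase.
    descriptions:
        Optional FASTA description strings (text after the first whitespace),
        retained for reports but ignored for identity.
    """

    ids: tuple[str, ...]
    residues: np.ndarray
    descriptions: tuple[str, ...] = ()
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        res = np.asarray(self.residues, dtype="S1")
        if res.ndim != 2:
            raise AlignmentError("residue matrix must be two-dimensional")
        self.residues = np.char.upper(res)
        if not self.descriptions:
            self.descriptions = ("",) * len(self.ids)
        else:
            self.descriptions = tuple(self.descriptions)
        n, L = self.residues.shape
        if n < 1 or L < 1:
            raise AlignmentError("alignment must contain at least one sequence and one column")
        if len(self.ids) != n:
            raise AlignmentError(f"{len(self.ids)} ids for {n} sequence rows")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence id(s): {', '.join(dupes)}")

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of sequences."""
        return self.residues.shape[0]

    @property
    def L(self) -> int:
        """Number of columns (sites)."""
        return self.residues.shape[1]

    @property
    def codes(self) -> np.ndarray:
        """``(n, L)`` int8 matrix: A,C,G,T -> 0..3; everything else -> -1."""
        if self._codes is None:
            self._codes = _ENCODE[self.residues.view(np.uint8)]
        return self._codes

    # -- accessors --------------------------------------------------------
    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"no sequence with id {seq_id!r}") from None

    def sequence(self, key: int | str) -> str:
        """Return one row as a string, by position or by id."""
        i = key if isinstance(key, int) else self.index(key)
        return self.residues[i].tobytes().decode("ascii")

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Row subset in the requested order (ids must exist)."""
        idx = [self.index(i) for i in ids]
        return Alignment(
            ids=tuple(self.ids[i] for i in idx),
            residues=self.residues[idx].copy(),
            descriptions=tuple(self.descriptions[i] for i in idx),
        )

    @classmethod
    def from_sequences(
        cls,
        records: Iterable[tuple[str, str]],
        descriptions: Sequence[str] | None = None,
    ) -> "Alignment":
        """Build an alignment from ``(id, sequence)`` pairs of equal length."""
        records = list(records)
        if not records:
            raise AlignmentError("no sequences given")
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            ref = len(records[0][1])
            bad = next(i for i, s in records if len(s) != ref)
            raise AlignmentError(f"unequal sequence lengths (offending record: {bad!r})")
        mat = np.array([list(s.encode("ascii")) for _, s in records], dtype=np.uint8)
        return cls(
            ids=tuple(i for i, _ in records),
            residues=mat.view("S1"),
            descriptions=tuple(descriptions) if descriptions else (),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.ids == other.ids and bool(np.array_equal(self.residues, other.residues))


@dataclass(frozen=True)
class TrimReport:
    """What :func:`trim_to_shared_window` removed.

    ``start``/``stop`` index the retained window, 0-based half-open; the
    human-readable summary reports 1-based inclusive coordinates.
    """

    original_columns: int
    start: int
    stop: int

    @property
    def kept_columns(self) -> int:
        return self.stop - self.start

    @property
    def dropped_before(self) -> int:
        return self.start

    @property
    def dropped_after(self) -> int:
        return self.original_columns - self.stop

    def summary(self) -> str:
        return (
            f"kept columns {self.start + 1}-{self.stop} of {self.original_columns} "
            f"({self.kept_columns} sites; dropped {self.dropped_before} leading, "
            f"{self.dropped_after} trailing)"
        )


def read_alignment(source, format: str = "fasta") -> Alignment:
    """Read an alignment from a path or handle.

    All records must have identical length; ids must be unique; residues are
    uppercased.  Record order is preserved.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            records = list(SeqIO.parse(fh, format))
    else:
        records = list(SeqIO.parse(source, format))
    if not records:
        raise AlignmentError("no sequences found in input")
    ref_len = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != ref_len:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {ref_len}: "
                "input is not a rectangular alignment"
            )
    descriptions = tuple(
        rec.description[len(rec.id) :].strip() if rec.description.startswith(rec.id) else rec.description
        for rec in records
    )
    return Alignment.from_sequences(
        [(rec.id, str(rec.seq)) for rec in records], descriptions=descriptions
    )


def write_alignment(aln: Alignment, dest, format: str = "fasta") -> None:
    """Write an alignment to a path or handle (FASTA by default)."""
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.ids[i], description=aln.descriptions[i])
        for i in range(aln.n)
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(records, fh, format)
    else:
        SeqIO.write(records, dest, format)


def _informative_span(row: np.ndarray) -> tuple[int, int]:
    """First/last+1 column of *row* holding an informative (non-missing) base."""
    missing = np.isin(row.view(np.uint8), np.frombuffer(bytes(EDGE_MISSING), dtype=np.uint8))
    informative = np.flatnonzero(~missing)
    if informative.size == 0:
        return (0, 0)
    return (int(informative[0]), int(informative[-1]) + 1)


def trim_to_shared_window(
    records: Alignment | Iterable[tuple[str, str]],
    coords: dict[str, int] | None = None,
) -> tuple[Alignment, TrimReport]:
    """Trim an alignment to the maximal contiguous window covered by every record.

    Records are assumed to sit on a common coordinate system with only leading
    and trailing data missing (gap characters or runs of ``N``).  When *coords*
    is given, each raw sequence is first placed at its 0-based start offset on
    a shared coordinate canvas padded with gaps.  Internal missing bases (a
    lone ``N`` inside the covered span) are retained, not trimmed.

    Returns the trimmed :class:`Alignment` plus a :class:`TrimReport` stating
    how many columns were dropped on either side.
    """
    if isinstance(records, Alignment):
        aln = records
    else:
        pairs = list(records)
        if coords:
            canvas_len = max(coords.get(i, 0) + len(s) for i, s in pairs)
            padded = []
            for seq_id, seq in pairs:
                start = coords.get(seq_id, 0)
                padded.append((seq_id, "-" * start + seq + "-" * (canvas_len - start - len(seq))))
            pairs = padded
        aln = Alignment.from_sequences(pairs)

    starts, stops = zip(*(_informative_span(aln.residues[i]) for i in range(aln.n)))
    lo, hi = max(starts), min(stops)
    if hi <= lo:
        raise AlignmentError("records share no common sequence window")
    report = TrimReport(original_columns=aln.L, start=lo, stop=hi)
    trimmed = Alignment(
        ids=aln.ids,
        residues=aln.residues[:, lo:hi].copy(),
        descriptions=aln.descriptions,
    )
    return trimmed, report
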