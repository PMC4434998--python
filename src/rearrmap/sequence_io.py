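"""FASTA input/output and alphabet preprocessing.

DNA sequences are held as plain uppercase strings over {A, C, G, T} after
preprocessing.  Any other byte (N, IUPAC ambiguity codes, gap characters,
lowercase soft-masking is upper-cased first) is replaced by a uniformly
distributed random nucleotide, so that such stretches carry maximal
information content and cannot spuriously match anything.  The original
locations of replaced bytes are retained as ``masked_intervals``.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte code (A=0, C=1, G=2, T=3) lookup for the 256 possible input bytes
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_CODE[_b] = _i
_CODE_TO_BYTE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Sequence:
    """A named DNA sequence with provenance metadata.

    Attributes
    ----------
    name:
        Label (FASTA header word, or a synthetic label).
    symbols:
        The sequence itself.  After :func:`replace_non_acgt` it contains
        only A, C, G, T.
    masked_intervals:
        Sorted, non-overlapping half-open intervals that originally held
        non-ACGT symbols before preprocessing.
    record_boundaries:
        Cumulative start offsets of the records that were concatenated to
        form this sequence (empty for a single record).
    """

    name: str
    symbols: str
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)
    record_boundaries: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.symbols)

    def codes(self) -> np.ndarray:
        """Return the sequence as a uint8 array with A=0, C=1, G=2, T=3.

        Requires a preprocessed (pure-ACGT) sequence.
        """
        arr = _BYTE_TO_CODE[np.frombuffer(self.symbols.encode("ascii"), dtype=np.uint8)]
        if arr.size and arr.max() > 3:
            raise ValueError(
                f"sequence {self.name!r} contains non-ACGT symbols; "
                "run replace_non_acgt first"
            )
        return arr


def read_fasta(path: str, concatenate: bool = False) -> Sequence:
    """Read a FASTA file into a single :class:`Sequence`.

    Symbols are upper-cased but otherwise left as found (non-ACGT bytes
    are still present); call :func:`replace_non_acgt` before modelling.

    Parameters
    ----------
    path:
        FASTA file (single- or multi-record, wrapped or unwrapped lines).
    concatenate:
        Join multiple records in file order into one sequence, recording
        each record's start offset in ``record_boundaries``.  Without this
        flag a multi-record file is an error.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
    if len(records) > 1 and not concatenate:
        raise ValueError(
            f"{path}: {len(records)} records found; pass concatenate=True to join them"
        )
    boundaries: list[int] = []
    parts: list[str] = []
    offset = 0
    for rec in records:
        boundaries.append(offset)
        parts.append(str(rec.seq).upper())
        offset += len(rec.seq)
    return Sequence(
        name=records[0].id,
        symbols="".join(parts),
        record_boundaries=boundaries if len(records) > 1 else [],
    )


def write_fasta(seq: Sequence, path: str, width: int = 60) -> None:
    """Write ``seq`` to ``path`` as FASTA with ``width``-column wrapping."""
    with open(path, "w") as fh:
        fh.write(f">{seq.name}\n")
        s = seq.symbols
        for i in range(0, len(s), width):
            fh.write(s[i : i + width] + "\n")


def _intervals_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open intervals of True runs in a boolean array."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def replace_non_acgt(seq: Sequence, seed: int = 1) -> Sequence:
    """Replace every non-ACGT symbol by a uniform random nucleotide.

    Length is preserved and the replaced runs are recorded in
    ``masked_intervals``.  Identical (sequence, seed) pairs yield
    identical output.
    """
    raw = np.frombuffer(seq.symbols.encode("ascii"), dtype=np.uint8)
    codes = _BYTE_TO_CODE[raw]
    mask = codes > 3
    if mask.any():
        rng = np.random.default_rng(seed)
        fill = rng.integers(0, 4, size=int(mask.sum()), dtype=np.uint8)
        out = raw.copy()
        out[mask] = _CODE_TO_BYTE[fill]
        symbols = out.tobytes().decode("ascii")
    else:
        symbols = seq.symbols
    return Sequence(
        name=seq.name,
        symbols=symbols,
        masked_intervals=_intervals_from_mask(mask),
        record_boundaries=list(seq.record_boundaries),
    )


def reverse_complement(seq: Sequence) -> Sequence:
    """Reverse-complement a preprocessed sequence (A<->T, C<->G).

    Masked intervals are mirrored into the new coordinate system, so the
    operation is an involution on the full record.
    """
    n = len(seq.symbols)
    mirrored = sorted((n - e, n - s) for s, e in seq.masked_intervals)
    return Sequence(
        name=seq.name,
        symbols=seq.symbols.translate(_COMPLEMENT)[::-1],
        masked_intervals=mirrored,
        record_boundaries=[],
    )
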