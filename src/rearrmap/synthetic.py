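"""Seeded generation of synthetic rearranged sequence pairs.

A target is assembled from a reference by an explicit edit script of
block operations: ``copy`` (direct or inverted, with optional point
substitutions), ``novel`` (fresh random sequence, information-unrelated
to the reference) and ``n_run`` (an all-N stretch, to exercise the
non-ACGT preprocessing).  The generator records the exact planted
intervals and orientations as ground truth, so recovery can be scored
against known breakpoints.

Substitution convention: a copied position selected at rate ``r`` is
replaced by a symbol drawn uniformly from the 3 OTHER nucleotides, so the
effective mismatch rate equals ``r`` exactly.  (The other common
convention, drawing from all 4, gives an effective rate of 3r/4.)

One global seed expands deterministically into an independent stream per
operation, so appending an operation never perturbs earlier blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np

from .profile import DIRECT, INVERTED
from .sequence_io import Sequence, _CODE_TO_BYTE, reverse_complement, write_fasta


@dataclass
class CopyOp:
    """Copy reference[src_start : src_start+length], optionally
    reverse-complemented, with i.i.d. point substitutions."""

    src_start: int
    length: int
    orientation: str = DIRECT
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in (DIRECT, INVERTED):
            raise ValueError(f"orientation must be direct|inverted, got {self.orientation}")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError(f"substitution_rate must be in [0,1], got {self.substitution_rate}")


@dataclass
class NovelOp:
    """A block of fresh i.i.d. random sequence."""

    length: int


@dataclass
class NRunOp:
    """A block of N's (emulates an unsequenced stretch)."""

    length: int


BlockOp = Union[CopyOp, NovelOp, NRunOp]
EditScript = list  # ordered list of BlockOp


@dataclass
class PlantedBlock:
    """Ground truth for one target block produced by one operation."""

    kind: str  # copy | novel | n_run
    target_start: int
    target_end: int
    ref_start: int | None = None
    ref_end: int | None = None
    orientation: str | None = None


def random_sequence(length: int, seed: int, name: str = "random") -> Sequence:
    """I.i.d. uniform sequence over {A,C,G,T}; reproducible per seed."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return Sequence(name=name, symbols=_CODE_TO_BYTE[codes].tobytes().decode("ascii"))


def _mutate(symbols: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0 or not symbols:
        return symbols
    from .sequence_io import _BYTE_TO_CODE

    codes = _BYTE_TO_CODE[np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)].copy()
    hit = rng.random(len(codes)) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # shift by 1..3 mod 4: uniform over the three other symbols
        shift = rng.integers(1, 4, size=n_hit, dtype=np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return _CODE_TO_BYTE[codes].tobytes().decode("ascii")


def apply_script(
    reference: Sequence, script: EditScript, seed: int, target_name: str = "target"
) -> tuple[Sequence, list[PlantedBlock]]:
    """Assemble a target block by block and record the planted truth.

    The returned target may contain N's (from ``n_run`` operations) and
    must then be preprocessed before modelling.  Truth intervals tile the
    target exactly, one per operation.
    """
    parts: list[str] = []
    truth: list[PlantedBlock] = []
    pos = 0
    for op_index, op in enumerate(script):
        rng = np.random.default_rng([seed, op_index])
        if isinstance(op, CopyOp):
            if not (0 <= op.src_start and op.src_start + op.length <= len(reference)):
                raise ValueError(
                    f"copy source [{op.src_start},{op.src_start + op.length}) outside "
                    f"reference of length {len(reference)}"
                )
            block = reference.symbols[op.src_start : op.src_start + op.length]
            if op.orientation == INVERTED:
                block = reverse_complement(Sequence("block", block)).symbols
            block = _mutate(block, op.substitution_rate, rng)
            truth.append(PlantedBlock("copy", pos, pos + op.length,
                                      op.src_start, op.src_start + op.length,
                                      op.orientation))
        elif isinstance(op, NovelOp):
            codes = rng.integers(0, 4, size=op.length, dtype=np.uint8)
            block = _CODE_TO_BYTE[codes].tobytes().decode("ascii")
            truth.append(PlantedBlock("novel", pos, pos + op.length))
        elif isinstance(op, NRunOp):
            block = "N" * op.length
            truth.append(PlantedBlock("n_run", pos, pos + op.length))
        else:
            raise TypeError(f"unknown operation type: {op!r}")
        parts.append(block)
        pos += len(block)
    return Sequence(name=target_name, symbols="".join(parts)), truth


# -- script and fixture serialization ----------------------------------------


def script_to_json(script: EditScript, path: str) -> None:
    ops = []
    for op in script:
        if isinstance(op, CopyOp):
            ops.append({"op": "copy", "src_start": op.src_start, "length": op.length,
                        "orientation": op.orientation,
                        "substitution_rate": op.substitution_rate})
        elif isinstance(op, NovelOp):
            ops.append({"op": "novel", "length": op.length})
        else:
            ops.append({"op": "n_run", "length": op.length})
    with open(path, "w") as fh:
        json.dump({"format": "rearrmap-script", "version": 1, "ops": ops}, fh, indent=1)


def script_from_json(path: str) -> EditScript:
    with open(path) as fh:
        doc = json.load(fh)
    script: EditScript = []
    for d in doc["ops"]:
        if d["op"] == "copy":
            script.append(CopyOp(d["src_start"], d["length"],
                                 d.get("orientation", DIRECT),
                                 d.get("substitution_rate", 0.0)))
        elif d["op"] == "novel":
            script.append(NovelOp(d["length"]))
        elif d["op"] == "n_run":
            script.append(NRunOp(d["length"]))
        else:
            raise ValueError(f"unknown op {d['op']!r} in {path}")
    return script


def write_fixture(
    reference: Sequence, target: Sequence, truth: list[PlantedBlock],
    ref_path: str, target_path: str, truth_path: str,
) -> None:
    """Write a generated pair as two FASTA files plus a truth TSV."""
    write_fasta(reference, ref_path)
    write_fasta(target, target_path)
    with open(truth_path, "w") as fh:
        fh.write("kind\ttarget_start\ttarget_end\tref_start\tref_end\torientation\n")
        for b in truth:
            rs = "" if b.ref_start is None else b.ref_start
            re_ = "" if b.ref_end is None else b.ref_end
            fh.write(f"{b.kind}\t{b.target_start}\t{b.target_end}\t{rs}\t{re_}\t{b.orientation or ''}\n")
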