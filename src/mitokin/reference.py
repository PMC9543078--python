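"""Circular mitochondrial reference sequences.

Positions are 1-based and inclusive, following the forensic rCRS
convention; the sequence is circular (position L is adjacent to position 1)
although circularity only matters when generating synthetic references —
comparisons operate on fixed 1..L coordinates.

Certain homopolymeric cytosine tracts in the hypervariable regions are
length-variable within and between individuals and are conventionally
excluded from forensic comparison; these are carried on the reference as
``masked_ranges``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"

#: HVI, HVII and HVIII C-stretch intervals (1-based, inclusive) masked from
#: comparison on a 16,569-position mitochondrial reference.
DEFAULT_MASKED_RANGES: tuple[tuple[int, int], ...] = (
    (16183, 16194),
    (302, 310),
    (568, 573),
)

RCRS_LENGTH = 16569


class ReferenceError(ValueError):
    """Invalid reference sequence or masked-range definition."""


@dataclass(frozen=True)
class CircularReference:
    """A circular DNA reference with 1-based coordinates and masked intervals.

    Parameters
    ----------
    name:
        Text label; haplotypes record this label so that two haplotypes are
        only ever compared against the same reference.
    sequence:
        Uppercase A/C/G/T string of length ``L >= 1``.
    masked_ranges:
        Inclusive 1-based intervals excluded from variant reporting and
        comparison. Defaults to the three hypervariable C-stretches when the
        sequence has the canonical 16,569-base length, else empty.
    """

    name: str
    sequence: str
    masked_ranges: tuple[tuple[int, int], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ReferenceError("reference sequence must be non-empty")
        if set(seq) - set(BASES):
            bad = sorted(set(seq) - set(BASES))
            raise ReferenceError(f"reference contains non-ACGT characters: {bad}")
        ranges = self.masked_ranges
        if ranges is None:
            ranges = DEFAULT_MASKED_RANGES if len(seq) == RCRS_LENGTH else ()
        ranges = tuple(tuple(r) for r in ranges)
        for lo, hi in ranges:
            if not (1 <= lo <= hi <= len(seq)):
                raise ReferenceError(f"masked range {lo}-{hi} outside [1, {len(seq)}]")
        object.__setattr__(self, "masked_ranges", ranges)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ReferenceError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]

    def is_masked(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.masked_ranges)

    @classmethod
    def from_fasta(cls, path, masked_ranges=None) -> "CircularReference":
        """Load a single-record FASTA file."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ReferenceError(f"expected exactly one FASTA record, found {len(records)}")
        rec = records[0]
        return cls(name=rec.id, sequence=str(rec.seq), masked_ranges=masked_ranges)

    def to_fasta(self, path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([rec], str(path), "fasta")


# Anchor bases required so that the variant tokens used by the bundled
# two-family fixture parse against the synthetic reference.
_FIXTURE_ANCHORS = {
    146: "T",
    2833: "A",
    8470: "A",
    8817: "A",
    9012: "T",
    16247: "A",
    16280: "A",
    16320: "C",
    16344: "C",
}


def bundled_reference() -> CircularReference:
    """Deterministic synthetic 16,569-base mitochondrial-like reference.

    The true rCRS sequence is not required by any computation here: positions
    act as labels. This sequence is generated from a fixed seed, with
    cytosine homopolymer tracts placed in the three masked hypervariable
    C-stretch intervals and fixed anchor bases at the positions used by the
    bundled fixtures. Users with the real rCRS can load it with
    :meth:`CircularReference.from_fasta` instead.
    """
    rng = np.random.default_rng(RCRS_LENGTH)
    seq = list(rng.choice(list(BASES), size=RCRS_LENGTH))
    for lo, hi in DEFAULT_MASKED_RANGES:
        seq[lo - 1 : hi] = "C" * (hi - lo + 1)
    for pos, base in _FIXTURE_ANCHORS.items():
        seq[pos - 1] = base
    return CircularReference(name="synthetic-mt-16569", sequence="".join(seq))
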