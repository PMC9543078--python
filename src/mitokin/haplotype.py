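"""Mitochondrial haplotypes as difference lists against a circular reference.

A haplotype is the set of positions at which a sample differs from the
reference, written in the forensic variant-string dialect:

* ``A16247G`` — substitution: reference ``A`` at 16247 replaced by ``G``;
* ``T146Y`` — point heteroplasmy: two bases present, encoded with the
  two-base IUPAC codes (R/Y/S/W/K/M);
* ``315.1C`` — insertion of ``C`` between positions 315 and 316 (ordinal
  suffixes ``.1``, ``.2``, … name successive inserted bases);
* ``249DEL`` — deletion of the reference base at 249;
* ``315.1C+`` — length heteroplasmy: a variable-length homopolymer
  insertion at that anchor (simulator-generated; none occur outside the
  masked C-stretches in real casework data modelled here).

Nomenclature normalisation follows forensic convention: insertions and
deletions inside a homopolymer run are re-anchored at the 3'-most
equivalent placement on the light strand, and variants inside the masked
hypervariable C-stretch intervals are dropped.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .reference import CircularReference

__all__ = [
    "IUPAC_CODES",
    "iupac_expand",
    "iupac_encode",
    "PositionCall",
    "VariantKind",
    "Variant",
    "MitoHaplotype",
    "parse_haplotype",
    "parse_haplotype_table",
    "encode_haplotype",
    "normalize",
    "call_at",
    "HaplotypeError",
    "UnsupportedIupacError",
    "MaskedPositionError",
]


class HaplotypeError(ValueError):
    """Malformed variant token, inconsistent haplotype, or bad query."""


class UnsupportedIupacError(HaplotypeError):
    """IUPAC code that is unknown or denotes more than two bases."""


class MaskedPositionError(HaplotypeError):
    """Query at a position inside a masked (C-stretch) range."""


#: Two-base IUPAC ambiguity codes plus the four unambiguous bases.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
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
}

_ALLELES_TO_CODE = {alleles: code for code, alleles in IUPAC_CODES.items()}


def iupac_expand(code: str) -> frozenset[str]:
    """Expand a one- or two-base IUPAC code to its allele set.

    Codes denoting three or four bases (N, B, D, H, V) are rejected:
    three-allele mixtures are unsupported in this comparison model.
    """
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise UnsupportedIupacError(
            f"unsupported IUPAC code {code!r}: only A/C/G/T and the "
            "two-base codes R/Y/S/W/K/M are allowed"
        ) from None


def iupac_encode(alleles: Iterable[str]) -> str:
    """Inverse of :func:`iupac_expand`: allele set -> single character."""
    key = frozenset(a.upper() for a in alleles)
    try:
        return _ALLELES_TO_CODE[key]
    except KeyError:
        raise UnsupportedIupacError(
            f"allele set {sorted(key)} has no supported IUPAC code"
        ) from None


@dataclass(frozen=True)
class PositionCall:
    """Base call at one reference position.

    Either homoplasmic (one allele) or a two-allele point heteroplasmy. For
    heteroplasmies the minor allele frequency ``maf`` (read fraction of the
    less-frequent base, in (0, 0.5]) and the identity of the minor allele
    may be recorded when known; both are ``None`` for calls parsed from
    variant strings, which carry no quantitative information.
    """

    position: int
    alleles: frozenset[str]
    maf: Optional[float] = None
    minor_allele: Optional[str] = None

    def __post_init__(self) -> None:
        alleles = frozenset(a.upper() for a in self.alleles)
        object.__setattr__(self, "alleles", alleles)
        if not alleles or len(alleles) > 2:
            raise HaplotypeError(
                f"a call carries 1 or 2 alleles, got {sorted(alleles)}"
            )
        if alleles - set("ACGT"):
            raise HaplotypeError(f"non-ACGT alleles: {sorted(alleles)}")
        if len(alleles) == 1:
            if self.maf is not None or self.minor_allele is not None:
                raise HaplotypeError("homoplasmic calls carry no MAF/minor allele")
        else:
            if self.maf is not None and not 0.0 < self.maf <= 0.5:
                raise HaplotypeError(f"MAF must lie in (0, 0.5], got {self.maf}")
            if self.minor_allele is not None and self.minor_allele not in alleles:
                raise HaplotypeError(
                    f"minor allele {self.minor_allele!r} not in {sorted(alleles)}"
                )

    @property
    def is_heteroplasmic(self) -> bool:
        return len(self.alleles) == 2

    @property
    def iupac(self) -> str:
        return iupac_encode(self.alleles)


class VariantKind(enum.Enum):
    SUBSTITUTION = "substitution"
    POINT_HETEROPLASMY = "point_heteroplasmy"
    INSERTION = "insertion"
    DELETION = "deletion"
    LENGTH_HETEROPLASMY = "length_heteroplasmy"


_POINT_KINDS = {VariantKind.SUBSTITUTION, VariantKind.POINT_HETEROPLASMY}


@dataclass(frozen=True)
class Variant:
    """One difference from the reference.

    Point kinds (substitution / point heteroplasmy) carry a
    :class:`PositionCall`; indel kinds carry the inserted base (insertions
    are single-base, named ``pos.ordinal``) or mark deletion of the
    reference base at ``position``. Length heteroplasmy is an insertion-like
    record whose copy number is variable within the individual.
    """

    kind: VariantKind
    position: int
    ordinal: int = 0
    call: Optional[PositionCall] = None
    base: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HaplotypeError(f"position must be >= 1, got {self.position}")
        if self.kind in _POINT_KINDS:
            if self.call is None or self.call.position != self.position:
                raise HaplotypeError("point variant requires a call at its position")
            if self.ordinal != 0:
                raise HaplotypeError("point variants take no ordinal suffix")
            want_het = self.kind is VariantKind.POINT_HETEROPLASMY
            if self.call.is_heteroplasmic != want_het:
                raise HaplotypeError(f"{self.kind.value} has wrong allele count")
        elif self.kind is VariantKind.DELETION:
            if self.ordinal != 0 or self.call is not None:
                raise HaplotypeError("deletion takes no ordinal or call")
        else:  # insertion / length heteroplasmy
            if self.ordinal < 1:
                raise HaplotypeError("insertion ordinal starts at 1")
            if self.base not in set("ACGT"):
                raise HaplotypeError(f"insertion requires one A/C/G/T base, got {self.base!r}")

    @property
    def is_point(self) -> bool:
        return self.kind in _POINT_KINDS

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.position, self.ordinal)

    def token(self, reference: CircularReference) -> str:
        """Render in the forensic variant-string dialect."""
        if self.is_point:
            ref = reference.base(self.position)
            return f"{ref}{self.position}{self.call.iupac}"
        if self.kind is VariantKind.DELETION:
            return f"{self.position}DEL"
        suffix = "+" if self.kind is VariantKind.LENGTH_HETEROPLASMY else ""
        return f"{self.position}.{self.ordinal}{self.base}{suffix}"


@dataclass(frozen=True)
class MitoHaplotype:
    """A sample's differences from a named reference.

    An empty variant tuple means identity with the reference over all
    unmasked, covered positions. ``no_call`` lists positions with missing
    coverage; these are excluded from comparison entirely.
    """

    sample_id: str
    variants: tuple[Variant, ...] = ()
    reference_name: str = ""
    no_call: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        variants = tuple(sorted(self.variants, key=lambda v: v.sort_key))
        object.__setattr__(self, "variants", variants)
        point_positions = [v.position for v in variants if v.is_point]
        if len(point_positions) != len(set(point_positions)):
            raise HaplotypeError(f"{self.sample_id}: duplicate point-variant position")
        keys = [v.sort_key for v in variants if not v.is_point]
        if len(keys) != len(set(keys)):
            raise HaplotypeError(f"{self.sample_id}: duplicate indel position/ordinal")

    @property
    def point_variants(self) -> dict[int, Variant]:
        return {v.position: v for v in self.variants if v.is_point}

    @property
    def indel_variants(self) -> dict[tuple[int, int], Variant]:
        return {v.sort_key: v for v in self.variants if not v.is_point}


_POINT_RE = re.compile(r"^([ACGT])(\d+)([ACGTRYSWKM])$")
_INS_RE = re.compile(r"^(\d+)\.(\d+)([ACGT])(\+?)$")
_DEL_RE = re.compile(r"^(\d+)DEL$")


def _ref_base_checked(reference: CircularReference, position: int, token: str) -> str:
    if not 1 <= position <= reference.length:
        raise HaplotypeError(
            f"token {token!r}: position {position} outside [1, {reference.length}]"
        )
    return reference.base(position)


def _parse_token(token: str, reference: CircularReference) -> Variant:
    tok = token.strip().upper()
    m = _POINT_RE.match(tok)
    if m:
        ref_base, pos_s, alt = m.groups()
        position = int(pos_s)
        actual = _ref_base_checked(reference, position, token)
        if actual != ref_base:
            raise HaplotypeError(
                f"token {token!r}: reference base is {actual}, not {ref_base}"
            )
        alleles = iupac_expand(alt)
        if len(alleles) == 1:
            if alleles == {ref_base}:
                raise HaplotypeError(f"token {token!r}: substitution equals reference")
            kind = VariantKind.SUBSTITUTION
        else:
            kind = VariantKind.POINT_HETEROPLASMY
        return Variant(kind=kind, position=position,
                       call=PositionCall(position=position, alleles=alleles))
    m = _INS_RE.match(tok)
    if m:
        pos_s, ord_s, base, lh = m.groups()
        position = int(pos_s)
        _ref_base_checked(reference, position, token)
        kind = VariantKind.LENGTH_HETEROPLASMY if lh else VariantKind.INSERTION
        return Variant(kind=kind, position=position, ordinal=int(ord_s), base=base)
    m = _DEL_RE.match(tok)
    if m:
        position = int(m.group(1))
        _ref_base_checked(reference, position, token)
        return Variant(kind=VariantKind.DELETION, position=position)
    raise HaplotypeError(f"malformed variant token {token!r}")


def parse_haplotype(
    text: str, reference: CircularReference, sample_id: str = "sample"
) -> MitoHaplotype:
    """Parse a whitespace-separated variant string into a haplotype.

    An empty string yields the reference-identical haplotype.
    """
    variants = tuple(_parse_token(tok, reference) for tok in text.split())
    return MitoHaplotype(sample_id=sample_id, variants=variants,
                         reference_name=reference.name)


def parse_haplotype_table(path, reference: CircularReference) -> dict[str, MitoHaplotype]:
    """Read a ``sample_id<TAB>tokens`` file, one sample per line."""
    haplotypes: dict[str, MitoHaplotype] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample_id, _, tokens = line.partition("\t")
            if sample_id in haplotypes:
                raise HaplotypeError(f"duplicate sample id {sample_id!r}")
            haplotypes[sample_id] = parse_haplotype(tokens, reference, sample_id)
    return haplotypes


def encode_haplotype(h: MitoHaplotype, reference: CircularReference) -> str:
    """Canonical variant-string rendering (position-sorted tokens)."""
    return " ".join(v.token(reference) for v in h.variants)


def write_haplotype_table(haplotypes: Mapping[str, MitoHaplotype],
                          reference: CircularReference, path) -> None:
    with open(path, "w") as fh:
        for sample_id in haplotypes:
            fh.write(f"{sample_id}\t{encode_haplotype(haplotypes[sample_id], reference)}\n")


def _shift_deletion_3prime(position: int, reference: CircularReference) -> int:
    # deleting ref[p] and ref[p+1] yield the same sequence iff the bases match
    p = position
    while p + 1 <= reference.length and reference.base(p + 1) == reference.base(p):
        p += 1
    return p


def _shift_insertion_3prime(position: int, base: str, reference: CircularReference) -> int:
    # inserting b after p equals inserting after p+1 iff ref[p+1] == b
    p = position
    while p + 1 <= reference.length and reference.base(p + 1) == base:
        p += 1
    return p


def normalize(h: MitoHaplotype, reference: CircularReference) -> MitoHaplotype:
    """Apply forensic nomenclature normalisation.

    Insertions and deletions inside homopolymer runs are re-anchored at the
    3'-most equivalent placement on the light strand; variants whose
    position lies in a masked range are removed; variants are
    position-sorted. Idempotent. Insertion groups with mixed bases at one
    anchor are left in place (only homopolymer placements are ambiguous).
    """
    shifted: list[Variant] = []
    # group insertions by original anchor so ordinals stay consecutive
    ins_groups: dict[int, list[Variant]] = {}
    for v in h.variants:
        if v.kind in (VariantKind.INSERTION, VariantKind.LENGTH_HETEROPLASMY):
            ins_groups.setdefault(v.position, []).append(v)
        elif v.kind is VariantKind.DELETION:
            shifted.append(replace(v, position=_shift_deletion_3prime(v.position, reference)))
        else:
            shifted.append(v)
    for anchor, group in ins_groups.items():
        bases = {v.base for v in group}
        if len(bases) == 1:
            new_anchor = _shift_insertion_3prime(anchor, group[0].base, reference)
        else:
            new_anchor = anchor
        for i, v in enumerate(sorted(group, key=lambda v: v.ordinal), start=1):
            shifted.append(replace(v, position=new_anchor, ordinal=i))
    kept = tuple(v for v in shifted if not reference.is_masked(v.position))
    return MitoHaplotype(sample_id=h.sample_id, variants=kept,
                         reference_name=h.reference_name,
                         no_call=h.no_call)


def call_at(h: MitoHaplotype, position: int, reference: CircularReference) -> PositionCall:
    """Effective call at a position: the variant's call if present, else the
    homoplasmic reference base."""
    if reference.is_masked(position):
        raise MaskedPositionError(f"position {position} lies in a masked range")
    reference.base(position)  # bounds check
    v = h.point_variants.get(position)
    if v is not None:
        return v.call
    return PositionCall(position=position, alleles=frozenset(reference.base(position)))
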