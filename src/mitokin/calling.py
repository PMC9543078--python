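"""Per-position base calling from read-count pileups.

Heteroplasmy is called purely on the minor allele frequency: a position is
heteroplasmic when the second-most-frequent base exceeds the MAF threshold
(strictly greater than, default 20%). No base-quality or strand model is
applied — the frequency threshold is the entire rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .haplotype import MitoHaplotype, PositionCall, Variant, VariantKind, normalize
from .reference import BASES, CircularReference


class PileupError(ValueError):
    """Pileup malformed or inconsistent with the reference."""


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds for MAF-based calling.

    maf_threshold:
        Minor allele fraction that must be *strictly exceeded* to call point
        heteroplasmy; default 0.20.
    min_depth:
        Positions with fewer reads are no-calls. Default 1: no minimum
        coverage is required, matching permissive forensic variant calling;
        raise it for casework-grade data.
    """

    maf_threshold: float = 0.20
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError(f"maf_threshold must be in [0, 0.5), got {self.maf_threshold}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass(frozen=True)
class Pileup:
    """Read counts per base over positions 1..L.

    ``counts`` is an (L, 4) integer array with columns ordered A, C, G, T.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise PileupError(f"counts must be (L, 4), got {counts.shape}")
        if (counts < 0).any():
            raise PileupError("negative read counts")
        counts.flags.writeable = False
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row(self, position: int) -> dict[str, int]:
        return dict(zip(BASES, (int(c) for c in self.counts[position - 1])))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(1, self.length + 1))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pileup":
        df = pd.read_csv(path, sep="\t")
        required = ["position", *BASES]
        if list(df.columns[:5]) != required:
            raise PileupError(f"pileup TSV must have columns {required}, got {list(df.columns)}")
        df = df.sort_values("position")
        if not np.array_equal(df["position"].to_numpy(), np.arange(1, len(df) + 1)):
            raise PileupError("pileup positions must cover 1..L without gaps")
        return cls(counts=df[list(BASES)].to_numpy())


def call_position(
    counts: Mapping[str, int], config: CallingConfig = CallingConfig(), position: int = 1
) -> Optional[PositionCall]:
    """Call one position from base counts; ``None`` signals a no-call.

    The top two bases b1, b2 are taken by count (ties broken by the fixed
    order A < C < G < T for determinism); with ``maf = count(b2)/depth`` the
    call is heteroplasmic {b1, b2} iff ``maf > maf_threshold``, else
    homoplasmic {b1}. Depth below ``min_depth`` (including zero coverage)
    is a no-call.
    """
    clean = {b: int(counts.get(b, 0)) for b in BASES}
    if any(c < 0 for c in clean.values()):
        raise PileupError(f"negative counts: {counts}")
    depth = sum(clean.values())
    if depth < config.min_depth or depth == 0:
        return None
    ordered = sorted(BASES, key=lambda b: (-clean[b], b))
    b1, b2 = ordered[0], ordered[1]
    maf = clean[b2] / depth
    if maf > config.maf_threshold:
        return PositionCall(position=position, alleles=frozenset((b1, b2)),
                            maf=maf, minor_allele=b2)
    return PositionCall(position=position, alleles=frozenset(b1))


def call_haplotype(
    pileup: Pileup,
    reference: CircularReference,
    config: CallingConfig = CallingConfig(),
    sample_id: str = "sample",
) -> MitoHaplotype:
    """Call every position of a pileup and collect differences from the
    reference into a normalised haplotype.

    No-call positions (depth below threshold) are recorded on the
    haplotype's ``no_call`` set and excluded from downstream comparison.
    Masked positions are skipped entirely.
    """
    if pileup.length != reference.length:
        raise PileupError(
            f"pileup covers {pileup.length} positions, reference has {reference.length}"
        )
    variants: list[Variant] = []
    no_call: set[int] = set()
    depths = pileup.depth()
    for position in range(1, reference.length + 1):
        if reference.is_masked(position):
            continue
        if depths[position - 1] < max(config.min_depth, 1):
            no_call.add(position)
            continue
        call = call_position(pileup.row(position), config, position=position)
        if call is None:
            no_call.add(position)
            continue
        ref_allele = frozenset(reference.base(position))
        if call.alleles == ref_allele:
            continue
        kind = (VariantKind.POINT_HETEROPLASMY if call.is_heteroplasmic
                else VariantKind.SUBSTITUTION)
        variants.append(Variant(kind=kind, position=position, call=call))
    h = MitoHaplotype(sample_id=sample_id, variants=tuple(variants),
                      reference_name=reference.name, no_call=frozenset(no_call))
    return normalize(h, reference)
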