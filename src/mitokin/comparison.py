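"""Pairwise haplotype comparison and three-tier outcome classification.

Two heteroplasmy-handling modes are supported, mirroring the two readings of
forensic guidelines:

* ``isfg`` — point (and length) heteroplasmy is not evidence of difference
  when an allele is shared: a heteroplasmic call conflicts with another call
  only when their allele sets are disjoint.
* ``strict`` — any inequality of calls counts, so a heteroplasmic call
  against a homoplasmic one is a difference even when they share a base.

The outcome for a pair depends only on the number of differing positions
(the SWGDAM counting rule): 0 differences -> cannot exclude from the same
maternal lineage, exactly 1 -> inconclusive, 2 or more -> exclude.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .haplotype import MitoHaplotype, PositionCall, Variant, VariantKind, call_at
from .pedigree import MaternalPair
from .reference import CircularReference


class ComparisonError(ValueError):
    """Haplotypes not comparable (different references, missing data)."""


class Mode(str, enum.Enum):
    ISFG = "isfg"
    STRICT = "strict"


class Outcome(str, enum.Enum):
    CANNOT_EXCLUDE = "cannot_exclude"
    INCONCLUSIVE = "inconclusive"
    EXCLUDE = "exclude"


def classify(n_diff: int) -> Outcome:
    """SWGDAM three-tier counting rule on the number of differing positions."""
    if n_diff < 0:
        raise ComparisonError(f"difference count cannot be negative: {n_diff}")
    if n_diff == 0:
        return Outcome.CANNOT_EXCLUDE
    if n_diff == 1:
        return Outcome.INCONCLUSIVE
    return Outcome.EXCLUDE


def position_differs(c1: PositionCall, c2: PositionCall, mode: Mode) -> bool:
    """Do two calls at the same position count as a difference?

    Both homoplasmic: differ iff the bases differ (both modes). With at
    least one heteroplasmy: strict mode requires exact allele-set equality;
    isfg mode reports a difference only when the allele sets are disjoint —
    a heteroplasmic base matching the homoplasmic type in the comparison
    sample is not a reportable difference. Two heteroplasmies with disjoint
    allele sets (never observed in casework data modelled here) count as a
    difference in both modes, since no allele is shared.
    """
    if c1.position != c2.position:
        raise ComparisonError("calls are at different positions")
    mode = Mode(mode)
    if mode is Mode.STRICT:
        return c1.alleles != c2.alleles
    return c1.alleles.isdisjoint(c2.alleles)


def _indel_differs(v1: Variant | None, v2: Variant | None, mode: Mode) -> bool:
    # token-level equality; a length-heteroplasmy record against a
    # concordant fixed-length insertion (or against absence) mirrors the
    # point-heteroplasmy logic: ignored in isfg mode, counted in strict.
    if v1 is None and v2 is None:
        return False
    if v1 is not None and v2 is not None and v1.kind == v2.kind and v1.base == v2.base:
        return False
    kinds = {v.kind for v in (v1, v2) if v is not None}
    bases = {v.base for v in (v1, v2) if v is not None}
    if VariantKind.LENGTH_HETEROPLASMY in kinds and len(bases) == 1:
        return mode is Mode.STRICT
    return True


@dataclass(frozen=True)
class ComparisonResult:
    """Differences and outcome for one pair of haplotypes in one mode."""

    id_a: str
    id_b: str
    mode: Mode
    differing_positions: tuple[str, ...]
    n_diff: int
    outcome: Outcome
    meioses: int | None = None


def count_differences(
    h1: MitoHaplotype,
    h2: MitoHaplotype,
    mode: Mode,
    reference: CircularReference,
) -> ComparisonResult:
    """Count differing positions between two normalised haplotypes.

    Only the union of the two variant position sets needs inspection: at
    every other position both samples carry the reference base. Positions
    lacking coverage (no-call) in either sample are excluded from the
    comparison entirely, as are masked positions (removed by
    normalisation).
    """
    if h1.reference_name != h2.reference_name:
        raise ComparisonError(
            f"haplotypes use different references: {h1.reference_name!r} vs "
            f"{h2.reference_name!r}"
        )
    mode = Mode(mode)
    skip = h1.no_call | h2.no_call
    differing: list[tuple[tuple[int, int], str]] = []

    p1, p2 = h1.point_variants, h2.point_variants
    for position in sorted(set(p1) | set(p2)):
        if position in skip:
            continue
        c1 = call_at(h1, position, reference)
        c2 = call_at(h2, position, reference)
        if position_differs(c1, c2, mode):
            v = p1.get(position) or p2.get(position)
            differing.append(((position, 0), v.token(reference)))

    i1, i2 = h1.indel_variants, h2.indel_variants
    for key in sorted(set(i1) | set(i2)):
        if key[0] in skip:
            continue
        v1, v2 = i1.get(key), i2.get(key)
        if _indel_differs(v1, v2, mode):
            differing.append((key, (v1 or v2).token(reference)))

    differing.sort()
    tokens = tuple(tok for _, tok in differing)
    return ComparisonResult(
        id_a=h1.sample_id, id_b=h2.sample_id, mode=mode,
        differing_positions=tokens, n_diff=len(tokens),
        outcome=classify(len(tokens)),
    )


@dataclass
class OutcomeTable:
    """Aggregated three-tier outcome counts for one comparison mode."""

    mode: Mode
    counts: dict[Outcome, int]

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    def count(self, outcome: Outcome) -> int:
        return self.counts.get(outcome, 0)

    def percentage(self, outcome: Outcome) -> float:
        if self.n_pairs == 0:
            raise ComparisonError("no pairs compared")
        return 100.0 * self.count(outcome) / self.n_pairs

    def as_row(self) -> list[int]:
        return [self.count(o) for o in Outcome]


def compare_all(
    pairs: Sequence[MaternalPair],
    haplotypes: Mapping[str, MitoHaplotype],
    mode: Mode,
    reference: CircularReference,
) -> tuple[OutcomeTable, list[ComparisonResult], pd.DataFrame]:
    """Compare every maternal pair and aggregate outcomes.

    Returns the outcome table, the per-pair results, and a
    meioses x n_diff count matrix (rows indexed by meiosis count, columns
    by number of differences) for examining whether differences accumulate
    with meiotic distance.
    """
    mode = Mode(mode)
    results: list[ComparisonResult] = []
    for pair in pairs:
        for sample in (pair.id_a, pair.id_b):
            if sample not in haplotypes:
                raise ComparisonError(f"no haplotype for paired individual {sample!r}")
        res = count_differences(haplotypes[pair.id_a], haplotypes[pair.id_b],
                                mode, reference)
        results.append(ComparisonResult(
            id_a=res.id_a, id_b=res.id_b, mode=mode,
            differing_positions=res.differing_positions, n_diff=res.n_diff,
            outcome=res.outcome, meioses=pair.meioses,
        ))
    counts = Counter(r.outcome for r in results)
    table = OutcomeTable(mode=mode, counts={o: counts.get(o, 0) for o in Outcome})

    if results:
        cells = Counter((r.meioses, r.n_diff) for r in results)
        meio = sorted({m for m, _ in cells})
        ndiff = sorted({d for _, d in cells})
        matrix = pd.DataFrame(0, index=pd.Index(meio, name="meioses"),
                              columns=pd.Index(ndiff, name="n_diff"))
        for (m, d), c in cells.items():
            matrix.loc[m, d] = c
    else:
        matrix = pd.DataFrame(index=pd.Index([], name="meioses"),
                              columns=pd.Index([], name="n_diff"))
    return table, results, matrix


def results_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    """Comparison report table: one row per pair."""
    return pd.DataFrame([
        {
            "id_a": r.id_a, "id_b": r.id_b,
            "meioses": r.meioses, "mode": r.mode.value,
            "n_diff": r.n_diff,
            "differing_positions": ";".join(r.differing_positions),
            "outcome": r.outcome.value,
        }
        for r in results
    ])


def write_report_csv(results: Iterable[ComparisonResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)
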