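"""Synthetic pedigrees, mtDNA transmissions, and read-count pileups.

The generator stands in for a deep island-isolate study cohort: ~45
maternal families sampled over the last four generations, a few hundred
sampled individuals forming a few thousand maternally related pairs, rare
private substitutions, and point heteroplasmies that drift through a
germline bottleneck between mother and child.

Heteroplasmy transmission is modelled as a single binomial bottleneck: the
child's minor-allele fraction is Binomial(N_b, maf)/N_b, so the MAF is a
martingale across one transmission and fixation/loss become more likely as
the bottleneck size N_b shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .haplotype import MitoHaplotype, PositionCall, Variant, VariantKind, normalize
from .calling import Pileup
from .pedigree import Individual, Pedigree
from .reference import BASES, CircularReference, bundled_reference


class SimulationError(ValueError):
    """Impossible simulation shape or invalid configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shape and transmission-model parameters.

    Pedigree shape defaults emulate the modelled cohort: 45 maternal
    families, six generations deep, individuals from the last four
    generations eligible for sampling, with a per-female Poisson offspring
    distribution and a sampling fraction tuned so roughly 225 individuals
    are sampled in expectation.

    Transmission rates are per genome per mother-to-child transmission.
    De-novo heteroplasmies start at a MAF drawn uniformly from
    (de_novo_maf_lo, 0.5] — above the 20% calling threshold by default so
    simulated events are observable; lower ``de_novo_maf_lo`` to exercise
    sub-threshold heteroplasmy that NGS calling misses.

    The read-depth model is a log-normal matched to a median of ~370X,
    clipped to the observed 139-1316X range.
    """

    n_families: int = 45
    generations_total: int = 6
    sampled_generations: int = 4
    offspring_mean: float = 2.5
    sampling_fraction: float = 0.28
    substitution_rate: float = 0.006
    heteroplasmy_rate: float = 0.02
    bottleneck_size: int = 30
    fixation_threshold: float = 0.0
    de_novo_maf_lo: float = 0.20
    depth_median: float = 370.0
    depth_sigma: float = 0.35
    depth_min: int = 139
    depth_max: int = 1316
    error_rate: float = 0.001
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "heteroplasmy_rate", "sampling_fraction",
                     "fixation_threshold", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.bottleneck_size < 1:
            raise SimulationError("bottleneck_size must be >= 1")
        if self.n_families < 1 or self.generations_total < 1:
            raise SimulationError("need at least one family and one generation")
        if self.sampled_generations < 1:
            raise SimulationError("sampled_generations must be >= 1")
        if not 0 < self.depth_min <= self.depth_max:
            raise SimulationError("invalid depth range")
        if not 0.0 <= self.de_novo_maf_lo < 0.5:
            raise SimulationError("de_novo_maf_lo must be in [0, 0.5)")


@dataclass(frozen=True)
class TransmissionEvent:
    """What happened to the mtDNA between one mother and one child."""

    mother_id: str
    child_id: str
    inherited: tuple[str, ...] = ()
    maf_shifts: tuple[tuple[int, float, float], ...] = ()  # position, maf before/after
    fixations: tuple[int, ...] = ()
    losses: tuple[int, ...] = ()
    de_novo_substitutions: tuple[int, ...] = ()
    de_novo_heteroplasmies: tuple[int, ...] = ()


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Grow disjoint maternal clans and flag the sampled individuals.

    Each family starts from one founding mother; every female has a
    Poisson(offspring_mean) number of children with sex drawn 1:1. Only
    individuals born in the last ``sampled_generations`` generations are
    eligible for sampling, each kept with probability
    ``sampling_fraction``.
    """
    if config.offspring_mean <= 0:
        raise SimulationError("offspring_mean must be positive: the pedigree cannot grow")
    first_sampled_gen = config.generations_total - config.sampled_generations + 1
    individuals: list[Individual] = []
    for fam_idx in range(1, config.n_families + 1):
        family = f"F{fam_idx}"
        founder_id = f"{family}-G1-1"
        individuals.append(Individual(id=founder_id, mother_id=None, sex="F",
                                      family=family,
                                      sampled=first_sampled_gen <= 1
                                      and bool(rng.random() < config.sampling_fraction)))
        mothers = [founder_id]
        for gen in range(2, config.generations_total + 1):
            children: list[str] = []
            counter = 0
            for mother in mothers:
                for _ in range(int(rng.poisson(config.offspring_mean))):
                    counter += 1
                    cid = f"{family}-G{gen}-{counter}"
                    sex = "F" if rng.random() < 0.5 else "M"
                    sampled = gen >= first_sampled_gen and bool(
                        rng.random() < config.sampling_fraction)
                    individuals.append(Individual(id=cid, mother_id=mother, sex=sex,
                                                  family=family, sampled=sampled))
                    if sex == "F":
                        children.append(cid)
            mothers = children
            if not mothers:
                break
    return Pedigree(individuals)


def _point_variant_from_call(call: PositionCall) -> Variant:
    kind = (VariantKind.POINT_HETEROPLASMY if call.is_heteroplasmic
            else VariantKind.SUBSTITUTION)
    return Variant(kind=kind, position=call.position, call=call)


def transmit(
    mother_hap: MitoHaplotype,
    reference: CircularReference,
    config: SimulationConfig,
    rng: np.random.Generator,
    child_id: str = "child",
) -> tuple[MitoHaplotype, TransmissionEvent]:
    """One mother-to-child mtDNA transmission.

    Homoplasmic variants are inherited verbatim. Each heteroplasmic
    variant's minor-allele fraction is resampled through the bottleneck as
    Binomial(N_b, maf)/N_b; draws of 0 or 1 (or fractions below the
    fixation threshold) convert the position to homoplasmic. De-novo
    substitutions and heteroplasmies arise at Poisson-distributed counts at
    uniformly random unmasked positions not already variant.
    """
    variants: list[Variant] = []
    inherited, shifts, fixations, losses = [], [], [], []
    for v in mother_hap.variants:
        if v.kind is not VariantKind.POINT_HETEROPLASMY:
            variants.append(v)
            inherited.append(v.token(reference))
            continue
        call = v.call
        maf = call.maf if call.maf is not None else 0.25
        minor = call.minor_allele or min(call.alleles)
        (major,) = call.alleles - {minor}
        f = rng.binomial(config.bottleneck_size, maf) / config.bottleneck_size
        if min(f, 1 - f) <= config.fixation_threshold or f in (0.0, 1.0):
            survivor = minor if f >= 0.5 else major
            if survivor != reference.base(v.position):
                variants.append(Variant(
                    kind=VariantKind.SUBSTITUTION, position=v.position,
                    call=PositionCall(position=v.position, alleles=frozenset(survivor))))
            (fixations if survivor == minor else losses).append(v.position)
        else:
            new_minor, new_maf = (minor, f) if f <= 0.5 else (major, 1 - f)
            variants.append(Variant(
                kind=VariantKind.POINT_HETEROPLASMY, position=v.position,
                call=PositionCall(position=v.position, alleles=call.alleles,
                                  maf=new_maf, minor_allele=new_minor)))
            shifts.append((v.position, maf, new_maf))

    occupied = {v.position for v in variants}
    de_novo_subs, de_novo_hets = [], []

    def free_position() -> Optional[int]:
        for _ in range(100):
            pos = int(rng.integers(1, reference.length + 1))
            if pos not in occupied and not reference.is_masked(pos):
                return pos
        return None

    for _ in range(int(rng.poisson(config.substitution_rate))):
        pos = free_position()
        if pos is None:
            continue
        ref_base = reference.base(pos)
        alt = str(rng.choice([b for b in BASES if b != ref_base]))
        variants.append(Variant(kind=VariantKind.SUBSTITUTION, position=pos,
                                call=PositionCall(position=pos, alleles=frozenset(alt))))
        occupied.add(pos)
        de_novo_subs.append(pos)
    for _ in range(int(rng.poisson(config.heteroplasmy_rate))):
        pos = free_position()
        if pos is None:
            continue
        ref_base = reference.base(pos)
        alt = str(rng.choice([b for b in BASES if b != ref_base]))
        maf = float(rng.uniform(config.de_novo_maf_lo, 0.5))
        maf = max(maf, 1e-9)
        variants.append(Variant(
            kind=VariantKind.POINT_HETEROPLASMY, position=pos,
            call=PositionCall(position=pos, alleles=frozenset((ref_base, alt)),
                              maf=maf, minor_allele=alt)))
        occupied.add(pos)
        de_novo_hets.append(pos)

    child = normalize(MitoHaplotype(sample_id=child_id, variants=tuple(variants),
                                    reference_name=mother_hap.reference_name),
                      reference)
    event = TransmissionEvent(
        mother_id=mother_hap.sample_id, child_id=child_id,
        inherited=tuple(inherited), maf_shifts=tuple(shifts),
        fixations=tuple(fixations), losses=tuple(losses),
        de_novo_substitutions=tuple(de_novo_subs),
        de_novo_heteroplasmies=tuple(de_novo_hets),
    )
    return child, event


def simulate_haplotypes(
    pedigree: Pedigree,
    reference: CircularReference,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, MitoHaplotype], list[TransmissionEvent]]:
    """Drop a reference-identical founder haplotype into every clan and
    transmit it down the maternal links in deterministic id order."""
    haplotypes: dict[str, MitoHaplotype] = {}
    events: list[TransmissionEvent] = []
    order = sorted(pedigree.individuals,
                   key=lambda i: (len(pedigree.maternal_ancestry(i)), i))
    for individual_id in order:
        ind = pedigree.individuals[individual_id]
        if ind.mother_id is None:
            haplotypes[individual_id] = MitoHaplotype(
                sample_id=individual_id, reference_name=reference.name)
        else:
            child, event = transmit(haplotypes[ind.mother_id], reference, config,
                                    rng, child_id=individual_id)
            haplotypes[individual_id] = child
            events.append(event)
    return haplotypes, events


def simulate_reads(
    hap: MitoHaplotype,
    reference: CircularReference,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Pileup:
    """Draw a read-count pileup for one haplotype.

    Depth per position is log-normal around the configured median, clipped
    to [depth_min, depth_max]. Reads are drawn from the sample's true
    allele mix (heteroplasmy MAF respected) with the per-base error rate
    redistributed uniformly over the other three bases.
    """
    L = reference.length
    base_index = {b: i for i, b in enumerate(BASES)}
    probs = np.zeros((L, 4))
    for position in range(1, L + 1):
        probs[position - 1, base_index[reference.base(position)]] = 1.0
    for v in hap.variants:
        if v.kind is VariantKind.SUBSTITUTION:
            probs[v.position - 1] = 0.0
            (allele,) = v.call.alleles
            probs[v.position - 1, base_index[allele]] = 1.0
        elif v.kind is VariantKind.POINT_HETEROPLASMY:
            maf = v.call.maf if v.call.maf is not None else 0.25
            minor = v.call.minor_allele or min(v.call.alleles)
            (major,) = v.call.alleles - {minor}
            probs[v.position - 1] = 0.0
            probs[v.position - 1, base_index[minor]] = maf
            probs[v.position - 1, base_index[major]] = 1.0 - maf
        # indels do not alter point pileups in this model
    e = config.error_rate
    probs = probs * (1 - e) + (1 - probs) * (e / 3.0)

    depth = np.exp(rng.normal(np.log(config.depth_median), config.depth_sigma, size=L))
    depth = np.clip(np.rint(depth), config.depth_min, config.depth_max).astype(np.int64)
    counts = np.empty((L, 4), dtype=np.int64)
    for i in range(L):
        counts[i] = rng.multinomial(depth[i], probs[i])
    return Pileup(counts=counts)


def build_two_family_fixture(
    reference: Optional[CircularReference] = None,
) -> tuple[Pedigree, dict[str, MitoHaplotype], CircularReference]:
    """Deterministic two-clan fixture mirroring the modelled casework
    structure (no randomness).

    Clan FAM8: seven sampled maternal relatives, one childless member
    carrying the private A16247G substitution. Clan FAM12: 59 sampled
    maternal relatives, one childless member carrying A8817G and two
    members heteroplasmic at 2833 (R, minor-allele fractions 0.39 for A and
    0.27 for G). Everyone else is reference-identical, so the expected
    comparison outcomes are exactly enumerable: 6 + 58 = 64 inconclusive
    pairs and no exclusions under isfg rules.
    """
    reference = reference or bundled_reference()
    individuals: list[Individual] = []
    haplotypes: dict[str, MitoHaplotype] = {}

    def add(ind_id, mother_id, sex, family, tokens=""):
        individuals.append(Individual(id=ind_id, mother_id=mother_id, sex=sex,
                                      family=family, sampled=True))
        variants = []
        for tok in tokens.split():
            from .haplotype import _parse_token  # local: fixture-only
            variants.append(_parse_token(tok, reference))
        haplotypes[ind_id] = MitoHaplotype(sample_id=ind_id, variants=tuple(variants),
                                           reference_name=reference.name)

    # FAM8: founding mother, two daughters; one daughter has four children,
    # the youngest of whom is the childless substitution carrier.
    add("FAM8-1", None, "F", "FAM8")
    add("FAM8-2", "FAM8-1", "F", "FAM8")
    add("FAM8-3", "FAM8-1", "F", "FAM8")
    for i, sex in zip(range(4, 8), "MMMF"):
        add(f"FAM8-{i}", "FAM8-2", sex, "FAM8")
    # re-register the carrier with its variant
    haplotypes["FAM8-7"] = MitoHaplotype(
        sample_id="FAM8-7",
        variants=(
            Variant(kind=VariantKind.SUBSTITUTION, position=16247,
                    call=PositionCall(position=16247, alleles=frozenset("G"))),),
        reference_name=reference.name)

    # FAM12: founding mother with four daughters, each with 13-14 children.
    add("FAM12-1", None, "F", "FAM12")
    counter = 2
    branch_heads = []
    for _ in range(4):
        head = f"FAM12-{counter}"
        add(head, "FAM12-1", "F", "FAM12")
        branch_heads.append(head)
        counter += 1
    per_branch = [14, 14, 13, 13]  # 1 + 4 + 54 = 59 members
    members_by_branch = []
    for head, k in zip(branch_heads, per_branch):
        kids = []
        for j in range(k):
            cid = f"FAM12-{counter}"
            add(cid, head, "F" if j % 2 else "M", "FAM12")
            kids.append(cid)
            counter += 1
        members_by_branch.append(kids)
    sub_carrier = members_by_branch[0][-1]
    haplotypes[sub_carrier] = MitoHaplotype(
        sample_id=sub_carrier,
        variants=(
            Variant(kind=VariantKind.SUBSTITUTION, position=8817,
                    call=PositionCall(position=8817, alleles=frozenset("G"))),),
        reference_name=reference.name)
    for carrier, maf, minor in ((members_by_branch[1][0], 0.39, "A"),
                                (members_by_branch[2][0], 0.27, "G")):
        haplotypes[carrier] = MitoHaplotype(
            sample_id=carrier,
            variants=(
                Variant(kind=VariantKind.POINT_HETEROPLASMY, position=2833,
                        call=PositionCall(position=2833, alleles=frozenset("AG"),
                                          maf=maf, minor_allele=minor)),),
            reference_name=reference.name)

    pedigree = Pedigree(individuals)
    return pedigree, haplotypes, reference
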