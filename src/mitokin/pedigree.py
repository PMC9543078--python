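"""Maternal pedigrees: clans, meiosis counting, and pair enumeration.

Only strictly maternal links are modelled — each individual has at most one
mother and paternal relationships are ignored. The maternal links therefore
form a forest whose roots are founding mothers; a *maternal clan* is all
individuals tracing to one founder. The meiosis distance between two clan
members is the number of mother-to-child transmissions on the maternal path
through their most recent common maternal ancestor (mother-child = 1,
siblings = 2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd


class PedigreeError(ValueError):
    """Structural problem: cycle, dangling mother, male mother, bad schema."""


class NotMaternallyRelatedError(PedigreeError):
    """Two individuals share no common maternal ancestor."""


@dataclass(frozen=True)
class Individual:
    id: str
    mother_id: Optional[str] = None
    sex: str = "U"  # F / M / U(nknown)
    family: str = ""
    sampled: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "U"):
            raise PedigreeError(f"sex must be F/M/U, got {self.sex!r}")
        if self.mother_id == "":
            object.__setattr__(self, "mother_id", None)


@dataclass(frozen=True)
class MaternalPair:
    """Unordered pair of sampled clan members with their meiosis count."""

    id_a: str
    id_b: str
    meioses: int

    def __post_init__(self) -> None:
        if self.meioses < 1:
            raise PedigreeError(f"meioses must be >= 1, got {self.meioses}")
        # canonical order so (a,b) == (b,a)
        if self.id_b < self.id_a:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)


class Pedigree:
    """Validated collection of individuals with maternal links."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals.values():
            if ind.mother_id is None:
                continue
            mother = self.individuals.get(ind.mother_id)
            if mother is None:
                raise PedigreeError(
                    f"{ind.id}: mother {ind.mother_id!r} not in pedigree"
                )
            if mother.sex == "M":
                raise PedigreeError(f"{mother.id} is male but listed as mother of {ind.id}")
        # cycle check by walking each maternal line with a visited set
        state: dict[str, int] = {}  # 0 = visiting, 1 = done
        for start in self.individuals:
            path = []
            node: Optional[str] = start
            while node is not None and state.get(node) != 1:
                if state.get(node) == 0:
                    raise PedigreeError(f"maternal cycle involving {node!r}")
                state[node] = 0
                path.append(node)
                node = self.individuals[node].mother_id
            for n in path:
                state[n] = 1

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.individuals

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.mother_id is None]

    def maternal_ancestry(self, individual_id: str) -> dict[str, int]:
        """Map each maternal ancestor (including self) to its mother-link
        distance from ``individual_id``."""
        if individual_id not in self.individuals:
            raise PedigreeError(f"unknown individual {individual_id!r}")
        out: dict[str, int] = {}
        node, d = individual_id, 0
        while node is not None:
            out[node] = d
            node = self.individuals[node].mother_id
            d += 1
        return out

    def clan_root(self, individual_id: str) -> str:
        ancestry = self.maternal_ancestry(individual_id)
        return max(ancestry, key=ancestry.get)


def load_pedigree(path) -> Pedigree:
    """Read the tab-separated pedigree schema:
    ``id  mother_id  sex  family  sampled`` with sampled coded 0/1 and an
    empty mother_id marking a founder."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["id", "mother_id", "sex", "family", "sampled"]
    if list(df.columns) != required:
        raise PedigreeError(f"pedigree TSV must have columns {required}, got {list(df.columns)}")
    return Pedigree(
        Individual(
            id=row.id,
            mother_id=row.mother_id or None,
            sex=row.sex or "U",
            family=row.family,
            sampled=row.sampled == "1",
        )
        for row in df.itertuples()
    )


def write_pedigree(pedigree: Pedigree, path) -> None:
    rows = [
        {"id": i.id, "mother_id": i.mother_id or "", "sex": i.sex,
         "family": i.family, "sampled": int(i.sampled)}
        for i in pedigree.individuals.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def from_ped_rows(rows: Iterable[Iterable[str]]) -> Pedigree:
    """Convert 6-column PED-format rows (family, id, father, mother, sex,
    phenotype), keeping only the maternal column; sex 2 = F, 1 = M."""
    individuals = []
    for fam, iid, _father, mother, sex, _pheno in rows:
        individuals.append(Individual(
            id=str(iid),
            mother_id=None if str(mother) in ("0", "") else str(mother),
            sex={"1": "M", "2": "F"}.get(str(sex), "U"),
            family=str(fam),
            sampled=True,
        ))
    return Pedigree(individuals)


def maternal_clans(pedigree: Pedigree) -> dict[str, list[str]]:
    """Partition all individuals by their founding mother (maternal root)."""
    clans: dict[str, list[str]] = {}
    for individual_id in pedigree.individuals:
        clans.setdefault(pedigree.clan_root(individual_id), []).append(individual_id)
    return clans


def meioses_between(pedigree: Pedigree, a: str, b: str) -> int:
    """Mother-link distance between two individuals through their most
    recent common maternal ancestor."""
    if a == b:
        raise PedigreeError("meiosis distance requires two distinct individuals")
    anc_a = pedigree.maternal_ancestry(a)
    node, d_b = b, 0
    while node is not None:
        if node in anc_a:
            return anc_a[node] + d_b
        node = pedigree.individuals[node].mother_id
        d_b += 1
    raise NotMaternallyRelatedError(f"{a!r} and {b!r} share no maternal ancestor")


def enumerate_pairs(pedigree: Pedigree) -> tuple[list[MaternalPair], Counter]:
    """All unordered pairs of *sampled* individuals within each maternal
    clan, with the histogram of meiosis counts.

    Unsampled individuals route maternal paths but never appear in pairs;
    the pair count equals sum over clans of C(k, 2) for sampled clan
    sizes k.
    """
    pairs: list[MaternalPair] = []
    for members in maternal_clans(pedigree).values():
        sampled = sorted(m for m in members if pedigree.individuals[m].sampled)
        for a, b in combinations(sampled, 2):
            pairs.append(MaternalPair(a, b, meioses_between(pedigree, a, b)))
    histogram = Counter(p.meioses for p in pairs)
    return pairs, histogram
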