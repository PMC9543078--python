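"""Study orchestration: run the full interpretation and emit report tables.

``run_study`` ties the modules together — normalise haplotypes (calling
them from pileups first if needed), enumerate maternal pairs, compare every
pair under both heteroplasmy-handling modes, and summarise outcomes with
binomial confidence intervals plus a chi-squared contrast of the two modes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .calling import CallingConfig, Pileup, call_haplotype
from .comparison import (ComparisonResult, Mode, Outcome, OutcomeTable,
                         compare_all, results_to_frame)
from .haplotype import MitoHaplotype, normalize
from .pedigree import MaternalPair, Pedigree, enumerate_pairs
from .reference import CircularReference

logger = logging.getLogger("mitokin")

#: Conventional control-region and hypervariable-segment boundaries
#: (1-based, inclusive). The control region wraps the origin.
DEFAULT_REGIONS = {
    "HVI": (16024, 16365),
    "HVII": (57, 372),
    "HVIII": (438, 574),
    "control": ((16024, 16569), (1, 576)),
}


def region_annotate(position: int, length: int = 16569, regions=None) -> str:
    """Label a position as hypervariable / control / coding region."""
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside [1, {length}]")
    regions = regions or DEFAULT_REGIONS
    for name in ("HVI", "HVII", "HVIII"):
        lo, hi = regions[name]
        if lo <= position <= hi:
            return f"{name} (Control region)"
    for lo, hi in regions["control"]:
        if lo <= position <= hi:
            return "Control region"
    return "Coding region"


@dataclass
class StudyReport:
    """Everything the interpretation run produces, table-shaped."""

    meiosis_histogram: dict[int, int]
    n_pairs: int
    variant_table: pd.DataFrame  # token, region, type, lineage count
    outcome_tables: dict[str, dict]  # per mode: counts/percentages/CIs
    meiosis_matrices: dict[str, pd.DataFrame]
    chi2_modes: dict
    metadata: dict

    def validate(self) -> None:
        total = sum(self.meiosis_histogram.values())
        if total != self.n_pairs:
            raise ValueError("meiosis histogram total != pair total")
        for mode, summary in self.outcome_tables.items():
            if summary["n_pairs"] != self.n_pairs:
                raise ValueError(f"{mode} outcome total != pair total")


def chi2_between_modes(counts_a: Sequence[int], counts_b: Sequence[int]):
    """Chi-squared contrast of two outcome-count rows
    (cannot_exclude, inconclusive, exclude)."""
    from .stats import pearson_chi2

    return pearson_chi2([list(counts_a), list(counts_b)])


def _variant_table(results: Sequence[ComparisonResult],
                   haplotypes: Mapping[str, MitoHaplotype],
                   pedigree: Pedigree) -> pd.DataFrame:
    """Differing-variant list with region annotation and the number of
    maternal lineages each variant appears in (among compared samples)."""
    rows = []
    all_tokens = sorted({t for r in results for t in r.differing_positions},
                        key=_token_position)
    for tok in all_tokens:
        position = _token_position(tok)
        lineages = set()
        kind = "Substitution"
        for sample_id, hap in haplotypes.items():
            for v in hap.variants:
                if v.position == position:
                    if v.kind.value == "point_heteroplasmy":
                        kind = "Point heteroplasmy"
                    elif v.kind.value in ("insertion", "deletion"):
                        kind = v.kind.value.capitalize()
                    elif v.kind.value == "length_heteroplasmy":
                        kind = "Length heteroplasmy"
                    if sample_id in pedigree:
                        lineages.add(pedigree.clan_root(sample_id))
        rows.append({"variant": tok, "region": region_annotate(position),
                     "type": kind, "lineages": len(lineages)})
    return pd.DataFrame(rows, columns=["variant", "region", "type", "lineages"])


def _token_position(token: str) -> int:
    digits = "".join(ch for ch in token.lstrip("ACGT") if ch.isdigit() or ch == ".")
    return int(float(digits.split(".")[0])) if digits else 0


def run_study(
    pedigree: Pedigree,
    reference: CircularReference,
    haplotypes: Optional[Mapping[str, MitoHaplotype]] = None,
    pileups: Optional[Mapping[str, Pileup]] = None,
    calling_config: CallingConfig = CallingConfig(),
    modes: Sequence[Mode] = (Mode.ISFG, Mode.STRICT),
    seed: Optional[int] = None,
) -> tuple[StudyReport, dict[str, list[ComparisonResult]]]:
    """Execute the full interpretation over a pedigree and sequence data.

    Exactly one of ``haplotypes`` (pre-called variant strings) or
    ``pileups`` (per-sample read counts, called here under the MAF rule)
    must cover every sampled individual.
    """
    from .stats import outcome_summary

    if (haplotypes is None) == (pileups is None):
        raise ValueError("provide exactly one of haplotypes or pileups")
    if pileups is not None:
        logger.info("calling haplotypes from %d pileups", len(pileups))
        haplotypes = {sid: call_haplotype(p, reference, calling_config, sample_id=sid)
                      for sid, p in pileups.items()}
    else:
        haplotypes = {sid: normalize(h, reference) for sid, h in haplotypes.items()}

    sampled = [i for i, ind in pedigree.individuals.items() if ind.sampled]
    missing = [s for s in sampled if s not in haplotypes]
    if missing:
        raise ValueError(f"no sequence data for sampled individuals: {missing[:5]}")

    pairs, histogram = enumerate_pairs(pedigree)
    logger.info("enumerated %d maternal pairs across %d sampled individuals",
                len(pairs), len(sampled))

    outcome_tables: dict[str, dict] = {}
    matrices: dict[str, pd.DataFrame] = {}
    all_results: dict[str, list[ComparisonResult]] = {}
    chi2_rows = {}
    for mode in modes:
        mode = Mode(mode)
        table, results, matrix = compare_all(pairs, haplotypes, mode, reference)
        outcome_tables[mode.value] = outcome_summary(table.as_row())
        matrices[mode.value] = matrix
        all_results[mode.value] = results
        chi2_rows[mode.value] = table.as_row()
        logger.info("mode %s: %s", mode.value,
                    {o.value: c for o, c in table.counts.items()})

    chi2_block: dict = {}
    if len(chi2_rows) == 2:
        rows = list(chi2_rows.values())
        res = chi2_between_modes(rows[0], rows[1])
        chi2_block = {"statistic": round(res.statistic, 3), "df": res.df,
                      "p_value": res.p_value, "rows": chi2_rows}

    first_mode = Mode(modes[0]).value
    variant_table = _variant_table(all_results[first_mode], haplotypes, pedigree)

    config_digest = hashlib.sha256(
        json.dumps({"maf_threshold": calling_config.maf_threshold,
                    "min_depth": calling_config.min_depth,
                    "modes": [Mode(m).value for m in modes]},
                   sort_keys=True).encode()).hexdigest()[:12]
    report = StudyReport(
        meiosis_histogram=dict(sorted(histogram.items())),
        n_pairs=len(pairs),
        variant_table=variant_table,
        outcome_tables=outcome_tables,
        meiosis_matrices=matrices,
        chi2_modes=chi2_block,
        metadata={"seed": seed, "config_digest": config_digest,
                  "mitokin_version": __version__,
                  "n_sampled": len(sampled), "reference": reference.name},
    )
    report.validate()
    return report, all_results


def write_report(report: StudyReport,
                 results: Mapping[str, Sequence[ComparisonResult]],
                 out_dir) -> None:
    """Write the CSV/JSON report bundle and a plain-text run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"meioses": list(report.meiosis_histogram),
         "pairs": list(report.meiosis_histogram.values())}
    ).to_csv(out / "meiosis_histogram.csv", index=False)
    report.variant_table.to_csv(out / "differing_variants.csv", index=False)
    for mode, matrix in report.meiosis_matrices.items():
        matrix.to_csv(out / f"meiosis_by_ndiff_{mode}.csv")
    for mode, res in results.items():
        results_to_frame(res).to_csv(out / f"comparisons_{mode}.csv", index=False)
    stats_block = {"outcomes": report.outcome_tables,
                   "chi_squared_modes": report.chi2_modes,
                   "n_pairs": report.n_pairs}
    (out / "stats.json").write_text(json.dumps(stats_block, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(report.metadata, indent=2))
    lines = [f"pairs compared: {report.n_pairs}"]
    for mode, summary in report.outcome_tables.items():
        counts = {k: v["count"] for k, v in summary["outcomes"].items()}
        lines.append(f"mode {mode}: {counts}")
    if report.chi2_modes:
        lines.append(f"chi2 between modes: {report.chi2_modes['statistic']} "
                     f"(df={report.chi2_modes['df']})")
    (out / "run.log").write_text("\n".join(lines) + "\n")
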