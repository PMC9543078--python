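# Methods

`mitokin` implements the interpretation procedure used in forensic kinship
testing with whole mitochondrial genomes: maternally related individuals
are compared haplotype-to-haplotype, differences are counted under explicit
rules for point and length heteroplasmy, and each pair receives one of
three outcomes. Because real multigenerational cohorts of this kind are not
publicly deposited, the package also ships a synthetic-data generator that
emulates the shape of such a study (a deep island-isolate pedigree sampled
over its last four generations) so the whole pipeline is testable end to
end without any download.

## Haplotypes and nomenclature

A haplotype is the set of differences between a sample and a circular
reference with 1-based coordinates (the rCRS numbering convention;
positions act as labels, so a bundled deterministic synthetic 16,569-base
reference is provided and the real rCRS can be substituted as FASTA).
Variant strings use the forensic dialect: `A16247G` (substitution), `T146Y`
(point heteroplasmy as a two-base IUPAC code), `315.1C` (insertion),
`249DEL` (deletion). Three- and four-allele mixtures (IUPAC N/B/D/H/V) are
rejected rather than truncated: the comparison semantics below are defined
on one- and two-allele calls, and silently collapsing a triallelic call
would fabricate certainty the data do not contain.

Normalisation follows the convention that indels are anchored at the
3'-most equivalent placement on the light strand. For a single-base indel
inside a homopolymer run every placement within the run yields the same
edited sequence; the implementation shifts the anchor rightwards while the
next reference base matches, which the test suite checks against a
brute-force oracle that enumerates every placement by string comparison and
takes the maximum position. Insertion groups with mixed bases at one anchor
are left in place — only homopolymer placements are ambiguous. Circularity
is not considered when shifting: the control-region C-stretches this matters
for sit far from the origin, and the simulator never generates
origin-spanning indels.

Three homopolymeric C-tracts (16183–16194, 302–310, 568–573) are
length-variable within individuals and are conventionally excluded from
comparison; they are attached to the reference as masked ranges and any
variant whose (normalised) position falls inside one is dropped. The common
`315.1C` insertion lies outside the 302–310 masked interval and remains
reportable — masking is strictly positional.

## Variant calling

Calling from per-position read counts is purely frequency-based: with the
top two bases b1, b2 at a position and `maf = count(b2)/depth`, the call is
the heteroplasmy {b1, b2} iff `maf` strictly exceeds the threshold
(default 0.20), else the homoplasmic {b1}. Ties for the top base are broken
by the fixed order A < C < G < T so that calling is deterministic. The
default minimum depth is 1 read — no coverage threshold — reflecting
permissive forensic practice for this data type; real casework should
raise `min_depth`. Zero-coverage (or sub-threshold) positions become
no-calls, which are excluded from comparison entirely: comparing only the
shared covered range is the conservative choice and avoids counting absence
of data as difference. Lowering the threshold can only add heteroplasmic
calls, never remove variants; this monotonicity is property-tested.

## Pedigrees and meiosis counting

Only strictly maternal links exist in the model; the mother relation forms
a forest whose roots are founding mothers, and a maternal clan is one tree.
The meiosis distance between two clan members is the number of
mother-to-child transmissions on the path through their most recent common
maternal ancestor: mother–child = 1, siblings = 2. With individuals sampled
only from the last few generations of a deep pedigree this definition
produces distances up to ~18, the range such studies report. Pairs are
enumerated over sampled individuals only; unsampled ancestors route paths
but never appear in pairs, so the pair count is the sum of C(k, 2) over
sampled clan sizes. The implementation is checked against an independent
graph-shortest-path oracle on random pedigrees.

## Comparison modes and classification

Every pair is compared under two heteroplasmy-handling rules:

* **isfg** — heteroplasmy is not evidence of difference when an allele is
  shared: two calls differ only if their allele sets are disjoint. Where
  one of the heteroplasmic bases matches the homoplasmic type in the
  comparison sample, no difference is reported.
* **strict** — any call inequality counts, so R vs A is a difference.

Two heteroplasmies with disjoint allele sets (e.g. R vs Y) count as a
difference in both modes: the shared-allele rationale fails, and although
no such case is expected in real maternal pairs the rule must still decide.
Non-C-stretch indels require token-level equality in both modes; a
length-heteroplasmy record against a concordant fixed-length insertion
mirrors the point-heteroplasmy logic (ignored under isfg, counted under
strict). This path is exercised only by simulated data, since length
heteroplasmy outside the masked C-stretches does not occur in the casework
data the model emulates.

Classification is the SWGDAM counting rule and depends only on the number
of differing positions: 0 → cannot exclude, 1 → inconclusive, ≥2 →
exclude. Since every isfg-mode difference is also a strict-mode difference,
the cannot-exclude count under isfg is always ≥ the strict one — a
property test and the deterministic fixture both verify this.

## Statistics

Outcome rates are reported with two 95% binomial intervals: Clopper-Pearson
(exact, conservative; lower bound exactly 0 at x = 0, bounds otherwise from
Beta quantiles) as prescribed for forensic reporting, and Wilson's score
interval as the narrower near-nominal alternative. The Wilson z is the
exact normal quantile (≈1.959964), not the rounded 1.96 — at n ≈ 2339 the
difference is visible in the second decimal of the percentage bounds.
Percentages and bounds are displayed to 2 decimal places. Both methods are
cross-checked against statsmodels in the tests, and Clopper-Pearson
empirical coverage is verified ≥ 95% on a binomial grid (p ∈ {0.003, 0.03,
0.1}, n = 2339, 2000 replicates).

Mode contrasts use Pearson's chi-squared on the 2×3 outcome-count table
without continuity correction; all-zero rows/columns are dropped with the
degrees of freedom reduced and the result flagged. Fisher's exact test is
exact for 2×2 tables and Monte-Carlo for larger ones (column-label
permutation preserves both margins; the add-one estimator is reported with
its standard error and is tested against full margin enumeration on small
tables).

## The simulator

The generator emulates the *shape* of a deep maternal-isolate study, not
any real pedigree topology. Defaults: 45 maternal families grown 6
generations deep with a Poisson(2.5) offspring distribution per female,
individuals from the last 4 generations sampled with probability 0.28 —
which puts the expected sampled count near 225 and yields a few thousand
maternal pairs spanning roughly 1–18 meioses.

Transmission: homoplasmic variants are inherited verbatim. Each
heteroplasmic position passes through a single binomial bottleneck — the
child's minor-allele count is Binomial(N_b, maf), with fixation or loss
when the draw hits the boundary — so the allele frequency is a martingale
across one transmission and drift variance grows as N_b shrinks. A single
bottleneck was chosen over multi-round Wright-Fisher for transparency: one
parameter (N_b, default 30, the order of magnitude reported for the human
germline mtDNA bottleneck) controls all drift behaviour, and the
loss probability has the closed form (1 − maf)^N_b used as a test oracle.
De-novo events arrive as Poisson counts per transmission at uniformly
random unmasked non-variant positions; the default rates (0.006
substitutions, 0.02 heteroplasmies per genome per transmission) are chosen
to match the observed scale of a few private events per few hundred
transmissions. De-novo heteroplasmies start above the 20% calling
threshold by default so they are observable; lowering `de_novo_maf_lo`
produces the sub-threshold heteroplasmy that NGS calling reports as a
homoplasmic substitution — the known failure mode of a fixed MAF cutoff.

Reads: depth per position is log-normal with median 370X (σ = 0.35 in log
space, clipped to the 139–1316X range; only those three depth statistics
are modelled, so the distribution family is a pragmatic choice), and base
errors redistribute a per-base error probability (default 0.001) uniformly
over the other three bases. With all rates and errors at zero the full
simulate → pileup → call → compare pipeline returns 100% cannot-exclude,
which is both a test and an acceptance property.

`build_two_family_fixture()` is deterministic (no RNG): a 7-member clan
with one childless carrier of the private substitution A16247G, and a
59-member clan with one childless A8817G carrier plus two individuals
heteroplasmic at 2833 (R; minor-allele fractions 0.39 and 0.27). The
expected outcomes are exactly enumerable — 6 + 58 = 64 inconclusive pairs
and no exclusions among 1732 pairs under isfg rules; under strict rules
174 inconclusive and 2 excluded — and serve as frozen oracles.

What passing tests on synthetic data do **not** show: the generator does
not reproduce any real pedigree topology or meiosis histogram, real
haplogroup background variation, strand bias, alignment artefacts, or
contamination; conclusions about real casework rest on the rule
implementations, not on the simulator.

## Numerical and design notes

* Problem sizes in tests and the acceptance script are desk-scale: the
  200–300 bp homopolymer-rich test references and 3–4 family simulations
  exercise every code path while keeping the whole suite in seconds.
* Region annotation (control region 16024–16569 and 1–576; HVI 16024–16365,
  HVII 57–372, HVIII 438–574) uses cited-convention boundaries and is
  configurable, since guideline documents name the regions without printing
  boundaries.
* Meiosis distance, comparison, and classification are all deterministic;
  the only RNG consumers are the simulator and the Monte-Carlo Fisher test,
  both of which take explicit seeds and are byte-reproducible.
* Degenerate inputs: empty haplotypes are valid (reference-identical);
  a chi-squared table with dropped zero margins adjusts df; Fisher on a
  zero-margin table returns p = 1 (single attainable configuration).

## Limitations

* No alignment or read mapping: input is variant strings or per-position
  counts; BAM ingestion, strand/quality filtering, and haplogroup-aware
  alignment are out of scope.
* No likelihood-ratio or haplotype-frequency weighting of matches;
  classification is purely count-based.
* Heteroplasmy is limited to two alleles per position; tissue-specific
  heteroplasmy differences are not modelled.
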