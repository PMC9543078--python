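"""Pedigree growth, bottleneck heteroplasmy transmission, and read simulation."""

import numpy as np
import pytest

from mitokin import (CallingConfig, MitoHaplotype, Mode, Outcome, PositionCall,
                     SimulationConfig, Variant, VariantKind, call_haplotype,
                     compare_all, enumerate_pairs, maternal_clans,
                     simulate_haplotypes, simulate_pedigree, simulate_reads,
                     transmit)
from mitokin.simulate import SimulationError


def het_mother(ref, position=None, maf=0.3, sample_id="mum"):
    """Haplotype with one point heteroplasmy: minor allele is non-reference."""
    position = position or 120
    ref_base = ref.base(position)
    alt = "A" if ref_base != "A" else "G"
    v = Variant(kind=VariantKind.POINT_HETEROPLASMY, position=position,
                call=PositionCall(position=position, alleles=frozenset((ref_base, alt)),
                                  maf=maf, minor_allele=alt))
    return MitoHaplotype(sample_id, (v,), ref.name), position, alt


class TestTransmit:
    def test_zero_rates_no_heteroplasmy_is_identity(self, small_ref):
        config = SimulationConfig(substitution_rate=0, heteroplasmy_rate=0)
        mother = MitoHaplotype("mum", (), small_ref.name)
        rng = np.random.default_rng(0)
        child, event = transmit(mother, small_ref, config, rng, "kid")
        assert child.variants == ()
        assert not event.de_novo_substitutions and not event.de_novo_heteroplasmies

    def test_homoplasmic_variants_inherited_verbatim(self, small_ref):
        config = SimulationConfig(substitution_rate=0, heteroplasmy_rate=0)
        position = 30
        alt = "A" if small_ref.base(position) != "A" else "G"
        mother = MitoHaplotype("mum", (
            Variant(kind=VariantKind.SUBSTITUTION, position=position,
                    call=PositionCall(position, frozenset(alt))),), small_ref.name)
        child, _ = transmit(mother, small_ref, config, np.random.default_rng(1), "kid")
        assert child.variants == mother.variants

    def test_minor_allele_frequency_is_a_martingale(self, small_ref):
        """Across one bottleneck the expected minor-allele frequency equals
        the mother's MAF."""
        config = SimulationConfig(substitution_rate=0, heteroplasmy_rate=0,
                                  bottleneck_size=30)
        mother, position, alt = het_mother(small_ref, maf=0.3)
        rng = np.random.default_rng(42)
        freqs = []
        for _ in range(10_000):
            child, _ = transmit(mother, small_ref, config, rng, "kid")
            v = child.point_variants.get(position)
            if v is None:
                freqs.append(0.0)  # minor (non-reference) allele lost
            elif v.kind is VariantKind.SUBSTITUTION:
                freqs.append(1.0)  # minor allele fixed
            else:
                f = v.call.maf if v.call.minor_allele == alt else 1 - v.call.maf
                freqs.append(f)
        # SE of the mean ~ sd(Binomial(30, .3)/30)/sqrt(1e4) ~ 0.00084
        assert np.mean(freqs) == pytest.approx(0.3, abs=0.005)

    def test_loss_probability_matches_binomial_zero_draw(self, small_ref):
        config = SimulationConfig(substitution_rate=0, heteroplasmy_rate=0,
                                  bottleneck_size=10)
        mother, position, alt = het_mother(small_ref, maf=0.1)
        rng = np.random.default_rng(7)
        losses = 0
        reps = 10_000
        for _ in range(reps):
            child, event = transmit(mother, small_ref, config, rng, "kid")
            losses += position in event.losses
        expected = 0.9 ** 10  # ~0.3487
        assert losses / reps == pytest.approx(expected, abs=0.02)

    def test_smaller_bottleneck_fixes_or_loses_more(self, small_ref):
        def fix_loss_rate(n_b, seed):
            config = SimulationConfig(substitution_rate=0, heteroplasmy_rate=0,
                                      bottleneck_size=n_b)
            mother, position, _ = het_mother(small_ref, maf=0.3)
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(3000):
                _, event = transmit(mother, small_ref, config, rng, "kid")
                hits += (position in event.losses) or (position in event.fixations)
            return hits / 3000

        assert fix_loss_rate(5, 1) > fix_loss_rate(50, 2)


class TestSimulatePedigree:
    def test_minimal_two_generation_family(self):
        config = SimulationConfig(n_families=1, generations_total=2,
                                  sampled_generations=2, offspring_mean=1.0,
                                  sampling_fraction=1.0)
        # offspring_mean 1 may still produce 0 children; find a seed that does not
        ped = simulate_pedigree(config, np.random.default_rng(3))
        clans = maternal_clans(ped)
        assert len(clans) == 1

    def test_clan_count_equals_n_families(self):
        config = SimulationConfig(n_families=45, generations_total=3,
                                  offspring_mean=1.5)
        ped = simulate_pedigree(config, np.random.default_rng(5))
        assert len(maternal_clans(ped)) == 45

    def test_pair_count_is_sum_of_binomials_over_sampled_clans(self):
        config = SimulationConfig(n_families=6, generations_total=4,
                                  offspring_mean=2.0, sampling_fraction=0.8)
        ped = simulate_pedigree(config, np.random.default_rng(9))
        pairs, _ = enumerate_pairs(ped)
        clans = maternal_clans(ped)
        expected = sum(
            k * (k - 1) // 2
            for members in clans.values()
            for k in [sum(ped.individuals[m].sampled for m in members)])
        assert len(pairs) == expected

    def test_zero_offspring_mean_flagged(self):
        config = SimulationConfig(offspring_mean=0.0)
        with pytest.raises(SimulationError, match="cannot grow"):
            simulate_pedigree(config, np.random.default_rng(0))

    def test_same_seed_reproduces_everything(self, small_ref):
        config = SimulationConfig(n_families=3, generations_total=4,
                                  offspring_mean=2.0, sampling_fraction=1.0,
                                  substitution_rate=0.05, heteroplasmy_rate=0.05)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            ped = simulate_pedigree(config, rng)
            haps, events = simulate_haplotypes(ped, small_ref, config, rng)
            runs.append((sorted(ped.individuals),
                         {s: h.variants for s, h in haps.items()}, len(events)))
        assert runs[0] == runs[1]


class TestSimulateReads:
    def test_depth_respects_configured_bounds(self, small_ref):
        config = SimulationConfig(depth_median=370, depth_min=139, depth_max=1316)
        hap = MitoHaplotype("s", (), small_ref.name)
        pileup = simulate_reads(hap, small_ref, config, np.random.default_rng(2))
        depth = pileup.depth()
        assert depth.min() >= 139 and depth.max() <= 1316

    def test_error_free_homoplasmic_reads_recover_haplotype(self, small_ref):
        config = SimulationConfig(error_rate=0.0, depth_median=50,
                                  depth_min=1, depth_max=200)
        position = 30
        alt = "A" if small_ref.base(position) != "A" else "G"
        hap = MitoHaplotype("s", (
            Variant(kind=VariantKind.SUBSTITUTION, position=position,
                    call=PositionCall(position, frozenset(alt))),), small_ref.name)
        pileup = simulate_reads(hap, small_ref, config, np.random.default_rng(4))
        called = call_haplotype(pileup, small_ref, sample_id="s")
        assert called.variants == hap.variants

    def test_heteroplasmy_maf_recovered_within_binomial_bounds(self, small_ref):
        config = SimulationConfig(error_rate=0.0, depth_median=370,
                                  depth_min=370, depth_max=370)
        mother, position, alt = het_mother(small_ref, maf=0.39, sample_id="s")
        pileup = simulate_reads(mother, small_ref, config, np.random.default_rng(8))
        (v,) = call_haplotype(pileup, small_ref, sample_id="s").variants
        assert v.kind is VariantKind.POINT_HETEROPLASMY
        # 99% binomial band for 370 draws at p = 0.39 is ~0.39 +/- 0.065
        assert v.call.maf == pytest.approx(0.39, abs=0.07)


class TestEndToEnd:
    def test_zero_mutation_zero_error_gives_all_cannot_exclude(self, small_ref):
        """Simulation -> pileups -> calling -> comparison with every rate at
        zero must classify every maternal pair as cannot-exclude."""
        config = SimulationConfig(n_families=3, generations_total=4,
                                  sampled_generations=4, offspring_mean=1.8,
                                  sampling_fraction=1.0,
                                  substitution_rate=0.0, heteroplasmy_rate=0.0,
                                  error_rate=0.0, depth_median=40,
                                  depth_min=5, depth_max=100)
        rng = np.random.default_rng(77)
        ped = simulate_pedigree(config, rng)
        haps, _ = simulate_haplotypes(ped, small_ref, config, rng)
        sampled = [i for i, ind in ped.individuals.items() if ind.sampled]
        called = {}
        for sample_id in sampled:
            pileup = simulate_reads(haps[sample_id], small_ref, config, rng)
            called[sample_id] = call_haplotype(pileup, small_ref,
                                               CallingConfig(), sample_id)
        pairs, _ = enumerate_pairs(ped)
        assert pairs, "simulated pedigree produced no sampled pairs"
        for mode in Mode:
            table, _, _ = compare_all(pairs, called, mode, small_ref)
            assert table.count(Outcome.CANNOT_EXCLUDE) == table.n_pairs
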