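"""Genome profiles, the rank-sum test against its enumeration oracle and
scipy, group comparisons on planted effects, trends, and localization."""

import numpy as np
import pytest
import scipy.stats

from domarch.architecture import build_architecture
from domarch.comparative_stats import (
    Alternative,
    GenomeProfile,
    Method,
    build_profiles,
    compare_groups,
    exact_rank_sum_p,
    localization_fractions,
    rank_sum_test,
    size_trend,
)
from domarch.io_formats import (
    GenomeMetadata,
    Gram,
    Habitat,
    Kingdom,
    Localization,
    LocalizationRecord,
    Oxygen,
)
from domarch.synthetic_data import CohortConfig, sample_counts, truth_profiles

from conftest import make_hit


def meta(taxon="T1", kingdom=Kingdom.EUBACTERIA, oxygen=Oxygen.AEROBIC,
         habitat=Habitat.AQUATIC, gram=Gram.NEGATIVE, size=4.0):
    return GenomeMetadata(taxon_id=taxon, organism=taxon, kingdom=kingdom,
                          phylum="Proteobacteria", gram=gram, habitat=habitat,
                          oxygen=oxygen, genome_size_mb=size)


def profile(metadata, n, loc=None, domains=None, multi=0):
    loc = loc or {Localization.NAN: n}
    return GenomeProfile(metadata=metadata, n_pdz_proteins=n,
                         n_pdz_domains=domains if domains is not None else n,
                         n_multidomain=multi, loc_counts=loc)


class TestBuildProfiles:
    def test_tandem_only_protein_is_not_multidomain(self):
        archs = {
            "p1": build_architecture("p1", [
                make_hit("p1", "PDZ", start=10, end=90),
                make_hit("p1", "PDZ", start=110, end=190),
            ]),
            "p2": build_architecture("p2", [
                make_hit("p2", "PDZ", start=10, end=90),
                make_hit("p2", "Trypsin", start=120, end=340),
            ]),
        }
        locs = [LocalizationRecord("p1", Localization.SP),
                LocalizationRecord("p2", Localization.TM)]
        (prof,) = build_profiles(archs, locs, [meta()], {"p1": "T1", "p2": "T1"})
        assert prof.n_pdz_proteins == 2
        assert prof.n_pdz_domains == 3
        assert prof.n_multidomain == 1
        assert sum(prof.loc_counts.values()) == prof.n_pdz_proteins

    def test_genome_without_pdz_gets_zero_profile(self):
        (prof,) = build_profiles({}, [], [meta()], {})
        assert prof.n_pdz_proteins == prof.n_pdz_domains == prof.n_multidomain == 0

    def test_unknown_genome_raises(self):
        archs = {"p1": build_architecture("p1", [make_hit("p1", "PDZ")])}
        with pytest.raises(ValueError, match="p1"):
            build_profiles(archs, [], [meta()], {"p1": "NOPE"})


class TestRankSum:
    def test_exact_small_sample_one_sided(self):
        res = rank_sum_test([1, 2], [3, 4], Alternative.LESS)
        assert res.method is Method.EXACT
        assert res.p == pytest.approx(1 / 6)

    def test_identical_samples_two_sided(self):
        res = rank_sum_test([1, 2, 3] * 4, [1, 2, 3] * 4, Alternative.TWO_SIDED)
        assert res.p >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0], Alternative.LESS)

    def test_oracle_enumeration_examples(self):
        assert exact_rank_sum_p([1, 2], [3, 4], "LESS") == pytest.approx(1 / 6)
        assert exact_rank_sum_p([5], [1], "GREATER") == pytest.approx(0.5)

    def test_oracle_lower_bound(self, rng):
        from math import comb
        for _ in range(20):
            n1, n2 = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            p = exact_rank_sum_p(x, y, "GREATER")
            assert 1 / comb(n1 + n2, n1) <= p <= 1

    def test_test_agrees_with_oracle_exact_path(self, rng):
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 7))
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            for alt in Alternative:
                assert rank_sum_test(x, y, alt).p == pytest.approx(
                    exact_rank_sum_p(x, y, alt))

    def test_normal_close_to_exact_one_sided(self, rng):
        # one-sided, as used throughout the group comparisons; the two-sided
        # p doubles a tail and with it the approximation error
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(8, 15))
            n1 = int(rng.integers(3, n - 2))
            vals = rng.normal(size=n)
            x, y = vals[:n1], vals[n1:]
            for alt in (Alternative.GREATER, Alternative.LESS):
                pn = rank_sum_test(x, y, alt, method="normal").p
                pe = exact_rank_sum_p(x, y, alt)
                worst = max(worst, abs(pn - pe))
        assert worst <= 0.02

    def test_matches_scipy_with_ties(self, rng):
        """Independent cross-check of the tie-corrected normal path."""
        for _ in range(25):
            x = rng.poisson(5, size=20).astype(float)
            y = rng.poisson(6, size=25).astype(float)
            ours = rank_sum_test(x, y, Alternative.GREATER)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="greater",
                                           method="asymptotic")
            assert ours.U == pytest.approx(ref.statistic)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-8)


class TestCompareGroups:
    def test_planted_oxygen_effect_detected(self):
        cfg = CohortConfig(n_genomes=60, seed=77, balanced_phenotypes=True,
                           oxygen_means={Oxygen.AEROBIC: 8.0, Oxygen.ANAEROBIC: 3.0},
                           habitat_factors={Habitat.MULTIPLE: 1.0},
                           size_scaling=False)
        profiles = truth_profiles(sample_counts(cfg))
        (comp,) = compare_groups(profiles, "oxygen", measure="proteins")
        assert comp.left_label == "NON_AEROBIC"
        assert comp.right_label == "AEROBIC"
        assert comp.result.significant

    def test_na_genomes_excluded_and_small_groups_skipped(self, caplog):
        profiles = [profile(meta(f"T{i}", gram=Gram.NEGATIVE), 3) for i in range(4)]
        profiles.append(profile(meta("T9", gram=Gram.NA), 3))
        with caplog.at_level("WARNING"):
            out = compare_groups(profiles, "gram")
        assert out == []  # no Gram-positive genomes at all
        assert "skipping" in caplog.text

    def test_direction_is_right_side_higher(self):
        low = [profile(meta(f"A{i}", oxygen=Oxygen.ANAEROBIC), 1) for i in range(10)]
        high = [profile(meta(f"B{i}", oxygen=Oxygen.AEROBIC), 10) for i in range(10)]
        (comp,) = compare_groups(low + high, "oxygen", measure="proteins")
        assert comp.result.alternative is Alternative.LESS
        assert comp.result.significant

    def test_bh_adjustment_monotone(self):
        profiles = [profile(meta(f"E{i}", kingdom=Kingdom.EUBACTERIA), 5 + i % 3)
                    for i in range(10)]
        profiles += [profile(meta(f"A{i}", kingdom=Kingdom.ARCHAEA), 2) for i in range(5)]
        profiles += [profile(meta(f"F{i}", kingdom=Kingdom.FUNGI), 1) for i in range(5)]
        out = compare_groups(profiles, "kingdom", measure="proteins", adjust=True)
        for c in out:
            assert c.p_adjusted is not None and c.p_adjusted >= c.result.p


class TestSizeTrend:
    def test_perfect_monotone_relation(self):
        profiles = [profile(meta(f"T{i}", size=1.0 + i), 2 * i + 1) for i in range(8)]
        rho, p = size_trend(profiles, Kingdom.EUBACTERIA)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_counts_rejected(self):
        profiles = [profile(meta(f"T{i}", size=1.0 + i), 3) for i in range(8)]
        with pytest.raises(ValueError):
            size_trend(profiles, Kingdom.EUBACTERIA)

    def test_permuted_sizes_give_small_rho(self, rng):
        counts = list(range(40))
        rng.shuffle(counts)
        profiles = [profile(meta(f"T{i}", size=1.0 + i), counts[i]) for i in range(40)]
        rho, p = size_trend(profiles, Kingdom.EUBACTERIA)
        assert abs(rho) < 0.35

    def test_planted_eubacterial_trend_only(self):
        cfg = CohortConfig(n_genomes=80, seed=5)
        profiles = truth_profiles(sample_counts(cfg))
        rho, p = size_trend(profiles, Kingdom.EUBACTERIA)
        assert rho > 0 and p < 0.05


class TestLocalizationFractions:
    def test_fraction_arithmetic(self):
        prof = profile(meta(), 10, loc={Localization.TM: 5, Localization.SP: 3,
                                        Localization.TMSP: 1, Localization.CYT: 1})
        table = localization_fractions([prof])
        assert table.loc["ALL", "CYT"] == pytest.approx(0.1)
        assert table.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])

    def test_nan_category_excluded_from_denominator(self):
        prof = profile(meta(), 4, loc={Localization.TM: 2, Localization.CYT: 1,
                                       Localization.NAN: 1, Localization.SP: 0,
                                       Localization.TMSP: 0})
        table = localization_fractions([prof])
        assert table.loc["ALL", "TM"] == pytest.approx(2 / 3)

    def test_zero_known_category_is_error(self):
        prof = profile(meta(), 2, loc={Localization.NAN: 2})
        with pytest.raises(ValueError):
            localization_fractions([prof])
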