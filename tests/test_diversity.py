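"""Diversity estimators, the exact HWE test and the locus screen."""

import numpy as np
import pytest

from valleypop.datamodel import MISSING, DataError, GenotypeTable
from valleypop.diversity import (
    allele_frequencies,
    expected_heterozygosity_unbiased,
    genotype_counts_at_locus,
    hwe_exact_test,
    null_allele_frequency,
    observed_heterozygosity,
    screen_loci,
    summarise_loci,
)
from valleypop.simulate import SimulationConfig, simulate_allele_freqs, simulate_genotypes


def table_from_calls(calls):
    calls = np.asarray(calls)
    return GenotypeTable(
        [f"s{i}" for i in range(calls.shape[0])],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
    )


class TestAlleleFrequencies:
    def test_simple_tally(self):
        t = table_from_calls([[[1, 1]], [[1, 2]]])
        assert allele_frequencies(t, "L0") == {1: 0.75, 2: 0.25}

    def test_missing_excluded_from_denominator(self):
        t = table_from_calls([[[1, 1]], [[MISSING, MISSING]]])
        assert allele_frequencies(t, "L0") == {1: 1.0}

    def test_matches_brute_force_tally(self, rng):
        calls = rng.integers(1, 5, size=(6, 1, 2))
        t = table_from_calls(calls)
        freqs = allele_frequencies(t, "L0")
        flat = list(np.sort(calls, axis=2).ravel())
        for a, f in freqs.items():
            assert f == pytest.approx(flat.count(a) / 12)

    def test_all_missing_raises(self):
        t = table_from_calls([[[MISSING, MISSING]]])
        with pytest.raises(DataError):
            allele_frequencies(t, "L0")


class TestHeterozygosity:
    def test_observed_fraction(self):
        t = table_from_calls([[[1, 2]], [[1, 1]]])
        assert observed_heterozygosity(t, "L0") == 0.5
        t2 = table_from_calls([[[1, 2]], [[2, 3]]])
        assert observed_heterozygosity(t2, "L0") == 1.0

    def test_observed_matches_direct_count(self, rng):
        calls = rng.integers(1, 4, size=(20, 1, 2))
        t = table_from_calls(calls)
        direct = np.mean(calls[:, 0, 0] != calls[:, 0, 1])
        assert observed_heterozygosity(t, "L0") == pytest.approx(direct)

    @pytest.mark.parametrize(
        "p, n, expected",
        [((0.5, 0.5), 2, 4 / 3 * 0.5), ((1.0,), 5, 0.0), ((0.2, 0.3, 0.5), 10, 20 / 19 * 0.62)],
    )
    def test_unbiased_h_e_closed_form(self, p, n, expected):
        assert expected_heterozygosity_unbiased(p, n) == pytest.approx(expected)

    def test_unbiased_exceeds_plugin_by_exact_factor(self, rng):
        p = rng.dirichlet(np.ones(4))
        n = 17
        plug = 1 - np.sum(p**2)
        assert expected_heterozygosity_unbiased(p, n) == pytest.approx(
            plug * 2 * n / (2 * n - 1)
        )


class TestHweExact:
    def test_balanced_biallelic_is_p_one(self):
        assert hwe_exact_test({(1, 1): 1, (1, 2): 2, (2, 2): 1}) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_exact_test({(1, 1): 10}) == 1.0

    def test_strong_heterozygote_deficit(self):
        p = hwe_exact_test({(1, 1): 10, (2, 2): 10})
        # full-enumeration value for complete het deficit at n_A = n_B = 20
        assert p < 0.01

    def test_biallelic_enumeration_sums_conditional_distribution(self):
        # p-value = sum of conditional probabilities <= observed; check that
        # summing the whole distribution gives 1
        from valleypop.diversity import _hwe_exact_biallelic

        assert _hwe_exact_biallelic(0, 20, 0) <= 1.0
        total = _hwe_exact_biallelic(5, 10, 5)
        assert 0 < total <= 1.0

    def test_monte_carlo_deterministic_given_seed(self):
        counts = {(1, 1): 4, (1, 2): 3, (2, 3): 5, (3, 3): 2, (1, 3): 1}
        p1 = hwe_exact_test(counts, n_mc=500, seed=7)
        p2 = hwe_exact_test(counts, n_mc=500, seed=7)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_pvalues_superuniform_under_null(self):
        """Exact-test p-values are stochastically >= uniform on HWE data."""
        rng = np.random.default_rng(99)
        pvals = []
        n = 40
        for _ in range(500):
            q = rng.uniform(0.15, 0.85)
            geno = rng.choice(3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2])
            counts = {
                (1, 1): int(np.sum(geno == 0)),
                (1, 2): int(np.sum(geno == 1)),
                (2, 2): int(np.sum(geno == 2)),
            }
            pvals.append(hwe_exact_test(counts))
        pvals = np.asarray(pvals)
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert np.mean(pvals <= t) <= t + 0.03


class TestNullAllele:
    def test_closed_form(self):
        assert null_allele_frequency(0.73, 0.58) == pytest.approx(0.0867, abs=5e-4)
        assert null_allele_frequency(0.5, 0.5) == 0.0
        assert null_allele_frequency(0.4, 0.6) < 0  # retained as-is


class TestScreen:
    def _summaries(self, seed=0, n_bad=3, n_loci=27):
        """Simulate marker panel with n_bad loci showing null-allele-style
        heterozygote deficits (half of true heterozygotes read homozygous)."""
        rng = np.random.default_rng(seed)
        n = 120
        calls = np.zeros((n, n_loci, 2), dtype=np.int64)
        for j in range(n_loci):
            p = rng.dirichlet(np.ones(6)) + 0.02
            p /= p.sum()
            a = rng.choice(6, size=n, p=p) + 1
            b = rng.choice(6, size=n, p=p) + 1
            if j < n_bad:
                het = a != b
                fake = het & (rng.random(n) < 0.6)
                b = np.where(fake, a, b)
            calls[:, j, 0] = a
            calls[:, j, 1] = b
        t = GenotypeTable(
            [f"s{i}" for i in range(n)], [f"L{j:02d}" for j in range(n_loci)], calls
        )
        return summarise_loci(t, n_mc=2000, seed=seed)

    def test_panel_screen_discards_deficit_loci(self):
        summaries = self._summaries()
        retained, discarded = screen_loci(summaries)
        assert sorted(discarded) == ["L00", "L01", "L02"]
        assert len(retained) == 24

    def test_hwe_panel_all_retained(self):
        cfg = SimulationConfig(
            seed=5, n_per_population=(60, 60), n_loci=10, f_st=0.01,
            f_inbreeding=0.0, missing_rate=0.0,
        )
        table, _ = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
        summaries = summarise_loci(table, n_mc=1000, seed=3)
        retained, discarded = screen_loci(summaries)
        assert discarded == []

    def test_alpha_zero_is_vacuous(self):
        summaries = self._summaries()
        retained, discarded = screen_loci(summaries, hwe_alpha=0.0)
        assert discarded == []


def test_mean_ho_matches_he_without_inbreeding():
    """Under random mating (f = 0) observed and expected heterozygosity agree."""
    cfg = SimulationConfig(
        seed=17, n_per_population=(100,), population_names=("only",),
        n_loci=200, f_st=0.0, f_inbreeding=0.0, missing_rate=0.0,
    )
    table, _ = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
    summaries = summarise_loci(table, n_mc=1, seed=0)
    h_o = np.mean([s.h_obs for s in summaries])
    h_e = np.mean([s.h_exp for s in summaries])
    assert h_o == pytest.approx(h_e, abs=0.02)
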