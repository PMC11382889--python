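"""Hierarchical AMOVA: sums of squares against a brute-force pairwise
oracle, F-statistic identities, permutation tests and the stratified suite."""

import numpy as np
import pytest

from valleypop.amova import (
    AmovaResult,
    amova_components,
    f_statistics_from_components,
    percent_variation,
    permutation_test,
    run_amova_suite,
)
from valleypop.datamodel import (
    MISSING,
    DataError,
    GenotypeTable,
    join_tables,
    make_metadata,
)
from valleypop.simulate import SimulationConfig, simulate_allele_freqs, simulate_genotypes


# ---------------------------------------------------------------------------
# Independent oracle: sums of squares from the pairwise mismatch matrix
# ---------------------------------------------------------------------------

def brute_force_ss(calls_locus, labels):
    """SS per stratum from squared pairwise allele mismatches.

    For any set of M allele copies, SS = (1/M) * sum_{i<j} d2_ij with
    d2 = 1 when the copies differ.  Typed individuals only.
    """
    labels = np.asarray(labels)
    typed = calls_locus[:, 0] != MISSING
    calls = calls_locus[typed]
    labs = labels[typed]

    def ss_of(copies):
        M = len(copies)
        total = 0.0
        for i in range(M):
            for j in range(i + 1, M):
                total += float(copies[i] != copies[j])
        return total / M

    all_copies = calls.ravel()
    ss_total = ss_of(all_copies)
    ss_wp = sum(ss_of(calls[labs == g].ravel()) for g in set(labs))
    ss_wi = sum(ss_of(pair) for pair in calls)
    return ss_total - ss_wp, ss_wp - ss_wi, ss_wi


def random_instance(rng, max_n=10):
    n = int(rng.integers(4, max_n + 1))
    n1 = int(rng.integers(2, n - 1))
    calls = rng.integers(1, 4, size=(n, 1, 2))
    if rng.random() < 0.3:  # sprinkle missing genotypes
        calls[rng.integers(0, n)] = MISSING
    labels = np.array(["p1"] * n1 + ["p2"] * (n - n1))
    table = GenotypeTable([f"s{i}" for i in range(n)], ["L0"], calls)
    return table, labels


class TestSumsOfSquares:
    def test_hand_example_matches_oracle(self, tiny_two_pop):
        table, labels = tiny_two_pop
        res = amova_components(table, labels)
        ss_a, ss_b, ss_c = brute_force_ss(table.calls[:, 0, :], labels)
        assert res.ss[0] == pytest.approx(ss_a)
        assert res.ss[1] == pytest.approx(ss_b)
        assert res.ss[2] == pytest.approx(ss_c)

    def test_random_instances_match_oracle(self, rng):
        """Exhaustive check on 200 random instances with <= 10 individuals."""
        checked = 0
        while checked < 200:
            table, labels = random_instance(rng)
            typed = table.typed_mask()[:, 0]
            sizes = [np.sum(typed & (labels == g)) for g in set(labels)]
            if min(sizes) < 2:
                continue
            res = amova_components(table, labels)
            oracle = brute_force_ss(table.calls[:, 0, :], labels)
            for got, want in zip(res.ss[:3], oracle):
                assert got == pytest.approx(want, abs=1e-9)
            checked += 1


class TestFStatistics:
    def test_published_component_arithmetic(self):
        f_is, f_st, f_it = f_statistics_from_components(0.120, 1.454, 6.102)
        assert round(f_st, 3) == 0.016
        f_is, f_st, f_it = f_statistics_from_components(0.112, 1.424, 6.139)
        assert round(f_st, 3) == 0.015

    def test_zero_between_component(self):
        _, f_st, _ = f_statistics_from_components(0.0, 1.3, 4.2)
        assert f_st == 0.0

    def test_fixation_identity_to_machine_precision(self, rng):
        for _ in range(50):
            a, b, c = rng.uniform(0.01, 5.0, size=3)
            f_is, f_st, f_it = f_statistics_from_components(a, b, c)
            assert (1 - f_it) == pytest.approx((1 - f_is) * (1 - f_st), rel=1e-12)

    def test_nonpositive_total_raises(self):
        with pytest.raises(DataError):
            f_statistics_from_components(-1.0, 0.5, 0.4)


class TestPercentVariation:
    def test_published_percentages(self):
        pct = percent_variation(0.120, 1.454, 6.102)
        assert pct[0] == pytest.approx(1.57, abs=0.02)
        assert pct[1] == pytest.approx(18.94, abs=0.02)
        assert pct[2] == pytest.approx(79.49, abs=0.02)
        assert sum(pct) == pytest.approx(100.0)
        assert percent_variation(0.148, 1.566, 6.147)[0] == pytest.approx(1.88, abs=0.02)

    def test_degenerate_single_component(self):
        assert percent_variation(1.0, 0.0, 0.0) == (100.0, 0.0, 0.0)

    def test_negative_component_truncated(self):
        pct = percent_variation(-0.3, 1.0, 1.0)
        assert pct[0] == 0.0
        assert sum(pct) == pytest.approx(100.0)


class TestComponents:
    def test_identical_populations_give_no_between_signal(self, rng):
        half = rng.integers(1, 4, size=(10, 3, 2))
        calls = np.concatenate([half, half])
        table = GenotypeTable([f"s{i}" for i in range(20)], ["A", "B", "C"], calls)
        labels = np.array(["p1"] * 10 + ["p2"] * 10)
        res = amova_components(table, labels)
        assert res.sigma2[0] <= 1e-12
        assert res.sigma2_truncated[0] == 0.0
        assert res.percent[0] == 0.0

    def test_df_bookkeeping(self):
        cfg = SimulationConfig(seed=1, missing_rate=0.0)
        table, meta = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
        res = amova_components(table, meta["population"].to_numpy())
        assert res.df == (1, 169, 171, 341)

    def test_balding_nichols_fst_recovery(self):
        cfg = SimulationConfig(
            seed=8, n_per_population=(100, 100), n_loci=200,
            f_st=0.1, f_inbreeding=0.0, missing_rate=0.0,
        )
        table, meta = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
        res = amova_components(table, meta["population"].to_numpy())
        assert res.f_st == pytest.approx(0.1, abs=0.02)

    def test_single_population_raises(self, rng):
        table, _ = random_instance(rng)
        with pytest.raises(DataError):
            amova_components(table, ["p1"] * table.n_samples)


class TestPermutation:
    def test_fixed_differences_give_minimum_p(self):
        calls = np.zeros((12, 5, 2), dtype=np.int64)
        calls[:6] = 1
        calls[6:] = 2
        table = GenotypeTable([f"s{i}" for i in range(12)], [f"L{j}" for j in range(5)], calls)
        labels = np.array(["p1"] * 6 + ["p2"] * 6)
        p = permutation_test(table, labels, "F_ST", n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    @pytest.mark.parametrize("stat", ["F_ST", "F_IS", "F_IT"])
    def test_p_in_unit_interval(self, rng, stat):
        cfg = SimulationConfig(
            seed=3, n_per_population=(12, 12), n_loci=4,
            f_st=0.02, f_inbreeding=0.05, missing_rate=0.0,
        )
        table, meta = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
        p = permutation_test(table, meta["population"].to_numpy(), stat, n_perm=49, seed=4)
        assert 0 < p <= 1

    def test_null_p_uniform_mean(self):
        """Without structure, permutation p-values centre near 0.5."""
        ps = []
        for s in range(40):
            cfg = SimulationConfig(
                seed=s, n_per_population=(12, 12), n_loci=5,
                f_st=0.0, f_inbreeding=0.0, missing_rate=0.0,
                allele_count_mean=4.0, allele_count_range=(2, 8),
            )
            table, meta = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
            ps.append(
                permutation_test(table, meta["population"].to_numpy(), "F_ST",
                                 n_perm=99, seed=1000 + s)
            )
        assert np.mean(ps) == pytest.approx(0.5, abs=0.12)

    def test_degenerate_labels_raise(self, rng):
        table, _ = random_instance(rng)
        with pytest.raises(DataError):
            permutation_test(table, ["p1"] * table.n_samples, "F_ST", n_perm=9, seed=0)


class TestSuite:
    def test_sex_strata_agree_without_sex_effect(self):
        cfg = SimulationConfig(
            seed=21, n_per_population=(80, 80), n_loci=60,
            f_st=0.05, f_inbreeding=0.0, missing_rate=0.0,
        )
        table, meta = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
        bundle = join_tables(table, meta)
        res = run_amova_suite(bundle, n_permutations=0, permute=False)
        assert res["all"] is not None
        for stratum in ("males", "females"):
            assert res[stratum].f_st == pytest.approx(res["all"].f_st, abs=0.03)

    def test_missing_stratum_skipped(self, rng):
        cfg = SimulationConfig(
            seed=2, n_per_population=(6, 6), n_loci=3, sex_ratio=0.0,
            missing_rate=0.0,
        )
        table, meta = simulate_genotypes(simulate_allele_freqs(cfg), cfg)
        bundle = join_tables(table, meta)
        res = run_amova_suite(bundle, strata=("males",), permute=False)
        assert res["males"] is None

    def test_table_layout(self, tiny_two_pop):
        table, labels = tiny_two_pop
        res = amova_components(table, labels)
        tab = res.table()
        assert list(tab["df"]) == [1, 2, 4, 7]
        assert tab.shape[0] == 4
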