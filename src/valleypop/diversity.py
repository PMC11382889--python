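"""Per-locus diversity summaries and marker screening.

Implements allele-frequency tallies, observed heterozygosity, Nei's
unbiased expected heterozygosity, an exact conditional Hardy–Weinberg test
(full enumeration for biallelic loci, Monte Carlo otherwise), a
Brookfield-style null-allele estimate, and a configurable retain/discard
screen combining HWE departure with the null-allele estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import MISSING, DataError, GenotypeTable


def allele_frequencies(
    table: GenotypeTable, locus: str, sample_subset=None
) -> dict[int, float]:
    """Allele frequencies at one locus, missing genotypes excluded.

    Returns ``{allele_code: frequency}`` summing to 1 over observed alleles.
    """
    counts = allele_counts(table, locus, sample_subset)
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}


def allele_counts(
    table: GenotypeTable, locus: str, sample_subset=None
) -> dict[int, int]:
    j = table.locus_index(locus)
    calls = table.calls[:, j, :]
    if sample_subset is not None:
        calls = calls[table.sample_index(sample_subset)]
    typed = calls[calls[:, 0] != MISSING]
    if typed.size == 0:
        raise DataError(f"locus {locus!r}: all genotypes missing in subset")
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    return {int(a): int(c) for a, c in zip(alleles, counts)}


def observed_heterozygosity(
    table: GenotypeTable, locus: str, sample_subset=None
) -> float:
    """Fraction of typed genotypes carrying two distinct alleles."""
    j = table.locus_index(locus)
    calls = table.calls[:, j, :]
    if sample_subset is not None:
        calls = calls[table.sample_index(sample_subset)]
    typed = calls[calls[:, 0] != MISSING]
    if typed.shape[0] == 0:
        raise DataError(f"locus {locus!r}: all genotypes missing in subset")
    return float(np.mean(typed[:, 0] != typed[:, 1]))


def expected_heterozygosity_unbiased(freqs, n_genotypes: int) -> float:
    """Nei's unbiased H_E = (2n / (2n - 1)) * (1 - sum p_i^2)."""
    if n_genotypes < 1:
        raise DataError("need at least one typed genotype for H_E")
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, float)
    two_n = 2 * n_genotypes
    return float(two_n / (two_n - 1) * (1.0 - np.sum(p**2)))


def null_allele_frequency(h_e: float, h_o: float) -> float:
    """Brookfield estimator r = (H_E - H_O) / (1 + H_E).

    May be negative when H_O exceeds H_E; returned as-is (screening applies
    a threshold to the positive part).
    """
    return (h_e - h_o) / (1.0 + h_e)


# ---------------------------------------------------------------------------
# Exact Hardy–Weinberg test
# ---------------------------------------------------------------------------

def _log_conditional_prob(genotype_counts: np.ndarray) -> float:
    """Log probability of a genotype-count array conditional on allele counts.

    ``genotype_counts`` is a symmetric (J, J) matrix holding homozygote
    counts on the diagonal and heterozygote counts split across (i, j) and
    (j, i) — callers pass the upper triangle in full and zeros below.
    P = n! * prod(allele_count_k!) * 2^n_het / ((2n)! * prod(genotype_count!))
    """
    g = genotype_counts
    n = g.sum()
    het = n - np.trace(g)
    # allele k copies: 2*g[k,k] + off-diagonal row k + off-diagonal column k
    allele = g.sum(axis=0) + g.sum(axis=1)
    return float(
        gammaln(n + 1)
        + np.sum(gammaln(allele + 1))
        + het * np.log(2.0)
        - gammaln(2 * n + 1)
        - np.sum(gammaln(g + 1))
    )


def hwe_exact_test(
    genotype_counts: dict[tuple[int, int], int],
    n_mc: int = 10_000,
    seed: int = 0,
) -> float:
    """Exact conditional test of Hardy–Weinberg genotype proportions.

    ``genotype_counts`` maps unordered allele pairs to counts.  For
    biallelic loci the conditional distribution over heterozygote counts is
    fully enumerated; for more alleles a Monte Carlo version pairs random
    shuffles of the observed allele copies (``n_mc`` draws, seeded).  The
    statistic is the conditional probability itself, so the test is
    two-sided.  A monomorphic locus returns p = 1.0 by convention.
    """
    alleles = sorted({a for pair in genotype_counts for a in pair})
    idx = {a: i for i, a in enumerate(alleles)}
    J = len(alleles)
    if J == 1:
        return 1.0
    g = np.zeros((J, J), dtype=np.int64)
    for (a, b), c in genotype_counts.items():
        i, j = sorted((idx[a], idx[b]))
        g[i, j] += c
    n = int(g.sum())
    if n < 3:
        raise DataError("need at least 3 genotypes for the HWE exact test")

    if J == 2:
        return _hwe_exact_biallelic(
            n_aa=int(g[0, 0]), n_ab=int(g[0, 1]), n_bb=int(g[1, 1])
        )

    logp_obs = _log_conditional_prob(g)
    copies = np.repeat(
        np.arange(J), g.sum(axis=0) + g.sum(axis=1)
    )  # 2n allele copies
    rng = np.random.default_rng(seed)
    hits = 0
    tol = 1e-9
    for _ in range(n_mc):
        rng.shuffle(copies)
        pairs = copies.reshape(n, 2)
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        sim = np.zeros((J, J), dtype=np.int64)
        np.add.at(sim, (lo, hi), 1)
        if _log_conditional_prob(sim) <= logp_obs + tol:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def _hwe_exact_biallelic(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Full enumeration of the conditional heterozygote-count distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    log_base = gammaln(n + 1) + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)

    def logp(h):  # h heterozygotes, same parity as n_a
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return (
            log_base
            + h * np.log(2.0)
            - gammaln(aa + 1)
            - gammaln(h + 1)
            - gammaln(bb + 1)
        )

    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    logps = np.array([logp(int(h)) for h in hs])
    obs = logp(n_ab)
    return float(min(np.exp(logps[logps <= obs + 1e-9]).sum(), 1.0))


def genotype_counts_at_locus(
    table: GenotypeTable, locus: str, sample_subset=None
) -> dict[tuple[int, int], int]:
    j = table.locus_index(locus)
    calls = table.calls[:, j, :]
    if sample_subset is not None:
        calls = calls[table.sample_index(sample_subset)]
    typed = calls[calls[:, 0] != MISSING]
    out: dict[tuple[int, int], int] = {}
    for a, b in typed:
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Locus summaries and screening
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    k_alleles: int
    h_obs: float
    h_exp: float
    hwe_p: float
    null_allele: float
    flag: str = "retain"
    reasons: list[str] = field(default_factory=list)


def summarise_locus(
    table: GenotypeTable,
    locus: str,
    sample_subset=None,
    n_mc: int = 10_000,
    seed: int = 0,
) -> LocusSummary:
    counts = allele_counts(table, locus, sample_subset)
    n = sum(counts.values()) // 2
    freqs = {a: c / (2 * n) for a, c in counts.items()}
    k = len(counts)
    h_o = observed_heterozygosity(table, locus, sample_subset)
    h_e = expected_heterozygosity_unbiased(freqs, n) if k > 1 else 0.0
    if k > 1 and n >= 3:
        p = hwe_exact_test(
            genotype_counts_at_locus(table, locus, sample_subset),
            n_mc=n_mc,
            seed=seed,
        )
    else:
        p = 1.0
    return LocusSummary(
        locus=locus,
        n_typed=n,
        k_alleles=k,
        h_obs=h_o,
        h_exp=h_e,
        hwe_p=p,
        null_allele=null_allele_frequency(h_e, h_o),
    )


def summarise_loci(
    table: GenotypeTable, sample_subset=None, n_mc: int = 10_000, seed: int = 0
) -> list[LocusSummary]:
    return [
        summarise_locus(table, loc, sample_subset, n_mc=n_mc, seed=seed + j)
        for j, loc in enumerate(table.loci)
    ]


def screen_loci(
    summaries: list[LocusSummary],
    hwe_alpha: float = 0.05,
    null_allele_max: float = 0.2,
    bonferroni: bool = True,
) -> tuple[list[str], list[str]]:
    """Partition loci into (retained, discarded) with per-locus reasons.

    A locus is discarded when it departs from Hardy–Weinberg at the
    (optionally Bonferroni-corrected) ``hwe_alpha`` level AND its estimated
    null-allele frequency exceeds ``null_allele_max`` — i.e. the departure
    looks like a genotyping artefact, not mere inbreeding.  ``hwe_alpha=0``
    disables the filter.  Flags and reasons are written onto the summaries.
    """
    alpha = hwe_alpha / len(summaries) if (bonferroni and summaries) else hwe_alpha
    retained, discarded = [], []
    for s in summaries:
        reasons = []
        if alpha > 0 and s.hwe_p < alpha:
            reasons.append(f"HWE p={s.hwe_p:.4g} < alpha={alpha:.4g}")
        if s.null_allele > null_allele_max:
            reasons.append(
                f"null-allele estimate {s.null_allele:.3f} > {null_allele_max}"
            )
        if len(reasons) == 2:
            s.flag = "discard"
            s.reasons = reasons
            discarded.append(s.locus)
        else:
            s.flag = "retain"
            s.reasons = reasons
            retained.append(s.locus)
    return retained, discarded


def summary_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": s.locus,
                "n_typed": s.n_typed,
                "k_alleles": s.k_alleles,
                "h_obs": s.h_obs,
                "h_exp": s.h_exp,
                "hwe_p": s.hwe_p,
                "null_allele": s.null_allele,
                "flag": s.flag,
            }
            for s in summaries
        ]
    )
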