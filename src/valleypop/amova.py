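"""Three-level hierarchical AMOVA for diploid multilocus genotypes.

Variance in allelic identity is partitioned among populations (sigma2_a),
among individuals within populations (sigma2_b) and within individuals
(sigma2_c), locus by locus, using the number-of-different-alleles distance.
F-statistics follow from the components:

    F_ST = sigma2_a / total
    F_IS = sigma2_b / (sigma2_b + sigma2_c)
    F_IT = (sigma2_a + sigma2_b) / total

so that (1 - F_IT) = (1 - F_IS)(1 - F_ST) exactly.  Sums of squares are
computed from allele-count tallies; on any instance they equal the
brute-force average of squared pairwise allele mismatches within groups.
Significance is assessed by permutation with a scheme per statistic
(individuals among populations for F_ST; allele copies within populations
for F_IS; allele copies across all individuals for F_IT).

Multi-locus statistics are ratios of variance components summed over loci
(the "ratio of sums" convention); per-locus ratios and their plain mean are
also reported because the field's reporting conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, DataError, GenotypeTable

STRATA_NAMES = (
    "among populations",
    "among individuals within populations",
    "within individuals",
)


@dataclass
class AmovaResult:
    """Variance components, F-statistics and bookkeeping for one AMOVA."""

    df: tuple[int, int, int, int]  # among pops, among ind, within ind, total
    ss: tuple[float, float, float, float]
    sigma2: tuple[float, float, float]  # raw (possibly negative) estimates
    sigma2_truncated: tuple[float, float, float]
    percent: tuple[float, float, float]
    f_is: float
    f_st: float
    f_it: float
    f_is_mean_of_ratios: float = float("nan")
    f_st_mean_of_ratios: float = float("nan")
    f_it_mean_of_ratios: float = float("nan")
    per_locus: pd.DataFrame | None = None
    p_values: dict = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    skipped_loci: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Result in the conventional four-row AMOVA layout."""
        rows = list(STRATA_NAMES) + ["total"]
        sig = list(self.sigma2) + [sum(self.sigma2)]
        pct = list(self.percent) + [100.0]
        return pd.DataFrame(
            {
                "source of variation": rows,
                "df": list(self.df),
                "sum of squares": list(self.ss),
                "variance component": sig,
                "percent of variation": pct,
            }
        )


# ---------------------------------------------------------------------------
# Per-locus preprocessing and sums of squares
# ---------------------------------------------------------------------------

def _prepare_loci(table: GenotypeTable, loci=None):
    """Recode allele calls per locus to dense 0..J-1 indices.

    Returns (locus_name, typed_individual_index, alleles(n_t, 2), J) per
    locus, skipping loci with no typed genotypes.
    """
    loci = list(table.loci) if loci is None else list(loci)
    prepped, skipped = [], []
    for name in loci:
        j = table.locus_index(name)
        calls = table.calls[:, j, :]
        typed = np.flatnonzero(calls[:, 0] != MISSING)
        if typed.size == 0:
            skipped.append(name)
            continue
        sub = calls[typed]
        codes, al = np.unique(sub, return_inverse=True)
        prepped.append((name, typed, al.reshape(sub.shape), len(codes)))
    return prepped, skipped


def _locus_ss(pop: np.ndarray, typed: np.ndarray, al: np.ndarray, J: int, P: int):
    """Sums of squares and df for one locus given population codes ``pop``.

    With mismatch distance d^2 = 1 between different allele copies, the SS
    of a set of M copies with allele tallies m_k is (M - sum m_k^2 / M) / 2.
    """
    pops_t = pop[typed]
    n_t = typed.size
    flat = al.ravel()
    m_tot = np.bincount(flat, minlength=J).astype(float)
    M = 2.0 * n_t
    ss_total = (M - (m_tot**2).sum() / M) / 2.0

    m_pop = np.bincount(
        (np.repeat(pops_t, 2) * J + flat), minlength=P * J
    ).reshape(P, J).astype(float)
    M_p = m_pop.sum(axis=1)
    present = M_p > 0
    ss_within_pops = float(
        ((M_p[present] - (m_pop[present] ** 2).sum(axis=1) / M_p[present]) / 2.0).sum()
    )
    ss_a = ss_total - ss_within_pops
    ss_wi = 0.5 * float(np.count_nonzero(al[:, 0] != al[:, 1]))
    ss_b = ss_within_pops - ss_wi

    p_eff = int(present.sum())
    df_a, df_b, df_c = p_eff - 1, n_t - p_eff, n_t
    # coefficient of sigma2_a in E[MS_a] for unequal sample sizes
    n_c = (M - (M_p[present] ** 2).sum() / M) / df_a if df_a > 0 else np.nan
    return ss_a, ss_b, ss_wi, df_a, df_b, df_c, n_c


def _locus_components(pop, typed, al, J, P):
    ss_a, ss_b, ss_c, df_a, df_b, df_c, n_c = _locus_ss(pop, typed, al, J, P)
    if df_a < 1 or df_b < 1:
        raise DataError("AMOVA needs >=2 populations with >=2 individuals each")
    ms_c = ss_c / df_c
    ms_b = ss_b / df_b
    ms_a = ss_a / df_a
    s2_c = ms_c
    s2_b = (ms_b - ms_c) / 2.0
    s2_a = (ms_a - ms_b) / n_c
    return (ss_a, ss_b, ss_c), (s2_a, s2_b, s2_c)


def f_statistics_from_components(s2_a: float, s2_b: float, s2_c: float):
    """(F_IS, F_ST, F_IT) from the three variance components."""
    total = s2_a + s2_b + s2_c
    if total <= 0:
        raise DataError("total variance must be positive for F-statistics")
    f_st = s2_a / total
    within = s2_b + s2_c
    f_is = s2_b / within if within > 0 else float("nan")
    f_it = (s2_a + s2_b) / total
    return f_is, f_st, f_it


def percent_variation(s2_a: float, s2_b: float, s2_c: float):
    """Per-stratum share of total variance, negatives truncated at zero."""
    comps = np.maximum([s2_a, s2_b, s2_c], 0.0)
    total = comps.sum()
    if total <= 0:
        raise DataError("total variance must be positive")
    pct = comps / total * 100.0
    return float(pct[0]), float(pct[1]), float(pct[2])


def _encode_pops(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    code = {g: i for i, g in enumerate(groups)}
    return np.array([code[l] for l in labels], dtype=np.intp), groups


def amova_components(
    table: GenotypeTable, labels, loci=None
) -> AmovaResult:
    """Locus-by-locus AMOVA; multi-locus components are sums over loci."""
    pop, groups = _encode_pops(labels)
    P = len(groups)
    if P < 2:
        raise DataError(
            "single population: among-populations stratum undefined; "
            "use a two-level (within-population) analysis instead"
        )
    counts = np.bincount(pop, minlength=P)
    if (counts < 2).any():
        raise DataError("each population needs >=2 individuals")
    prepped, skipped = _prepare_loci(table, loci)
    if not prepped:
        raise DataError("no loci with typed genotypes")

    rows = []
    ss_sum = np.zeros(3)
    s2_sum = np.zeros(3)
    for name, typed, al, J in prepped:
        ss, s2 = _locus_components(pop, typed, al, J, P)
        ss_sum += ss
        s2_sum += s2
        row = {"locus": name, "ss_a": ss[0], "ss_b": ss[1], "ss_c": ss[2],
               "sigma2_a": s2[0], "sigma2_b": s2[1], "sigma2_c": s2[2]}
        tot = sum(s2)
        if tot > 0 and (s2[1] + s2[2]) > 0:
            row["f_is"], row["f_st"], row["f_it"] = f_statistics_from_components(*s2)
        else:
            row["f_is"] = row["f_st"] = row["f_it"] = np.nan
        rows.append(row)
    per_locus = pd.DataFrame(rows)

    n = table.n_samples
    df = (P - 1, n - P, n, 2 * n - 1)
    f_is, f_st, f_it = f_statistics_from_components(*s2_sum)
    return AmovaResult(
        df=df,
        ss=(float(ss_sum[0]), float(ss_sum[1]), float(ss_sum[2]), float(ss_sum.sum())),
        sigma2=tuple(float(x) for x in s2_sum),
        sigma2_truncated=tuple(float(max(x, 0.0)) for x in s2_sum),
        percent=percent_variation(*s2_sum),
        f_is=f_is,
        f_st=f_st,
        f_it=f_it,
        f_is_mean_of_ratios=float(per_locus["f_is"].mean(skipna=True)),
        f_st_mean_of_ratios=float(per_locus["f_st"].mean(skipna=True)),
        f_it_mean_of_ratios=float(per_locus["f_it"].mean(skipna=True)),
        per_locus=per_locus,
        skipped_loci=skipped,
    )


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _multilocus_stat(prepped, pop, P, which: str) -> float:
    s2_sum = np.zeros(3)
    for _, typed, al, J in prepped:
        _, s2 = _locus_components(pop, typed, al, J, P)
        s2_sum += s2
    f_is, f_st, f_it = f_statistics_from_components(*s2_sum)
    return {"F_IS": f_is, "F_ST": f_st, "F_IT": f_it}[which]


def permutation_test(
    table: GenotypeTable,
    labels,
    statistic: str = "F_ST",
    n_perm: int = 10_000,
    seed: int = 0,
    loci=None,
) -> float:
    """Permutation p-value for one multi-locus F-statistic.

    Schemes: F_ST permutes whole individuals among populations; F_IS
    permutes allele copies among individuals within each population; F_IT
    permutes allele copies among all individuals.  p uses the add-one rule
    (never exactly zero).
    """
    if statistic not in ("F_ST", "F_IS", "F_IT"):
        raise DataError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    pop, groups = _encode_pops(labels)
    P = len(groups)
    if P < 2:
        raise DataError("permutation test needs >=2 populations")
    prepped, _ = _prepare_loci(table, loci)
    rng = np.random.default_rng(seed)
    observed = _multilocus_stat(prepped, pop, P, statistic)

    hits = 0
    for _ in range(n_perm):
        if statistic == "F_ST":
            perm_pop = rng.permutation(pop)
            stat = _multilocus_stat(prepped, perm_pop, P, statistic)
        else:
            shuffled = []
            for name, typed, al, J in prepped:
                flat = al.ravel().copy()
                if statistic == "F_IT":
                    rng.shuffle(flat)
                else:  # F_IS: shuffle copies within each population
                    copy_pop = np.repeat(pop[typed], 2)
                    for p in range(P):
                        sel = np.flatnonzero(copy_pop == p)
                        flat[sel] = flat[sel[rng.permutation(sel.size)]]
                shuffled.append((name, typed, flat.reshape(al.shape), J))
            stat = _multilocus_stat(shuffled, pop, P, statistic)
        if stat >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Stratified suite
# ---------------------------------------------------------------------------

def run_amova_suite(
    bundle,
    strata=("all", "males", "females"),
    n_permutations: int = 10_000,
    seed: int = 0,
    loci=None,
    permute: bool = True,
) -> dict[str, AmovaResult | None]:
    """AMOVA for all individuals and, optionally, each sex separately.

    Strata with fewer than two individuals in any population are skipped
    (result ``None``).  Permutation p-values for all three F-statistics are
    attached when ``permute`` is true.
    """
    table = bundle.genotypes
    pops = bundle.population_labels()
    sexes = bundle.sex_labels()
    sex_of = {"males": "male", "females": "female"}
    out: dict[str, AmovaResult | None] = {}
    for stratum in strata:
        if stratum == "all":
            keep = np.ones(table.n_samples, dtype=bool)
        else:
            keep = sexes == sex_of[stratum]
        ids = [s for s, k in zip(table.samples, keep) if k]
        labels = pops[keep]
        ok = len(ids) >= 4 and all(
            np.count_nonzero(labels == g) >= 2 for g in set(labels)
        ) and len(set(labels)) >= 2
        if not ok:
            out[stratum] = None
            continue
        sub = table.subset_samples(ids)
        result = amova_components(sub, labels, loci)
        if permute:
            for k, stat in enumerate(("F_ST", "F_IS", "F_IT")):
                result.p_values[stat] = permutation_test(
                    sub, labels, stat, n_perm=n_permutations, seed=seed + k,
                    loci=loci,
                )
            result.n_permutations = n_permutations
            result.seed = seed
        out[stratum] = result
    return out


def format_amova_table(results: dict[str, AmovaResult | None]) -> str:
    """Human-readable text table in the conventional stratified layout."""
    lines = []
    for stratum, res in results.items():
        lines.append(f"== {stratum} ==")
        if res is None:
            lines.append("  (skipped: insufficient individuals)")
            continue
        tab = res.table()
        lines.append(tab.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
        lines.append(
            f"F_IS = {res.f_is:.3f}  F_ST = {res.f_st:.3f}  F_IT = {res.f_it:.3f}"
        )
        if res.p_values:
            lines.append(
                "p-values: "
                + "  ".join(f"{k} = {v:.4g}" for k, v in res.p_values.items())
            )
        lines.append("")
    return "\n".join(lines)
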