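"""Bayesian admixture clustering for multilocus genotypes.

A Gibbs sampler over the classic admixture model: each individual i carries
a membership vector q_i on the K-simplex, each cluster k carries allele
frequencies p_kl. per locus, and every allele copy has a latent cluster of
origin z.  Sweeps alternate

1. z | q, p   — categorical, proportional to q_ik * p_k,l,allele;
2. p | z      — Dirichlet conjugate update; under the correlated-frequency
                model, cluster frequencies are drawn around shared ancestral
                frequencies with a per-cluster drift parameter F updated by
                Metropolis (prior structure of the F-model: Dirichlet with
                concentration p_ancestral * (1 - F) / F);
3. q | z      — Dirichlet(alpha + per-cluster copy counts);
4. alpha      — Metropolis with uniform prior on (0, alpha_max].

Missing genotypes contribute no likelihood term.  The recorded trace is the
observed-data log-likelihood ln P(X | p, q); the model evidence for a given
K is estimated from the trace as mean - variance/2, and K is chosen by the
second-order rate of change of that estimate across K (the Delta-K
criterion), standardised by the between-replicate standard deviation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .datamodel import MISSING, DataError, GenotypeTable


@dataclass
class McmcConfig:
    """Sampler settings.

    ``iterations`` counts post-burn-in sampling sweeps; ``burn_in`` sweeps
    are run first and discarded (the usual MCMC-reps + burn-in convention).
    Desk-scale defaults (20,000 sweeps + 5,000 burn-in, thinning 10) keep a
    five-replicate K = 1..5 scan tractable on one core; production-scale
    runs simply raise ``iterations``/``burn_in``.  ``locprior`` is reserved:
    the sampling-location prior is not implemented and must stay False.
    """

    iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 10
    seed: int = 0
    frequency_model: str = "correlated"  # or "uncorrelated"
    alpha_update: str = "metropolis"  # or "fixed"
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_prop_sd: float = 0.1
    drift_init: float = 0.05
    drift_prop_sd: float = 0.05
    drift_update_every: int = 5  # Metropolis step for F every n-th sweep
    lambda_prior: float = 1.0
    locprior: bool = False

    def __post_init__(self) -> None:
        if self.frequency_model not in ("correlated", "uncorrelated"):
            raise DataError(f"unknown frequency model {self.frequency_model!r}")
        if self.alpha_update not in ("metropolis", "fixed"):
            raise DataError(f"unknown alpha update {self.alpha_update!r}")
        if self.locprior:
            raise DataError("the sampling-location prior is not implemented")
        if self.iterations < self.thinning:
            raise DataError("iterations must cover at least one thinning interval")


@dataclass
class PosteriorRun:
    """Posterior summaries and traces from one MCMC run."""

    k: int
    samples: list[str]
    loci: list[str]
    q: np.ndarray  # (N, K) posterior-mean memberships
    p_hat: np.ndarray  # (K, L, Jmax) posterior-mean cluster allele freqs
    lnl_trace: np.ndarray
    alpha_trace: np.ndarray
    drift_trace: np.ndarray
    config: McmcConfig
    warnings: list[str] = field(default_factory=list)


def _dense_alleles(table: GenotypeTable):
    """Per-locus dense allele codes: (N, L, 2) int array, -1 for missing."""
    N, L = table.n_samples, table.n_loci
    out = np.full((N, L, 2), -1, dtype=np.int64)
    n_alleles = np.zeros(L, dtype=np.int64)
    for l in range(L):
        calls = table.calls[:, l, :]
        typed = calls[:, 0] != MISSING
        if not typed.any():
            n_alleles[l] = 1
            continue
        codes, inv = np.unique(calls[typed], return_inverse=True)
        out[typed, l, :] = inv.reshape(-1, 2)
        n_alleles[l] = len(codes)
    return out, n_alleles


def run_mcmc(table: GenotypeTable, k: int, config: McmcConfig | None = None) -> PosteriorRun:
    """Run the admixture Gibbs sampler at a fixed cluster count ``k``."""
    config = config or McmcConfig()
    if k < 1:
        raise DataError("k must be >= 1")
    if k > table.n_samples:
        raise DataError("k exceeds the number of individuals")
    rng = np.random.default_rng(config.seed)
    alleles, n_alleles = _dense_alleles(table)
    N, L = table.n_samples, table.n_loci
    Jmax = int(n_alleles.max())
    a_safe = np.where(alleles < 0, 0, alleles)
    mask = alleles >= 0  # (N, L, 2)
    valid = np.arange(Jmax)[None, :] < n_alleles[:, None]  # (L, Jmax)
    l_idx = np.arange(L)[None, :, None]

    # empirical overall frequencies serve as the (fixed) ancestral vector
    flat = (a_safe + np.arange(L)[None, :, None] * Jmax)[mask]
    tally = np.bincount(flat, minlength=L * Jmax).reshape(L, Jmax).astype(float)
    tally += 0.01 * valid  # floor so every valid allele has support
    p_anc = tally / tally.sum(axis=1, keepdims=True)

    lam = config.lambda_prior * valid
    alpha = config.alpha_init
    drift = np.full(k, config.drift_init)
    Q = np.full((N, k), 1.0 / k)
    P = np.broadcast_to(p_anc, (k, L, Jmax)).copy()

    def dirichlet_rows(shape_params):
        g = rng.standard_gamma(shape_params)
        tot = g.sum(axis=-1, keepdims=True)
        tot = np.where(tot <= 0, 1.0, tot)
        out = g / tot
        return out

    def drift_logpost(f: float, p_row: np.ndarray) -> float:
        if not (0.0 < f < 1.0):
            return -np.inf
        c = (1.0 - f) / f
        conc = c * p_anc
        logp = np.log(np.clip(p_row, 1e-300, None))
        per_locus = (
            gammaln(c)
            - np.where(valid, gammaln(conc), 0.0).sum(axis=1)
            + np.where(valid, (conc - 1.0) * logp, 0.0).sum(axis=1)
        )
        return float(per_locus.sum())

    n_total = config.burn_in + config.iterations
    n_keep = -(-config.iterations // config.thinning)
    lnl_trace = np.empty(n_keep)
    alpha_trace = np.empty(n_keep)
    drift_trace = np.empty((n_keep, k))
    q_accum = np.zeros((N, k))
    p_accum = np.zeros((k, L, Jmax))
    kept = 0
    warnings: list[str] = []

    for sweep in range(n_total):
        # --- z | q, p ------------------------------------------------
        p_sel = P[:, l_idx, a_safe]  # (k, N, L, 2)
        w = Q.T[:, :, None, None] * p_sel
        wsum = w.sum(axis=0)
        record = sweep >= config.burn_in and (sweep - config.burn_in) % config.thinning == 0
        if record:
            lnl = float(np.log(np.clip(wsum, 1e-300, None))[mask].sum())
        if k == 1:
            z = np.zeros((N, L, 2), dtype=np.int64)
        else:
            cum = np.cumsum(w, axis=0)
            u = rng.random((N, L, 2)) * cum[-1]
            z = (u[None, :, :, :] < cum).argmax(axis=0)

        # --- p | z ---------------------------------------------------
        zflat = (z * (L * Jmax) + np.arange(L)[None, :, None] * Jmax + a_safe)[mask]
        counts = np.bincount(zflat, minlength=k * L * Jmax).reshape(k, L, Jmax)
        if config.frequency_model == "uncorrelated":
            shape = lam[None, :, :] + counts
        else:
            conc = ((1.0 - drift) / drift)[:, None, None] * p_anc[None, :, :]
            shape = conc * valid[None, :, :] + counts
        P = dirichlet_rows(shape)
        P[:, ~valid] = 0.0

        if (
            config.frequency_model == "correlated"
            and sweep % config.drift_update_every == 0
        ):
            for kk in range(k):
                prop = drift[kk] + rng.normal(0.0, config.drift_prop_sd)
                if 0.0 < prop < 1.0:
                    cur = drift_logpost(drift[kk], P[kk])
                    new = drift_logpost(prop, P[kk])
                    if np.log(rng.random()) < new - cur:
                        drift[kk] = prop

        # --- q | z ---------------------------------------------------
        iflat = (np.arange(N)[:, None, None] * k + z)[mask]
        n_ik = np.bincount(iflat, minlength=N * k).reshape(N, k).astype(float)
        Q = dirichlet_rows(alpha + n_ik)
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)

        # --- alpha ---------------------------------------------------
        if config.alpha_update == "metropolis" and k > 1:
            prop = alpha + rng.normal(0.0, config.alpha_prop_sd)
            if 0.0 < prop <= config.alpha_max:
                logq = np.log(Q).sum()

                def alpha_loglik(a):
                    return N * (gammaln(k * a) - k * gammaln(a)) + (a - 1.0) * logq

                if np.log(rng.random()) < alpha_loglik(prop) - alpha_loglik(alpha):
                    alpha = prop

        if record:
            lnl_trace[kept] = lnl
            alpha_trace[kept] = alpha
            drift_trace[kept] = drift
            q_accum += Q
            p_accum += P
            kept += 1

    if kept == 0:
        raise DataError("no post-burn-in samples recorded; check thinning")
    return PosteriorRun(
        k=k,
        samples=list(table.samples),
        loci=list(table.loci),
        q=q_accum / kept,
        p_hat=p_accum / kept,
        lnl_trace=lnl_trace[:kept],
        alpha_trace=alpha_trace[:kept],
        drift_trace=drift_trace[:kept],
        config=config,
        warnings=warnings,
    )


def estimate_lnP(run: PosteriorRun) -> float:
    """Model-evidence estimate: mean(lnL) - var(lnL)/2 over the trace.

    Uses the unbiased (ddof = 1) sample variance; needs a trace of length
    at least 2.
    """
    trace = np.asarray(run.lnl_trace if isinstance(run, PosteriorRun) else run, float)
    if trace.size < 2:
        raise DataError("lnL trace too short to estimate ln P(X|K)")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def evanno_delta_k(lnp_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Delta-K table from replicate evidence estimates per K.

    Columns: ``k, mean_lnp, sd_lnp, lprime, lsecond, delta_k``.  Delta-K is
    undefined at the smallest and largest K tested; a zero between-replicate
    standard deviation leaves Delta-K as NaN (flagged).  The selected K
    (argmax Delta-K) is stored in ``df.attrs['selected_k']``.
    """
    ks = sorted(lnp_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise DataError("need >=3 consecutive K values for Delta-K")
    if any(len(lnp_by_k[k]) < 2 for k in ks):
        raise DataError("need >=2 replicates per K for Delta-K")
    mean = np.array([np.mean(lnp_by_k[k]) for k in ks])
    sd = np.array([np.std(lnp_by_k[k], ddof=1) for k in ks])
    lprime = np.full(len(ks), np.nan)
    lprime[1:] = np.diff(mean)
    lsecond = np.full(len(ks), np.nan)
    lsecond[1:-1] = np.abs(lprime[2:] - lprime[1:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = lsecond / np.where(sd > 0, sd, np.nan)
    df = pd.DataFrame(
        {
            "k": ks,
            "mean_lnp": mean,
            "sd_lnp": sd,
            "lprime": lprime,
            "lsecond": lsecond,
            "delta_k": delta,
        }
    )
    if np.isfinite(delta).any():
        df.attrs["selected_k"] = int(np.array(ks)[np.nanargmax(delta)])
    else:
        df.attrs["selected_k"] = None
    return df


def align_replicates(q_matrices: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Resolve label switching across replicate Q matrices.

    Each replicate's columns are permuted to minimise the summed absolute
    difference to the first replicate (exhaustive search over K! for
    K <= 8, Hungarian assignment above; both are exact for this separable
    cost).  Returns the aligned matrices and their element-wise mean.
    """
    mats = [np.asarray(q, float) for q in q_matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise DataError("replicate Q matrices differ in shape")
    K = shape[1]
    ref = mats[0]
    aligned = [ref]
    for m in mats[1:]:
        cost = np.abs(m[:, :, None] - ref[:, None, :]).sum(axis=0)  # cost[j, k]
        if K <= 8:
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(K)):
                c = cost[list(perm), range(K)].sum()
                if c < best_cost:
                    best, best_cost = perm, c
            order = list(best)
        else:
            rows, cols = linear_sum_assignment(cost)
            order = [int(rows[list(cols).index(k)]) for k in range(K)]
        aligned.append(m[:, order])
    return aligned, np.mean(aligned, axis=0)


def structure_report(mean_q: np.ndarray, samples: list[str], metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-individual memberships plus per-population mean membership.

    Individuals are grouped by population label (the stacked-bar layout of
    assignment plots); the per-population means are in ``df.attrs``.
    """
    meta = metadata.set_index("sample_id")
    pops = meta.loc[samples, "population"].to_numpy()
    K = mean_q.shape[1]
    df = pd.DataFrame(mean_q, columns=[f"q{k + 1}" for k in range(K)])
    df.insert(0, "sample_id", samples)
    df.insert(1, "population", pops)
    df = df.sort_values(["population", "sample_id"]).reset_index(drop=True)
    pop_means = df.groupby("population")[[f"q{k + 1}" for k in range(K)]].mean()
    df.attrs["population_means"] = pop_means
    return df


def run_structure_analysis(
    table: GenotypeTable,
    k_range=range(1, 6),
    replicates: int = 5,
    config: McmcConfig | None = None,
) -> dict:
    """K scan with replicates: runs, evidence estimates, Delta-K, alignment.

    Replicate r at cluster count K uses seed ``base_seed + 1000 * K + r`` so
    runs are independent but reproducible.
    """
    config = config or McmcConfig()
    runs: dict[int, list[PosteriorRun]] = {}
    lnp: dict[int, list[float]] = {}
    for k in k_range:
        runs[k] = []
        lnp[k] = []
        for r in range(replicates):
            cfg = replace(config, seed=config.seed + 1000 * k + r)
            run = run_mcmc(table, k, cfg)
            runs[k].append(run)
            lnp[k].append(estimate_lnP(run))
    evanno = evanno_delta_k(lnp)
    selected = evanno.attrs["selected_k"]
    aligned_mean = {}
    for k in runs:
        if k == 1:
            aligned_mean[k] = np.ones((table.n_samples, 1))
            continue
        _, mean_q = align_replicates([r.q for r in runs[k]])
        aligned_mean[k] = mean_q
    return {
        "runs": runs,
        "lnp": lnp,
        "evanno": evanno,
        "selected_k": selected,
        "mean_q": aligned_mean,
    }
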