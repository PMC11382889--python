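"""Phenotypic divergence: P_ST estimation and comparison with F_ST.

P_ST is the phenotypic analogue of Q_ST, computed from total (not purely
additive) variance components:

    P_ST = g * s2_B / (g * s2_B + 2 * h2 * s2_W)

where s2_B and s2_W are the between- and within-population variance
components of the trait, g is the proportion of the between-population
variance assumed additive, and h2 the within-population narrow-sense
heritability.  Comparing P_ST with neutral-marker F_ST classifies a trait
as under diversifying selection (P_ST > F_ST), indistinguishable from
drift, or under uniform/stabilising selection (P_ST < F_ST).  Because g
and h2 are unknown for wild populations, P_ST is evaluated over a
(g, h2) grid and the critical g/h2 ratio at which P_ST = F_ST is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataError

DEFAULT_G_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
DEFAULT_H2_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class TraitVarComponents:
    """One-way unequal-n moment estimates of trait variance components."""

    trait: str
    sigma2_between: float  # raw; may be negative
    sigma2_within: float
    group_sizes: dict
    n0: float  # effective per-group size in the moment estimator

    @property
    def sigma2_between_truncated(self) -> float:
        return max(self.sigma2_between, 0.0)


@dataclass
class PstResult:
    trait: str
    f_st: float
    pst_null: float  # at g = h2 = 1
    grid: pd.DataFrame  # columns g, h2, pst, classification
    critical_ratio: float  # (g/h2)* where P_ST = F_ST; inf if s2_B = 0
    components: TraitVarComponents
    classification: str = ""
    robustness: float = float("nan")  # fraction of grid agreeing with headline

    def __post_init__(self) -> None:
        self.classification = classify(self.pst_null, self.f_st)
        agree = (self.grid["classification"] == self.classification).mean()
        self.robustness = float(agree)


def trait_variance_components(values, labels, trait: str = "") -> TraitVarComponents:
    """Between/within variance components by the unequal-n moment method.

    s2_W = MS_within; s2_B = (MS_between - MS_within) / n0 with
    n0 = (N - sum n_i^2 / N) / (k - 1).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise DataError("need >=2 groups for variance components")
    sizes, means = {}, {}
    for g in groups:
        v = values[labels == g]
        if v.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
        sizes[g] = int(v.size)
        means[g] = float(v.mean())
    N = values.size
    k = len(groups)
    grand = values.mean()
    ss_between = sum(sizes[g] * (means[g] - grand) ** 2 for g in groups)
    ss_within = sum(
        ((values[labels == g] - means[g]) ** 2).sum() for g in groups
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - sum(n * n for n in sizes.values()) / N) / (k - 1)
    return TraitVarComponents(
        trait=trait,
        sigma2_between=(ms_between - ms_within) / n0,
        sigma2_within=ms_within,
        group_sizes=sizes,
        n0=n0,
    )


def pst(s2_b: float, s2_w: float, g: float = 1.0, h2: float = 1.0) -> float:
    """P_ST = g*s2_B / (g*s2_B + 2*h2*s2_W); negative s2_B is floored at 0."""
    if not (0.0 < g <= 1.0) or not (0.0 < h2 <= 1.0):
        raise DataError("g and h2 must lie in (0, 1]")
    s2_b = max(float(s2_b), 0.0)
    s2_w = float(s2_w)
    if s2_w < 0:
        raise DataError("within-group variance must be >= 0")
    denom = g * s2_b + 2.0 * h2 * s2_w
    if denom == 0.0:
        raise DataError("both variance components are zero; P_ST undefined")
    return g * s2_b / denom


def classify(pst_value: float, f_st: float, tol: float = 1e-9) -> str:
    if pst_value > f_st + tol:
        return "diversifying"
    if pst_value < f_st - tol:
        return "uniform"
    return "indistinguishable"


def critical_g_h2_ratio(s2_b: float, s2_w: float, f_st: float) -> float:
    """(g/h2)* where P_ST crosses F_ST: 2*F_ST*s2_W / ((1 - F_ST)*s2_B)."""
    s2_b = max(float(s2_b), 0.0)
    if s2_b == 0.0:
        return float("inf")
    return 2.0 * f_st * s2_w / ((1.0 - f_st) * s2_b)


def pst_sensitivity(
    components: TraitVarComponents,
    f_st: float,
    g_grid=DEFAULT_G_GRID,
    h2_grid=DEFAULT_H2_GRID,
) -> PstResult:
    """Evaluate P_ST and its classification over a (g, h2) grid."""
    if len(g_grid) == 0 or len(h2_grid) == 0:
        raise DataError("g and h2 grids must be non-empty")
    s2_b = components.sigma2_between_truncated
    s2_w = components.sigma2_within
    rows = []
    for g in g_grid:
        for h2 in h2_grid:
            v = pst(s2_b, s2_w, g, h2)
            rows.append(
                {"g": g, "h2": h2, "pst": v, "classification": classify(v, f_st)}
            )
    return PstResult(
        trait=components.trait,
        f_st=f_st,
        pst_null=pst(s2_b, s2_w, 1.0, 1.0),
        grid=pd.DataFrame(rows),
        critical_ratio=critical_g_h2_ratio(s2_b, s2_w, f_st),
        components=components,
    )


def pst_fst_compare(result: PstResult) -> dict:
    """Headline classification at the g/h2 = 1 null plus grid robustness."""
    return {
        "trait": result.trait,
        "pst_null": result.pst_null,
        "f_st": result.f_st,
        "classification": result.classification,
        "fraction_of_grid_agreeing": result.robustness,
        "critical_g_h2_ratio": result.critical_ratio,
    }


def pst_bootstrap_ci(
    values,
    labels,
    g: float = 1.0,
    h2: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for P_ST, resampling individuals within groups.

    A degenerate resample with zero within-group variance contributes
    P_ST = 1 by convention.
    """
    if n_boot < 1:
        raise DataError("n_boot must be >= 1")
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    per_group = [values[labels == g_] for g_ in groups]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        vs, ls = [], []
        for gi, v in enumerate(per_group):
            vs.append(v[rng.integers(0, v.size, v.size)])
            ls.append(np.full(v.size, gi))
        v_all = np.concatenate(vs)
        l_all = np.concatenate(ls)
        comp = trait_variance_components(v_all, l_all)
        if comp.sigma2_within == 0.0:
            stats[b] = 1.0 if comp.sigma2_between_truncated > 0 else 0.0
        else:
            stats[b] = pst(comp.sigma2_between, comp.sigma2_within, g, h2)
    lo = (1.0 - level) / 2.0
    return float(np.quantile(stats, lo)), float(np.quantile(stats, 1.0 - lo))
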