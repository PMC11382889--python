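"""Synthetic genotype, trait and dispersal data with known truth.

Genotypes follow the Balding–Nichols (F-model) construction: each locus
has ancestral allele frequencies p drawn from a symmetric Dirichlet, and
each subpopulation's frequencies are drawn Dirichlet(p * (1 - F_ST) / F_ST),
so the expected divergence between subpopulations is F_ST by construction.
Within-population departure from random mating is injected by an
inbreeding parameter f: a genotype is autozygous (one allele copied twice)
with probability f, otherwise two copies are drawn independently, giving
P(homozygote i) = p_i^2 + f p_i (1 - p_i) and an expected F_IS of f.

Traits are normal with fixed population mean offsets scaled so that the
one-way moment estimator of the between-group component targets the
configured sigma2_B (equivalently a target P_ST at g = h2 = 1), mimicking
a habitat-driven slope effect such as the one-egg clutch-size difference
between valley slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    AnalysisBundle,
    DataError,
    GenotypeTable,
    join_tables,
    make_metadata,
    make_trait_table,
)
from .dispersal import study_recaptures


@dataclass
class TraitSpec:
    """Trait generator knobs: target P_ST at g = h2 = 1, within variance, mean."""

    mean: float
    sigma2_within: float
    target_pst: float = 0.0
    integer: bool = False  # round to positive integers (clutch size)

    @property
    def sigma2_between(self) -> float:
        if not (0.0 <= self.target_pst < 1.0):
            raise DataError("target P_ST must lie in [0, 1)")
        return 2.0 * self.sigma2_within * self.target_pst / (1.0 - self.target_pst)


#: Default trait specs shaped like the study traits: clutch size in eggs
#: (integer), body mass in grams, tarsus length in millimetres, with
#: between-slope divergence targeting the reported P_ST values.
STUDY_TRAITS: dict[str, TraitSpec] = {
    "clutch_size": TraitSpec(mean=8.5, sigma2_within=1.44, target_pst=0.052, integer=True),
    "body_mass": TraitSpec(mean=11.0, sigma2_within=0.36, target_pst=0.013),
    "tarsus_length": TraitSpec(mean=16.8, sigma2_within=0.25, target_pst=0.005),
}


@dataclass
class SimulationConfig:
    """All generator knobs; the seed is mandatory.

    Defaults emulate the study conditions: two subpopulations of 78 and 93
    diploid individuals, 24 microsatellite loci with 2-40 alleles each
    (mean about 14), divergence F_ST = 0.016 and within-population
    inbreeding f = 0.19.
    """

    seed: int
    n_per_population: tuple[int, ...] = (78, 93)
    population_names: tuple[str, ...] = ("east", "west")
    n_loci: int = 24
    allele_count_mean: float = 14.0
    allele_count_range: tuple[int, int] = (2, 40)
    dirichlet_concentration: float = 1.0
    f_st: float = 0.016
    f_inbreeding: float = 0.19
    traits: dict[str, TraitSpec] = field(default_factory=lambda: dict(STUDY_TRAITS))
    sex_ratio: float = 0.5  # fraction male
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_st < 1.0):
            raise DataError("F_ST must lie in [0, 1)")
        if not (0.0 <= self.f_inbreeding < 1.0):
            raise DataError("inbreeding f must lie in [0, 1)")
        if len(self.n_per_population) != len(self.population_names):
            raise DataError("population sizes and names differ in length")
        if not (0.0 <= self.missing_rate < 1.0):
            raise DataError("missing rate must lie in [0, 1)")


def simulate_allele_freqs(config: SimulationConfig, rng=None) -> list[np.ndarray]:
    """Per-locus (n_populations, J_l) frequency arrays under the F-model.

    Allele counts per locus are 2 + Poisson(mean - 2), clipped to the
    configured range.  F_ST = 0 is the no-divergence limit (all populations
    share the ancestral frequencies).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.allele_count_range
    P = len(config.n_per_population)
    out = []
    for _ in range(config.n_loci):
        J = int(np.clip(2 + rng.poisson(config.allele_count_mean - 2), lo, hi))
        anc = rng.dirichlet(np.full(J, config.dirichlet_concentration))
        anc = np.clip(anc, 1e-6, None)
        anc /= anc.sum()
        if config.f_st == 0.0:
            freqs = np.tile(anc, (P, 1))
        else:
            conc = anc * (1.0 - config.f_st) / config.f_st
            freqs = rng.dirichlet(conc, size=P)
        out.append(freqs)
    return out


def simulate_genotypes(
    freqs: list[np.ndarray], config: SimulationConfig, rng=None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Draw diploid genotypes with inbreeding f and apply missingness.

    Allele index j at any locus maps to the opaque fragment-length-style
    code 100 + 2j shared across populations.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    sizes = config.n_per_population
    names = config.population_names
    n_total = sum(sizes)
    f = config.f_inbreeding
    calls = np.zeros((n_total, len(freqs), 2), dtype=np.int64)
    for l, pop_freqs in enumerate(freqs):
        row = 0
        J = pop_freqs.shape[1]
        codes = 100 + 2 * np.arange(J)
        for p, n in enumerate(sizes):
            pf = pop_freqs[p]
            a = rng.choice(J, size=n, p=pf)
            b = rng.choice(J, size=n, p=pf)
            autozygous = rng.random(n) < f
            b = np.where(autozygous, a, b)
            calls[row : row + n, l, 0] = codes[a]
            calls[row : row + n, l, 1] = codes[b]
            row += n
    if config.missing_rate > 0:
        drop = rng.random((n_total, len(freqs))) < config.missing_rate
        calls[drop] = MISSING

    samples, pops = [], []
    for name, n in zip(names, sizes):
        for i in range(n):
            samples.append(f"{name[0]}{i + 1:03d}")
            pops.append(name)
    table = GenotypeTable(samples, [f"L{l + 1:02d}" for l in range(len(freqs))], calls)
    sexes = np.where(rng.random(n_total) < config.sex_ratio, "male", "female")
    forest_by_pop = {"east": ("holm_oak", "dry_oak"), "west": ("scots_pine", "humid_oak")}
    forests = [
        forest_by_pop.get(p, ("", ""))[int(rng.random() < 0.5)] if p in forest_by_pop else ""
        for p in pops
    ]
    meta = make_metadata(
        samples, pops, forest=forests, sex=list(sexes),
        ring_id=[f"ring_{s}" for s in samples],
    )
    return table, meta


def simulate_traits(
    metadata: pd.DataFrame, traits: dict[str, TraitSpec], seed: int
) -> pd.DataFrame:
    """Group-mean-shift + normal-noise traits keyed by sample ID.

    Population mean offsets are fixed (not redrawn per replicate) and
    scaled so the unequal-n moment estimator targets sigma2_B exactly:
    with group sizes n_i, offsets are proportional to the other groups'
    sizes, normalised so the weighted between-group mean square equals
    sigma2_B.  Integer traits are rounded to the nearest positive integer.
    """
    rng = np.random.default_rng(seed)
    pops = metadata["population"].to_numpy()
    groups = list(dict.fromkeys(pops))
    sizes = np.array([np.count_nonzero(pops == g) for g in groups], float)
    N = sizes.sum()
    k = len(groups)
    n0 = (N - np.sum(sizes**2) / N) / (k - 1)
    rows = []
    for name, spec in traits.items():
        # the moment estimator recovers (between-group mean square)/n0, so
        # the fixed offsets must satisfy sum n_i*mu_i^2/(k-1) = n0*sigma2_B
        s2b_target = spec.sigma2_between * n0
        if k == 2:
            n1, n2 = sizes
            c = np.sqrt(s2b_target * (k - 1) / (n1 * n2 * N)) if s2b_target > 0 else 0.0
            offsets = np.array([-c * n2, c * n1])
        else:
            raw = np.linspace(-1.0, 1.0, k) * sizes.mean() / sizes
            raw -= np.average(raw, weights=sizes)
            q = np.sum(sizes * raw**2) / (k - 1)
            offsets = (
                raw * np.sqrt(s2b_target / q) if s2b_target > 0 and q > 0 else np.zeros(k)
            )
        mean_of = {g: spec.mean + offsets[i] for i, g in enumerate(groups)}
        vals = np.array([mean_of[p] for p in pops]) + rng.normal(
            0.0, np.sqrt(spec.sigma2_within), size=len(pops)
        )
        if spec.integer:
            vals = np.maximum(np.round(vals), 1.0)
        rows.extend(
            {"sample_id": s, "trait": name, "value": v}
            for s, v in zip(metadata["sample_id"], vals)
        )
    return make_trait_table(rows)


def make_study_fixture(
    seed: int, config: SimulationConfig | None = None
) -> tuple[AnalysisBundle, dict]:
    """One-call dataset shaped like the study, plus a truth manifest.

    Returns an analysis bundle (genotypes, metadata, traits; dispersal
    records attached as ``manifest['recaptures']``) and a manifest of every
    true parameter for recovery tests.
    """
    config = config or SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed)
    freqs = simulate_allele_freqs(config, rng)
    table, meta = simulate_genotypes(freqs, config, rng)
    traits = simulate_traits(meta, config.traits, seed + 7)
    bundle = join_tables(table, meta, traits)
    manifest = {
        "seed": seed,
        "f_st": config.f_st,
        "f_inbreeding": config.f_inbreeding,
        "n_loci": config.n_loci,
        "n_per_population": tuple(config.n_per_population),
        "alleles_per_locus": [f.shape[1] for f in freqs],
        "trait_pst": {t: s.target_pst for t, s in config.traits.items()},
        "trait_sigma2_within": {t: s.sigma2_within for t, s in config.traits.items()},
        "recaptures": study_recaptures(),
    }
    return bundle, manifest
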