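"""Core data containers for diploid multilocus genotype analyses.

The central object is :class:`GenotypeTable`: an ``(n_samples, n_loci, 2)``
integer array of allele codes with a single missing sentinel.  Allele codes
are opaque positive integers (typically fragment lengths); no repeat-motif
arithmetic is ever applied to them.  Genotypes are unordered pairs — a
heterozygote ``(a, b)`` is identical to ``(b, a)`` and both are canonicalised
to sorted order on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.  A genotype is either fully typed
#: (two codes > 0) or fully missing (both entries equal MISSING).
MISSING: int = -1

EAST = "east"
WEST = "west"

#: Forest formation -> valley slope.  The east-facing slope carries the Holm
#: oak and dry Pyrenean oak formations; the west-facing slope the Scots pine
#: and humid Pyrenean oak formations.
FOREST_TO_SLOPE: dict[str, str] = {
    "holm_oak": EAST,
    "dry_oak": EAST,
    "scots_pine": WEST,
    "humid_oak": WEST,
}


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class GenotypeTable:
    """Diploid allele calls for ``samples`` x ``loci``.

    Parameters
    ----------
    samples : list of str
        Ordered unique sample identifiers.
    loci : list of str
        Ordered unique locus identifiers.
    calls : ndarray of int, shape (n_samples, n_loci, 2)
        Allele codes, canonicalised so ``calls[..., 0] <= calls[..., 1]``
        for typed genotypes; both entries ``MISSING`` otherwise.
    """

    samples: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.samples), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {m} loci x ploidy 2"
            )
        if len(set(self.samples)) != n:
            raise DataError("duplicate sample IDs")
        if len(set(self.loci)) != m:
            raise DataError("duplicate locus IDs")
        # promote half-missing calls to fully missing; heterozygote symmetry
        half = (self.calls == MISSING).sum(axis=2) == 1
        self.n_half_missing_promoted = int(half.sum())
        self.calls[half] = MISSING
        typed = self.calls[..., 0] != MISSING
        if np.any(self.calls[typed] <= 0):
            raise DataError("allele codes must be positive integers")
        self.calls = np.sort(self.calls, axis=2)
        # sorting puts MISSING (<0) first; keep missing pairs as (MISSING, MISSING)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n_samples, n_loci)`` mask of fully typed genotypes."""
        return self.calls[..., 0] != MISSING

    def n_missing(self) -> int:
        return int((~self.typed_mask()).sum())

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[s] for s in ids], dtype=np.intp)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def subset_samples(self, ids) -> "GenotypeTable":
        idx = self.sample_index(ids)
        return GenotypeTable(list(ids), list(self.loci), self.calls[idx].copy())

    def subset_loci(self, loci) -> "GenotypeTable":
        idx = [self.loci.index(l) for l in loci]
        return GenotypeTable(list(self.samples), list(loci), self.calls[:, idx].copy())

    def sorted_by_sample(self) -> "GenotypeTable":
        """Canonical sample order (sorted by ID) for seed-reproducible permutations."""
        order = sorted(self.samples)
        return self.subset_samples(order)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


def make_metadata(
    sample_ids,
    population,
    forest=None,
    sex=None,
    ring_id=None,
) -> pd.DataFrame:
    """Build a sample-metadata frame.

    Columns: ``sample_id, population, forest, sex, ring_id``.  Every sample
    must carry a population label; sex may be ``unknown``.
    """
    n = len(sample_ids)

    def _col(x, default):
        if x is None:
            return [default] * n
        return list(x)

    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "population": list(population),
            "forest": _col(forest, ""),
            "sex": _col(sex, "unknown"),
            "ring_id": _col(ring_id, ""),
        }
    )
    if df["sample_id"].duplicated().any():
        raise DataError("duplicate sample IDs in metadata")
    if df["population"].isna().any() or (df["population"] == "").any():
        raise DataError("every sample needs a population label")
    return df


def make_trait_table(records) -> pd.DataFrame:
    """Long-format trait table: ``sample_id, trait, value``.

    Replicate measurements of the same sample x trait are averaged.
    Clutch size must be a positive integer; mass and tarsus positive reals.
    """
    df = pd.DataFrame(records, columns=["sample_id", "trait", "value"])
    df["value"] = df["value"].astype(float)
    df = (
        df.groupby(["sample_id", "trait"], as_index=False, sort=True)["value"]
        .mean()
    )
    if (df["value"] <= 0).any():
        raise DataError("trait values must be positive")
    cs = df.loc[df["trait"] == "clutch_size", "value"]
    if not np.allclose(cs, np.round(cs)):
        raise DataError("clutch size must be integer-valued")
    return df


@dataclass
class RecaptureRecord:
    """One capture–mark–recapture natal-dispersal record."""

    ring_id: str
    natal_forest: str
    breeding_forest: str
    year_natal: int = 0
    year_breeding: int = 0

    def __post_init__(self) -> None:
        for f in (self.natal_forest, self.breeding_forest):
            if f not in FOREST_TO_SLOPE:
                raise DataError(f"unknown forest label: {f!r}")

    @property
    def natal_slope(self) -> str:
        return FOREST_TO_SLOPE[self.natal_forest]

    @property
    def breeding_slope(self) -> str:
        return FOREST_TO_SLOPE[self.breeding_forest]


@dataclass
class AnalysisBundle:
    """Genotypes, metadata and traits inner-joined on sample ID."""

    genotypes: GenotypeTable
    metadata: pd.DataFrame
    traits: pd.DataFrame | None = None
    dropped_ids: dict = field(default_factory=dict)
    trait_missing_ids: list = field(default_factory=list)

    def population_labels(self) -> np.ndarray:
        meta = self.metadata.set_index("sample_id")
        return meta.loc[self.genotypes.samples, "population"].to_numpy()

    def sex_labels(self) -> np.ndarray:
        meta = self.metadata.set_index("sample_id")
        return meta.loc[self.genotypes.samples, "sex"].to_numpy()


def join_tables(
    genotypes: GenotypeTable,
    metadata: pd.DataFrame,
    traits: pd.DataFrame | None = None,
) -> AnalysisBundle:
    """Inner-join genotypes and metadata (and optionally traits) on sample ID.

    Samples present in only one table are dropped and reported in
    ``bundle.dropped_ids``; samples lacking trait values are retained and
    listed in ``bundle.trait_missing_ids``.  Output sample order is sorted by
    ID so downstream permutation tests do not depend on file order.
    """
    geno_ids = set(genotypes.samples)
    meta_ids = set(metadata["sample_id"])
    keep = sorted(geno_ids & meta_ids)
    if not keep:
        raise DataError("no sample IDs shared between genotypes and metadata")
    dropped = {
        "genotypes_only": sorted(geno_ids - meta_ids),
        "metadata_only": sorted(meta_ids - geno_ids),
    }
    gt = genotypes.subset_samples(keep)
    meta = (
        metadata[metadata["sample_id"].isin(keep)]
        .sort_values("sample_id")
        .reset_index(drop=True)
    )
    trait_missing: list[str] = []
    tr = None
    if traits is not None:
        tr = traits[traits["sample_id"].isin(keep)].reset_index(drop=True)
        with_traits = set(tr["sample_id"])
        trait_missing = sorted(geno_ids & meta_ids - with_traits)
    return AnalysisBundle(gt, meta, tr, dropped, trait_missing)
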