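"""Readers and writers for the text formats microsatellite data travel in.

Supported formats:

* GenePop (2- or 3-digit allele encoding, ``POP``-delimited groups);
* the STRUCTURE input format (one-row-per-individual or two-rows-per-
  individual, configurable missing code);
* headered CSV for traits and capture–mark–recapture records.

Readers return a :class:`~valleypop.datamodel.GenotypeTable` plus a
metadata frame, and writers are exact inverses up to row order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    DataError,
    GenotypeTable,
    RecaptureRecord,
    make_metadata,
)


class ParseError(DataError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def read_genepop(path) -> tuple[GenotypeTable, pd.DataFrame]:
    """Read a GenePop file.

    Populations are labelled ``pop1, pop2, ...`` in file order; allele code
    0 (or 000) maps to missing.  Returns the genotype table (file order
    preserved) and a metadata frame.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty GenePop file")
    # line 1 is a free-text title
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if not chunk:
            raise ParseError(f"line {i + 1}: blank line in locus list")
        loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError("no POP line found; malformed header")
    if not loci:
        raise ParseError("no locus names before first POP line")

    samples: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_no = 0
    width = None
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            pop_no += 1
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'sample , genotypes'")
        name, _, geno = line.partition(",")
        name = name.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"line {lineno}: {len(fields)} genotypes for {len(loci)} loci"
            )
        calls = []
        for f in fields:
            if not re.fullmatch(r"\d+", f) or len(f) not in (4, 6):
                raise ParseError(
                    f"line {lineno}: unknown allele encoding width in {f!r}"
                )
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"line {lineno}: mixed 2- and 3-digit encodings"
                )
            a, b = int(f[:w]), int(f[w:])
            calls.append((a if a else MISSING, b if b else MISSING))
        samples.append(name)
        pops.append(f"pop{pop_no}")
        rows.append(calls)
    if not samples:
        raise ParseError("no samples found after POP lines")
    table = GenotypeTable(samples, loci, np.array(rows, dtype=np.int64))
    meta = make_metadata(samples, pops)
    return table, meta


def write_genepop(path, table: GenotypeTable, populations, title="valleypop export") -> None:
    """Write GenePop text; ``populations`` gives each sample's group label.

    Encoding width is 3 digits unless every allele code fits in 2.
    """
    populations = np.asarray(populations)
    max_code = int(table.calls.max(initial=0))
    if max_code > 999:
        raise DataError("allele codes exceed 3-digit GenePop encoding")
    width = 2 if max_code < 100 else 3
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        # keep samples grouped by population, in first-appearance order
        seen = dict.fromkeys(populations)
        for pop in seen:
            fh.write("POP\n")
            for i in np.flatnonzero(populations == pop):
                parts = []
                for a, b in table.calls[i]:
                    a = 0 if a == MISSING else a
                    b = 0 if b == MISSING else b
                    parts.append(f"{a:0{width}d}{b:0{width}d}")
                fh.write(f"{table.samples[i]} , " + " ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE input format
# ---------------------------------------------------------------------------

@dataclass
class StructureFormatConfig:
    """Dialect switches for the STRUCTURE text format.

    ``two_row``: each individual occupies two rows, one allele per locus per
    row.  ``one_row``: one row with two adjacent columns per locus.
    """

    dialect: str = "two_row"
    missing_code: int = -9
    header: bool = True

    def __post_init__(self) -> None:
        if self.dialect not in ("two_row", "one_row"):
            raise DataError(f"unknown STRUCTURE dialect {self.dialect!r}")


def read_structure_format(
    path, config: StructureFormatConfig | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    config = config or StructureFormatConfig()
    with open(path) as fh:
        lines = [l for l in fh.read().splitlines() if l.strip()]
    start = 0
    loci = None
    if config.header:
        loci = lines[0].split()
        start = 1
    body = [l.split() for l in lines[start:]]
    if not body:
        raise ParseError("no individual rows in STRUCTURE file")
    n_loci = len(loci) if loci else (
        len(body[0]) - 2 if config.dialect == "two_row" else (len(body[0]) - 2) // 2
    )
    if loci is None:
        loci = [f"locus{j + 1}" for j in range(n_loci)]

    samples: list[str] = []
    pops: list[str] = []
    rows = []
    miss = config.missing_code
    if config.dialect == "two_row":
        if len(body) % 2:
            raise ParseError("odd number of rows in two-row STRUCTURE file")
        for r in range(0, len(body), 2):
            top, bot = body[r], body[r + 1]
            if top[0] != bot[0] or top[1] != bot[1]:
                raise ParseError(
                    f"rows {r + 1 + start}/{r + 2 + start}: "
                    "inconsistent allele-row pairing (label or pop differ)"
                )
            if len(top) != n_loci + 2 or len(bot) != n_loci + 2:
                raise ParseError(f"row {r + 1 + start}: wrong column count")
            samples.append(top[0])
            pops.append(f"pop{top[1]}")
            a = [int(x) for x in top[2:]]
            b = [int(x) for x in bot[2:]]
            rows.append(
                [
                    (MISSING if x == miss else x, MISSING if y == miss else y)
                    for x, y in zip(a, b)
                ]
            )
    else:
        for r, row in enumerate(body):
            if len(row) != 2 * n_loci + 2:
                raise ParseError(f"row {r + 1 + start}: wrong column count")
            samples.append(row[0])
            pops.append(f"pop{row[1]}")
            vals = [int(x) for x in row[2:]]
            rows.append(
                [
                    (
                        MISSING if vals[2 * j] == miss else vals[2 * j],
                        MISSING if vals[2 * j + 1] == miss else vals[2 * j + 1],
                    )
                    for j in range(n_loci)
                ]
            )
    table = GenotypeTable(samples, loci, np.array(rows, dtype=np.int64))
    meta = make_metadata(samples, pops)
    return table, meta


def write_structure_format(
    path,
    table: GenotypeTable,
    populations,
    config: StructureFormatConfig | None = None,
) -> None:
    config = config or StructureFormatConfig()
    populations = np.asarray(populations)
    # map population labels to 1-based integers in first-appearance order
    pop_code = {p: k + 1 for k, p in enumerate(dict.fromkeys(populations))}
    miss = config.missing_code
    with open(path, "w") as fh:
        if config.header:
            fh.write(" ".join(table.loci) + "\n")
        for i, sample in enumerate(table.samples):
            code = pop_code[populations[i]]
            a = [int(x) for x in table.calls[i, :, 0]]
            b = [int(x) for x in table.calls[i, :, 1]]
            a = [miss if x == MISSING else x for x in a]
            b = [miss if x == MISSING else x for x in b]
            if config.dialect == "two_row":
                fh.write(f"{sample} {code} " + " ".join(map(str, a)) + "\n")
                fh.write(f"{sample} {code} " + " ".join(map(str, b)) + "\n")
            else:
                inter = " ".join(f"{x} {y}" for x, y in zip(a, b))
                fh.write(f"{sample} {code} " + inter + "\n")


# ---------------------------------------------------------------------------
# CSV side tables
# ---------------------------------------------------------------------------

def read_traits_csv(path) -> pd.DataFrame:
    """Long-format trait CSV with columns ``sample_id, trait, value``."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    need = {"sample_id", "trait", "value"}
    if not need.issubset(df.columns):
        raise ParseError(f"trait CSV must have columns {sorted(need)}")
    from .datamodel import make_trait_table

    return make_trait_table(df[["sample_id", "trait", "value"]])


def write_traits_csv(path, traits: pd.DataFrame) -> None:
    traits.to_csv(path, index=False)


def read_recaptures_csv(path) -> list[RecaptureRecord]:
    df = pd.read_csv(path, dtype={"ring_id": str})
    need = {"ring_id", "natal_forest", "breeding_forest"}
    if not need.issubset(df.columns):
        raise ParseError(f"recapture CSV must have columns {sorted(need)}")
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            RecaptureRecord(
                ring_id=row.ring_id,
                natal_forest=row.natal_forest,
                breeding_forest=row.breeding_forest,
                year_natal=int(getattr(row, "year_natal", 0) or 0),
                year_breeding=int(getattr(row, "year_breeding", 0) or 0),
            )
        )
    return recs


def write_recaptures_csv(path, records) -> None:
    pd.DataFrame(
        [
            {
                "ring_id": r.ring_id,
                "natal_forest": r.natal_forest,
                "breeding_forest": r.breeding_forest,
                "year_natal": r.year_natal,
                "year_breeding": r.year_breeding,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
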