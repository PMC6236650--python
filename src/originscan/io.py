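"""Sample-table data model and delimited-text I/O.

The central container is :class:`SampleTable`: georeferenced landrace
accessions scored at L multi-allelic microsatellite loci (one or more allele
copies per sample per locus) plus optional GBSSI-S/GBSSI-L genotypes. The
on-disk form is a delimited text file with one row per accession and columns

    sample_id, region, latitude, longitude, <locus columns>, gbssi_s, gbssi_l

where locus columns are recognised by a configurable prefix and any other
columns are carried through untouched as opaque metadata. Millet landraces
are strongly selfing, so the default scoring is one allele copy per sample
per locus (``copies_per_sample = 1``); two-call diploid-style tables are
supported by joining calls with ``/`` inside a cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = "NA"
MISSING_INPUT_CODES = {"", "NA", "na", "NaN", "nan", "-9", "?"}

GBSSI_S_GENOTYPES = {"S0/S0", "S0/S-15", "S-15/S-15"}
GBSSI_L_ALLELES = ("LC", "LY", "Lf")
GBSSI_L_GENOTYPES = {"LC/LC", "LY/LY", "Lf/Lf", "LC/LY", "LC/Lf", "LY/Lf"}

CORE_COLUMNS = ("sample_id", "region", "latitude", "longitude")
GBSSI_COLUMNS = ("gbssi_s", "gbssi_l")


class FormatError(ValueError):
    """The file does not have the expected header/layout."""


class ValidationError(ValueError):
    """The table content violates an invariant of the data model."""


@dataclass(frozen=True)
class Dialect:
    """How a delimited sample table is laid out on disk."""

    delimiter: str = ","
    missing_code: str = MISSING
    copies_per_sample: int = 1
    locus_prefix: str = "locus_"

    def is_missing(self, token: str) -> bool:
        return token is None or str(token).strip() in MISSING_INPUT_CODES | {self.missing_code}


@dataclass
class SampleTable:
    """Georeferenced multi-locus genotypes for a set of accessions.

    ``df`` holds one row per sample with the canonical columns above; allele
    calls are stored as strings (repeat-length integers serialise as their
    decimal text), with :data:`MISSING` as the single canonical missing
    sentinel. Coordinates are floats with NaN for missing.
    """

    df: pd.DataFrame
    locus_names: list[str]
    copies_per_sample: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        df = self.df
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id(s): {sorted(set(dup))}")
        for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
            vals = df[col].to_numpy(dtype=float)
            bad = np.where(~np.isnan(vals) & ((vals < lo) | (vals > hi)))[0]
            if len(bad):
                row = int(bad[0])
                raise ValidationError(
                    f"{col} out of range for sample "
                    f"{df['sample_id'].iloc[row]!r} (row {row}): {vals[row]}"
                )
        for name in self.locus_names:
            if name not in df.columns:
                raise ValidationError(f"locus column {name!r} absent from table")
        p = self.copies_per_sample
        for name in self.locus_names:
            for row, cell in enumerate(df[name]):
                calls = _split_calls(cell)
                if len(calls) != p and calls != [MISSING]:
                    raise ValidationError(
                        f"locus {name!r}, sample {df['sample_id'].iloc[row]!r}: "
                        f"expected {p} call(s), got {len(calls)}"
                    )
        for col, allowed in (("gbssi_s", GBSSI_S_GENOTYPES), ("gbssi_l", GBSSI_L_GENOTYPES)):
            if col in df.columns:
                vals = set(df[col].dropna()) - {MISSING}
                bad = vals - allowed
                if bad:
                    raise ValidationError(f"invalid {col} genotype(s): {sorted(bad)}")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.df)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def coords(self) -> np.ndarray:
        """(n, 2) lat/lon array with NaN where missing."""
        return self.df[["latitude", "longitude"]].to_numpy(dtype=float)

    def allele_codes(self) -> tuple[np.ndarray, list[list[str]]]:
        """Integer-code the genotype calls.

        Returns ``(codes, labels)`` where ``codes`` has shape
        (n_samples, n_loci * copies_per_sample) with -1 for missing calls,
        and ``labels[l]`` lists the allele labels of locus l in code order.
        Codes for locus l occupy columns ``l*P .. (l+1)*P``.
        """
        p = self.copies_per_sample
        codes = np.full((self.n_samples, self.n_loci * p), -1, dtype=np.int32)
        labels: list[list[str]] = []
        for l, name in enumerate(self.locus_names):
            cells = [_split_calls(c) for c in self.df[name]]
            seen = sorted({c for calls in cells for c in calls if c != MISSING})
            lookup = {lab: i for i, lab in enumerate(seen)}
            labels.append(seen)
            for row, calls in enumerate(cells):
                for j, call in enumerate(calls[:p]):
                    if call != MISSING:
                        codes[row, l * p + j] = lookup[call]
        return codes, labels

    def with_genotypes_permuted(self, order: Sequence[int]) -> "SampleTable":
        """Reassign whole genotype vectors (all loci + GBSSI jointly) to the
        existing sample coordinates according to ``order``."""
        order = np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(self.n_samples)):
            raise ValueError("order must be a permutation of all row indices")
        geno_cols = list(self.locus_names) + [c for c in GBSSI_COLUMNS if c in self.df.columns]
        df = self.df.copy()
        df[geno_cols] = self.df[geno_cols].to_numpy()[order]
        return SampleTable(df, list(self.locus_names), self.copies_per_sample)

    def equals(self, other: "SampleTable") -> bool:
        return (
            self.locus_names == other.locus_names
            and self.copies_per_sample == other.copies_per_sample
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def _parse_coord(token, dialect: Dialect) -> float:
    if dialect.is_missing(token):
        return float("nan")
    try:
        return float(token)
    except (TypeError, ValueError):
        return float("nan")


def _split_calls(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return [MISSING]
    text = str(cell).strip()
    if text in MISSING_INPUT_CODES:
        return [MISSING]
    return [c.strip() if c.strip() not in MISSING_INPUT_CODES else MISSING for c in text.split("/")]


def make_table(
    records: Iterable[dict],
    locus_names: Sequence[str],
    copies_per_sample: int = 1,
) -> SampleTable:
    """Build a SampleTable from plain dicts (one per sample)."""
    df = pd.DataFrame(list(records))
    for col in CORE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(
                "" if col in ("sample_id", "region") else np.nan, index=df.index, dtype=object
            )
    df["latitude"] = df["latitude"].astype(float)
    df["longitude"] = df["longitude"].astype(float)
    for name in locus_names:
        if name not in df.columns:
            df[name] = pd.Series(MISSING, index=df.index, dtype=object)
        df[name] = ["/".join(_split_calls(c)) for c in df[name]]
    return SampleTable(df, list(locus_names), copies_per_sample)


def read_samples(path, dialect: Dialect = Dialect()) -> SampleTable:
    """Read and validate a delimited sample table.

    Rows whose coordinate cells are unparseable are retained with the
    coordinate flagged missing; numeric coordinates outside the valid range
    raise :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "latitude" not in df.columns or "longitude" not in df.columns:
        raise FormatError(
            f"header must include sample_id/latitude/longitude; got {list(df.columns)}"
        )
    locus_names = [c for c in df.columns if c.startswith(dialect.locus_prefix)]
    out = pd.DataFrame()
    out["sample_id"] = df["sample_id"].str.strip()
    out["region"] = df["region"].str.strip() if "region" in df.columns else ""
    for col in ("latitude", "longitude"):
        # float() is correctly rounded (pd.to_numeric's fast parser is not),
        # keeping write -> read -> write byte-stable
        out[col] = np.array(
            [_parse_coord(t, dialect) for t in df[col]], dtype=float
        )
    for name in locus_names:
        out[name] = ["/".join(_split_calls(c)) for c in df[name]]
    for col in GBSSI_COLUMNS:
        if col in df.columns:
            out[col] = [MISSING if dialect.is_missing(c) else str(c).strip() for c in df[col]]
    extras = [
        c
        for c in df.columns
        if c not in set(CORE_COLUMNS) | set(GBSSI_COLUMNS) | set(locus_names)
    ]
    for col in extras:
        out[col] = df[col]
    return SampleTable(out, locus_names, dialect.copies_per_sample)


def write_samples(table: SampleTable, path, dialect: Dialect = Dialect()) -> None:
    """Write a table as delimited text losslessly re-loadable by read_samples."""
    cols = (
        ["sample_id", "region", "latitude", "longitude"]
        + list(table.locus_names)
        + [c for c in GBSSI_COLUMNS if c in table.df.columns]
    )
    extras = [c for c in table.df.columns if c not in cols]
    out = table.df[cols + extras].copy()
    out.to_csv(path, sep=dialect.delimiter, index=False, na_rep=dialect.missing_code)


def geolocated_subset(table: SampleTable) -> SampleTable:
    """Samples with both coordinates present (and hence in range), order kept.

    Mirrors the real pipeline step of excluding accessions whose provenance
    is too vague to place on the map.
    """
    coords = table.coords()
    keep = ~np.isnan(coords).any(axis=1)
    df = table.df.loc[keep].reset_index(drop=True)
    return SampleTable(df, list(table.locus_names), table.copies_per_sample)
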