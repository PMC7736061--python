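"""Genotype and sample-metadata containers and readers.

The pipeline's universal input is a biallelic SNP genotype matrix coded as the
count of the alternate allele (0/1/2) with loci as rows and samples as columns
(the SNP-major layout genotyping platforms export).  Missing calls are held as
a dedicated sentinel.  Two on-disk forms are supported: a canonical CSV dialect
and VCF 4.x import (GT field only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Distinct from all valid calls {0,1,2}.
MISSING: int = -1

#: Marker for a hatchery-identified strain the hatchery could not name.
UNKNOWN_POPULATION: str = "Unknown"

_VALID_CALLS = frozenset({0, 1, 2, MISSING})


class GenotypeFormatError(ValueError):
    """A genotype file violates the matrix contract (bad cell, duplicate id)."""


class MetadataError(ValueError):
    """A sample-metadata table violates its contract."""


class LookupMismatchError(KeyError):
    """Requested locus/sample identifiers are absent from a matrix."""


@dataclass
class GenotypeMatrix:
    """Loci x samples diploid allele-count matrix.

    Parameters
    ----------
    locus_ids : sequence of str
        Unique locus identifiers, one per row of ``calls``.
    sample_ids : sequence of str
        Unique sample identifiers, one per column of ``calls``.
    calls : ndarray of int
        Count of the alternate allele per (locus, sample); ``MISSING`` marks
        a missing call.
    """

    locus_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = [str(x) for x in self.locus_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 2:
            raise GenotypeFormatError("calls must be a 2-D loci x samples array")
        if self.calls.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.sample_ids)} samples"
            )
        for name, ids in (("locus", self.locus_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise GenotypeFormatError(f"duplicate {name} identifiers: {dupes}")
        bad = ~np.isin(self.calls, list(_VALID_CALLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"invalid call {self.calls[i, j]} at locus "
                f"{self.locus_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def to_frame(self) -> pd.DataFrame:
        """Return a loci x samples DataFrame with NaN for missing calls."""
        x = self.calls.astype(float)
        x[x == MISSING] = np.nan
        return pd.DataFrame(x, index=self.locus_ids, columns=self.sample_ids)

    def subset(
        self,
        loci: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Sub-matrix in the requested identifier order; the source is untouched."""
        locus_idx = _resolve(self.locus_ids, loci, "locus")
        sample_idx = _resolve(self.sample_ids, samples, "sample")
        return GenotypeMatrix(
            [self.locus_ids[i] for i in locus_idx],
            [self.sample_ids[j] for j in sample_idx],
            self.calls[np.ix_(locus_idx, sample_idx)].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.locus_ids == other.locus_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.calls, other.calls)
        )


def _resolve(ids: list[str], wanted: Sequence[str] | None, kind: str) -> list[int]:
    if wanted is None:
        return list(range(len(ids)))
    pos = {name: i for i, name in enumerate(ids)}
    missing = [w for w in wanted if w not in pos]
    if missing:
        raise LookupMismatchError(f"unknown {kind} identifiers: {missing}")
    return [pos[w] for w in wanted]


def subset_matrix(
    g: GenotypeMatrix,
    loci: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Functional alias for :meth:`GenotypeMatrix.subset`."""
    return g.subset(loci, samples)


# ---------------------------------------------------------------------------
# Canonical CSV dialect: header "locus_id,<sample>,...", one row per locus,
# cells 0/1/2, empty or NA for missing.
# ---------------------------------------------------------------------------

def read_genotype_csv(path) -> GenotypeMatrix:
    """Read a genotype matrix from the canonical CSV layout.

    Empty cells and ``NA`` (any case) become the missing sentinel.  Any other
    cell outside {0,1,2} raises :class:`GenotypeFormatError` naming the
    offending (locus, sample) coordinate.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0)
    locus_ids = [str(x) for x in df.index]
    sample_ids = [str(c) for c in df.columns]
    calls = np.full(df.shape, MISSING, dtype=np.int16)
    values = df.to_numpy()
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            cell = values[i, j].strip()
            if cell == "" or cell.upper() == "NA":
                continue
            if cell in ("0", "1", "2"):
                calls[i, j] = int(cell)
            else:
                raise GenotypeFormatError(
                    f"invalid cell {cell!r} at locus {locus_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
    return GenotypeMatrix(locus_ids, sample_ids, calls)


def write_genotype_csv(g: GenotypeMatrix, path) -> None:
    """Write the canonical CSV; missing calls become empty cells."""
    df = pd.DataFrame(
        g.calls.astype(object), index=g.locus_ids, columns=g.sample_ids
    )
    df = df.mask(df == MISSING, "")
    df.index.name = "locus_id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# VCF import
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Import biallelic SNP records from a VCF as an ALT-allele count matrix.

    Each GT is converted to the count of the ALT allele (``./.`` -> missing).
    Multiallelic records are skipped with a logged warning.  Locus identifiers
    are the VCF ID when set, otherwise ``CHROM:POS`` (1-based, as in the
    source format).
    """
    from cyvcf2 import VCF

    reader = VCF(str(path))
    sample_ids = list(reader.samples)
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for variant in reader:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        row = np.empty(len(sample_ids), dtype=np.int16)
        for j, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            row[j] = MISSING if (a < 0 or b < 0) else a + b
        vid = variant.ID
        locus_ids.append(vid if vid else f"{variant.CHROM}:{variant.POS}")
        rows.append(row)
    if n_skipped:
        logger.warning("skipped %d non-biallelic VCF records", n_skipped)
        warnings.warn(
            f"skipped {n_skipped} non-biallelic VCF records", stacklevel=2
        )
    if not rows:
        raise GenotypeFormatError(f"no biallelic records found in {path}")
    return GenotypeMatrix(locus_ids, sample_ids, np.vstack(rows))


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "role", "population", "hatchery_id", "country"]


@dataclass
class SampleMetadata:
    """Sample table: role (core | hatchery), strain label, hatchery, country.

    ``population`` holds the core strain label for core samples and the
    hatchery-identified strain for hatchery samples; ``None`` marks an unknown
    identified strain.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                df[col] = None
        df = df[METADATA_COLUMNS]
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise MetadataError(f"duplicate sample_id values: {dupes}")
        roles = set(df["role"])
        if not roles <= {"core", "hatchery"}:
            raise MetadataError(f"unknown roles: {sorted(roles - {'core', 'hatchery'})}")
        df["population"] = df["population"].map(_normalize_population)
        core = df["role"] == "core"
        if df.loc[core, "population"].isna().any():
            bad = df.loc[core & df["population"].isna(), "sample_id"].tolist()
            raise MetadataError(f"core samples without a population label: {bad}")
        hatch = df["role"] == "hatchery"
        hid = df.loc[hatch, "hatchery_id"]
        if hid.isna().any() or (hid.astype(str).str.strip() == "").any():
            bad = df.loc[
                hatch & (df["hatchery_id"].isna() | (df["hatchery_id"].astype(str).str.strip() == "")),
                "sample_id",
            ].tolist()
            raise MetadataError(f"hatchery samples without hatchery_id: {bad}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def core_samples(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "core"]

    def hatchery_samples(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "hatchery"]

    def population_of(self) -> pd.Series:
        """sample_id -> population (NaN where unknown)."""
        return self.table.set_index("sample_id")["population"]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        wanted = set(sample_ids)
        return SampleMetadata(self.table[self.table["sample_id"].isin(wanted)])


def _normalize_population(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text.lower() == "unknown":
        return None
    return text


def read_sample_metadata(path) -> SampleMetadata:
    """Read the metadata CSV (columns sample_id, role, population, hatchery_id,
    country) and validate the role rules."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", None)
    if "sample_id" not in df.columns or "role" not in df.columns:
        raise MetadataError("metadata file must have sample_id and role columns")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Strain -> ancestral group lookup
# ---------------------------------------------------------------------------

GROUP_GIFT = "GIFT"
GROUP_GIFT_DERIVED = "GIFT-derived"
GROUP_NON_GIFT_NILOTICUS = "non-GIFT O. niloticus"
GROUP_NON_GIFT_MOSSAMBICUS = "non-GIFT O. mossambicus"

#: Ancestral group of each sampled core strain.  GIFT-WF and GIFTFF descend
#: wholly from the original GIFT population; BEST, GET-ExCEL, Molobicus and
#: the Nile x Moss hybrid carry GIFT ancestry among others; Abbassa,
#: Chitralada and FaST are independent O. niloticus strains; O. mossambicus
#: is its own species group.
DEFAULT_STRAIN_GROUPS: Mapping[str, str] = {
    "GIFT-WF": GROUP_GIFT,
    "GIFTFF": GROUP_GIFT,
    "BEST": GROUP_GIFT_DERIVED,
    "GET-ExCEL": GROUP_GIFT_DERIVED,
    "Molobicus": GROUP_GIFT_DERIVED,
    "Nile x Moss": GROUP_GIFT_DERIVED,
    "Abbassa": GROUP_NON_GIFT_NILOTICUS,
    "Chitralada": GROUP_NON_GIFT_NILOTICUS,
    "FaST": GROUP_NON_GIFT_NILOTICUS,
    "O. mossambicus": GROUP_NON_GIFT_MOSSAMBICUS,
}
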