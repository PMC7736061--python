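"""Locus-level quality control.

Two filters, applied sequentially: minor allele frequency below a cutoff
(default < 0.01), then — among the survivors — missingness above a cutoff
(default > 0.25, strictly).  Running MAF first keeps the two removed sets
disjoint so the accounting identity n_input = removed_maf + removed_missing +
retained always holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


def locus_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus ALT-allele frequency, MAF, missingness and call count.

    ``alt_freq`` is computed over non-missing calls only; a locus with zero
    calls gets ``alt_freq`` NaN, ``maf`` 0 and ``missing_rate`` 1.
    """
    if g.n_loci == 0 or g.n_samples == 0:
        raise ValueError("genotype matrix is empty")
    called = g.calls != MISSING
    n_called = called.sum(axis=1)
    alt_sum = np.where(called, g.calls, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    maf = np.where(n_called > 0, np.minimum(alt_freq, 1.0 - alt_freq), 0.0)
    missing_rate = 1.0 - n_called / g.n_samples
    return pd.DataFrame(
        {
            "alt_freq": alt_freq,
            "maf": maf,
            "missing_rate": missing_rate,
            "n_called": n_called,
        },
        index=pd.Index(g.locus_ids, name="locus_id"),
    )


@dataclass
class QcReport:
    """Accounting of the two sequential locus filters."""

    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int
    removed_maf_ids: list[str] = field(default_factory=list)
    removed_missing_ids: list[str] = field(default_factory=list)
    maf_min: float = 0.01
    max_missing: float = 0.25

    def __post_init__(self) -> None:
        assert self.n_input == (
            self.n_removed_maf + self.n_removed_missing + self.n_retained
        ), "QC accounting identity violated"

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_missing": self.n_removed_missing,
            "n_retained": self.n_retained,
            "maf_min": self.maf_min,
            "max_missing": self.max_missing,
            "removed_maf_ids": self.removed_maf_ids,
            "removed_missing_ids": self.removed_missing_ids,
        }


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing: float = 0.25,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove loci with MAF < ``maf_min``, then loci with missingness
    > ``max_missing`` among the survivors.

    Both comparisons are strict, reading the filter wording literally:
    a locus at exactly the MAF cutoff is kept, a locus at exactly the
    missingness cutoff is kept.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    if g.n_loci == 0:
        return g, QcReport(0, 0, 0, 0, maf_min=maf_min, max_missing=max_missing)
    stats = locus_stats(g)
    fail_maf = stats["maf"].to_numpy() < maf_min
    fail_missing = (~fail_maf) & (stats["missing_rate"].to_numpy() > max_missing)
    keep = ~(fail_maf | fail_missing)
    locus_ids = np.asarray(g.locus_ids, dtype=object)
    report = QcReport(
        n_input=g.n_loci,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_missing.sum()),
        n_retained=int(keep.sum()),
        removed_maf_ids=list(locus_ids[fail_maf]),
        removed_missing_ids=list(locus_ids[fail_missing]),
        maf_min=maf_min,
        max_missing=max_missing,
    )
    if report.n_retained == 0:
        warnings.warn("all loci removed by QC filters", stacklevel=2)
    filtered = g.subset(loci=list(locus_ids[keep]))
    return filtered, report
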