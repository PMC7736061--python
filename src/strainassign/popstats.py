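"""Per-population allele frequencies and pairwise differentiation statistics.

For two populations with ALT-allele frequencies p_i and p_j at a locus the
two per-locus statistics used for marker ranking are

    FST = (HT - HS) / HT        with  HT = 2 p̄ (1 - p̄),  p̄ = (p_i + p_j)/2,
                                      HS = (2 p_i (1-p_i) + 2 p_j (1-p_j)) / 2
    δ   = |p_i - p_j|

This is the GST-style two-population form without sample-size weighting; the
two statistics obey the identity FST = δ² / (2 HT) whenever HT > 0.  Both are
descriptive inputs to ranking, not small-sample-corrected estimators.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class PopAlleleFreqs:
    """Per-population, per-locus ALT-allele frequencies.

    ``freqs``: loci x populations DataFrame, NaN where a population has zero
    calls at the locus.  ``n_called``: matching called-sample counts.
    """

    freqs: pd.DataFrame
    n_called: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.freqs.index)


def pop_allele_frequencies(
    g: GenotypeMatrix,
    meta: SampleMetadata,
    populations: list[str] | None = None,
) -> PopAlleleFreqs:
    """ALT-allele frequency per population per locus.

    p = (sum of non-missing calls) / (2 * called samples) within each
    population; loci with zero calls in a population are NaN there.
    """
    pop_of = meta.population_of()
    sample_pops = pop_of.reindex(g.sample_ids)
    if populations is None:
        populations = sorted({p for p in sample_pops if isinstance(p, str)})
    freq_cols = {}
    count_cols = {}
    for pop in populations:
        members = [s for s in g.sample_ids if sample_pops.get(s) == pop]
        if not members:
            raise ValueError(f"population {pop!r} has no samples in the matrix")
        sub = g.subset(samples=members)
        called = sub.calls != MISSING
        n_called = called.sum(axis=1)
        alt_sum = np.where(called, sub.calls, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
        freq_cols[pop] = p
        count_cols[pop] = n_called
    index = pd.Index(g.locus_ids, name="locus_id")
    return PopAlleleFreqs(
        pd.DataFrame(freq_cols, index=index),
        pd.DataFrame(count_cols, index=index),
    )


def expected_heterozygosity(p):
    """Hardy–Weinberg expected heterozygosity 2p(1-p); vectorized."""
    p = np.asarray(p, dtype=float)
    defined = ~np.isnan(p)
    if np.any((p[defined] < 0) | (p[defined] > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return out if out.ndim else float(out)


def fst_locus(p_i, p_j):
    """Two-population per-locus FST = (HT - HS)/HT.

    HT is the expected heterozygosity at the unweighted mean frequency, HS the
    unweighted mean of the two within-population heterozygosities.  Returns 0
    where HT = 0 (both populations fixed for the same allele) so that ranking
    is total; NaN inputs propagate.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    hs = (expected_heterozygosity(p_i) + expected_heterozygosity(p_j)) / 2.0
    p_bar = (p_i + p_j) / 2.0
    ht = 2.0 * p_bar * (1.0 - p_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    fst = np.where(np.isnan(p_i) | np.isnan(p_j), np.nan, fst)
    return fst if fst.ndim else float(fst)


def delta_locus(p_i, p_j):
    """Absolute allele-frequency difference |p_i - p_j|; NaN propagates."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    out = np.abs(p_i - p_j)
    return out if out.ndim else float(out)


@dataclass
class PairStatTable:
    """Long table of per-(population pair, locus) statistics.

    Columns: pop_i, pop_j (pair ordered pop_i < pop_j), locus_id, fst, delta,
    HT, HS.  Loci undefined in either member of a pair are omitted for that
    pair.
    """

    table: pd.DataFrame

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(
            set(zip(self.table["pop_i"], self.table["pop_j"]))
        )

    def for_pair(self, pair: tuple[str, str]) -> pd.DataFrame:
        i, j = sorted(pair)
        sel = (self.table["pop_i"] == i) & (self.table["pop_j"] == j)
        if not sel.any():
            raise KeyError(f"pair {(i, j)} not present in the statistics table")
        return self.table[sel]


def all_pairwise_stats(freqs: PopAlleleFreqs) -> PairStatTable:
    """FST and δ for every locus over every unordered population pair.

    P populations give P(P-1)/2 pairs.  Rows where either frequency is
    undefined are dropped for that pair (logged).
    """
    pops = freqs.populations
    if len(pops) < 2:
        raise ValueError("at least two populations are required")
    locus_ids = np.asarray(freqs.locus_ids, dtype=object)
    frames = []
    n_dropped = 0
    for a, b in itertools.combinations(sorted(pops), 2):
        p_i = freqs.freqs[a].to_numpy()
        p_j = freqs.freqs[b].to_numpy()
        defined = ~(np.isnan(p_i) | np.isnan(p_j))
        n_dropped += int((~defined).sum())
        pi, pj = p_i[defined], p_j[defined]
        hs = (expected_heterozygosity(pi) + expected_heterozygosity(pj)) / 2.0
        p_bar = (pi + pj) / 2.0
        ht = 2.0 * p_bar * (1.0 - p_bar)
        frames.append(
            pd.DataFrame(
                {
                    "pop_i": a,
                    "pop_j": b,
                    "locus_id": locus_ids[defined],
                    "fst": fst_locus(pi, pj),
                    "delta": delta_locus(pi, pj),
                    "HT": ht,
                    "HS": hs,
                }
            )
        )
    if n_dropped:
        logger.info(
            "omitted %d (pair, locus) rows with undefined frequencies", n_dropped
        )
    return PairStatTable(pd.concat(frames, ignore_index=True))
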