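"""Synthetic genotype fixtures with the structure the pipeline assumes.

Populations diverge from a common founder under the Balding–Nichols model:
given founder frequency p and divergence F, the drifted frequency is drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is p and whose variance is
F·p(1-p).  Composite (admixed) strains are convex combinations of parent
frequency vectors.  Genotypes are Hardy–Weinberg draws, Binomial(2, p) per
locus; missingness is uniform at random.  Hatchery stocks are drawn from
lightly re-drifted versions of their source strain, each carrying a
hatchery-identified strain label that is wrong with a configurable mislabel
probability — the ground-truth tables make every downstream stage testable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, SampleMetadata

#: Sample counts of the ten core strains in the default design.
DEFAULT_CORE_COUNTS: dict[str, int] = {
    "GIFT-WF": 99,
    "GIFTFF": 47,
    "BEST": 47,
    "GET-ExCEL": 94,
    "Molobicus": 172,
    "Nile x Moss": 21,
    "Abbassa": 122,
    "Chitralada": 94,
    "FaST": 120,
    "O. mossambicus": 36,
}


@dataclass
class PopulationSpec:
    """One simulated population.

    ``f`` is the Balding–Nichols divergence applied to its base frequencies;
    ``admixture`` (optional) mixes the *drifted* frequency vectors of earlier
    populations before a final drift of ``f`` is applied, modelling composite
    strains at the allele-frequency level.
    """

    label: str
    n: int
    f: float = 0.15
    admixture: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f < 1.0):
            raise ValueError(f"divergence F must be in [0, 1), got {self.f}")
        if self.admixture is not None:
            w = np.asarray(list(self.admixture.values()), dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    f"admixture weights for {self.label!r} must be "
                    "non-negative and sum to 1"
                )


@dataclass
class HatcherySpec:
    """One simulated hatchery: ~10 broodstock drawn from a source strain."""

    hatchery_id: str
    source: str
    n: int = 10
    f: float = 0.02
    mislabel_prob: float = 0.0
    country: str = "Bangladesh"


@dataclass
class SimDesign:
    """Full fixture design; :func:`default_design` mirrors the real study's
    population structure at desk scale (1,000 loci)."""

    n_loci: int = 1000
    founder_low: float = 0.05
    founder_high: float = 0.95
    populations: list[PopulationSpec] = field(default_factory=list)
    hatcheries: list[HatcherySpec] = field(default_factory=list)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        known = set(labels)
        for h in self.hatcheries:
            if h.source not in known:
                raise ValueError(f"hatchery {h.hatchery_id!r} sources unknown "
                                 f"strain {h.source!r}")


def default_design(
    n_loci: int = 1000,
    f: float = 0.15,
    hatcheries_per_strain: int = 20,
    hatchery_n: int = 10,
    mislabel_prob: float = 0.0,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> SimDesign:
    """Ten core populations with the study's sample counts, plus hatcheries.

    The default hatchery block — 200 hatcheries of ~10 broodstock each —
    mirrors the scale of the real survey (205 hatcheries, ~2,000 samples).

    Core strains drift independently from a shared founder at divergence
    ``f`` except the composite strains: BEST and Nile x Moss mix GIFT-WF with
    O. mossambicus ancestry, Molobicus mixes GIFT-WF, FaST and O. mossambicus
    — echoing the real strains' hybrid origins at the allele-frequency level.
    """
    pops = []
    for label, n in DEFAULT_CORE_COUNTS.items():
        admix = None
        if label == "BEST":
            admix = {"GIFT-WF": 0.7, "O. mossambicus": 0.3}
        elif label == "Nile x Moss":
            admix = {"GIFT-WF": 0.5, "O. mossambicus": 0.5}
        elif label == "Molobicus":
            admix = {"GIFT-WF": 0.4, "FaST": 0.3, "O. mossambicus": 0.3}
        pops.append(PopulationSpec(label, n, f=f, admixture=admix))
    # admixture parents must be generated first
    order = {"GIFT-WF": 0, "O. mossambicus": 1, "FaST": 2}
    pops.sort(key=lambda p: order.get(p.label, 10))
    strains = list(DEFAULT_CORE_COUNTS)
    hatcheries = []
    i = 0
    for strain in strains:
        for j in range(hatcheries_per_strain):
            i += 1
            country = "Bangladesh" if i % 2 else "Philippines"
            hatcheries.append(
                HatcherySpec(
                    f"H{i:03d}", strain, n=hatchery_n,
                    mislabel_prob=mislabel_prob, country=country,
                )
            )
    return SimDesign(
        n_loci=n_loci,
        populations=pops,
        hatcheries=hatcheries,
        missing_rate=missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def drift_freqs(founder_p: np.ndarray, f: float, rng) -> np.ndarray:
    """Balding–Nichols drift: Beta(p(1-F)/F, (1-p)(1-F)/F) per locus.

    F = 0 returns the founder frequencies unchanged; loci fixed in the
    founder (p of 0 or 1) stay fixed.
    """
    if not (0.0 <= f < 1.0):
        raise ValueError(f"F must be in [0, 1), got {f}")
    founder_p = np.asarray(founder_p, dtype=float)
    if f == 0.0:
        return founder_p.copy()
    rng = np.random.default_rng(rng)
    scale = (1.0 - f) / f
    out = founder_p.copy()
    poly = (founder_p > 0) & (founder_p < 1)
    p = founder_p[poly]
    out[poly] = rng.beta(p * scale, (1.0 - p) * scale)
    return out


def admix_freqs(parents: Sequence[np.ndarray], weights: Sequence[float]) -> np.ndarray:
    """Convex combination of parent frequency vectors per locus."""
    weights = np.asarray(weights, dtype=float)
    if len(parents) != len(weights):
        raise ValueError("number of parents and weights differ")
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    stacked = np.vstack([np.asarray(p, dtype=float) for p in parents])
    return weights @ stacked


def sample_genotypes(
    p: np.ndarray, n: int, rng, sample_prefix: str = "S", locus_ids=None
) -> GenotypeMatrix:
    """Hardy–Weinberg genotypes: each call ~ Binomial(2, p_locus)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    p = np.asarray(p, dtype=float)
    calls = rng.binomial(2, p[:, None], size=(len(p), n)).astype(np.int16)
    if locus_ids is None:
        locus_ids = [f"L{i + 1:05d}" for i in range(len(p))]
    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(list(locus_ids), sample_ids, calls)


# ---------------------------------------------------------------------------
# Fixture assembly
# ---------------------------------------------------------------------------

@dataclass
class FixtureTruth:
    """Ground truth for test oracles."""

    sample_source: pd.Series        # sample_id -> true source strain
    hatchery_source: pd.DataFrame   # hatchery_id, true_source, identified, mislabeled
    population_freqs: pd.DataFrame  # loci x strains true frequencies


def make_fixture(
    design: SimDesign,
) -> tuple[GenotypeMatrix, SampleMetadata, FixtureTruth]:
    """Generate core + hatchery genotypes, metadata and ground truth.

    Fully reproducible from ``design.seed``: the same design yields identical
    matrices, metadata and truth tables.
    """
    rng = np.random.default_rng(design.seed)
    locus_ids = [f"L{i + 1:05d}" for i in range(design.n_loci)]
    founder = rng.uniform(design.founder_low, design.founder_high, design.n_loci)

    pop_freqs: dict[str, np.ndarray] = {}
    for pop in design.populations:
        if pop.admixture is None:
            base = founder
        else:
            base = admix_freqs(
                [pop_freqs[parent] for parent in pop.admixture],
                list(pop.admixture.values()),
            )
        pop_freqs[pop.label] = drift_freqs(base, pop.f, rng)

    blocks, meta_rows, truth_rows = [], [], []
    for pop in design.populations:
        gm = sample_genotypes(
            pop_freqs[pop.label], pop.n, rng,
            sample_prefix=f"{_slug(pop.label)}-", locus_ids=locus_ids,
        )
        blocks.append(gm)
        for sid in gm.sample_ids:
            meta_rows.append(
                {"sample_id": sid, "role": "core", "population": pop.label,
                 "hatchery_id": None, "country": None}
            )
            truth_rows.append({"sample_id": sid, "true_source": pop.label})

    strains = [p.label for p in design.populations]
    hatch_truth = []
    for h in design.hatcheries:
        hf = drift_freqs(pop_freqs[h.source], h.f, rng)
        gm = sample_genotypes(
            hf, h.n, rng, sample_prefix=f"{h.hatchery_id}-", locus_ids=locus_ids
        )
        mislabeled = bool(rng.random() < h.mislabel_prob)
        if mislabeled:
            others = [s for s in strains if s != h.source]
            identified = others[int(rng.integers(len(others)))]
        else:
            identified = h.source
        blocks.append(gm)
        for sid in gm.sample_ids:
            meta_rows.append(
                {"sample_id": sid, "role": "hatchery", "population": identified,
                 "hatchery_id": h.hatchery_id, "country": h.country}
            )
            truth_rows.append({"sample_id": sid, "true_source": h.source})
        hatch_truth.append(
            {"hatchery_id": h.hatchery_id, "true_source": h.source,
             "identified": identified, "mislabeled": mislabeled}
        )

    calls = np.hstack([b.calls for b in blocks])
    sample_ids = [sid for b in blocks for sid in b.sample_ids]
    if design.missing_rate > 0:
        drop = rng.random(calls.shape) < design.missing_rate
        calls = np.where(drop, MISSING, calls)
    genotypes = GenotypeMatrix(locus_ids, sample_ids, calls)
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = FixtureTruth(
        sample_source=pd.DataFrame(truth_rows).set_index("sample_id")["true_source"],
        hatchery_source=pd.DataFrame(
            hatch_truth,
            columns=["hatchery_id", "true_source", "identified", "mislabeled"],
        ),
        population_freqs=pd.DataFrame(pop_freqs, index=locus_ids),
    )
    return genotypes, meta, truth


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "" for c in label)[:12]
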