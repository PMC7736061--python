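"""Strain assignment of hatchery samples and core-population validation.

Individuals are assigned the strain with the greatest posterior membership
probability from a fitted DAPC.  Individuals missing more than a panel
missingness cutoff (default 25%) of the model's loci, or with a tied maximum
posterior, are unassignable.  Hatcheries are assigned their modal strain —
the strain carried by the most assignable individuals — and accepted only
when the modal fraction reaches the confidence threshold (default 0.75) with
no tie.  Strain labels can be collapsed to ancestral groups (GIFT,
GIFT-derived, non-GIFT O. niloticus, non-GIFT O. mossambicus) and the
aggregation re-run at group level.

Core-population validation masks a stratified 25% of each population, fits on
the rest, predicts the masked individuals, and averages the resulting
percentage confusion matrix over repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dapc import DAPC, DAPCResults
from .io import MISSING, GenotypeMatrix, SampleMetadata

logger = logging.getLogger(__name__)

UNASSIGNED = "Unassigned"


@dataclass
class AssignmentTable:
    """Per-individual posteriors and argmax assignments.

    ``table`` columns: one posterior column per group, then
    ``assigned_strain`` (NaN when unassignable), ``max_posterior`` and
    ``status`` in {assigned, missing_exceeded, tie}.
    """

    table: pd.DataFrame
    groups: list[str]

    @property
    def assigned(self) -> pd.Series:
        return self.table["assigned_strain"]

    def posterior_matrix(self) -> pd.DataFrame:
        return self.table[self.groups]


def assign_individuals(
    m: DAPCResults,
    g: GenotypeMatrix,
    max_missing_panel: float = 0.25,
) -> AssignmentTable:
    """Argmax-posterior strain per sample, with panel-missingness gating.

    Samples whose missing rate over the model's loci exceeds
    ``max_missing_panel`` are unassignable; exact posterior ties are flagged
    and left unassigned.
    """
    sub = g.subset(loci=m.locus_ids)
    miss_rate = (sub.calls == MISSING).mean(axis=0)
    post = m.predict_membership(g)
    vals = post.to_numpy()
    status = np.full(g.n_samples, "assigned", dtype=object)
    assigned = np.empty(g.n_samples, dtype=object)
    max_post = np.full(g.n_samples, np.nan)
    for i in range(g.n_samples):
        if miss_rate[i] > max_missing_panel or np.isnan(vals[i]).all():
            status[i] = "missing_exceeded"
            assigned[i] = None
            continue
        row = vals[i]
        top = row.max()
        winners = np.flatnonzero(row == top)
        if len(winners) > 1:
            status[i] = "tie"
            assigned[i] = None
            logger.info("posterior tie for sample %s", g.sample_ids[i])
            continue
        assigned[i] = post.columns[winners[0]]
        max_post[i] = top
    out = post.copy()
    out["assigned_strain"] = assigned
    out["max_posterior"] = max_post
    out["status"] = status
    out.index.name = "sample_id"
    return AssignmentTable(out, list(post.columns))


@dataclass
class HatcheryAssignment:
    """Modal-strain aggregation for one hatchery."""

    hatchery_id: str
    n_sampled: int
    n_assignable: int
    counts: dict[str, int]
    modal_strain: str | None
    modal_fraction: float
    status: str  # assigned | below_threshold | tie


def aggregate_hatchery(
    a: AssignmentTable,
    meta: SampleMetadata,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Modal strain per hatchery with the confidence-threshold rule.

    modal_fraction = (modal-strain count) / (assignable individuals); the
    hatchery is ``assigned`` only when modal_fraction >= threshold and the
    mode is unique.  Ties and hatcheries with no assignable individual are
    surfaced, never silently broken.
    """
    hatch = meta.hatchery_samples().set_index("sample_id")
    rows = []
    for hatchery_id, sample_ids in hatch.groupby("hatchery_id").groups.items():
        present = [s for s in sample_ids if s in a.table.index]
        sub = a.table.loc[present]
        assigned = sub["assigned_strain"].dropna()
        counts = assigned.value_counts().to_dict()
        n_assignable = int(len(assigned))
        if n_assignable == 0:
            rows.append(
                HatcheryAssignment(
                    str(hatchery_id), len(present), 0, {}, None, np.nan,
                    "below_threshold",
                )
            )
            continue
        top = max(counts.values())
        modal = sorted(k for k, v in counts.items() if v == top)
        fraction = top / n_assignable
        if len(modal) > 1:
            status, modal_strain = "tie", None
        elif fraction >= threshold:
            status, modal_strain = "assigned", modal[0]
        else:
            status, modal_strain = "below_threshold", modal[0]
        rows.append(
            HatcheryAssignment(
                str(hatchery_id), len(present), n_assignable, counts,
                modal_strain, fraction, status,
            )
        )
    out = pd.DataFrame(
        [
            {
                "hatchery_id": r.hatchery_id,
                "n_sampled": r.n_sampled,
                "n_assignable": r.n_assignable,
                "modal_strain": r.modal_strain,
                "modal_fraction": r.modal_fraction,
                "status": r.status,
                "counts": r.counts,
            }
            for r in rows
        ]
    )
    return out.sort_values("hatchery_id").reset_index(drop=True)


def map_groups(labels: Sequence[str], mapping: Mapping[str, str]) -> list[str]:
    """Relabel strains to ancestral groups; the map must cover every label."""
    unmapped = sorted({l for l in labels if l is not None and l not in mapping})
    if unmapped:
        raise ValueError(f"strain labels missing from the group map: {unmapped}")
    return [mapping[l] if l is not None else None for l in labels]


def map_assignment_groups(
    a: AssignmentTable, mapping: Mapping[str, str]
) -> AssignmentTable:
    """Collapse an individual-level AssignmentTable from strains to groups.

    Posterior columns of strains in the same group are summed; the assigned
    label is re-mapped directly (the argmax strain's group), preserving the
    modal-count semantics of group-level aggregation.
    """
    groups = map_groups(a.groups, mapping)
    post = a.posterior_matrix()
    collapsed = post.T.groupby(np.asarray(groups)).sum().T
    out = collapsed.copy()
    out["assigned_strain"] = [
        mapping[s] if isinstance(s, str) else None for s in a.table["assigned_strain"]
    ]
    out["max_posterior"] = a.table["max_posterior"]
    out["status"] = a.table["status"]
    return AssignmentTable(out, list(collapsed.columns))


# ---------------------------------------------------------------------------
# Core-population cross-validation (confusion matrices)
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """True x predicted percentage matrix averaged over masking repeats."""

    percentages: pd.DataFrame  # rows: true strain; cols: predicted + Unassigned
    counts: pd.DataFrame
    n_reps: int

    def diagonal(self) -> pd.Series:
        labels = [l for l in self.percentages.index if l in self.percentages.columns]
        return pd.Series(
            [self.percentages.at[l, l] for l in labels], index=labels
        )


def crossvalidate_core(
    g: GenotypeMatrix,
    labels: Sequence[str],
    mask_fraction: float = 0.25,
    reps: int = 10,
    n_pca: int | str = "auto",
    xval_grid: Sequence[int] | None = None,
    xval_reps: int = 10,
    seed: int = 0,
) -> ConfusionMatrix:
    """Masked cross-validation of core populations.

    Per repeat, a stratified ``mask_fraction`` of each population is masked,
    the model is fitted on the rest, and masked individuals are assigned by
    greatest posterior membership.  Tallies are averaged over ``reps`` into a
    row-percentage matrix (each row sums to 100 over predicted labels plus
    Unassigned).

    ``n_pca='auto'`` chooses the retained-PC count once, by stratified
    cross-validation on the full data, and reuses it for every repeat.
    """
    labels = np.asarray([str(l) for l in labels], dtype=object)
    groups = sorted(set(labels))
    min_needed = int(np.ceil(1.0 / mask_fraction))
    for gname in groups:
        if (labels == gname).sum() < min_needed:
            raise ValueError(
                f"population {gname!r} has fewer than {min_needed} members"
            )
    rng = np.random.default_rng(seed)
    if n_pca == "auto":
        model = DAPC(g, labels)
        if xval_grid is None:
            hi = max(2, min(model.rank, len(labels) - 1))
            xval_grid = sorted({max(2, hi // 8), max(2, hi // 4), hi // 2, hi})
        xv = model.xval_npca(
            xval_grid, reps=xval_reps, seed=int(rng.integers(2**31 - 1))
        )
        n_pca = xv.chosen_n_pca
        logger.info("auto n_pca -> %d (grid %s)", n_pca, list(xval_grid))
    n_pca = int(n_pca)

    pred_labels = groups + [UNASSIGNED]
    counts = pd.DataFrame(0.0, index=groups, columns=pred_labels)
    sample_ids = np.asarray(g.sample_ids, dtype=object)
    for _ in range(reps):
        masked_idx = []
        for gname in groups:
            idx = np.flatnonzero(labels == gname)
            n_mask = max(1, int(round(mask_fraction * len(idx))))
            masked_idx.extend(rng.permutation(idx)[:n_mask])
        masked_idx = np.asarray(masked_idx)
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[masked_idx] = False
        g_train = g.subset(samples=list(sample_ids[train_mask]))
        g_test = g.subset(samples=list(sample_ids[masked_idx]))
        res = DAPC(g_train, labels[train_mask]).fit(n_pca=n_pca)
        table = assign_individuals(res, g_test, max_missing_panel=1.0)
        truth = labels[masked_idx]
        for t, p in zip(truth, table.assigned):
            counts.at[t, p if isinstance(p, str) else UNASSIGNED] += 1
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return ConfusionMatrix(pct, counts, reps)


# ---------------------------------------------------------------------------
# Agreement cross-tabulations (hatchery-identified vs DAPC-assigned)
# ---------------------------------------------------------------------------

def agreement_table(
    a: AssignmentTable,
    meta: SampleMetadata,
    level: str = "individual",
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Cross-tabulate hatchery-identified strain against DAPC-assigned strain.

    ``level='individual'`` tabulates samples; ``level='hatchery'`` tabulates
    modal hatchery assignments (only hatcheries with a modal strain).  Rows
    are hatchery-identified strains ('Unknown' where the hatchery could not
    name one); cells are row percentages.
    """
    hatch = meta.hatchery_samples().set_index("sample_id")
    if level == "individual":
        idx = [s for s in a.table.index if s in hatch.index]
        identified = hatch.loc[idx, "population"].fillna("Unknown")
        assigned = a.table.loc[idx, "assigned_strain"].fillna(UNASSIGNED)
        ct = pd.crosstab(identified, assigned)
    elif level == "hatchery":
        agg = aggregate_hatchery(a, meta, threshold=threshold)
        ident_by_hatch = (
            hatch.groupby("hatchery_id")["population"]
            .agg(lambda s: s.dropna().iloc[0] if s.notna().any() else "Unknown")
        )
        rows = agg[agg["modal_strain"].notna()]
        ct = pd.crosstab(
            ident_by_hatch.reindex(rows["hatchery_id"]).fillna("Unknown").to_numpy(),
            rows["modal_strain"].to_numpy(),
        )
    else:
        raise ValueError("level must be 'individual' or 'hatchery'")
    return ct.div(ct.sum(axis=1), axis=0) * 100.0


def agreement_rate(
    a: AssignmentTable,
    meta: SampleMetadata,
    model_populations: Sequence[str],
    level: str = "hatchery",
    threshold: float = 0.75,
) -> float:
    """Fraction of cases where the hatchery-identified strain matches the
    DAPC assignment, restricted to cases whose identified strain is one of
    the model's populations (hatcheries with unknown strain are excluded)."""
    hatch = meta.hatchery_samples().set_index("sample_id")
    known = set(model_populations)
    if level == "individual":
        idx = [
            s
            for s in a.table.index
            if s in hatch.index and hatch.at[s, "population"] in known
        ]
        sub = a.table.loc[idx]
        sub = sub[sub["assigned_strain"].notna()]
        if len(sub) == 0:
            return float("nan")
        truth = hatch.loc[sub.index, "population"]
        return float((sub["assigned_strain"] == truth).mean())
    if level == "hatchery":
        agg = aggregate_hatchery(a, meta, threshold=threshold)
        ident = (
            hatch.groupby("hatchery_id")["population"]
            .agg(lambda s: s.dropna().iloc[0] if s.notna().any() else None)
        )
        agg = agg[agg["modal_strain"].notna()]
        agg = agg[agg["hatchery_id"].map(ident).isin(known)]
        if len(agg) == 0:
            return float("nan")
        return float(
            (agg["modal_strain"] == agg["hatchery_id"].map(ident)).mean()
        )
    raise ValueError("level must be 'individual' or 'hatchery'")
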