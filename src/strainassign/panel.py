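"""Informative-SNP panel construction.

For every population pair, loci are ranked by a differentiation metric (FST or
δ) and the top N taken; the panel is the de-duplicated union over all pairs
and metrics.  Ties in the metric are broken by locus identifier ascending so
panel membership is deterministic and invariant to input row order.  Each
panel locus keeps its provenance — which (pair, metric, rank) selections put
it there — so a panel file can explain why each SNP is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .popstats import PairStatTable

METRICS = ("fst", "delta")


@dataclass
class PanelDefinition:
    """Selected loci with per-(pair, metric) rank provenance."""

    locus_ids: list[str]
    provenance: dict[str, list[tuple[tuple[str, str], str, int]]]
    top_n: int
    metrics: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        """One row per panel locus: selection count, best rank, metrics."""
        rows = []
        for locus in self.locus_ids:
            triples = self.provenance[locus]
            rows.append(
                {
                    "locus_id": locus,
                    "n_selecting_pairs": len({pair for pair, _, _ in triples}),
                    "best_rank": min(rank for _, _, rank in triples),
                    "metrics": ",".join(sorted({m for _, m, _ in triples})),
                }
            )
        return pd.DataFrame(rows)


def rank_pair(
    stats: PairStatTable,
    pair: tuple[str, str],
    metric: str = "fst",
    top_n: int = 75,
) -> list[str]:
    """Top ``top_n`` loci for one population pair under one metric.

    Sorted by metric descending, ties broken by locus_id ascending; returns
    fewer than ``top_n`` loci only when the pair has fewer defined loci.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    sub = stats.for_pair(pair)
    ordered = sub.sort_values(
        [metric, "locus_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered["locus_id"].head(top_n).tolist()


def build_panel(
    stats: PairStatTable,
    top_n: int = 75,
    metrics: tuple[str, ...] = ("fst", "delta"),
) -> PanelDefinition:
    """Union of per-pair top-N rankings over the requested metrics.

    The returned locus list is sorted by identifier, making the panel
    invariant to the row order of the input table.
    """
    if not metrics:
        raise ValueError("at least one metric is required")
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    if stats.table.empty:
        raise ValueError("empty statistics table")
    provenance: dict[str, list[tuple[tuple[str, str], str, int]]] = {}
    for pair in stats.pairs:
        for metric in metrics:
            for rank, locus in enumerate(rank_pair(stats, pair, metric, top_n), 1):
                provenance.setdefault(locus, []).append((pair, metric, rank))
    locus_ids = sorted(provenance)
    return PanelDefinition(locus_ids, provenance, top_n, tuple(metrics))
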