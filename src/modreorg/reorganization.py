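"""Module-reorganization maps between two partitions and homotopic splits.

``compare_partitions`` cross-tabulates region membership between a source
(e.g. control) and a target (e.g. patient) partition and, for each source
module, lists the target modules receiving its members — the flow picture
of how modules break apart. ``homotopic_splits`` flags every homotopic pair
whose two members carry different module labels within a single partition
(a "broken" pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from modreorg.atlas_io import AtlasError, RegionAtlas
from modreorg.modularity import ModulePartition


@dataclass
class ReorganizationMap:
    """Source -> target module flow of a region set.

    ``table`` is the (source module x target module) contingency table of
    region counts. ``flows`` lists, per (source, target) cell with >= 1
    member, the region indices that moved. ``match`` gives each source
    module its maximal-overlap target module (ties broken toward the larger
    target module, then the lower label), with the Jaccard overlap alongside.
    """

    table: pd.DataFrame
    flows: list[dict]
    match: dict[int, dict]

    def to_dict(self) -> dict:
        return {
            "cross_tab": {str(s): {str(t): int(v)
                                   for t, v in row.items() if v}
                          for s, row in self.table.iterrows()},
            "flows": self.flows,
            "match": {str(s): m for s, m in self.match.items()},
        }


def compare_partitions(p_source: ModulePartition,
                       p_target: ModulePartition,
                       region_ids: list[int] | None = None
                       ) -> ReorganizationMap:
    """Cross-tabulate two partitions of the same region set."""
    src = p_source.labels
    tgt = p_target.labels
    if src.shape != tgt.shape:
        raise ValueError(
            f"partitions cover different region counts: "
            f"{src.shape[0]} vs {tgt.shape[0]}"
        )
    if region_ids is None:
        region_ids = list(range(1, src.shape[0] + 1))
    src_mods = np.arange(1, src.max() + 1)
    tgt_mods = np.arange(1, tgt.max() + 1)
    table = pd.DataFrame(0, index=src_mods, columns=tgt_mods)
    for s, t in zip(src, tgt):
        table.loc[s, t] += 1

    flows = []
    for s in src_mods:
        for t in tgt_mods:
            members = [region_ids[i] for i in range(len(src))
                       if src[i] == s and tgt[i] == t]
            if members:
                flows.append({"source": int(s), "target": int(t),
                              "regions": members})

    tgt_sizes = {int(t): int((tgt == t).sum()) for t in tgt_mods}
    match: dict[int, dict] = {}
    for s in src_mods:
        row = table.loc[s]
        best = max(tgt_mods,
                   key=lambda t: (row[t], tgt_sizes[int(t)], -int(t)))
        overlap = int(row[best])
        union = int((src == s).sum()) + tgt_sizes[int(best)] - overlap
        match[int(s)] = {
            "target": int(best),
            "overlap": overlap,
            "jaccard": overlap / union if union else 0.0,
        }
    return ReorganizationMap(table=table, flows=flows, match=match)


@dataclass
class HomotopicSplitReport:
    """Per-pair split flags under one partition, with summary counts."""

    records: pd.DataFrame   # left, right, module_left, module_right, split
    n_pairs: int
    n_split: int
    subset: str | None = None

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "n_pairs": self.n_pairs,
            "n_split": self.n_split,
            "pairs": self.records.to_dict(orient="records"),
        }


def homotopic_splits(p: ModulePartition, atlas: RegionAtlas,
                     subset: str | None = None) -> HomotopicSplitReport:
    """Flag homotopic pairs whose members fall in different modules.

    ``subset`` restricts to a named pair set; unknown names raise with the
    list of available subsets.
    """
    if p.labels.shape[0] != atlas.n_regions:
        raise ValueError(
            f"partition covers {p.labels.shape[0]} regions but atlas has "
            f"{atlas.n_regions}"
        )
    try:
        pairs = atlas.subset_pairs(subset)
    except AtlasError:
        raise
    rows = []
    for left, right in pairs:
        ml = int(p.labels[atlas.index_of(left)])
        mr = int(p.labels[atlas.index_of(right)])
        rows.append({"left": left, "right": right,
                     "module_left": ml, "module_right": mr,
                     "split": ml != mr})
    records = pd.DataFrame(rows)
    return HomotopicSplitReport(
        records=records,
        n_pairs=len(rows),
        n_split=int(records["split"].sum()) if rows else 0,
        subset=subset,
    )
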