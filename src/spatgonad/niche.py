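"""Neighborhood selection and niche composition around target pixels.

The vicinity of a target pixel is the set of pixels within Chebyshev
distance ``r`` on the grid (default r = 1: the eight surrounding pixels),
the central pixel excluded. Neighborhoods are collected per sample — a
neighbor never crosses section boundaries — deduplicated across targets,
and the targets themselves are appended to form the final selection.

Composition tallies the *neighbor* pixels (targets are excluded from the
tally, so a germ target adjacent to another germ target is not its own
niche) by cell type within each (target_subtype, stage) group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .annotate import CellLabelTable
from .gridio import SpatialSample

__all__ = ["NicheSelection", "NicheTable", "select_neighborhood", "niche_composition"]


@dataclass
class NicheSelection:
    """Targets plus their deduplicated grid neighbors within one sample."""

    target_ids: list[str]
    radius: int
    neighbor_ids: list[str]      # deduplicated, sample pixel order; may include other targets
    final_ids: list[str]         # neighbors union targets
    sample_id: str
    target_subtype: str | None = None
    stage: str | None = None

    def tally_ids(self) -> list[str]:
        """Pixels entering the composition tally: final minus targets."""
        targets = set(self.target_ids)
        return [p for p in self.final_ids if p not in targets]


@dataclass
class NicheTable:
    """Neighbor counts and proportions by cell type per (subtype, stage)."""

    df: pd.DataFrame

    def proportions(self, target_subtype: str, stage: str) -> pd.Series:
        sel = self.df[
            (self.df["target_subtype"] == target_subtype)
            & (self.df["stage"] == stage)
        ]
        return sel.set_index("cell_type")["proportion"]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def select_neighborhood(
    sample: SpatialSample,
    target_ids,
    r: int = 1,
    target_subtype: str | None = None,
) -> NicheSelection:
    """Collect pixels within Chebyshev distance [1, r] of any target.

    Neighbors are pooled across targets, deduplicated (kept in the sample's
    pixel order) and the targets appended. Unknown target ids raise.
    """
    if r < 1:
        raise ValueError("neighborhood radius must be >= 1")
    target_ids = list(target_ids)
    index_of = {p: i for i, p in enumerate(sample.pixel_ids)}
    for t in target_ids:
        if t not in index_of:
            raise KeyError(f"target pixel {t!r} not present in sample {sample.sample_id!r}")
    if sample.n_pixels == 0 or not target_ids:
        return NicheSelection(
            target_ids=target_ids, radius=r, neighbor_ids=[],
            final_ids=list(target_ids), sample_id=sample.sample_id,
            target_subtype=target_subtype, stage=sample.stage,
        )
    tree = cKDTree(sample.coords)
    t_idx = np.array([index_of[t] for t in target_ids])
    hits = tree.query_ball_point(sample.coords[t_idx], r=r, p=np.inf)
    neighbor_set: set[int] = set()
    for ti, hit in zip(t_idx, hits):
        neighbor_set.update(h for h in hit if h != ti)  # vicinity excludes the center
    neighbor_ids = [sample.pixel_ids[i] for i in sorted(neighbor_set)]
    final = list(dict.fromkeys(neighbor_ids + target_ids))
    return NicheSelection(
        target_ids=target_ids,
        radius=r,
        neighbor_ids=neighbor_ids,
        final_ids=final,
        sample_id=sample.sample_id,
        target_subtype=target_subtype,
        stage=sample.stage,
    )


def niche_composition(
    selections: NicheSelection | list[NicheSelection],
    labels: CellLabelTable,
) -> NicheTable:
    """Cell-type composition of the neighbor pixels per (subtype, stage).

    Selections sharing a (target_subtype, stage) group — e.g. replicate
    sections of one stage — are pooled. Every tallied pixel must be
    labelled. Groups with zero neighbors are emitted with total 0 and
    NaN proportions, flagged ``undefined``.
    """
    if isinstance(selections, NicheSelection):
        selections = [selections]
    type_of = labels.df["cell_type"]
    groups: dict[tuple, list[str]] = {}
    for sel in selections:
        key = (sel.target_subtype, sel.stage)
        groups.setdefault(key, []).extend(sel.tally_ids())
    rows = []
    for (subtype, stage), ids in sorted(
        groups.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))
    ):
        unlabeled = [p for p in ids if p not in type_of.index]
        if unlabeled:
            raise KeyError(
                f"unlabelled pixels in niche tally (e.g. {unlabeled[:5]})"
            )
        total = len(ids)
        if total == 0:
            rows.append(
                {
                    "target_subtype": subtype, "stage": stage,
                    "cell_type": pd.NA, "count": 0, "total": 0,
                    "proportion": np.nan, "undefined": True,
                }
            )
            continue
        counts = pd.Series([type_of[p] for p in ids]).value_counts().sort_index()
        for cell_type, count in counts.items():
            rows.append(
                {
                    "target_subtype": subtype, "stage": stage,
                    "cell_type": cell_type, "count": int(count),
                    "total": total,
                    "proportion": count / total, "undefined": False,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["target_subtype", "stage", "cell_type", "count", "total",
                 "proportion", "undefined"],
    )
    return NicheTable(df=df)
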