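"""Boundary-referenced depth of pixels within a tissue section.

For each pixel i the statistic is depth_i = dist_i / D, where dist_i is the
minimum Euclidean distance from the pixel to a set of reference boundary
pixels (the outermost pixels of the section) and D is the section diameter,
operationalized as the maximum pairwise Euclidean distance among the tissue
pixels. Depth is translation invariant and unchanged under uniform scaling
of the coordinates; for convex sections the maximum attainable depth is
0.5 (up to grid discreteness).

The reference set can be supplied manually (mirroring hand-labelled
outermost pixels, e.g. to exclude a mesonephros-abutting edge) or extracted
automatically as the pixels with fewer than four 4-neighbors inside the
tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .annotate import CellLabelTable
from .stats import bh_adjust, ranksum, star_annotation

__all__ = [
    "DepthResult",
    "StageTestResult",
    "tissue_boundary",
    "section_diameter",
    "compute_depth",
    "depth_stage_test",
]

logger = logging.getLogger(__name__)


def tissue_boundary(coords) -> np.ndarray:
    """Boundary pixels of a coordinate set: fewer than four 4-neighbors inside.

    Returns the boundary coordinates in the input order.
    """
    coords = np.asarray(coords, dtype=int).reshape(-1, 2)
    if coords.shape[0] == 0:
        raise ValueError("empty coordinate set")
    inside = {tuple(c) for c in coords}
    out = []
    for x, y in coords:
        n4 = sum(
            (x + dx, y + dy) in inside
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))
        )
        if n4 < 4:
            out.append((x, y))
    return np.array(out, dtype=int).reshape(-1, 2)


def section_diameter(coords) -> float:
    """Maximum pairwise Euclidean distance among the pixels (the caliper
    diameter of the section); 0 for a single pixel."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty coordinate set")
    if n == 1:
        return 0.0
    if n > 2000:
        # the diameter is attained on the convex hull
        try:
            coords = coords[ConvexHull(coords).vertices]
        except QhullError:
            pass  # degenerate (collinear) sections: fall through to brute force
    return float(pdist(coords).max())


@dataclass
class DepthResult:
    """Per-pixel distances and normalized depths for one section.

    ``df`` columns: pixel_id, x, y, dist, depth, plus cell_type /
    germ_subtype / stage / sample_id when labels and metadata were supplied.
    """

    reference_set: np.ndarray
    D: float
    df: pd.DataFrame
    sample_id: str | None = None
    stage: str | None = None

    def summaries(self, by: str = "germ_subtype") -> pd.DataFrame:
        """n / mean / median depth per (``by``, stage) group."""
        cols = [c for c in (by, "stage") if c in self.df.columns]
        if not cols:
            raise ValueError(f"column {by!r} not attached to this result")
        grouped = self.df.dropna(subset=[by]).groupby(cols, observed=True)["depth"]
        out = grouped.agg(n="size", mean="mean", median="median").reset_index()
        return out

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def compute_depth(
    coords,
    reference_set,
    D: float,
    pixel_ids=None,
    labels: CellLabelTable | None = None,
    stage: str | None = None,
    sample_id: str | None = None,
) -> DepthResult:
    """Minimum distance to the reference set and normalized depth per pixel.

    The reference set need not be a subset of the section (a manually
    supplied list is used verbatim). ``D`` must be positive; pass the value
    from :func:`section_diameter` or a measured diameter.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    reference_set = np.asarray(reference_set, dtype=float).reshape(-1, 2)
    if reference_set.shape[0] == 0:
        raise ValueError("empty reference set")
    if D <= 0:
        raise ValueError(f"section diameter must be positive, got {D}")
    dist, _ = cKDTree(reference_set).query(coords)
    dist = np.asarray(dist, dtype=float)
    df = pd.DataFrame(
        {
            "pixel_id": pixel_ids if pixel_ids is not None
            else [f"{int(x)}x{int(y)}" for x, y in coords],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "dist": dist,
            "depth": dist / D,
        }
    )
    if labels is not None:
        lab = labels.df.reindex(df["pixel_id"])
        df["cell_type"] = lab["cell_type"].values
        df["germ_subtype"] = lab["germ_subtype"].values
    if stage is not None:
        df["stage"] = stage
    if sample_id is not None:
        df["sample_id"] = sample_id
    return DepthResult(
        reference_set=reference_set, D=float(D), df=df,
        sample_id=sample_id, stage=stage,
    )


@dataclass
class StageTestResult:
    """Consecutive-stage depth comparisons for one subtype.

    ``table`` has one row per consecutive stage pair with the rank-sum
    p-value, BH-adjusted p and star tier; ``monotone_decreasing`` reports
    whether the stage mean depths strictly decrease along the stage order
    (the cortical-migration signature).
    """

    subtype: str | None
    stage_order: tuple
    table: pd.DataFrame
    stage_means: pd.Series
    monotone_decreasing: bool

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def depth_stage_test(
    result: DepthResult | pd.DataFrame,
    subtype: str | None,
    stage_order,
    subtype_col: str = "germ_subtype",
    min_group: int = 3,
) -> StageTestResult:
    """Compare depth distributions between consecutive developmental stages.

    ``subtype`` selects rows whose ``subtype_col`` equals the label; pass
    ``None`` to pool every pixel with a non-null value in that column (all
    germ pixels when the column is germ_subtype). Two-sided rank-sum tests
    between consecutive stages, BH adjustment across the comparisons, star
    tiers, and a flag for strictly decreasing stage means.
    """
    df = result.df if isinstance(result, DepthResult) else result
    for col in (subtype_col, "stage", "depth"):
        if col not in df.columns:
            raise ValueError(f"depth table lacks a {col!r} column")
    if subtype is None:
        sel = df[df[subtype_col].notna()]
    else:
        sel = df[df[subtype_col] == subtype]
    stage_order = tuple(stage_order)
    groups = {s: sel.loc[sel["stage"] == s, "depth"].to_numpy() for s in stage_order}
    usable = [s for s in stage_order if groups[s].size >= min_group]
    for s in stage_order:
        if 0 < groups[s].size < min_group:
            logger.warning(
                "stage %s has %d pixels of %r (< %d); skipped",
                s, groups[s].size, subtype, min_group,
            )
    if len(usable) < 2:
        raise ValueError("need at least two stages with enough pixels")

    rows = []
    for a, b in zip(usable[:-1], usable[1:]):
        res = ranksum(groups[a], groups[b])
        rows.append(
            {
                "stage_a": a, "stage_b": b,
                "n_a": res.n1, "n_b": res.n2,
                "mean_a": float(groups[a].mean()),
                "mean_b": float(groups[b].mean()),
                "p": res.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["stars"] = [star_annotation(a) for a in table["adj_p"]]
    means = pd.Series({s: float(groups[s].mean()) for s in usable})
    monotone = bool(np.all(np.diff(means.to_numpy()) < 0))
    return StageTestResult(
        subtype=subtype,
        stage_order=stage_order,
        table=table,
        stage_means=means,
        monotone_decreasing=monotone,
    )
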