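"""Cell-type assignment, rule-based subtype reassignment, marker detection.

Pixels are typed by the argmax of per-type marker module scores (ties broken
lexicographically and flagged), optionally refined by a rule that reassigns
every pixel expressing a diagnostic gene above a threshold — the
code-level counterpart of reassigning SYCP3-expressing cells to the meiotic
germ subtype. Marker genes per cluster are found with one-vs-rest Wilcoxon
rank-sum tests under the conventional pre-filters (minimum in-cluster
expression fraction 10%, log2 fold change >= 0.5) and Benjamini-Hochberg
correction within each cluster's comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix
from .scoring import ModuleScore
from .stats import bh_adjust, ranksum

__all__ = [
    "CellLabelTable",
    "MarkerTable",
    "assign_cell_types",
    "reassign_by_marker",
    "find_markers",
    "top_markers",
]

logger = logging.getLogger(__name__)

#: the three fetal germ cell subtypes; membership drives the germ_subtype column
GERM_SUBTYPES = ("Mitotic_PGC", "RA_Oogonia", "Meiotic_Oogonia")

SOURCE_SCORE = "score_argmax"
SOURCE_RULE = "rule_reassigned"
SOURCE_TRUTH = "truth_injected"


@dataclass
class CellLabelTable:
    """Per-pixel cell-type and germ-subtype assignments with provenance.

    ``df`` is indexed by pixel_id with columns cell_type, germ_subtype
    (NaN for non-germ pixels), source, margin (top score minus runner-up),
    tie (bool).
    """

    df: pd.DataFrame
    germ_subtypes: tuple = GERM_SUBTYPES

    def __post_init__(self):
        required = {"cell_type", "germ_subtype", "source", "margin", "tie"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")

    @property
    def pixel_ids(self) -> list[str]:
        return list(self.df.index)

    def cell_type(self, pixel_id: str) -> str:
        return self.df.at[pixel_id, "cell_type"]

    def germ_pixels(self, subtype: str | None = None) -> list[str]:
        """Pixel ids carrying a germ subtype (optionally one subtype)."""
        sub = self.df["germ_subtype"].dropna()
        if subtype is not None:
            sub = sub[sub == subtype]
        return list(sub.index)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="pixel_id")

    @classmethod
    def from_truth(cls, truth_df: pd.DataFrame, germ_subtypes=GERM_SUBTYPES):
        """Build a label table from a ground-truth per-pixel table.

        Useful for exercising downstream stages independently of the
        annotation step.
        """
        germ = (
            truth_df["germ_subtype"].to_numpy()
            if "germ_subtype" in truth_df.columns else pd.NA
        )
        df = pd.DataFrame(
            {
                "cell_type": truth_df["cell_type"].to_numpy(),
                "germ_subtype": germ,
                "source": SOURCE_TRUTH,
                "margin": np.nan,
                "tie": False,
            },
            index=pd.Index(truth_df["pixel_id"].to_numpy(), name="pixel_id"),
        )
        return cls(df=df, germ_subtypes=tuple(germ_subtypes))


@dataclass
class MarkerTable:
    """Per (cluster, gene) marker statistics.

    Columns: cluster, gene, log2fc, frac_in, frac_out, p, adj_p,
    significant.
    """

    df: pd.DataFrame
    params: dict = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        return self.df[self.df["significant"]]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def assign_cell_types(
    scores: dict[str, ModuleScore] | list[ModuleScore],
    germ_subtypes=GERM_SUBTYPES,
) -> CellLabelTable:
    """Assign each pixel the cell type with the highest marker module score.

    Ties are broken by lexicographic type name and flagged; the margin
    (top minus runner-up score) is recorded. All candidate types must be
    scored on the same pixels.
    """
    if isinstance(scores, list):
        scores = {s.module_name: s for s in scores}
    if len(scores) < 2:
        raise ValueError("need at least two candidate cell types")
    names = sorted(scores)
    pixel_ids = scores[names[0]].pixel_ids
    for n in names[1:]:
        if scores[n].pixel_ids != pixel_ids:
            raise ValueError(
                f"type {n!r} scored on different pixels than {names[0]!r}"
            )
    mat = np.vstack([scores[n].scores for n in names])  # types x pixels
    order = np.argsort(-mat, axis=0, kind="stable")  # stable: ties keep lexicographic order
    best = order[0]
    second = order[1]
    top = mat[best, np.arange(mat.shape[1])]
    runner = mat[second, np.arange(mat.shape[1])]
    margin = top - runner
    tie = margin == 0
    cell_type = [names[i] for i in best]
    germ = [t if t in germ_subtypes else pd.NA for t in cell_type]
    df = pd.DataFrame(
        {
            "cell_type": cell_type,
            "germ_subtype": germ,
            "source": SOURCE_SCORE,
            "margin": margin,
            "tie": tie,
        },
        index=pd.Index(pixel_ids, name="pixel_id"),
    )
    return CellLabelTable(df=df, germ_subtypes=tuple(germ_subtypes))


def reassign_by_marker(
    labels: CellLabelTable,
    norm: NormalizedMatrix,
    gene: str,
    threshold: float,
    new_label: str,
) -> CellLabelTable:
    """Reassign every pixel expressing ``gene`` above ``threshold``.

    Pixels with normalized value strictly greater than the threshold get
    ``new_label`` with source ``rule_reassigned``; all others are untouched.
    Returns a new table.
    """
    values = norm.gene_values(gene)  # raises KeyError if absent
    value_of = dict(zip(norm.pixel_ids, values))
    df = labels.df.copy()
    hit = [pid for pid in df.index if value_of.get(pid, 0.0) > threshold]
    df.loc[hit, "cell_type"] = new_label
    df.loc[hit, "source"] = SOURCE_RULE
    df.loc[hit, "germ_subtype"] = (
        new_label if new_label in labels.germ_subtypes else pd.NA
    )
    logger.info(
        "reassign_by_marker: %d pixels with %s > %g relabelled %r",
        len(hit), gene, threshold, new_label,
    )
    return CellLabelTable(df=df, germ_subtypes=labels.germ_subtypes)


def find_markers(
    norm: NormalizedMatrix,
    labels: CellLabelTable,
    min_frac: float = 0.10,
    min_log2fc: float = 0.5,
    alpha: float = 0.05,
    min_cluster_size: int = 3,
    pseudo: float = 1e-9,
) -> MarkerTable:
    """One-vs-rest Wilcoxon marker detection with expression-fraction and
    fold-change pre-filters.

    For each cluster, genes with in-cluster expression fraction >=
    ``min_frac`` (share of pixels with nonzero expression) and log2 fold
    change >= ``min_log2fc`` are tested with a two-sided rank-sum test on
    the normalized values; BH adjustment treats the full gene universe as
    the family for each cluster's comparison (screened-out genes enter at
    p = 1), the convention of the standard marker-detection routines. Fold
    change is computed on expm1-backtransformed means:
    log2((mean expm1 in + pseudo) / (mean expm1 out + pseudo)). Only
    positive markers are reported. Clusters smaller than
    ``min_cluster_size`` are skipped with a warning.
    """
    order = {p: i for i, p in enumerate(norm.pixel_ids)}
    common = [p for p in labels.pixel_ids if p in order]
    if not common:
        raise ValueError("label table shares no pixels with the matrix")
    cluster_of = labels.df.loc[common, "cell_type"]
    clusters = sorted(cluster_of.unique())
    if len(clusters) < 2:
        raise ValueError("marker detection needs at least two clusters")

    expm1 = np.expm1(norm.values)
    nonzero = norm.values > 0
    rows = []
    for cluster in clusters:
        in_ids = [p for p in common if cluster_of[p] == cluster]
        out_ids = [p for p in common if cluster_of[p] != cluster]
        if len(in_ids) < min_cluster_size:
            logger.warning(
                "cluster %r has %d pixels (< %d); skipped",
                cluster, len(in_ids), min_cluster_size,
            )
            continue
        ii = np.array([order[p] for p in in_ids])
        oo = np.array([order[p] for p in out_ids])
        frac_in = nonzero[:, ii].mean(axis=1)
        frac_out = nonzero[:, oo].mean(axis=1)
        mean_in = expm1[:, ii].mean(axis=1)
        mean_out = expm1[:, oo].mean(axis=1)
        log2fc = np.log2((mean_in + pseudo) / (mean_out + pseudo))
        tested = np.flatnonzero((frac_in >= min_frac) & (log2fc >= min_log2fc))
        if tested.size == 0:
            continue
        pvals = np.array(
            [ranksum(norm.values[g, ii], norm.values[g, oo]).p_value for g in tested]
        )
        # BH family = the full gene universe of this cluster's comparison:
        # genes screened out by the pre-filters enter as p = 1, so the
        # correction is not conditioned on having survived the fold-change
        # screen (screen-then-correct-within-screen inflates the realized
        # false-discovery rate badly under label permutation)
        padded = np.concatenate([pvals, np.ones(norm.n_genes - tested.size)])
        adj = bh_adjust(padded)[: tested.size]
        for g, p, a in zip(tested, pvals, adj):
            rows.append(
                {
                    "cluster": cluster,
                    "gene": norm.gene_ids[g],
                    "log2fc": float(log2fc[g]),
                    "frac_in": float(frac_in[g]),
                    "frac_out": float(frac_out[g]),
                    "p": float(p),
                    "adj_p": float(a),
                    "significant": bool(a < alpha),
                }
            )
    columns = ["cluster", "gene", "log2fc", "frac_in", "frac_out", "p",
               "adj_p", "significant"]
    df = pd.DataFrame(rows, columns=columns)
    return MarkerTable(
        df=df,
        params={"min_frac": min_frac, "min_log2fc": min_log2fc, "alpha": alpha},
    )


def top_markers(table: MarkerTable, k: int = 5) -> MarkerTable:
    """Per cluster, the k significant markers with largest fold change.

    Ties are broken by gene symbol; clusters with fewer than k significant
    markers return all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = table.significant()
    if sig.empty:
        return MarkerTable(df=sig.copy(), params=dict(table.params, k=k))
    out = (
        sig.sort_values(["cluster", "log2fc", "gene"],
                        ascending=[True, False, True])
        .groupby("cluster", sort=True, group_keys=False)
        .head(k)
        .reset_index(drop=True)
    )
    return MarkerTable(df=out, params=dict(table.params, k=k))
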