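"""Pixel QC and normalization preceding all scoring.

QC removes low-quality pixels by total transcript count. Normalization is
log library-size scaling: value(g, p) = log(1 + count * scale_factor /
total(p)), a deterministic stand-in for variance-stabilizing regressions
that all downstream rank-based and difference-of-means statistics tolerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gridio import SpatialSample

__all__ = ["NormalizedMatrix", "qc_filter", "normalize"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL_COUNTS = 100
DEFAULT_SCALE_FACTOR = 10_000.0


@dataclass
class NormalizedMatrix:
    """Log-normalized gene-by-pixel expression.

    ``values`` is dense genes x pixels on the natural-log scale; zeros in
    the counts stay exactly zero here.
    """

    values: np.ndarray
    gene_ids: list[str]
    pixel_ids: list[str]
    scale_factor: float
    source: SpatialSample | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.pixel_ids)):
            raise ValueError("values shape does not match gene/pixel lists")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        """Per-pixel normalized values of one gene."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.pixel_ids)


def qc_filter(
    sample: SpatialSample, min_total_counts: int = DEFAULT_MIN_TOTAL_COUNTS
) -> SpatialSample:
    """Retain exactly the pixels whose total count meets the threshold.

    Order is preserved; the retained/removed split is logged. An empty
    result is legal and produces a warning. Idempotent.
    """
    if min_total_counts < 0:
        raise ValueError("min_total_counts must be >= 0")
    totals = sample.total_counts()
    keep = np.flatnonzero(totals >= min_total_counts)
    n_removed = sample.n_pixels - keep.size
    logger.info(
        "qc_filter(%s): retained %d / %d pixels (threshold %d)",
        sample.sample_id, keep.size, sample.n_pixels, min_total_counts,
    )
    if keep.size == 0 and sample.n_pixels > 0:
        logger.warning(
            "qc_filter(%s): no pixels pass total-count threshold %d",
            sample.sample_id, min_total_counts,
        )
    if n_removed == 0:
        return sample
    return sample.subset_pixels(keep)


def qc_report(sample: SpatialSample, filtered: SpatialSample, path=None) -> pd.DataFrame:
    """One-row QC summary (pixels before/after, count quantiles); optional TSV."""
    totals = sample.total_counts()
    row = {
        "sample_id": sample.sample_id,
        "stage": sample.stage,
        "pixels_in": sample.n_pixels,
        "pixels_retained": filtered.n_pixels,
        "pixels_removed": sample.n_pixels - filtered.n_pixels,
        "median_total": float(np.median(totals)) if totals.size else float("nan"),
        "min_total": int(totals.min()) if totals.size else 0,
        "max_total": int(totals.max()) if totals.size else 0,
    }
    df = pd.DataFrame([row])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def normalize(
    sample: SpatialSample, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """Log library-size normalization.

    value(g, p) = log(1 + count(g, p) * scale_factor / total(p)). Invariant
    to rescaling any pixel's counts by a positive factor.

    Raises
    ------
    ValueError
        If any pixel has zero total counts (run :func:`qc_filter` first).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = sample.total_counts()
    if np.any(totals == 0):
        bad = [sample.pixel_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(
            f"pixels with zero total counts (e.g. {bad}); apply qc_filter "
            "with min_total_counts >= 1 before normalizing"
        )
    dense = sample.counts.toarray().astype(float)
    values = np.log1p(dense * (scale_factor / totals)[None, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=list(sample.gene_ids),
        pixel_ids=list(sample.pixel_ids),
        scale_factor=scale_factor,
        source=sample,
    )
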