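"""Reading and writing pixel-grid spatial samples.

A section arrives as a sparse gene-by-pixel count matrix whose pixel (column)
labels encode the grid coordinates. The label dialect is ``"<x>x<y>"`` with
non-negative base-10 integers: ``x`` is the column index, ``y`` the row
index, origin top-left, 0-based. ``y`` is rendered downward in figures, the
usual orientation for section images. Distances downstream are in pixel
units; the physical pixel pitch (10 um for the high-definition grids this
targets) is carried as metadata for axis annotation only — the depth
statistic is scale-free.

The on-disk layout is Matrix Market (coordinate, 1-based) + ``genes.tsv``
(one symbol per line) + ``pixels.tsv`` (one pixel label per line).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialSample",
    "parse_pixel_coordinates",
    "format_pixel_label",
    "load_counts",
    "write_tidy",
]

_LABEL_RE = re.compile(r"^(\d+)x(\d+)$")


class PixelLabelError(ValueError):
    """A pixel label does not follow the ``"<x>x<y>"`` dialect."""


def parse_pixel_coordinates(label: str) -> tuple[int, int]:
    """Decode a pixel label ``"<x>x<y>"`` into integer grid coordinates.

    >>> parse_pixel_coordinates("12x34")
    (12, 34)
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise PixelLabelError(
            f"malformed pixel label {label!r}: expected '<x>x<y>' with "
            "non-negative base-10 integers"
        )
    return int(m.group(1)), int(m.group(2))


def format_pixel_label(x: int, y: int) -> str:
    """Inverse of :func:`parse_pixel_coordinates`."""
    if x < 0 or y < 0:
        raise PixelLabelError(f"coordinates must be non-negative, got ({x}, {y})")
    return f"{x}x{y}"


@dataclass
class SpatialSample:
    """One tissue section on a pixel grid.

    Attributes
    ----------
    pixel_ids : list of str
        Ordered pixel labels, unique within the sample.
    coords : (n_pixels, 2) int array
        Grid coordinates (x, y) per pixel, unique within the sample.
    counts : sparse matrix, genes x pixels
        Non-negative integer UMI counts.
    gene_ids : list of str
        Gene symbols, one per matrix row.
    sample_id : str
        Per-section identifier (one section per sample).
    stage : str
        Developmental stage label, e.g. one of E24/E27/E30/E35/E50.
    pixel_pitch : float
        Physical pixel spacing in micrometres; annotation metadata only.
    """

    pixel_ids: list[str]
    coords: np.ndarray
    counts: sp.spmatrix
    gene_ids: list[str]
    sample_id: str
    stage: str
    pixel_pitch: float = 10.0
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        self.counts = sp.csr_matrix(self.counts)
        if len(self.pixel_ids) != len(set(self.pixel_ids)):
            raise ValueError(f"duplicate pixel labels in sample {self.sample_id!r}")
        if self.coords.shape != (len(self.pixel_ids), 2):
            raise ValueError("coords must be (n_pixels, 2)")
        seen = {tuple(c) for c in self.coords}
        if len(seen) != len(self.pixel_ids):
            raise ValueError(f"duplicate pixel coordinates in sample {self.sample_id!r}")
        if self.counts.shape != (len(self.gene_ids), len(self.pixel_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.pixel_ids)} pixels"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(data.dtype, np.integer) and not np.allclose(
                data, np.round(data)
            ):
                raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self._validated = True

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def total_counts(self) -> np.ndarray:
        """Per-pixel library size (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_pixels(self, index: np.ndarray) -> "SpatialSample":
        """New sample restricted to the given pixel positions, order preserved."""
        index = np.asarray(index)
        return SpatialSample(
            pixel_ids=[self.pixel_ids[i] for i in index],
            coords=self.coords[index],
            counts=self.counts[:, index],
            gene_ids=list(self.gene_ids),
            sample_id=self.sample_id,
            stage=self.stage,
            pixel_pitch=self.pixel_pitch,
        )


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def load_counts(
    matrix_path,
    genes_path,
    pixels_path,
    sample_id: str,
    stage: str,
    pixel_pitch: float = 10.0,
) -> SpatialSample:
    """Load a gene-by-pixel sample from Matrix Market + sidecar lists.

    Grid coordinates are extracted from the pixel labels (``"<x>x<y>"``
    dialect). Duplicate pixel labels and non-integral counts are rejected.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = _read_lines(genes_path)
    pixels = _read_lines(pixels_path)
    if mat.shape != (len(genes), len(pixels)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes "
            f"x {len(pixels)} pixels"
        )
    if len(pixels) != len(set(pixels)):
        dupes = sorted({p for p in pixels if pixels.count(p) > 1})
        raise ValueError(f"duplicate pixel labels in {pixels_path}: {dupes[:5]}")
    data = np.asarray(mat.data if sp.issparse(mat) else mat)
    if data.size and not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"non-integer counts in {matrix_path}")
    coords = np.array([parse_pixel_coordinates(p) for p in pixels], dtype=int)
    if len(pixels) == 0:
        coords = coords.reshape(0, 2)
    return SpatialSample(
        pixel_ids=pixels,
        coords=coords,
        counts=sp.csr_matrix(mat, dtype=np.int64),
        gene_ids=genes,
        sample_id=sample_id,
        stage=stage,
        pixel_pitch=pixel_pitch,
    )


def write_tidy(sample: SpatialSample, path) -> pd.DataFrame:
    """Write the tidy per-pixel table (id, coordinates, library size) as TSV."""
    df = pd.DataFrame(
        {
            "pixel_id": sample.pixel_ids,
            "x": sample.coords[:, 0],
            "y": sample.coords[:, 1],
            "total_counts": sample.total_counts(),
            "stage": sample.stage,
            "sample_id": sample.sample_id,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
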