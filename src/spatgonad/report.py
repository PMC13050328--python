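"""Spatial rendering and run manifests.

Figures are byproducts: everything quantitative is asserted on TSV/JSON
outputs, never on rendered pixels. Maps follow section-image conventions:
equal aspect, y axis increasing downward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .gridio import SpatialSample  # noqa: E402

__all__ = ["RunManifest", "spatial_map", "write_manifest", "file_sha256"]

logger = logging.getLogger(__name__)

UNASSIGNED_COLOR = "#bdbdbd"


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run.

    The config echo plus seeds suffice to reproduce the run; every output
    file is listed. Stage timings are emitted to the run log rather than
    stored here so that manifests are byte-identical across reruns.
    """

    config: dict
    seeds: dict
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    figure_info: dict = field(default_factory=dict)
    version: str = ""

    def add_output(self, path) -> None:
        name = str(path)
        if name not in self.outputs:
            self.outputs.append(name)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "input_hashes": self.input_hashes,
            "outputs": sorted(self.outputs),
            "figure_info": self.figure_info,
            "version": self.version,
        }


def write_manifest(manifest: RunManifest, path) -> Path:
    """Write the manifest JSON atomically (write-to-temp then rename)."""
    path = Path(path)
    payload = json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".manifest-", suffix=".json")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def spatial_map(
    sample: SpatialSample,
    values: dict | pd.Series,
    path,
    palette: dict | str | None = None,
    title: str | None = None,
    point_size: float = 6.0,
) -> dict:
    """Scatter the pixels at their grid coordinates, coloured by value.

    ``values`` maps pixel_id to either a categorical label (legend) or a
    number (colorbar with bounds at the data min/max). Pixels missing from
    ``values`` are drawn in a neutral colour and counted with a warning.
    Returns a small info dict (legend entries or colorbar bounds) for the
    manifest.
    """
    if isinstance(values, dict):
        values = pd.Series(values)
    vals = values.reindex(sample.pixel_ids)
    missing = int(vals.isna().sum())
    if missing:
        logger.warning("spatial_map: %d pixels without a value drawn as unassigned", missing)
    x, y = sample.coords[:, 0], sample.coords[:, 1]
    fig, ax = plt.subplots(figsize=(6, 6))
    info: dict = {"n_unassigned": missing}
    numeric = pd.api.types.is_numeric_dtype(vals.dropna())
    if numeric and not vals.dropna().empty:
        known = vals.notna().to_numpy()
        sc = ax.scatter(
            x[known], y[known], c=vals[known].astype(float), s=point_size,
            cmap=palette if isinstance(palette, str) else "viridis",
            marker="s", linewidths=0,
        )
        cbar = fig.colorbar(sc, ax=ax, shrink=0.8)
        vmin = float(vals.dropna().min())
        vmax = float(vals.dropna().max())
        sc.set_clim(vmin, vmax)
        info["colorbar"] = [vmin, vmax]
        if missing:
            ax.scatter(x[~known], y[~known], color=UNASSIGNED_COLOR,
                       s=point_size, marker="s", linewidths=0)
        del cbar
    else:
        labels = sorted(vals.dropna().unique())
        cmap = plt.get_cmap("tab20")
        for i, lab in enumerate(labels):
            mask = (vals == lab).to_numpy()
            color = (palette or {}).get(lab) if isinstance(palette, dict) else None
            ax.scatter(x[mask], y[mask], s=point_size, marker="s", linewidths=0,
                       color=color or cmap(i % 20), label=str(lab))
        if missing:
            ax.scatter(x[vals.isna().to_numpy()], y[vals.isna().to_numpy()],
                       s=point_size, marker="s", linewidths=0,
                       color=UNASSIGNED_COLOR, label="unassigned")
        ax.legend(markerscale=2, fontsize=7, loc="center left",
                  bbox_to_anchor=(1.01, 0.5))
        info["legend_entries"] = [str(lab) for lab in labels] + (
            ["unassigned"] if missing else []
        )
    ax.set_aspect("equal")
    ax.invert_yaxis()  # section images: y grows downward
    ax.set_xlabel(f"x (pixel, {sample.pixel_pitch:g} um pitch)")
    ax.set_ylabel("y (pixel)")
    ax.set_title(title or sample.sample_id)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return info
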