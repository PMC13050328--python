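"""Synthetic stratified-gonad sections with known ground truth.

The generator emulates the organization of a fetal ovary section on a
10 um pixel grid: an elliptical tissue mask, concentric zones laid out by
normalized distance to the tissue boundary (outer cortex dominated by
surface-epithelium cells, inner cortex by second-wave pregranulosa, medulla
by first-wave pregranulosa with interstitial and endothelial cells), a
lateral mesenchymal strip standing in for the gonad-mesonephros interface,
and three germ-cell subtypes whose radial position shifts cortically across
five developmental stages. Counts are negative-binomial with per-gene
baseline means, multiplicative marker enrichment per cell type, and
zone-restricted pathway modules (BMP- and retinoic-acid-like).

Germ pixels are placed by weighted sampling plus deterministic swap
refinement so that their realized mean normalized depth matches the
per-stage target to within +/-0.02 — the migration recovery experiments
therefore have exact ground truth by construction. Zone geometry reuses the
same boundary / diameter / depth definitions as the estimator module, so
generator and estimator share one geometry.

Identical (blueprint, stage, seed) triples yield byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import depth as _depth
from .gridio import SpatialSample, format_pixel_label, load_counts

__all__ = [
    "ZoneSpec",
    "GonadBlueprint",
    "GroundTruth",
    "default_blueprint",
    "simulate_section",
    "write_fixture",
    "load_fixture",
]

STAGES = ("E24", "E27", "E30", "E35", "E50")
GERM_SUBTYPES = ("Mitotic_PGC", "RA_Oogonia", "Meiotic_Oogonia")

#: realized germ mean depth must land within this of the per-stage target
GERM_DEPTH_TOL = 0.02
_INNER_TOL = 0.01  # the sampler aims tighter than the guarantee


@dataclass(frozen=True)
class ZoneSpec:
    """One concentric zone: cell-type mixture over a relative-depth band.

    ``band`` is [lo, hi) on depth / max-depth, i.e. fractions of the tissue
    radius measured inward from the boundary (the last zone's band is
    closed at 1).
    """

    name: str
    mixture: dict[str, float]
    band: tuple[float, float]


@dataclass(frozen=True)
class GonadBlueprint:
    """Everything needed to simulate a stratified-gonad section.

    ``germ_depth_mean`` gives the per-stage target mean normalized depth of
    the germ pixels; with the migration scenario enabled it must strictly
    decrease along ``stage_order`` (cortical migration). ``germ_counts``
    maps stage -> subtype -> pixel count. Negative-binomial counts use
    mean ``nb_mean`` x per-gene baseline x marker / module folds, with
    dispersion ``nb_dispersion`` (variance = mu + mu^2 / dispersion).
    """

    grid_width: int = 150
    grid_height: int = 150
    pixel_pitch: float = 10.0
    stage_order: tuple = STAGES
    zone_spec: tuple = (
        ZoneSpec("outer_cortex",
                 {"OSEC": 0.70, "PreGC_II": 0.15, "Interstitial": 0.10,
                  "Endothelial": 0.05},
                 (0.0, 0.22)),
        ZoneSpec("inner_cortex",
                 {"PreGC_II": 0.60, "OSEC": 0.10, "Interstitial": 0.20,
                  "Endothelial": 0.10},
                 (0.22, 0.50)),
        ZoneSpec("medulla",
                 {"PreGC_I": 0.55, "Interstitial": 0.30, "Endothelial": 0.15},
                 (0.50, 1.0)),
    )
    interface_zone: ZoneSpec = ZoneSpec(
        "interface", {"Mesenchymal": 0.80, "Interstitial": 0.20}, (0.0, 1.0)
    )
    interface_width_frac: float = 0.10
    germ_depth_mean: dict = field(
        default_factory=lambda: {
            "E24": 0.45, "E27": 0.35, "E30": 0.25, "E35": 0.18, "E50": 0.10,
        }
    )
    germ_counts: dict = field(
        default_factory=lambda: {
            "E24": {"Mitotic_PGC": 300},
            "E27": {"Mitotic_PGC": 260, "RA_Oogonia": 40},
            "E30": {"Mitotic_PGC": 140, "RA_Oogonia": 160},
            "E35": {"Mitotic_PGC": 40, "RA_Oogonia": 200, "Meiotic_Oogonia": 60},
            "E50": {"RA_Oogonia": 150, "Meiotic_Oogonia": 150},
        }
    )
    marker_panel: dict = field(
        default_factory=lambda: {
            "OSEC": ["LHX9", "KRT19", "UPK3B", "KRT8",
                     "KRT18", "CDH1", "EPCAM", "MSLN"],
            "PreGC_I": ["WNT6", "FOXL2", "IRX3", "GNG13",
                        "FST", "ESR2", "SERPINE2", "GATM"],
            "PreGC_II": ["TOX3", "MAN1A1", "KITLG", "HMGCS2",
                         "WNT4", "RSPO1", "OSR1", "LGR5"],
            "Interstitial": ["NR2F1", "PDGFRA", "TCF21", "ARX",
                             "MAF", "COL3A1", "GLI1", "PTCH1"],
            "Endothelial": ["PECAM1", "COL15A1", "CDH5", "KDR",
                            "CLDN5", "FLT1", "EGFL7", "SOX18"],
            "Mesenchymal": ["COL1A1", "DCN", "LUM", "POSTN",
                            "COL5A1", "FBN1", "VIM", "TWIST1"],
            "Mitotic_PGC": ["POU5F1", "PRDM1", "TFAP2C", "NANOG",
                            "LIN28A", "SALL4", "DPPA3", "KIT"],
            "RA_Oogonia": ["DAZL", "DDX4", "ZGLP1", "STRA8",
                           "MAEL", "PIWIL2", "RARB", "TDRD5"],
            "Meiotic_Oogonia": ["SYCP3", "SYCP1", "SPO11", "REC8",
                                "DMC1", "HORMAD1", "PRDM9", "MEIOB"],
        }
    )
    marker_fold: float = 10.0
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    module_spec: dict = field(
        default_factory=lambda: {
            "BMP": (["BMP2", "BMP4", "ID1", "ID2", "ID3", "SMAD6"],
                    ("outer_cortex", "inner_cortex"), 3.0),
            "RA": (["ALDH1A1", "RDH10", "CRABP1", "CRABP2", "CYP26B1"],
                   ("inner_cortex",), 3.0),
        }
    )
    n_background_genes: int = 150
    migration_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.grid_width < 3 or self.grid_height < 3:
            raise ValueError("grid dimensions must be >= 3")
        bands = sorted(z.band for z in self.zone_spec)
        if bands[0][0] != 0.0 or bands[-1][1] != 1.0:
            raise ValueError("radial bands must cover [0, 1]")
        for (lo1, hi1), (lo2, _) in zip(bands[:-1], bands[1:]):
            if not np.isclose(hi1, lo2):
                raise ValueError("radial bands must be disjoint and contiguous")
        for z in self.zone_spec + (self.interface_zone,):
            if not np.isclose(sum(z.mixture.values()), 1.0):
                raise ValueError(f"zone {z.name!r} mixture must sum to 1")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        for name, (_, _, fold) in self.module_spec.items():
            if fold < 1:
                raise ValueError(f"module {name!r} fold must be >= 1")
        if self.migration_enabled:
            means = [self.germ_depth_mean[s] for s in self.stage_order
                     if s in self.germ_depth_mean]
            if any(b >= a for a, b in zip(means[:-1], means[1:])):
                raise ValueError(
                    "germ_depth_mean must strictly decrease across stages "
                    "when the migration scenario is enabled"
                )
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")

    def gene_ids(self) -> list[str]:
        genes: list[str] = []
        for panel in self.marker_panel.values():
            genes.extend(panel)
        for gene_list, _, _ in self.module_spec.values():
            genes.extend(gene_list)
        genes.extend(f"BG{i:04d}" for i in range(self.n_background_genes))
        return list(dict.fromkeys(genes))

    def gene_base_means(self) -> np.ndarray:
        """Per-gene lognormal baseline factors, fixed by the blueprint seed
        so the same gene keeps its baseline across stages and sections."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 9001]))
        return rng.lognormal(mean=0.0, sigma=0.7, size=len(self.gene_ids()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_spec"] = [dataclasses.asdict(z) for z in self.zone_spec]
        d["interface_zone"] = dataclasses.asdict(self.interface_zone)
        return d


def default_blueprint(seed: int = 0, **overrides) -> GonadBlueprint:
    """The standard study conditions; override any field by keyword."""
    return dataclasses.replace(GonadBlueprint(seed=seed), **overrides) \
        if overrides else GonadBlueprint(seed=seed)


@dataclass
class GroundTruth:
    """Realized per-pixel truth and derived truth summaries for one section."""

    pixels: pd.DataFrame          # pixel_id, x, y, zone, cell_type, germ_subtype, dist, depth, rel_depth
    niche: pd.DataFrame           # target_subtype, stage, cell_type, count, total, proportion
    germ_depth: pd.DataFrame      # subtype, stage, n, mean
    stage: str

    def germ_mean_depth(self, subtype: str | None = None) -> float:
        if subtype is None:
            sel = self.pixels[self.pixels["germ_subtype"].notna()]
        else:
            sel = self.pixels[self.pixels["germ_subtype"] == subtype]
        return float(sel["depth"].mean())


def _ellipse_mask_coords(width: int, height: int) -> np.ndarray:
    """Grid centers inside the axis-aligned ellipse inscribed in the grid."""
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    a, b = max(cx, 0.5), max(cy, 0.5)
    xs, ys = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
    inside = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
    return np.column_stack([xs[inside], ys[inside]]).astype(int)


def _place_germ(
    depths: np.ndarray, n: int, target: float, rng: np.random.Generator,
    stage: str,
) -> np.ndarray:
    """Indices of n pixels whose mean depth is within the tolerance of target.

    Weighted draw around the target followed by deterministic greedy swaps.
    """
    m = depths.size
    if n > m:
        raise ValueError(
            f"stage {stage}: {n} germ pixels requested but only {m} tissue "
            f"pixels available in the target depth band around {target:.2f}"
        )
    order = np.sort(depths)
    lo_mean = order[:n].mean()
    hi_mean = order[-n:].mean()
    if not (lo_mean - _INNER_TOL <= target <= hi_mean + _INNER_TOL):
        raise ValueError(
            f"stage {stage}: target germ mean depth {target:.3f} is outside "
            f"the attainable band [{lo_mean:.3f}, {hi_mean:.3f}] for "
            f"{n} pixels on this section"
        )
    w = np.exp(-0.5 * ((depths - target) / 0.04) ** 2) + 1e-12
    chosen = rng.choice(m, size=n, replace=False, p=w / w.sum())
    selected = np.zeros(m, dtype=bool)
    selected[chosen] = True
    mean = depths[selected].mean()
    for _ in range(5 * n):
        if abs(mean - target) <= _INNER_TOL:
            break
        need = (target - mean) * n  # total depth change required
        sel_idx = np.flatnonzero(selected)
        uns_idx = np.flatnonzero(~selected)
        if uns_idx.size == 0:
            break
        # drop the selected pixel most opposed to the needed direction and
        # bring in the unselected pixel that best supplies the change
        i = sel_idx[np.argmax(depths[sel_idx])] if need < 0 else \
            sel_idx[np.argmin(depths[sel_idx])]
        ideal = depths[i] + need
        j = uns_idx[np.argmin(np.abs(depths[uns_idx] - ideal))]
        new_mean = mean + (depths[j] - depths[i]) / n
        if abs(new_mean - target) >= abs(mean - target):
            break  # no improving swap left
        selected[i] = False
        selected[j] = True
        mean = new_mean
    if abs(mean - target) > GERM_DEPTH_TOL:
        raise ValueError(
            f"stage {stage}: germ placement converged to mean depth "
            f"{mean:.3f}, outside +/-{GERM_DEPTH_TOL} of target {target:.3f}"
        )
    return np.flatnonzero(selected)


def _truth_niche(
    coords: np.ndarray, cell_type: np.ndarray, germ_subtype: np.ndarray,
    stage: str,
) -> pd.DataFrame:
    """Adjacency-proportion truth by brute-force 8-neighborhood scan.

    Independent of the estimator: direct offset lookups, no trees.
    """
    pos = {tuple(c): i for i, c in enumerate(coords)}
    rows = []
    for subtype in GERM_SUBTYPES:
        targets = np.flatnonzero(germ_subtype == subtype)
        if targets.size == 0:
            continue
        target_set = set(targets.tolist())
        neighbor_set: set[int] = set()
        for t in targets:
            x, y = coords[t]
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    if dx == 0 and dy == 0:
                        continue
                    j = pos.get((x + dx, y + dy))
                    if j is not None and j not in target_set:
                        neighbor_set.add(j)
        total = len(neighbor_set)
        counts: dict[str, int] = {}
        for j in neighbor_set:
            counts[cell_type[j]] = counts.get(cell_type[j], 0) + 1
        for ct in sorted(counts):
            rows.append(
                {
                    "target_subtype": subtype, "stage": stage, "cell_type": ct,
                    "count": counts[ct], "total": total,
                    "proportion": counts[ct] / total,
                }
            )
    return pd.DataFrame(
        rows, columns=["target_subtype", "stage", "cell_type", "count",
                       "total", "proportion"],
    )


def simulate_section(
    blueprint: GonadBlueprint, stage: str, seed: int = 0
) -> tuple[SpatialSample, GroundTruth]:
    """Simulate one section at the given developmental stage.

    Returns the count sample plus the realized ground truth (per-pixel
    zone / type / subtype, adjacency-proportion truth, germ depth truth).
    """
    if stage not in blueprint.stage_order:
        raise ValueError(f"unknown stage {stage!r}; expected one of {blueprint.stage_order}")
    stage_idx = blueprint.stage_order.index(stage)
    rng = np.random.default_rng(
        np.random.SeedSequence([blueprint.seed, stage_idx, seed])
    )

    coords = _ellipse_mask_coords(blueprint.grid_width, blueprint.grid_height)
    n_pix = coords.shape[0]
    boundary = _depth.tissue_boundary(coords)
    D = _depth.section_diameter(coords)
    dres = _depth.compute_depth(coords, boundary, D)
    dist = dres.df["dist"].to_numpy()
    depths = dres.df["depth"].to_numpy()
    rel = depths / depths.max() if depths.max() > 0 else depths

    # zones: radial band on relative depth, overridden by the lateral
    # mesenchymal interface strip
    zone = np.empty(n_pix, dtype=object)
    for z in blueprint.zone_spec:
        lo, hi = z.band
        in_band = (rel >= lo) & ((rel < hi) | (hi >= 1.0) & (rel <= 1.0))
        zone[in_band] = z.name
    if blueprint.interface_width_frac > 0:
        x = coords[:, 0]
        cut = x.min() + blueprint.interface_width_frac * (x.max() - x.min())
        zone[x <= cut] = blueprint.interface_zone.name

    # somatic cell types from the zone mixtures
    cell_type = np.empty(n_pix, dtype=object)
    zones_by_name = {z.name: z for z in blueprint.zone_spec}
    zones_by_name[blueprint.interface_zone.name] = blueprint.interface_zone
    for name, z in zones_by_name.items():
        idx = np.flatnonzero(zone == name)
        if idx.size == 0:
            continue
        types = sorted(z.mixture)
        probs = np.array([z.mixture[t] for t in types])
        cell_type[idx] = rng.choice(types, size=idx.size, p=probs / probs.sum())

    # germ placement to the per-stage depth target
    germ_subtype = np.full(n_pix, None, dtype=object)
    stage_counts = blueprint.germ_counts.get(stage, {})
    n_germ = sum(stage_counts.values())
    if n_germ:
        target = blueprint.germ_depth_mean[stage]
        germ_idx = _place_germ(depths, n_germ, target, rng, stage)
        germ_idx = rng.permutation(germ_idx)
        offset = 0
        for subtype in GERM_SUBTYPES:
            k = stage_counts.get(subtype, 0)
            take = germ_idx[offset:offset + k]
            offset += k
            cell_type[take] = subtype
            germ_subtype[take] = subtype

    # negative-binomial counts: mean = nb_mean x gene baseline x folds
    genes = blueprint.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    base = blueprint.nb_mean * blueprint.gene_base_means()
    mu = np.tile(base[:, None], (1, n_pix))
    for ct, panel in blueprint.marker_panel.items():
        cols = np.flatnonzero(cell_type == ct)
        if cols.size == 0:
            continue
        rows = [gene_index[g] for g in panel if g in gene_index]
        mu[np.ix_(rows, cols)] *= blueprint.marker_fold
    for _name, (gene_list, active_zones, fold) in blueprint.module_spec.items():
        cols = np.flatnonzero(np.isin(zone, list(active_zones)))
        if cols.size == 0:
            continue
        rows = [gene_index[g] for g in gene_list if g in gene_index]
        mu[np.ix_(rows, cols)] *= fold
    theta = blueprint.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    pixel_ids = [format_pixel_label(x, y) for x, y in coords]
    sample = SpatialSample(
        pixel_ids=pixel_ids,
        coords=coords,
        counts=sp.csr_matrix(counts),
        gene_ids=genes,
        sample_id=f"{stage}_sim{seed}",
        stage=stage,
        pixel_pitch=blueprint.pixel_pitch,
    )
    pixels = pd.DataFrame(
        {
            "pixel_id": pixel_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "zone": zone,
            "cell_type": cell_type,
            "germ_subtype": germ_subtype,
            "dist": dist,
            "depth": depths,
            "rel_depth": rel,
        }
    )
    germ_rows = []
    for subtype in GERM_SUBTYPES:
        sel = pixels[pixels["germ_subtype"] == subtype]
        if len(sel):
            germ_rows.append(
                {"subtype": subtype, "stage": stage, "n": len(sel),
                 "mean": float(sel["depth"].mean())}
            )
    truth = GroundTruth(
        pixels=pixels,
        niche=_truth_niche(coords, cell_type, germ_subtype, stage),
        germ_depth=pd.DataFrame(
            germ_rows, columns=["subtype", "stage", "n", "mean"]
        ),
        stage=stage,
    )
    return sample, truth


def write_fixture(
    sample: SpatialSample,
    truth: GroundTruth | None,
    directory,
    blueprint: GonadBlueprint | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a sample (and optionally its truth) as a plain-text fixture.

    Layout: ``matrix.mtx`` (Matrix Market coordinate, 1-based),
    ``genes.tsv``, ``pixels.tsv`` (one ``<x>x<y>`` label per line),
    ``truth_pixels.tsv`` / ``truth_niche.tsv`` / ``truth_depth.tsv``, and a
    ``config.json`` echo. Round-trips losslessly through
    :func:`spatgonad.gridio.load_counts`.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{directory} is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(sample.counts))
    (directory / "genes.tsv").write_text(
        "".join(g + "\n" for g in sample.gene_ids)
    )
    (directory / "pixels.tsv").write_text(
        "".join(p + "\n" for p in sample.pixel_ids)
    )
    if truth is not None:
        truth.pixels.to_csv(directory / "truth_pixels.tsv", sep="\t", index=False)
        truth.niche.to_csv(directory / "truth_niche.tsv", sep="\t", index=False)
        truth.germ_depth.to_csv(directory / "truth_depth.tsv", sep="\t", index=False)
    config = {
        "sample_id": sample.sample_id,
        "stage": sample.stage,
        "pixel_pitch": sample.pixel_pitch,
        "blueprint": blueprint.to_dict() if blueprint is not None else None,
    }
    (directory / "config.json").write_text(
        json.dumps(config, indent=2, sort_keys=True) + "\n"
    )
    return directory


def load_fixture(directory) -> tuple[SpatialSample, GroundTruth | None]:
    """Load a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    config = json.loads((directory / "config.json").read_text())
    sample = load_counts(
        directory / "matrix.mtx",
        directory / "genes.tsv",
        directory / "pixels.tsv",
        sample_id=config["sample_id"],
        stage=config["stage"],
        pixel_pitch=config.get("pixel_pitch", 10.0),
    )
    truth = None
    truth_path = directory / "truth_pixels.tsv"
    if truth_path.exists():
        pixels = pd.read_csv(truth_path, sep="\t")
        niche = pd.read_csv(directory / "truth_niche.tsv", sep="\t")
        germ_depth = pd.read_csv(directory / "truth_depth.tsv", sep="\t")
        truth = GroundTruth(
            pixels=pixels, niche=niche, germ_depth=germ_depth,
            stage=config["stage"],
        )
    return sample, truth
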