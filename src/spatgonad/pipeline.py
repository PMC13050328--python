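"""End-to-end orchestration: simulate -> QC -> normalize -> score ->
annotate -> markers -> depth -> niche -> report.

The pipeline is deterministic for a fixed (config, seed): rerunning into a
fresh directory reproduces every TSV/JSON byte for byte. Stage timings are
logged, not stored in outputs.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import (
    CellLabelTable, assign_cell_types, find_markers, reassign_by_marker,
    top_markers,
)
from .depth import compute_depth, depth_stage_test, section_diameter, tissue_boundary
from .gridio import write_tidy
from .niche import niche_composition, select_neighborhood
from .preprocess import normalize, qc_filter, qc_report
from .report import RunManifest, spatial_map, write_manifest
from .scoring import score_named_modules
from .synthetic import default_blueprint, simulate_section

__all__ = ["default_config", "run_all"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """The full default configuration, mirroring every documented default."""
    return {
        "stages": ["E24", "E27", "E30", "E35", "E50"],
        "blueprint": {},                # GonadBlueprint field overrides
        "qc": {"min_total_counts": 100},
        "normalize": {"scale_factor": 10_000.0},
        "scoring": {"n_bins": 24, "n_ctrl": 100},
        "annotation": {
            "min_frac": 0.10,
            "min_log2fc": 0.5,
            "alpha": 0.05,
            "top_k": 5,
            # threshold ~ 3 UMIs at ~300 counts/pixel on the log scale,
            # separating spiked meiotic expression from sampling background
            "reassign": {"gene": "SYCP3", "threshold": 4.5,
                         "new_label": "Meiotic_Oogonia"},
        },
        "niche": {"radius": 1},
        "figures": True,
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_all(config: dict | None = None, seed: int = 0, outdir="run") -> RunManifest:
    """Run the full synthetic-study pipeline and write all artifacts.

    Returns the manifest; also writes it as ``manifest.json`` in
    ``outdir``.
    """
    cfg = _merge(default_config(), config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bp_overrides = dict(cfg["blueprint"])
    bp_overrides.setdefault("seed", seed)
    blueprint = default_blueprint(**bp_overrides)
    manifest = RunManifest(
        config=cfg, seeds={"seed": seed, "blueprint_seed": blueprint.seed},
        version=__version__,
    )

    def emit(name, writer):
        path = outdir / name
        writer(path)
        manifest.add_output(name)
        return path

    qc_rows = []
    depth_frames = []
    niche_frames = []
    sel_rows = []
    t0 = time.perf_counter()
    for stage in cfg["stages"]:
        t_stage = time.perf_counter()
        sample, truth = simulate_section(blueprint, stage, seed=seed)
        filtered = qc_filter(sample, cfg["qc"]["min_total_counts"])
        qc_rows.append(qc_report(sample, filtered))
        emit(f"tidy_{stage}.tsv", lambda p, s=filtered: write_tidy(s, p))
        norm = normalize(filtered, cfg["normalize"]["scale_factor"])

        # pathway / epigenetic-style module maps
        module_sets = {name: spec[0] for name, spec in blueprint.module_spec.items()}
        mods = score_named_modules(
            norm, module_sets, seed=seed, **cfg["scoring"]
        )
        mod_df = pd.DataFrame({"pixel_id": norm.pixel_ids})
        for m in mods:
            mod_df[m.module_name] = m.scores
        emit(f"module_scores_{stage}.tsv",
             lambda p, d=mod_df: d.to_csv(p, sep="\t", index=False))

        # marker-score annotation + rule reassignment
        type_scores = score_named_modules(
            norm, blueprint.marker_panel, seed=seed, **cfg["scoring"]
        )
        labels = assign_cell_types(type_scores)
        # refine germ subtypes by the diagnostic-gene rule; applied within
        # the germ-labelled pixels only, mirroring subclustering of the
        # germ population before reassignment
        re_cfg = cfg["annotation"]["reassign"]
        germ_ids = labels.germ_pixels()
        if re_cfg and re_cfg.get("gene") in norm.gene_ids and germ_ids:
            sub = CellLabelTable(
                df=labels.df.loc[germ_ids].copy(),
                germ_subtypes=labels.germ_subtypes,
            )
            sub = reassign_by_marker(
                sub, norm, re_cfg["gene"], re_cfg["threshold"],
                re_cfg["new_label"],
            )
            new_df = labels.df.copy()
            new_df.loc[germ_ids] = sub.df
            labels = CellLabelTable(df=new_df, germ_subtypes=labels.germ_subtypes)
        emit(f"labels_{stage}.tsv", lambda p, l=labels: l.to_tsv(p))

        markers = find_markers(
            norm, labels,
            min_frac=cfg["annotation"]["min_frac"],
            min_log2fc=cfg["annotation"]["min_log2fc"],
            alpha=cfg["annotation"]["alpha"],
        )
        emit(f"markers_{stage}.tsv", lambda p, m=markers: m.to_tsv(p))
        emit(f"top_markers_{stage}.tsv",
             lambda p, m=top_markers(markers, cfg["annotation"]["top_k"]): m.to_tsv(p))

        # boundary-referenced depth
        boundary = tissue_boundary(filtered.coords)
        D = section_diameter(filtered.coords)
        dres = compute_depth(
            filtered.coords, boundary, D, pixel_ids=filtered.pixel_ids,
            labels=labels, stage=stage, sample_id=filtered.sample_id,
        )
        emit(f"depth_{stage}.tsv", lambda p, d=dres: d.to_tsv(p))
        depth_frames.append(dres.df)

        # germ-subtype neighborhoods; composed per stage since pixel labels
        # repeat across sections
        stage_selections = []
        present = set(filtered.pixel_ids)
        for subtype in sorted(set(labels.df["germ_subtype"].dropna())):
            targets = [t for t in labels.germ_pixels(subtype) if t in present]
            if targets:
                stage_selections.append(
                    select_neighborhood(
                        filtered, targets, r=cfg["niche"]["radius"],
                        target_subtype=subtype,
                    )
                )
        if stage_selections:
            niche_frames.append(niche_composition(stage_selections, labels).df)
            sel_rows.extend(
                {"pixel_id": pid, "role": role, "sample_id": sel.sample_id,
                 "target_subtype": sel.target_subtype, "stage": sel.stage}
                for sel in stage_selections
                for role, ids in (("target", sel.target_ids),
                                  ("neighbor", sel.tally_ids()))
                for pid in ids
            )

        if cfg["figures"]:
            info = spatial_map(
                filtered, labels.df["cell_type"], outdir / f"map_types_{stage}.png",
                title=f"{stage}: cell types",
            )
            manifest.add_output(f"map_types_{stage}.png")
            manifest.figure_info[f"map_types_{stage}.png"] = info
            info = spatial_map(
                filtered, dres.df.set_index("pixel_id")["depth"],
                outdir / f"map_depth_{stage}.png", title=f"{stage}: depth",
            )
            manifest.add_output(f"map_depth_{stage}.png")
            manifest.figure_info[f"map_depth_{stage}.png"] = info
        logger.info("stage %s done in %.2f s", stage, time.perf_counter() - t_stage)

    emit("qc_report.tsv",
         lambda p: pd.concat(qc_rows, ignore_index=True).to_csv(p, sep="\t", index=False))

    depth_all = pd.concat(depth_frames, ignore_index=True)
    emit("depth_all.tsv", lambda p: depth_all.to_csv(p, sep="\t", index=False))
    try:
        stage_test = depth_stage_test(depth_all, None, cfg["stages"])
        emit("depth_stage_test.tsv", lambda p: stage_test.to_tsv(p))
    except ValueError as exc:
        logger.warning("depth stage test skipped: %s", exc)

    if niche_frames:
        emit("niche_composition.tsv",
             lambda p: pd.concat(niche_frames, ignore_index=True)
             .to_csv(p, sep="\t", index=False))
        emit("niche_selection.tsv",
             lambda p: pd.DataFrame(sel_rows).to_csv(p, sep="\t", index=False))

    manifest.add_output("manifest.json")
    write_manifest(manifest, outdir / "manifest.json")
    logger.info("run complete in %.2f s", time.perf_counter() - t0)
    return manifest
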