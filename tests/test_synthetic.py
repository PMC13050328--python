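"""Synthetic stratified-gonad generator: determinism, geometry, truth."""

import numpy as np
import pytest

from spatgonad import (
    default_blueprint,
    ranksum,
    simulate_section,
    write_fixture,
)
from spatgonad.synthetic import GERM_DEPTH_TOL, _ellipse_mask_coords


class TestBlueprintValidation:
    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            default_blueprint(grid_width=2)

    def test_subunit_fold_rejected(self):
        with pytest.raises(ValueError, match="marker_fold"):
            default_blueprint(marker_fold=0.5)

    def test_non_decreasing_migration_targets_rejected(self):
        with pytest.raises(ValueError, match="strictly decrease"):
            default_blueprint(
                germ_depth_mean={"E24": 0.2, "E27": 0.3, "E30": 0.25,
                                 "E35": 0.18, "E50": 0.10}
            )

    def test_gappy_bands_rejected(self):
        from spatgonad import ZoneSpec

        with pytest.raises(ValueError, match="bands"):
            default_blueprint(
                zone_spec=(
                    ZoneSpec("a", {"OSEC": 1.0}, (0.0, 0.3)),
                    ZoneSpec("b", {"PreGC_I": 1.0}, (0.5, 1.0)),
                )
            )

    def test_unknown_stage_rejected(self, small_blueprint):
        with pytest.raises(ValueError, match="stage"):
            simulate_section(small_blueprint, "E99", seed=0)


class TestDeterminism:
    def test_same_inputs_give_identical_sections(self, small_blueprint):
        s1, t1 = simulate_section(small_blueprint, "E30", seed=7)
        s2, t2 = simulate_section(small_blueprint, "E30", seed=7)
        assert (s1.counts != s2.counts).nnz == 0
        assert s1.pixel_ids == s2.pixel_ids
        assert t1.pixels.equals(t2.pixels)
        assert t1.niche.equals(t2.niche)

    def test_different_seed_changes_counts(self, small_blueprint):
        s1, _ = simulate_section(small_blueprint, "E30", seed=7)
        s2, _ = simulate_section(small_blueprint, "E30", seed=8)
        assert (s1.counts != s2.counts).nnz > 0

    def test_fixture_bytes_identical_across_runs(self, small_blueprint, tmp_path):
        for d in ("a", "b"):
            s, t = simulate_section(small_blueprint, "E27", seed=3)
            write_fixture(s, t, tmp_path / d, blueprint=small_blueprint)
        for name in ("matrix.mtx", "genes.tsv", "pixels.tsv",
                     "truth_pixels.tsv", "truth_niche.tsv", "config.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()


class TestGeometry:
    def test_ellipse_mask_matches_direct_enumeration(self):
        """40x40 grid: the mask equals the brute-force set of centers
        satisfying the ellipse inequality."""
        coords = _ellipse_mask_coords(40, 40)
        cx = cy = (40 - 1) / 2
        expected = {
            (x, y)
            for x in range(40)
            for y in range(40)
            if ((x - cx) / cx) ** 2 + ((y - cy) / cy) ** 2 <= 1.0
        }
        assert {tuple(c) for c in coords} == expected

    def test_zone_bands_match_brute_force_assignment(self, small_section,
                                                     small_blueprint):
        """Outside the interface strip, each pixel's zone is exactly the
        radial band containing its relative depth."""
        _, truth = small_section
        px = truth.pixels
        core = px[px["zone"] != "interface"]
        mismatches = 0
        for _, row in core.iterrows():
            expected = None
            for z in small_blueprint.zone_spec:
                lo, hi = z.band
                if lo <= row.rel_depth < hi or (hi >= 1.0 and row.rel_depth <= 1.0):
                    expected = z.name
                    break
            if expected != row.zone:
                mismatches += 1
        assert mismatches <= 2

    def test_interface_strip_is_lateral_and_mesenchymal(self, small_section,
                                                        small_blueprint):
        _, truth = small_section
        px = truth.pixels
        strip = px[px["zone"] == "interface"]
        assert len(strip) > 0
        cut = px["x"].min() + small_blueprint.interface_width_frac * (
            px["x"].max() - px["x"].min()
        )
        assert (strip["x"] <= cut).all()
        frac_mes = (strip["cell_type"] == "Mesenchymal").mean()
        assert frac_mes > 0.6


class TestGermPlacement:
    @pytest.mark.parametrize("stage", ["E24", "E30", "E50"])
    def test_realized_mean_depth_hits_target(self, small_blueprint, stage):
        _, truth = simulate_section(small_blueprint, stage, seed=2)
        target = small_blueprint.germ_depth_mean[stage]
        assert abs(truth.germ_mean_depth() - target) <= GERM_DEPTH_TOL

    def test_oversized_request_names_the_band(self, small_blueprint):
        import dataclasses

        bad = dataclasses.replace(
            small_blueprint,
            germ_counts={"E24": {"Mitotic_PGC": 10**6}},
        )
        with pytest.raises(ValueError, match="band"):
            simulate_section(bad, "E24", seed=0)

    def test_subtype_counts_respected(self, small_blueprint):
        _, truth = simulate_section(small_blueprint, "E35", seed=4)
        counts = truth.pixels["germ_subtype"].value_counts()
        for subtype, n in small_blueprint.germ_counts["E35"].items():
            assert counts.get(subtype, 0) == n


class TestCountModel:
    def test_null_folds_make_types_indistinguishable(self, null_section):
        """With marker and module folds at 1, per-gene mean counts do not
        differ between cell types (rank-sum p > 0.01 for >= 95% of genes)."""
        sample, truth = null_section
        counts = sample.counts.toarray()
        ct = truth.pixels["cell_type"].to_numpy()
        types = [t for t in np.unique(ct) if (ct == t).sum() >= 400]
        assert len(types) >= 2
        rng = np.random.default_rng(0)
        a = rng.choice(np.flatnonzero(ct == types[0]), 400, replace=False)
        b = rng.choice(np.flatnonzero(ct == types[1]), 400, replace=False)
        ps = [
            ranksum(counts[g, a], counts[g, b]).p_value
            for g in range(sample.n_genes)
        ]
        assert np.mean(np.array(ps) > 0.01) >= 0.95

    def test_marker_genes_enriched_in_their_type(self, small_section,
                                                 small_blueprint):
        sample, truth = small_section
        counts = sample.counts.toarray()
        ct = truth.pixels["cell_type"].to_numpy()
        gi = {g: i for i, g in enumerate(sample.gene_ids)}
        for cell_type in ("OSEC", "PreGC_I"):
            own = ct == cell_type
            other = ~own
            for gene in small_blueprint.marker_panel[cell_type][:3]:
                assert counts[gi[gene], own].mean() > 3 * counts[gi[gene], other].mean()


class TestWriteFixture:
    def test_refuses_nonempty_dir_without_overwrite(self, small_section, tmp_path):
        sample, truth = small_section
        (tmp_path / "x").mkdir()
        (tmp_path / "x" / "stale.txt").write_text("old\n")
        with pytest.raises(FileExistsError):
            write_fixture(sample, truth, tmp_path / "x")
        write_fixture(sample, truth, tmp_path / "x", overwrite=True)
        assert not (tmp_path / "x" / "stale.txt").exists()

    def test_triplet_line_count_equals_nnz(self, tmp_path):
        from conftest import make_sample

        sample = make_sample(
            [(0, 0), (1, 0), (2, 0)], [[1, 0, 2], [0, 0, 3]]
        )
        write_fixture(sample, None, tmp_path / "toy")
        lines = (tmp_path / "toy" / "matrix.mtx").read_text().splitlines()
        data_lines = [
            l for l in lines[1:] if l.strip() and not l.startswith("%")
        ][1:]  # drop the size header
        assert len(data_lines) == sample.counts.nnz == 3

    def test_empty_sample_round_trips(self, tmp_path):
        import scipy.sparse as sp

        from spatgonad import SpatialSample
        from spatgonad.synthetic import load_fixture

        empty = SpatialSample(
            pixel_ids=[], coords=np.empty((0, 2), dtype=int),
            counts=sp.csr_matrix((3, 0), dtype=np.int64),
            gene_ids=["A", "B", "C"], sample_id="void", stage="E24",
        )
        write_fixture(empty, None, tmp_path / "void")
        loaded, _ = load_fixture(tmp_path / "void")
        assert loaded.n_pixels == 0
        assert loaded.gene_ids == ["A", "B", "C"]
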