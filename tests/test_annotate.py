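"""Cell-type assignment, rule reassignment, marker detection."""

import numpy as np
import pandas as pd
import pytest

from spatgonad import (
    CellLabelTable,
    MarkerTable,
    NormalizedMatrix,
    assign_cell_types,
    find_markers,
    reassign_by_marker,
    top_markers,
)
from spatgonad.scoring import ModuleScore


def score_of(name, values, pixel_ids=None):
    values = np.asarray(values, dtype=float)
    return ModuleScore(
        module_name=name, gene_set=["X"], control_assignment={},
        scores=values,
        pixel_ids=pixel_ids or [f"{i}x0" for i in range(values.size)],
        n_bins=1, n_ctrl=1, seed=0,
    )


def norm_matrix(values, gene_ids, pixel_ids=None):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=values, gene_ids=gene_ids,
        pixel_ids=pixel_ids or [f"{i}x0" for i in range(values.shape[1])],
        scale_factor=1.0,
    )


class TestAssign:
    def test_argmax_and_margin(self):
        labels = assign_cell_types(
            {"A": score_of("A", [1.0]), "B": score_of("B", [0.2])}
        )
        row = labels.df.iloc[0]
        assert row["cell_type"] == "A"
        assert row["margin"] == pytest.approx(0.8)
        assert not row["tie"]

    def test_exact_tie_goes_lexicographic_and_flags(self):
        labels = assign_cell_types(
            {"B": score_of("B", [0.5]), "A": score_of("A", [0.5])}
        )
        row = labels.df.iloc[0]
        assert row["cell_type"] == "A"
        assert row["tie"]

    def test_per_pixel_constant_shift_changes_nothing(self):
        rng = np.random.default_rng(5)
        a, b, c = rng.normal(size=(3, 20))
        shift = rng.normal(size=20) * 10
        base = assign_cell_types(
            {"A": score_of("A", a), "B": score_of("B", b), "C": score_of("C", c)}
        )
        shifted = assign_cell_types(
            {"A": score_of("A", a + shift), "B": score_of("B", b + shift),
             "C": score_of("C", c + shift)}
        )
        assert shifted.df["cell_type"].tolist() == base.df["cell_type"].tolist()

    def test_mismatched_pixels_rejected(self):
        with pytest.raises(ValueError, match="different pixels"):
            assign_cell_types(
                {"A": score_of("A", [1.0, 2.0]),
                 "B": score_of("B", [1.0], pixel_ids=["9x9"])}
            )

    def test_single_type_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            assign_cell_types({"A": score_of("A", [1.0])})


class TestReassign:
    def make_labels(self, n):
        return assign_cell_types(
            {"A": score_of("A", np.ones(n)), "B": score_of("B", np.zeros(n))}
        )

    def test_threshold_below_min_reassigns_all(self):
        norm = norm_matrix([[1.0, 2.0, 3.0]], ["G"])
        labels = reassign_by_marker(self.make_labels(3), norm, "G", 0.5, "B")
        assert (labels.df["cell_type"] == "B").all()
        assert (labels.df["source"] == "rule_reassigned").all()

    def test_threshold_above_max_changes_nothing(self):
        norm = norm_matrix([[1.0, 2.0, 3.0]], ["G"])
        labels = reassign_by_marker(self.make_labels(3), norm, "G", 99.0, "B")
        assert (labels.df["cell_type"] == "A").all()

    def test_exactly_the_expressing_pixels_reassigned(self):
        """5 pixels, gene expressed (value > 0) in exactly two."""
        norm = norm_matrix([[0.0, 1.2, 0.0, 0.7, 0.0]], ["SYCP3"])
        labels = reassign_by_marker(
            self.make_labels(5), norm, "SYCP3", 0.0, "B"
        )
        assert labels.df["cell_type"].tolist() == ["A", "B", "A", "B", "A"]

    def test_absent_gene_is_error(self):
        norm = norm_matrix([[1.0]], ["G"])
        with pytest.raises(KeyError):
            reassign_by_marker(self.make_labels(1), norm, "NOPE", 0.0, "B")


class TestFindMarkers:
    def exchangeable_norm(self, n_per=12, n_genes=8, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.gamma(2, 1, size=(n_genes, 2 * n_per))
        return norm_matrix(values, [f"G{i}" for i in range(n_genes)])

    def labels_for(self, norm, n_per):
        df = pd.DataFrame(
            {
                "cell_type": ["c1"] * n_per + ["c2"] * n_per,
                "germ_subtype": pd.NA,
                "source": "truth_injected",
                "margin": np.nan,
                "tie": False,
            },
            index=pd.Index(norm.pixel_ids, name="pixel_id"),
        )
        return CellLabelTable(df=df)

    def test_identical_expression_yields_no_significant_rows(self):
        norm = self.exchangeable_norm()
        table = find_markers(norm, self.labels_for(norm, 12))
        assert int(table.df["significant"].sum()) == 0

    def test_low_fraction_gene_gated_before_testing(self):
        """A gene expressed in 1 of 20 in-cluster pixels (5%) never reaches
        the table, however extreme its values."""
        values = np.zeros((2, 40))
        values[0, 0] = 50.0          # 5% of cluster c1
        values[1] = np.linspace(1, 2, 40)
        norm = norm_matrix(values, ["RARE", "BASE"])
        labels = self.labels_for(norm, 20)
        table = find_markers(norm, labels, min_frac=0.10)
        assert "RARE" not in table.df["gene"].tolist()

    def test_spiked_gene_detected(self):
        rng = np.random.default_rng(1)
        values = rng.gamma(2, 1, size=(6, 60))
        values[2, :30] += 3.0        # spiked in cluster c1
        norm = norm_matrix(values, [f"G{i}" for i in range(6)])
        table = find_markers(norm, self.labels_for(norm, 30))
        sig = table.significant()
        assert ("c1", "G2") in list(zip(sig["cluster"], sig["gene"]))

    def test_bh_monotone_in_rawp_within_cluster(self):
        rng = np.random.default_rng(2)
        values = rng.gamma(2, 1, size=(12, 60))
        values[:6, :30] += rng.uniform(0.5, 2.5, size=(6, 1))
        norm = norm_matrix(values, [f"G{i}" for i in range(12)])
        table = find_markers(norm, self.labels_for(norm, 30))
        for _, grp in table.df.groupby("cluster"):
            srt = grp.sort_values("p")
            assert np.all(np.diff(srt["adj_p"]) >= -1e-12)
            assert np.all(srt["adj_p"] >= srt["p"] - 1e-12)

    def test_undersized_cluster_skipped_with_warning(self, caplog):
        import logging

        norm = self.exchangeable_norm(n_per=12)
        labels = self.labels_for(norm, 12)
        labels.df.iloc[:2, labels.df.columns.get_loc("cell_type")] = "tiny"
        with caplog.at_level(logging.WARNING):
            find_markers(norm, labels)
        assert any("skipped" in rec.message for rec in caplog.records)


class TestTopMarkers:
    def make_table(self, rows):
        df = pd.DataFrame(
            rows, columns=["cluster", "gene", "log2fc", "frac_in", "frac_out",
                           "p", "adj_p", "significant"],
        )
        return MarkerTable(df=df)

    def test_orders_by_fold_change(self):
        table = self.make_table(
            [("c", g, fc, 0.5, 0.1, 0.001, 0.01, True)
             for g, fc in [("g1", 3.0), ("g2", 2.0), ("g3", 1.0)]]
        )
        top = top_markers(table, k=2)
        assert top.df["gene"].tolist() == ["g1", "g2"]

    def test_cluster_with_fewer_markers_returns_all(self):
        table = self.make_table(
            [("c", "g1", 1.0, 0.5, 0.1, 0.001, 0.01, True),
             ("c", "g2", 2.0, 0.5, 0.1, 0.001, 0.01, True)]
        )
        assert len(top_markers(table, k=5).df) == 2

    def test_empty_table_stays_empty(self):
        assert top_markers(self.make_table([]), k=5).df.empty

    def test_insignificant_rows_excluded(self):
        table = self.make_table(
            [("c", "g1", 5.0, 0.5, 0.1, 0.2, 0.4, False),
             ("c", "g2", 1.0, 0.5, 0.1, 0.001, 0.01, True)]
        )
        assert top_markers(table, k=5).df["gene"].tolist() == ["g2"]
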