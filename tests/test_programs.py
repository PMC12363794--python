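"""Normalization, signature scoring, subtype/module assignment, smoothing, DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastichrom import programs, synthio
from plastichrom.config import ConfigError, SimConfig


def _expr(mat, cells=None, genes=None):
    mat = np.asarray(mat, dtype=float)
    cells = cells or [f"c{i}" for i in range(mat.shape[0])]
    genes = genes or [f"g{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=cells, columns=genes)


class TestNormalizeLog:
    def test_equal_depths_scale_by_one(self):
        counts = _expr([[1, 3], [2, 2], [0, 4]])  # all totals = 4
        norm = programs.normalize_log(counts)
        assert np.allclose(norm.to_numpy(), np.log1p(counts.to_numpy()))

    def test_depth_invariance_of_profile(self):
        # doubling one (non-median) cell's counts must not move its
        # normalized profile: the depth scaling cancels the factor
        counts = _expr([[1, 3, 0], [5, 2, 1], [2, 2, 2], [0, 4, 4], [3, 3, 3]])
        doubled = counts.copy()
        doubled.iloc[0] *= 2
        a = programs.normalize_log(counts)
        b = programs.normalize_log(doubled)
        assert np.allclose(a.iloc[0].to_numpy(), b.iloc[0].to_numpy())
        assert np.allclose(a.iloc[1:].to_numpy(), b.iloc[1:].to_numpy())

    def test_single_cell_hand_arithmetic(self):
        norm = programs.normalize_log(_expr([[0, 1, 3]]))
        assert np.allclose(norm.to_numpy()[0], np.log1p([0, 1, 3]))

    def test_zero_total_cell_dropped(self):
        norm = programs.normalize_log(_expr([[1, 1], [0, 0]]))
        assert list(norm.index) == ["c0"]


class TestScoreSignature:
    def test_singleton_set_equals_gene_zscore(self):
        norm = _expr(np.random.default_rng(0).random((30, 4)))
        score = programs.score_signature(norm, ["g2"])
        col = norm["g2"].to_numpy()
        z = (col - col.mean()) / col.std(ddof=0)
        assert np.allclose(score.to_numpy(), z)

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(1)
        mat = rng.random((20, 3))
        mat[:, 1] = 0.7  # constant
        norm = _expr(mat)
        with_const = programs.score_signature(norm, ["g0", "g1", "g2"])
        without = programs.score_signature(norm, ["g0", "g2"])
        assert np.allclose(with_const.to_numpy(), without.to_numpy())

    def test_all_constant_set_is_error(self):
        norm = _expr(np.ones((10, 2)))
        with pytest.raises(programs.GeneSetError):
            programs.score_signature(norm, ["g0", "g1"], name="flat")

    def test_empty_overlap_is_error_naming_the_set(self):
        norm = _expr(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(programs.GeneSetError, match="mystery"):
            programs.score_signature(norm, ["absent"], name="mystery")

    def test_gene_order_invariance(self):
        norm = _expr(np.random.default_rng(2).random((15, 5)))
        a = programs.score_signature(norm, ["g0", "g3", "g4"])
        b = programs.score_signature(norm, ["g4", "g0", "g3"])
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_planted_program_separates_cluster(self):
        cfg = SimConfig(seed=5, n_cells=2_000, n_genes=500, n_clusters=2,
                        program_size=50, program_effect=1.0)
        counts, meta, truth = synthio.make_sc_counts(cfg)
        norm = programs.normalize_log(counts)
        score = programs.score_signature(norm, truth.program_genes["program_cluster0"])
        labels = (meta.set_index("cell_id")["cluster"].reindex(score.index) == 0).to_numpy()
        auroc = stats.mannwhitneyu(score[labels], score[~labels]).statistic / (
            labels.sum() * (~labels).sum()
        )
        assert auroc > 0.9


class TestAssignSubtype:
    def test_single_marker_set_rejected(self):
        scores = pd.DataFrame({"BL": [1.0]}, index=["c0"])
        with pytest.raises(ConfigError):
            programs.assign_subtype(scores, level="cell")

    def test_hand_argmax_and_margin(self):
        scores = pd.DataFrame([[2.0, -1.0, 0.3]], columns=["BL", "L2", "L1.1"], index=["c0"])
        out = programs.assign_subtype(scores, level="cell")
        assert out.loc["c0", "subtype"] == "BL"
        assert out.loc["c0", "margin"] == pytest.approx(1.7)

    def test_exact_tie_is_ambiguous(self):
        scores = pd.DataFrame([[1.0, 1.0, 0.0]], columns=["A", "B", "C"], index=["c0"])
        out = programs.assign_subtype(scores, level="cell")
        assert out.loc["c0", "subtype"] == "ambiguous"
        assert "A" in out.loc["c0", "runner_up"] and "B" in out.loc["c0", "runner_up"]

    def test_cluster_level_recovers_planted_markers(self, small_cfg):
        counts, meta, truth = synthio.make_sc_counts(small_cfg)
        norm = programs.normalize_log(counts)
        scores = programs.score_signatures(norm, truth.program_genes)
        clusters = meta.set_index("cell_id")["cluster"]
        out = programs.assign_subtype(scores, level="cluster", clusters=clusters)
        for cl in range(small_cfg.n_clusters):
            got = out.loc[out["cluster"] == cl, "subtype"].unique()
            assert list(got) == [f"program_cluster{cl}"]


class TestMrtfModules:
    @staticmethod
    def _scores(rows):
        return pd.DataFrame(rows, columns=list(programs.MRTF_MODULE_ORDER))

    def test_dominant_group_maps_to_module(self):
        per_cell, _ = programs.mrtf_modules(self._scores([[2.0, 0.1, 0.1],
                                                          [0.0, 3.0, 0.1],
                                                          [0.0, 0.1, 3.0]]))
        assert per_cell["module"].tolist() == [0, 1, 2]

    def test_all_equal_breaks_tie_by_group_order(self):
        per_cell, _ = programs.mrtf_modules(self._scores([[1.0, 1.0, 1.0]]))
        assert per_cell["module"].iloc[0] == 0  # NEPC_TFs first
        assert bool(per_cell["tied"].iloc[0])

    def test_output_is_a_partition(self):
        rng = np.random.default_rng(0)
        per_cell, _ = programs.mrtf_modules(self._scores(rng.normal(size=(100, 3))))
        assert per_cell["module"].isin([0, 1, 2]).all()
        assert len(per_cell) == 100

    def test_missing_group_set_rejected(self):
        bad = pd.DataFrame({"NEPC_TFs": [1.0], "adeno_TFs": [0.0]})
        with pytest.raises(ConfigError):
            programs.mrtf_modules(bad)

    def test_planted_nepc_program_enriches_vehicle_cells(self):
        # NEPC program planted in cluster 0 (a vehicle cluster): module 0
        # should be more frequent among vehicle cells
        cfg = SimConfig(seed=9, n_cells=2_000, n_genes=600, n_clusters=4,
                        program_size=50, program_effect=1.0,
                        program_clusters=[0, 1, 2])
        counts, meta, _ = synthio.make_sc_counts(cfg)
        norm = programs.normalize_log(counts)
        truth_sets = {
            "NEPC_TFs": [f"gene{i:05d}" for i in range(0, 50)],        # cluster 0 (vehicle)
            "transition_TFs": [f"gene{i:05d}" for i in range(50, 100)],  # cluster 1
            "adeno_TFs": [f"gene{i:05d}" for i in range(100, 150)],      # cluster 2
        }
        scores = programs.score_signatures(norm, truth_sets)
        per_cell, _ = programs.mrtf_modules(scores, meta.set_index("cell_id"))
        treatment = meta.set_index("cell_id")["treatment"].reindex(per_cell.index)
        veh = (per_cell.loc[treatment == "vehicle", "module"] == 0)
        ezh = (per_cell.loc[treatment == "EZH2i", "module"] == 0)
        stat, p = np.array([veh.sum(), ezh.sum()]), None
        from statsmodels.stats.proportion import proportions_ztest

        z, p = proportions_ztest([veh.sum(), ezh.sum()], [len(veh), len(ezh)],
                                 alternative="larger")
        assert p < 0.01


class TestPseudotimeProfile:
    def test_constant_score_fits_constant(self):
        rng = np.random.default_rng(0)
        pt = pd.Series(rng.random(50))
        score = pd.Series(np.full(50, 2.5))
        prof = programs.pseudotime_profile(score, pt, df=4)
        assert np.allclose(prof["fitted"], 2.5, atol=1e-8)

    def test_identity_in_spline_span_is_exact(self):
        rng = np.random.default_rng(1)
        pt = pd.Series(rng.random(200))
        prof = programs.pseudotime_profile(pt.copy(), pt, df=3)
        assert np.max(np.abs(prof["fitted"] - prof["pseudotime"])) < 1e-6

    def test_monotone_trend_recovered_under_noise(self):
        rng = np.random.default_rng(2)
        pt = pd.Series(rng.random(2_000))
        truth = 2 * pt - 1 + 0.5 * np.sin(3 * pt)
        score = pd.Series(truth + rng.normal(scale=0.5, size=len(pt)))
        prof = programs.pseudotime_profile(score, pt, df=6)
        grid_truth = 2 * prof["pseudotime"] - 1 + 0.5 * np.sin(3 * prof["pseudotime"])
        rho = stats.spearmanr(prof["fitted"], grid_truth).statistic
        assert rho > 0.95

    def test_df_exceeding_distinct_values_rejected(self):
        pt = pd.Series([0.0, 0.2, 0.4, 0.6, 0.8] * 3)
        score = pd.Series(np.arange(15.0))
        with pytest.raises(ConfigError):
            programs.pseudotime_profile(score, pt, df=5)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigError):
            programs.pseudotime_profile(pd.Series([1.0] * 5), pd.Series(np.linspace(0, 1, 5)))


class TestDeRank:
    def test_overlapping_groups_rejected(self):
        norm = _expr(np.random.default_rng(0).random((6, 3)))
        with pytest.raises(programs.InputError):
            programs.de_rank(norm, ["c0", "c1", "c2"], ["c2", "c3", "c4"])

    def test_all_zero_gene_is_null(self):
        mat = np.random.default_rng(0).random((6, 3))
        mat[:, 1] = 0.0
        norm = _expr(mat)
        out = programs.de_rank(norm, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        row = out.set_index("gene_id").loc["g1"]
        assert row["effect"] == 0.0 and row["p"] == 1.0

    def test_hand_arithmetic_effect(self):
        norm = _expr([[4.0], [4.0], [4.0], [1.0], [1.0], [1.0]])
        out = programs.de_rank(norm, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert out["effect"].iloc[0] == pytest.approx(np.log2(5) - np.log2(2))

    def test_null_labels_center_effects_at_zero(self):
        rng = np.random.default_rng(3)
        counts = _expr(rng.poisson(2.0, size=(2_000, 5_000)))
        norm = programs.normalize_log(counts)
        cells = list(norm.index)
        out = programs.de_rank(norm, cells[:1000], cells[1000:])
        assert np.abs(out["effect"]).mean() < 0.05

    def test_ranking_is_deterministic_under_ties(self):
        norm = _expr(np.ones((6, 4)) * [[1, 2, 3, 4]] * 6)
        a = programs.de_rank(norm, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        b = programs.de_rank(norm, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
        assert a["gene_id"].tolist() == b["gene_id"].tolist()
        assert a["gene_id"].tolist() == sorted(a["gene_id"].tolist())
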