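"""Four-state calling, transition tabulation and DE-class enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from plastichrom import chromstate, synthio
from plastichrom.config import ConfigError, SimConfig
from plastichrom.states import STATES, classify


def _promoters(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def _bed(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


def _empty_peaks():
    return {(m, c): _bed([]) for m in synthio.MARKS for c in synthio.CONDITIONS}


class TestAssignMarkPresence:
    def test_hand_interval_overlap(self):
        # peak [100,200) and TSS=1500 with window=2000: window [-500,3500) clips to [0,3500)
        promoters = _promoters([["g1", "chr1", 1500, "+"]])
        peaks = _empty_peaks()
        peaks[("H3K4me3", "cond1")] = _bed([["chr1", 100, 200]])
        presence = chromstate.assign_mark_presence(peaks, promoters, window=2000)
        row = presence.set_index(["gene_id", "condition"]).loc[("g1", "cond1")]
        assert bool(row["has_k4"]) and not bool(row["has_k27"])

    def test_empty_peak_files_give_all_absent(self):
        promoters = _promoters([["g1", "chr1", 1000, "+"], ["g2", "chr2", 5000, "-"]])
        presence = chromstate.assign_mark_presence(_empty_peaks(), promoters, window=500)
        assert len(presence) == 4  # 2 genes x 2 conditions
        assert not presence[["has_k4", "has_k27"]].to_numpy().any()

    def test_adjacent_non_overlapping_peak_is_absent(self):
        promoters = _promoters([["g1", "chr1", 1000, "+"]])
        peaks = _empty_peaks()
        # half-open peak [1500, 2000) does not reach window [500, 1500)
        peaks[("H3K4me3", "cond1")] = _bed([["chr1", 1500, 2000]])
        presence = chromstate.assign_mark_presence(peaks, promoters, window=500)
        assert not presence["has_k4"].any()

    def test_majority_rule_over_replicates(self):
        promoters = _promoters([["g1", "chr1", 1000, "+"]])
        hit, miss = _bed([["chr1", 900, 1100]]), _bed([["chr9", 1, 2]])
        peaks = _empty_peaks()
        peaks[("H3K4me3", "cond1")] = [hit, miss, miss]  # 1 of 3 < majority
        presence = chromstate.assign_mark_presence(peaks, promoters, window=500)
        got = presence.set_index(["gene_id", "condition"])
        assert not got.loc[("g1", "cond1"), "has_k4"]
        peaks[("H3K4me3", "cond1")] = [hit, hit, miss]  # 2 of 3 passes
        presence = chromstate.assign_mark_presence(peaks, promoters, window=500)
        assert presence.set_index(["gene_id", "condition"]).loc[("g1", "cond1"), "has_k4"]

    def test_multi_tss_gene_uses_union_of_windows(self):
        promoters = _promoters([["g1", "chr1", 1000, "+"], ["g1", "chr1", 90_000, "+"]])
        peaks = _empty_peaks()
        peaks[("H3K27me3", "cond2")] = _bed([["chr1", 89_900, 90_100]])
        presence = chromstate.assign_mark_presence(peaks, promoters, window=500)
        got = presence.set_index(["gene_id", "condition"])
        assert got.loc[("g1", "cond2"), "has_k27"]

    def test_round_trip_recovers_planted_marks(self, small_cfg):
        promoters, truth = synthio.make_promoters(small_cfg)
        peaks = synthio.make_peaks(promoters, truth.promoter_states, window=1000)
        presence = chromstate.assign_mark_presence(peaks, promoters, window=2000)
        states = chromstate.call_states(presence)
        wide = states.pivot(index="gene_id", columns="condition", values="state")
        planted = truth.promoter_states.set_index("gene_id")
        assert (wide["cond1"] == planted["state_cond1"]).all()
        assert (wide["cond2"] == planted["state_cond2"]).all()


class TestCallStates:
    @pytest.mark.parametrize(
        "k4,k27,expected",
        [(True, False, "Active"), (False, True, "Repressed"),
         (True, True, "Bivalent"), (False, False, "Unmarked")],
    )
    def test_truth_table(self, k4, k27, expected):
        assert classify(k4, k27) == expected
        presence = pd.DataFrame(
            [{"gene_id": "g", "condition": "cond1", "has_k4": k4, "has_k27": k27}]
        )
        assert chromstate.call_states(presence)["state"].iloc[0] == expected

    def test_truth_table_is_a_bijection(self):
        combos = list(itertools.product([False, True], repeat=2))
        states = {classify(k4, k27) for k4, k27 in combos}
        assert states == set(STATES)

    def test_duplicate_record_rejected(self):
        presence = pd.DataFrame(
            [{"gene_id": "g", "condition": "cond1", "has_k4": True, "has_k27": False}] * 2
        )
        with pytest.raises(chromstate.InputError):
            chromstate.call_states(presence)


def _calls(mapping):
    return pd.DataFrame({"gene_id": list(mapping), "state": list(mapping.values())})


class TestTransitionMatrix:
    def test_hand_count(self):
        s1 = _calls({"a": "Active", "b": "Active", "c": "Unmarked"})
        s2 = _calls({"a": "Bivalent", "b": "Bivalent", "c": "Unmarked"})
        table = chromstate.transition_matrix(s1, s2)
        assert table.counts.loc["Active", "Bivalent"] == 2
        assert table.counts.loc["Unmarked", "Unmarked"] == 1
        assert table.total == 3

    def test_identity_has_zero_off_diagonal(self):
        calls = _calls({"a": "Active", "b": "Repressed", "c": "Bivalent"})
        table = chromstate.transition_matrix(calls, calls)
        off = table.counts.to_numpy() - np.diag(np.diag(table.counts.to_numpy()))
        assert (off == 0).all()

    def test_swapping_conditions_transposes_counts(self):
        s1 = _calls({"a": "Active", "b": "Repressed", "c": "Bivalent", "d": "Active"})
        s2 = _calls({"a": "Bivalent", "b": "Repressed", "c": "Unmarked", "d": "Active"})
        fwd = chromstate.transition_matrix(s1, s2).counts.to_numpy()
        rev = chromstate.transition_matrix(s2, s1).counts.to_numpy()
        assert np.array_equal(fwd, rev.T)

    def test_one_condition_only_genes_reported_not_counted(self):
        s1 = _calls({"a": "Active", "x": "Bivalent"})
        s2 = _calls({"a": "Active", "y": "Unmarked"})
        table = chromstate.transition_matrix(s1, s2)
        assert table.total == 1
        assert table.only_cond1 == ["x"] and table.only_cond2 == ["y"]

    def test_empty_intersection_rejected(self):
        with pytest.raises(chromstate.InputError):
            chromstate.transition_matrix(_calls({"a": "Active"}), _calls({"b": "Active"}))

    def test_kernel_recovery_within_multinomial_error(self):
        cfg = SimConfig(seed=3, n_promoters=10_000)
        _, truth = synthio.make_promoters(cfg)
        st = truth.promoter_states
        table = chromstate.transition_matrix(
            st[["gene_id", "state_cond1"]].rename(columns={"state_cond1": "state"}),
            st[["gene_id", "state_cond2"]].rename(columns={"state_cond2": "state"}),
        )
        emp = table.row_normalized().to_numpy()
        kernel = cfg.kernel
        rows = table.counts.sum(axis=1).to_numpy()
        se = np.sqrt(kernel * (1 - kernel) / rows[:, None])
        assert (np.abs(emp - kernel) <= 3 * se).all()


def brute_hypergeom_sf(k, n_total, n_sig, n_class):
    """P(X >= k) by exhaustive enumeration over all draws of size n_class."""
    population = [1] * n_sig + [0] * (n_total - n_sig)
    hits = total = 0
    for combo in itertools.combinations(range(n_total), n_class):
        total += 1
        if sum(population[i] for i in combo) >= k:
            hits += 1
    return hits / total


class TestIntegrateWithDe:
    @staticmethod
    def _transitions(states2, states1=None):
        genes = [f"g{i}" for i in range(len(states2))]
        s1 = states1 or ["Active"] * len(states2)
        return chromstate.transition_matrix(
            _calls(dict(zip(genes, s1))), _calls(dict(zip(genes, states2)))
        )

    def test_no_de_genes_gives_p_one(self):
        table = self._transitions(["Active", "Bivalent", "Unmarked", "Repressed"])
        de = pd.DataFrame({"gene_id": ["g0", "g1"], "effect": [1.0, 1.0],
                           "p": [0.5, 0.5], "q": [0.9, 0.9]})
        enr = chromstate.integrate_with_de(table, de, direction="up", q_max=0.05)
        assert (enr["p"] == 1.0).all()
        assert enr["n_de"].sum() == 0

    def test_hypergeometric_matches_exhaustive_enumeration(self):
        # 12-gene universe, 4 bivalent, 5 DE-up of which 3 bivalent
        states2 = ["Bivalent"] * 4 + ["Active"] * 8
        de_up = ["g0", "g1", "g2", "g5", "g6"]
        table = self._transitions(states2)
        de = pd.DataFrame({"gene_id": de_up, "effect": 1.0, "p": 0.001, "q": 0.01})
        enr = chromstate.integrate_with_de(table, de, direction="up", q_max=0.05)
        got = enr.set_index(["class_type", "class"]).loc[("cond2_state", "Bivalent"), "p"]
        expected = brute_hypergeom_sf(k=3, n_total=12, n_sig=5, n_class=4)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_direction_filter_respects_sign(self):
        table = self._transitions(["Bivalent", "Active"])
        de = pd.DataFrame({"gene_id": ["g0", "g1"], "effect": [-2.0, 2.0],
                           "p": [1e-5, 1e-5], "q": [1e-4, 1e-4]})
        up = chromstate.integrate_with_de(table, de, direction="up")
        down = chromstate.integrate_with_de(table, de, direction="down")
        up_biv = up.set_index(["class_type", "class"]).loc[("cond2_state", "Bivalent"), "n_de"]
        down_biv = down.set_index(["class_type", "class"]).loc[("cond2_state", "Bivalent"), "n_de"]
        assert up_biv == 0 and down_biv == 1

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        states2 = list(rng.choice(STATES, size=40))
        table = self._transitions(states2)
        de = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "effect": rng.normal(size=40),
            "p": rng.random(40),
        })
        de["q"] = np.minimum(de["p"] * 2, 1.0)
        a = chromstate.integrate_with_de(table, de)
        b = chromstate.integrate_with_de(table, de.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a, b)
        assert a["p"].between(0, 1).all() and a["q"].between(0, 1).all()

    def test_bad_q_max_rejected(self):
        table = self._transitions(["Active", "Bivalent"])
        de = pd.DataFrame({"gene_id": ["g0"], "effect": [1.0], "p": [0.01], "q": [0.02]})
        with pytest.raises(ConfigError):
            chromstate.integrate_with_de(table, de, q_max=0.0)
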