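"""Tests of the co-abundance group machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import cagpipe as cp
from cagpipe.cag import CorrelationMatrix, _pearson_of_tau_rows
from cagpipe.io_prep import GenusAbundanceTable

from _oracles import bh_adjust, kendall_tau_b


def rel_table(columns: dict, ids=None) -> GenusAbundanceTable:
    df = pd.DataFrame(columns)
    df.index = ids or [f"s{i}" for i in range(len(df))]
    df = df.div(df.sum(axis=1), axis=0)
    return GenusAbundanceTable(df, "relative")


class TestKendallMatrix:
    def test_perfect_concordance_and_discordance(self):
        table = rel_table(
            {"up": [1.0, 2.0, 3.0], "up2": [2.0, 4.0, 6.0], "down": [3.0, 2.0, 1.0]}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = cp.kendall_matrix(table)
        assert corr.tau.at["up", "up2"] == pytest.approx(1.0)
        assert corr.tau.at["up", "down"] == pytest.approx(-1.0)
        assert corr.tau.at["up", "up"] == 1.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=30)
    def test_ties_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=8).astype(float)
        y = rng.integers(0, 4, size=8).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        df = pd.DataFrame({"x": x + 1, "y": y + 1, "z": rng.random(8) + 0.1})
        df.index = [f"s{i}" for i in range(8)]
        table = GenusAbundanceTable(
            df.div(df.sum(axis=1), axis=0), "relative"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = cp.kendall_matrix(table)
        rel = table.data
        assert corr.tau.at["x", "y"] == pytest.approx(
            kendall_tau_b(rel["x"], rel["y"]), abs=1e-12
        )

    def test_constant_genus_excluded_with_warning(self):
        df = pd.DataFrame(
            {"a": [0.2, 0.3, 0.4, 0.5], "const": [0.5] * 4, "b": [0.3, 0.2, 0.1, 0.0]}
        )
        df["b"] = 1.0 - df["a"] - df["const"]
        table = GenusAbundanceTable(
            df.set_index(pd.Index([f"s{i}" for i in range(4)])), "relative"
        )
        with pytest.warns(UserWarning):
            corr = cp.kendall_matrix(table)
        assert corr.excluded == ["const"]
        assert np.isnan(corr.tau.at["const", "a"])
        assert "const" not in corr.defined_taxa()

    def test_exclude_argument_drops_taxon(self):
        table = rel_table(
            {"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1], "unidentified": [1.0, 3, 2, 4]}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = cp.kendall_matrix(table, exclude=("unidentified",))
        assert "unidentified" not in corr.taxon_ids

    def test_symmetry_and_q_monotone_in_p(self, cohort_corr):
        tau = cohort_corr.tau.to_numpy()
        np.testing.assert_allclose(tau, tau.T, atol=1e-12)
        iu = np.triu_indices(tau.shape[0], k=1)
        p = cohort_corr.p.to_numpy()[iu]
        q = cohort_corr.q.to_numpy()[iu]
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestQvalues:
    def test_all_ones(self):
        np.testing.assert_allclose(cp.estimate_qvalues(np.ones(20)), 1.0)

    def test_empty(self):
        assert cp.estimate_qvalues(np.array([])).size == 0

    def test_small_sets_equal_bh_oracle(self, rng):
        p = rng.random(50)  # below the smoother threshold -> pi0 = 1
        np.testing.assert_allclose(cp.estimate_qvalues(p), bh_adjust(p), atol=1e-12)

    def test_qvalues_bounded_and_order_preserving(self, rng):
        p = rng.random(500) ** 2
        q = cp.estimate_qvalues(p)
        assert (q <= 1.0 + 1e-12).all() and (q >= 0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_no_larger_than_bh(self, rng):
        # pi0 <= 1 can only shrink q relative to plain BH
        p = np.concatenate([rng.random(300) * 0.01, rng.random(300)])
        q = cp.estimate_qvalues(p)
        assert (q <= bh_adjust(p) + 1e-9).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cp.estimate_qvalues(np.array([0.5, 1.5]))


def _corr_from_tau(tau: np.ndarray, ids) -> CorrelationMatrix:
    t = pd.DataFrame(tau, index=ids, columns=ids)
    p = pd.DataFrame(np.zeros_like(tau), index=ids, columns=ids)
    return CorrelationMatrix(tau=t, p=p, q=p.copy())


class TestClusterGenera:
    def test_anti_correlated_blocks_recovered(self):
        ids = [f"g{i}" for i in range(6)]
        tau = np.full((6, 6), 0.8)
        tau[:3, 3:] = -0.8
        tau[3:, :3] = -0.8
        np.fill_diagonal(tau, 1.0)
        part = cp.cluster_genera(_corr_from_tau(tau, ids), k=2)
        labels = part.assignment
        assert labels[ids[0]] == labels[ids[1]] == labels[ids[2]]
        assert labels[ids[3]] == labels[ids[4]] == labels[ids[5]]
        assert labels[ids[0]] != labels[ids[3]]

    def test_k_equals_n_gives_singletons(self):
        ids = [f"g{i}" for i in range(5)]
        rng = np.random.default_rng(0)
        tau = rng.uniform(-0.2, 0.2, (5, 5))
        tau = (tau + tau.T) / 2
        np.fill_diagonal(tau, 1.0)
        part = cp.cluster_genera(_corr_from_tau(tau, ids), k=5)
        assert sorted(part.assignment) == [1, 2, 3, 4, 5]

    def test_k_too_large_rejected(self):
        ids = ["a", "b", "c"]
        tau = np.eye(3)
        with pytest.raises(ValueError, match="exceeds"):
            cp.cluster_genera(_corr_from_tau(tau, ids), k=4)

    def test_pearson_of_tau_rows_matches_brute_force(self, rng):
        t = rng.uniform(-1, 1, (10, 10))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 1.0)
        fast = _pearson_of_tau_rows(t)
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                keep = [k for k in range(10) if k not in (i, j)]
                expect = np.corrcoef(t[i, keep], t[j, keep])[0, 1]
                assert fast[i, j] == pytest.approx(expect, abs=1e-10)

    def test_planted_blocks_recovered_exactly(self, cohort, cohort_corr):
        part = cp.cluster_genera(cohort_corr, k=9)
        truth = [cohort["blocks"].block_of[g] for g in part.assignment.index]
        assert adjusted_rand_score(truth, part.assignment.to_numpy()) == 1.0

    def test_recovery_degrades_as_rho_decreases(self, design):
        md = cp.sample_metadata(design, seed=30)
        aris = []
        for rho in (0.9, 0.0):
            gids = [f"g{i:03d}" for i in range(1, 41)]
            blocks = cp.default_blocks(gids, n_blocks=5, rho_within=rho, effect_size=0.5)
            cfg = cp.GeneratorConfig(n_genera=40, blocks=blocks, seed=30)
            rel = cp.to_relative(cp.sample_genus_counts(cfg, md))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = cp.kendall_matrix(rel)
            part = cp.cluster_genera(corr, k=5)
            truth = [blocks.block_of[g] for g in part.assignment.index]
            aris.append(adjusted_rand_score(truth, part.assignment.to_numpy()))
        assert aris[0] > aris[1]
        assert aris[1] < 0.5  # no latent blocks left to find


class TestLabelCags:
    def test_named_after_dominant_member(self):
        table = rel_table(
            {"Bacteroides": [5.0, 6.0], "minor": [1.0, 1.0], "tiny": [0.5, 0.4]}
        )
        ids = ["Bacteroides", "minor", "tiny"]
        part = cp.cluster_genera(_corr_from_tau(np.eye(3), ids), k=1)
        named = cp.label_cags(part, table)
        assert named.display_name(1) == "Bacteroides CAG"

    def test_singleton_cag_named_after_only_member(self):
        ids = ["solo", "w", "x", "y", "z"]
        tau = np.full((5, 5), 0.9)
        tau[0, 1:] = tau[1:, 0] = 0.0
        np.fill_diagonal(tau, 1.0)
        table = rel_table(
            {
                "solo": [1.0, 2.0],
                "w": [2.0, 3.0],
                "x": [3.0, 4.0],
                "y": [4.0, 5.0],
                "z": [5.0, 6.0],
            }
        )
        part = cp.cluster_genera(_corr_from_tau(tau, ids), k=2)
        named = cp.label_cags(part, table)
        solo_cag = named.assignment["solo"]
        assert part.members(solo_cag) == ["solo"]
        assert named.display_name(solo_cag) == "solo CAG"

    def test_deterministic(self, cohort, cohort_corr):
        a = cp.label_cags(cp.cluster_genera(cohort_corr, k=9), cohort["relative"])
        b = cp.label_cags(cp.cluster_genera(cohort_corr, k=9), cohort["relative"])
        assert a.names == b.names
        pd.testing.assert_series_equal(a.assignment, b.assignment)


class TestTransitionProfiles:
    def _small_inputs(self):
        z = pd.DataFrame(
            {"a": [1.0, -1.0, 0.5, -0.5], "b": [0.2, 0.1, -0.1, -0.2],
             "c": [2.0, -2.0, 1.0, -1.0]},
            index=["s1", "s2", "s3", "s4"],
        )
        assignment = pd.Series([1, 1, 2], index=["a", "b", "c"], name="cag_id")
        part = cp.cag.CAGPartition(assignment=assignment, k=2)
        md = pd.DataFrame(
            {"age_years": [1, 1, 30, 30], "age_group": ["1", "1", "30", "30"]},
            index=z.index,
        )
        return z, part, md

    def test_single_member_cag_equals_its_zscores(self):
        z, part, md = self._small_inputs()
        prof = cp.transition_profiles(z, part, md)
        np.testing.assert_allclose(prof.profile["CAG 2"], z["c"])

    def test_conservation_identity(self):
        z, part, md = self._small_inputs()
        prof = cp.transition_profiles(z, part, md)
        np.testing.assert_allclose(
            prof.profile.sum(axis=1), z.sum(axis=1), atol=1e-9
        )

    def test_conservation_identity_on_cohort(self, cohort, cohort_corr, cohort_zscores):
        part = cp.cluster_genera(cohort_corr, k=9)
        prof = cp.transition_profiles(cohort_zscores, part, cohort["metadata"])
        np.testing.assert_allclose(
            prof.profile.sum(axis=1).to_numpy(),
            cohort_zscores[list(part.assignment.index)].sum(axis=1).to_numpy(),
            atol=1e-9,
        )

    def test_elderly_block_medians_increase_across_life(self, cohort, cohort_zscores):
        blocks = cohort["blocks"]
        elderly_block = next(
            b for b, t in blocks.trend_of.items() if t == "elderly_high"
        )
        members = [g for g, b in blocks.block_of.items() if b == elderly_block]
        assignment = pd.Series(1, index=pd.Index(members, name="taxon_id"))
        part = cp.cag.CAGPartition(assignment=assignment, k=1)
        prof = cp.transition_profiles(
            cohort_zscores[members], part, cohort["metadata"]
        )
        med = prof.group_summary.set_index("age_group")["median"]
        assert med["1"] < med["30"] < med["90"]

    def test_missing_age_group_column_rejected(self):
        z, part, md = self._small_inputs()
        with pytest.raises(ValueError, match="age_group"):
            cp.transition_profiles(z, part, md.drop(columns=["age_group"]))

    def test_outlier_flagging(self):
        vals = [0.0] * 11 + [100.0]
        z = pd.DataFrame({"a": vals}, index=[f"s{i}" for i in range(12)])
        part = cp.cag.CAGPartition(
            assignment=pd.Series([1], index=pd.Index(["a"], name="taxon_id")), k=1
        )
        md = pd.DataFrame(
            {"age_years": [30] * 12, "age_group": ["30"] * 12}, index=z.index
        )
        prof = cp.transition_profiles(z, part, md)
        assert len(prof.outliers) == 1
        assert prof.outliers["severity"].iloc[0] == "extreme"
        assert prof.outliers["sample_id"].iloc[0] == "s11"


class TestNetwork:
    def _corr(self, tau_ab, q_ab=0.01):
        ids = ["a", "b", "c"]
        tau = np.eye(3)
        tau[0, 1] = tau[1, 0] = tau_ab
        q = np.full((3, 3), 0.5)
        q[0, 1] = q[1, 0] = q_ab
        np.fill_diagonal(q, 0.0)
        t = pd.DataFrame(tau, index=ids, columns=ids)
        qd = pd.DataFrame(q, index=ids, columns=ids)
        return CorrelationMatrix(tau=t, p=qd.copy(), q=qd)

    def _table(self):
        return rel_table(
            {"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 5], "c": [1.0, 1, 2, 2]}
        )

    def test_tau_exactly_at_cutoff_excluded(self):
        net = cp.build_network(self._corr(0.30), self._table())
        assert len(net.edges) == 0

    def test_negative_edge_retained(self):
        net = cp.build_network(self._corr(-0.5, q_ab=0.01), self._table())
        assert len(net.edges) == 1
        assert net.edges["sign"].iloc[0] == "negative"
        assert net.summary["n_negative_edges"] == 1

    def test_insignificant_q_excluded(self):
        net = cp.build_network(self._corr(0.9, q_ab=0.2), self._table())
        assert len(net.edges) == 0

    def test_planted_anticorrelated_pair_appears_negative(self):
        rng = np.random.default_rng(8)
        up = rng.random(40) + 0.5
        df = pd.DataFrame(
            {
                "up": up,
                "down": 2.0 - up,  # perfectly anti-correlated
                "noise1": rng.random(40) + 0.5,
                "noise2": rng.random(40) + 0.5,
            },
            index=[f"s{i}" for i in range(40)],
        )
        table = GenusAbundanceTable(df.div(df.sum(axis=1), axis=0), "relative")
        corr = cp.kendall_matrix(table)
        net = cp.build_network(corr, table)
        neg = net.edges[net.edges["sign"] == "negative"]
        pairs = set(map(tuple, neg[["source", "target"]].to_numpy()))
        assert ("down", "up") in pairs or ("up", "down") in pairs

    def test_node_display_restricted_to_prevalent_taxa(self):
        df = pd.DataFrame(
            {"common": [1.0, 1, 1, 1], "rare": [1.0, 0, 0, 0]},
            index=[f"s{i}" for i in range(4)],
        )
        table = GenusAbundanceTable(df.div(df.sum(axis=1), axis=0), "relative")
        ids = ["common", "rare"]
        tau = np.eye(2)
        t = pd.DataFrame(tau, index=ids, columns=ids)
        corr = CorrelationMatrix(tau=t, p=t.copy() * 0, q=t.copy() * 0)
        net = cp.build_network(corr, table)
        assert bool(net.nodes.at["common", "displayed"])
        assert not bool(net.nodes.at["rare", "displayed"])

    def test_null_cohort_produces_fdr_controlled_edges(self, design):
        """With no planted structure, spurious-edge FDP stays below 0.10."""
        md = cp.sample_metadata(design, seed=50)
        fdps = []
        for seed in range(20):
            gids = [f"g{i:03d}" for i in range(1, 51)]
            blocks = cp.default_blocks(
                gids, n_blocks=1, rho_within=0.0, effect_size=0.0,
                trends=("flat",),
            )
            cfg = cp.GeneratorConfig(n_genera=50, blocks=blocks, seed=seed)
            rel = cp.to_relative(cp.sample_genus_counts(cfg, md))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = cp.kendall_matrix(rel)
            net = cp.build_network(corr, rel)
            n_edges = net.summary["n_edges"]
            fdps.append(0.0 if n_edges == 0 else 1.0)  # any edge is false here
        assert np.mean(fdps) <= 0.10
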