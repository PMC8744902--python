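"""Exact PageRank-sensitivity derivative, aggregates and influencer selection."""

import numpy as np
import pandas as pd
import pytest

import regomax as rx
from conftest import make_group_frame, make_planted_instance, random_stochastic, \
    reduced_from_matrix


class TestPerturbation:
    def test_zero_element_is_fixed_point(self):
        GR = np.array([[0.0, 0.4], [1.0, 0.6]])
        assert np.array_equal(rx.perturb_reduced_matrix(GR, 0, 0, 0.3), GR)

    def test_unit_element_is_fixed_point(self):
        GR = np.array([[1.0, 0.4], [0.0, 0.6]])
        out = rx.perturb_reduced_matrix(GR, 0, 0, 0.7)
        assert out[0, 0] == pytest.approx(1.0)

    def test_hand_2x2_column(self):
        GR = np.array([[0.3, 0.6], [0.7, 0.4]])
        out = rx.perturb_reduced_matrix(GR, 0, 1, 0.1)
        assert out[:, 1] == pytest.approx([0.66 / 1.06, 0.4 / 1.06])
        assert np.array_equal(out[:, 0], GR[:, 0])

    @pytest.mark.parametrize("eps", [-0.05, 0.01, 0.3])
    def test_stays_column_stochastic(self, eps):
        rng = np.random.default_rng(8)
        GR = random_stochastic(6, rng)
        out = rx.perturb_reduced_matrix(GR, 2, 4, eps)
        assert out.sum(axis=0) == pytest.approx(np.ones(6), abs=1e-12)


class TestExactDerivative:
    def test_zero_coupling_gives_zero_vector(self):
        GR = np.array([[0.0, 1.0], [1.0, 0.0]])
        rs = reduced_from_matrix(GR)
        assert not rx.pagerank_sensitivity(rs, 0, 0).any()
        assert rx.sensitivity_matrix(rs).D[0, 0] == 0.0

    def test_matches_central_finite_difference(self):
        # oracle: finite-difference quotient of the perturbed PageRank
        rng = np.random.default_rng(42)
        worst = 0.0
        for trial in range(4):
            rs = reduced_from_matrix(random_stochastic(20, rng))
            pairs = rng.integers(0, 20, size=(25, 2))
            for a, b in pairs:
                a, b = int(a), int(b)
                exact = rx.pagerank_sensitivity(rs, a, b)
                eps = 1e-6
                pp = rx.reduced_pagerank(
                    rx.perturb_reduced_matrix(rs.GR, a, b, eps), tol=1e-15)
                pm = rx.reduced_pagerank(
                    rx.perturb_reduced_matrix(rs.GR, a, b, -eps), tol=1e-15)
                fd = (pp - pm) / (2 * eps) / rs.Pr
                worst = max(worst, np.abs(exact - fd).max() / np.abs(exact).max())
        assert worst < 1e-6

    def test_zero_sum_of_weighted_derivative(self):
        rng = np.random.default_rng(1)
        rs = reduced_from_matrix(random_stochastic(12, rng))
        for a, b in [(0, 3), (5, 5), (11, 2)]:
            vec = rx.pagerank_sensitivity(rs, a, b)
            assert abs((vec * rs.Pr).sum()) < 1e-12

    def test_rank_one_closed_form(self):
        # all columns equal to Pr: D[a, b] = (1 - Pr(a)) Pr(b) exactly
        rng = np.random.default_rng(2)
        pr = rng.random(15) + 0.05
        pr /= pr.sum()
        GR = np.tile(pr.reshape(-1, 1), (1, 15))
        rs = reduced_from_matrix(GR)
        D = rx.sensitivity_matrix(rs).D
        closed = (1 - pr[:, None]) * pr[None, :]
        off = ~np.eye(15, dtype=bool)
        assert np.abs(D - closed)[off].max() < 1e-10

    def test_matrix_consistent_with_vector_route(self, reduced500):
        D = rx.sensitivity_matrix(reduced500).D
        rng = np.random.default_rng(3)
        for a, b in rng.integers(0, reduced500.Nr, size=(10, 2)):
            vec = rx.pagerank_sensitivity(reduced500, int(a), int(b))
            assert D[a, b] == pytest.approx(vec[int(a)], abs=1e-12)

    def test_background_proportional_to_source_pagerank(self, reduced500):
        # soft diagnostic: D[a, b] correlates with Pr(b) when Gpr dominates
        D = rx.sensitivity_matrix(reduced500).D
        pr = reduced500.Pr
        off = ~np.eye(reduced500.Nr, dtype=bool)
        corr = np.corrcoef(D[off], np.tile(pr, (reduced500.Nr, 1))[off])[0, 1]
        neg_frac = float((D[off] < 0).mean())
        print(f"D vs Pr(b) correlation {corr:.3f}; negative fraction {neg_frac:.4f}")


class TestAggregates:
    @pytest.fixture(scope="class")
    @staticmethod
    def group54():
        ids = [f"p{i}" for i in range(54)]
        frame = make_group_frame(ids, counts=(4, 20, 20))
        extra = pd.DataFrame(
            dict(Kg=np.arange(45, 55), subgroup="x",
                 subgroup_index=np.arange(1, 11),
                 node_id=ids[44:], protein_name=ids[44:])
        )
        return rx.ProteinGroupTable(pd.concat([frame, extra], ignore_index=True))

    def test_sums_match_brute_force(self, group54):
        rng = np.random.default_rng(9)
        D = rng.normal(size=(54, 54))
        sm = rx.SensitivityMatrix(D=D, Pr=np.full(54, 1 / 54))
        agg = rx.aggregate_sensitivity(sm, group54)
        gf = group54.frame
        ud = gf[gf.subgroup.isin(["u", "d"])].index.to_numpy()
        tx = gf[gf.subgroup.isin(["t", "x"])].index.to_numpy()
        # brute-force double loops
        for _, row in agg.Ds_ud.iterrows():
            b = row["Kg"] - 1
            assert row["Ds_ud"] == pytest.approx(sum(D[a, b] for a in ud))
        for _, row in agg.Ds_TGFbeta.iterrows():
            a = row["Kg"] - 1
            assert row["Ds_TGFbeta"] == pytest.approx(
                sum(D[a, b] for b in range(4))
            )
        assert len(agg.pair_ranking) == len(ud) * len(tx) == 560
        assert (np.diff(agg.pair_ranking["Dab"].to_numpy()) <= 1e-12).all()

    def test_constant_matrix_sums_and_tie_order(self, group54):
        D = np.full((54, 54), 0.25)
        sm = rx.SensitivityMatrix(D=D, Pr=np.full(54, 1 / 54))
        agg = rx.aggregate_sensitivity(sm, group54)
        assert agg.Ds_ud["Ds_ud"].to_numpy() == pytest.approx(np.full(14, 40 * 0.25))
        # ranking degenerates to ascending (Kg_a, Kg_b) tie-break order
        pairs = list(zip(agg.pair_ranking["Kg_a"], agg.pair_ranking["Kg_b"]))
        assert pairs == sorted(pairs)

    def test_size_mismatch_rejected(self, group54):
        sm = rx.SensitivityMatrix(D=np.zeros((10, 10)), Pr=np.full(10, 0.1))
        with pytest.raises(ValueError, match="match"):
            rx.aggregate_sensitivity(sm, group54)


class TestSelectXProteins:
    def test_planted_influencers_recovered(self, planted_instance):
        _, aug, groups, truth = planted_instance
        model = rx.build_google_matrix(aug)
        res = rx.select_x_proteins(aug, model, groups)
        top3 = set(res.ds_5plus5["node_id"].head(3))
        assert len(top3 & set(truth.planted_influencer_ids)) >= 2
        assert set(truth.planted_influencer_ids) <= set(res.selected_ids)
        # extended table gains n_select contiguous Kx rows
        ext = res.groups_extended.frame
        assert len(ext) == 54
        assert (ext["subgroup"].tail(10) == "x").all()

    def test_no_candidates_is_explicit_error(self):
        # closed ring among internals: nothing outside points at the targets
        n = 50
        recs = [(f"g{i}", f"g{(i + 1) % 44}", 1) for i in range(44)]
        recs += [(f"g{i}", f"g{45 + (i + 1) % 5}", 1) for i in range(45, 50)]
        net = rx.SignedDirectedNetwork.from_edge_records(
            recs, nodes=[f"g{i}" for i in range(n)])
        groups = rx.ProteinGroupTable(make_group_frame(net.node_ids)).bind(net)
        model = rx.build_google_matrix(net)
        with pytest.raises(ValueError, match="no external candidates"):
            rx.select_x_proteins(net, model, groups)

    def test_candidates_all_link_into_targets(self, planted_instance):
        _, aug, groups, truth = planted_instance
        model = rx.build_google_matrix(aug)
        res = rx.select_x_proteins(aug, model, groups)
        tgt = {aug.node_index(t) for t in truth.target_ids}
        internal = set(groups.node_indices.tolist())
        for cid in res.candidate_ids:
            j = aug.node_index(cid)
            assert j not in internal
            targets_hit = set(aug.tgt[aug.src == j]) & tgt
            assert targets_hit
        assert res.n_candidate_links >= len(res.candidate_ids)
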