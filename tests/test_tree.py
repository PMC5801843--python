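"""Tree container, I/O, branching times, shared times, pruning, priors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radiate.simulate import SimConfig, sim_tree
from radiate.tree import (
    CalibrationPrior,
    ParseError,
    Phylogeny,
    TreeError,
    branching_times,
    parse_tree,
    prior_quantile,
    prune,
    shared_time_matrix,
)

NEXUS_EXAMPLE = """#NEXUS
[ a comment that must be skipped ]
BEGIN TAXA;
    DIMENSIONS NTAX=3;
    TAXLABELS 'sp one' sp_two sp3;
END;
BEGIN TREES;
    TRANSLATE
        1 'sp one',
        2 sp_two,
        3 sp3
    ;
    TREE t1 = [&R] ((1:1.0,2:1.0):1.0,3:2.0);
END;
"""


class TestParsing:
    def test_two_tip_newick(self):
        t = parse_tree("(A:1,B:1);")
        assert t.n_tips == 2 and t.root_height == pytest.approx(1.0)

    def test_four_tip_newick(self, four_tip_tree):
        t = four_tip_tree
        assert t.n_tips == 4
        assert t.root_height == pytest.approx(3.0)
        assert t.is_ultrametric()
        assert sorted(t.tip_labels) == ["A", "B", "C", "D"]

    def test_nexus_translate_quoted_and_comments(self):
        t = parse_tree(NEXUS_EXAMPLE)
        assert sorted(t.tip_labels) == ["sp one", "sp3", "sp_two"]
        assert t.root_height == pytest.approx(2.0)

    def test_underscores_preserved_verbatim(self):
        t = parse_tree("(Phymaturus_palluma:1,Phymaturus_patagonicus:1);")
        assert "Phymaturus_palluma" in t.tip_labels

    def test_malformed_raises_parse_error(self):
        with pytest.raises(ParseError):
            parse_tree("((A:1,B:1:2;")

    def test_missing_branch_lengths_raise(self):
        with pytest.raises(ParseError):
            parse_tree("((A,B),C);")

    def test_polytomy_resolved_with_warning(self):
        with pytest.warns(UserWarning, match="polytom"):
            t = parse_tree("(A:1,B:1,C:1);")
        assert t.n_tips == 3
        assert all(len(t.children[v]) in (0, 2) for v in range(t.n_nodes))

    def test_slight_age_noise_repaired(self):
        t = parse_tree("((A:1.00001,B:1):2,(C:2,D:2):1);")
        assert t.is_ultrametric()

    def test_gross_non_ultrametricity_refused(self):
        with pytest.raises(TreeError, match="ultrametric"):
            parse_tree("((A:0.5,B:1):2,(C:2,D:2):1);")

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_newick_round_trip(self, seed):
        t = sim_tree(SimConfig(process="yule", lambda0=1.0, n_tips=12),
                     np.random.default_rng(seed))
        t2 = parse_tree(t.to_newick())
        assert sorted(t2.tip_labels) == sorted(t.tip_labels)
        b1, b2 = branching_times(t), branching_times(t2)
        np.testing.assert_allclose(b1.ages, b2.ages, atol=1e-9)
        S1 = shared_time_matrix(t, order=sorted(t.tip_labels))
        S2 = shared_time_matrix(t2, order=sorted(t.tip_labels))
        np.testing.assert_allclose(S1, S2, atol=1e-9)


class TestBranchingTimes:
    def test_four_tip_example(self, four_tip_tree):
        bt = branching_times(four_tip_tree)
        np.testing.assert_allclose(bt.ages, [3.0, 2.0, 1.0])
        assert bt.n_tips == 4

    def test_two_tip_depth_one(self):
        bt = branching_times(parse_tree("(A:1,B:1);"))
        np.testing.assert_allclose(bt.ages, [1.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_summation_oracle(self, seed):
        t = sim_tree(SimConfig(process="yule", lambda0=1.0, n_tips=10),
                     np.random.default_rng(seed))
        # oracle: recompute each internal node's age by summing path lengths
        # from the root independently of the stored depths
        def path_depth(v):
            d = 0.0
            while t.parent[v] >= 0:
                d += t.edge_length[v]
                v = t.parent[v]
            return d
        ages = sorted(
            (t.root_height - path_depth(v) for v in t.internal_nodes), reverse=True
        )
        np.testing.assert_allclose(branching_times(t).ages, ages, atol=1e-12)

    def test_count_and_range_invariant(self):
        for seed in range(5):
            t = sim_tree(SimConfig(process="yule", lambda0=1.0, n_tips=17),
                         np.random.default_rng(seed))
            bt = branching_times(t)
            assert len(bt.ages) == t.n_tips - 1
            assert np.all(bt.ages > 0) and bt.ages[0] == pytest.approx(t.root_height)


class TestSharedTimes:
    def test_star_tree(self):
        with pytest.warns(UserWarning):
            t = parse_tree("(A:2,B:2,C:2);")
        S = shared_time_matrix(t, order=["A", "B", "C"])
        np.testing.assert_allclose(np.diag(S), 2.0)
        np.testing.assert_allclose(S - np.diag(np.diag(S)), 0.0, atol=1e-12)

    def test_four_tip_example(self, four_tip_tree):
        S = shared_time_matrix(four_tip_tree, order=["A", "B", "C", "D"])
        assert S[0, 1] == pytest.approx(2.0)
        assert S[2, 3] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(S), 3.0)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_quadratic_mrca_oracle(self, seed):
        t = sim_tree(SimConfig(process="yule", lambda0=1.0, n_tips=20),
                     np.random.default_rng(seed))
        S = shared_time_matrix(t)
        idx = t.tip_index()
        desc = t.descendant_tips()

        def mrca_depth(a, b):
            # deepest node having both tips below it
            best = 0.0
            for v in t.internal_nodes:
                below = set(int(x) for x in desc[v])
                if a in below and b in below:
                    best = max(best, t.depth[v])
            return best

        labels = t.tip_labels
        for i in range(0, 20, 3):
            for j in range(0, 20, 5):
                if i == j:
                    continue
                a, b = idx[labels[i]], idx[labels[j]]
                assert S[i, j] == pytest.approx(mrca_depth(a, b), abs=1e-10)

    def test_symmetric_positive_semidefinite(self):
        t = sim_tree(SimConfig(process="yule", lambda0=1.0, n_tips=15),
                     np.random.default_rng(9))
        S = shared_time_matrix(t)
        np.testing.assert_allclose(S, S.T)
        assert np.min(np.linalg.eigvalsh(S)) > -1e-9


class TestPrune:
    def test_keep_all_is_identity(self, four_tip_tree):
        p = prune(four_tip_tree, ["A", "B", "C", "D"])
        np.testing.assert_allclose(
            branching_times(p).ages, branching_times(four_tip_tree).ages
        )

    def test_keep_cherry_crowns_at_mrca(self, four_tip_tree):
        p = prune(four_tip_tree, ["A", "B"])
        assert p.n_tips == 2
        # the MRCA of A and B sits at age 1 in this tree
        assert p.root_height == pytest.approx(1.0)

    def test_unknown_species_listed(self, four_tip_tree):
        with pytest.raises(TreeError, match="X"):
            prune(four_tip_tree, ["A", "X"])

    def test_pruned_58_to_41_stays_ultrametric(self, study_fixture):
        tree, traits = study_fixture
        sub = prune(tree, list(traits.index))
        assert sub.n_tips == len(traits)
        assert sub.is_ultrametric()

    @pytest.mark.parametrize("seed", [5, 6])
    def test_branching_times_restrict_to_surviving_mrcas(self, seed):
        rng = np.random.default_rng(seed)
        t = sim_tree(SimConfig(process="yule", lambda0=1.0, n_tips=14), rng)
        keep = sorted(rng.choice(t.tip_labels, 8, replace=False))
        p = prune(t, keep)
        # oracle: MRCA ages of kept-tip pairs recomputed from the full tree
        S = shared_time_matrix(t, order=keep)
        full_mrca_ages = t.root_height - S[np.triu_indices(len(keep), 1)]
        expected = np.sort(np.unique(np.round(full_mrca_ages, 10)))[::-1]
        got = np.sort(np.unique(np.round(branching_times(p).ages, 10)))[::-1]
        np.testing.assert_allclose(got, expected[: len(got)], atol=1e-9)
        assert len(got) == p.n_tips - 1 or len(np.unique(got)) == len(got)


class TestCalibrationPrior:
    def test_published_median_and_upper_bound(self):
        prior = CalibrationPrior(offset=18.5, meanlog=1.0, sdlog=1.5)
        assert prior_quantile(prior, 0.5) == pytest.approx(21.22, abs=5e-3)
        assert prior_quantile(prior, 0.95) == pytest.approx(50.55, abs=5e-3)

    def test_degenerate_sdlog_zero(self):
        prior = CalibrationPrior(offset=10.0, meanlog=0.5, sdlog=0.0)
        for p in (0.01, 0.5, 0.99):
            assert prior.quantile(p) == pytest.approx(10.0 + np.exp(0.5))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_probability(self, p):
        with pytest.raises(ValueError):
            prior_quantile(CalibrationPrior(0.0, 0.0, 1.0), p)

    def test_negative_sdlog_rejected(self):
        with pytest.raises(ValueError):
            CalibrationPrior(0.0, 0.0, -1.0)
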