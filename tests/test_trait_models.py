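"""Body-size data rule, Gaussian trait-model covariances, GLS, fits, ancestors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from radiate.simulate import SimConfig, sim_tree, sim_traits
from radiate.trait_models import (
    ancestral_states,
    fit_trait_models,
    gls_loglik,
    model_vcv,
    species_svl,
)
from radiate.tree import parse_tree, shared_time_matrix

from conftest import scaled_yule


class TestSpeciesSVL:
    def test_upper_two_thirds_rule_single_sex(self):
        raw = pd.DataFrame({"species": "x", "sex": "f", "svl_mm": [90, 96, 102]})
        with pytest.warns(UserWarning, match="single sex"):
            out = species_svl(raw)
        assert out["x"] == pytest.approx(math.log(99.0))

    def test_identical_specimens(self):
        raw = pd.DataFrame({"species": "x", "sex": ["m", "f"], "svl_mm": [88.0, 88.0]})
        assert species_svl(raw)["x"] == pytest.approx(math.log(88.0))

    def test_two_sex_averaging(self):
        raw = pd.DataFrame(
            {"species": "x", "sex": ["m"] * 3 + ["f"] * 3,
             "svl_mm": [80, 90, 100, 70, 80, 90]}
        )
        # males -> mean(90,100)=95; females -> mean(80,90)=85; ln(90)
        assert species_svl(raw)["x"] == pytest.approx(math.log(90.0), abs=1e-12)
        assert species_svl(raw)["x"] == pytest.approx(4.4998, abs=1e-4)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            species_svl(pd.DataFrame({"species": ["x"], "svl_mm": [80]}))


@pytest.fixture(scope="module")
def vcv_tree():
    return scaled_yule(21, n_tips=12, height=5.0)


class TestModelVCV:
    @pytest.fixture
    def tree(self, vcv_tree):
        return vcv_tree

    def test_delta_one_is_bm(self, tree):
        bm = model_vcv(tree, "BM", {"sigma2": 2.0})
        dl = model_vcv(tree, "Delta", {"sigma2": 2.0, "delta": 1.0})
        np.testing.assert_allclose(bm, dl, atol=1e-12)

    def test_eb_limit_is_bm(self, tree):
        bm = model_vcv(tree, "BM", {"sigma2": 1.0})
        eb = model_vcv(tree, "EB", {"sigma2": 1.0, "a": -1e-9})
        np.testing.assert_allclose(eb, bm, atol=1e-6)

    def test_ou_alpha_zero_falls_back_to_bm(self, tree):
        bm = model_vcv(tree, "BM", {"sigma2": 1.0})
        ou = model_vcv(tree, "OU", {"sigma2": 1.0, "alpha": 0.0})
        np.testing.assert_allclose(ou, bm)

    def test_ou_three_tip_hand_formula(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        alpha, s2 = 0.5, 1.3
        V = model_vcv(t, "OU", {"sigma2": s2, "alpha": alpha},
                      S=shared_time_matrix(t, order=["A", "B", "C"]))
        T = 2.0

        def entry(s):
            return s2 / (2 * alpha) * math.exp(-2 * alpha * (T - s)) * (
                1 - math.exp(-2 * alpha * s))

        np.testing.assert_allclose(np.diag(V), entry(2.0))
        assert V[0, 1] == pytest.approx(entry(1.0))
        assert V[0, 2] == pytest.approx(entry(0.0))
        assert V[0, 2] == pytest.approx(0.0, abs=1e-15)

    def test_eb_positive_a_rejected(self, tree):
        with pytest.raises(ValueError):
            model_vcv(tree, "EB", {"a": 0.1})


class TestGLS:
    def test_star_tree_reduces_to_iid_normal(self):
        n, s2 = 7, 0.4
        rng = np.random.default_rng(0)
        z = rng.normal(2.0, 1.0, n)
        logL, z0 = gls_loglik(z, s2 * np.eye(n))
        assert z0 == pytest.approx(z.mean())
        assert logL == pytest.approx(
            stats.norm.logpdf(z, z.mean(), math.sqrt(s2)).sum())

    def test_matches_dense_mvn_oracle(self):
        t = scaled_yule(31, n_tips=5, height=3.0)
        S = shared_time_matrix(t)
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, 5)
        V = 0.7 * S + 0.01 * np.eye(5)
        logL, z0 = gls_loglik(z, V)
        oracle = stats.multivariate_normal.logpdf(z, mean=np.full(5, z0), cov=V)
        assert logL == pytest.approx(oracle, abs=1e-10)

    def test_translation_equivariance(self):
        t = scaled_yule(32, n_tips=8, height=3.0)
        S = shared_time_matrix(t)
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, 8)
        l1, z1 = gls_loglik(z, S)
        l2, z2 = gls_loglik(z + 5.0, S)
        assert l2 == pytest.approx(l1, abs=1e-9)
        assert z2 - z1 == pytest.approx(5.0, abs=1e-9)

    def test_singular_vcv_names_duplicates(self):
        V = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(linalg.LinAlgError, match="near-duplicate|singular"):
            gls_loglik(np.array([0.0, 1.0]), V)


class TestFits:
    def test_aicc_reconstruction_of_published_rows(self):
        from radiate.diversification import aicc
        assert aicc(43.587975, 2, 41) == pytest.approx(-82.86016, abs=5e-6)
        assert aicc(53.605606, 3, 41) == pytest.approx(-100.5625, abs=1e-4)

    def test_bm_data_make_eb_collapse_to_bm(self):
        tree = scaled_yule(41, n_tips=30, height=15.0)
        cfg = SimConfig(trait_model="bm",
                        trait_params={"sigma2": 0.002, "z0": 4.5},
                        missing_fraction=0.0)
        z = sim_traits(tree, cfg, np.random.default_rng(4))
        fits = {f.model: f for f in fit_trait_models(tree, z)}
        assert fits["EB"].a == pytest.approx(0.0, abs=1e-8)
        assert fits["EB"].at_bound
        assert fits["EB"].logL == pytest.approx(fits["BM"].logL, abs=1e-4)

    def test_nesting_over_bm(self, study_fixture):
        tree, traits = study_fixture
        fits = {f.model: f for f in fit_trait_models(tree, traits)}
        for m in ("OU", "EB", "Delta"):
            assert fits[m].logL >= fits["BM"].logL - 1e-6
        ks = {"BM": 2, "OU": 3, "EB": 3, "Delta": 3}
        for m, f in fits.items():
            assert f.k_params == ks[m]

    def test_delta_pinned_at_upper_bound_for_late_burst(self):
        tree = scaled_yule(42, n_tips=30, height=15.0)
        cfg = SimConfig(trait_model="delta",
                        trait_params={"sigma2": 0.002, "delta": 3.0, "z0": 4.5},
                        missing_fraction=0.0)
        z = sim_traits(tree, cfg, np.random.default_rng(5))
        fit = [f for f in fit_trait_models(tree, z) if f.model == "Delta"][0]
        assert fit.delta == pytest.approx(3.0, abs=1e-5)
        assert fit.at_bound

    def test_likelihood_invariant_to_tip_reordering(self, study_fixture):
        tree, traits = study_fixture
        shuffled = traits.sample(frac=1.0, random_state=0)
        a = fit_trait_models(tree, traits)
        b = fit_trait_models(tree, shuffled)
        for fa, fb in zip(a, b):
            assert fa.model == fb.model
            assert fa.logL == pytest.approx(fb.logL, abs=1e-9)


class TestAncestralStates:
    def test_constant_trait(self):
        t = scaled_yule(51, n_tips=6, height=3.0)
        z = pd.Series(1.7, index=t.tip_labels)
        anc = ancestral_states(t, z)
        np.testing.assert_allclose(anc["state"], 1.7, atol=1e-9)
        np.testing.assert_allclose(anc["variance"], 0.0, atol=1e-12)

    def test_two_tip_symmetry(self):
        t = parse_tree("(A:1,B:1);")
        anc = ancestral_states(t, pd.Series({"A": 0.0, "B": 2.0}))
        assert anc["state"].iloc[0] == pytest.approx(1.0)

    def test_root_equals_gls_root(self, study_fixture):
        tree, traits = study_fixture
        sub = tree.prune(list(traits.index))
        S = shared_time_matrix(sub)
        _, z0 = gls_loglik(traits.loc[sub.tip_labels].to_numpy(), S)
        anc = ancestral_states(tree, traits)
        root_row = anc.loc[anc["age"].idxmax()]
        assert root_row["state"] == pytest.approx(z0, abs=1e-9)

    def test_matches_rerooted_gls_oracle(self):
        """ML ancestral state at a node equals the GLS root state of the tree
        re-rooted there; the oracle uses only pairwise path distances."""
        t = scaled_yule(52, n_tips=10, height=4.0)
        rng = np.random.default_rng(6)
        z = pd.Series(rng.normal(0, 1, 10), index=t.tip_labels)
        anc = ancestral_states(t, z)

        # pairwise distances between tips, and node-to-tip distances
        S = shared_time_matrix(t)
        order = t.tip_labels
        zv = z.loc[order].to_numpy()
        depth = t.depth
        for v in t.internal_nodes:
            # distance from node v to each tip via their MRCA
            dv = []
            for lab in order:
                i = t.tip_index()[lab]
                a, anc_set = i, set()
                u = i
                while u >= 0:
                    anc_set.add(u)
                    u = t.parent[u]
                w = int(v)
                while w not in anc_set and w >= 0:
                    w = t.parent[w]
                mrca = w
                dv.append(depth[int(v)] + depth[i] - 2 * depth[mrca])
            dv = np.array(dv)
            D = depth[t.tips][None, :] + depth[t.tips][:, None] - 2 * S
            # shared times with respect to a root placed at v
            Sv = 0.5 * (dv[None, :] + dv[:, None] - D)
            _, z0v = gls_loglik(zv, Sv + 1e-12 * np.eye(len(zv)))
            assert anc.loc[int(v), "state"] == pytest.approx(z0v, abs=1e-6)
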