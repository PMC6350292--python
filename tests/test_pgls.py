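"""Brownian covariance, Pagel's lambda and the GLS fit."""

import numpy as np
import pytest
import scipy.stats as sps

from oxygc.pgls import (
    CONTRASTS,
    DegenerateDesignError,
    EmptyGroupError,
    PhyloCovariance,
    brownian_covariance,
    encode_oxygen,
    lambda_transform,
    log_transform_gc,
    pgls_fit,
)
from oxygc.synthetic import SimulationConfig, simulate_gc_trait, simulate_tree
from oxygc.treekit import read_newick


def mrca_depth_oracle(tree):
    """Independent covariance oracle: explicit per-pair MRCA path walk."""
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]

    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    def depth(node):
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        anc_i = {id(a) for a in path_to_root(leaves[i])}
        C[i, i] = depth(leaves[i])
        for j in range(i + 1, n):
            node = leaves[j]
            while id(node) not in anc_i:
                node = node.parent_node
            C[i, j] = C[j, i] = depth(node)
    return labels, C


class TestCovariance:
    def test_star_tree_identity(self):
        tree = read_newick("(a:1,b:1,c:1,d:1);", rooted=True)
        cov = brownian_covariance(tree)
        np.testing.assert_allclose(cov.C, np.eye(4))

    def test_two_cherry(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);", rooted=True)
        cov = brownian_covariance(tree)
        i = {l: k for k, l in enumerate(cov.labels)}
        assert cov.C[i["a"], i["b"]] == pytest.approx(1.0)
        assert cov.C[i["a"], i["c"]] == pytest.approx(0.0)
        assert cov.C[i["a"], i["a"]] == pytest.approx(2.0)

    @pytest.mark.parametrize("newick", [
        "((((a:1,b:2):1,c:1.5):2,d:4):1,e:0.5);",  # comb
        "((a:1,b:1):2,(c:2,(d:1,e:1):1):1);",
    ])
    def test_matches_mrca_oracle(self, newick):
        tree = read_newick(newick, rooted=True)
        cov = brownian_covariance(tree)
        labels, C = mrca_depth_oracle(read_newick(newick, rooted=True))
        order = [labels.index(l) for l in cov.labels]
        np.testing.assert_allclose(cov.C, C[np.ix_(order, order)], atol=1e-12)

    def test_unrooted_rejected(self):
        tree = read_newick("(a:1,b:1,c:1,d:1);", rooted=False)
        with pytest.raises(ValueError, match="rooted"):
            brownian_covariance(tree)

    def test_invariants_on_random_tree(self):
        cov = brownian_covariance(simulate_tree(20, seed=4))
        C = cov.C
        assert np.allclose(C, C.T)
        off = C - np.diag(np.diag(C))
        assert np.all(off <= np.minimum.outer(np.diag(C), np.diag(C)) + 1e-12)
        assert np.all(C >= 0)


class TestLambdaTransform:
    def setup_method(self):
        self.cov = brownian_covariance(
            read_newick("((a:1,b:1):1,(c:1,d:1):1);", rooted=True)
        )

    def test_identity_at_one(self):
        np.testing.assert_allclose(lambda_transform(self.cov, 1.0).C, self.cov.C)

    def test_diagonal_at_zero(self):
        out = lambda_transform(self.cov, 0.0).C
        np.testing.assert_allclose(out, np.diag(np.diag(self.cov.C)))

    def test_half(self):
        i = {l: k for k, l in enumerate(self.cov.labels)}
        out = lambda_transform(self.cov, 0.5).C
        assert out[i["a"], i["b"]] == pytest.approx(0.5)
        assert out[i["a"], i["a"]] == pytest.approx(2.0)

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_range(self, lam):
        with pytest.raises(ValueError):
            lambda_transform(self.cov, lam)


class TestPGLSFit:
    def test_star_tree_equals_ols(self):
        n = 12
        cov = PhyloCovariance([f"t{i}" for i in range(n)], np.eye(n))
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        fit = pgls_fit(y, x, cov, lambda_mode=1.0)
        ols = sps.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, abs=1e-8)
        assert fit.intercept == pytest.approx(ols.intercept, abs=1e-8)
        assert fit.se_slope == pytest.approx(ols.stderr, abs=1e-8)
        assert fit.p_two_tailed == pytest.approx(ols.pvalue, abs=1e-8)

    def test_lambda_zero_is_ols_on_any_ultrametric_tree(self):
        tree = simulate_tree(15, seed=8)
        cov = brownian_covariance(tree)
        # equal tip depths: lambda=0 gives sigma^2 I, so GLS == OLS
        rng = np.random.default_rng(9)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(size=15)
        fit = pgls_fit(y, x, cov, lambda_mode=0.0)
        ols = sps.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, abs=1e-8)
        assert fit.p_two_tailed == pytest.approx(ols.pvalue, abs=1e-8)

    def test_against_r_nlme_brownian_gls(self):
        """Frozen oracle: R nlme::gls with ape::corBrownian on this exact
        fixture gave intercept 3.562047483558, slope 0.173592051868,
        se 0.034002531429, t 5.105268477800, p 0.002209936445."""
        tree = read_newick(
            "(((a:1,b:1):2,(c:1.5,d:1.5):1.5):1,"
            "((e:1.8,f:1.8):1.2,(g:2.5,h:2.5):0.5):1);",
            rooted=True,
        )
        order = list("abcdefgh")
        x = np.array([2, 2, 3, 3, 2, 3, 3, 2], float)
        y = np.array([3.91, 3.95, 4.10, 4.05, 3.88, 4.02, 4.15, 3.90])
        fit = pgls_fit(y, x, brownian_covariance(tree).subset(order), lambda_mode=1.0)
        assert fit.intercept == pytest.approx(3.562047483558, abs=1e-9)
        assert fit.slope == pytest.approx(0.173592051868, abs=1e-9)
        assert fit.se_slope == pytest.approx(0.034002531429, abs=1e-9)
        assert fit.t == pytest.approx(5.105268477800, abs=1e-8)
        assert fit.p_two_tailed == pytest.approx(0.002209936445, abs=1e-9)

    def test_t_sign_matches_slope_and_p_range(self):
        tree = simulate_tree(25, seed=12)
        cov = brownian_covariance(tree)
        rng = np.random.default_rng(12)
        x = rng.choice([2.0, 3.0], size=25)
        for slope in (-4.0, 4.0):
            y = slope * x + rng.normal(size=25)
            fit = pgls_fit(y, x, cov, lambda_mode="ml")
            assert np.sign(fit.t) == np.sign(fit.slope)
            assert 0.0 <= fit.p_two_tailed <= 1.0
            assert 0.0 <= fit.lambda_hat <= 1.0

    def test_ml_lambda_recovery_extremes(self):
        """lambda=1 data yield high lambda-hat; iid data yield low lambda-hat."""
        tree = simulate_tree(150, seed=33)
        states = dict.fromkeys(
            (lf.taxon.label for lf in tree.leaf_node_iter()), "aerobe"
        )
        for k in list(states)[::2]:
            states[k] = "anaerobe"
        cfg = SimulationConfig(n_tips=150, slope_true=0.0, lambda_true=1.0, seed=33)
        labels, y, x, _ = simulate_gc_trait(tree, states, cfg)
        cov = brownian_covariance(tree)
        assert pgls_fit(y, x, cov, "ml").lambda_hat > 0.8
        cfg0 = SimulationConfig(n_tips=150, slope_true=0.0, lambda_true=0.0, seed=34)
        _, y0, x0, _ = simulate_gc_trait(tree, states, cfg0)
        assert pgls_fit(y0, x0, cov, "ml").lambda_hat < 0.2

    def test_constant_predictor(self):
        cov = PhyloCovariance(list("abc"), np.eye(3))
        with pytest.raises(DegenerateDesignError):
            pgls_fit([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], cov)


class TestEncoding:
    def test_obligate_contrast(self):
        states = {
            "o1": "obligate aerobe", "o2": "obligate aerobe",
            "n1": "obligate anaerobe", "n2": "obligate anaerobe",
            "n3": "obligate anaerobe", "x": "aerobe",
        }
        ids, codes = encode_oxygen(states, "obligate_aerobes vs obligate_anaerobes")
        assert len(ids) == 5 and "x" not in ids
        assert sorted(codes) == [2, 2, 2, 3, 3]

    def test_plain_aerobe_excluded_from_obligate_vs_anaerobe(self):
        states = {"a": "aerobe", "o": "obligate aerobe", "n": "anaerobe"}
        ids, codes = encode_oxygen(states, "obligate_aerobes vs anaerobes")
        assert set(ids) == {"o", "n"}

    def test_empty_group(self):
        with pytest.raises(EmptyGroupError):
            encode_oxygen({"a": "aerobe"}, "obligate_aerobes vs obligate_anaerobes")

    def test_seven_contrasts_defined(self):
        assert len(CONTRASTS) == 7


class TestLogTransform:
    @pytest.mark.parametrize("gc,expected", [(1.0, np.log(100)), (0.5, np.log(50))])
    def test_examples(self, gc, expected):
        assert log_transform_gc(gc) == pytest.approx(expected, abs=1e-5)

    def test_domain_error(self):
        for bad in (0.0, -0.2, 1.2):
            with pytest.raises(ValueError):
                log_transform_gc(bad)

    def test_log10_option(self):
        assert log_transform_gc(0.5, base="10") == pytest.approx(np.log10(50))
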