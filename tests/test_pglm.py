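"""Phylogenetic logistic regression: independence-limit oracle, collinearity
diagnostics, stepwise hierarchy, AICc algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from extirpa.pglm import (aicc, backward_model_selection, build_design,
                          collinearity_screen, fit_phylo_logistic)
from extirpa.synth import simulate_phylogeny, simulate_trait_suite


def firth_logistic_oracle(X: np.ndarray, y: np.ndarray,
                          max_iter: int = 200) -> np.ndarray:
    """Classic Firth bias-reduced logistic regression by IRLS (test oracle)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        M = X.T * W @ X
        Minv = np.linalg.inv(M)
        h = np.einsum("ij,ij->i", (W[:, None] * X) @ Minv, X)
        g = X.T @ (y - mu + h * (0.5 - mu))
        beta = beta + Minv @ g
        if np.max(np.abs(g)) < 1e-12:
            break
    return beta


@pytest.fixture(scope="module")
def sim_data():
    tree = simulate_phylogeny(120, seed=900)
    traits = simulate_trait_suite(tree, seed=901)
    rng = np.random.default_rng(902)
    eta = -0.3 + 1.0 * (traits.growth_form - traits.growth_form.mean())
    y = (rng.random(len(traits)) < expit(eta)).astype(int)
    table = traits.copy()
    table["status"] = y
    return tree, table


class TestIndependenceLimit:
    def test_alpha_inf_matches_firth_oracle(self, sim_data):
        tree, table = sim_data
        design = build_design(table, "status",
                              ["growth_form", "wing_size", "host_specificity"],
                              interactions=False)
        fit = fit_phylo_logistic(tree, design, alpha=np.inf)
        X = np.column_stack([np.ones(len(table)), design.X.to_numpy()])
        oracle = firth_logistic_oracle(X, table["status"].to_numpy(float))
        assert np.max(np.abs(fit.beta.to_numpy() - oracle)) < 1e-4

    def test_star_phylogeny_matches_firth_oracle(self, sim_data):
        _, table = sim_data
        n = len(table)
        # star tree: every pair of tips at the same large distance
        dist = pd.DataFrame(2.0 * (1 - np.eye(n)) * 100.0,
                            index=table.index, columns=table.index)
        design = build_design(table, "status", ["growth_form", "wing_size"],
                              interactions=False)
        # on a star tree all tips are exchangeable; the independence limit
        # (large alpha) is the regime the oracle equivalence refers to
        fit = fit_phylo_logistic(dist, design, alpha=50.0)
        X = np.column_stack([np.ones(n), design.X.to_numpy()])
        oracle = firth_logistic_oracle(X, table["status"].to_numpy(float))
        assert np.max(np.abs(fit.beta.to_numpy() - oracle)) < 1e-4

    def test_separable_data_stays_finite_within_btol(self, sim_data):
        tree, table = sim_data
        sub = table.iloc[:20].copy()
        sub["sep"] = np.arange(20.0)
        sub["status"] = (sub["sep"] > 9).astype(int)  # complete separation
        design = build_design(sub, "status", ["sep"], interactions=False)
        fit = fit_phylo_logistic(tree.prune_to(list(sub.index)), design,
                                 alpha=np.inf)
        assert np.all(np.isfinite(fit.beta))
        X = np.column_stack([np.ones(20), design.X.to_numpy()])
        assert np.max(np.abs(X @ fit.beta.to_numpy())) <= 1000.0

    def test_constant_response_error(self, sim_data):
        tree, table = sim_data
        bad = table.copy()
        bad["status"] = 1
        design = build_design(bad, "status", ["growth_form"], interactions=False)
        with pytest.raises(ValueError, match="constant"):
            fit_phylo_logistic(tree, design)

    def test_singular_design_lists_aliased_columns(self, sim_data):
        tree, table = sim_data
        dup = table.copy()
        dup["copy_gf"] = dup["growth_form"]
        design = build_design(dup, "status", ["growth_form", "copy_gf"],
                              interactions=False)
        with pytest.raises(ValueError, match="aliased"):
            fit_phylo_logistic(tree, design)


class TestDesign:
    def test_default_interaction_exclusions(self, sim_data):
        _, table = sim_data
        design = build_design(
            table, "status",
            ["host_specificity", "growth_form", "geographic_range",
             "color_category", "wing_size"])
        inter = set(design.interaction_terms)
        assert len(inter) == 7  # 10 pairs minus 3 excluded
        for banned in ("wing_size:geographic_range",
                       "geographic_range:wing_size",
                       "growth_form:color_category",
                       "geographic_range:color_category"):
            assert banned not in inter

    def test_drop_main_with_live_interaction_refused(self, sim_data):
        _, table = sim_data
        design = build_design(table, "status", ["growth_form", "wing_size"],
                              interactions=[("growth_form", "wing_size")])
        with pytest.raises(ValueError, match="interactions"):
            design.drop_term("growth_form")


class TestCollinearity:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(3)
        n = 400
        table = pd.DataFrame({
            "a": rng.normal(size=n), "b": rng.normal(size=n),
            "c": rng.normal(size=n), "status": rng.integers(0, 2, n)})
        design = build_design(table, "status", ["a", "b", "c"],
                              interactions=False)
        rep = collinearity_screen(design)
        assert rep.max_abs_rho < 0.15
        assert rep.max_gvif < 1.1

    def test_duplicated_predictor_flagged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": x, "status": (x > 0).astype(int)})
        design = build_design(table, "status", ["a", "b"], interactions=False)
        rep = collinearity_screen(design)
        assert rep.spearman_matrix.loc["a", "b"] == pytest.approx(1.0)
        assert not np.isfinite(rep.max_gvif) or rep.max_gvif > 1e6

    def test_spearman_matches_rank_oracle(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.integers(1, 5, size=(60, 5)).astype(float),
                             columns=list("abcde"))
        table["status"] = rng.integers(0, 2, 60)
        design = build_design(table, "status", list("abcde"),
                              interactions=False)
        rep = collinearity_screen(design)
        from scipy.stats import rankdata

        for i, u in enumerate("abcde"):
            for v in "abcde"[i + 1:]:
                ru, rv = rankdata(table[u]), rankdata(table[v])
                expected = np.corrcoef(ru, rv)[0, 1]
                assert rep.spearman_matrix.loc[u, v] == pytest.approx(
                    expected, abs=1e-12)

    def test_constant_predictor_excluded_with_warning(self):
        table = pd.DataFrame({"a": [1.0] * 30,
                              "b": np.arange(30.0),
                              "c": np.arange(30.0)[::-1],
                              "status": [0, 1] * 15})
        design = build_design(table, "status", ["a", "b", "c"],
                              interactions=False, center=False)
        with pytest.warns(UserWarning, match="constant"):
            rep = collinearity_screen(design)
        assert rep.excluded_constant == ["a"]


class TestStepwise:
    def test_strong_terms_survive_with_no_removals(self):
        tree = simulate_phylogeny(250, seed=910)
        traits = simulate_trait_suite(tree, seed=911)
        rng = np.random.default_rng(912)
        eta = 2.2 * (traits.growth_form - traits.growth_form.mean())
        y = (rng.random(250) < expit(eta)).astype(int)
        table = traits.copy()
        table["status"] = y
        design = build_design(table, "status", ["growth_form"],
                              interactions=False)
        sel = backward_model_selection(tree, design, alpha=np.inf)
        assert sel.removal_log == []
        assert sel.selected_design.terms == ["growth_form"]

    def test_hierarchy_interactions_removed_before_parents(self, sim_data):
        tree, table = sim_data
        design = build_design(table, "status",
                              ["growth_form", "wing_size", "host_specificity"])
        sel = backward_model_selection(tree, design, alpha=np.inf)
        seen_main_drop = {}
        for entry in sel.removal_log:
            if entry["kind"] == "main":
                seen_main_drop[entry["dropped"]] = entry["step"]
            else:
                for parent in entry["dropped"].split(":"):
                    # a parent main effect must not have been dropped earlier
                    assert parent not in seen_main_drop

    def test_null_model_flagged(self):
        rng = np.random.default_rng(913)
        tree = simulate_phylogeny(80, seed=914)
        table = pd.DataFrame({"noise": rng.normal(size=80),
                              "status": rng.integers(0, 2, 80)},
                             index=tree.tip_labels)
        design = build_design(table, "status", ["noise"], interactions=False)
        sel = backward_model_selection(tree, design, alpha=np.inf)
        if sel.reached_null:
            assert sel.selected_design.terms == []
        else:  # noise happened to be significant; removal log stays empty
            assert sel.selected_design.terms == ["noise"]


class TestAICc:
    def test_reduces_to_aic_for_large_n(self):
        ll, k = -123.4, 7
        aic = -2 * ll + 2 * k
        assert abs(aicc(ll, k, 10**6) - aic) < 1e-3

    def test_penalizes_extra_parameters_at_small_n(self):
        assert aicc(-50.0, 6, 30) > aicc(-50.0, 5, 30)

    def test_infinite_when_saturated(self):
        assert aicc(-10.0, 10, 11) == float("inf")


class TestWaldCalibration:
    def test_type_one_error_near_nominal_under_null(self):
        """beta = 0 on random trees: 0.05-level rejection within +/-0.03
        (200 replicates, n = 300 tips, alpha estimated)."""
        ps = []
        for rep in range(200):
            tree = simulate_phylogeny(300, seed=5000 + rep)
            traits = simulate_trait_suite(tree, seed=6000 + rep)
            rng = np.random.default_rng(7000 + rep)
            table = traits.copy()
            table["status"] = rng.integers(0, 2, 300)
            design = build_design(table, "status", ["growth_form"],
                                  interactions=False)
            ps.append(float(fit_phylo_logistic(tree, design).p["growth_form"]))
        rate = float(np.mean(np.asarray(ps) < 0.05))
        assert abs(rate - 0.05) <= 0.03
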