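"""Piecewise SEM: candidate enumeration, fitting, d-separation, ranking,
path effects."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macrosem import (
    GridSpec,
    PsemSpec,
    SimulationConfig,
    build_weights,
    dsep_tests,
    enumerate_candidates,
    fishers_c,
    fit_psem,
    path_effects,
    rank_and_select,
    simulate_structural_cell_table,
)
from macrosem.psem import SATURATED, _basis_set


@pytest.fixture(scope="module")
def fitted_example():
    g = GridSpec(15, 15, 100.0)
    w = build_weights(g, "queen")
    cfg = SimulationConfig(grid_rows=15, grid_cols=15, sar_lambda=0.4,
                           noise_sd=0.3, seed=77)
    table, truth = simulate_structural_cell_table(g, cfg, weights=w)
    spec = PsemSpec(edges=(
        ("aet", "richness"), ("temp_seasonality", "richness"),
        ("temp_seasonality", "mean_dr"), ("mean_dr", "richness"),
    ), name="gen")
    fit = fit_psem(spec, table, w)
    return g, w, table, spec, fit


class TestSpecValidation:
    def test_cyclic_raises(self):
        with pytest.raises(ValueError, match="cyclic"):
            PsemSpec(edges=(("a", "b"), ("b", "a"), ("a", "richness")))

    def test_response_outgoing_edge_raises(self):
        with pytest.raises(ValueError, match="outgoing"):
            PsemSpec(edges=(("richness", "a"), ("a", "b")))

    def test_endogenous_and_exogenous_partition(self):
        s = PsemSpec(edges=(("x", "m"), ("m", "richness"), ("x", "richness")))
        assert s.endogenous == ["m", "richness"]
        assert s.exogenous == ["x"]


class TestEnumeration:
    def test_single_exog_single_endo_three_specs(self):
        specs = enumerate_candidates(["x"], [["m"]], response="richness")
        assert len(specs) == 3
        edge_sets = {frozenset(s.edges) for s in specs}
        assert frozenset({("x", "richness")}) in edge_sets
        assert frozenset({("x", "m"), ("m", "richness")}) in edge_sets
        assert frozenset({("x", "richness"), ("x", "m"), ("m", "richness")}) in edge_sets

    def test_empty_rules_raise(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_candidates([], [], response="richness")

    def test_saturated_spec_present_exactly_once(self):
        specs = enumerate_candidates(["x", "y"], [["m"], ["m"]], response="richness")
        sat = frozenset({
            ("x", "richness"), ("y", "richness"), ("x", "m"), ("y", "m"),
            ("m", "richness"),
        })
        matches = [s for s in specs if frozenset(s.edges) == sat]
        assert len(matches) == 1

    def test_explicit_list_deduplicated(self):
        a = PsemSpec(edges=(("x", "richness"),), name="a")
        b = PsemSpec(edges=(("x", "richness"),), name="b")
        out = enumerate_candidates([], [], explicit=[a, b])
        assert len(out) == 1 and out[0].name == "a"


class TestFitPsem:
    def test_single_equation_aicc_additivity_base_case(self, fitted_example):
        g, w, table, _, _ = fitted_example
        spec = PsemSpec(edges=(("aet", "richness"),), name="one")
        fit = fit_psem(spec, table, w)
        assert len(fit.equations) == 1
        assert fit.total_aicc == fit.equations["richness"].aicc

    def test_total_aicc_additivity(self, fitted_example):
        g, w, table, spec, fit = fitted_example
        # removing the mean_dr equation removes exactly its AICc
        reduced = PsemSpec(
            edges=tuple(e for e in spec.edges if e[1] != "mean_dr"), name="red"
        )
        rfit = fit_psem(reduced, table, w)
        assert fit.total_aicc - rfit.total_aicc == pytest.approx(
            fit.equations["mean_dr"].aicc
        )

    def test_cell_order_permutation_invariance(self, fitted_example):
        g, w, table, spec, fit = fitted_example
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        table_p = table.iloc[perm]
        w_p = build_weights(
            GridSpec(g.n_rows, g.n_cols, g.cell_size,
                     retained=np.asarray(table_p.index)),
            "queen",
        )
        fit_p = fit_psem(spec, table_p, w_p)
        for endo in fit.equations:
            assert np.allclose(
                fit.equations[endo].beta, fit_p.equations[endo].beta, atol=1e-8
            )
            assert fit.equations[endo].lam == pytest.approx(
                fit_p.equations[endo].lam, abs=1e-6
            )

    def test_missing_variable_raises(self, fitted_example):
        g, w, table, *_ = fitted_example
        spec = PsemSpec(edges=(("not_a_column", "richness"),))
        with pytest.raises(KeyError, match="not_a_column"):
            fit_psem(spec, table, w)

    def test_r2_reported_per_equation(self, fitted_example):
        *_, fit = fitted_example
        assert set(fit.r2) == {"richness", "mean_dr"}
        assert all(0.0 <= v <= 1.0 for v in fit.r2.values())


class TestBasisSetAndDsep:
    def test_saturated_dag_empty_basis(self):
        spec = PsemSpec(edges=(
            ("x", "m"), ("y", "m"), ("x", "richness"), ("y", "richness"),
            ("m", "richness"),
        ))
        assert _basis_set(spec) == []

    def test_one_missing_edge_one_claim(self):
        spec = PsemSpec(edges=(
            ("x", "m"), ("y", "m"), ("x", "richness"), ("m", "richness"),
        ))  # only y -> richness missing
        claims = _basis_set(spec)
        assert claims == [("y", "richness")]

    def test_exogenous_pairs_excluded(self):
        spec = PsemSpec(edges=(("x", "richness"), ("y", "richness")))
        assert _basis_set(spec) == []

    def test_fishers_c_hand_value(self):
        c, df, p = fishers_c([0.5, 0.5])
        assert c == pytest.approx(2.7726, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.5966, abs=1e-4)
        assert p == pytest.approx(stats.chi2.sf(-2 * 2 * np.log(0.5), 4))

    def test_zero_p_floored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            c, df, p = fishers_c([0.0, 0.5])
        assert "flooring" in caplog.text
        assert np.isfinite(c)

    def test_saturated_model_yields_marker(self, fitted_example):
        g, w, table, *_ = fitted_example
        sat = PsemSpec(edges=(
            ("aet", "mean_dr"), ("temp_seasonality", "mean_dr"),
            ("aet", "richness"), ("temp_seasonality", "richness"),
            ("mean_dr", "richness"),
        ))
        res = dsep_tests(sat, table, w)
        assert res.saturated
        assert res.marker == SATURATED
        assert res.fisher_c is None  # never reported as zero

    def test_dsep_on_generating_model(self, fitted_example):
        g, w, table, spec, _ = fitted_example
        res = dsep_tests(spec, table, w)
        assert not res.saturated
        assert res.df == 2 * len(res.claims)
        assert 0.0 <= res.p_value <= 1.0


class TestRanking:
    def _dummy_fit(self, name, aicc_value, k):
        spec = PsemSpec(edges=(("x", "richness"),), name=name)

        class Dummy:
            pass

        d = Dummy()
        d.spec = spec
        d.total_aicc = aicc_value
        d.total_k = k
        d.r2 = {}
        d.equations = {"richness": None}
        return d

    def test_delta_aicc(self):
        fits = [self._dummy_fit("a", 10.0, 4), self._dummy_fit("b", 12.5, 4)]
        ranked, best = rank_and_select(fits)
        assert best.spec.name == "a"
        assert list(ranked["delta_aicc"]) == [0.0, 2.5]

    def test_tie_broken_by_fewer_parameters_and_flagged(self):
        fits = [self._dummy_fit("big", 10.0, 6), self._dummy_fit("small", 10.0, 4)]
        ranked, best = rank_and_select(fits)
        assert best.spec.name == "small"
        assert ranked["tied"].all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rank_and_select([])


def brute_force_effects(edges, coefs, response):
    """Exhaustive DFS path enumeration oracle over a small DAG."""
    children = {}
    for a, b in edges:
        children.setdefault(a, []).append(b)

    def all_paths(u):
        if u == response:
            return [[u]]
        return [[u] + rest for v in children.get(u, []) for rest in all_paths(v)]

    out = {}
    nodes = {n for e in edges for n in e} - {response}
    for var in nodes:
        direct = coefs.get((var, response), 0.0)
        indirect = 0.0
        for path in all_paths(var):
            if len(path) <= 2:
                continue
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= coefs[(a, b)]
            indirect += prod
        out[var] = (direct, indirect, direct + indirect)
    return out


class TestPathEffects:
    def _fit_with_coefs(self, edges, coefs):
        """Build a PsemFit-shaped object carrying known coefficients."""
        spec = PsemSpec(edges=tuple(edges), name="t")

        class Eq:
            def __init__(self, parents, endo):
                self.predictors = ["intercept"] + parents
                self._c = {p: coefs[(p, endo)] for p in parents}

            def coefficient(self, name):
                return self._c[name]

        g = spec.graph()
        equations = {
            endo: Eq(sorted(g.predecessors(endo)), endo)
            for endo in spec.endogenous
        }
        from macrosem.psem import PsemFit
        return PsemFit(spec=spec, equations=equations, total_aicc=0.0,
                       total_k=0, r2={})

    def test_chain_rule(self):
        edges = [("x", "m"), ("m", "richness")]
        coefs = {("x", "m"): 0.5, ("m", "richness"): 0.4}
        eff = path_effects(self._fit_with_coefs(edges, coefs))
        assert eff.loc["x", "direct"] == 0.0
        assert eff.loc["x", "indirect"] == pytest.approx(0.2)

    def test_direct_plus_chain(self):
        edges = [("x", "m"), ("m", "richness"), ("x", "richness")]
        coefs = {("x", "m"): 0.5, ("m", "richness"): 0.4, ("x", "richness"): 0.3}
        eff = path_effects(self._fit_with_coefs(edges, coefs))
        assert eff.loc["x", "total"] == pytest.approx(0.3 + 0.2)

    def test_against_brute_force_on_random_dags(self, rng):
        nodes = ["a", "b", "c", "d", "e"]
        for case in range(100):
            r = np.random.default_rng(case)
            order = list(r.permutation(nodes)) + ["richness"]
            edges, coefs = [], {}
            for i, u in enumerate(order[:-1]):
                for v in order[i + 1:]:
                    if r.random() < 0.4:
                        edges.append((u, v))
                        coefs[(u, v)] = float(r.normal())
            if not any(v == "richness" for _, v in edges):
                edges.append((order[0], "richness"))
                coefs[(order[0], "richness")] = 0.1
            # prune nodes with no path to richness from the coef map needs
            # no handling: path_effects only multiplies along real paths
            eff = path_effects(self._fit_with_coefs(edges, coefs))
            oracle = brute_force_effects(edges, coefs, "richness")
            for var, (d, ind, tot) in oracle.items():
                if var not in eff.index:
                    continue
                assert eff.loc[var, "direct"] == pytest.approx(d, abs=1e-10)
                assert eff.loc[var, "indirect"] == pytest.approx(ind, abs=1e-10)
                assert eff.loc[var, "total"] == pytest.approx(tot, abs=1e-10)
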