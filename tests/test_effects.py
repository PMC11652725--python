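"""SEM fitting, adjustment-set identification, effect decomposition, and the
percentage-decline conversion."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aircausal as ac
from aircausal.effects import GROUPS
from aircausal.errors import IdentifiabilityError, OrientationError
from aircausal.simulate import learning_nodes, reference_edges, true_params
from aircausal.structure import Pdag


def _reference_pdag(outcome="log_tac"):
    return Pdag(learning_nodes(outcome), frozenset(reference_edges(outcome)))


class TestFitSem:
    def test_parentless_node_gets_sample_mean(self, small_cohort):
        coeffs = ac.fit_sem(_reference_pdag(), small_cohort)
        assert coeffs.fits["age"].coef == {}
        assert coeffs.fits["age"].intercept == pytest.approx(small_cohort.data["age"].mean())

    def test_recovers_wall_thickness_slope(self, big_cohort, default_cfg):
        coeffs = ac.fit_sem(_reference_pdag(), big_cohort)
        d_hat = coeffs.coef("log_wt", "log_tac")
        # 3 SE bound, SE ~ sigma_t / (sqrt(n) * sd(WT residual))
        se = default_cfg.tac_sd / (np.sqrt(big_cohort.n) * default_cfg.wt_sd)
        assert abs(d_hat - default_cfg.wt_to_tac) < 3 * se

    def test_refit_is_bit_identical_and_residuals_nonnegative(self, small_cohort):
        a = ac.fit_sem(_reference_pdag(), small_cohort)
        b = ac.fit_sem(_reference_pdag(), small_cohort)
        for node in a.fits:
            assert a.fits[node].resid_sd >= 0
            assert a.fits[node].coef == b.fits[node].coef

    def test_matches_statsmodels_ols(self, small_cohort):
        import statsmodels.api as sm

        coeffs = ac.fit_sem(_reference_pdag(), small_cohort)
        df = ac.encode_severity(small_cohort, "dummies").data
        X = sm.add_constant(df[["sev_mild", "sev_moderate", "sev_severe", "bmi", "scanner"]])
        ref = sm.OLS(df["log_wt"], X).fit()
        fit = coeffs.fits["log_wt"]
        assert fit.coef["bmi"] == pytest.approx(ref.params["bmi"], abs=1e-10)
        assert fit.coef["sev_severe"] == pytest.approx(ref.params["sev_severe"], abs=1e-10)
        assert fit.intercept == pytest.approx(ref.params["const"], abs=1e-8)


class TestAdjustmentSets:
    def test_textbook_single_door(self):
        g = nx.DiGraph([("x", "m"), ("m", "y"), ("x", "y")])
        assert ac.single_door_set(g, "x", "y") == ("m",)

    def test_bare_edge_needs_no_adjustment(self):
        g = nx.DiGraph([("x", "y")])
        assert ac.single_door_set(g, "x", "y") == ()

    def test_textbook_back_door(self):
        g = nx.DiGraph([("c", "x"), ("c", "y"), ("x", "y")])
        assert ac.back_door_set(g, "x", "y") == ("c",)

    def test_exogenous_treatment_needs_no_back_door(self):
        g = nx.DiGraph([("x", "m"), ("m", "y"), ("x", "y")])
        assert ac.back_door_set(g, "x", "y") == ()

    def test_reference_graph_sets(self):
        pdag = _reference_pdag()
        sd = ac.single_door_set(pdag, "severity", "log_tac")
        assert "log_wt" in sd and "scanner" in sd
        g = pdag.directed_graph()
        g.remove_edge("severity", "log_tac")
        assert ac.d_separated(g, "severity", "log_tac", set(sd))
        assert ac.back_door_set(pdag, "severity", "log_tac") == ()

    def test_sets_match_exhaustive_search(self):
        """The returned sets are the lexicographically first minimum-cardinality
        admissible sets, per brute force over all subsets."""
        pdag = _reference_pdag()
        g = pdag.directed_graph()
        gm = g.copy()
        gm.remove_edge("severity", "log_tac")
        pool = [v for v in g.nodes if v not in ("severity", "log_tac")]
        admissible = [
            z
            for k in range(len(pool) + 1)
            for z in itertools.combinations(sorted(pool), k)
            if not set(z) & nx.descendants(g, "log_tac")
            and ac.d_separated(gm, "severity", "log_tac", set(z))
        ]
        assert ac.single_door_set(pdag, "severity", "log_tac") == admissible[0]

    def test_missing_edge_is_identifiability_error(self):
        g = nx.DiGraph([("x", "m"), ("m", "y")])
        with pytest.raises(IdentifiabilityError):
            ac.single_door_set(g, "x", "y")

    def test_relevant_undirected_edge_raises(self):
        edges = set(reference_edges("log_tac")) - {("severity", "log_wt")}
        pdag = Pdag(
            learning_nodes("log_tac"),
            frozenset(edges),
            frozenset({frozenset(("severity", "log_wt"))}),
        )
        with pytest.raises(OrientationError):
            ac.single_door_set(pdag, "severity", "log_tac")

    def test_irrelevant_undirected_edge_tolerated(self):
        pdag = Pdag(
            learning_nodes("log_tac"),
            frozenset(reference_edges("log_tac")),
            frozenset({frozenset(("bmi", "log_lung_size"))}),
        )
        sd = ac.single_door_set(pdag, "severity", "log_tac")
        assert "log_wt" in sd


class TestPercentChange:
    @pytest.mark.parametrize(
        "alpha, decline",
        [(-0.047, 4.59), (-0.086, 8.24), (0.0, 0.0)],
    )
    def test_printed_identities(self, alpha, decline):
        assert ac.percent_decline(alpha) == pytest.approx(decline, abs=0.005)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(alpha=st.floats(-3, 3))
    def test_inverse_recovers_coefficient(self, alpha):
        pct = ac.percent_change(alpha)
        assert np.log1p(pct / 100.0) == pytest.approx(alpha, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(-2, 2, 101)
        vals = [ac.percent_change(a) for a in grid]
        assert np.all(np.diff(vals) > 0)


class TestDecomposition:
    def test_population_effects_equal_generator_truth(self, implied, default_cfg):
        truth = true_params(default_cfg)
        for outcome, d_key, i_key in (
            ("log_tac", "direct_tac", "indirect_tac"),
            ("log_tac_p", "direct_tacp", "indirect_tacp"),
        ):
            dec = ac.decompose(_reference_pdag(outcome), implied, outcome=outcome)
            for grp, a, bd in zip(GROUPS, truth[d_key], truth[i_key]):
                assert dec.direct[grp] == pytest.approx(a, abs=1e-10)
                assert dec.indirect[grp] == pytest.approx(bd, abs=1e-10)
                assert abs(dec.consistency_delta[grp]) < 1e-10

    def test_product_method_matches_difference_method_on_samples(self, recovery_runs):
        for pdag, dec in recovery_runs["log_tac"]:
            for grp in GROUPS:
                # both estimate the same mediated effect; 3-SE-scale slack
                assert dec.indirect[grp] == pytest.approx(
                    dec.indirect_difference[grp], abs=0.02
                )

    def test_mediatorless_graph_total_equals_direct(self, implied):
        pdag = Pdag(("severity", "log_tac"), frozenset({("severity", "log_tac")}))
        direct = ac.direct_effect(pdag, implied)
        total = ac.total_effect(pdag, implied)
        for grp in GROUPS:
            assert total[grp] == pytest.approx(direct[grp], abs=1e-10)
        coeffs = ac.fit_sem(pdag, implied)
        with pytest.raises(IdentifiabilityError):
            ac.indirect_effect(coeffs, pdag)

    def test_zero_mediation_slope_gives_zero_indirect(self, implied):
        coeffs = ac.fit_sem(_reference_pdag(), implied)
        coeffs.fits["log_tac"].coef["log_wt"] = 0.0
        ind = ac.indirect_effect(coeffs, _reference_pdag())
        assert all(v == 0.0 for v in ind.values())

    def test_null_direct_effects_recovered_as_zero(self):
        cfg = ac.default_config(n=20_000, seed=13, direct_tac=(0.0, 0.0, 0.0))
        cohort = ac.apply_log_transforms(ac.generate_cohort(cfg))
        dec = ac.decompose(_reference_pdag(), cohort)
        for grp in GROUPS:
            assert abs(dec.direct[grp]) < 0.02  # ~3 SE at this n

    def test_parents_adjustment_agrees_with_minimal_on_reference_graph(self, implied):
        dec = ac.decompose(_reference_pdag(), implied)
        for grp in GROUPS:
            assert dec.direct_parents_adjusted[grp] == pytest.approx(dec.direct[grp], abs=1e-10)

    def test_deterministic_repeat(self, small_cohort):
        a = ac.decompose(_reference_pdag(), small_cohort)
        b = ac.decompose(_reference_pdag(), small_cohort)
        assert a.direct == b.direct and a.indirect == b.indirect and a.total == b.total

    def test_percent_decline_table_signs(self, implied):
        dec = ac.decompose(_reference_pdag(), implied)
        table = dec.percent_declines().set_index("group")
        assert (table[["direct_decline_pct", "indirect_decline_pct"]] > 0).all().all()
        assert table.loc["severe", "direct_decline_pct"] == pytest.approx(
            ac.percent_decline(-0.39), abs=1e-9
        )
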