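import numpy as np
import pytest
from scipy import stats

import phylopaths as pp
from phylopaths.dsep import ClaimResult, DsepFit, average_paths, select_models
from phylopaths.graphs import CausalDAG, IndependenceClaim


class TestFishersC:
    def test_all_pvalues_one(self):
        c, df, p = pp.fishers_c([1.0, 1.0, 1.0])
        assert (c, df, p) == (0.0, 6, 1.0)

    def test_closed_form_pair_of_halves(self):
        c, df, p = pp.fishers_c([0.5, 0.5])
        assert c == pytest.approx(-4 * np.log(0.5), abs=1e-12)
        assert df == 4
        assert p == pytest.approx(stats.chi2.sf(c, 4), abs=1e-12)
        assert p == pytest.approx(0.5966, abs=1e-4)

    def test_empty_claim_list_is_saturated(self):
        assert pp.fishers_c([]) == (0.0, 0, 1.0)

    def test_zero_pvalue_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            c, _, _ = pp.fishers_c([0.0, 0.5])
        assert np.isfinite(c)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            pp.fishers_c([1.5])
        with pytest.raises(ValueError):
            pp.fishers_c([-0.1])

    def test_uniform_pvalues_give_chisquare_distribution(self):
        # with k claims and uniform p-values, C ~ chi-square(2k)
        rng = np.random.default_rng(12)
        k = 12
        draws = [pp.fishers_c(rng.uniform(size=k))[0] for _ in range(10_000)]
        ks = stats.kstest(draws, stats.chi2(2 * k).cdf)
        assert ks.pvalue > 0.01


class TestCICc:
    @pytest.mark.parametrize("C,q,n,expected,places", [
        (16.53, 9, 47, 39.39, 2),
        (11.46, 13, 68, 44.2, 1),
        (32.01, 8, 24, 57.61, 2),
        (16.24, 12, 202, 41.9, 1),
        (15.64, 12, 92, 43.59, 2),
    ])
    def test_published_worked_examples(self, C, q, n, expected, places):
        assert round(pp.cicc(C, q, n), places) == pytest.approx(expected)
        assert pp.cicc(C, q, n) == pytest.approx(expected, abs=0.01)

    def test_zero_parameters(self):
        assert pp.cicc(0.0, 0, 10) == 0.0

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError, match="undefined"):
            pp.cicc(1.0, 9, 10)

    def test_large_n_limit_is_c_plus_2q(self):
        assert pp.cicc(5.0, 7, 10**6) == pytest.approx(5.0 + 14.0, abs=0.01)


def make_fit(model_id, pvals, q, n, vertices=("a", "b", "u"), edges=()):
    dag = CausalDAG(list(vertices), list(edges), name=model_id)
    claims = [
        ClaimResult(
            claim=IndependenceClaim(x="a", y="b", conditioning_set=frozenset(),
                                    response="b"),
            p_value=p, engine="pgls")
        for p in pvals
    ]
    fit = DsepFit(model_id=model_id, model=dag, claims=claims, n=n)
    # q is normally the DAG's edge count; override via a stub model
    fit.model.edges = [("x%d" % i, "y%d" % i) for i in range(q)]
    return fit


class TestSelection:
    def test_delta_from_published_pair(self):
        # two competing bat-visitor models: their CICc difference is 1.4
        c_best = pp.cicc(16.53, 9, 47)
        c_other = pp.cicc(14.68, 10, 47)
        assert round(c_other - c_best, 1) == 1.4

    def test_single_model_table(self):
        fit = make_fit("only", [0.5, 0.5], 3, 30)
        table = select_models([fit])
        assert table.delta[0] == 0.0
        assert table.omega[0] == 1.0
        assert bool(table.supported[0]) == (fit.p >= 0.05)

    def test_equal_cicc_gives_equal_weights(self):
        fits = [make_fit(f"m{i}", [0.5, 0.5], 3, 30) for i in range(3)]
        table = select_models(fits)
        assert np.allclose(table.omega, 1 / 3)
        assert np.allclose(table.delta, 0.0)

    def test_sorted_ascending_and_delta_nonnegative(self):
        fits = [make_fit("weak", [0.01, 0.02], 3, 30),
                make_fit("strong", [0.9, 0.8], 3, 30)]
        table = select_models(fits)
        assert table.fits[0].model_id == "strong"
        assert np.all(np.diff([f.CICc for f in table.fits]) >= 0)
        assert np.all(table.delta >= 0) and table.delta[0] == 0
        assert table.omega.sum() == pytest.approx(1.0)

    def test_weights_invariant_to_cicc_shift(self):
        # adding a constant to every CICc (e.g. through shared claims)
        # leaves the weights unchanged
        fits_a = [make_fit("m1", [0.9], 3, 50), make_fit("m2", [0.4], 3, 50)]
        fits_b = [make_fit("m1", [0.9], 5, 50), make_fit("m2", [0.4], 5, 50)]
        ta, tb = select_models(fits_a), select_models(fits_b)
        assert np.allclose(sorted(ta.omega), sorted(tb.omega), atol=1e-12)

    def test_support_requires_both_rules(self):
        good = make_fit("good", [0.9], 3, 50)
        bad_p = make_fit("bad", [1e-6, 1e-6, 1e-6, 1e-6], 3, 50)
        table = select_models([good, bad_p])
        by_id = {f.model_id: s for f, s in zip(table.fits, table.supported)}
        assert by_id["good"]
        assert not by_id["bad_p" if "bad_p" in by_id else "bad"]

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            select_models([])


class TestAveraging:
    def _table(self, specs, delta_threshold=2.0):
        """specs: list of (model_id, edges, pvals)."""
        fits = []
        for model_id, edges, pvals in specs:
            dag = CausalDAG(["a", "b", "c", "u"], edges, name=model_id)
            claims = [ClaimResult(
                claim=IndependenceClaim(x="a", y="u",
                                        conditioning_set=frozenset(),
                                        response="u"),
                p_value=p, engine="pgls") for p in pvals]
            fits.append(DsepFit(model_id=model_id, model=dag, claims=claims,
                                n=60))
        return select_models(fits, delta_threshold=delta_threshold)

    def test_single_supported_model_is_identity(self):
        table = self._table([("m", [("a", "u")], [0.9])])
        avg = average_paths(table, {"m": {("a", "u"): (0.7, 0.1)}})
        assert avg.beta_avg[("a", "u")] == 0.7
        assert avg.se_avg[("a", "u")] == pytest.approx(0.1)

    def test_equal_weights_average_symmetrically(self):
        table = self._table([
            ("m1", [("a", "u")], [0.5]),
            ("m2", [("a", "u")], [0.5]),
        ])
        avg = average_paths(table, {
            "m1": {("a", "u"): (0.4, 0.1)},
            "m2": {("a", "u"): (0.6, 0.1)},
        })
        assert avg.beta_avg[("a", "u")] == pytest.approx(0.5)

    def test_weighted_mean_and_unconditional_se_match_hand_computation(self):
        # three models with distinct CICc; weights and averages computed
        # by hand from the definition
        specs = [("m1", [("a", "u")], [0.9]),
                 ("m2", [("a", "u")], [0.6]),
                 ("m3", [("a", "u"), ("b", "u")], [0.3])]
        table = self._table(specs, delta_threshold=10.0)
        path_fits = {
            "m1": {("a", "u"): (0.5, 0.10)},
            "m2": {("a", "u"): (0.3, 0.20)},
            "m3": {("a", "u"): (0.8, 0.15), ("b", "u"): (-0.2, 0.30)},
        }
        avg = average_paths(table, path_fits)
        omega = {f.model_id: w for f, w in zip(table.fits, table.omega)}
        w = np.array([omega[m] for m in ("m1", "m2", "m3")])
        w = w / w.sum()
        b = np.array([0.5, 0.3, 0.8])
        expected = float(w @ b)
        assert avg.beta_avg[("a", "u")] == pytest.approx(expected, abs=1e-12)
        s = np.array([0.10, 0.20, 0.15])
        expected_se = float(w @ np.sqrt(s**2 + (b - expected) ** 2))
        assert avg.se_avg[("a", "u")] == pytest.approx(expected_se, abs=1e-12)
        # edge ("b","u") occurs in m3 only: conditional averaging renormalises
        assert avg.beta_avg[("b", "u")] == pytest.approx(-0.2)
        assert avg.contributing_models[("b", "u")] == ["m3"]

    def test_no_supported_models_rejected(self):
        table = self._table([("m", [("a", "u")], [1e-8, 1e-8, 1e-8, 1e-8])])
        with pytest.raises(ValueError, match="supported"):
            average_paths(table, {})


class TestRunDsep:
    def test_claims_counted_and_pvalues_collected(self, small_dataset):
        data, cov = small_dataset
        design = data.to_design()
        fit = pp.run_dsep(data.truth.dag, design, cov)
        n_vertices = len(data.truth.dag.vertices)
        expected_claims = n_vertices * (n_vertices - 1) // 2 - data.truth.dag.q
        assert fit.k == expected_claims
        assert fit.evaluable
        assert all(0 <= p <= 1 for p in fit.claim_pvalues)
        assert fit.n == design.n
        assert fit.CICc >= fit.C

    def test_generating_model_passes_dsep(self):
        # data simulated from the DAG: its independencies hold, so the
        # d-sep p-value is ~uniform and should rarely fall below 0.05
        passes = 0
        for seed in range(6):
            cfg = pp.default_config(seed=700 + seed, n_species=80)
            tree = pp.simulate_tree(80, seed=700 + seed)
            data = pp.simulate_traits(tree, cfg)
            fit = pp.run_dsep(data.truth.dag, data.to_design(), pp.vcv(tree))
            passes += fit.p >= 0.05
        assert passes >= 5

    def test_missing_vertex_rejected(self, small_dataset):
        data, cov = small_dataset
        dag = CausalDAG(["nope", "urban"], [], binary_vertex="urban")
        with pytest.raises(KeyError, match="nope"):
            pp.run_dsep(dag, data.to_design(), cov)
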