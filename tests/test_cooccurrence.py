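import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from camcooccur import cooccurrence as co
from camcooccur.synth import SimulationConfig, simulate_covariates, simulate_detection_data

finite = st.floats(-8, 8, allow_nan=False)


class TestCovariates:
    def test_zscore_values(self):
        tab = co.standardize_covariates(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(tab.data["x"], [-1, 0, 1])
        assert abs(tab.data["x"].mean()) < 1e-12
        assert abs(tab.data["x"].std(ddof=1) - 1) < 1e-12

    def test_standardization_is_idempotent(self):
        x = np.random.default_rng(0).normal(5, 3, 40)
        once = co.standardize_covariates(pd.DataFrame({"x": x}))
        twice = co.standardize_covariates(once.data)
        assert np.allclose(once.data["x"], twice.data["x"], atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="flat"):
            co.standardize_covariates(pd.DataFrame({"flat": [2.0, 2.0, 2.0]}))

    def test_back_transform(self):
        tab = co.standardize_covariates(pd.DataFrame({"x": [10.0, 20.0, 30.0]}))
        assert np.allclose(tab.original("x", tab.data["x"].to_numpy()), [10, 20, 30])


class TestCollinearityScreen:
    def test_monotone_transforms_flagged(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "double": 2 * x + 1, "neg": -x})
        screen = co.screen_collinearity(df)
        by_pair = {frozenset((r.var1, r.var2)): r for r in screen.itertuples()}
        assert by_pair[frozenset(("x", "double"))].rho == pytest.approx(1.0)
        assert by_pair[frozenset(("x", "neg"))].rho == pytest.approx(-1.0)
        assert all(r.flagged for r in by_pair.values())

    def test_boundary_rho_exactly_point_seven(self):
        # rank formula: 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = (0,4,1,1,0) -> 0.7
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [1, 4, 2, 3, 5]})
        screen = co.screen_collinearity(df, threshold=0.7)
        assert screen["rho"].iloc[0] == pytest.approx(0.7)
        assert bool(screen["flagged"].iloc[0])


class TestNaturalParameters:
    def test_symmetric_point(self):
        assert np.allclose(co.natural_to_psi(0, 0, 0), 0.25)

    def test_log3_point(self):
        psi = co.natural_to_psi(np.log(3), 0, 0)[0]
        assert np.allclose(psi, [3 / 8, 3 / 8, 1 / 8, 1 / 8])

    @given(finite, finite, finite)
    def test_normalization_and_roundtrip(self, f1, f2, f12):
        psi = co.natural_to_psi(f1, f2, f12)
        assert psi.min() >= 0
        assert abs(psi.sum() - 1) < 1e-10
        g1, g2, g12 = co.psi_to_natural(psi[0])
        assert np.allclose([g1, g2, g12], [f1, f2, f12], atol=1e-8)

    @given(finite, finite)
    def test_independence_identity_when_f12_zero(self, f1, f2):
        p11, p10, p01, p00 = co.natural_to_psi(f1, f2, 0.0)[0]
        assert p11 * p00 == pytest.approx(p10 * p01, abs=1e-12)

    def test_infinite_input_rejected(self):
        with pytest.raises(ValueError):
            co.natural_to_psi(np.inf, 0, 0)


def brute_force_loglik(y1, y2, p1, p2, psi):
    """Enumerate the four latent states explicitly."""
    total = 0.0
    for z1, z2, cell in ((1, 1, psi[0]), (1, 0, psi[1]), (0, 1, psi[2]), (0, 0, psi[3])):
        lik = cell
        for y, z, p in ((y1, z1, p1), (y2, z2, p2)):
            for yj, pj in zip(y, p):
                if np.isnan(yj):
                    continue
                if z == 1:
                    lik *= pj if yj == 1 else (1 - pj)
                elif yj == 1:
                    lik *= 0.0
        total += lik
    return np.log(total)


class TestSiteLikelihood:
    def test_uninformative_history_has_likelihood_one(self):
        y = {1: [0.0, 0.0], 2: [0.0, 0.0]}
        p = {1: [0.0, 0.0], 2: [0.0, 0.0]}
        assert co.site_loglik(y, p, [0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.0)

    def test_detection_forces_presence_states(self):
        # a species-1 detection zeroes the z1=0 terms, so only psi11+psi10 remain
        y = {1: [1.0], 2: [0.0]}
        p = {1: [1.0], 2: [0.0]}
        psi = [0.1, 0.2, 0.3, 0.4]
        assert co.site_loglik(y, p, psi) == pytest.approx(np.log(0.1 + 0.2))

    def test_matches_latent_state_enumeration(self):
        """Exhaustive check over every 2^(2J) history for J <= 3 occasions."""
        rng = np.random.default_rng(5)
        for J in (1, 2, 3):
            p1 = rng.uniform(0.1, 0.9, J)
            p2 = rng.uniform(0.1, 0.9, J)
            psi = rng.dirichlet(np.ones(4))
            for y1 in itertools.product((0.0, 1.0), repeat=J):
                for y2 in itertools.product((0.0, 1.0), repeat=J):
                    got = co.site_loglik({1: y1, 2: y2}, {1: p1, 2: p2}, psi)
                    want = brute_force_loglik(y1, y2, p1, p2, psi)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_missing_occasions_are_excluded(self):
        full = co.site_loglik({1: [1.0], 2: [0.0]}, {1: [0.5], 2: [0.5]}, [0.25] * 4)
        padded = co.site_loglik(
            {1: [1.0, np.nan], 2: [0.0, np.nan]}, {1: [0.5, 0.5], 2: [0.5, 0.5]}, [0.25] * 4
        )
        assert padded == pytest.approx(full)


class TestWaldCI:
    def test_zero_se_degenerates(self):
        assert co.wald_ci(3.0, 0.0) == (3.0, 3.0)

    def test_point_ninetyfive_uses_1_96(self):
        lo, hi = co.wald_ci(0.0, 1.0)
        assert (lo, hi) == (-1.96, 1.96)

    def test_other_levels_use_normal_quantile(self):
        lo, hi = co.wald_ci(0.0, 1.0, level=0.90)
        assert hi == pytest.approx(1.6449, abs=1e-4)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            co.wald_ci(0.0, -1.0)


def _dummy_model(label, aic, k=5):
    spec = co.ModelSpec(label)
    return co.TwoSpeciesModel(
        spec=spec, param_names=[], estimates=np.array([]), se=np.array([]),
        loglik=-(aic - 2 * k) / 2, k=k, aic=aic, converged=True, n_sites=10,
    )


class TestModelTable:
    def test_single_model(self):
        tab = co.model_table([_dummy_model("only", 100.0)])
        assert tab["dAIC"].iloc[0] == 0 and tab["weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_closed_form(self):
        tab = co.model_table([_dummy_model(s, a) for s, a in [("a", 10), ("b", 12), ("c", 14)]])
        w = np.exp([0, -1, -2])
        assert np.allclose(tab["weight"], w / w.sum())
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_nonconverged_excluded_and_duplicates_rejected(self):
        bad = _dummy_model("bad", 5.0)
        bad.converged = False
        tab = co.model_table([_dummy_model("ok", 10.0), bad])
        assert list(tab["model"]) == ["ok"]
        with pytest.raises(ValueError, match="duplicate"):
            co.model_table([_dummy_model("same", 1.0), _dummy_model("same", 2.0)])

    def test_aic_ties_broken_by_parameter_count(self):
        tab = co.model_table([_dummy_model("big", 10.0, k=8), _dummy_model("small", 10.0, k=4)])
        assert list(tab["model"]) == ["small", "big"]


def nested_grid_search(machine, lo=-3.0, hi=3.0, coarse=1.0, final=2e-3):
    """Independent optimisation oracle: a coarse full-dimensional grid scan
    followed by shrinking 3^k neighbourhood refinement (diagonal moves
    included, so likelihood ridges do not trap it)."""
    axes = [np.arange(lo, hi + 1e-9, coarse)] * machine.k
    best_theta, best_val = None, np.inf
    for point in itertools.product(*axes):
        v = machine.negloglik(np.array(point))
        if v < best_val:
            best_theta, best_val = np.array(point), v
    step = coarse
    moves = np.array(list(itertools.product((-1, 0, 1), repeat=machine.k)), dtype=float)
    while step > final:
        improved = True
        while improved:
            improved = False
            for mv in moves:
                trial = best_theta + step * mv
                v = machine.negloglik(trial)
                if v < best_val - 1e-12:
                    best_theta, best_val = trial, v
                    improved = True
        step /= 2.0
    return best_theta


@pytest.fixture(scope="module")
def recovery_data():
    cfg = SimulationConfig(
        seed=99, n_stations=50, n_surveys=10, station_use_prob=1.0, occasion_failure_prob=0.0,
        f1={"(Intercept)": 0.5, "tree_cover": 1.0},
        f2={"(Intercept)": -0.5, "plantation_dist": -0.8},
        f12={"(Intercept)": 1.5},
        p1={"(Intercept)": -1.0}, p2={"(Intercept)": -0.6},
    )
    data, truth = simulate_detection_data(cfg, simulate_covariates(cfg))
    return cfg, data, truth


class TestFitting:
    def test_recovers_generating_coefficients(self, recovery_data):
        cfg, data, _ = recovery_data
        spec = co.ModelSpec("gen", f1=("tree_cover",), f2=("plantation_dist",))
        m = co.fit(spec, data)
        assert m.converged and m.k == 7
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * m.k)
        truth = {
            "f1:(Intercept)": 0.5, "f1:tree_cover": 1.0,
            "f2:(Intercept)": -0.5, "f2:plantation_dist": -0.8,
            "f12:(Intercept)": 1.5, "p1:(Intercept)": -1.0, "p2:(Intercept)": -0.6,
        }
        for name, true_val in truth.items():
            assert abs(m.coef(name) - true_val) < 3 * m.coef_se(name) + 0.05

    def test_tiny_dataset_matches_grid_search(self):
        """Intercept-only MLE agrees with a cyclic grid-search oracle."""
        # a fixture where every detection combination occurs, so the MLE is
        # interior and the bounded grid oracle can reach it
        cfg = SimulationConfig(
            seed=2, n_stations=10, n_surveys=1, station_use_prob=1.0, occasion_failure_prob=0.0,
            f1={"(Intercept)": 0.3}, f2={"(Intercept)": 0.2}, f12={"(Intercept)": 0.3},
            p1={"(Intercept)": -0.2}, p2={"(Intercept)": -0.2},
        )
        data, _ = simulate_detection_data(cfg, simulate_covariates(cfg))
        spec = co.ModelSpec("null")
        m = co.fit(spec, data, n_starts=3, seed=0)
        machine = co._LikelihoodMachine(spec, data)
        oracle = nested_grid_search(machine)
        assert machine.negloglik(oracle) == pytest.approx(-m.loglik, abs=1e-4)
        assert np.allclose(m.estimates, oracle, atol=1e-2)

    def test_nested_model_loglik_dominance(self, recovery_data):
        cfg, data, _ = recovery_data
        free = co.fit(co.ModelSpec("free"), data)
        fixed = co.fit(co.ModelSpec("fixed", fix_f12_zero=True), data)
        assert free.loglik >= fixed.loglik - 1e-6
        assert fixed.k == free.k - 1

    def test_species_relabelling_symmetry(self, recovery_data):
        """Swapping the species pair swaps the marginal occupancies."""
        cfg, data, _ = recovery_data
        m = co.fit(co.ModelSpec("a", f1=("tree_cover",), f2=("plantation_dist",)), data)
        import copy

        swapped = copy.copy(data)
        swapped.species_pair = (data.species_pair[1], data.species_pair[0])
        m2 = co.fit(co.ModelSpec("b", f1=("plantation_dist",), f2=("tree_cover",)), swapped)
        pred = co.predict_occupancy(m, data.site_covariates)
        pred2 = co.predict_occupancy(m2, data.site_covariates)
        assert np.allclose(pred["marginal1"], pred2["marginal2"], atol=1e-3)
        assert np.allclose(pred["marginal2"], pred2["marginal1"], atol=1e-3)

    def test_missing_covariate_rejected(self, recovery_data):
        _, data, _ = recovery_data
        with pytest.raises(ValueError, match="nonexistent"):
            co.fit(co.ModelSpec("bad", f1=("nonexistent",)), data)

    def test_spec_limits_occupancy_covariates(self):
        with pytest.raises(ValueError):
            co.ModelSpec("x", f1=("a", "b"))
        with pytest.raises(ValueError):
            co.ModelSpec("x", f12=("a",), fix_f12_zero=True)


class TestPrediction:
    def _intercept_model(self, f12_value, fix=False):
        spec = co.ModelSpec("m", fix_f12_zero=fix)
        names = ["f1:(Intercept)", "f2:(Intercept)"] + ([] if fix else ["f12:(Intercept)"])
        est = [0.0, 0.0] + ([] if fix else [f12_value])
        return co.TwoSpeciesModel(
            spec=spec, param_names=names, estimates=np.array(est, float),
            se=np.full(len(est), 0.1), loglik=0.0, k=len(est), aic=0.0,
            converged=True, n_sites=1,
        )

    def test_conditional_equals_marginal_under_independence(self):
        m = self._intercept_model(0.0, fix=True)
        grid = pd.DataFrame(index=range(3)).assign(dummy=0.0)
        out = co.predict_occupancy(m, grid)
        assert np.allclose(out["psi1_given_2"], out["marginal1"])
        assert np.allclose(out["psi1_given_not2"], out["marginal1"])

    def test_positive_association_raises_conditional(self):
        out = co.predict_occupancy(self._intercept_model(2.56), pd.DataFrame({"d": [0.0]}))
        assert out["psi1_given_2"].iloc[0] == pytest.approx(expit(2.56), abs=1e-12)
        assert out["psi1_given_2"].iloc[0] > out["psi1_given_not2"].iloc[0]
        psi_cols = out[["psi11", "psi10", "psi01", "psi00"]].to_numpy()
        assert psi_cols.sum() == pytest.approx(1.0, abs=1e-10)
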