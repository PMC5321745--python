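"""Turnover events, transition probabilities, rate estimation, the
hierarchical turnover model and the detection GLMs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import make_landscape
from metacap.capacity import SpomParams
from metacap.landscape import OccupancyHistory, quality_index
from metacap.turnover import (contingency_chi2, extract_events,
                              fit_detection_models, fit_turnover_glmm,
                              glmm_records, standardize,
                              transition_probabilities, turnover_rate)


class TestExtractEvents:
    def test_hand_enumeration(self):
        # p1: 1,0,1  p2: 0,0,1 -> 1 extinction of 1 opp; 2 colonizations of 3 opps
        occ = np.array([[1.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        hist = OccupancyHistory(years=np.arange(3), occupied=occ)
        ev = extract_events(hist)
        ext = ev[ev.state_from == 1]
        col = ev[ev.state_from == 0]
        assert (len(ext), int(ext.event.sum())) == (1, 1)
        assert (len(col), int(col.event.sum())) == (3, 2)
        assert turnover_rate(ev) == pytest.approx(0.75)

    def test_missing_middle_year_drops_transitions(self):
        occ = np.array([[1.0, np.nan, 1.0]])
        hist = OccupancyHistory(years=np.arange(3), occupied=occ)
        assert len(extract_events(hist)) == 0

    def test_event_conservation(self):
        rng = np.random.default_rng(6)
        occ = rng.choice([0.0, 1.0, np.nan], size=(30, 12), p=[0.45, 0.45, 0.1])
        hist = OccupancyHistory(years=np.arange(12), occupied=occ)
        ev = extract_events(hist)
        both = (~np.isnan(occ[:, :-1]) & ~np.isnan(occ[:, 1:])).sum()
        assert len(ev) == both

    def test_static_and_alternating_rates(self):
        static = OccupancyHistory(years=np.arange(4), occupied=np.ones((3, 4)))
        assert turnover_rate(extract_events(static)) == 0.0
        alt = OccupancyHistory(years=np.arange(4),
                               occupied=np.tile([1.0, 0.0], (3, 2)))
        assert turnover_rate(extract_events(alt)) == 1.0


class TestTransitionProbabilities:
    def test_printed_rate_arithmetic(self):
        land = make_landscape([0.0, 1.0])
        q = quality_index(land)  # Q = 0
        params = SpomParams(e=0.38, c=0.11, ex=0.23, im=0.44, em=0.22, alpha=0.93,
                            y=1.40)
        P_col, P_ext = transition_probabilities(land, q, params, np.array([0.0, 1.0]))
        assert P_ext[0] == pytest.approx(1 - np.exp(-0.38), abs=1e-4)  # 0.3161
        # S_1 = 1 * e^{-0.93} with unit areas; scale S to 1 via c check instead:
        assert P_col[1] == 0.0  # no occupied sources for patch 2
        P_col1 = 1 - np.exp(-0.11 * 1.0)
        assert P_col1 == pytest.approx(0.10417, abs=1e-4)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(7)
        land = make_landscape(list(rng.uniform(0, 4, 15)), list(rng.uniform(0, 4, 15)),
                              areas=list(rng.lognormal(-2, 1, 15)))
        q = quality_index(land)
        params = SpomParams.turnover_estimates()
        occ = rng.integers(0, 2, 15).astype(float)
        P_col, P_ext = transition_probabilities(land, q, params, occ)
        assert np.all((P_col >= 0) & (P_col < 1)) and np.all((P_ext > 0) & (P_ext < 1))
        # P_ext decreasing in area, P_col increasing in occupancy
        land_big = make_landscape(list(land.coords[:, 0]), list(land.coords[:, 1]),
                                  areas=list(land.areas * 2))
        _, P_ext_big = transition_probabilities(land_big, q, params, occ)
        assert np.all(P_ext_big < P_ext)
        P_col_full, _ = transition_probabilities(land, q, params, np.ones(15))
        assert np.all(P_col_full >= P_col)


class TestContingency:
    def test_persistence_by_viability_table(self):
        """Extinct-for-5-years counts by viability class: 79/92 below vs
        5/33 above the threshold."""
        out = contingency_chi2([[79, 13], [5, 28]])
        assert out["chi2"] == pytest.approx(55.1, abs=0.05)
        assert out["p"] < 1e-4

    def test_independence_gives_zero(self):
        assert contingency_chi2([[10, 10], [10, 10]])["chi2"] == 0.0

    def test_perfect_association_closed_form(self):
        assert contingency_chi2([[20, 0], [0, 20]])["chi2"] == pytest.approx(40.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            contingency_chi2([[5, 0], [7, 0]])


def simulate_glmm_records(seed, n_net=50, n_years=15, n_patch=20,
                          beta=(0.8, 0.8, 0.25), tau=1.5, rho=0.7, a0=-2.0):
    """Records drawn from the varying-intercepts logistic model itself."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta)
    G2 = n_net * n_patch
    u = tau * rng.standard_normal(n_net * n_years)
    v = rho * rng.standard_normal(G2)
    net = np.repeat(np.arange(n_net), n_patch)
    frames = []
    for t in range(n_years):
        X = rng.standard_normal((G2, 3))
        g1 = net * n_years + t
        eta = a0 + u[g1] + v[np.arange(G2)] + X @ beta
        frames.append(pd.DataFrame({
            "event": (rng.random(G2) < expit(eta)).astype(int),
            "area02": X[:, 0], "connectivity": X[:, 1], "f_S_disp": X[:, 2],
            "network_year": g1, "patch": np.arange(G2),
        }))
    return pd.concat(frames, ignore_index=True)


class TestTurnoverGlmm:
    @pytest.fixture(scope="class")
    def fitted(self):
        rec = simulate_glmm_records(seed=21)
        fit = fit_turnover_glmm(rec, n_warmup=800, n_samples=1200, chains=2, seed=3)
        return rec, fit

    def test_recovers_planted_coefficients(self, fitted):
        _, fit = fitted
        truth = {"area02": 0.8, "connectivity": 0.8, "f_S_disp": 0.25,
                 "tau": 1.5, "rho": 0.7}
        for name, tv in truth.items():
            lo, hi = fit.summary.loc[name, ["ci2.5", "ci97.5"]]
            assert lo - 0.05 <= tv <= hi + 0.05, (name, lo, hi, tv)

    def test_odds_ratio_is_exp_of_median(self, fitted):
        _, fit = fitted
        for name in ("area02", "connectivity", "f_S_disp", "alpha0"):
            assert fit.summary.loc[name, "odds_ratio"] == pytest.approx(
                np.exp(fit.summary.loc[name, "median"]))

    def test_chains_mix(self, fitted):
        _, fit = fitted
        assert fit.diagnostics["max_rhat"] < 1.1

    def test_constant_covariate_centred_at_zero(self):
        rec = simulate_glmm_records(seed=22, n_net=20, n_years=8, n_patch=10,
                                    beta=(0.8, 0.8, 0.0))
        rec["f_S_disp"] = 0.42  # no signal at all
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_turnover_glmm(rec, n_warmup=300, n_samples=400, chains=1, seed=4)
        lo, hi = fit.summary.loc["f_S_disp", ["ci2.5", "ci97.5"]]
        assert lo < 0 < hi

    def test_agrees_with_variational_mixed_glm(self):
        """Independent cross-check: statsmodels' variational Bayes mixed
        logistic model should give fixed effects close to the MCMC fit
        (small dataset so the VB optimisation stays fast)."""
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        rec = simulate_glmm_records(seed=30, n_net=12, n_years=8, n_patch=10,
                                    tau=1.0, rho=0.5)
        fit = fit_turnover_glmm(rec, n_warmup=600, n_samples=900, chains=1, seed=5)
        X = pd.DataFrame({c: standardize(rec[c].to_numpy())
                          for c in ("area02", "connectivity", "f_S_disp")})
        X.insert(0, "const", 1.0)
        g1 = pd.Categorical(rec["network_year"]).codes
        g2 = pd.Categorical(rec["patch"]).codes
        import scipy.sparse as sp
        Z1 = sp.csr_matrix((np.ones(len(rec)), (np.arange(len(rec)), g1)))
        Z2 = sp.csr_matrix((np.ones(len(rec)), (np.arange(len(rec)), g2)))
        exog_vc = sp.hstack([Z1, Z2]).tocsr()
        ident = np.concatenate([np.zeros(Z1.shape[1], int), np.ones(Z2.shape[1], int)])
        model = BinomialBayesMixedGLM(rec["event"].to_numpy(), X.to_numpy(),
                                      exog_vc, ident,
                                      fe_p=10.0, vcp_p=3.0)
        vb = model.fit_vb()
        for i, name in enumerate(["area02", "connectivity", "f_S_disp"]):
            assert vb.fe_mean[1 + i] == pytest.approx(
                fit.summary.loc[name, "median"], abs=0.15)

    def test_glmm_records_assembly(self, small_study):
        cfg, st = small_study
        ev = extract_events(st["observed_history"], st["assignment"])
        rec = glmm_records(ev, st["landscape"], st["observed_history"],
                           cfg.params, state_from=0)
        assert {"area02", "connectivity", "network_year"} <= set(rec.columns)
        assert (rec["state_from"] == 0).all()
        assert rec["area02"].equals(pd.Series(
            st["landscape"].areas[rec["patch"].to_numpy()] ** 0.2,
            index=rec.index, name="area02"))


class TestDetectionModels:
    def test_recovery_and_convergence(self):
        from metacap.synthetic_data import SynthConfig, generate_control_data
        cfg = SynthConfig()
        ctrl = generate_control_data(cfg, n_visits=400, seed=13)
        fits = fit_detection_models(ctrl, seed=13)
        truth = [cfg.detect_intercept, cfg.detect_log_area, cfg.detect_per_group]
        g = fits.group_detection
        for i, tv in enumerate(truth):
            assert abs(g["mean"].iloc[i] - tv) < 3 * g["sd"].iloc[i]
        # larger populations are less likely to be missed entirely
        assert fits.patch_nondetection.loc["total_groups", "mean"] < 0
        # non-detected populations are smaller
        assert fits.population_size.loc["nondetected", "mean"] < 0
        assert fits.diagnostics["max_rhat"] < 1.01

    def test_nondetection_fraction_matches_design(self):
        """Roughly one occupied patch in ten is missed by the main survey
        (consistent with 29/200 = 14.5% being an upper-range outcome)."""
        from metacap.synthetic_data import SynthConfig, generate_control_data
        ctrl = generate_control_data(SynthConfig(), n_visits=4000, seed=1)
        nondet = 1 - ctrl["detected"].mean()
        assert 0.05 < nondet < 0.15
        assert 29 / 200 == pytest.approx(0.145)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_detection_models(pd.DataFrame(columns=["area_ha", "groups_main",
                                                       "groups_total", "detected"]))

    def test_all_detected_flagged(self):
        ctrl = pd.DataFrame({"area_ha": [0.1, 0.2, 0.4, 1.0] * 10,
                             "groups_main": [2, 3, 4, 8] * 10,
                             "groups_total": [2, 3, 4, 8] * 10,
                             "detected": [1] * 40})
        with pytest.warns(UserWarning, match="detected"):
            fits = fit_detection_models(ctrl, seed=2, n_warmup=400, n_samples=600)
        # prior regularization keeps the intercept finite but strongly negative
        assert fits.patch_nondetection.loc["intercept", "mean"] < 0
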