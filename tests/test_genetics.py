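"""Dispersive-genotype frequencies, emigrant/immigrant pools and the
network-level association machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_landscape
from metacap.capacity import SpomParams
from metacap.genetics import (emigrant_freq, fdisp_from_counts, immigrant_freq,
                              network_association, snp_panel_qq)


class TestFdispFromCounts:
    def test_examples(self):
        assert fdisp_from_counts(10, 0, 0, 15).f_disp == 0.0
        assert fdisp_from_counts(0, 5, 5, 15).f_disp == 1.0
        g = fdisp_from_counts(50, 40, 10, 15)
        assert g.f_disp == pytest.approx(0.5)
        assert g.allele_freq_C == pytest.approx(0.30)

    def test_inclusion_rule_strictly_more_than_ten_groups(self):
        assert not fdisp_from_counts(5, 5, 0, 10).included
        assert fdisp_from_counts(5, 5, 0, 11).included

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fdisp_from_counts(0, 0, 0, 5)

    @given(n_AA=st.integers(0, 50), n_CC=st.integers(1, 50))
    @settings(max_examples=30, deadline=None)
    def test_dominance_equals_additive_without_heterozygotes_iff_cc_only(self, n_AA, n_CC):
        """With n_AC = 0, f_disp = n_CC/total while freq_C = n_CC/total as
        well — the two measures coincide exactly on this subfamily."""
        dom = fdisp_from_counts(n_AA, 0, n_CC, 15, model="dominance")
        add = fdisp_from_counts(n_AA, 0, n_CC, 15, model="additive")
        assert dom.f_disp == pytest.approx(add.f_disp)


class TestEmigrantFreq:
    @pytest.mark.parametrize("f,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)])
    def test_examples(self, f, expected):
        assert emigrant_freq(f, 2.0) == pytest.approx(expected, abs=1e-4)

    @given(f=st.floats(0.01, 0.99), Delta=st.floats(1.01, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_monotone_and_identity_at_delta_one(self, f, Delta):
        assert emigrant_freq(f, 1.0) == pytest.approx(f)
        assert emigrant_freq(f, Delta) > f
        assert emigrant_freq(min(f + 0.01, 1), Delta) > emigrant_freq(f, Delta)
        assert emigrant_freq(f, Delta + 0.5) > emigrant_freq(f, Delta)


class TestImmigrantFreq:
    def test_single_source_identity(self):
        land = make_landscape([0.0, 1.0])
        f = np.array([np.nan, 0.6])
        # Delta=1 so the emigrant pool equals the resident frequency
        fS = immigrant_freq(land, f, np.array([0.0, 1.0]),
                            SpomParams(Delta=1.0))
        assert fS[0] == pytest.approx(0.6)

    def test_shared_frequency_independent_of_geometry(self):
        rng = np.random.default_rng(1)
        land = make_landscape(list(rng.uniform(0, 5, 8)), list(rng.uniform(0, 5, 8)),
                              areas=list(rng.lognormal(0, 1, 8)))
        f = np.full(8, 0.4)
        fS = immigrant_freq(land, f, np.ones(8), SpomParams(Delta=2.0))
        np.testing.assert_allclose(fS, emigrant_freq(0.4, 2.0))

    def test_equal_weight_sources_average(self):
        land = make_landscape([0.0, 1.0, -1.0])
        f = np.array([np.nan, 0.5, 0.0])  # emigrant pools 2/3 and 0
        fS = immigrant_freq(land, f, np.array([0.0, 1.0, 1.0]), SpomParams(Delta=2.0))
        assert fS[0] == pytest.approx(1 / 3, abs=1e-9)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(2)
        land = make_landscape(list(rng.uniform(0, 3, 10)), list(rng.uniform(0, 3, 10)),
                              areas=list(rng.lognormal(0, 1, 10)))
        f = rng.uniform(0, 1, 10)
        occ = np.ones(10)
        params = SpomParams(Delta=2.0)
        fS = immigrant_freq(land, f, occ, params)
        f_em = emigrant_freq(f, 2.0)
        assert np.all(fS >= f_em.min() - 1e-12) and np.all(fS <= f_em.max() + 1e-12)

    def test_isolated_target_undefined(self):
        land = make_landscape([0.0, 1.0])
        fS = immigrant_freq(land, np.array([np.nan, 0.5]), np.array([0.0, 0.0]),
                            SpomParams())
        assert np.isnan(fS[0])


def planted_network_table(seed, n=26, a=0.8, b=0.2, noise=0.04):
    rng = np.random.default_rng(seed)
    turnover = rng.uniform(0.02, 0.3, n)
    pooled = rng.lognormal(1.5, 0.8, n)
    f = np.clip(0.25 + a * turnover - b * (np.log10(pooled) - np.log10(pooled).mean())
                + noise * rng.standard_normal(n), 0.01, 0.99)
    lam = rng.uniform(6, 20, n)
    p_lam = np.clip(1 - 5.47 / lam + 0.5 * (f - f.mean())
                    + 0.05 * rng.standard_normal(n), 0, 1)
    return pd.DataFrame({"turnover_rate": turnover, "pooled_area_ha": pooled,
                         "f_disp": f, "lambda_M": lam, "mean_p_lambda": p_lam,
                         "extinct_5y": rng.random(n) < 0.2})


class TestNetworkAssociation:
    def test_planted_effect_signs_and_r2(self):
        hits = 0
        for seed in range(10):
            res = network_association(planted_network_table(seed))
            co = res["freq_on_turnover_area"].params
            if co["turnover_rate"] > 0 and co["log10_pooled_area"] < 0 \
                    and res["R2_freq"] > 0.2:
                hits += 1
        assert hits >= 9

    def test_size_regressions_present(self):
        res = network_association(planted_network_table(1))
        assert 0 <= res["R2_size_joint"] <= 1
        assert res["R2_size_joint"] >= max(res["R2_size_lambda_only"],
                                           res["R2_size_freq_only"]) - 1e-9
        assert "persistence_ttest" in res

    def test_zero_variance_predictor_dropped(self):
        t = planted_network_table(2)
        t["turnover_rate"] = 0.1
        with pytest.warns(UserWarning, match="zero-variance"):
            res = network_association(t)
        assert "turnover_rate" not in res["freq_on_turnover_area"].params.index

    def test_too_few_networks_rejected(self):
        with pytest.raises(ValueError):
            network_association(planted_network_table(3).iloc[:3])


class TestSnpPanelQq:
    def _null_tables(self, seed, n_snps=18, n_networks=26):
        rng = np.random.default_rng(seed)
        base = planted_network_table(seed + 1000, n=n_networks)
        out = {}
        for s in range(n_snps):
            t = base.copy()
            t["allele_freq"] = rng.uniform(0.1, 0.9, n_networks)
            out[f"snp{s}"] = t
        return out

    def test_null_panel_slope_near_one(self):
        qq = snp_panel_qq(self._null_tables(4), seed=0)
        assert 0.7 <= qq["slope"] <= 1.3

    def test_analytic_expected_option(self):
        qq = snp_panel_qq(self._null_tables(5), expected="analytic", seed=0)
        n = len(qq["p_expected"])
        np.testing.assert_allclose(qq["p_expected"], np.arange(1, n + 1) / (n + 1))

    def test_outlier_exclusion_changes_slope_set(self):
        tables = self._null_tables(6)
        # plant one strongly associated SNP
        t = tables["snp0"]
        t["allele_freq"] = np.clip(0.3 + 1.5 * t["turnover_rate"]
                                   + 0.01 * np.random.default_rng(0).standard_normal(len(t)),
                                   0.01, 0.99)
        qq = snp_panel_qq(tables, seed=0)
        assert qq["min_p_snp"] == "snp0"

    def test_needs_three_snps(self):
        with pytest.raises(ValueError):
            snp_panel_qq(dict(list(self._null_tables(7).items())[:2]), seed=0)
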