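"""Dispersive-genotype frequencies and their association with metapopulation
dynamics.

A biallelic SNP (A/C) is associated with flight metabolism and dispersal:
AC and CC carriers disperse faster than AA homozygotes.  ``f_disp`` is the
pooled frequency of the dispersive genotypes in a network sample
(dominance model) or the C-allele frequency (additive model).  Because the
dispersive genotypes emigrate ``Delta`` times faster, their frequency is
enriched among emigrants (``f_tilde``) and hence among the immigrants
arriving at a patch (``f_S_disp``, a connectivity-share weighted average
over source patches).  Network-level regressions relate ``f_disp`` to
population turnover, pooled habitat area and metapopulation size, and a
panel of reference SNPs calibrates those associations against the
population-structure null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class NetworkGenetics:
    """Genotype summary for one network sample."""

    f_disp: float
    allele_freq_C: float
    n_total: int
    included: bool


MIN_FAMILY_GROUPS = 10  # a network sample needs more than this many larval groups


def fdisp_from_counts(n_AA: int, n_AC: int, n_CC: int,
                      n_family_groups: int, model: str = "dominance") -> NetworkGenetics:
    """Dispersive-genotype frequency from genotype counts.

    Dominance model: f_disp = (n_AC + n_CC)/total (AC and CC share the
    high-dispersal phenotype).  Additive model: f_disp = C-allele
    frequency.  ``included`` flags samples from more than
    ``MIN_FAMILY_GROUPS`` larval family groups.
    """
    counts = np.array([n_AA, n_AC, n_CC], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty genotype sample")
    fd = (n_AC + n_CC) / total
    fc = (n_AC + 2 * n_CC) / (2 * total)
    if model == "dominance":
        f = fd
    elif model == "additive":
        f = fc
    else:
        raise ValueError("model must be 'dominance' or 'additive'")
    return NetworkGenetics(f_disp=float(f), allele_freq_C=float(fc),
                           n_total=int(total), included=n_family_groups > MIN_FAMILY_GROUPS)


def emigrant_freq(f, Delta: float = 2.0):
    """Dispersive-genotype frequency among emigrants from a source patch:
    f_tilde = Delta*f / (Delta*f + (1 - f)); dispersive genotypes leave
    ``Delta`` times faster than the sedentary homozygote."""
    f = np.asarray(f, dtype=float)
    if Delta <= 0:
        raise ValueError("Delta must be > 0")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f must lie in [0, 1]")
    out = Delta * f / (Delta * f + (1.0 - f))
    return float(out) if out.ndim == 0 else out


def immigrant_freq(landscape, resident_f, occupancy, params, target=None):
    """Dispersive-genotype frequency among immigrants at each patch.

    ``f^S_i = sum_j w_ij * f_tilde_j`` where ``w_ij`` is source j's share
    of patch i's connectivity:
    ``w_ij = p_j*A_j^em*exp(-alpha*d_ij) / sum_k p_k*A_k^em*exp(-alpha*d_ik)``.
    Patches with zero total connectivity (no occupied sources in reach)
    get NaN.  ``target`` optionally restricts to a subset of patch indices.
    """
    from .capacity import kernel

    f = np.asarray(resident_f, dtype=float)
    p = np.asarray(occupancy, dtype=float)
    f_em = emigrant_freq(np.nan_to_num(f), params.Delta)
    contrib = kernel(landscape.distance_matrix, params.alpha) * \
        (p * landscape.areas ** params.em)[None, :]
    np.fill_diagonal(contrib, 0.0)
    # sources without a defined resident frequency cannot contribute
    contrib[:, np.isnan(f)] = 0.0
    tot = contrib.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fS = np.where(tot > 0, contrib @ f_em / np.maximum(tot, 1e-300), np.nan)
    return fS if target is None else fS[np.asarray(target)]


def pooled_network_genetics(genotypes: pd.DataFrame, snp_id: str,
                            model: str = "dominance") -> pd.DataFrame:
    """Per-network genotype summaries for one SNP from a long-format
    genotype table (network_id, snp_id, n_AA, n_AC, n_CC, n_family_groups)."""
    sub = genotypes[genotypes["snp_id"] == snp_id]
    rows = []
    for _, r in sub.iterrows():
        g = fdisp_from_counts(r["n_AA"], r["n_AC"], r["n_CC"],
                              r["n_family_groups"], model=model)
        rows.append({"network_id": r["network_id"], "f_disp": g.f_disp,
                     "allele_freq_C": g.allele_freq_C, "n_total": g.n_total,
                     "included": g.included})
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X)).fit()


def network_association(network_table: pd.DataFrame, freq_col: str = "f_disp") -> dict:
    """Network-level association regressions for a genotype frequency.

    Expects one row per network with columns ``f_disp`` (or ``freq_col``),
    ``turnover_rate``, ``pooled_area_ha``, ``lambda_M``, ``mean_p_lambda``
    and optionally ``extinct_5y`` (boolean: extinct/apparently extinct for
    at least five years).

    Returns OLS fits of (a) frequency on turnover + log10 pooled area, (b)
    metapopulation size on lambda_M + frequency, (c) the two simple
    regressions of size on each predictor alone, and (d) a two-sample
    t-test of the frequency between persistent and extinct-for-5-years
    networks when the flag column is present.
    """
    t = network_table.copy()
    if len(t) < 4:
        raise ValueError("need at least 4 networks for the association regressions")
    freq = t[freq_col].to_numpy(dtype=float)
    X_a = pd.DataFrame({"turnover_rate": t["turnover_rate"].to_numpy(dtype=float),
                        "log10_pooled_area": np.log10(t["pooled_area_ha"].to_numpy(dtype=float))})
    dropped = [c for c in X_a.columns
               if X_a[c].std() <= 1e-12 * (1 + abs(X_a[c].mean()))]
    if dropped:
        warnings.warn(f"zero-variance predictors dropped: {dropped}")
        X_a = X_a.drop(columns=dropped)
    fit_a = _ols(freq, X_a)
    out = {"freq_on_turnover_area": fit_a,
           "R2_freq": float(fit_a.rsquared),
           "F_freq": float(fit_a.fvalue),
           "p_F_freq": float(fit_a.f_pvalue)}
    if "mean_p_lambda" in t and "lambda_M" in t:
        y = t["mean_p_lambda"].to_numpy(dtype=float)
        fit_b = _ols(y, pd.DataFrame({"lambda_M": t["lambda_M"], freq_col: freq}))
        fit_lam = _ols(y, pd.DataFrame({"lambda_M": t["lambda_M"]}))
        fit_f = _ols(y, pd.DataFrame({freq_col: freq}))
        out.update({
            "size_on_lambda_freq": fit_b,
            "R2_size_joint": float(fit_b.rsquared),
            "R2_size_lambda_only": float(fit_lam.rsquared),
            "R2_size_freq_only": float(fit_f.rsquared),
            "p_size_freq": float(fit_b.pvalues[freq_col]),
        })
    if "extinct_5y" in t:
        ext = t["extinct_5y"].to_numpy(dtype=bool)
        if 0 < ext.sum() < len(t):
            tt = stats.ttest_ind(freq[~ext], freq[ext], equal_var=True)
            out["persistence_ttest"] = {"t": float(tt.statistic), "p": float(tt.pvalue),
                                        "df": len(t) - 2}
    return out


def snp_panel_qq(per_snp_tables: dict[str, pd.DataFrame],
                 statistic: str = "turnover_area_F",
                 n_replicates: int = 100,
                 expected: str = "sampled",
                 outliers: tuple = (),
                 seed: int = 0) -> dict:
    """Compare the panel of per-SNP association p-values with the uniform null.

    For every SNP (key of ``per_snp_tables``) the Fig-2-style regression is
    run on its network table; ``statistic`` selects which p-value enters
    the panel: ``"turnover_area_F"`` (F-test of frequency on
    turnover + area) or ``"size_t"`` (t-test of the frequency coefficient
    in the metapopulation-size regression).  Sorted observed p-values are
    regressed on expected uniform order statistics — by default the mean of
    ``n_replicates`` seeded Uniform(0,1) draws (``expected="sampled"``), or
    the analytic quantiles i/(n+1) (``expected="analytic"``).  The slope is
    reported excluding declared ``outliers``, together with the replicate
    mean and sd of the null slope.
    """
    pvals = {}
    for snp, table in per_snp_tables.items():
        try:
            res = network_association(table, freq_col="allele_freq"
                                      if "allele_freq" in table else "f_disp")
        except (ValueError, KeyError) as err:
            warnings.warn(f"SNP {snp} excluded: {err}")
            continue
        if statistic == "turnover_area_F":
            pvals[snp] = res["p_F_freq"]
        elif statistic == "size_t":
            pvals[snp] = res["p_size_freq"]
        else:
            raise ValueError("unknown statistic")
    if len(pvals) < 3:
        raise ValueError("need at least 3 SNPs with sufficient coverage")
    snps = sorted(pvals, key=pvals.get)
    obs = np.array([pvals[s] for s in snps])
    keep = np.array([s not in outliers for s in snps])
    n = len(obs)
    rng = np.random.default_rng(seed)
    if expected == "sampled":
        draws = np.sort(rng.random((n_replicates, n)), axis=1)
        exp = draws.mean(axis=0)
    elif expected == "analytic":
        exp = np.arange(1, n + 1) / (n + 1)
        draws = np.sort(rng.random((n_replicates, n)), axis=1)
    else:
        raise ValueError("expected must be 'sampled' or 'analytic'")

    def _slope(y, x):
        return float(np.polyfit(x, y, 1)[0])

    slope = _slope(obs[keep], exp[keep])
    rep_slopes = np.array([_slope(np.sort(rng.random(n))[keep], exp[keep])
                           for _ in range(n_replicates)])
    return {
        "snps_sorted": snps,
        "p_observed": obs,
        "p_expected": exp,
        "slope": slope,
        "replicate_slope_mean": float(rep_slopes.mean()),
        "replicate_slope_sd": float(rep_slopes.std(ddof=1)),
        "min_p_snp": snps[0],
    }
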