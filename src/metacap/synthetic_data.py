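"""Synthetic study generator: clustered landscapes, multi-year surveys with
imperfect detection, and network genotype samples.

The generator emulates the statistical structure of a long-term butterfly
metapopulation survey in a highly fragmented landscape: thousands of very
small dry-meadow patches (log-normal areas, median 0.06 ha, ~1% above
2 ha) laid out as a clustered point process; annual presence/absence
surveys driven by the fitted stochastic patch occupancy dynamics; partial
survey coverage in the early years and imperfect detection of small
populations; and network-level genotype samples of a dispersal-associated
SNP whose frequency follows a planted structural equation in population
turnover and pooled habitat area, alongside neutral SNPs independent of
the dynamics.  Every output is a pure function of (config, seed), and a
truth record stores every planted parameter for recovery reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .capacity import SpomParams
from .landscape import Landscape, OccupancyHistory, quality_index
from .networks import NetworkAssignment
from .spom_sim import SimConfig, simulate
from .turnover import extract_events, turnover_rate


@dataclass(frozen=True)
class SynthConfig:
    """Study-generator settings; defaults are the study conditions.

    Landscape: ``n_patches`` offspring of ``n_clusters`` uniformly placed
    parents with Gaussian spread ``cluster_spread_km`` in a
    ``domain_km`` box.  Areas are log-normal with ``median_area_ha`` and
    exceedance ``p_exceed`` above ``exceed_ha`` (sigma solved from the
    exceedance equation).  Survey: ``years`` annual surveys; the first
    ``partial_years`` cover only a random ``coverage`` fraction of
    patches.  Detection: per-larval-group detection is logistic in log
    area and the number of groups present; a patch is recorded occupied
    iff at least one group is found.  Group counts are zero-truncated
    negative binomial with area-scaled mean.  Genetics: the candidate SNP
    frequency follows f = a0 + a1*turnover - a2*log10(pooled area) +
    noise; ``n_neutral_snps`` SNPs are independent of the dynamics.
    """

    n_patches: int = 900
    n_clusters: int = 30
    cluster_spread_km: float = 0.55
    domain_km: tuple = (30.0, 30.0)
    median_area_ha: float = 0.06
    exceed_ha: float = 2.0
    p_exceed: float = 0.01
    params: SpomParams = field(default_factory=SpomParams.turnover_estimates)
    years: int = 22
    burn_in: int = 10
    partial_years: int = 6
    coverage: float = 1 / 3
    detect_intercept: float = 0.8
    detect_log_area: float = 0.2
    detect_per_group: float = 0.3
    groups_mean_at_median: float = 5.0
    groups_area_exp: float = 0.3
    groups_dispersion: float = 0.5
    n_neutral_snps: int = 18
    a0: float = 0.25
    a1_turnover: float = 0.7
    a2_log10_area: float = 0.20
    f_noise_sd: float = 0.04
    groups_per_network: int = 20
    larvae_per_group: int = 3

    def __post_init__(self) -> None:
        if self.n_patches < 1 or self.n_clusters < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if self.p_exceed >= 0.5 and self.exceed_ha > self.median_area_ha:
            raise ValueError("infeasible exceedance: p >= 0.5 above the median")


def lognormal_sigma(median: float, exceed: float, p_exceed: float) -> float:
    """Log-scale sd solved from P(A > exceed) = p_exceed with the given
    median: sigma = (ln exceed - ln median) / z_{1-p}."""
    z = stats.norm.ppf(1 - p_exceed)
    if z <= 0:
        raise ValueError("infeasible exceedance probability")
    return (np.log(exceed) - np.log(median)) / z


def generate_landscape(config: SynthConfig, seed: int = 0,
                       return_assignment: bool = False):
    """Clustered landscape with log-normal areas and random quality.

    Parent points are uniform in the domain; each patch is assigned to a
    parent and offset by an isotropic Gaussian.  With
    ``return_assignment`` the generative cluster labels are returned as a
    :class:`NetworkAssignment` (relabelled contiguously).
    """
    rng = np.random.default_rng(seed)
    parents = rng.uniform((0, 0), config.domain_km, size=(config.n_clusters, 2))
    labels = rng.integers(config.n_clusters, size=config.n_patches)
    xy = parents[labels] + config.cluster_spread_km * rng.standard_normal((config.n_patches, 2))
    sigma = lognormal_sigma(config.median_area_ha, config.exceed_ha, config.p_exceed)
    areas = np.exp(np.log(config.median_area_ha) + sigma * rng.standard_normal(config.n_patches))
    host_probs = np.array([0.15, 0.35, 0.30, 0.20])
    patches = pd.DataFrame({
        "id": [f"p{i}" for i in range(config.n_patches)],
        "x_km": xy[:, 0],
        "y_km": xy[:, 1],
        "area_ha": areas,
        "host_plantago": rng.choice(4, size=config.n_patches, p=host_probs),
        "host_veronica": rng.choice(4, size=config.n_patches,
                                    p=[0.45, 0.30, 0.15, 0.10]),
        "pct_dry": rng.beta(2, 5, config.n_patches),
        "pct_low": rng.beta(2, 3, config.n_patches),
        "pct_grazed": rng.beta(1.2, 4, config.n_patches),
    })
    landscape = Landscape.from_patches(patches)
    if return_assignment:
        codes = pd.factorize(labels)[0]
        return landscape, NetworkAssignment(network_id=codes,
                                            n_networks=codes.max() + 1)
    return landscape


def _zt_negbin(rng, mean, dispersion, size):
    """Zero-truncated negative binomial by rejection of zeros."""
    mean = np.broadcast_to(mean, size).astype(float)
    r = dispersion
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.negative_binomial(r, p[zero] if p.ndim else p, size=zero.sum())
        zero = out == 0
    return out


def _apply_detection(config, landscape, true_hist, rng):
    """Thin the true history through the group-level detection model.

    Occupied patch-years get a zero-truncated negative-binomial group
    count with area-scaled mean; each group is found with a logistic
    detection probability increasing in patch area and group number; the
    patch is recorded occupied iff at least one group is found.  Early
    partial-coverage years mask a random patch subset entirely.
    """
    n, T = true_hist.occupied.shape
    A = landscape.areas
    occ_true = true_hist.occupied == 1
    n_groups = np.zeros((n, T), dtype=int)
    mu = config.groups_mean_at_median * (A / config.median_area_ha) ** config.groups_area_exp
    for t in range(T):
        occ_t = occ_true[:, t]
        if occ_t.any():
            n_groups[occ_t, t] = _zt_negbin(rng, mu[occ_t],
                                            config.groups_dispersion,
                                            (int(occ_t.sum()),))
    eta = (config.detect_intercept + config.detect_log_area * np.log(A)[:, None]
           + config.detect_per_group * n_groups)
    p_det = expit(eta)
    groups_found = rng.binomial(n_groups, np.where(n_groups > 0, p_det, 0.0))
    occ_obs = np.where(occ_true, (groups_found >= 1).astype(float), 0.0)
    ng_obs = groups_found.astype(float)
    # partial survey coverage in the early years
    for t in range(min(config.partial_years, T)):
        unsurveyed = rng.random(n) >= config.coverage
        occ_obs[unsurveyed, t] = np.nan
        ng_obs[unsurveyed, t] = np.nan
    return (OccupancyHistory(years=true_hist.years, occupied=occ_obs, n_groups=ng_obs),
            n_groups)


def _genotype_counts(rng, freq_C, n_individuals):
    """Hardy-Weinberg genotype counts at a given C-allele frequency."""
    probs = np.array([(1 - freq_C) ** 2, 2 * freq_C * (1 - freq_C), freq_C**2])
    return rng.multinomial(n_individuals, probs)


def generate_study(config: SynthConfig, seed: int = 0) -> dict:
    """Generate a complete synthetic study.

    Returns a dict with the landscape, the network assignment, the true
    and observed occupancy histories, the genotype table (long format:
    one row per network per SNP), and a ``truth`` record of every planted
    parameter.  The occupancy process is burned in for ``config.burn_in``
    years from random initial occupancy before the survey window starts.
    """
    rng = np.random.default_rng(seed)
    landscape, assignment = generate_landscape(config, seed=int(rng.integers(2**31)),
                                               return_assignment=True)
    q = quality_index(landscape)
    sim_cfg = SimConfig(params=config.params,
                        years=config.years + config.burn_in,
                        init_occupancy="random-p", init_p=0.5,
                        seed=int(rng.integers(2**31)))
    sim = simulate(landscape, q, sim_cfg)
    occ_true = sim.history.occupied[:, config.burn_in:]
    true_hist = OccupancyHistory(years=np.arange(config.years), occupied=occ_true)
    observed, n_groups_true = _apply_detection(config, landscape, true_hist, rng)

    # --- network-level genotype frequencies with the planted structure
    events = extract_events(true_hist, assignment)
    tr = turnover_rate(events, per="network")
    pooled = np.array([landscape.areas[assignment.members(k)].sum()
                       for k in range(assignment.n_networks)])
    turn = tr.reindex(range(assignment.n_networks)).to_numpy(dtype=float)
    turn = np.nan_to_num(turn, nan=np.nanmean(turn))
    log_area_c = np.log10(pooled) - np.mean(np.log10(pooled))
    f_true = np.clip(config.a0 + config.a1_turnover * turn
                     - config.a2_log10_area * log_area_c
                     + config.f_noise_sd * rng.standard_normal(assignment.n_networks),
                     0.02, 0.98)
    n_ind = config.groups_per_network * config.larvae_per_group
    rows = []
    for k in range(assignment.n_networks):
        freq_C = 1.0 - np.sqrt(1.0 - f_true[k])  # dominance-consistent HW allele freq
        nAA, nAC, nCC = _genotype_counts(rng, freq_C, n_ind)
        rows.append({"network_id": k, "snp_id": "candidate", "n_AA": nAA,
                     "n_AC": nAC, "n_CC": nCC,
                     "n_family_groups": config.groups_per_network})
    for s in range(config.n_neutral_snps):
        mu = rng.uniform(0.15, 0.85)
        kappa = 60.0  # within-SNP between-network concentration
        for k in range(assignment.n_networks):
            fk = rng.beta(mu * kappa, (1 - mu) * kappa)
            nAA, nAC, nCC = _genotype_counts(rng, fk, n_ind)
            rows.append({"network_id": k, "snp_id": f"neutral_{s}", "n_AA": nAA,
                         "n_AC": nAC, "n_CC": nCC,
                         "n_family_groups": config.groups_per_network})
    genotypes = pd.DataFrame(rows)
    truth = {
        "params": config.params,
        "a0": config.a0, "a1_turnover": config.a1_turnover,
        "a2_log10_area": config.a2_log10_area,
        "f_noise_sd": config.f_noise_sd,
        "f_disp_true": f_true,
        "turnover_true": turn,
        "pooled_area": pooled,
        "detect_coefficients": (config.detect_intercept, config.detect_log_area,
                                config.detect_per_group),
    }
    return {
        "landscape": landscape,
        "assignment": assignment,
        "quality": q,
        "true_history": true_hist,
        "observed_history": observed,
        "n_groups_true": n_groups_true,
        "genotypes": genotypes,
        "truth": truth,
    }


def generate_control_data(config: SynthConfig, n_visits: int = 300,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic control-survey table for the detection GLMs.

    Draws occupied patches (areas from the landscape model), true group
    counts, and per-group detection outcomes; returns one row per control
    visit to an occupied patch with columns ``area_ha``, ``groups_main``,
    ``groups_total``, ``detected``.
    """
    rng = np.random.default_rng(seed)
    sigma = lognormal_sigma(config.median_area_ha, config.exceed_ha, config.p_exceed)
    A = np.exp(np.log(config.median_area_ha) + sigma * rng.standard_normal(n_visits))
    mu = config.groups_mean_at_median * (A / config.median_area_ha) ** config.groups_area_exp
    total = _zt_negbin(rng, mu, config.groups_dispersion, (n_visits,))
    p_det = expit(config.detect_intercept + config.detect_log_area * np.log(A)
                  + config.detect_per_group * total)
    found = rng.binomial(total, p_det)
    return pd.DataFrame({"area_ha": A, "groups_main": found,
                         "groups_total": total,
                         "detected": (found >= 1).astype(int)})


def truth_report(truth: dict, fitted: dict) -> pd.DataFrame:
    """Per-parameter recovery table: truth, estimate, interval, covered.

    ``fitted`` maps parameter name -> (estimate, lo, hi); truth values are
    looked up in the truth record (SpomParams attributes are resolved
    through the ``params`` entry).
    """
    rows = []
    params = truth.get("params")
    for name, (est, lo, hi) in fitted.items():
        if name in truth:
            tv = truth[name]
        elif params is not None and hasattr(params, name):
            tv = getattr(params, name)
        else:
            raise KeyError(f"no truth value recorded for {name!r}")
        rows.append({"parameter": name, "truth": float(tv), "estimate": float(est),
                     "lo": float(lo), "hi": float(hi),
                     "covered": bool(lo <= tv <= hi)})
    return pd.DataFrame(rows)
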