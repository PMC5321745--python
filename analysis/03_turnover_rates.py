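"""Estimate colonization/extinction parameters from annual turnover events.

Extracts the observed year-to-year transitions from the survey, runs the
Bayesian fit of the mechanistic transition probabilities (posterior over
alpha, y, ex, im, em, e, c with the extinction threshold delta = e/c
summarised from the joint draws), and fits the hierarchical logistic
turnover models with patch area, connectivity and the immigrant
dispersive-genotype frequency as covariates.

Usage: python analysis/03_turnover_rates.py [--study results/study] [--fast]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from metacap.genetics import immigrant_freq, pooled_network_genetics
from metacap.landscape import (incidence_from_history, load_occupancy,
                               load_patch_table, quality_index)
from metacap.networks import load_assignment
from metacap.synthetic_data import SynthConfig
from metacap.turnover import (estimate_rates, extract_events, fit_turnover_glmm,
                              glmm_records, turnover_rate)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--fast", action="store_true",
                    help="shorter MCMC (for smoke runs)")
    args = ap.parse_args()

    land = load_patch_table(args.study / "patches.csv")
    assign = load_assignment(args.study / "networks.csv", land)
    hist = load_occupancy(args.study / "occupancy.csv", land)
    q = quality_index(land)

    events = extract_events(hist, assign, land)
    ext = events[events.state_from == 1]
    col = events[events.state_from == 0]
    print(f"extinction events: {int(ext.event.sum())}/{len(ext)} opportunities")
    print(f"colonization events: {int(col.event.sum())}/{len(col)} opportunities")
    print(f"overall turnover rate: {turnover_rate(events):.3f}")

    mcmc = dict(n_warmup=300, n_samples=300) if args.fast else \
        dict(n_warmup=800, n_samples=800)
    rates = estimate_rates(land, q, hist, seed=args.seed, **mcmc)
    print("\nposterior summaries (annual transition model):")
    print(rates.summary.round(3))

    # hierarchical logistic models with the genotype covariate
    params = SynthConfig().params
    inc = incidence_from_history(hist)
    gen = pooled_network_genetics(
        __import__("pandas").read_csv(args.study / "genotypes.csv"), "candidate")
    f_net = gen.set_index("network_id")["f_disp"]
    resident_f = f_net.reindex(np.asarray(assign.network_id)).to_numpy()
    fS = immigrant_freq(land, resident_f, np.clip(np.nan_to_num(inc.p_bar), 0, 1),
                        params)
    glmm_cfg = dict(n_warmup=300, n_samples=400, chains=1) if args.fast else \
        dict(n_warmup=800, n_samples=1200, chains=2)
    out = {"rates": {k: rates.summary.loc[k, "mean"] for k in rates.summary.index},
           "delta_ci": [rates.summary.loc["delta", "ci2.5"],
                        rates.summary.loc["delta", "ci97.5"]]}
    for state, label in ((0, "colonization"), (1, "extinction")):
        rec = glmm_records(events, land, hist, params, f_S_disp=fS,
                           state_from=state).dropna(subset=["f_S_disp"])
        fit = fit_turnover_glmm(rec, seed=args.seed, **glmm_cfg)
        print(f"\n{label} model ({len(rec)} records):")
        print(fit.summary.round(3))
        out[label] = {name: {"median": float(fit.summary.loc[name, "median"]),
                             "or": float(fit.summary.loc[name, "odds_ratio"])}
                      for name in fit.summary.index}

    args.out.mkdir(parents=True, exist_ok=True)
    rates.summary.to_csv(args.out / "rate_posteriors.csv")
    (args.out / "turnover_fits.json").write_text(
        json.dumps(out, indent=2, default=float))
    print(f"\nwritten to {args.out}/rate_posteriors.csv and turnover_fits.json")


if __name__ == "__main__":
    main()
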