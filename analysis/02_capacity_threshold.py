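"""Metapopulation capacity, extinction threshold and equilibrium occupancy.

Loads the study written by 01_generate_study.py, fits the equilibrium
incidence model in two stages (structure only, then structure + habitat
quality) on the large well-occupied networks, computes each network's
metapopulation capacity, classifies networks against the fitted
extinction threshold, and checks how well capacity predicts observed
metapopulation size.  Writes the per-network table that the turnover and
genetics steps consume.

Usage: python analysis/02_capacity_threshold.py [--study results/study]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from metacap.capacity import SpomParams
from metacap.landscape import (incidence_from_history, load_occupancy,
                               load_patch_table, quality_index)
from metacap.networks import load_assignment
from metacap.occupancy_fit import (fit_quality_logistic, fit_stage1, fit_stage2,
                                   network_fit_statistics, predict_incidence)
from metacap.capacity import patch_connectivity
from metacap.pipeline import build_network_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--min-patches", type=int, default=15,
                    help="network-size filter for the incidence fit "
                         "(the synthetic networks are ~30 patches)")
    args = ap.parse_args()

    land = load_patch_table(args.study / "patches.csv")
    assign = load_assignment(args.study / "networks.csv", land)
    hist = load_occupancy(args.study / "occupancy.csv", land)
    q = quality_index(land)
    inc = incidence_from_history(hist)

    fit1 = fit_stage1(inc, land, assign, min_patches=args.min_patches)
    fit2 = fit_stage2(inc, land, q, assign, min_patches=args.min_patches)
    print("stage 1 (structure only):  delta = %.2f  x = %.3f"
          % (fit1.delta_hat, fit1.x_hat))
    print("stage 2 (with quality):    delta = %.2f (%.2f-%.2f)  x = %.3f  y = %.2f"
          % (fit2.delta_hat, *fit2.ci95["delta"], fit2.x_hat, fit2.y_hat))

    # quality logistic: how much do the raw quality variables add to the
    # structure-only prediction?
    conn = SpomParams()
    _, R = patch_connectivity(land, np.clip(np.nan_to_num(inc.p_bar), 0, 1),
                              conn, return_area_free=True)
    pred1 = predict_incidence(land.areas, 0 * q.q_tilde, R,
                              fit1.delta_hat, fit1.x_hat, 0.0)
    ql = fit_quality_logistic(inc, pred1, q.components,
                              n_years=inc.n_observed_years)
    print("quality logistic pseudo-R2: %.2f" % ql.pseudo_r2)
    print(ql.summary.round(3))

    params = SpomParams().with_delta(fit2.delta_hat)
    params = SpomParams(e=params.e, c=params.c, ex=params.ex,
                        im=params.im, em=params.em, alpha=params.alpha,
                        y=fit2.y_hat)
    table = build_network_table(land, assign, hist, q, params)
    stats_out = network_fit_statistics(table, params.delta)
    n_below = int((~table["viable"]).sum())
    print(f"\nnetworks below threshold: {n_below}/{len(table)} "
          f"({n_below / len(table):.0%})")
    print("capacity vs observed size: R2 = %.2f over %d networks"
          % (stats_out["R2_all"], stats_out["n_all"]))
    if np.isfinite(stats_out.get("r_viable", np.nan)):
        print("equilibrium prediction vs observed (viable networks): "
              "r = %.2f (t_%d = %.2f)"
              % (stats_out["r_viable"], stats_out["n_viable"] - 2,
                 stats_out["t_viable"]))

    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "network_table.csv", index=False)
    (args.out / "incidence_fit.json").write_text(json.dumps({
        "stage1": {"delta": fit1.delta_hat, "x": fit1.x_hat},
        "stage2": {"delta": fit2.delta_hat, "x": fit2.x_hat, "y": fit2.y_hat,
                   "ci95": {k: list(v) for k, v in fit2.ci95.items()}},
        "network_fit": {k: v for k, v in stats_out.items()
                        if isinstance(v, (int, float))},
        "quality_logistic_pseudo_r2": ql.pseudo_r2,
    }, indent=2))
    print(f"\nnetwork table -> {args.out / 'network_table.csv'}")


if __name__ == "__main__":
    main()
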