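"""Network-level genetics: dispersive-genotype frequency vs turnover,
habitat area and metapopulation size, plus the SNP-panel QQ comparison.

Merges the candidate-SNP frequencies into the network table, runs the
association regressions (frequency on turnover + pooled area;
metapopulation size on capacity + frequency; persistence t-test), and
calibrates the candidate's signal against the panel of neutral SNPs via
the uniform-null QQ slope.

Usage: python analysis/04_genetics.py [--study results/study]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from metacap.genetics import network_association, snp_panel_qq
from metacap.pipeline import per_snp_network_tables


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    table = pd.read_csv(args.out / "network_table.csv")
    genotypes = pd.read_csv(args.study / "genotypes.csv")
    if "f_disp" not in table:
        from metacap.genetics import pooled_network_genetics
        gen = pooled_network_genetics(genotypes, "candidate")
        table = table.merge(gen, on="network_id", how="left")

    sub = table[table["included"].fillna(False)].dropna(
        subset=["turnover_rate", "f_disp"])
    res = network_association(sub)
    co = res["freq_on_turnover_area"].params
    print(f"networks with adequate genetic samples: {len(sub)}")
    print("f_disp ~ turnover + log10(pooled area):")
    print(f"  R2 = {res['R2_freq']:.2f} (F = {res['F_freq']:.2f}, "
          f"p = {res['p_F_freq']:.2g})")
    print(f"  turnover coefficient {co['turnover_rate']:+.2f}, "
          f"area coefficient {co['log10_pooled_area']:+.3f}")
    print("metapopulation size ~ capacity + f_disp:")
    print(f"  joint R2 = {res['R2_size_joint']:.2f}; capacity alone "
          f"{res['R2_size_lambda_only']:.2f}; f_disp alone "
          f"{res['R2_size_freq_only']:.2f}")
    if "persistence_ttest" in res:
        t = res["persistence_ttest"]
        print(f"f_disp, persistent vs extinct>=5y networks: "
              f"t_{t['df']} = {t['t']:.2f}, p = {t['p']:.3f}")

    pertabs = per_snp_network_tables(table, genotypes)
    qq_turn = snp_panel_qq(pertabs, statistic="turnover_area_F",
                           outliers=("candidate",), seed=args.seed)
    qq_size = snp_panel_qq(pertabs, statistic="size_t",
                           outliers=("candidate",), seed=args.seed)
    print(f"\nSNP panel ({len(pertabs)} SNPs):")
    for name, qq in (("turnover/area", qq_turn), ("size", qq_size)):
        print(f"  {name}: slope {qq['slope']:.2f} excluding candidate "
              f"(null replicates {qq['replicate_slope_mean']:.2f} "
              f"+/- {qq['replicate_slope_sd']:.2f}); "
              f"min-p SNP: {qq['min_p_snp']}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "genetics.json").write_text(json.dumps({
        "n_networks": len(sub),
        "R2_freq": res["R2_freq"],
        "turnover_coef": float(co["turnover_rate"]),
        "area_coef": float(co["log10_pooled_area"]),
        "R2_size_joint": res["R2_size_joint"],
        "R2_size_lambda_only": res["R2_size_lambda_only"],
        "R2_size_freq_only": res["R2_size_freq_only"],
        "qq_slope_turnover": qq_turn["slope"],
        "qq_slope_size": qq_size["slope"],
        "qq_min_p_snp": qq_turn["min_p_snp"],
    }, indent=2, default=float))
    print(f"\nwritten to {args.out / 'genetics.json'}")


if __name__ == "__main__":
    main()
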