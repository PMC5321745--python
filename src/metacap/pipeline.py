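"""End-to-end assembly: from raw tables to the per-network analysis table.

The network table — one row per network with metapopulation capacity,
observed mean weighted occupancy, pooled habitat area, turnover rate,
external connectivity and the dispersive-genotype frequency — is the unit
of the headline network-level regressions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .capacity import SpomParams, build_M, classify_networks
from .genetics import pooled_network_genetics
from .landscape import Landscape, OccupancyHistory, QualityIndex
from .networks import NetworkAssignment, network_summaries
from .turnover import extract_events, turnover_rate


def build_network_table(
    landscape: Landscape,
    assignment: NetworkAssignment,
    history: OccupancyHistory,
    q: QualityIndex,
    params: SpomParams,
    genotypes: pd.DataFrame | None = None,
    candidate_snp: str = "candidate",
    genetic_model: str = "dominance",
    extinct_window: int = 5,
) -> pd.DataFrame:
    """Per-network summary table for the landscape-level analyses.

    Capacity is computed per network from the network's submatrix of M;
    ``extinct_5y`` flags networks with at least ``extinct_window``
    consecutive observed years without a single occupied patch.  When a
    genotype table is given, the candidate SNP's pooled frequency and its
    inclusion flag join the table.
    """
    M = build_M(landscape, q, params)
    table = network_summaries(assignment, landscape, history=history, M=M,
                              alpha=params.alpha).table.copy()
    events = extract_events(history, assignment)
    tr = turnover_rate(events, per="network")
    table["turnover_rate"] = tr.reindex(table["network_id"]).to_numpy()
    cls = classify_networks(table["lambda_M"].to_numpy(), params.delta)
    table["viable"] = cls["viable"]
    table["p_lambda_star"] = 1.0 - params.delta / table["lambda_M"]

    # extinct (no occupied patch) for >= extinct_window observed years
    flags = []
    occ = np.asarray(history.occupied, dtype=float)
    for k in table["network_id"]:
        sub = occ[assignment.members(int(k))]
        with np.errstate(invalid="ignore"):
            any_occ = np.nansum(sub, axis=0) > 0
        observed_years = ~np.all(np.isnan(sub), axis=0)
        empty = (~any_occ) & observed_years
        # longest run of consecutive empty observed years
        run = best = 0
        for e in empty:
            run = run + 1 if e else 0
            best = max(best, run)
        flags.append(best >= extinct_window)
    table["extinct_5y"] = flags

    if genotypes is not None:
        gen = pooled_network_genetics(genotypes, candidate_snp, model=genetic_model)
        table = table.merge(gen[["network_id", "f_disp", "allele_freq_C",
                                 "n_total", "included"]],
                            on="network_id", how="left")
    return table


def per_snp_network_tables(network_table: pd.DataFrame, genotypes: pd.DataFrame,
                           min_networks: int = 4) -> dict:
    """One association-ready table per SNP (additive allele frequency),
    restricted to networks with included samples; SNPs covering fewer than
    ``min_networks`` networks are dropped."""
    out = {}
    for snp in genotypes["snp_id"].unique():
        gen = pooled_network_genetics(genotypes, snp, model="additive")
        gen = gen[gen["included"]]
        t = network_table.drop(columns=[c for c in ("f_disp", "allele_freq_C",
                                                    "n_total", "included")
                                        if c in network_table],
                               errors="ignore")
        merged = t.merge(gen[["network_id", "f_disp"]].rename(
            columns={"f_disp": "allele_freq"}), on="network_id", how="inner")
        merged = merged.dropna(subset=["allele_freq", "turnover_rate"])
        if len(merged) >= min_networks:
            out[snp] = merged
    return out
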