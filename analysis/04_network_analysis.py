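#!/usr/bin/env python
"""Per-network accuracy tables and modality comparisons.

Repeats the identification analysis inside each of the 10 functional
networks (and the whole-brain pool) for FC, GMV and COMB at both
timepoints, each cell with its own bootstrap CI and permutation null.
Then compares modalities with a paired t-test across the 11 network
accuracies (FC vs GMV), tests whether COMB wins "best modality" in more
cells than chance, and compares the two timepoints.
"""

from pathlib import Path

import pandas as pd

from dyadprint import (
    best_count_test,
    best_modality_counts,
    compare_timepoints,
    paired_comparison,
    per_network_analysis,
    read_cohort,
)

REPO = Path(__file__).resolve().parent.parent
ROOT = REPO / "results"
COHORT = REPO / "scratch" / "cohort"
N_BOOT = N_PERM = 300
SEED = 4


def load(tp: str):
    d = COHORT / tp
    fc, atlas = read_cohort(
        d / "children_fc.tsv", d / "parents_fc.tsv", d / "dyad_map.tsv",
        node_metadata_path=d / "node_metadata.tsv",
        covariates_path=d / "covariates.tsv", modality="FC",
    )
    gmv, _ = read_cohort(
        d / "children_gmv.tsv", d / "parents_gmv.tsv", d / "dyad_map.tsv",
        covariates_path=d / "covariates.tsv", modality="GMV",
    )
    return fc, gmv, atlas


def main() -> None:
    tables = {}
    for tp in ("age11", "age13"):
        fc, gmv, atlas = load(tp)
        table = per_network_analysis(fc, gmv, atlas, n_boot=N_BOOT, n_perm=N_PERM, seed=SEED)
        table.to_csv(ROOT / f"network_accuracy_{tp}.tsv", sep="\t",
                     index=False, float_format="%.4g")
        tables[tp] = table

        a = table.query("modality == 'FC'").set_index("network")["accuracy"]
        b = table.query("modality == 'GMV'").set_index("network")["accuracy"]
        cmp_fg = paired_comparison(a.to_numpy(), b.to_numpy())
        print(f"{tp}: FC vs GMV across {cmp_fg.n_pairs} networks: "
              f"t({cmp_fg.df}) = {cmp_fg.t_stat:.2f}, p = {cmp_fg.p_value:.3f}, "
              f"Hedges g = {cmp_fg.hedges_g:.2f}")

    combined = pd.concat(tables.values())
    counts = best_modality_counts(combined)
    n_cases = sum(counts.values())
    p_best = best_count_test(list(counts.values()), n_perm=10_000, seed=SEED)
    winner = max(counts, key=counts.get)
    print(f"best-modality counts over {n_cases} (network x age) cases: {counts}; "
          f"{winner} leads, p = {p_best:.4g} vs uniform-thirds chance")

    for mod in ("FC", "GMV"):
        res = compare_timepoints(tables["age11"], tables["age13"], mod)
        print(f"{mod} age11 vs age13: t({res.df}) = {res.t_stat:.2f}, "
              f"p = {res.p_value:.3f}, Hedges g = {res.hedges_g:.2f}")
    print(f"wrote per-network tables under {ROOT}")


if __name__ == "__main__":
    main()
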