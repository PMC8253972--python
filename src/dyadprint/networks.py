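"""Network-restricted and covariate-split analysis drivers.

Atlas nodes are grouped into functional networks (canonically 10, plus
the whole-brain pool "ALL"); the identification analysis is repeated on
the features of each network — FC edges with both endpoints inside the
network, between-network edge sets, or the network's GMV nodes — each
with its own permutation null, so networks of different sizes are
compared fairly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    DyadCohort,
    FeatureMatrix,
    Modality,
    NetworkAtlas,
    ValidationError,
    assemble_comb,
    split_edge_label,
)
from .preprocess import median_split
from .resampling import (
    ComparisonResult,
    bootstrap_ci,
    paired_comparison,
    permutation_test,
)
from .similarity import (
    AccuracyEstimate,
    per_child_winning_rates,
    similarity_matrix,
    winning_rate_accuracy,
)

logger = logging.getLogger(__name__)

ALL_LABEL = "ALL"


# ---------------------------------------------------------------------
# Feature masks
# ---------------------------------------------------------------------

def _check_label(atlas: NetworkAtlas, label: str) -> None:
    if label != ALL_LABEL and label not in atlas.networks:
        raise ValidationError(
            f"unknown network {label!r}; valid labels: {atlas.networks + [ALL_LABEL]}"
        )


def within_network_edge_mask(
    atlas: NetworkAtlas, network_label: str, edge_ids: Sequence[str]
) -> list[str]:
    """FC edges whose both endpoints carry ``network_label`` (or all
    edges for ALL), in the cohort's edge order."""
    _check_label(atlas, network_label)
    if network_label == ALL_LABEL:
        return list(edge_ids)
    members = set(atlas.nodes_in_network(network_label))
    out = []
    for e in edge_ids:
        a, b = split_edge_label(e)
        if a in members and b in members:
            out.append(e)
    return out


def between_network_edge_mask(
    atlas: NetworkAtlas, label_a: str, label_b: str, edge_ids: Sequence[str]
) -> list[str]:
    """FC edges with one endpoint in each of two distinct networks
    (symmetric in the pair)."""
    if label_a == label_b:
        raise ValidationError("between-network mask needs two distinct labels; use the within-network mask")
    _check_label(atlas, label_a)
    _check_label(atlas, label_b)
    ma = set(atlas.nodes_in_network(label_a))
    mb = set(atlas.nodes_in_network(label_b))
    out = []
    for e in edge_ids:
        a, b = split_edge_label(e)
        if (a in ma and b in mb) or (a in mb and b in ma):
            out.append(e)
    return out


def network_node_mask(
    atlas: NetworkAtlas, network_label: str, node_ids: "Sequence[str] | None" = None
) -> list[str]:
    """GMV features (nodes) belonging to a network (all nodes for ALL)."""
    _check_label(atlas, network_label)
    pool = list(node_ids) if node_ids is not None else list(atlas.node_ids)
    if network_label == ALL_LABEL:
        return pool
    members = set(atlas.nodes_in_network(network_label))
    return [n for n in pool if n in members]


# ---------------------------------------------------------------------
# Per-network analysis
# ---------------------------------------------------------------------

def _spawn_seeds(seed: "int | None", n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def analyze_masked(
    cohort: DyadCohort,
    feature_mask: "Iterable[str] | None" = None,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: "int | None" = None,
) -> AccuracyEstimate:
    """Accuracy + bootstrap CI + permutation p for one feature mask.

    Set ``n_boot``/``n_perm`` to 0 to skip the corresponding stage (the
    estimate then carries None for that field).
    """
    sim = similarity_matrix(cohort, feature_mask)
    est = winning_rate_accuracy(sim)
    sboot, sperm = _spawn_seeds(seed, 2)
    if n_boot > 0:
        boot = bootstrap_ci(sim, n_boot=n_boot, seed=sboot)
        est.ci95 = boot.ci95
        est.boot_draws = boot.draws
        est.n_boot = n_boot
    if n_perm > 0:
        perm = permutation_test(sim, n_perm=n_perm, seed=sperm)
        est.permutation_p = perm.p_value
        est.null_draws = perm.null_draws
        est.n_perm = n_perm
    est.seed = seed
    return est


def build_comb_cohort(fc: DyadCohort, gmv: DyadCohort, standardize: bool = True) -> DyadCohort:
    """Concatenate a cohort's FC and GMV matrices into a COMB cohort."""
    if fc.dyad_map != gmv.dyad_map:
        raise ValidationError("FC and GMV cohorts must share the same dyad map")
    children = assemble_comb(fc.children, gmv.children, standardize=standardize)
    parents = assemble_comb(fc.parents, gmv.parents, standardize=standardize)
    return DyadCohort(children, parents, list(fc.dyad_map), fc.covariates)


def _network_masks(
    atlas: NetworkAtlas,
    network: str,
    fc: "DyadCohort | None",
    gmv: "DyadCohort | None",
) -> dict[str, "list[str] | None"]:
    masks: dict[str, "list[str] | None"] = {}
    if fc is not None:
        masks["FC"] = within_network_edge_mask(atlas, network, fc.feature_ids)
    if gmv is not None:
        masks["GMV"] = network_node_mask(atlas, network, gmv.feature_ids)
    if fc is not None and gmv is not None:
        masks["COMB"] = masks["FC"] + masks["GMV"]  # type: ignore[operator]
    return masks


def per_network_analysis(
    fc_cohort: "DyadCohort | None",
    gmv_cohort: "DyadCohort | None",
    atlas: NetworkAtlas,
    modalities: Sequence[str] = ("FC", "GMV", "COMB"),
    networks: "Sequence[str] | None" = None,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: "int | None" = None,
    comb_standardize: bool = True,
) -> pd.DataFrame:
    """Accuracy table over (network ∪ ALL) × modality.

    Each cell gets its own bootstrap CI and its own permutation null
    (networks differ in feature count, so nulls are not shared). The
    best modality per network is flagged for the best-count test. Cells
    whose mask has fewer than 3 features are marked not-computable
    (NaN row) and the run continues.
    """
    nets = list(networks) if networks is not None else atlas.networks + [ALL_LABEL]
    cohorts: dict[str, DyadCohort] = {}
    if "FC" in modalities:
        if fc_cohort is None:
            raise ValidationError("FC requested but no FC cohort given")
        cohorts["FC"] = fc_cohort
    if "GMV" in modalities:
        if gmv_cohort is None:
            raise ValidationError("GMV requested but no GMV cohort given")
        cohorts["GMV"] = gmv_cohort
    if "COMB" in modalities:
        if fc_cohort is None or gmv_cohort is None:
            raise ValidationError("COMB requires both FC and GMV cohorts")
        cohorts["COMB"] = build_comb_cohort(fc_cohort, gmv_cohort, standardize=comb_standardize)

    seeds = iter(_spawn_seeds(seed, len(nets) * len(modalities)))
    rows = []
    for net in nets:
        masks = _network_masks(atlas, net, fc_cohort, gmv_cohort)
        for mod in modalities:
            cell_seed = next(seeds)
            mask = masks.get(mod)
            if mask is not None and len(mask) < 3:
                logger.warning("network %s / %s: only %d feature(s); cell not computable",
                               net, mod, len(mask))
                rows.append(dict(network=net, modality=mod, n_features=len(mask),
                                 accuracy=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                                 p_value=np.nan))
                continue
            est = analyze_masked(cohorts[mod], mask, n_boot=n_boot, n_perm=n_perm, seed=cell_seed)
            rows.append(dict(
                network=net, modality=mod,
                n_features=len(mask) if mask is not None else cohorts[mod].children.n_features,
                accuracy=est.accuracy,
                ci_lo=est.ci95[0] if est.ci95 else np.nan,
                ci_hi=est.ci95[1] if est.ci95 else np.nan,
                p_value=est.permutation_p if est.permutation_p is not None else np.nan,
            ))
    table = pd.DataFrame(rows)
    table["best"] = False
    for net, grp in table.groupby("network"):
        valid = grp.dropna(subset=["accuracy"])
        if len(valid):
            table.loc[valid["accuracy"].idxmax(), "best"] = True
    return table


def best_modality_counts(table: pd.DataFrame) -> dict[str, int]:
    """Wins per modality over the networks of one or more accuracy
    tables (input to the best-count test)."""
    wins = table.loc[table["best"], "modality"].value_counts().to_dict()
    return {m: int(wins.get(m, 0)) for m in table["modality"].unique()}


# ---------------------------------------------------------------------
# Covariate splits
# ---------------------------------------------------------------------

@dataclass
class SplitResult:
    tables: dict[str, pd.DataFrame]              # subgroup -> per-network table
    comparisons: dict[str, ComparisonResult]     # modality -> paired test across networks
    labels: pd.Series                            # child -> subgroup label


def _subgroup_labels(
    cohort: DyadCohort, split: str, scores: "pd.Series | None"
) -> pd.Series:
    kids = cohort.child_ids
    if split == "sex":
        if cohort.covariates is None:
            raise ValidationError("sex split needs covariates")
        lab = cohort.covariates.column("sex").reindex(kids)
        if lab.isna().any():
            raise ValidationError(f"missing sex for {list(lab.index[lab.isna()])}")
        return lab
    if split == "median":
        if scores is None:
            raise ValidationError("median split needs a scores series")
        s = scores.reindex(kids).to_numpy(dtype=float)
        return pd.Series(median_split(s), index=kids)
    raise ValidationError(f"unknown split {split!r}; use 'sex' or 'median'")


def covariate_split_analysis(
    fc_cohort: "DyadCohort | None",
    gmv_cohort: "DyadCohort | None",
    atlas: NetworkAtlas,
    split: str = "sex",
    scores: "pd.Series | None" = None,
    modalities: Sequence[str] = ("FC", "GMV", "COMB"),
    networks: "Sequence[str] | None" = None,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: "int | None" = None,
    strangers: str = "subgroup",
) -> SplitResult:
    """Run the full per-network analysis independently inside each
    subgroup, then compare subgroups with a paired t-test across the
    network-level accuracies.

    By default similarities are computed only among subgroup members
    (stranger parents drawn from the subgroup). ``strangers='all'``
    instead scores each subgroup child against the full parent pool;
    that variant reports point accuracies only (no CI/p).
    """
    ref = fc_cohort if fc_cohort is not None else gmv_cohort
    if ref is None:
        raise ValidationError("need at least one cohort")
    labels = _subgroup_labels(ref, split, scores)
    groups = [g for g in labels.dropna().unique() if g != ""]
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 subgroups, got {groups}")
    kid_pos = {c: i for i, c in enumerate(ref.child_ids)}

    tables: dict[str, pd.DataFrame] = {}
    seeds = _spawn_seeds(seed, len(groups))
    for g, gseed in zip(sorted(groups), seeds):
        idx = [kid_pos[c] for c in labels.index[labels == g]]
        if len(idx) < 3:
            raise ValidationError(f"subgroup {g!r} has only {len(idx)} dyads (need >= 3)")
        if strangers == "subgroup":
            sub_fc = fc_cohort.subset_dyads(idx) if fc_cohort is not None else None
            sub_gmv = gmv_cohort.subset_dyads(idx) if gmv_cohort is not None else None
            tables[g] = per_network_analysis(
                sub_fc, sub_gmv, atlas, modalities=modalities, networks=networks,
                n_boot=n_boot, n_perm=n_perm, seed=gseed,
            )
        elif strangers == "all":
            tables[g] = _fullpool_subgroup_table(
                fc_cohort, gmv_cohort, atlas, idx, modalities, networks
            )
        else:
            raise ValidationError("strangers must be 'subgroup' or 'all'")

    comparisons: dict[str, ComparisonResult] = {}
    g1, g2 = sorted(groups)
    for mod in modalities:
        a = tables[g1].query("modality == @mod").set_index("network")["accuracy"]
        b = tables[g2].query("modality == @mod").set_index("network")["accuracy"]
        common = [n for n in a.index if n in b.index
                  and np.isfinite(a[n]) and np.isfinite(b[n])]
        if len(common) >= 3:
            comparisons[mod] = paired_comparison(a[common].to_numpy(), b[common].to_numpy())
    return SplitResult(tables=tables, comparisons=comparisons, labels=labels)


def _fullpool_subgroup_table(
    fc_cohort: "DyadCohort | None",
    gmv_cohort: "DyadCohort | None",
    atlas: NetworkAtlas,
    child_idx: Sequence[int],
    modalities: Sequence[str],
    networks: "Sequence[str] | None",
) -> pd.DataFrame:
    """Point accuracies per network for a subgroup of children scored
    against the full parent pool."""
    nets = list(networks) if networks is not None else atlas.networks + [ALL_LABEL]
    cohorts: dict[str, DyadCohort] = {}
    if "FC" in modalities and fc_cohort is not None:
        cohorts["FC"] = fc_cohort
    if "GMV" in modalities and gmv_cohort is not None:
        cohorts["GMV"] = gmv_cohort
    if "COMB" in modalities and fc_cohort is not None and gmv_cohort is not None:
        cohorts["COMB"] = build_comb_cohort(fc_cohort, gmv_cohort)
    idx = np.asarray(child_idx)
    rows = []
    for net in nets:
        masks = _network_masks(atlas, net, fc_cohort, gmv_cohort)
        for mod in modalities:
            mask = masks.get(mod)
            if mod not in cohorts or (mask is not None and len(mask) < 3):
                continue
            sim = similarity_matrix(cohorts[mod], mask)
            rates = per_child_winning_rates(sim)
            rows.append(dict(
                network=net, modality=mod,
                n_features=len(mask) if mask is not None else cohorts[mod].children.n_features,
                accuracy=float(rates[idx].mean()),
                ci_lo=np.nan, ci_hi=np.nan, p_value=np.nan,
            ))
    table = pd.DataFrame(rows)
    table["best"] = False
    return table


def compare_timepoints(
    table_a: pd.DataFrame, table_b: pd.DataFrame, modality: str
) -> ComparisonResult:
    """Paired t-test (with Hedges g) between two timepoints' per-network
    accuracy profiles for one modality, matched by network label."""
    a = table_a.query("modality == @modality").set_index("network")["accuracy"]
    b = table_b.query("modality == @modality").set_index("network")["accuracy"]
    common = [n for n in a.index if n in b.index and np.isfinite(a[n]) and np.isfinite(b[n])]
    if len(common) < 3:
        raise ValidationError("need at least 3 matched networks")
    return paired_comparison(a[common].to_numpy(), b[common].to_numpy())
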