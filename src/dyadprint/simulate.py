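"""Synthetic parent-child cohort generator with known ground truth.

The generator emulates the statistical structure the identification
analysis assumes: a cohort of N parent-child dyads (default 84, the
study scale) whose feature vectors share a tunable transmission
component. Parent features are Gaussian around a per-feature population
mean μ_f; the child's value is

    c(f) = μ_f + α·(p(f) − μ_f) + sqrt(1 − α²)·ε,   ε ~ N(0, noise_sd)

so that with unit noise the child-parent correlation at feature f is
exactly α. α can be overridden per network (planting discriminative
feature sets), per timepoint, and per covariate subgroup (planting
accuracy differences); features given a large shared μ_f are
group-consistent but non-discriminative. Every planted quantity is
recorded in the ground-truth record.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CovariateTable,
    DyadCohort,
    FeatureMatrix,
    Modality,
    NetworkAtlas,
    ValidationError,
    edge_labels,
    split_edge_label,
)

#: the 10 canonical functional networks (medial frontal, frontoparietal,
#: default mode, motor, three visual, cingulo-opercular, subcortical,
#: cerebellum)
NETWORK_NAMES = ("MF", "FP", "DMN", "Mot", "VisI", "VisII", "VisA", "Cing", "Sub", "Cer")
LOBE_NAMES = ("PFC", "Mot", "Ins", "Par", "Tem", "Occ", "Lim", "Cer", "Sub", "Bsm")

#: study composition: 84 dyads, 39 daughters / 45 sons
DEFAULT_N_DYADS = 84
DEFAULT_FEMALE_FRAC = 39 / 84


@dataclass
class SyntheticSpec:
    """Parameters of a simulated dyad cohort.

    alpha is the global transmission coefficient (child-parent feature
    correlation) in [0, 1]; overrides plant structure for recovery
    tests. consistent_frac of features receive population offset
    consistent_mean (group-consistent, non-discriminative features).
    subgroup_effects maps a subgroup key — a sex label ('M'/'F'),
    'upper_testosterone' or 'upper_cbcl' — to an additive α delta for
    children in that subgroup.
    """

    n_dyads: int = DEFAULT_N_DYADS
    n_nodes: int = 40
    gmv_nodes: "int | None" = None
    alpha: float = 0.5
    alpha_by_network: "dict[str, float] | None" = None
    consistent_mean: float = 0.0
    consistent_frac: float = 0.0
    timepoints: tuple[str, ...] = ("age11",)
    alpha_by_timepoint: "dict[str, float] | None" = None
    subgroup_effects: "dict[str, float] | None" = None
    noise_sd: float = 1.0
    female_frac: float = DEFAULT_FEMALE_FRAC
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.n_dyads < 3:
            raise ValidationError("need at least 3 dyads")
        if self.n_nodes < 3:
            raise ValidationError("need at least 3 atlas nodes")
        for d in (self.alpha_by_network or {}), (self.alpha_by_timepoint or {}):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ValidationError("alpha overrides must lie in [0, 1]")
        if self.alpha_by_network:
            bad = sorted(set(self.alpha_by_network) - set(NETWORK_NAMES))
            if bad:
                raise ValidationError(f"unknown network(s) in alpha_by_network: {bad}")
        if self.alpha_by_timepoint:
            bad = sorted(set(self.alpha_by_timepoint) - set(self.timepoints))
            if bad:
                raise ValidationError(f"unknown timepoint(s) in alpha_by_timepoint: {bad}")
        if not 0 <= self.consistent_frac <= 1:
            raise ValidationError("consistent_frac must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    fc: dict[str, DyadCohort]
    gmv: dict[str, DyadCohort]
    atlas: NetworkAtlas
    ground_truth: dict


def make_atlas(n_nodes: int, networks: Sequence[str] = NETWORK_NAMES) -> NetworkAtlas:
    """Node metadata emulating the canonical 10-network scheme: nodes
    assigned round-robin to networks and lobes, alternating hemispheres."""
    nodes = [f"node{i:03d}" for i in range(n_nodes)]
    network_of = {n: networks[i % len(networks)] for i, n in enumerate(nodes)}
    lobe_of = {n: LOBE_NAMES[(i // len(networks)) % len(LOBE_NAMES)] for i, n in enumerate(nodes)}
    hemi_of = {n: ("L" if i % 2 == 0 else "R") for i, n in enumerate(nodes)}
    return NetworkAtlas(nodes, network_of, lobe_of, hemi_of)


def _children_given_parents(
    parents: np.ndarray,
    alpha: np.ndarray,
    mu: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    eps = rng.normal(0.0, noise_sd, size=parents.shape)
    return mu + alpha * (parents - mu) + np.sqrt(1.0 - alpha**2) * eps


def simulate_feature_cohort(
    n_dyads: int,
    n_features: int,
    alpha: "float | np.ndarray" = 0.0,
    mu: "float | np.ndarray" = 0.0,
    noise_sd: float = 1.0,
    seed: "int | np.random.Generator | None" = None,
    modality: "Modality | str" = Modality.GMV,
    feature_ids: "Sequence[str] | None" = None,
) -> DyadCohort:
    """Single-modality cohort: parents ~ N(μ_f, 1), children generated by
    the shared-component model. alpha may be scalar, per-feature (M,), or
    per-child-per-feature (N, M). With alpha = 0, child and parent
    vectors are statistically independent (the null cohort)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n_features,))
    alpha_arr = np.broadcast_to(np.asarray(alpha, dtype=float), (n_dyads, n_features))
    parents = rng.normal(0.0, 1.0, size=(n_dyads, n_features)) + mu_arr
    children = _children_given_parents(parents, alpha_arr, mu_arr, noise_sd, rng)
    kids = [f"child{i:03d}" for i in range(n_dyads)]
    pars = [f"parent{i:03d}" for i in range(n_dyads)]
    fids = list(feature_ids) if feature_ids is not None else [f"f{i:05d}" for i in range(n_features)]
    return DyadCohort(
        FeatureMatrix(kids, fids, children, modality),
        FeatureMatrix(pars, fids, parents, modality),
        list(zip(kids, pars)),
    )


def _feature_alphas(
    spec: SyntheticSpec, atlas: NetworkAtlas, base: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature α for FC edges (override applies when both endpoints
    sit in the overridden network) and for GMV nodes."""
    overrides = spec.alpha_by_network or {}
    nodes = atlas.node_ids
    net = [atlas.network_of[n] for n in nodes]
    gmv_alpha = np.array([overrides.get(g, base) for g in net])
    fc_alpha = np.array(
        [
            overrides[net[i]] if net[i] == net[j] and net[i] in overrides else base
            for i in range(1, len(nodes))
            for j in range(i)
        ]
    )
    return fc_alpha, gmv_alpha


def _covariates(
    spec: SyntheticSpec, rng: np.random.Generator, kids: list[str], timepoint: str
) -> tuple[CovariateTable, dict]:
    n = spec.n_dyads
    n_f = int(round(spec.female_frac * n))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sex)
    z_tst = rng.normal(size=n)
    z_cbcl = rng.normal(size=n)
    # testosterone lives on a squared scale (sqrt-transform downstream
    # restores approximate normality); levels rise from age 11 to 13
    base = 2.0 if timepoint == "age11" else 4.0
    testosterone = (base + 0.45 * z_tst) ** 2
    internal = np.clip(10 + 6 * z_cbcl + rng.normal(0, 2, n), 0, None)
    external = np.clip(10 + 6 * z_cbcl + rng.normal(0, 2, n), 0, None)
    cbcl = (internal + external) / 2
    mean_fd = rng.lognormal(mean=np.log(0.10), sigma=0.4, size=n)
    table = CovariateTable(
        pd.DataFrame(
            {
                "sex": sex,
                "timepoint": timepoint,
                "mean_fd": mean_fd,
                "testosterone": testosterone,
                "cbcl": cbcl,
            },
            index=kids,
        )
    )
    latents = {"testosterone": z_tst, "cbcl": z_cbcl, "sex": sex}
    return table, latents


def _child_deltas(spec: SyntheticSpec, latents: dict) -> np.ndarray:
    deltas = np.zeros(spec.n_dyads)
    for key, delta in (spec.subgroup_effects or {}).items():
        if key in ("M", "F"):
            member = latents["sex"] == key
        elif key == "upper_testosterone":
            member = latents["testosterone"] > np.median(latents["testosterone"])
        elif key == "upper_cbcl":
            member = latents["cbcl"] > np.median(latents["cbcl"])
        else:
            raise ValidationError(
                f"unknown subgroup key {key!r}; use 'M', 'F', 'upper_testosterone' or 'upper_cbcl'"
            )
        deltas[member] += delta
    return deltas


def simulate_cohort(spec: SyntheticSpec) -> SimulatedCohort:
    """Generate FC and GMV dyad cohorts (per timepoint) plus atlas and a
    ground-truth record of every planted parameter.

    Parents are shared across timepoints (scanned once); children are
    redrawn per timepoint with that timepoint's α. Deterministic given
    (spec, spec.seed).
    """
    rng = np.random.default_rng(spec.seed)
    atlas = make_atlas(spec.n_nodes)
    n = spec.n_dyads
    n_gmv = spec.gmv_nodes if spec.gmv_nodes is not None else spec.n_nodes
    fc_ids = edge_labels(atlas.node_ids)
    gmv_ids = list(atlas.node_ids[:n_gmv]) if n_gmv <= spec.n_nodes else [
        f"node{i:03d}" for i in range(n_gmv)
    ]
    m_fc, m_gmv = len(fc_ids), len(gmv_ids)

    # population means: a random consistent_frac of features get offset
    cons_fc = np.zeros(m_fc)
    cons_gmv = np.zeros(m_gmv)
    k_fc = int(round(spec.consistent_frac * m_fc))
    k_gmv = int(round(spec.consistent_frac * m_gmv))
    idx_fc = rng.choice(m_fc, size=k_fc, replace=False) if k_fc else np.array([], dtype=int)
    idx_gmv = rng.choice(m_gmv, size=k_gmv, replace=False) if k_gmv else np.array([], dtype=int)
    cons_fc[idx_fc] = spec.consistent_mean
    cons_gmv[idx_gmv] = spec.consistent_mean

    parents_fc = rng.normal(size=(n, m_fc)) + cons_fc
    parents_gmv = rng.normal(size=(n, m_gmv)) + cons_gmv
    kids = [f"child{i:03d}" for i in range(n)]
    pars = [f"parent{i:03d}" for i in range(n)]
    dyads = list(zip(kids, pars))

    fc_cohorts: dict[str, DyadCohort] = {}
    gmv_cohorts: dict[str, DyadCohort] = {}
    truth: dict = {
        "spec": asdict(spec),
        "consistent_fc": [fc_ids[i] for i in idx_fc],
        "consistent_gmv": [gmv_ids[i] for i in idx_gmv],
        "alpha": {},
        "child_alpha_delta": {},
    }
    for tp in spec.timepoints:
        base = (spec.alpha_by_timepoint or {}).get(tp, spec.alpha)
        a_fc, _ = _feature_alphas(spec, atlas, base)
        overrides = spec.alpha_by_network or {}
        a_gmv = np.array(
            [
                overrides.get(atlas.network_of[g], base) if g in atlas.network_of else base
                for g in gmv_ids
            ]
        )
        cov, latents = _covariates(spec, rng, kids, tp)
        deltas = _child_deltas(spec, latents)
        al_fc = np.clip(a_fc[None, :] + deltas[:, None], 0.0, 1.0)
        al_gmv = np.clip(a_gmv[None, :] + deltas[:, None], 0.0, 1.0)
        children_fc = _children_given_parents(parents_fc, al_fc, cons_fc, spec.noise_sd, rng)
        children_gmv = _children_given_parents(parents_gmv, al_gmv, cons_gmv, spec.noise_sd, rng)
        fc_cohorts[tp] = DyadCohort(
            FeatureMatrix(kids, fc_ids, children_fc, Modality.FC),
            FeatureMatrix(pars, fc_ids, parents_fc, Modality.FC),
            dyads, cov,
        )
        gmv_cohorts[tp] = DyadCohort(
            FeatureMatrix(kids, gmv_ids, children_gmv, Modality.GMV),
            FeatureMatrix(pars, gmv_ids, parents_gmv, Modality.GMV),
            dyads, cov,
        )
        truth["alpha"][tp] = {"fc": a_fc, "gmv": a_gmv}
        truth["child_alpha_delta"][tp] = deltas
    return SimulatedCohort(fc=fc_cohorts, gmv=gmv_cohorts, atlas=atlas, ground_truth=truth)


def simulate_motion_series(
    n_frames: int,
    offender_rate: float = 0.05,
    seed: "int | np.random.Generator | None" = None,
) -> np.ndarray:
    """Framewise-displacement series (mm): low-motion baseline with
    Bernoulli(offender_rate) spikes above the 0.5 mm scrub threshold."""
    if n_frames < 1:
        raise ValidationError("need at least 1 frame")
    if not 0 <= offender_rate <= 1:
        raise ValidationError("offender_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = np.abs(rng.normal(0.10, 0.05, size=n_frames))
    baseline = np.minimum(baseline, 0.45)  # baseline never offends
    spikes = rng.random(n_frames) < offender_rate
    fd = np.where(spikes, rng.uniform(0.55, 1.2, size=n_frames), baseline)
    return fd


def simulate_motion_cohort(
    n_subjects: int,
    n_frames: int = 250,
    offender_rate: float = 0.05,
    seed: "int | None" = None,
    prefix: str = "subj",
) -> dict[str, np.ndarray]:
    """Independent FD series per subject (feeds the motion negative
    control: unrelated child/parent motion distributions should identify
    dyads at chance)."""
    rng = np.random.default_rng(seed)
    return {
        f"{prefix}{i:03d}": simulate_motion_series(n_frames, offender_rate, rng)
        for i in range(n_subjects)
    }
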