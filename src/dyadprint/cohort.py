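"""Domain containers and tab-separated I/O for parent-child feature cohorts.

The unit of analysis is the *dyad*: a child matched to their own parent.
Each subject carries one feature vector per modality — functional
connectivity (FC) edges obtained by vectorizing the strictly lower
triangle of a symmetric node-by-node correlation matrix, regional gray
matter volumes (GMV, one value per atlas node), their concatenation
(COMB), or a head-motion distribution vector (MOTION).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: separator inside an FC edge label "nodeA–nodeB" (en dash: node ids
#: themselves routinely contain ASCII hyphens).
EDGE_SEP = "–"

VALID_SEX = frozenset({"M", "F"})
VALID_TIMEPOINTS = frozenset({"age11", "age13"})


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


class Modality(str, Enum):
    FC = "FC"
    GMV = "GMV"
    COMB = "COMB"
    MOTION = "MOTION"


def _as_modality(m: "Modality | str") -> Modality:
    return Modality(m.upper()) if isinstance(m, str) and not isinstance(m, Modality) else Modality(m)


@dataclass
class FeatureMatrix:
    """Subjects × features values for a single modality.

    ``values[s, f]`` is subject ``subject_ids[s]``'s value for feature
    ``feature_ids[f]``. All values must be finite; ids must be unique.
    """

    subject_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    modality: Modality

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.modality = _as_modality(self.modality)
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_ids)} features"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicated subject_id in FeatureMatrix")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicated feature_id in FeatureMatrix")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at subject {self.subject_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )

    # -- convenience -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: "Modality | str") -> "FeatureMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), modality)

    def subset_subjects(self, ids: Sequence[str]) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown subject ids: {missing}")
        idx = [pos[s] for s in ids]
        return FeatureMatrix(list(ids), self.feature_ids, self.values[idx], self.modality)

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        idx = [pos[f] for f in ids]
        return FeatureMatrix(self.subject_ids, list(ids), self.values[:, idx], self.modality)


@dataclass
class CovariateTable:
    """Per-child covariates: sex, timepoint, mean framewise displacement
    (mm), testosterone (pg/mL, raw scale) and CBCL score. Any numeric
    column may be absent (NaN) per subject; categorical labels come from
    fixed sets."""

    data: pd.DataFrame

    COLUMNS = ("sex", "timepoint", "mean_fd", "testosterone", "cbcl")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValidationError("duplicated subject_id in covariates")
        for col in ("mean_fd", "testosterone", "cbcl"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            vals = df[col].to_numpy(dtype=float)
            if np.any(np.isinf(vals)):
                raise ValidationError(f"infinite value in covariate {col!r}")
        for col, valid in (("sex", VALID_SEX), ("timepoint", VALID_TIMEPOINTS)):
            present = df[col].dropna()
            bad = sorted(set(present) - valid)
            if bad:
                raise ValidationError(f"invalid {col} labels {bad}; expected one of {sorted(valid)}")
        self.data = df[list(self.COLUMNS)]

    def for_subjects(self, ids: Sequence[str]) -> "CovariateTable":
        out = self.data.reindex([str(s) for s in ids])
        return CovariateTable(out)

    def column(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass
class NetworkAtlas:
    """Node metadata: functional-network, anatomical-lobe and hemisphere
    assignment per atlas node (the canonical scheme groups 268 nodes
    into 10 functional networks)."""

    node_ids: list[str]
    network_of: dict[str, str]
    lobe_of: dict[str, str]
    hemisphere_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids = [str(n) for n in self.node_ids]
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicated node_id in atlas")
        for n in self.node_ids:
            if n not in self.network_of:
                raise ValidationError(f"node {n!r} has no network assignment")
            if n not in self.lobe_of:
                raise ValidationError(f"node {n!r} has no lobe assignment")
        bad_h = {h for h in self.hemisphere_of.values()} - {"L", "R"}
        if bad_h:
            raise ValidationError(f"invalid hemisphere labels {sorted(bad_h)}")

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self.node_ids:
            seen.setdefault(self.network_of[n], None)
        return list(seen)

    @property
    def lobes(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self.node_ids:
            seen.setdefault(self.lobe_of[n], None)
        return list(seen)

    def nodes_in_network(self, label: str) -> list[str]:
        return [n for n in self.node_ids if self.network_of[n] == label]


@dataclass
class DyadCohort:
    """Paired child/parent feature matrices plus the dyad map.

    ``dyad_map[i] = (child_id, parent_id)`` defines dyad i; the map is a
    bijection between the child and parent subject sets. Children and
    parents are stored re-ordered to dyad order, so row i of both
    matrices belongs to dyad i.
    """

    children: FeatureMatrix
    parents: FeatureMatrix
    dyad_map: list[tuple[str, str]]
    covariates: CovariateTable | None = None

    def __post_init__(self) -> None:
        if self.children.modality != self.parents.modality:
            raise ValidationError(
                f"modality mismatch: children {self.children.modality} vs parents {self.parents.modality}"
            )
        if self.children.feature_ids != self.parents.feature_ids:
            raise ValidationError("children and parents must share identical feature_ids")
        self.dyad_map = [(str(c), str(p)) for c, p in self.dyad_map]
        if len(self.dyad_map) < 3:
            raise ValidationError(f"need at least 3 dyads, got {len(self.dyad_map)}")
        kids = [c for c, _ in self.dyad_map]
        pars = [p for _, p in self.dyad_map]
        if len(set(kids)) != len(kids):
            dup = sorted({c for c in kids if kids.count(c) > 1})
            raise ValidationError(f"child appears in more than one dyad: {dup}")
        if len(set(pars)) != len(pars):
            dup = sorted({p for p in pars if pars.count(p) > 1})
            raise ValidationError(f"parent appears in more than one dyad: {dup}")
        if set(kids) != set(self.children.subject_ids):
            raise ValidationError("dyad_map children do not match child subject set")
        if set(pars) != set(self.parents.subject_ids):
            raise ValidationError("dyad_map parents do not match parent subject set")
        # realign rows to dyad order
        self.children = self.children.subset_subjects(kids)
        self.parents = self.parents.subset_subjects(pars)
        if self.covariates is not None:
            self.covariates = self.covariates.for_subjects(kids)

    @property
    def n_dyads(self) -> int:
        return len(self.dyad_map)

    @property
    def child_ids(self) -> list[str]:
        return [c for c, _ in self.dyad_map]

    @property
    def parent_ids(self) -> list[str]:
        return [p for _, p in self.dyad_map]

    @property
    def feature_ids(self) -> list[str]:
        return self.children.feature_ids

    @property
    def modality(self) -> Modality:
        return self.children.modality

    def subset_dyads(self, indices: Sequence[int]) -> "DyadCohort":
        dm = [self.dyad_map[i] for i in indices]
        kids = [c for c, _ in dm]
        pars = [p for _, p in dm]
        return DyadCohort(
            self.children.subset_subjects(kids),
            self.parents.subset_subjects(pars),
            dm,
            self.covariates.for_subjects(kids) if self.covariates is not None else None,
        )

    def mask_features(self, feature_ids: Sequence[str]) -> "DyadCohort":
        return DyadCohort(
            self.children.subset_features(feature_ids),
            self.parents.subset_features(feature_ids),
            list(self.dyad_map),
            self.covariates,
        )


# ---------------------------------------------------------------------
# FC vectorization
# ---------------------------------------------------------------------

def edge_labels(node_ids: Sequence[str]) -> list[str]:
    """Edge labels for the strictly-lower-triangle ordering: row-major
    over pairs (i, j) with i > j (0-based)."""
    node_ids = [str(n) for n in node_ids]
    return [
        f"{node_ids[i]}{EDGE_SEP}{node_ids[j]}"
        for i in range(1, len(node_ids))
        for j in range(i)
    ]


def split_edge_label(label: str) -> tuple[str, str]:
    a, sep, b = label.partition(EDGE_SEP)
    if not sep:
        raise ValidationError(f"{label!r} is not an edge label (missing {EDGE_SEP!r})")
    return a, b


def vectorize_lower_triangle(
    matrix: np.ndarray, node_ids: Sequence[str], tol: float = 1e-8
) -> tuple[np.ndarray, list[str]]:
    """Vectorize a symmetric node×node matrix into its n(n−1)/2 strictly
    lower-triangular entries (row-major over i > j), labeled by node pair.

    The diagonal is discarded. A 268-node matrix yields 35,778 edges.
    """
    matrix = np.asarray(matrix, dtype=float)
    node_ids = [str(n) for n in node_ids]
    n = len(node_ids)
    if matrix.shape != (n, n):
        raise ValidationError(f"matrix shape {matrix.shape} does not match {n} node ids")
    tri = np.tril_indices(n, k=-1)
    off = matrix[tri]
    if not np.all(np.isfinite(off)):
        k = int(np.argmax(~np.isfinite(off)))
        raise ValidationError(
            f"non-finite off-diagonal entry at ({tri[0][k]}, {tri[1][k]})"
        )
    asym = np.abs(matrix - matrix.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > tol:
        raise ValidationError(
            f"matrix is not symmetric: |A[{worst[0]},{worst[1]}] - A[{worst[1]},{worst[0]}]| "
            f"= {asym[worst]:.3g} > {tol:g}"
        )
    return off.copy(), edge_labels(node_ids)


def unvectorize_lower_triangle(
    values: np.ndarray, node_ids: Sequence[str], diagonal: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle` (used as round-trip
    oracle): re-embed an edge vector into a symmetric matrix."""
    n = len(node_ids)
    values = np.asarray(values, dtype=float)
    if values.size != n * (n - 1) // 2:
        raise ValidationError(f"expected {n * (n - 1) // 2} values, got {values.size}")
    out = np.full((n, n), float(diagonal))
    tri = np.tril_indices(n, k=-1)
    out[tri] = values
    out[(tri[1], tri[0])] = values
    return out


# ---------------------------------------------------------------------
# COMB assembly
# ---------------------------------------------------------------------

def assemble_comb(
    fc: FeatureMatrix, gmv: FeatureMatrix, standardize: bool = True
) -> FeatureMatrix:
    """Concatenate FC then GMV features per subject into one COMB vector.

    With ``standardize`` (default) each feature column is z-scored across
    subjects within its own modality before concatenation, putting
    correlations (|x| ≤ 1) and volumes on a common scale.
    """
    if set(fc.subject_ids) != set(gmv.subject_ids):
        diff = sorted(set(fc.subject_ids) ^ set(gmv.subject_ids))
        raise ValidationError(f"subject sets differ between FC and GMV: {diff}")
    gmv = gmv.subset_subjects(fc.subject_ids)

    def _cols(fm: FeatureMatrix) -> np.ndarray:
        if not standardize:
            return fm.values
        mu = fm.values.mean(axis=0)
        sd = fm.values.std(axis=0, ddof=1) if fm.n_subjects > 1 else np.ones(fm.n_features)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValidationError(
                f"cannot z-score constant feature column(s): "
                f"{[fm.feature_ids[i] for i in zero[:5]]}"
            )
        return (fm.values - mu) / sd

    values = np.hstack([_cols(fc), _cols(gmv)])
    return FeatureMatrix(fc.subject_ids, fc.feature_ids + gmv.feature_ids, values, Modality.COMB)


# ---------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------

def read_feature_matrix(path: "str | Path", modality: "Modality | str") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    if df[first].duplicated().any():
        dup = sorted(df[first][df[first].duplicated()].unique())
        raise ValidationError(f"duplicated subject_id in {path}: {dup}")
    df = df.set_index(first)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValidationError(
                f"non-numeric feature cell in {path}, column {col!r}, "
                f"row(s) {list(bad[:3])}"
            ) from exc
    if df.isna().any().any():
        raise ValidationError(f"missing feature values in {path}; incomplete subjects must be excluded")
    return FeatureMatrix.from_frame(df, modality)


def write_feature_matrix(fm: FeatureMatrix, path: "str | Path") -> None:
    df = fm.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_dyad_map(path: "str | Path") -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["child_id", "parent_id"]:
        raise ValidationError(
            f"dyad map must have columns child_id<TAB>parent_id, got {list(df.columns)}"
        )
    return [(str(c), str(p)) for c, p in zip(df["child_id"], df["parent_id"])]


def read_node_metadata(path: "str | Path") -> NetworkAtlas:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"node_id", "network", "lobe"}
    if not required <= set(df.columns):
        raise ValidationError(f"node metadata needs columns {sorted(required)}, got {list(df.columns)}")
    nodes = list(df["node_id"])
    hemi = (
        dict(zip(nodes, df["hemisphere"])) if "hemisphere" in df.columns else {}
    )
    return NetworkAtlas(nodes, dict(zip(nodes, df["network"])), dict(zip(nodes, df["lobe"])), hemi)


def read_covariates(path: "str | Path") -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValidationError("covariates TSV needs a subject_id column")
    return CovariateTable(df.set_index("subject_id"))


def read_cohort(
    features_child_path: "str | Path",
    features_parent_path: "str | Path",
    dyad_map_path: "str | Path",
    node_metadata_path: "str | Path | None" = None,
    covariates_path: "str | Path | None" = None,
    modality: "Modality | str" = Modality.FC,
    strict: bool = True,
) -> tuple[DyadCohort, NetworkAtlas | None]:
    """Load and validate a full cohort from TSV files.

    With ``strict`` (default), a dyad-map row naming an unknown subject
    is an error; with ``strict=False`` such rows are dropped and logged.
    """
    children = read_feature_matrix(features_child_path, modality)
    parents = read_feature_matrix(features_parent_path, modality)
    dyads = read_dyad_map(dyad_map_path)

    known_c, known_p = set(children.subject_ids), set(parents.subject_ids)
    bad = [(c, p) for c, p in dyads if c not in known_c or p not in known_p]
    if bad:
        names = [c if c not in known_c else p for c, p in bad]
        if strict:
            raise ValidationError(f"dyad map references unknown subject(s): {names}")
        logger.warning("dropping %d dyad(s) with unknown subjects: %s", len(bad), names)
        dyads = [d for d in dyads if d not in bad]
    kept_c = {c for c, _ in dyads}
    kept_p = {p for _, p in dyads}
    extra_c = sorted(known_c - kept_c)
    extra_p = sorted(known_p - kept_p)
    if extra_c or extra_p:
        logger.info("dropping unmapped subjects: children=%s parents=%s", extra_c, extra_p)
        children = children.subset_subjects([c for c, _ in dyads])
        parents = parents.subset_subjects([p for _, p in dyads])

    cov = read_covariates(covariates_path) if covariates_path is not None else None
    atlas = read_node_metadata(node_metadata_path) if node_metadata_path is not None else None
    cohort = DyadCohort(children, parents, dyads, cov)
    logger.info("loaded cohort: N=%d dyads, M=%d features (%s)", cohort.n_dyads,
                cohort.children.n_features, cohort.modality.value)
    return cohort, atlas


def write_cohort(cohort: DyadCohort, out_dir: "str | Path", atlas: NetworkAtlas | None = None) -> dict[str, Path]:
    """Write a cohort to the TSV layout read by :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = cohort.modality.value.lower()
    paths = {
        "children": out / f"children_{m}.tsv",
        "parents": out / f"parents_{m}.tsv",
        "dyads": out / "dyad_map.tsv",
    }
    write_feature_matrix(cohort.children, paths["children"])
    write_feature_matrix(cohort.parents, paths["parents"])
    pd.DataFrame(cohort.dyad_map, columns=["child_id", "parent_id"]).to_csv(
        paths["dyads"], sep="\t", index=False
    )
    if cohort.covariates is not None:
        paths["covariates"] = out / "covariates.tsv"
        df = cohort.covariates.data.copy()
        df.index.name = "subject_id"
        df.to_csv(paths["covariates"], sep="\t", float_format="%.17g")
    if atlas is not None:
        paths["nodes"] = out / "node_metadata.tsv"
        pd.DataFrame(
            {
                "node_id": atlas.node_ids,
                "network": [atlas.network_of[n] for n in atlas.node_ids],
                "lobe": [atlas.lobe_of[n] for n in atlas.node_ids],
                "hemisphere": [atlas.hemisphere_of.get(n, "L") for n in atlas.node_ids],
            }
        ).to_csv(paths["nodes"], sep="\t", index=False)
    return paths
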