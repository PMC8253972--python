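"""Per-feature contribution measures.

Which edges (FC) or regions (GMV) drive dyad identification? For dyad i
and feature f the *product* φ_ii(f) multiplies the child's and parent's
(per-subject z-scored) values; stranger products φ_ij(f) use another
dyad's parent. The empirical probability P_i(f) counts how often a
stranger product beats the dyad product in either direction, the
*differential power* DP(f) = Σ_i −ln P_i(f) rewards features whose dyad
product reliably wins, and the *group consistency* φ̄(f) = mean_i φ_ii(f)
flags features that are large in everyone and hence not discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import DyadCohort, FeatureMatrix, NetworkAtlas, ValidationError


def zscore_subject_vectors(
    features: FeatureMatrix, feature_mask: "Iterable[str] | None" = None
) -> FeatureMatrix:
    """Center and scale each subject's (masked) vector by its own mean
    and sample SD (ddof=1), so that Σ_f z_c(f)·z_p(f)/(M−1) equals the
    child-parent Pearson correlation."""
    if feature_mask is not None:
        features = features.subset_features(list(feature_mask))
    if features.n_features < 3:
        raise ValidationError("need at least 3 features to standardize")
    X = features.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance subject vector(s): {[features.subject_ids[i] for i in zero[:5]]}"
        )
    return FeatureMatrix(
        features.subject_ids, features.feature_ids, (X - mu) / sd, features.modality
    )


@dataclass
class EdgeProducts:
    """Standardized child/parent values from which any product
    φ_ij(f) = X_i^child(f) · X_j^parent(f) is formed on demand."""

    feature_ids: list[str]
    child_values: np.ndarray   # N × M (z-scored per subject unless raw)
    parent_values: np.ndarray  # N × M
    standardized: bool

    @property
    def n_dyads(self) -> int:
        return self.child_values.shape[0]

    @property
    def dyad_products(self) -> np.ndarray:
        """φ_ii(f) for every dyad: N × M."""
        return self.child_values * self.parent_values

    def phi(self, i: int, j: int) -> np.ndarray:
        """φ_ij(f) = child i × parent j, length M."""
        return self.child_values[i] * self.parent_values[j]


def product_vectors(
    cohort: DyadCohort,
    feature_mask: "Iterable[str] | None" = None,
    standardize: bool = True,
) -> EdgeProducts:
    """Build the product machinery for a cohort; per-subject z-scoring
    (default) makes the dyad products decompose the Pearson similarity."""
    if feature_mask is not None:
        cohort = cohort.mask_features(list(feature_mask))
    if standardize:
        zc = zscore_subject_vectors(cohort.children).values
        zp = zscore_subject_vectors(cohort.parents).values
    else:
        zc = cohort.children.values
        zp = cohort.parents.values
    return EdgeProducts(list(cohort.feature_ids), zc, zp, standardize)


def empirical_probability(products: EdgeProducts, chunk: int = 256) -> np.ndarray:
    """P_i(f) = [#{j≠i: φ_ji(f) > φ_ii(f)} + #{j≠i: φ_ij(f) > φ_ii(f)}]
    / (2(N−1)), floored at 1/(2(N−1)) so that −ln P stays finite.

    Low P_i marks a discriminative feature. Each dyad faces exactly N−1
    strangers per comparison direction, hence the 2(N−1) denominator.
    """
    n = products.n_dyads
    if n < 2:
        raise ValidationError("empirical probability needs N >= 2")
    zc, zp = products.child_values, products.parent_values
    m = zc.shape[1]
    d = zc * zp  # φ_ii, N × M
    counts = np.zeros((n, m), dtype=np.int64)
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        # prod[j, i, f] = child j * parent i ; prod[i, j, f] = child i * parent j
        prod = zc[:, None, sl.start:sl.stop] * zp[None, :, sl.start:sl.stop]  # (child, parent, f)
        dd = d[:, sl]
        # direction 1: stranger child j with dyad-i's parent -> φ_ji > φ_ii
        counts[:, sl] += (prod > dd[None, :, :]).sum(axis=0)
        # direction 2: dyad-i's child with stranger parent j -> φ_ij > φ_ii
        counts[:, sl] += (prod > dd[:, None, :]).sum(axis=1)
    floor = 1.0 / (2 * (n - 1))
    return np.maximum(counts / (2 * (n - 1)), floor)


def differential_power(p_i: np.ndarray) -> np.ndarray:
    """DP(f) = Σ_i −ln(P_i(f)); larger = more helpful for
    identification. Zero iff every dyad's P_i(f) = 1."""
    p = np.asarray(p_i, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("P_i entries must lie in (0, 1]")
    return -np.log(p).sum(axis=0)


def group_consistency(products: EdgeProducts) -> np.ndarray:
    """φ̄(f) = mean over dyads of φ_ii(f). High values mark features
    similar across all dyads — group-consistent but not helpful for
    telling dyads apart."""
    return products.dyad_products.mean(axis=0)


@dataclass
class EdgeMeasureResult:
    feature_ids: list[str]
    phi_bar: np.ndarray  # group consistency per feature
    p_i: np.ndarray      # dyads × features empirical probabilities
    dp: np.ndarray       # differential power per feature
    n_dyads: int


def edge_measures(
    cohort: DyadCohort,
    feature_mask: "Iterable[str] | None" = None,
    standardize: bool = True,
) -> EdgeMeasureResult:
    """One-call computation of products, P_i, DP and φ̄ for a cohort."""
    products = product_vectors(cohort, feature_mask=feature_mask, standardize=standardize)
    p_i = empirical_probability(products)
    return EdgeMeasureResult(
        feature_ids=products.feature_ids,
        phi_bar=group_consistency(products),
        p_i=p_i,
        dp=differential_power(p_i),
        n_dyads=products.n_dyads,
    )


def top_percentile(
    measure: np.ndarray, feature_ids: Sequence[str], percentile: float
) -> list[str]:
    """Feature ids at or above the given empirical percentile (99.75 for
    the most discriminative FC edges, 90 for GMV regions).

    The cut is the ⌈(1 − percentile/100)·M⌉-th largest value, so a
    99.75th-percentile selection over 400 features keeps exactly 1 and
    over 35,778 edges keeps 90; ties at the cut are all included.
    """
    if not 0 < percentile < 100:
        raise ValidationError("percentile must be in (0, 100)")
    values = np.asarray(measure, dtype=float)
    if values.size != len(feature_ids):
        raise ValidationError("measure length must match feature_ids")
    k = max(1, int(np.ceil((1 - percentile / 100) * values.size)))
    cut = np.sort(values)[::-1][k - 1]
    return [f for f, v in zip(feature_ids, values) if v >= cut]


def lobe_normalized_counts(
    selected_nodes: Iterable[str], atlas: NetworkAtlas
) -> dict[str, float]:
    """Per anatomical lobe: (#selected nodes in lobe) / (#atlas nodes in
    lobe); selections spread across the brain give flat profiles."""
    selected = [str(n) for n in selected_nodes]
    unknown = sorted(set(selected) - set(atlas.node_ids))
    if unknown:
        raise ValidationError(f"selected node(s) not in atlas: {unknown}")
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for n in atlas.node_ids:
        lobe = atlas.lobe_of[n]
        totals[lobe] = totals.get(lobe, 0) + 1
        hits.setdefault(lobe, 0)
    for n in set(selected):
        hits[atlas.lobe_of[n]] += 1
    return {lobe: hits[lobe] / totals[lobe] for lobe in totals}
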