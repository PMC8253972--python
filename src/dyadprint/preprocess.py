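"""Vector-level preprocessing filters.

Everything here operates on already-extracted feature tables or
framewise-displacement (FD) series: scrubbing masks, motion distribution
vectors, ordinary-least-squares confound removal, and the subject
exclusion rules used by the motion- and phenotype-controlled analyses.
Image-level preprocessing is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .cohort import DyadCohort, FeatureMatrix, Modality, ValidationError

logger = logging.getLogger(__name__)

FD_THRESHOLD_MM = 0.5
MOTION_BINS = 20


def scrub_mask(fd_series: np.ndarray, threshold: float = FD_THRESHOLD_MM) -> np.ndarray:
    """Boolean keep-mask for motion scrubbing.

    For each offending frame o with FD(o) > threshold, frames
    {o−1, o, o+1, o+2} are removed (window clipped at the series
    bounds); under consecutive offenders the per-offender windows are
    unioned. Returns True for retained frames.
    """
    fd = np.asarray(fd_series, dtype=float)
    if fd.ndim != 1:
        raise ValidationError("FD series must be 1-D")
    if np.any(~np.isfinite(fd)) or np.any(fd < 0):
        raise ValidationError("FD values must be finite and non-negative")
    offenders = np.flatnonzero(fd > threshold)
    keep = np.ones(fd.size, dtype=bool)
    for o in offenders:
        keep[max(o - 1, 0) : min(o + 3, fd.size)] = False
    return keep


def motion_histogram(fd_series: np.ndarray) -> np.ndarray:
    """20-bin motion distribution vector over [0, 1] mm, bin width 0.05.

    Values above 1 mm are clipped into the last bin; the vector is
    normalized to sum to 1 so that it can be compared across scans of
    different (post-scrubbing) lengths.
    """
    fd = np.asarray(fd_series, dtype=float)
    if fd.size == 0:
        raise ValidationError("empty FD series")
    if np.any(~np.isfinite(fd)) or np.any(fd < 0):
        raise ValidationError("FD values must be finite and non-negative")
    edges = np.linspace(0.0, 1.0, MOTION_BINS + 1)
    counts, _ = np.histogram(np.clip(fd, 0.0, 1.0), bins=edges)
    return counts / counts.sum()


def motion_feature_matrix(fd_by_subject: Mapping[str, np.ndarray]) -> FeatureMatrix:
    """Stack per-subject motion histograms into a MOTION FeatureMatrix."""
    ids = list(fd_by_subject)
    rows = np.vstack([motion_histogram(fd_by_subject[s]) for s in ids])
    labels = [f"fd_bin_{i:02d}" for i in range(MOTION_BINS)]
    return FeatureMatrix(ids, labels, rows, Modality.MOTION)


def residualize_features(
    features: FeatureMatrix, confounds: "pd.DataFrame | np.ndarray"
) -> FeatureMatrix:
    """Regress confounds out of every feature column.

    Each column of ``features.values`` is replaced by its OLS residual on
    [intercept, confounds] across subjects; output columns have mean ~0.
    """
    if isinstance(confounds, pd.DataFrame):
        conf = confounds.reindex(features.subject_ids)
        if conf.isna().any().any():
            missing = list(conf.index[conf.isna().any(axis=1)])
            raise ValidationError(f"missing confound values for subjects {missing}")
        names = list(conf.columns)
        C = conf.to_numpy(dtype=float)
    else:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = [f"confound_{i}" for i in range(C.shape[1])]
    if C.shape[0] != features.n_subjects:
        raise ValidationError("confound rows must match feature-matrix subjects")

    X = np.column_stack([np.ones(C.shape[0]), C])
    # pivoted QR exposes (near-)collinear columns by tiny R diagonal
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if np.any(diag <= tol):
        dead = [piv[i] for i in np.flatnonzero(diag <= tol)]
        bad = sorted(names[i - 1] for i in dead if i > 0)
        raise ValidationError(f"rank-deficient confounds; collinear column(s): {bad}")

    beta, *_ = np.linalg.lstsq(X, features.values, rcond=None)
    resid = features.values - X @ beta
    return FeatureMatrix(features.subject_ids, features.feature_ids, resid, features.modality)


def high_motion_mask(mean_fd: np.ndarray, fraction: float = 0.25) -> np.ndarray:
    """Boolean exclusion mask: True for subjects in the top ``fraction``
    of mean FD. Ties at the cut are all excluded (conservative)."""
    fd = np.asarray(mean_fd, dtype=float)
    if np.any(~np.isfinite(fd)):
        raise ValidationError("mean FD must be finite for all subjects")
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    k = int(np.ceil(fraction * fd.size))
    cut = np.sort(fd)[::-1][k - 1]
    return fd >= cut


def exclude_high_motion(
    cohort: DyadCohort,
    fd_by_timepoint: "pd.DataFrame | None" = None,
    fraction: float = 0.25,
) -> DyadCohort:
    """Drop dyads whose child is in the top ``fraction`` of mean FD at
    *any* provided timepoint.

    ``fd_by_timepoint`` is children × timepoints; when omitted, the
    cohort covariates' single ``mean_fd`` column is used.
    """
    kids = cohort.child_ids
    if fd_by_timepoint is None:
        if cohort.covariates is None:
            raise ValidationError("no covariates; pass fd_by_timepoint explicitly")
        fd_by_timepoint = cohort.covariates.column("mean_fd").to_frame("mean_fd")
    fd = fd_by_timepoint.reindex(kids)
    if fd.isna().any().any():
        missing = list(fd.index[fd.isna().any(axis=1)])
        raise ValidationError(f"missing mean_fd for subjects {missing}")
    excluded = np.zeros(len(kids), dtype=bool)
    for col in fd.columns:
        excluded |= high_motion_mask(fd[col].to_numpy(), fraction)
    keep_idx = np.flatnonzero(~excluded)
    logger.info(
        "high-motion exclusion: retained %d/%d dyads (%.1f%%)",
        keep_idx.size, len(kids), 100 * keep_idx.size / len(kids),
    )
    return cohort.subset_dyads(keep_idx.tolist())


@dataclass
class OutlierMask:
    keep: np.ndarray    # True = retained (absent scores are retained)
    absent: np.ndarray  # True = score missing, keep slot is undefined


def exclude_phenotype_outliers(scores: np.ndarray, k: float = 1.5) -> OutlierMask:
    """Keep scores ≤ mean + k·SD (sample SD, n−1), computed over the
    present scores; absent (NaN) slots are flagged, not excluded."""
    s = np.asarray(scores, dtype=float)
    absent = np.isnan(s)
    present = s[~absent]
    if present.size == 0:
        raise ValidationError("all phenotype scores are absent")
    if present.size < 2:
        raise ValidationError("need at least 2 finite scores for mean + k*SD")
    cut = present.mean() + k * present.std(ddof=1)
    keep = np.ones(s.size, dtype=bool)
    keep[~absent] = present <= cut
    return OutlierMask(keep=keep, absent=absent)


def median_split(scores: np.ndarray) -> np.ndarray:
    """Label each score 'upper' (strictly above the median) or 'lower'
    (at or below it; ties assigned lower). Absent scores get ''.

    The split is invariant to any strictly monotone transform, e.g. the
    square-root transform applied to testosterone before analysis.
    """
    s = np.asarray(scores, dtype=float)
    finite = s[~np.isnan(s)]
    if finite.size < 4:
        raise ValidationError("need at least 4 finite scores to median-split")
    if np.all(finite == finite[0]):
        raise ValidationError("all scores identical; no median split possible")
    med = np.median(finite)
    out = np.empty(s.size, dtype=object)
    out[:] = ""
    out[~np.isnan(s)] = np.where(finite > med, "upper", "lower")
    n_up = int((out == "upper").sum())
    n_lo = int((out == "lower").sum())
    logger.info("median split: upper=%d lower=%d (median=%.4g)", n_up, n_lo, med)
    return out
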