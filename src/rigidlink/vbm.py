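"""Voxel-based morphometry statistics on preprocessed GMV volumes.

Covariate-adjusted voxelwise regression (t map for the behavioral
regressor with age/IQ covariates), Benjamini-Hochberg FDR thresholding,
sign-split maps, conjunction (voxelwise intersection), 26-connectivity
cluster extraction with peak reporting, ROI/whole-brain summaries, and
group-difference maps. The pipeline consumes already-preprocessed GMV
images; no segmentation/normalization/smoothing happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VoxelStatMap",
    "ClusterSet",
    "voxelwise_regression",
    "fdr_threshold",
    "signed_maps",
    "conjunction",
    "extract_clusters",
    "roi_mean_gmv",
    "whole_brain_gmv",
    "relative_gmv",
    "group_difference_map",
]


@dataclass
class VoxelStatMap:
    """Per-voxel t and two-sided (or one-sided) p for one regressor."""

    t_values: np.ndarray  # 3D, 0 outside mask
    p_values: np.ndarray  # 3D, 1 outside mask
    dof: int
    regressor: str
    mask: np.ndarray
    tail: str = "two-sided"


@dataclass
class ClusterSet:
    labels: np.ndarray  # 3D int label image, 0 = background
    table: pd.DataFrame  # label, size, peak_t, peak i/j/k, peak mm


def _stack_values(images) -> tuple[np.ndarray, np.ndarray, float]:
    """Accept a GMVStack or a list of 3D arrays (+ mask separately)."""
    if hasattr(images, "values") and hasattr(images, "mask"):
        return (
            np.asarray(images.values, dtype=float),
            np.asarray(images.mask, dtype=bool),
            float(getattr(images, "voxel_size_mm", 1.0)),
        )
    arr = np.asarray(images, dtype=float)
    return arr, np.ones(arr.shape[1:], dtype=bool), 1.0


def _design_matrix(
    behavior: np.ndarray, covariates: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    behavior = np.asarray(behavior, dtype=float)
    n = len(behavior)
    cols = [np.ones(n), behavior]
    names = ["intercept", "behavior"]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            for name in covariates.columns:
                cols.append(covariates[name].to_numpy(dtype=float))
                names.append(str(name))
        else:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] == n:
                cov = cov.T
            for i, row in enumerate(cov):
                cols.append(row)
                names.append(f"cov{i}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")
    return X, names


def _ols_t_map(
    Y: np.ndarray, X: np.ndarray, coef_index: int, tail: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """t and p for one coefficient, fitted simultaneously at all voxels.

    Y: (n_subjects, n_voxels); X: (n_subjects, k)."""
    n, k = X.shape
    dof = n - k
    if dof < 1:
        raise ValueError(f"not enough subjects ({n}) for {k} predictors")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (k, V)
    resid = Y - X @ beta
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[coef_index, coef_index], 1e-300))
    t = beta[coef_index] / se
    if tail == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    elif tail == "less":
        p = stats.t.cdf(t, dof)
    elif tail == "greater":
        p = stats.t.sf(t, dof)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, p, dof


def voxelwise_regression(
    images,
    behavior: np.ndarray,
    covariates=None,
    mask: np.ndarray | None = None,
    regressor_name: str = "behavior",
    tail: str = "two-sided",
) -> VoxelStatMap:
    """Per in-mask voxel, OLS of GMV on [intercept, behavior, covariates];
    returns the t/p map for the behavior coefficient."""
    values, stack_mask, _ = _stack_values(images)
    mask = stack_mask if mask is None else (np.asarray(mask, bool) & stack_mask)
    behavior = np.asarray(behavior, dtype=float)
    if np.ptp(behavior) == 0:
        raise ValueError("behavior vector is constant")
    if values.shape[0] != len(behavior):
        raise ValueError("number of images and behavior values differ")
    X, _ = _design_matrix(behavior, covariates)
    Y = values[:, mask]
    t, p, dof = _ols_t_map(Y, X, coef_index=1, tail=tail)
    t_map = np.zeros(mask.shape)
    p_map = np.ones(mask.shape)
    t_map[mask] = t
    p_map[mask] = p
    return VoxelStatMap(
        t_values=t_map, p_values=p_map, dof=dof, regressor=regressor_name,
        mask=mask, tail=tail,
    )


def fdr_threshold(stat_map: VoxelStatMap, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg over all in-mask voxel p-values; boolean mask
    of survivors."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie in (0,1), got {q}")
    mask = stat_map.mask
    if not mask.any():
        raise ValueError("empty analysis mask")
    p = stat_map.p_values[mask]
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.zeros(mask.shape, dtype=bool)
    out[mask] = reject
    return out


def signed_maps(
    stat_map: VoxelStatMap, fdr_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split FDR survivors by the sign of t: (positive, negative)."""
    pos = fdr_mask & (stat_map.t_values > 0)
    neg = fdr_mask & (stat_map.t_values < 0)
    return pos, neg


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise intersection of two suprathreshold masks."""
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"grid mismatch: {mask_a.shape} vs {mask_b.shape}")
    return mask_a & mask_b


def _mm_coords(ijk: np.ndarray, shape, voxel_size_mm: float, affine=None) -> np.ndarray:
    if affine is not None:
        homo = np.append(ijk, 1.0)
        return (affine @ homo)[:3]
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    return (np.asarray(ijk, dtype=float) - center) * voxel_size_mm


def extract_clusters(
    mask: np.ndarray,
    t_map: np.ndarray,
    voxel_size_mm: float = 1.0,
    affine: np.ndarray | None = None,
) -> ClusterSet:
    """26-connectivity components of a suprathreshold mask; per cluster,
    size and the max-|t| peak in voxel indices and mm."""
    mask = np.asarray(mask, bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n_clusters = ndimage.label(mask, structure=structure)
    rows = []
    for lab in range(1, n_clusters + 1):
        sel = labels == lab
        size = int(sel.sum())
        abs_t = np.where(sel, np.abs(t_map), -np.inf)
        peak_ijk = np.unravel_index(int(np.argmax(abs_t)), mask.shape)
        peak_mm = _mm_coords(np.asarray(peak_ijk), mask.shape, voxel_size_mm, affine)
        rows.append(
            {
                "label": lab,
                "size": size,
                "peak_t": float(t_map[peak_ijk]),
                "peak_i": peak_ijk[0],
                "peak_j": peak_ijk[1],
                "peak_k": peak_ijk[2],
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "size", "peak_t", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm",
        ],
    )
    if len(table):
        table = table.sort_values("size", ascending=False, ignore_index=True)
    return ClusterSet(labels=labels, table=table)


def roi_mean_gmv(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean GMV over an ROI."""
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    return float(np.asarray(image, dtype=float)[roi_mask].mean())


def whole_brain_gmv(image: np.ndarray, mask: np.ndarray) -> float:
    """Total in-mask GMV (sum of modulated voxel values)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    return float(np.asarray(image, dtype=float)[mask].sum())


def relative_gmv(image: np.ndarray, roi_mask: np.ndarray, mask: np.ndarray) -> float:
    """ROI mean GMV as a fraction of whole-brain total GMV; invariant to
    global rescaling of the image."""
    return roi_mean_gmv(image, roi_mask) / whole_brain_gmv(image, mask)


def group_difference_map(
    images_a,
    images_b,
    covariates=None,
    mask: np.ndarray | None = None,
    q: float = 0.05,
    tail: str = "two-sided",
) -> tuple[VoxelStatMap, np.ndarray]:
    """Per-voxel two-sample comparison (group A vs B) as OLS on a group
    indicator (+1 = group A) with optional covariates, plus the BH-FDR
    survivor mask. ``tail='less'`` flags voxels where group A < group B.
    """
    values_a, mask_a, vox = _stack_values(images_a)
    values_b, mask_b, _ = _stack_values(images_b)
    if values_a.shape[0] < 3 or values_b.shape[0] < 3:
        raise ValueError("each group needs at least 3 subjects")
    values = np.concatenate([values_a, values_b], axis=0)
    indicator = np.concatenate(
        [np.ones(values_a.shape[0]), np.zeros(values_b.shape[0])]
    )
    stack_mask = mask_a & mask_b
    mask = stack_mask if mask is None else (np.asarray(mask, bool) & stack_mask)
    from types import SimpleNamespace

    stat_map = voxelwise_regression(
        SimpleNamespace(values=values, mask=mask, voxel_size_mm=vox),
        indicator,
        covariates=covariates,
        regressor_name="group",
        tail=tail,
    )
    return stat_map, fdr_threshold(stat_map, q)
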