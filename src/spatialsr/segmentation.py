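"""Tissue-focus splitting and tumor/stroma compartment segmentation.

A slide is first split into tissue islands ("foci") by density-based
clustering of all cell positions (DBSCAN, 300-μm neighborhood, 50-point
minimum). Within each focus, Gaussian kernel intensity surfaces are
estimated from the cancer cells (KDE_tumor) and the panel-negative cells
(KDE_negative), each max-normalized; a cell position is labeled tumor
where KDE_tumor exceeds KDE_negative and stroma otherwise. Compartment
areas come from thresholding the normalized surfaces at 0.1, and distal
stroma (beyond 150 μm from the nearest cancer cell) can be trimmed to
harmonize tumor purity across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .data_model import CellTable

logger = logging.getLogger(__name__)

AREA_INTENSITY_THRESHOLD = 0.1
DEFAULT_PIXEL_SIZE = 10.0
MIN_GRID = 64  # minimum pixels per axis of a focus grid


class BandwidthError(ValueError):
    """Automatic bandwidth selection is impossible (fewer than 2 points)."""


@dataclass
class IntensitySurface:
    """Gaussian-kernel intensity on a regular pixel grid.

    ``values[i, j]`` is the intensity at x-center ``x0 + (i + 0.5)·px``
    and y-center ``y0 + (j + 0.5)·px``.
    """

    x0: float
    y0: float
    pixel_size: float
    values: np.ndarray
    bandwidth: float
    normalized: bool

    def max_normalized(self) -> "IntensitySurface":
        m = self.values.max() if self.values.size else 0.0
        vals = self.values / m if m > 0 else self.values.copy()
        return IntensitySurface(
            self.x0, self.y0, self.pixel_size, vals, self.bandwidth, True
        )

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the pixel grid at arbitrary points."""
        from scipy.interpolate import RegularGridInterpolator

        nx, ny = self.values.shape
        xc = self.x0 + (np.arange(nx) + 0.5) * self.pixel_size
        yc = self.y0 + (np.arange(ny) + 0.5) * self.pixel_size
        itp = RegularGridInterpolator(
            (xc, yc), self.values, bounds_error=False, fill_value=None, method="linear"
        )
        return itp(np.atleast_2d(points))


def split_foci(ct: CellTable, eps: float = 300.0, min_pts: int = 50) -> CellTable:
    """Assign tissue-island (focus) ids by DBSCAN on all cell positions.

    Density-reachable groups share an id (0, 1, ...); cells not reachable
    from any core point are noise and get id −1. Runs per sample.
    """
    if len(ct) == 0:
        raise ValueError("cannot split foci of an empty cell table")
    df = ct.df.copy()
    for sid in ct.sample_ids:
        mask = df["sample_id"] == sid
        xy = df.loc[mask, ["x", "y"]].to_numpy(dtype=float)
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(xy)
        df.loc[mask, "focus_id"] = labels
    out = CellTable(df=df)
    n_noise = int((df["focus_id"] == -1).sum())
    if n_noise:
        logger.info("%d cell(s) labeled as noise (focus_id = -1)", n_noise)
    return out


def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule bandwidth for a 2-d point pattern (isotropic)."""
    n = len(points)
    if n < 2:
        raise BandwidthError("Scott's rule needs at least 2 points")
    sd = float(np.mean(np.std(points, axis=0, ddof=1)))
    return max(sd * n ** (-1.0 / 6.0), 1e-6)


def select_bandwidth_lcv(
    points: np.ndarray,
    window: tuple[float, float, float, float],
    n_grid: int = 16,
) -> float:
    """Likelihood cross-validation bandwidth for a point-process KDE.

    Maximizes the leave-one-out log-likelihood Σ_i log λ̂_{−i}(x_i) over a
    logarithmic grid of ``n_grid`` bandwidths spanning [2 μm, window
    diagonal / 4]. When the criterion is degenerate (maximum on the grid
    boundary, i.e. monotone likelihood), falls back to Scott's rule.
    """
    n = len(points)
    if n < 2:
        raise BandwidthError("automatic bandwidth needs at least 2 points")
    xmin, xmax, ymin, ymax = window
    diag = float(np.hypot(xmax - xmin, ymax - ymin))
    grid = np.geomspace(2.0, max(diag / 4.0, 2.5), n_grid)

    d2 = _pairwise_sq_dists(points)
    np.fill_diagonal(d2, np.inf)  # leave-one-out
    best_h, best_ll = None, -np.inf
    lls = []
    for h in grid:
        lam = np.exp(-d2 / (2 * h * h)).sum(axis=1) / (2 * np.pi * h * h)
        ll = float(np.sum(np.log(np.maximum(lam, 1e-300))))
        lls.append(ll)
        if ll > best_ll:
            best_ll, best_h = ll, h
    i_best = int(np.argmax(lls))
    if i_best in (0, len(grid) - 1):
        fallback = scott_bandwidth(points)
        logger.info(
            "LCV bandwidth degenerate (boundary of grid); Scott fallback %.2f μm",
            fallback,
        )
        return fallback
    return float(best_h)


def _pairwise_sq_dists(points: np.ndarray, chunk: int = 2048) -> np.ndarray:
    n = len(points)
    out = np.empty((n, n))
    for i in range(0, n, chunk):
        diff = points[i : i + chunk, None, :] - points[None, :, :]
        out[i : i + chunk] = np.einsum("ijk,ijk->ij", diff, diff)
    return out


def compute_intensity_surface(
    points: np.ndarray,
    window: tuple[float, float, float, float],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    bandwidth: float | str = "auto",
    normalize: bool = True,
) -> IntensitySurface:
    """Gaussian-kernel intensity of a point pattern on a pixel grid.

    ``bandwidth="auto"`` selects by likelihood cross-validation (needs at
    least 2 points); the surface is max-normalized on request so that
    tumor and negative surfaces are comparable.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        points = points.reshape(0, 2)
    xmin, xmax, ymin, ymax = window
    if bandwidth == "auto":
        bw = select_bandwidth_lcv(points, window)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise BandwidthError("bandwidth must be positive")

    nx = max(int(np.ceil((xmax - xmin) / pixel_size)), MIN_GRID)
    ny = max(int(np.ceil((ymax - ymin) / pixel_size)), MIN_GRID)
    px = (xmax - xmin) / nx
    py = (ymax - ymin) / ny
    pix = float(max(px, py))
    # re-derive a square grid covering the window with the common pixel
    nx = max(int(np.ceil((xmax - xmin) / pix)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pix)), 1)
    xc = xmin + (np.arange(nx) + 0.5) * pix
    yc = ymin + (np.arange(ny) + 0.5) * pix

    if len(points):
        dx2 = (xc[:, None] - points[None, :, 0]) ** 2
        dy2 = (yc[:, None] - points[None, :, 1]) ** 2
        # separable Gaussian: sum_j exp(-(dx²+dy²)/2h²)
        ex = np.exp(-dx2 / (2 * bw * bw))
        ey = np.exp(-dy2 / (2 * bw * bw))
        vals = ex @ ey.T / (2 * np.pi * bw * bw)
    else:
        vals = np.zeros((nx, ny))
    surf = IntensitySurface(
        x0=xmin, y0=ymin, pixel_size=pix, values=vals, bandwidth=bw, normalized=False
    )
    return surf.max_normalized() if normalize else surf


def _focus_window(xy: np.ndarray, pad: float) -> tuple[float, float, float, float]:
    return (
        float(xy[:, 0].min() - pad),
        float(xy[:, 0].max() + pad),
        float(xy[:, 1].min() - pad),
        float(xy[:, 1].max() + pad),
    )


def _focus_surfaces(
    sub: pd.DataFrame, pixel_size: float
) -> tuple[IntensitySurface | None, IntensitySurface | None]:
    """Max-normalized tumor and negative surfaces for one focus."""
    xy = sub[["x", "y"]].to_numpy(dtype=float)
    window = _focus_window(xy, pad=2 * pixel_size)
    out = []
    for ct_name in ("cancer", "negative"):
        pts = sub.loc[sub["cell_type"] == ct_name, ["x", "y"]].to_numpy(dtype=float)
        if len(pts) < 2:
            out.append(None)
            continue
        try:
            surf = compute_intensity_surface(
                pts, window, pixel_size=pixel_size, bandwidth="auto", normalize=True
            )
        except BandwidthError:
            out.append(None)
            continue
        out.append(surf)
    return out[0], out[1]


def assign_compartments(
    ct: CellTable, pixel_size: float = DEFAULT_PIXEL_SIZE
) -> CellTable:
    """Label every cell tumor or stroma by comparing normalized surfaces.

    Per focus, the max-normalized cancer-cell surface is compared with
    the max-normalized negative-cell surface at each cell position
    (bilinear interpolation); tumor where the cancer surface is strictly
    greater, stroma otherwise (ties are stroma). Foci without cancer
    cells are entirely stroma; foci without negative cells entirely
    tumor.
    """
    if (ct.df["focus_id"] == CellTable.UNASSIGNED_FOCUS).any():
        raise ValueError("run split_foci before assign_compartments")
    df = ct.df.copy()
    for (sid, fid), idx in df.groupby(["sample_id", "focus_id"]).groups.items():
        sub = df.loc[idx]
        tumor_surf, neg_surf = _focus_surfaces(sub, pixel_size)
        pos = sub[["x", "y"]].to_numpy(dtype=float)
        if tumor_surf is None and neg_surf is None:
            # no density information at all: fall back on composition
            label = "tumor" if (sub["cell_type"] == "cancer").any() else "stroma"
            df.loc[idx, "compartment"] = label
            continue
        if tumor_surf is None:
            df.loc[idx, "compartment"] = "stroma"
            continue
        if neg_surf is None:
            df.loc[idx, "compartment"] = "tumor"
            continue
        kt = tumor_surf.interpolate(pos)
        kn = neg_surf.interpolate(pos)
        df.loc[idx, "compartment"] = np.where(kt > kn, "tumor", "stroma")
    return CellTable(df=df)


def compute_compartment_areas(
    ct: CellTable,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    threshold: float = AREA_INTENSITY_THRESHOLD,
) -> pd.DataFrame:
    """Tumor, stroma and total tissue areas (μm²) per sample and focus.

    Tumor area counts pixels whose max-normalized cancer surface is
    ≥ 0.1; total tissue counts pixels where the sum of the two
    normalized surfaces is ≥ 0.1; stroma is total − tumor (clipped at 0
    with a warning if numerically negative).
    """
    rows = []
    for (sid, fid), idx in ct.df.groupby(["sample_id", "focus_id"]).groups.items():
        sub = ct.df.loc[idx]
        tumor_surf, neg_surf = _focus_surfaces(sub, pixel_size)
        pixel_area = None
        if tumor_surf is not None:
            pixel_area = tumor_surf.pixel_size ** 2
            tumor_vals = tumor_surf.values
        else:
            tumor_vals = None
        if neg_surf is not None:
            pixel_area = neg_surf.pixel_size ** 2 if pixel_area is None else pixel_area
            neg_vals = neg_surf.values
        else:
            neg_vals = None
        if pixel_area is None:
            tumor_area = total_area = 0.0
        else:
            tumor_area = (
                float((tumor_vals >= threshold).sum()) * pixel_area
                if tumor_vals is not None
                else 0.0
            )
            if tumor_vals is not None and neg_vals is not None:
                combined = tumor_vals + neg_vals
            else:
                combined = tumor_vals if tumor_vals is not None else neg_vals
            total_area = (
                float((combined >= threshold).sum()) * pixel_area
            )
        stroma_area = total_area - tumor_area
        if stroma_area < 0:
            logger.warning(
                "negative stroma area (%.1f μm²) clipped to 0 for sample %s focus %s",
                stroma_area, sid, fid,
            )
            stroma_area = 0.0
        rows.append(
            {
                "sample_id": sid,
                "focus_id": fid,
                "tumor_area": tumor_area,
                "stroma_area": stroma_area,
                "total_area": tumor_area + stroma_area,
            }
        )
    return pd.DataFrame(rows)


def total_areas(areas: pd.DataFrame) -> pd.DataFrame:
    """Sum focus-level areas per sample."""
    return (
        areas.groupby("sample_id")[["tumor_area", "stroma_area", "total_area"]]
        .sum()
        .reset_index()
    )


def trim_distal_stroma(ct: CellTable, max_dist: float = 150.0) -> CellTable:
    """Drop stroma-compartment cells beyond ``max_dist`` of any cancer cell.

    Applied per sample using the cross nearest-cancer-cell distance.
    Tumor-compartment cells are never touched. A sample with no cancer
    cells is returned unchanged with a warning.
    """
    if (ct.df["compartment"] == "unassigned").any():
        raise ValueError("run assign_compartments before trim_distal_stroma")
    keep_parts = []
    for sid in ct.sample_ids:
        sub = ct.df[ct.df["sample_id"] == sid]
        cancer = sub.loc[sub["cell_type"] == "cancer", ["x", "y"]].to_numpy(dtype=float)
        if len(cancer) == 0:
            logger.warning("sample %s has no cancer cells; stroma trim skipped", sid)
            keep_parts.append(sub)
            continue
        tree = cKDTree(cancer)
        stroma_mask = (sub["compartment"] == "stroma").to_numpy()
        d = np.zeros(len(sub))
        if stroma_mask.any():
            d[stroma_mask], _ = tree.query(
                sub.loc[stroma_mask, ["x", "y"]].to_numpy(dtype=float), k=1
            )
        keep = ~stroma_mask | (d <= max_dist)
        keep_parts.append(sub[keep])
    return CellTable(df=pd.concat(keep_parts).reset_index(drop=True))
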