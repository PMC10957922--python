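"""Cross-type first-nearest-neighbor distances and their curve summaries.

A spatial relationship (SR) is the distribution of distances from each
cell of a *reference* type to its closest cell of a *target* type. The
statistic is asymmetric: A→B and B→A are distinct. Distances are computed
on the whole slide, ignoring tumor/stroma compartments and focus
boundaries.

Two curve summaries are derived per distance vector: a unit-area smoothed
empirical density (5-μm sliding window on a 1-μm grid), which is the
input to the Weibull mixed-effects fit, and the empirical G-function
(ECDF of the 1-NN distances) with its truncated area-under-curve
summaries G-AUC-T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .data_model import CellTable


class EmptyTargetError(ValueError):
    """No target cells available for a cross 1-NN query."""

    def __init__(self, msg: str, n_from: int, n_to: int):
        super().__init__(msg)
        self.n_from = n_from
        self.n_to = n_to


@dataclass
class NNDistanceSet:
    """1-NN distances for one (sample, from-type, to-type) triple."""

    sample_id: str
    from_type: str
    to_type: str
    distances: np.ndarray
    n_from: int
    n_to: int


@dataclass
class SmoothedPDF:
    """Unit-area smoothed empirical density on an integer μm grid."""

    grid: np.ndarray
    density: np.ndarray
    window: float


@dataclass
class GCurve:
    """Empirical G-function (ECDF of 1-NN distances) on a μm grid."""

    r: np.ndarray
    values: np.ndarray
    aucs: dict[float, float] = field(default_factory=dict)


def cross_nn_distances(
    ct: CellTable, from_type: str, to_type: str, sample_id: str | None = None
) -> NNDistanceSet:
    """Distance from every reference cell to its nearest target cell.

    For a self-self relationship a cell is excluded as its own neighbor
    (nearest *other* cell of the same type). Ties between equidistant
    targets are interchangeable: only the distance is reported.
    """
    if sample_id is not None:
        ct = ct.for_sample(sample_id)
    sids = ct.sample_ids
    if len(sids) > 1:
        raise ValueError("cross_nn_distances operates on a single sample; pass sample_id")
    sid = sids[0] if sids else ""

    ref = ct.coords(from_type)
    tgt = ct.coords(to_type)
    n_from, n_to = len(ref), len(tgt)
    self_self = from_type == to_type
    if n_from == 0:
        raise EmptyTargetError(
            f"no reference cells of type {from_type!r}", n_from, n_to
        )
    if n_to == 0 or (self_self and n_to < 2):
        raise EmptyTargetError(
            f"no usable target cells of type {to_type!r}", n_from, n_to
        )

    tree = cKDTree(tgt)
    if self_self:
        d, _ = tree.query(ref, k=2)
        dist = d[:, 1]
    else:
        dist, _ = tree.query(ref, k=1)
    return NNDistanceSet(
        sample_id=sid,
        from_type=from_type,
        to_type=to_type,
        distances=np.asarray(dist, dtype=float),
        n_from=n_from,
        n_to=n_to,
    )


def smooth_nn_pdf(d: NNDistanceSet | np.ndarray, window: float = 5.0, step: float = 1.0) -> SmoothedPDF:
    """Sliding-window smoothed density of a 1-NN distance vector.

    At each grid point t (integer multiples of ``step`` over
    [0, max(d) + window]) the distances in the half-open window
    [t − window/2, t + window/2) are counted; the curve is then divided
    by its trapezoidal AUC so that it integrates to one.
    """
    dist = d.distances if isinstance(d, NNDistanceSet) else np.asarray(d, dtype=float)
    if dist.size == 0:
        raise ValueError("cannot smooth an empty distance vector")
    grid = np.arange(0.0, np.max(dist) + window + step / 2, step)
    half = window / 2.0
    # Half-open membership [t-half, t+half): each distance contributes to
    # exactly window/step grid points at default settings.
    counts = np.array(
        [np.count_nonzero((dist >= t - half) & (dist < t + half)) for t in grid],
        dtype=float,
    )
    auc = np.trapezoid(counts, grid)
    if auc <= 0:
        raise ValueError("degenerate distance vector: zero-area histogram")
    return SmoothedPDF(grid=grid, density=counts / auc, window=window)


def empirical_g_curve(
    d: NNDistanceSet | np.ndarray,
    r_max: float | None = None,
    step: float = 1.0,
    border_window: tuple[np.ndarray, tuple[float, float, float, float]] | None = None,
) -> GCurve:
    """Empirical G-function: G(r) = fraction of 1-NN distances ≤ r.

    The primary estimator is the raw ECDF (no edge correction). A
    border-corrected variant (reduced-sample: reference cells closer to
    the window edge than r are discarded at that r) is available by
    passing ``border_window`` as (reference coordinates, (xmin, xmax,
    ymin, ymax)).
    """
    dist = d.distances if isinstance(d, NNDistanceSet) else np.asarray(d, dtype=float)
    if dist.size == 0:
        raise ValueError("cannot compute a G-function from no distances")
    if r_max is None:
        r_max = float(np.max(dist))
    r = np.arange(0.0, r_max + step / 2, step)
    if border_window is None:
        g = np.searchsorted(np.sort(dist), r, side="right") / dist.size
    else:
        coords, (xmin, xmax, ymin, ymax) = border_window
        edge = np.minimum.reduce(
            [coords[:, 0] - xmin, xmax - coords[:, 0], coords[:, 1] - ymin, ymax - coords[:, 1]]
        )
        g = np.empty_like(r)
        for i, ri in enumerate(r):
            keep = edge >= ri
            g[i] = np.mean(dist[keep] <= ri) if keep.any() else np.nan
    return GCurve(r=r, values=g)


def g_auc(g: GCurve, T: float) -> float:
    """Trapezoidal area under the G-function over [0, T] (μm).

    Thresholds beyond the computed grid extend it with the saturated
    value G = 1 (valid for the uncorrected estimator, which reaches 1 at
    the maximum observed distance).
    """
    if T <= 0:
        raise ValueError("threshold T must be positive")
    r, v = g.r, g.values
    if T > r[-1]:
        r = np.append(r, T)
        v = np.append(v, v[-1] if v[-1] >= 1.0 else 1.0)
    mask = r <= T
    rr, vv = r[mask], v[mask]
    if rr[-1] < T:
        # interpolate the partial trapezoid up to T
        vT = np.interp(T, r, v)
        rr = np.append(rr, T)
        vv = np.append(vv, vT)
    auc = float(np.trapezoid(vv, rr))
    g.aucs[T] = auc
    return auc
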