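"""Analysis of trap-force deflection scans.

A deflection scan is a grid of trap positions with the force components
(Fx, Fy) the particle exerts on the beam at each node, as measured by a
position-sensitive detector or produced by the ray-optics model / synthetic
generator.  This module turns scans into total-force maps, fits the otolith
boundary from the ridge of force maxima, decomposes forces into radial and
tangential parts, and summarises the birefringence-driven angular sectors
(two wide strong regions, two narrow weak regions around the circumference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DeflectionScan",
    "SectorStats",
    "InsufficientDataError",
    "total_force_map",
    "estimate_boundary",
    "radial_decomposition",
    "sector_statistics",
    "fit_sector_edges",
]


class InsufficientDataError(ValueError):
    """Not enough usable nodes for the requested fit."""


@dataclass(frozen=True)
class DeflectionScan:
    """Grid of trap positions with per-position force vectors.

    ``x_um``/``y_um`` are node coordinates (µm), ``fx_pn``/``fy_pn`` the force
    components (pN).  ``metadata`` carries scan power, grid step, etc.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    fx_pn: np.ndarray
    fy_pn: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in
                (self.x_um, self.y_um, self.fx_pn, self.fy_pn)]
        n = arrs[0].shape[0]
        if any(a.shape != (n,) for a in arrs):
            raise ValueError("all scan columns must be 1-D of equal length")
        if not all(np.all(np.isfinite(a)) for a in arrs[2:]):
            raise ValueError("force components must be finite")
        nodes = set(zip(arrs[0].tolist(), arrs[1].tolist()))
        if len(nodes) != n:
            raise ValueError("grid positions must be unique")

    def __len__(self) -> int:
        return self.x_um.shape[0]

    @property
    def grid_step_um(self) -> float:
        step = self.metadata.get("grid_step_um")
        if step is not None:
            return float(step)
        xs = np.unique(self.x_um)
        return float(np.min(np.diff(xs))) if xs.size > 1 else 1.0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **metadata) -> "DeflectionScan":
        return cls(
            x_um=df["x_um"].to_numpy(float),
            y_um=df["y_um"].to_numpy(float),
            fx_pn=df["Fx_pN"].to_numpy(float),
            fy_pn=df["Fy_pN"].to_numpy(float),
            metadata=metadata,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_um": self.x_um, "y_um": self.y_um,
             "Fx_pN": self.fx_pn, "Fy_pN": self.fy_pn}
        )

    @classmethod
    def read_csv(cls, path, **metadata) -> "DeflectionScan":
        return cls.from_dataframe(pd.read_csv(path), **metadata)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class SectorStats:
    """Force statistics in one angular sector of the edge band.

    ``mean_pn``/``sd_pn`` summarise |F| (the statistic usually quoted for
    measured maps).  ``amplitude_pn`` is the magnitude of the mean *radial*
    component: for a radial field with isotropic noise it is an unbiased
    amplitude estimate, free of the upward bias |F| picks up from noise.
    """

    angle_start_deg: float
    angle_stop_deg: float  # exclusive; may wrap past 360
    mean_pn: float
    sd_pn: float
    amplitude_pn: float
    n_points: int
    classification: str  # {"strong", "weak"}
    empty: bool = False


def total_force_map(scan: DeflectionScan) -> np.ndarray:
    """Per-node total force magnitude |F| = sqrt(Fx^2 + Fy^2), pN."""
    return np.hypot(scan.fx_pn, scan.fy_pn)


def _circle_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit -> (cx, cy, radius)."""
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy, c = sol
    return float(cx), float(cy), float(np.sqrt(c + cx**2 + cy**2))


def _ridge_points(
    scan: DeflectionScan, centre: tuple[float, float], n_bins: int
) -> np.ndarray:
    """Per-angular-bin ridge locations along radial rays from ``centre``.

    Within each bin the ridge point is the |F|-weighted centroid of the
    nodes in the upper part of the bin's force range (>= 60 % of the bin
    maximum): on a flat-topped noisy ridge this centres on the plateau
    instead of jumping to whichever node the noise favours.
    """
    mag = total_force_map(scan)
    dx, dy = scan.x_um - centre[0], scan.y_um - centre[1]
    r = np.hypot(dx, dy)
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    bins = np.minimum((ang / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    floor = 0.25 * mag.max()
    pts = []
    for b in range(n_bins):
        sel = np.flatnonzero((bins == b) & (r > 0))
        if sel.size == 0 or mag[sel].max() < floor:
            continue
        top = sel[mag[sel] >= 0.6 * mag[sel].max()]
        w = mag[top]
        pts.append(
            (np.average(scan.x_um[top], weights=w),
             np.average(scan.y_um[top], weights=w))
        )
    return np.asarray(pts, dtype=float)


def estimate_boundary(
    scan: DeflectionScan, n_angular_bins: int = 36
) -> tuple[tuple[float, float], float]:
    """Estimate the otolith centre and radius from the force ridge.

    The forces peak where the trap sits at the particle edge, so the ridge
    of local |F| maxima traces the boundary circle.  An initial centre (the
    centroid of the top-decile |F| nodes) seeds per-angular-bin ridge
    detection; a least-squares circle through the ridge points is refined
    once with ridge points recomputed about the fitted centre.
    """
    mag = total_force_map(scan)
    top = mag >= np.quantile(mag, 0.9)
    centre = (float(scan.x_um[top].mean()), float(scan.y_um[top].mean()))
    for _ in range(2):
        pts = _ridge_points(scan, centre, n_angular_bins)
        if pts.shape[0] < 6:
            raise InsufficientDataError(
                f"only {pts.shape[0]} ridge points; need at least 6"
            )
        cx, cy, radius = _circle_fit(pts[:, 0], pts[:, 1])
        centre = (cx, cy)
    return centre, radius


def radial_decomposition(
    scan: DeflectionScan, centre: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate (Fx, Fy) into the local radial frame about ``centre``.

    Returns ``(radial, tangential, valid)``: signed outward-radial and
    counterclockwise-tangential components (pN) and a validity mask.  A node
    exactly at the centre has no defined direction and is flagged invalid
    (components set to NaN).  Per node, radial^2 + tangential^2 equals
    Fx^2 + Fy^2 exactly.
    """
    dx, dy = scan.x_um - centre[0], scan.y_um - centre[1]
    r = np.hypot(dx, dy)
    valid = r > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy = dx / r, dy / r
    radial = scan.fx_pn * ux + scan.fy_pn * uy
    tangential = -scan.fx_pn * uy + scan.fy_pn * ux
    radial[~valid] = np.nan
    tangential[~valid] = np.nan
    return radial, tangential, valid


def _edge_band_mask(
    scan: DeflectionScan,
    centre: tuple[float, float],
    radius: float,
    band_um: float | None,
) -> np.ndarray:
    if band_um is None:
        band_um = scan.grid_step_um
    r = np.hypot(scan.x_um - centre[0], scan.y_um - centre[1])
    return np.abs(r - radius) <= band_um


def sector_statistics(
    scan: DeflectionScan,
    centre: tuple[float, float],
    sector_edges_deg,
    radius: float | None = None,
    band_um: float | None = None,
) -> list[SectorStats]:
    """Mean ± SD of |F| per angular sector of the edge band.

    ``sector_edges_deg`` are ascending angles in [0, 360); sector ``i`` spans
    ``[edges[i], edges[i+1])``, the last wrapping around to ``edges[0]``.
    Only nodes with |r - radius| <= band (default one grid step) are used.
    Sectors with mean at or above the midpoint of the extreme sector means
    are classified "strong", the rest "weak".  Empty sectors are flagged.
    """
    edges = np.asarray(sector_edges_deg, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("sector edges must be ascending with >= 2 entries")
    if radius is None:
        centre, radius = estimate_boundary(scan)
    band = _edge_band_mask(scan, centre, radius, band_um)
    mag = total_force_map(scan)[band]
    radial_all, _, _ = radial_decomposition(scan, centre)
    radial = radial_all[band]
    ang = np.mod(
        np.degrees(
            np.arctan2(scan.y_um[band] - centre[1], scan.x_um[band] - centre[0])
        ),
        360.0,
    )
    # rotate so the first edge is the origin; sectors then tile [0, 360)
    rel = np.mod(ang - edges[0], 360.0)
    rel_edges = np.concatenate([np.mod(edges - edges[0], 360.0), [360.0]])

    raw = []
    for i in range(edges.size):
        lo, hi = rel_edges[i], rel_edges[i + 1]
        sel = (rel >= lo) & (rel < hi)
        vals = mag[sel]
        rad = radial[sel]
        raw.append(
            {
                "start": float(edges[i]),
                "stop": float(edges[(i + 1) % edges.size]),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "amp": float(abs(np.nanmean(rad))) if vals.size else np.nan,
                "n": int(vals.size),
            }
        )
    means = [s["mean"] for s in raw if s["n"] > 0]
    thresh = 0.5 * (np.nanmax(means) + np.nanmin(means)) if means else np.nan
    return [
        SectorStats(
            angle_start_deg=s["start"],
            angle_stop_deg=s["stop"],
            mean_pn=s["mean"],
            sd_pn=s["sd"],
            amplitude_pn=s["amp"],
            n_points=s["n"],
            classification="strong"
            if (s["n"] > 0 and s["mean"] >= thresh)
            else "weak",
            empty=s["n"] == 0,
        )
        for s in raw
    ]


def fit_sector_edges(
    scan: DeflectionScan,
    centre: tuple[float, float],
    radius: float,
    n_sectors: int = 4,
    n_bins: int = 72,
    band_um: float | None = None,
) -> np.ndarray:
    """Fit free sector edges by change-point segmentation of the angular
    profile of edge-band |F|.

    The band magnitudes are binned by angle; the circular sequence of bin
    means is segmented into ``n_sectors`` contiguous arcs minimising the
    within-segment sum of squares (dynamic programming over bin boundaries,
    with the first boundary scanned over all bins).  Returns edge angles in
    degrees, ascending.
    """
    band = _edge_band_mask(scan, centre, radius, band_um)
    if band.sum() < n_sectors * 2:
        raise InsufficientDataError("too few edge-band nodes for segmentation")
    mag = total_force_map(scan)[band]
    ang = np.mod(
        np.arctan2(scan.y_um[band] - centre[1], scan.x_um[band] - centre[0]),
        2 * np.pi,
    )
    bins = np.minimum((ang / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    prof = np.full(n_bins, np.nan)
    for b in range(n_bins):
        v = mag[bins == b]
        if v.size:
            prof[b] = v.mean()
    prof = pd.Series(prof).interpolate(limit_direction="both").to_numpy()

    k = n_sectors
    best_cost, best_edges = np.inf, None
    for start in range(n_bins):
        seq = np.roll(prof, -start)
        c1 = np.concatenate([[0.0], np.cumsum(seq)])
        c2 = np.concatenate([[0.0], np.cumsum(seq**2)])

        def sse(i: int, j: int) -> float:  # cost of segment seq[i:j]
            s = c1[j] - c1[i]
            return (c2[j] - c2[i]) - s * s / (j - i)

        # cost[seg][j]: best cost of splitting seq[:j] into seg segments
        cost = np.full((k + 1, n_bins + 1), np.inf)
        back = np.zeros((k + 1, n_bins + 1), dtype=int)
        cost[0, 0] = 0.0
        for seg in range(1, k + 1):
            for j in range(seg, n_bins - (k - seg) + 1):
                prev = cost[seg - 1, seg - 1 : j]
                cands = prev + np.array([sse(i, j) for i in range(seg - 1, j)])
                i_best = int(np.argmin(cands))
                cost[seg, j] = cands[i_best]
                back[seg, j] = i_best + seg - 1
        if cost[k, n_bins] < best_cost:
            cuts = [n_bins]
            for seg in range(k, 0, -1):
                cuts.append(int(back[seg, cuts[-1]]))
            bounds = sorted(cuts[1:])  # k boundaries incl. 0, excl. n_bins
            best_cost = cost[k, n_bins]
            best_edges = sorted(((start + b) % n_bins) / n_bins * 360.0 for b in bounds)
    return np.asarray(best_edges, dtype=float)
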