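"""Spatial map processing: QC, smoothing, resampling, pivot extraction, means.

All interpolation is piecewise cubic: a periodic cubic spline along the
angular direction of each ring, followed by a (not-a-knot) cubic spline
radially.  Not-a-knot end conditions reproduce polynomial fields of degree
<= 3 in r exactly, which the test suite relies on.

Missing data: cells are NaN.  Splines are fitted through present cells
only; a query point is reported missing only when its local 4x4
(rings x meridians, periodic in theta) stencil is entirely missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .core import Cohort, EyeRecord, PolarGrid, TearFilmMap

__all__ = [
    "PivotLayout",
    "PivotVector",
    "QCResult",
    "make_standard_grid",
    "qc_check",
    "lowpass_filter",
    "resample_to_grid",
    "build_pivot_layout",
    "extract_pivots",
    "extract_ring_values",
    "global_mean",
    "group_mean_map",
    "difference_map",
    "estimate_centration",
]

#: Radius (mm) of the "central 3.5 mm" QC disc — 3.5 mm *diameter*.
CENTRAL_QC_RADIUS = 1.75
#: Default analysis-zone radius (mm) for the global mean.
DEFAULT_ZONE_RADIUS = 4.0
#: Pivot ring point counts (plus one centre point -> 121 total).
PIVOT_RING_COUNTS = (8, 16, 24, 32, 40)


def make_standard_grid(max_radius: float = 5.0, n_rings: int = 50,
                       n_meridians: int = 180) -> PolarGrid:
    """Evenly spaced standard corneal grid: rings in (0, max_radius], meridians in [0, 360)."""
    if max_radius <= 0:
        raise ValueError("max_radius must be positive")
    if n_rings < 2 or n_meridians < 8:
        raise ValueError("need n_rings >= 2 and n_meridians >= 8")
    rings = max_radius * np.arange(1, n_rings + 1) / n_rings
    angles = 360.0 * np.arange(n_meridians) / n_meridians
    return PolarGrid(ring_radii=rings, meridian_angles=angles)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCResult:
    passed: bool
    central_coverage: float
    reasons: frozenset

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to empty reasons")


def qc_check(tfm: TearFilmMap, min_coverage: float = 1.0) -> QCResult:
    """Image-quality gate: artefact flags plus central-coverage check.

    ``central_coverage`` is the fraction of non-missing cells with
    r <= 1.75 mm (the central 3.5 mm diameter disc); a map fails with
    reason ``incomplete_central_coverage`` when coverage < ``min_coverage``.
    """
    central = tfm.grid.ring_radii <= CENTRAL_QC_RADIUS
    cells = tfm.values[central, :]
    coverage = 1.0 if cells.size == 0 else float(np.isfinite(cells).mean())
    reasons = set(tfm.artefact_flags)
    if coverage < min_coverage:
        reasons.add("incomplete_central_coverage")
    return QCResult(passed=not reasons, central_coverage=coverage,
                    reasons=frozenset(reasons))


def record_qc(record: EyeRecord, min_coverage: float = 1.0) -> dict[str, QCResult]:
    """QC both tear-quality sessions of a record; a record passes if both maps pass."""
    return {
        "pre": qc_check(record.pre_map, min_coverage),
        "post": qc_check(record.post_map, min_coverage),
    }


def record_passes_qc(record: EyeRecord, min_coverage: float = 1.0) -> bool:
    return all(r.passed for r in record_qc(record, min_coverage).values())


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def lowpass_filter(tfm: TearFilmMap, sigma_r: float = 0.0,
                   sigma_theta: float = 0.0) -> TearFilmMap:
    """Separable Gaussian low-pass in (r, theta); theta wraps periodically.

    ``sigma_r`` is in mm, ``sigma_theta`` in degrees.  Missing cells are
    excluded from the kernels (masked normalisation) and remain missing.
    Zero sigmas return the map unchanged.
    """
    if sigma_r < 0 or sigma_theta < 0:
        raise ValueError("sigmas must be >= 0")
    if sigma_r == 0 and sigma_theta == 0:
        return tfm.copy_with()
    grid = tfm.grid
    dr = float(np.mean(np.diff(grid.ring_radii)))
    dth = float(np.mean(np.diff(grid.meridian_angles)))
    mask = np.isfinite(tfm.values).astype(float)
    vals = np.where(mask > 0, tfm.values, 0.0)

    def smooth(arr):
        if sigma_r > 0:
            arr = gaussian_filter1d(arr, sigma_r / dr, axis=0, mode="nearest")
        if sigma_theta > 0:
            arr = gaussian_filter1d(arr, sigma_theta / dth, axis=1, mode="wrap")
        return arr

    num, den = smooth(vals), smooth(mask)
    out = np.full_like(vals, np.nan)
    ok = (mask > 0) & (den > 0)
    out[ok] = num[ok] / den[ok]
    return tfm.copy_with(values=out)


# ---------------------------------------------------------------------------
# cubic interpolation on the polar grid
# ---------------------------------------------------------------------------

def _stencil_all_missing(values: np.ndarray, grid: PolarGrid,
                         r_q: np.ndarray, th_q: np.ndarray) -> np.ndarray:
    """True where the local 4x4 bicubic stencil around each query is all-missing."""
    miss = ~np.isfinite(values)
    nr, nm = values.shape
    ri = np.searchsorted(grid.ring_radii, r_q)
    r0 = np.clip(ri - 2, 0, max(nr - 4, 0))
    ti = np.searchsorted(grid.meridian_angles, th_q % 360.0)
    out = np.empty(r_q.shape, dtype=bool)
    for k in range(r_q.size):
        rows = slice(r0[k], min(r0[k] + 4, nr))
        cols = (ti[k] - 2 + np.arange(4)) % nm
        out[k] = bool(miss[rows, :][:, cols].all())
    return out


def _interp_polar(values: np.ndarray, grid: PolarGrid,
                  r_q: np.ndarray, th_q: np.ndarray) -> np.ndarray:
    """Piecewise-cubic tensor interpolation at scattered polar query points.

    Angular pass: periodic cubic spline per ring over present cells.
    Radial pass: not-a-knot cubic spline per distinct query angle.
    """
    r_q = np.asarray(r_q, dtype=float).ravel()
    th_q = np.asarray(th_q, dtype=float).ravel() % 360.0
    nr, nm = values.shape
    uniq_th, inv = np.unique(th_q, return_inverse=True)

    # angular pass: per-ring periodic cubic through present cells
    ring_at = np.full((nr, uniq_th.size), np.nan)
    angles = grid.meridian_angles
    for i in range(nr):
        row = values[i]
        ok = np.isfinite(row)
        n_ok = int(ok.sum())
        if n_ok == nm:
            x = np.concatenate([angles, [angles[0] + 360.0]])
            y = np.concatenate([row, [row[0]]])
            ring_at[i] = CubicSpline(x, y, bc_type="periodic")(uniq_th)
        elif n_ok >= 4:
            x = angles[ok]
            y = row[ok]
            x = np.concatenate([x, [x[0] + 360.0]])
            y = np.concatenate([y, [y[0]]])
            cs = CubicSpline(x, y, bc_type="periodic")
            # map query angles into the spline's periodic window
            q = x[0] + (uniq_th - x[0]) % 360.0
            ring_at[i] = cs(q)
        elif n_ok >= 2:
            x, y = angles[ok], row[ok]
            x = np.concatenate([x, [x[0] + 360.0]])
            y = np.concatenate([y, [y[0]]])
            q = x[0] + (uniq_th - x[0]) % 360.0
            ring_at[i] = np.interp(q, x, y)
        # n_ok < 2: ring unusable -> stays NaN

    # radial pass per distinct angle
    out = np.full(r_q.shape, np.nan)
    for j in range(uniq_th.size):
        col = ring_at[:, j]
        ok = np.isfinite(col)
        sel = inv == j
        n_ok = int(ok.sum())
        if n_ok >= 4:
            cs = CubicSpline(grid.ring_radii[ok], col[ok])  # not-a-knot
            out[sel] = cs(r_q[sel])
        elif n_ok >= 2:
            out[sel] = np.interp(r_q[sel], grid.ring_radii[ok], col[ok])
        elif n_ok == 1:
            out[sel] = col[ok][0]

    out[_stencil_all_missing(values, grid, r_q, th_q)] = np.nan
    return out


def resample_to_grid(tfm: TearFilmMap, target: PolarGrid) -> TearFilmMap:
    """Resample a map onto a target polar grid (no radial extrapolation)."""
    if target.max_radius > tfm.grid.max_radius * (1 + 1e-9):
        raise ValueError(
            f"target radius {target.max_radius} exceeds source extent "
            f"{tfm.grid.max_radius}; extrapolation is not supported"
        )
    if target == tfm.grid:
        return tfm.copy_with()
    r, th = target.mesh()
    vals = _interp_polar(tfm.values, tfm.grid, r.ravel(), th.ravel())
    vals = vals.reshape(target.shape)
    if tfm.modality == "tear_quality":
        vals = np.where(np.isfinite(vals), np.maximum(vals, 0.0), np.nan)
    return TearFilmMap(grid=target, values=vals, modality=tfm.modality,
                       session=tfm.session, artefact_flags=tfm.artefact_flags)


# ---------------------------------------------------------------------------
# pivot layout and extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PivotLayout:
    """121 radially arranged sampling points: centre + rings of 8/16/24/32/40.

    Ring radii sit at {0.2, 0.4, 0.6, 0.8, 1.0} x max_radius.  The OS
    layout mirrors OD through theta -> 180 - theta so that nasal points
    coincide across lateralities.
    """

    eye: str
    radii: np.ndarray    # (121,) mm
    angles: np.ndarray   # (121,) degrees in [0, 360)
    ring_counts: tuple = (1,) + PIVOT_RING_COUNTS

    def __post_init__(self):
        if self.radii.size != 121 or self.angles.size != 121:
            raise ValueError("pivot layout must have exactly 121 points")
        if self.radii[0] != 0:
            raise ValueError("first pivot must be the centre point")

    @property
    def n_points(self) -> int:
        return self.radii.size

    @property
    def max_radius(self) -> float:
        return float(self.radii.max())

    def cartesian(self) -> tuple[np.ndarray, np.ndarray]:
        th = np.deg2rad(self.angles)
        return self.radii * np.cos(th), self.radii * np.sin(th)


def build_pivot_layout(eye: str, max_radius: float = 5.0) -> PivotLayout:
    """Deterministic 121-point layout: centre, then rings inward->outward, CCW."""
    if eye not in ("OD", "OS"):
        raise ValueError("eye must be OD or OS")
    radii = [0.0]
    angles = [0.0]
    for k, count in enumerate(PIVOT_RING_COUNTS, start=1):
        r = 0.2 * k * max_radius
        th = 360.0 * np.arange(count) / count
        radii.extend([r] * count)
        angles.extend(th.tolist())
    radii = np.asarray(radii)
    angles = np.asarray(angles)
    if eye == "OS":
        angles = (180.0 - angles) % 360.0
    return PivotLayout(eye=eye, radii=radii, angles=angles)


@dataclass
class PivotVector:
    """Tear-quality values sampled at a pivot layout's 121 points."""

    layout: PivotLayout
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_points,):
            raise ValueError("values length must equal layout size")


def extract_pivots(tfm: TearFilmMap, layout: PivotLayout) -> PivotVector:
    """Sample the map at the 121 pivot locations by piecewise cubic interpolation."""
    if layout.max_radius > tfm.grid.max_radius * (1 + 1e-9):
        raise ValueError("pivot layout extends beyond the map's radial extent")
    vals = _interp_polar(tfm.values, tfm.grid, layout.radii, layout.angles)
    if tfm.modality == "tear_quality":
        vals = np.where(np.isfinite(vals), np.maximum(vals, 0.0), np.nan)
    return PivotVector(layout=layout, values=vals)


def extract_ring_values(tfm: TearFilmMap, radius: float,
                        angle_step: float) -> np.ndarray:
    """Values on one concentric ring at angles 0, step, ..., 360 - step."""
    if radius > tfm.grid.max_radius * (1 + 1e-9):
        raise ValueError("ring radius beyond map extent")
    if angle_step <= 0 or abs(360.0 / angle_step - round(360.0 / angle_step)) > 1e-9:
        raise ValueError("angle_step must divide 360")
    n = int(round(360.0 / angle_step))
    th = angle_step * np.arange(n)
    return _interp_polar(tfm.values, tfm.grid, np.full(n, float(radius)), th)


# ---------------------------------------------------------------------------
# regional and group statistics on maps
# ---------------------------------------------------------------------------

def global_mean(tfm: TearFilmMap, zone_radius: float = DEFAULT_ZONE_RADIUS) -> float:
    """Area-weighted mean over non-missing cells with r <= zone_radius."""
    if zone_radius > tfm.grid.max_radius * (1 + 1e-9):
        raise ValueError("zone_radius beyond map extent")
    w = tfm.grid.area_weights()
    in_zone = tfm.grid.ring_radii <= zone_radius + 1e-12
    w = w * in_zone[:, None] * np.isfinite(tfm.values)
    if w.sum() == 0:
        raise ValueError("all cells missing within the analysis zone")
    return float(np.nansum(w * np.nan_to_num(tfm.values)) / w.sum())


def group_mean_map(cohort: Cohort, group: str, session: str,
                   min_coverage: float = 1.0) -> TearFilmMap:
    """Cellwise mean map over QC-passing records of one wear-duration group."""
    if session not in ("pre", "post"):
        raise ValueError("session must be 'pre' or 'post'")
    recs = [r for r in cohort if r.group == group and record_passes_qc(r, min_coverage)]
    if not recs:
        raise ValueError(f"no QC-passing records in group {group}")
    grid = recs[0].pre_map.grid
    stack = np.stack([
        (r.pre_map if session == "pre" else r.post_map).values for r in recs
    ])
    with np.errstate(invalid="ignore"):
        vals = np.where(np.isfinite(stack).any(axis=0), np.nanmean(stack, axis=0), np.nan)
    return TearFilmMap(grid=grid, values=vals, modality="tear_quality", session=session)


def difference_map(post_mean: TearFilmMap, pre_mean: TearFilmMap) -> TearFilmMap:
    """Cellwise post - pre; missing where either input is missing."""
    if post_mean.grid != pre_mean.grid:
        raise ValueError("difference_map requires maps on the same grid")
    vals = post_mean.values - pre_mean.values
    out = TearFilmMap.__new__(TearFilmMap)
    out.grid = post_mean.grid
    out.values = vals
    out.modality = post_mean.modality
    out.session = "post"
    out.artefact_flags = post_mean.artefact_flags | pre_mean.artefact_flags
    return out


def estimate_centration(curvature_diff: TearFilmMap,
                        threshold: float = -0.5) -> tuple[float, float] | None:
    """Locate the treatment zone: area-weighted centroid of flattened cells.

    Flattened cells are those of the tangential curvature difference map
    with value <= threshold (dioptres).  Returns (x, y) in mm, or None
    when no cell qualifies.
    """
    if curvature_diff.modality != "tangential_curvature":
        raise ValueError("centration estimation needs a tangential_curvature difference map")
    sel = np.isfinite(curvature_diff.values) & (curvature_diff.values <= threshold)
    if not sel.any():
        return None
    w = curvature_diff.grid.area_weights()[sel]
    x, y = curvature_diff.grid.cartesian_mesh()
    return (float(np.sum(w * x[sel]) / w.sum()), float(np.sum(w * y[sel]) / w.sum()))
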