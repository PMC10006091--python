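"""3D dose reconstruction from a planar measured map, and DVH metrics.

A measured planar dose (the detector plane, here the isocenter plane z = 0)
is propagated onto a voxel phantom along divergent rays from a point focus:

    D_CT = D_Det * TPR(Z_CT) / TPR(Z_Det) * (a_Det / a_CT)^2

where Z are water-equivalent depths and a are geometric focus distances.
The TPR ratio accounts for the different thickness of overlying material,
the squared distance ratio for the inverse-square law.  Water-equivalent
depth is the geometric in-contour depth scaled by the mean relative
electron density of the traversed voxels:

    Z = Z_geom * (sum_i rho_i) / (n * rho_water)

Voxels between rays take linearly interpolated detector-plane values
(scattered linear interpolation of the measured points in the projected
plane coordinates), voxels outside the contour are zero, and voxels whose
projection falls outside the interpolation hull are flagged in a coverage
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .synthetic import BeamModel, VoxelPhantom
from .detector import MeasuredMap

__all__ = [
    "RayPath",
    "ReconstructedDose",
    "DvhResult",
    "trace_ray",
    "water_equivalent_depth",
    "reconstruct_point",
    "reconstruct_volume",
    "compute_dvh",
    "d50_percent_difference",
    "RayMissError",
]


class RayMissError(ValueError):
    """A ray does not intersect the phantom contour."""


@dataclass
class RayPath:
    """Sampled ray from the focus to a point inside the phantom."""

    focus: np.ndarray  # (3,) mm
    point: np.ndarray  # (3,) mm
    entry: np.ndarray  # (3,) mm — contour entry on the focus side
    densities: np.ndarray  # per-sample relative electron density (in-contour)
    geom_depth_mm: float  # path length entry -> point
    a_mm: float  # focus -> point distance

    @property
    def n_samples(self) -> int:
        return self.densities.size


@dataclass
class ReconstructedDose:
    """3D dose grid aligned to a VoxelPhantom, with provenance."""

    values: np.ndarray  # same shape as phantom.density (nz, ny, nx)
    phantom: VoxelPhantom
    source: str = ""
    n_uncovered: int = 0  # in-contour voxels outside the interpolation hull


@dataclass
class DvhResult:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    dose_bins: np.ndarray  # bin-edge doses (ascending)
    volume_fraction: np.ndarray  # fraction of volume receiving >= dose
    d50: float  # dose to 50% of the volume


# ---------------------------------------------------------------------------
# ray tracing and water-equivalent depth
# ---------------------------------------------------------------------------

def _density_at(phantom: VoxelPhantom, pts: np.ndarray):
    """Nearest-voxel density and contour flag at (n, 3) points (x, y, z)."""
    dx, dy, dz = phantom.spacing
    x0, y0, z0 = phantom.origin
    nz, ny, nx = phantom.density.shape
    ix = np.round((pts[:, 0] - x0) / dx).astype(int)
    iy = np.round((pts[:, 1] - y0) / dy).astype(int)
    iz = np.round((pts[:, 2] - z0) / dz).astype(int)
    valid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    ixc = np.clip(ix, 0, nx - 1)
    iyc = np.clip(iy, 0, ny - 1)
    izc = np.clip(iz, 0, nz - 1)
    rho = phantom.density[izc, iyc, ixc]
    inside = valid & phantom.contour[izc, iyc, ixc]
    return rho, inside


def trace_ray(
    phantom: VoxelPhantom,
    point,
    focus=None,
    *,
    step_mm: float | None = None,
) -> RayPath:
    """Trace the focus->point ray and sample densities from contour entry.

    The contour entry is located by bisection between the last out-of-contour
    and first in-contour probe; densities are then sampled at the midpoints
    of equal sub-segments between entry and point (sub-voxel step, default a
    quarter of the smallest voxel side).
    """
    point = np.asarray(point, dtype=float)
    focus = np.asarray(phantom.focus if focus is None else focus, dtype=float)
    if step_mm is None:
        step_mm = min(phantom.spacing) / 4.0

    direction = point - focus
    a = float(np.linalg.norm(direction))
    if a <= 0:
        raise ValueError("point coincides with the focus")
    direction = direction / a

    # probe from the focus to the point to find the contour entry
    n_probe = max(8, int(np.ceil(a / step_mm)))
    t = np.linspace(0.0, a, n_probe)
    _, inside = _density_at(phantom, focus[None, :] + t[:, None] * direction[None, :])
    if not inside.any():
        raise RayMissError("ray does not intersect the phantom contour")
    first_in = int(np.argmax(inside))
    if not inside[-1]:
        raise RayMissError("target point lies outside the phantom contour")

    t_lo = t[first_in - 1] if first_in > 0 else 0.0
    t_hi = t[first_in]
    for _ in range(40):  # bisection to locate the entry precisely
        t_mid = 0.5 * (t_lo + t_hi)
        _, ins = _density_at(phantom, (focus + t_mid * direction)[None, :])
        if ins[0]:
            t_hi = t_mid
        else:
            t_lo = t_mid
    t_entry = t_hi
    entry = focus + t_entry * direction

    depth = a - t_entry
    n_samp = max(2, int(np.ceil(depth / step_mm)))
    mids = t_entry + (np.arange(n_samp) + 0.5) * depth / n_samp
    rho, ins = _density_at(phantom, focus[None, :] + mids[:, None] * direction[None, :])
    densities = np.where(ins, rho, 0.0)

    return RayPath(
        focus=focus,
        point=point,
        entry=entry,
        densities=densities,
        geom_depth_mm=float(depth),
        a_mm=a,
    )


def water_equivalent_depth(ray: RayPath, phantom: VoxelPhantom | None = None) -> float:
    """Water-equivalent depth: geometric depth x mean relative density.

    ``phantom`` is accepted for interface symmetry; the ray already carries
    the sampled densities (relative to water, rho_water = 1).
    """
    if ray.n_samples == 0:
        raise RayMissError("ray carries no in-contour samples")
    return ray.geom_depth_mm * float(ray.densities.mean())


# ---------------------------------------------------------------------------
# point and volume reconstruction
# ---------------------------------------------------------------------------

def reconstruct_point(
    d_det: float,
    z_det: float,
    z_ct: float,
    a_det: float,
    a_ct: float,
    beam: BeamModel,
) -> float:
    """Dose at a voxel from the dose at its detector point (single ray)."""
    if a_det <= 0 or a_ct <= 0:
        raise ValueError("focus distances must be positive")
    if z_det < 0 or z_ct < 0:
        raise ValueError("depths must be non-negative")
    tpr_det = float(beam.tpr(z_det))
    if tpr_det == 0:
        raise ZeroDivisionError("TPR at the detector depth is zero")
    return float(d_det) * float(beam.tpr(z_ct)) / tpr_det * (a_det / a_ct) ** 2


def _wed_points(
    phantom: VoxelPhantom, pts: np.ndarray, focus: np.ndarray, n_samples: int = 48
) -> np.ndarray:
    """Water-equivalent depth at (n, 3) points with the same fixed midpoint
    quadrature as the voxel-grid pass (keeps detector-plane and voxel depths
    numerically consistent)."""
    z_front = phantom.z[0] - phantom.spacing[2] / 2.0
    vec = pts - focus[None, :]
    a = np.linalg.norm(vec, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_front = np.clip((z_front - focus[2]) / vec[:, 2], 0.0, 1.0)
    frac = t_front[:, None] + (np.arange(n_samples)[None, :] + 0.5) * (
        (1.0 - t_front[:, None]) / n_samples
    )
    samples = focus[None, None, :] + frac[:, :, None] * vec[:, None, :]
    rho, inside = _density_at(phantom, samples.reshape(-1, 3))
    rho = np.where(inside, rho, 0.0).reshape(pts.shape[0], n_samples)
    inside = inside.reshape(pts.shape[0], n_samples)
    n_in = inside.sum(axis=1)
    seg_len = a * (1.0 - t_front) / n_samples
    geom_depth = n_in * seg_len
    mean_rho = np.where(n_in > 0, rho.sum(axis=1) / np.maximum(n_in, 1), 0.0)
    out = geom_depth * mean_rho
    out[n_in == 0] = np.nan
    return out


def _wed_grid(phantom: VoxelPhantom, focus: np.ndarray, n_samples: int = 48):
    """Water-equivalent depth of every voxel, vectorised per z-slice.

    For each voxel, densities are sampled at ``n_samples`` midpoints along
    the focus ray between the phantom's front face and the voxel; the
    in-contour sample fraction gives the geometric depth, their mean density
    the scaling of the water-equivalent depth.
    """
    nz, ny, nx = phantom.density.shape
    xg, yg = np.meshgrid(phantom.x, phantom.y)  # (ny, nx)
    wed = np.zeros((nz, ny, nx))
    a_ct = np.zeros((nz, ny, nx))
    for iz, zv in enumerate(phantom.z):
        pts = np.stack([xg.ravel(), yg.ravel(), np.full(xg.size, zv)], axis=1)
        a_ct[iz] = np.linalg.norm(pts - focus[None, :], axis=1).reshape(ny, nx)
        w = _wed_points(phantom, pts, focus, n_samples)
        wed[iz] = np.nan_to_num(w, nan=0.0).reshape(ny, nx)
    return wed, a_ct


def reconstruct_volume(
    measured: MeasuredMap,
    phantom: VoxelPhantom,
    beam: BeamModel,
    *,
    plane_z_mm: float = 0.0,
    n_depth_samples: int = 48,
) -> ReconstructedDose:
    """Reconstruct 3D dose on the phantom from a planar measured map.

    The detector plane is the z = ``plane_z_mm`` plane inside the phantom
    (isocenter plane by default).  Each voxel is projected along its focus
    ray onto that plane; the measured dose and the detector-plane
    water-equivalent depth at the projected point are obtained by linear
    interpolation over the measured points, then scaled by the TPR ratio
    and the inverse-square factor.
    """
    if measured.n_points == 0:
        raise ValueError("measured map is empty")
    focus = np.asarray(phantom.focus, dtype=float)
    if focus[2] >= plane_z_mm:
        raise ValueError("focus must be upstream of the detector plane")

    # water-equivalent depth at each measured detector point (same midpoint
    # quadrature as the voxel pass); points whose rays miss the phantom
    # (outside its lateral extent) cannot anchor a depth and are left out of
    # the depth interpolation
    det_pts = np.column_stack(
        [measured.positions, np.full(measured.n_points, plane_z_mm)]
    )
    z_det_pts = _wed_points(phantom, det_pts, focus, n_depth_samples)
    _, pt_inside = _density_at(phantom, det_pts)
    z_det_pts[~pt_inside] = np.nan
    hit = ~np.isnan(z_det_pts)
    if not hit.any():
        raise RayMissError("no detector point's ray intersects the phantom")

    dose_itp = LinearNDInterpolator(measured.positions, measured.values)
    zdet_itp = LinearNDInterpolator(measured.positions[hit], z_det_pts[hit])

    wed, a_ct = _wed_grid(phantom, focus, n_samples=n_depth_samples)

    nz, ny, nx = phantom.density.shape
    xg, yg = np.meshgrid(phantom.x, phantom.y)
    out = np.zeros((nz, ny, nx))
    n_uncovered = 0
    for iz, zv in enumerate(phantom.z):
        s = (plane_z_mm - focus[2]) / (zv - focus[2])  # projection scale
        u = focus[0] + s * (xg - focus[0])
        v = focus[1] + s * (yg - focus[1])
        d_det = dose_itp(u, v)
        z_det = zdet_itp(u, v)
        a_det = np.sqrt((u - focus[0]) ** 2 + (v - focus[1]) ** 2 + (plane_z_mm - focus[2]) ** 2)
        covered = ~np.isnan(d_det) & ~np.isnan(z_det)
        in_contour = phantom.contour[iz]
        n_uncovered += int(np.count_nonzero(in_contour & ~covered))
        ok = covered & in_contour
        vals = np.zeros((ny, nx))
        if np.any(ok):
            tpr_ct = np.asarray(beam.tpr(np.clip(wed[iz][ok], 0.0, None)))
            tpr_det = np.asarray(beam.tpr(np.clip(z_det[ok], 0.0, None)))
            with np.errstate(invalid="ignore", divide="ignore"):
                vals[ok] = (
                    d_det[ok] * tpr_ct / tpr_det * (a_det[ok] / a_ct[iz][ok]) ** 2
                )
        out[iz] = np.clip(vals, 0.0, None)

    return ReconstructedDose(
        values=out,
        phantom=phantom,
        source=measured.source or measured.array_model,
        n_uncovered=n_uncovered,
    )


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

def compute_dvh(
    dose: ReconstructedDose | np.ndarray,
    mask: np.ndarray,
    structure: str = "structure",
    bin_fraction: float = 0.001,
) -> DvhResult:
    """Cumulative DVH and D50 of the voxels selected by ``mask``.

    Bin width is ``bin_fraction`` of the maximum in-mask dose (0.1% by
    default); D50 is found by linear inverse interpolation of the
    cumulative curve.
    """
    values = dose.values if isinstance(dose, ReconstructedDose) else np.asarray(dose)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match the dose grid")
    sel = values[mask]
    if sel.size == 0:
        raise ValueError("structure mask is empty")

    dmax = float(sel.max())
    if dmax <= 0:
        bins = np.array([0.0, 1.0])
    else:
        bins = np.arange(0.0, dmax * (1.0 + bin_fraction), dmax * bin_fraction)
    # fraction of volume receiving at least each bin dose
    order = np.sort(sel)
    vol = 1.0 - np.searchsorted(order, bins, side="left") / sel.size

    d50 = _dose_at_volume(bins, vol, 0.5)
    return DvhResult(structure=structure, dose_bins=bins, volume_fraction=vol, d50=d50)


def _dose_at_volume(bins: np.ndarray, vol: np.ndarray, fraction: float) -> float:
    """Inverse-interpolate the (monotone non-increasing) DVH at a volume."""
    if vol[0] < fraction:
        return 0.0
    idx = np.nonzero(vol <= fraction)[0]
    if idx.size == 0:
        return float(bins[-1])
    j = idx[0]
    if j == 0:
        return float(bins[0])
    v0, v1 = vol[j - 1], vol[j]
    if v0 == v1:
        return float(bins[j])
    w = (v0 - fraction) / (v0 - v1)
    return float(bins[j - 1] + w * (bins[j] - bins[j - 1]))


def d50_percent_difference(d50_recon: float, d50_ref: float) -> float:
    """|(D50_recon - D50_ref) / D50_ref| x 100."""
    if d50_ref == 0:
        raise ZeroDivisionError("reference D50 is zero")
    return abs((d50_recon - d50_ref) / d50_ref) * 100.0
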