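"""Gamma-index comparison of reference vs evaluated dose distributions.

For each reference point r_ref with dose D_ref above the low-dose
threshold, the gamma index is

    gamma(r_ref) = min over r  sqrt( |r - r_ref|^2 / DTA^2
                                     + (D_eval(r) - D_ref)^2 / dD_abs^2 )

with the evaluated distribution linearly interpolated on a fine sub-grid
(step DTA/10 by default) and the minimum searched inside a radius cap
(3 x DTA by default; 2 mm in profile mode).  dD_abs is the dose tolerance
in absolute units: a percentage of the maximum reference dose under global
normalization, of the local reference dose under local normalization.  A
point passes when gamma <= 1; the percent pass rate is taken over the
points above the threshold (default 10% of the maximum reference dose,
computed on the reference distribution).

The same windowed-search kernel serves planar (2D) and voxel-grid (3D)
comparisons and the per-point profile mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator

from .synthetic import GroundTruthDose
from .detector import MeasuredMap

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "EvaluatedField",
    "prepare_evaluated",
    "gamma_map",
    "gamma_map_3d",
    "pass_rate",
    "profile_compare",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Tolerance set: dose %, DTA mm, normalization, threshold, search cap."""

    dd_percent: float
    dta_mm: float
    normalization: str = "global"
    threshold_percent: float = 10.0
    search_cap_mm: float | None = None  # default 3 x DTA
    subgrid_mm: float | None = None  # default DTA / 10

    def __post_init__(self) -> None:
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("dose tolerance and DTA must be positive")
        if not 0 <= self.threshold_percent < 100:
            raise ValueError("threshold must be in [0, 100)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    @property
    def cap(self) -> float:
        return 3.0 * self.dta_mm if self.search_cap_mm is None else self.search_cap_mm

    @property
    def subgrid(self) -> float:
        return self.dta_mm / 10.0 if self.subgrid_mm is None else self.subgrid_mm

    def label(self) -> str:
        dd = f"{self.dd_percent:g}%"
        dta = f"{self.dta_mm:g}mm"
        return f"{dd}/{dta} {self.normalization}"


@dataclass
class GammaResult:
    """Per-reference-point gamma values and the threshold mask."""

    gamma: np.ndarray  # NaN below threshold; inf where no candidate existed
    mask: np.ndarray  # bool, True above threshold
    criteria: GammaCriteria
    reference_max: float

    @property
    def n_evaluated(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class EvaluatedField:
    """Evaluated distribution pre-interpolated on a uniform fine grid.

    ``axes`` are the fine-grid coordinates per array dimension (matching
    ``values`` dimension order); values are NaN where the evaluated
    distribution is undefined (outside the scattered-point hull or grid).
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray


# ---------------------------------------------------------------------------
# evaluated-field preparation
# ---------------------------------------------------------------------------

def _fine_axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = max(2, int(np.floor((hi - lo) / step)) + 1)
    return lo + step * np.arange(n)


def evaluated_bounds_for(
    reference: GroundTruthDose, criteria: GammaCriteria, extra_mm: float = 0.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fine-grid bounds (y, x) needed to score ``reference``: the bounding
    box of its above-threshold points padded by the search cap."""
    mask = reference.values >= criteria.threshold_percent / 100.0 * float(
        reference.values.max()
    )
    if not mask.any():
        ex = reference.extent
        return ((ex[2], ex[3]), (ex[0], ex[1]))
    pad = criteria.cap + extra_mm
    y = reference.y[mask.any(axis=1)]
    x = reference.x[mask.any(axis=0)]
    return ((y[0] - pad, y[-1] + pad), (x[0] - pad, x[-1] + pad))


def prepare_evaluated(
    evaluated: GroundTruthDose | MeasuredMap | EvaluatedField,
    subgrid_mm: float,
    bounds: tuple[tuple[float, float], ...],
) -> EvaluatedField:
    """Interpolate the evaluated distribution on a uniform fine grid.

    ``bounds`` are (lo, hi) per axis in array-dimension order (y, x for a
    planar map); the fine grid is clipped to the evaluated extent so that
    no extrapolation occurs.
    """
    if isinstance(evaluated, EvaluatedField):
        return evaluated
    if isinstance(evaluated, GroundTruthDose):
        ex = evaluated.extent
        lo_y, hi_y = max(bounds[0][0], ex[2]), min(bounds[0][1], ex[3])
        lo_x, hi_x = max(bounds[1][0], ex[0]), min(bounds[1][1], ex[1])
        ay = _fine_axis(lo_y, hi_y, subgrid_mm)
        ax = _fine_axis(lo_x, hi_x, subgrid_mm)
        itp = RegularGridInterpolator(
            (evaluated.y, evaluated.x),
            evaluated.values,
            bounds_error=False,
            fill_value=np.nan,
        )
        yy, xx = np.meshgrid(ay, ax, indexing="ij")
        vals = itp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(ay.size, ax.size)
        return EvaluatedField(axes=(ay, ax), values=vals)
    if isinstance(evaluated, MeasuredMap):
        pos = evaluated.positions
        lo_y = max(bounds[0][0], pos[:, 1].min())
        hi_y = min(bounds[0][1], pos[:, 1].max())
        lo_x = max(bounds[1][0], pos[:, 0].min())
        hi_x = min(bounds[1][1], pos[:, 0].max())
        ay = _fine_axis(lo_y, hi_y, subgrid_mm)
        ax = _fine_axis(lo_x, hi_x, subgrid_mm)
        itp = LinearNDInterpolator(pos, evaluated.values)
        xx, yy = np.meshgrid(ax, ay)
        vals = itp(xx, yy)
        return EvaluatedField(axes=(ay, ax), values=vals)
    raise TypeError(f"unsupported evaluated distribution: {type(evaluated)!r}")


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def _gamma_search(
    ref_pts: np.ndarray,  # (n, d) in axis order of `field.values`
    ref_vals: np.ndarray,  # (n,)
    fld: EvaluatedField,
    dd_abs: np.ndarray,  # (n,)
    dta_mm: float,
    cap_mm: float,
    chunk_elems: int = 4_000_000,
) -> np.ndarray:
    d = len(fld.axes)
    steps = [float(ax[1] - ax[0]) for ax in fld.axes]
    shape = fld.values.shape
    widths = [int(np.ceil(cap_mm / s)) + 1 for s in steps]

    # pad with +inf so every window index is in range and padded/undefined
    # candidates drop out of the minimum by themselves
    padded = np.pad(fld.values, [(w, w) for w in widths], constant_values=np.nan)
    padded[np.isnan(padded)] = np.inf
    flat_vals = padded.ravel()
    pshape = padded.shape
    strides = [int(np.prod(pshape[k + 1:], dtype=int)) for k in range(d)]

    # offset lattice, restricted to the search radius (plus half-node slop)
    off_ax = [np.arange(-w, w + 1) for w in widths]
    mesh = np.meshgrid(*off_ax, indexing="ij")
    r2 = sum((m * s) ** 2 for m, s in zip(mesh, steps))
    slop = np.sqrt(sum(s**2 for s in steps)) / 2.0
    keep = (r2 <= (cap_mm + slop) ** 2).ravel()
    off_flat = sum(m.ravel()[keep] * st for m, st in zip(mesh, strides))  # (W,)
    off_dx = [m.ravel()[keep] * s for m, s in zip(mesh, steps)]  # physical, per axis
    W = off_flat.size

    dd_abs = np.maximum(dd_abs, 1e-300)
    out = np.empty(ref_pts.shape[0])
    n_chunk = max(1, chunk_elems // W)
    cap2 = cap_mm**2
    for start in range(0, ref_pts.shape[0], n_chunk):
        pts = ref_pts[start:start + n_chunk]
        vals = ref_vals[start:start + n_chunk]
        dd = dd_abs[start:start + n_chunk]
        base = np.zeros(pts.shape[0], dtype=np.int64)
        d0 = []
        for k in range(d):
            ci = np.clip(
                np.round((pts[:, k] - fld.axes[k][0]) / steps[k]).astype(np.int64),
                0,
                shape[k] - 1,
            )
            base += (ci + widths[k]) * strides[k]
            d0.append(fld.axes[k][0] + ci * steps[k] - pts[:, k])
        flat = base[:, None] + off_flat[None, :]
        cand = flat_vals[flat]  # (n, W)
        dist2 = (d0[0][:, None] + off_dx[0][None, :]) ** 2
        for k in range(1, d):
            dist2 += (d0[k][:, None] + off_dx[k][None, :]) ** 2
        with np.errstate(invalid="ignore", over="ignore"):
            g2 = dist2 / dta_mm**2 + ((cand - vals[:, None]) / dd[:, None]) ** 2
            g2[dist2 > cap2] = np.inf
        out[start:start + n_chunk] = np.sqrt(g2.min(axis=1))
    return out


def _dd_abs_for(criteria: GammaCriteria, ref_vals: np.ndarray, ref_max: float) -> np.ndarray:
    if criteria.normalization == "global":
        return np.full(ref_vals.shape, criteria.dd_percent / 100.0 * ref_max)
    return criteria.dd_percent / 100.0 * ref_vals


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def gamma_map(
    reference: GroundTruthDose,
    evaluated: GroundTruthDose | MeasuredMap | EvaluatedField,
    criteria: GammaCriteria,
) -> GammaResult:
    """Planar gamma map of an evaluated distribution against a reference grid."""
    ref_max = float(reference.values.max())
    if ref_max > 0:
        mask = reference.values >= criteria.threshold_percent / 100.0 * ref_max
    else:
        mask = np.zeros(reference.values.shape, dtype=bool)
    gamma = np.full(reference.values.shape, np.nan)
    if not mask.any():
        warnings.warn("all reference points fall below the low-dose threshold")
        return GammaResult(gamma=gamma, mask=mask, criteria=criteria, reference_max=ref_max)

    cap = criteria.cap
    # fine grid only where it can be searched: above-threshold bbox + cap
    row_any = mask.any(axis=1)
    col_any = mask.any(axis=0)
    y_lo, y_hi = reference.y[row_any][[0, -1]]
    x_lo, x_hi = reference.x[col_any][[0, -1]]
    bounds = ((y_lo - cap, y_hi + cap), (x_lo - cap, x_hi + cap))
    fld = prepare_evaluated(evaluated, criteria.subgrid, bounds)
    if fld.values.size == 0 or np.all(np.isnan(fld.values)):
        warnings.warn("reference and evaluated distributions do not overlap")
        gamma[mask] = np.inf
        return GammaResult(gamma=gamma, mask=mask, criteria=criteria, reference_max=ref_max)

    yy, xx = np.meshgrid(reference.y, reference.x, indexing="ij")
    ref_pts = np.stack([yy[mask], xx[mask]], axis=1)
    ref_vals = reference.values[mask]
    dd_abs = _dd_abs_for(criteria, ref_vals, ref_max)
    gamma[mask] = _gamma_search(ref_pts, ref_vals, fld, dd_abs, criteria.dta_mm, cap)
    return GammaResult(gamma=gamma, mask=mask, criteria=criteria, reference_max=ref_max)


def gamma_map_3d(
    ref_values: np.ndarray,
    eval_values: np.ndarray,
    spacing_mm: tuple[float, float, float],
    criteria: GammaCriteria,
    *,
    subgrid_mm: float | None = None,
) -> GammaResult:
    """Voxel-grid gamma map (same kernel, three spatial dimensions).

    Both grids share the coordinate frame and spacing (axis order z, y, x;
    spacing given per axis).  ``subgrid_mm`` overrides the criteria
    sub-sampling for desk-scale voxel blocks.
    """
    ref_values = np.asarray(ref_values, dtype=float)
    eval_values = np.asarray(eval_values, dtype=float)
    if ref_values.ndim != 3 or eval_values.ndim != 3:
        raise ValueError("3D gamma expects 3D grids")
    sub = criteria.subgrid if subgrid_mm is None else subgrid_mm
    cap = criteria.cap
    ref_max = float(ref_values.max())
    if ref_max > 0:
        mask = ref_values >= criteria.threshold_percent / 100.0 * ref_max
    else:
        mask = np.zeros(ref_values.shape, dtype=bool)
    gamma = np.full(ref_values.shape, np.nan)
    if not mask.any():
        warnings.warn("all reference points fall below the low-dose threshold")
        return GammaResult(gamma=gamma, mask=mask, criteria=criteria, reference_max=ref_max)

    axes_coarse = [spacing_mm[k] * np.arange(ref_values.shape[k]) for k in range(3)]
    itp = RegularGridInterpolator(
        axes_coarse, eval_values, bounds_error=False, fill_value=np.nan
    )
    axes_fine = [_fine_axis(ax[0], ax[-1], sub) for ax in axes_coarse]
    mesh = np.meshgrid(*axes_fine, indexing="ij")
    fine = itp(np.stack([m.ravel() for m in mesh], axis=1)).reshape(
        [ax.size for ax in axes_fine]
    )
    fld = EvaluatedField(axes=tuple(axes_fine), values=fine)

    coords = np.meshgrid(*axes_coarse, indexing="ij")
    ref_pts = np.stack([c[mask] for c in coords], axis=1)
    ref_vals = ref_values[mask]
    dd_abs = _dd_abs_for(criteria, ref_vals, ref_max)
    gamma[mask] = _gamma_search(ref_pts, ref_vals, fld, dd_abs, criteria.dta_mm, cap)
    return GammaResult(gamma=gamma, mask=mask, criteria=criteria, reference_max=ref_max)


def pass_rate(result: GammaResult) -> float:
    """Percent of above-threshold points with gamma <= 1."""
    if result.n_evaluated == 0:
        raise ValueError("gamma result has no points above the threshold")
    g = result.gamma[result.mask]
    return 100.0 * float(np.count_nonzero(g <= 1.0)) / g.size


# ---------------------------------------------------------------------------
# profile mode
# ---------------------------------------------------------------------------

_PROFILE_DIRECTIONS = {
    "lateral": (1.0, 0.0),
    "longitudinal": (0.0, 1.0),
    # "positive slope" runs from upper left to lower right of the map
    "diagonal": (1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0)),
}


def profile_compare(
    measured: GroundTruthDose | MeasuredMap | EvaluatedField,
    calculated: GroundTruthDose,
    *,
    direction: str = "lateral",
    offset_mm: float = 0.0,
    step_mm: float = 1.0,
    search_mm: float = 2.0,
    criteria: GammaCriteria | None = None,
) -> pd.DataFrame:
    """Paired dose profiles along a line, with the per-point gamma.

    The line runs through the map centre, offset perpendicular by
    ``offset_mm``; for each calculated (reference) point on the line the
    minimum gamma is searched in the plane within ``search_mm`` (the 2 mm
    profile-mode search distance).  Returns a DataFrame with columns
    position_mm, x_mm, y_mm, d_calc, d_meas, gamma.
    """
    if direction not in _PROFILE_DIRECTIONS:
        raise ValueError(f"unknown profile direction: {direction!r}")
    ux, uy = _PROFILE_DIRECTIONS[direction]
    px, py = -uy, ux  # perpendicular

    ex = calculated.extent
    half = 0.5 * min(ex[1] - ex[0], ex[3] - ex[2])
    s = np.arange(-half, half + step_mm / 2, step_mm)
    x = ux * s + px * offset_mm
    y = uy * s + py * offset_mm
    inside = (x >= ex[0]) & (x <= ex[1]) & (y >= ex[2]) & (y <= ex[3])
    if not inside.any():
        raise ValueError("profile line lies outside the calculated grid")
    s, x, y = s[inside], x[inside], y[inside]

    calc_itp = RegularGridInterpolator(
        (calculated.y, calculated.x), calculated.values, bounds_error=False, fill_value=np.nan
    )
    d_calc = calc_itp(np.stack([y, x], axis=1))

    if criteria is None:
        crit = GammaCriteria(dd_percent=3.0, dta_mm=2.0, search_cap_mm=search_mm)
    else:
        crit = GammaCriteria(
            dd_percent=criteria.dd_percent,
            dta_mm=criteria.dta_mm,
            normalization=criteria.normalization,
            threshold_percent=criteria.threshold_percent,
            search_cap_mm=search_mm,
            subgrid_mm=criteria.subgrid_mm,
        )
    bounds = ((y.min() - search_mm, y.max() + search_mm), (x.min() - search_mm, x.max() + search_mm))
    fld = prepare_evaluated(measured, crit.subgrid, bounds)

    meas_itp = RegularGridInterpolator(
        fld.axes, fld.values, bounds_error=False, fill_value=np.nan
    )
    d_meas = meas_itp(np.stack([y, x], axis=1))

    ref_max = float(calculated.values.max())
    ok = ~np.isnan(d_calc)
    gamma = np.full(s.shape, np.nan)
    if ok.any():
        dd_abs = _dd_abs_for(crit, d_calc[ok], ref_max)
        gamma[ok] = _gamma_search(
            np.stack([y[ok], x[ok]], axis=1), d_calc[ok], fld, dd_abs, crit.dta_mm, search_mm
        )
    return pd.DataFrame(
        {
            "position_mm": s,
            "x_mm": x,
            "y_mm": y,
            "d_calc": d_calc,
            "d_meas": d_meas,
            "gamma": gamma,
        }
    )
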