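"""Ion-chamber array models, planar sampling, and two-acquisition coalescence.

Two commercial 2D arrays are modelled geometrically:

* 729-type: 27 x 27 chambers on a 10 mm square pitch, 5 x 5 mm^2 sensitive
  cross-section (5 mm edge-to-edge gaps), 27 x 27 cm^2 active area;
* 1500-type: 1405 chambers in a checkerboard — a 27 x 27 main grid (10 mm
  pitch) plus a 26 x 26 interstitial grid offset by (5, 5) mm — 4.4 x 4.4
  mm^2 apertures, 7.07 mm centre-to-centre between diagonal neighbours.

A chamber reading is the mean of the ground-truth dose over its square
aperture (uniform top-hat response, no lateral-response tails).  Coalescence
merges the isocenter acquisition with a +5 mm longitudinally couch-shifted
acquisition, doubling the sampling density along the shift axis; pairs of
near-coincident points are merged by averaging, and an inconsistent overlap
(dose disagreement above a tolerance) makes the coalescence fail, as it does
for real repeated acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic import GroundTruthDose

__all__ = [
    "DetectorArray",
    "MeasuredMap",
    "CoalescedMap",
    "CoalescenceError",
    "build_array",
    "sample",
    "coalesce",
    "sampling_frequency",
    "fill_factor",
    "MERGE_EPSILON_MM",
]

#: positional epsilon below which two sample points are "the same point"
MERGE_EPSILON_MM = 0.1

#: longitudinal couch shift of the second acquisition, mm
COALESCENCE_SHIFT_MM = 5.0


class CoalescenceError(RuntimeError):
    """Coalescence failed: overlapping points disagree beyond tolerance."""

    def __init__(self, max_discrepancy: float, tolerance: float):
        self.max_discrepancy = max_discrepancy
        self.tolerance = tolerance
        super().__init__(
            f"overlapping-point dose difference {max_discrepancy:.4g} "
            f"exceeds tolerance {tolerance:.4g}"
        )


@dataclass(frozen=True)
class DetectorArray:
    """Chamber-centre geometry of a 2D ion-chamber array."""

    model: str
    centers: np.ndarray  # (n, 2) chamber centres (x, y) mm, isocenter at (0,0)
    aperture_mm: float  # side of the square sensitive cross-section
    height_mm: float  # chamber height (metadata only)
    layout: str  # "square_grid" or "checkerboard"
    extent_mm: tuple[float, float]  # active area

    @property
    def n_chambers(self) -> int:
        return self.centers.shape[0]


@dataclass
class MeasuredMap:
    """Sparse dose samples from one acquisition of an array."""

    positions: np.ndarray  # (n, 2) mm — chamber centres + shift
    values: np.ndarray  # (n,)
    shift_mm: tuple[float, float]
    array_model: str
    source: str = ""

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


@dataclass
class CoalescedMap(MeasuredMap):
    """Union of two acquisitions, with an overlap-consistency report."""

    n_merged: int = 0
    max_overlap_discrepancy: float = 0.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _square_grid(n: int, pitch: float, offset: tuple[float, float] = (0.0, 0.0)):
    half = (n - 1) / 2.0 * pitch
    c = np.arange(n) * pitch - half
    xx, yy = np.meshgrid(c + offset[0], c + offset[1])
    return np.column_stack([xx.ravel(), yy.ravel()])


def build_array(model: str) -> DetectorArray:
    """Build the chamber geometry for model "d729" or "d1500"."""
    if model == "d729":
        centers = _square_grid(27, 10.0)
        return DetectorArray(
            model=model,
            centers=centers,
            aperture_mm=5.0,
            height_mm=5.0,
            layout="square_grid",
            extent_mm=(270.0, 270.0),
        )
    if model == "d1500":
        main = _square_grid(27, 10.0)
        inter = _square_grid(26, 10.0)  # 26x26 grid is already offset by (5,5)
        centers = np.vstack([main, inter])
        return DetectorArray(
            model=model,
            centers=centers,
            aperture_mm=4.4,
            height_mm=3.0,
            layout="checkerboard",
            extent_mm=(270.0, 270.0),
        )
    raise ValueError(f"unknown detector model: {model!r}")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample(
    dose: GroundTruthDose,
    array: DetectorArray,
    shift_mm: tuple[float, float] = (0.0, 0.0),
) -> MeasuredMap:
    """Acquire one measurement: aperture-averaged dose at each chamber.

    Each value is the mean of the ground-truth dose over the pixels whose
    centres fall inside the chamber's square aperture (fixed mid-point
    quadrature).  The dose grid must be finer than the aperture, and every
    shifted aperture must lie inside the grid.
    """
    if max(dose.spacing) >= array.aperture_mm:
        raise ValueError("dose grid must be finer than the chamber aperture")
    half = array.aperture_mm / 2.0
    x, y = dose.x, dose.y
    positions = array.centers + np.asarray(shift_mm, dtype=float)

    lo = positions - half
    hi = positions + half
    if (
        np.any(lo[:, 0] < x[0] - dose.spacing[0] / 2)
        or np.any(hi[:, 0] > x[-1] + dose.spacing[0] / 2)
        or np.any(lo[:, 1] < y[0] - dose.spacing[1] / 2)
        or np.any(hi[:, 1] > y[-1] + dose.spacing[1] / 2)
    ):
        bad = int(
            np.nonzero(
                (lo[:, 0] < x[0] - dose.spacing[0] / 2)
                | (hi[:, 0] > x[-1] + dose.spacing[0] / 2)
                | (lo[:, 1] < y[0] - dose.spacing[1] / 2)
                | (hi[:, 1] > y[-1] + dose.spacing[1] / 2)
            )[0][0]
        )
        raise ValueError(
            f"chamber {bad} at {tuple(positions[bad])} mm: aperture outside dose grid"
        )

    # half-open aperture [lo, hi): a pixel centre exactly on the upper edge
    # belongs to the next chamber, keeping the quadrature unbiased when the
    # grid aligns with the aperture boundary
    ix0 = np.searchsorted(x, lo[:, 0] - 1e-9, side="left")
    ix1 = np.searchsorted(x, hi[:, 0] - 1e-9, side="right")
    iy0 = np.searchsorted(y, lo[:, 1] - 1e-9, side="left")
    iy1 = np.searchsorted(y, hi[:, 1] - 1e-9, side="right")

    values = np.empty(array.n_chambers)
    for k in range(array.n_chambers):
        block = dose.values[iy0[k]:iy1[k], ix0[k]:ix1[k]]
        values[k] = block.mean()

    return MeasuredMap(
        positions=positions,
        values=values,
        shift_mm=tuple(np.asarray(shift_mm, dtype=float)),
        array_model=array.model,
    )


# ---------------------------------------------------------------------------
# coalescence
# ---------------------------------------------------------------------------

def coalesce(
    iso: MeasuredMap,
    shifted: MeasuredMap,
    tolerance: float = np.inf,
    *,
    merge_epsilon_mm: float = MERGE_EPSILON_MM,
) -> CoalescedMap:
    """Merge the isocenter acquisition with the couch-shifted acquisition.

    Sample points of both parents are kept; points of the two acquisitions
    closer than ``merge_epsilon_mm`` are duplicates and merged by averaging.
    If any duplicate pair's dose difference exceeds ``tolerance`` the
    coalescence fails with :class:`CoalescenceError` carrying the largest
    discrepancy (the real-world failure mode of inconsistent repeated
    measurements).
    """
    if iso.array_model != shifted.array_model:
        raise ValueError("cannot coalesce maps from different array models")

    tree = cKDTree(iso.positions)
    dist, idx = tree.query(shifted.positions, k=1)
    dup = dist <= merge_epsilon_mm

    max_disc = 0.0
    if np.any(dup):
        max_disc = float(np.max(np.abs(shifted.values[dup] - iso.values[idx[dup]])))
        if max_disc > tolerance:
            raise CoalescenceError(max_disc, tolerance)

    values = iso.values.copy()
    # average duplicates into the isocenter point
    for j in np.nonzero(dup)[0]:
        i = idx[j]
        values[i] = 0.5 * (iso.values[i] + shifted.values[j])

    positions = np.vstack([iso.positions, shifted.positions[~dup]])
    values = np.concatenate([values, shifted.values[~dup]])

    return CoalescedMap(
        positions=positions,
        values=values,
        shift_mm=iso.shift_mm,
        array_model=iso.array_model,
        source=f"coalesced({iso.source},{shifted.source})",
        n_merged=int(np.count_nonzero(dup)),
        max_overlap_discrepancy=max_disc,
    )


def acquire_coalesced(
    dose: GroundTruthDose,
    array: DetectorArray,
    tolerance: float = np.inf,
    shift_mm: float = COALESCENCE_SHIFT_MM,
) -> CoalescedMap:
    """Convenience: isocenter + (+shift longitudinal) acquisitions, coalesced."""
    iso = sample(dose, array, (0.0, 0.0))
    moved = sample(dose, array, (0.0, shift_mm))
    return coalesce(iso, moved, tolerance)


# ---------------------------------------------------------------------------
# sampling frequency & fill factor
# ---------------------------------------------------------------------------

def _min_spacing_along(points: np.ndarray, direction: str) -> float:
    """Minimum centre spacing along row/column/diagonal lines of a point set."""
    if direction == "row":
        along, across = points[:, 0], points[:, 1]
    elif direction == "column":
        along, across = points[:, 1], points[:, 0]
    elif direction == "diagonal":
        along = (points[:, 0] + points[:, 1]) / np.sqrt(2.0)
        across = (points[:, 1] - points[:, 0]) / np.sqrt(2.0)
    else:
        raise ValueError(f"unknown direction: {direction!r}")

    best = np.inf
    keys = np.round(across, 6)
    for key in np.unique(keys):
        u = np.sort(along[keys == key])
        if u.size > 1:
            d = np.diff(u)
            d = d[d > 1e-9]
            if d.size:
                best = min(best, float(d.min()))
    if not np.isfinite(best):
        raise ValueError("no line with two or more points along that direction")
    return best


def sampling_frequency(
    array: DetectorArray, direction: str, coalesced: bool = False
) -> float:
    """Spatial sampling frequency (mm^-1) along rows, columns or diagonals.

    Defined as 1 / (minimum centre spacing along the direction); with
    ``coalesced`` the point set is the union of the isocenter centres and
    the +5 mm longitudinally shifted centres, which is what doubles the
    along-row/column frequency of the checkerboard array from 0.1 to
    0.2 mm^-1.
    """
    pts = array.centers
    if coalesced:
        pts = np.vstack([pts, pts + np.array([0.0, COALESCENCE_SHIFT_MM])])
    return 1.0 / _min_spacing_along(pts, direction)


def fill_factor(
    array: DetectorArray, definition: str = "linear", coalesced: bool = False
) -> float:
    """Geometric detector-coverage fraction.

    "linear": fraction of a sampling line covered by sensitive aperture,
    aperture side / centre spacing along a row (0.5 for the 10 mm-pitch
    5 mm-aperture array).  "areal": total sensitive area / active area.
    Purely geometric — lateral response functions are not modelled, so the
    published response-overlap fill factors of the checkerboard array are
    not reproduced.
    """
    if definition == "linear":
        spacing = 1.0 / sampling_frequency(array, "row", coalesced=coalesced)
        return min(1.0, array.aperture_mm / spacing)
    if definition == "areal":
        n = array.n_chambers * (2 if coalesced else 1)
        return min(1.0, n * array.aperture_mm**2 / (array.extent_mm[0] * array.extent_mm[1]))
    raise ValueError(f"unknown fill-factor definition: {definition!r}")
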