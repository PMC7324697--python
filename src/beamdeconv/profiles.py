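"""Transverse beam profiles: data model, preprocessing, and penumbra metrics.

A :class:`Profile` is a transverse scan of relative dose versus off-axis
distance (mm), with the central axis (CAX) at ``x = 0``.  Scanning
ionization chambers blur the field edges (volume averaging), so the key
evaluation metric in this package is the 20--80% penumbra width and the
penumbra width difference (PWD) between a candidate profile and a
reference profile measured with a near-point detector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

__all__ = [
    "ProfileMeta",
    "Profile",
    "PenumbraReport",
    "resample_to_grid",
    "smooth",
    "normalize_cax",
    "penumbra_width",
    "pwd",
    "mse",
    "read_profile_csv",
    "write_profile_csv",
]


@dataclass(frozen=True)
class ProfileMeta:
    """Scan metadata: beam condition, geometry, and which detector took it."""

    energy: str = "6MV"
    modality: str = "FF"  # FF (flattened) or FFF (flattening-filter-free)
    field_size_mm: float = 100.0
    depth_mm: float = 100.0
    detector: str = ""
    role: str = "measured"  # measured | reference | deconvolved | true

    def to_dict(self) -> dict:
        return {
            "energy": self.energy,
            "modality": self.modality,
            "field_size_mm": self.field_size_mm,
            "depth_mm": self.depth_mm,
            "detector": self.detector,
            "role": self.role,
        }


@dataclass(frozen=True, eq=False)
class Profile:
    """One transverse scan on a uniform position grid.

    Parameters
    ----------
    positions
        Off-axis distance in mm, strictly increasing. After preprocessing
        the grid is uniform at 1 mm and contains a sample at x = 0.
    values
        Relative dose, dimensionless. After :func:`normalize_cax` the
        value at x = 0 equals 1.
    meta
        Beam/geometry/detector metadata.
    """

    positions: np.ndarray
    values: np.ndarray
    meta: ProfileMeta = field(default_factory=ProfileMeta)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or val.ndim != 1 or pos.size != val.size:
            raise ValueError("positions and values must be 1-D arrays of equal length")
        if pos.size < 2:
            raise ValueError("a profile needs at least two samples")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(val))):
            raise ValueError("positions and values must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    # -- grid helpers -----------------------------------------------------

    @property
    def step(self) -> float:
        """Grid spacing in mm (mean spacing; uniform after preprocessing)."""
        return float(np.mean(np.diff(self.positions)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.positions)
        return bool(np.allclose(d, d[0], rtol=0, atol=1e-9))

    def index_of_zero(self) -> int:
        """Index of the sample at x = 0 (raises if none within tolerance)."""
        i = int(np.argmin(np.abs(self.positions)))
        if abs(self.positions[i]) > 1e-6:
            raise ValueError("profile has no sample at x = 0")
        return i

    @property
    def cax_value(self) -> float:
        return float(self.values[self.index_of_zero()])

    def with_values(self, values: np.ndarray, role: str | None = None) -> "Profile":
        meta = self.meta if role is None else replace(self.meta, role=role)
        return Profile(self.positions.copy(), np.asarray(values, dtype=float), meta)


@dataclass(frozen=True)
class PenumbraReport:
    """20--80% penumbra widths of both field edges.

    ``crossings`` maps level labels ("left_20", "left_80", "right_20",
    "right_80") to the interpolated off-axis positions (mm) where the
    profile crosses 20% and 80% of the CAX value.
    """

    left_width: float
    right_width: float
    crossings: dict

    @property
    def mean_width(self) -> float:
        return 0.5 * (self.left_width + self.right_width)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def resample_to_grid(profile: Profile, step: float = 1.0) -> Profile:
    """Resample a profile onto a uniform grid containing x = 0.

    Uses monotone piecewise-cubic (PCHIP) interpolation, which does not
    overshoot on the steep penumbra edges the way a plain cubic spline can.
    The output grid spans the input range at spacing ``step`` and always
    includes a node at the central axis.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pos = profile.positions
    if pos[0] > 0 or pos[-1] < 0:
        raise ValueError("profile grid does not bracket x = 0")
    n_neg = math.floor(-pos[0] / step + 1e-12)
    n_pos = math.floor(pos[-1] / step + 1e-12)
    grid = np.arange(-n_neg, n_pos + 1) * step
    interp = PchipInterpolator(pos, profile.values)
    return Profile(grid, interp(grid), profile.meta)


def smooth(profile: Profile, window_pts: int = 5, poly_order: int = 2) -> Profile:
    """Savitzky–Golay smoothing (local least-squares polynomial fit).

    Endpoints are handled by fitting the terminal window's polynomial and
    evaluating it at the edge samples, so polynomials of degree
    ``<= poly_order`` pass through unchanged.
    """
    if window_pts % 2 != 1 or window_pts <= poly_order:
        raise ValueError("window_pts must be odd and greater than poly_order")
    if window_pts > profile.values.size:
        raise ValueError("smoothing window larger than profile")
    smoothed = savgol_filter(profile.values, window_pts, poly_order, mode="interp")
    return profile.with_values(smoothed)


def normalize_cax(profile: Profile) -> Profile:
    """Normalize so the central-axis value equals 1."""
    cax = profile.cax_value
    if cax <= 0:
        raise ValueError("central-axis value must be positive to normalize")
    return profile.with_values(profile.values / cax)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _edge_crossing(positions, values, level, from_left):
    """First bracketing of ``level`` scanning from the outermost sample inward.

    Returns the linearly interpolated crossing position. Scanning outside-in
    keeps the metric robust to noise dips inside the field.
    """
    n = values.size
    idx = range(n - 1) if from_left else range(n - 2, -1, -1)
    for i in idx:
        lo, hi = values[i], values[i + 1]
        if (lo - level) * (hi - level) <= 0 and lo != hi:
            t = (level - lo) / (hi - lo)
            return float(positions[i] + t * (positions[i + 1] - positions[i]))
        if lo == hi == level:
            return float(positions[i])
    side = "left" if from_left else "right"
    raise ValueError(
        f"profile never crosses the {level:.0%} level on the {side} edge "
        "(is it normalized to CAX = 1?)"
    )


def penumbra_width(profile: Profile, low: float = 0.2, high: float = 0.8) -> PenumbraReport:
    """20--80% penumbra width of each field edge.

    The profile must be normalized to CAX = 1. Each crossing is located by
    scanning from the outermost sample toward the axis and linearly
    interpolating within the first interval that brackets the level.
    """
    pos, val = profile.positions, profile.values
    crossings = {
        "left_20": _edge_crossing(pos, val, low, from_left=True),
        "left_80": _edge_crossing(pos, val, high, from_left=True),
        "right_20": _edge_crossing(pos, val, low, from_left=False),
        "right_80": _edge_crossing(pos, val, high, from_left=False),
    }
    return PenumbraReport(
        left_width=abs(crossings["left_80"] - crossings["left_20"]),
        right_width=abs(crossings["right_20"] - crossings["right_80"]),
        crossings=crossings,
    )


def pwd(candidate: Profile, reference: Profile) -> float:
    """Penumbra width difference W(candidate) − W(reference), mm, signed.

    Uses the mean of the left and right edge widths of each profile.
    """
    return penumbra_width(candidate).mean_width - penumbra_width(reference).mean_width


def mse(output: Profile, reference: Profile) -> float:
    """Mean squared pointwise difference over the common grid."""
    if output.values.size != reference.values.size or not np.allclose(
        output.positions, reference.positions, atol=1e-9
    ):
        raise ValueError("profiles must share a common grid")
    diff = output.values - reference.values
    return float(np.mean(diff * diff))


# ---------------------------------------------------------------------------
# CSV + JSON sidecar I/O
# ---------------------------------------------------------------------------


def write_profile_csv(profile: Profile, path: str | Path) -> None:
    """Write ``position_mm,value`` CSV plus a ``<name>.meta.json`` sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"position_mm": profile.positions, "value": profile.values}
    ).to_csv(path, index=False)
    sidecar = path.with_suffix("").with_suffix(".meta.json")
    sidecar.write_text(json.dumps(profile.meta.to_dict(), indent=1))


def read_profile_csv(path: str | Path) -> Profile:
    """Read a profile CSV; the metadata sidecar is optional."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"position_mm", "value"} <= set(df.columns):
        raise ValueError(f"{path} lacks required columns position_mm,value")
    sidecar = path.with_suffix("").with_suffix(".meta.json")
    meta = ProfileMeta(**json.loads(sidecar.read_text())) if sidecar.exists() else ProfileMeta()
    return Profile(df["position_mm"].to_numpy(), df["value"].to_numpy(), meta)
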