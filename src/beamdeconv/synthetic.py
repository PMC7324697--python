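"""Synthetic water-tank scan generator.

Produces true / reference / chamber-measured profile triplets with the
statistical structure the deconvolution method assumes: the true profile is
a sum-of-error-functions field edge model (with an optional linear
cone for flattening-filter-free beams), the chamber measurement is the true
profile convolved with a Gaussian detector-response kernel plus a small
additive noise, and the diode reference is the true profile plus the same
noise but no blurring.

The default geometry grid — seven square fields from 2x2 to 10x10 cm^2 at
depths 1.5, 5, 10 and 20 cm — gives 28 scans per beam condition, enough to
exercise the full train/test protocol without any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .kernel import convolve, make_kernel
from .profiles import Profile, ProfileMeta

__all__ = ["SyntheticConfig", "GeometryEntry", "true_profile", "simulate_measurement", "build_dataset"]

#: Gaussian response widths (mm) that emulate common scanning detectors.
#: CC13 follows measured characterizations (~2.6 mm); CC04 and FC65-P are
#: scaled so penumbra broadening orders as chamber size (CC04 < CC13 < FC65-P);
#: the EDGE diode's volume averaging is negligible.
DEFAULT_DETECTOR_SIGMA = {"CC04": 1.3, "CC13": 2.6, "FC65P": 2.9, "EDGE": 0.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings for one beam condition.

    Attributes
    ----------
    field_sizes_mm, depths_mm
        Geometry grid; defaults give the 7 x 4 = 28-scan condition.
    lambda0_mm, lambda_slope_per_mm
        Edge softness of the true profile: the erf edge parameter grows
        linearly with depth, lambda(d) = lambda0 + slope * d, emulating
        penumbra broadening with depth.
    magnification
        If True, the projected field half-width grows geometrically with
        depth, W(d) = W0 * (SAD + d - d_ref)/SAD; off by default.
    fff_cone_slope
        In-field linear falloff per mm of off-axis distance for
        flattening-filter-free beams (0 for flattened beams).
    tail_level
        Out-of-field transmission as a fraction of CAX dose.
    detector_sigma_mm
        Map of detector label to Gaussian response width (mm).
    noise_sd
        Additive Gaussian noise, as a fraction of the CAX value.
    """

    field_sizes_mm: tuple = (20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0)
    depths_mm: tuple = (15.0, 50.0, 100.0, 200.0)
    extra_halfspan_mm: float = 40.0
    lambda0_mm: float = 1.0
    lambda_slope_per_mm: float = 0.005
    magnification: bool = False
    sad_mm: float = 1000.0
    ref_depth_mm: float = 15.0
    fff_cone_slope: float = 0.0015
    tail_level: float = 0.015
    detector_sigma_mm: dict = field(default_factory=lambda: dict(DEFAULT_DETECTOR_SIGMA))
    noise_sd: float = 0.002
    grid_step_mm: float = 1.0
    energy: str = "6MV"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.tail_level < 0.1:
            raise ValueError("tail_level must be in [0, 0.1)")
        if any(s < 0 for s in self.detector_sigma_mm.values()):
            raise ValueError("detector sigma values must be non-negative")
        for d in self.depths_mm:
            if self.edge_softness(d) <= 0:
                raise ValueError(f"edge softness non-positive at depth {d} mm")

    def edge_softness(self, depth_mm: float) -> float:
        return self.lambda0_mm + self.lambda_slope_per_mm * depth_mm

    def halfspan(self, field_size_mm: float) -> float:
        return field_size_mm / 2.0 + self.extra_halfspan_mm


def true_profile(
    config: SyntheticConfig, field_size_mm: float, depth_mm: float, modality: str = "FF"
) -> Profile:
    """Analytic true profile for one geometry.

    The field edge is the classic error-function pair

        B(x) = 1/2 [erf((W/2 - x) / (sqrt(2) lam)) + erf((W/2 + x) / (sqrt(2) lam))]

    with W the field width and lam the depth-dependent edge softness.  FFF
    beams multiply the in-field dose by (1 - c |x|); a constant transmission
    tail is blended in out of field; the result is normalized to CAX = 1 on
    a 1 mm grid.
    """
    lam = config.edge_softness(depth_mm)
    width = field_size_mm
    if config.magnification:
        width *= (config.sad_mm + depth_mm - config.ref_depth_mm) / config.sad_mm
    half = config.halfspan(field_size_mm)
    n = int(round(half / config.grid_step_mm))
    x = np.arange(-n, n + 1) * config.grid_step_mm
    s = np.sqrt(2.0) * lam
    base = 0.5 * (erf((width / 2.0 - x) / s) + erf((width / 2.0 + x) / s))
    if modality == "FFF":
        base = base * (1.0 - config.fff_cone_slope * np.abs(x))
    vals = base + config.tail_level * (1.0 - base)
    vals = vals / vals[n]
    meta = ProfileMeta(
        energy=config.energy,
        modality=modality,
        field_size_mm=field_size_mm,
        depth_mm=depth_mm,
        detector="analytic",
        role="true",
    )
    return Profile(x, vals, meta)


def simulate_measurement(
    true: Profile, detector: str, config: SyntheticConfig, seed: int | None = None
) -> Profile:
    """Simulate one detector's scan of a true profile.

    Convolves with the detector's Gaussian response kernel, adds i.i.d.
    Gaussian noise (``noise_sd`` of CAX), and renormalizes to CAX = 1.
    A detector with sigma = 0 (the diode) returns a noise-only copy with
    role ``reference``; blurring detectors get role ``measured``.
    """
    if detector not in config.detector_sigma_mm:
        raise ValueError(f"unknown detector {detector!r}")
    sigma = config.detector_sigma_mm[detector]
    if sigma > 0:
        out = convolve(true, make_kernel(sigma, true.step))
        role = "measured"
    else:
        out = true.with_values(true.values.copy())
        role = "reference"
    rng = np.random.default_rng(config.seed if seed is None else seed)
    vals = out.values + rng.normal(0.0, config.noise_sd, size=out.values.size)
    prof = Profile(
        true.positions.copy(),
        vals,
        replace(true.meta, detector=detector, role=role),
    )
    return prof.with_values(vals / prof.cax_value)


@dataclass(frozen=True, eq=False)
class GeometryEntry:
    """All scans of one (field size, depth) geometry."""

    field_size_mm: float
    depth_mm: float
    true: Profile
    reference: Profile
    measured: dict  # detector label -> Profile


def build_dataset(config: SyntheticConfig, modality: str = "FF") -> list:
    """Generate the full geometry grid for one beam condition.

    Returns one :class:`GeometryEntry` per (field size, depth) — 28 at the
    defaults — each holding the analytic true profile, the diode reference,
    and one measured profile per blurring detector.  Deterministic under
    ``config.seed``: noise seeds are derived per geometry and detector.
    """
    root = np.random.SeedSequence(config.seed)
    entries = []
    detectors = sorted(config.detector_sigma_mm)
    for i, fs in enumerate(config.field_sizes_mm):
        for j, d in enumerate(config.depths_mm):
            truth = true_profile(config, fs, d, modality)
            geom_seed = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(i, j)
            ).generate_state(len(detectors))
            reference = None
            measured = {}
            for k, det in enumerate(detectors):
                prof = simulate_measurement(
                    truth, det, config, seed=int(geom_seed[k] & 0x7FFFFFFF)
                )
                if prof.meta.role == "reference":
                    reference = prof
                else:
                    measured[det] = prof
            entries.append(
                GeometryEntry(
                    field_size_mm=fs,
                    depth_mm=d,
                    true=truth,
                    reference=reference,
                    measured=measured,
                )
            )
    return entries
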