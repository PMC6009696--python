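"""Nuclear-envelope vs nucleoplasmic intensity profiling on 2D mid-sections.

A line scan is drawn through the nucleus-mask centroid of a mid-optical
section; intensity is sampled by bilinear interpolation at evenly spaced
points between the two boundary crossings and the position axis rescaled to
[0, 1] (0 and 1 = opposite boundary crossings, 0.5 = centre), so profiles
from nuclei of different diameters can be averaged pointwise.  Average
profiles are normalized to the mean peripheral intensity (mean of the two
profile endpoints) of a reference condition, which maps that reference
peripheral value to exactly 1.0.  A scalar peripheral/interior ratio
summarizes envelope enrichment, and total intensity per nuclear area and a
two-sample t test support condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

__all__ = [
    "Section",
    "LineProfile",
    "ProfileSummary",
    "ProfileGeometryError",
    "extract_line_profile",
    "average_profiles",
    "peripheral_ratio",
    "total_intensity_per_area",
    "compare_conditions",
]


class ProfileGeometryError(ValueError):
    """The scan line cannot be constructed for this section."""


@dataclass
class Section:
    """One 2D mid-optical section with its nucleus mask."""

    image: np.ndarray          # (y, x) intensities
    pixel_size: float          # µm
    nucleus_mask: np.ndarray   # boolean (y, x)
    condition: str = ""


@dataclass
class LineProfile:
    positions: np.ndarray      # in [0, 1], strictly increasing
    intensities: np.ndarray
    n_samples: int


@dataclass
class ProfileSummary:
    positions: np.ndarray
    mean_profile: np.ndarray   # normalized pointwise mean across nuclei
    normalization: float       # reference mean peripheral intensity
    peripheral_ratio: float
    n_nuclei: int


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ProfileGeometryError("empty nucleus mask")
    return idx.mean(axis=0)


def _mask_orientation(mask: np.ndarray) -> float:
    """Angle (radians, from the x axis) of the mask's major axis via the
    second central moments; 0 for a perfectly symmetric disk."""
    idx = np.argwhere(mask).astype(float)
    c = idx.mean(axis=0)
    d = idx - c
    cov = d.T @ d / len(d)
    evals, evecs = np.linalg.eigh(cov)
    vy, vx = evecs[:, int(np.argmax(evals))]
    return float(np.arctan2(vy, vx))


def _occupancy(mask, points) -> np.ndarray:
    """Bilinear mask occupancy at (row, col) points; outside reads 0."""
    pts = np.atleast_2d(points)
    return map_coordinates(mask.astype(np.float32), pts.T, order=1,
                           mode="constant", cval=0.0)


def _inside(mask, p) -> bool:
    return bool(_occupancy(mask, p)[0] >= 0.5)


def _boundary_distance(mask, centroid, direction, step=0.25) -> float:
    """Distance (pixels) from the centroid to the sub-pixel 0.5 crossing of
    the mask occupancy along ``direction``."""
    max_t = float(np.hypot(*mask.shape)) + step
    ts = np.arange(0.0, max_t, step)
    vals = _occupancy(mask, centroid[None, :] + ts[:, None] * direction[None, :])
    outside = np.flatnonzero(vals < 0.5)
    if outside.size == 0:
        raise ProfileGeometryError("scan line never leaves the mask")
    i = int(outside[0])
    if i == 0:
        raise ProfileGeometryError("scan start lies outside the mask")
    v_in, v_out = float(vals[i - 1]), float(vals[i])
    return float(ts[i - 1] + step * (v_in - 0.5) / (v_in - v_out))


def extract_line_profile(section: Section, angle="major", n_samples: int = 101,
                         rng: np.random.Generator | None = None) -> LineProfile:
    """Sample a line scan across the nucleus of one section.

    ``angle`` is in radians from the image x axis, or ``"major"`` (default:
    the mask's major axis) or ``"random"`` (requires ``rng``).  The line
    passes through the mask centroid; intensities are sampled by bilinear
    interpolation at ``n_samples`` evenly spaced points between the two
    boundary crossings, positions rescaled to [0, 1].
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    mask = section.nucleus_mask
    centroid = _mask_centroid(mask)
    if not _inside(mask, centroid):
        raise ProfileGeometryError("mask centroid lies outside the mask")
    if isinstance(angle, str):
        if angle == "major":
            theta = _mask_orientation(mask)
        elif angle == "random":
            if rng is None:
                raise ValueError("angle='random' requires an rng")
            theta = float(rng.uniform(0.0, np.pi))
        else:
            raise ValueError(f"unknown angle {angle!r}")
    else:
        theta = float(angle)
    d = np.array([np.sin(theta), np.cos(theta)])  # (row, col)

    # endpoints sit half a pixel inside each boundary crossing so the end
    # samples read nuclear intensity, not the edge's nucleus/background mix
    t_plus = _boundary_distance(mask, centroid, d) - 0.5
    t_minus = _boundary_distance(mask, centroid, -d) - 0.5
    if t_plus <= 0 or t_minus <= 0:
        raise ProfileGeometryError("line does not cross the boundary twice")
    b_plus = centroid + t_plus * d
    b_minus = centroid - t_minus * d

    frac = np.linspace(0.0, 1.0, n_samples)
    coords = b_minus[:, None] + (b_plus - b_minus)[:, None] * frac[None, :]
    intensities = map_coordinates(section.image.astype(float), coords, order=1,
                                  mode="nearest")
    return LineProfile(positions=frac, intensities=intensities, n_samples=n_samples)


def _profile_matrix(profiles) -> np.ndarray:
    if not profiles:
        raise ValueError("empty profile list")
    n = profiles[0].n_samples
    if any(p.n_samples != n for p in profiles):
        raise ValueError("profiles must share n_samples to be averaged")
    return np.stack([p.intensities for p in profiles])


def _peripheral_value(profile: np.ndarray) -> float:
    """Peripheral intensity of a profile: mean of its two endpoints."""
    return 0.5 * (float(profile[0]) + float(profile[-1]))


def average_profiles(profiles, reference_profiles) -> ProfileSummary:
    """Pointwise mean profile, normalized to the reference periphery.

    Both conditions are divided by the reference condition's mean peripheral
    intensity, so the reference peripheral value maps to exactly 1.0 (call
    with ``profiles is reference_profiles`` for the reference itself).
    """
    mat = _profile_matrix(profiles)
    ref = _profile_matrix(reference_profiles)
    norm = _peripheral_value(ref.mean(axis=0))
    if norm == 0:
        raise ValueError("reference peripheral intensity is zero")
    mean_profile = mat.mean(axis=0) / norm
    positions = profiles[0].positions
    return ProfileSummary(
        positions=positions,
        mean_profile=mean_profile,
        normalization=norm,
        peripheral_ratio=peripheral_ratio(
            LineProfile(positions, mean_profile, mean_profile.size)
        ),
        n_nuclei=mat.shape[0],
    )


def peripheral_ratio(profile: LineProfile, rim_fraction: float = 0.1) -> float:
    """Peripheral-to-interior intensity ratio of one profile.

    Mean intensity over the outer ``rim_fraction`` of positions at both ends
    divided by the mean over the central band; 1.0 for a flat profile,
    larger for envelope-enriched staining.
    """
    if not 0.0 < rim_fraction < 0.5:
        raise ValueError("rim_fraction must be in (0, 0.5)")
    if profile.n_samples < 10:
        raise ValueError("need at least 10 samples for a stable ratio")
    pos = profile.positions
    vals = profile.intensities
    rim = (pos <= rim_fraction) | (pos >= 1.0 - rim_fraction)
    core = ~rim
    if not core.any():
        raise ValueError("rim_fraction leaves no interior samples")
    return float(vals[rim].mean() / vals[core].mean())


def total_intensity_per_area(section: Section) -> float:
    """Total intensity inside the nucleus mask per µm^2 of nuclear area."""
    mask = section.nucleus_mask
    npix = int(mask.sum())
    if npix == 0:
        raise ValueError("empty nucleus mask")
    area = npix * section.pixel_size**2
    return float(section.image[mask].sum()) / area


def compare_conditions(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test on per-nucleus intensity statistics.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Two identical zero-variance groups give
    (0, 1) rather than an undefined statistic.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
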