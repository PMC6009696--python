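"""Percent radial distance (%RD) of chromosome territories and its statistics.

The positioning statistic: from the nucleus centre *N*, the ray through the
territory centre *C* is extended to the point *B* where it leaves the
nucleus.  With R = |NC| and Y = |NB|,

    %RD = (R / Y) * 100

so 0% is the nuclear centre and 100% the periphery, independent of nuclear
size and shape along that ray.  This module computes the statistic per
territory, aggregates values per condition x chromosome (sample median and
20%-wide bin frequencies), compares conditions with the Mann-Whitney U test,
and builds shift tables: Δ = median(condition) − median(reference) in
percentage points, positive toward the periphery, plus the within-condition
separation Δ(CTa − CTb) = median_a − median_b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import (
    NucleusMask,
    SegmentationError,
    extract_nucleus,
    extract_territories,
)
from .synthetic import Scene

__all__ = [
    "TerritoryMeasurement",
    "ConditionSummary",
    "SegConfig",
    "GeometryError",
    "BIN_EDGES",
    "boundary_intersection",
    "percent_rd",
    "measure_scene",
    "summarize",
    "compare",
    "shift_table",
]

log = logging.getLogger(__name__)

BIN_EDGES = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])  # 20%-wide %RD bins


class GeometryError(ValueError):
    """Ray/boundary construction is undefined for the given points."""


@dataclass
class TerritoryMeasurement:
    """One territory's geometry: N, C, B, R = |NC|, Y = |NB|, %RD."""

    N: np.ndarray
    C: np.ndarray
    B: np.ndarray
    R: float
    Y: float
    percent_rd: float
    channel: str
    scene_id: str = ""
    clamped: bool = False


@dataclass
class ConditionSummary:
    """Pooled %RD values of one chromosome under one condition."""

    condition: str
    chromosome: str
    values: np.ndarray
    n: int
    median: float
    bin_frequencies: np.ndarray  # fractions over [0,20),[20,40),[40,60),[60,80),[80,100]


@dataclass(frozen=True)
class SegConfig:
    """Segmentation settings used by :func:`measure_scene`."""

    threshold_method: str = "otsu"
    threshold_value: float | None = None
    max_objects: int = 2
    min_volume: float = 0.5  # µm^3
    clip_to_nucleus: bool = True
    step: float | None = None  # boundary march step (µm); default min(voxel)/2


def _mask_values(mask: np.ndarray, voxel_size, points) -> np.ndarray:
    """Trilinear occupancy of the mask at physical points.

    The boolean grid is treated as an indicator sampled at voxel centres
    ``(i + 0.5) * voxel_size``; interpolating it gives a sub-voxel surface
    at the 0.5 level instead of the voxel staircase, which would otherwise
    bias boundary distances low.  Points outside the grid read 0.
    """
    from scipy.ndimage import map_coordinates

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = (pts / np.asarray(voxel_size, dtype=float)) - 0.5
    return map_coordinates(mask.astype(np.float32), coords.T, order=1,
                           mode="constant", cval=0.0)


def _point_in_mask(mask: np.ndarray, voxel_size, p) -> bool:
    return bool(_mask_values(mask, voxel_size, p)[0] >= 0.5)


def boundary_intersection(mask, N, C, *, voxel_size=None, step: float | None = None):
    """March from N through C to the point B where the ray leaves the mask.

    ``mask`` may be a :class:`NucleusMask` or a boolean grid (then
    ``voxel_size`` is required).  Sampling advances in increments of
    ``step`` (default: half the smallest voxel dimension) along the mask's
    trilinear occupancy; B is the linear interpolation of the 0.5 crossing
    between the last sample inside and the first outside, giving sub-voxel
    placement without a surface mesh.  The contract |NB| >= |NC| holds.
    """
    if isinstance(mask, NucleusMask):
        voxel_size = mask.voxel_size
        mask = mask.mask
    if voxel_size is None:
        raise ValueError("voxel_size is required when mask is a plain array")
    N = np.asarray(N, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.allclose(C, N):
        raise GeometryError("C coincides with N: ray direction is undefined")
    if not _point_in_mask(mask, voxel_size, N):
        raise GeometryError("nucleus centre N lies outside the mask")
    if step is None:
        step = float(min(voxel_size)) / 2.0
    if step <= 0:
        raise ValueError("step must be positive")

    d = C - N
    r_c = float(np.linalg.norm(d))
    d /= r_c
    max_t = float(np.linalg.norm(np.asarray(mask.shape) * np.asarray(voxel_size))) + step
    ts = np.arange(0.0, max_t, step)
    vals = _mask_values(mask, voxel_size, N[None, :] + ts[:, None] * d[None, :])
    outside = np.flatnonzero(vals < 0.5)
    if outside.size == 0:
        raise GeometryError("ray never left the mask (mask spans the frame?)")
    i_out = int(outside[0])  # i_out >= 1 since N itself is inside
    v_in, v_out = float(vals[i_out - 1]), float(vals[i_out])
    frac = (v_in - 0.5) / (v_in - v_out)
    t_b = ts[i_out - 1] + frac * step
    if t_b < r_c:
        t_b = r_c  # C marginally past the interpolated boundary; clamped later
    return N + t_b * d


def percent_rd(N, C, B) -> float:
    """%RD = 100 |NC| / |NB|, clamped to [0, 100].

    C = N gives 0 (nuclear centre); C = B gives 100 (periphery).  Values
    marginally above 100 — a blurred centroid just outside the interpolated
    boundary radius — are clamped and logged.
    """
    N = np.asarray(N, dtype=float)
    y = float(np.linalg.norm(np.asarray(B, dtype=float) - N))
    if y == 0.0:
        raise GeometryError("|NB| is zero; %RD is undefined")
    r = float(np.linalg.norm(np.asarray(C, dtype=float) - N))
    value = 100.0 * r / y
    if value > 100.0:
        log.warning("%%RD %.3f clamped to 100", value)
        return 100.0
    return value


def measure_scene(scene: Scene, seg_config: SegConfig = SegConfig()) -> list[TerritoryMeasurement]:
    """Segment a scene and measure %RD for every extracted territory.

    One measurement per territory object (each homolog counts separately).
    Territories whose centroid falls outside the nucleus mask are skipped
    with a logged per-territory error.
    """
    cfg = seg_config
    nucleus = extract_nucleus(scene, method=cfg.threshold_method, value=cfg.threshold_value)
    out: list[TerritoryMeasurement] = []
    for channel in ("green", "red"):
        objects = extract_territories(
            scene, channel,
            max_objects=cfg.max_objects, min_volume=cfg.min_volume,
            nucleus_mask=nucleus, clip_to_nucleus=cfg.clip_to_nucleus,
            method=cfg.threshold_method, value=cfg.threshold_value,
        )
        for obj in objects:
            if not _point_in_mask(nucleus.mask, nucleus.voxel_size, obj.center):
                log.warning("scene %s: %s territory centroid outside nucleus mask; skipped",
                            scene.scene_id, channel)
                continue
            if np.allclose(obj.center, nucleus.center):
                # territory exactly at the centre: %RD is 0 by definition
                out.append(TerritoryMeasurement(
                    N=nucleus.center, C=obj.center, B=nucleus.center.copy(),
                    R=0.0, Y=np.nan, percent_rd=0.0,
                    channel=channel, scene_id=scene.scene_id,
                ))
                continue
            B = boundary_intersection(nucleus, nucleus.center, obj.center, step=cfg.step)
            r = float(np.linalg.norm(obj.center - nucleus.center))
            y = float(np.linalg.norm(B - nucleus.center))
            prd = percent_rd(nucleus.center, obj.center, B)
            out.append(TerritoryMeasurement(
                N=nucleus.center, C=obj.center, B=B, R=r, Y=y,
                percent_rd=prd, channel=channel, scene_id=scene.scene_id,
                clamped=(100.0 * r / y > 100.0),
            ))
    log.info("scene %s: %d territories measured", scene.scene_id, len(out))
    return out


def summarize(values, condition: str, chromosome: str) -> ConditionSummary:
    """Median, n, and 20%-bin frequency distribution of pooled %RD values.

    Bins are left-closed ([0,20), [20,40), ...) with the last bin closed at
    100, so a value of exactly 20 counts in [20,40) and 100 in [80,100].
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty set of %RD values")
    counts, _ = np.histogram(vals, bins=BIN_EDGES)
    return ConditionSummary(
        condition=condition,
        chromosome=chromosome,
        values=vals,
        n=int(vals.size),
        median=float(np.median(vals)),
        bin_frequencies=counts / vals.size,
    )


def compare(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two %RD samples.

    Accepts :class:`ConditionSummary` objects or raw sequences.  U is the
    statistic for the first sample (number of (a, b) pairs with a > b, ties
    counting one half).  The null distribution is enumerated exactly when
    both samples have at most 8 untied observations; otherwise the
    tie-corrected normal approximation (with continuity correction) is used.
    """
    x = a.values if isinstance(a, ConditionSummary) else np.asarray(list(a), float)
    y = b.values if isinstance(b, ConditionSummary) else np.asarray(list(b), float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _medians_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        required = {"condition", "chromosome", "median"}
        if not required.issubset(summaries.columns):
            raise ValueError(f"medians frame needs columns {sorted(required)}")
        return summaries[["condition", "chromosome", "median"]].copy()
    rows = [
        {"condition": s.condition, "chromosome": s.chromosome, "median": s.median}
        for s in summaries
    ]
    return pd.DataFrame(rows)


def shift_table(summaries, reference: str,
                pair: tuple[str, str] | None = None) -> pd.DataFrame:
    """Shift table of median %RD per condition against a reference condition.

    ``summaries`` is a list of :class:`ConditionSummary` or a tidy DataFrame
    with columns (condition, chromosome, median) — e.g. printed medians.
    For every chromosome the output holds ``median_<chr>`` and
    ``delta_<chr>`` = median − median(reference), in percentage points with
    '+' meaning movement toward the nuclear periphery.  With
    ``pair=(chrA, chrB)`` a ``delta_<chrA>_<chrB>`` column gives
    median_A − median_B within each condition.  Condition order follows the
    input; the reference row has Δ = 0 by construction.
    """
    df = _medians_frame(summaries)
    conditions = list(dict.fromkeys(df["condition"]))
    chromosomes = list(dict.fromkeys(df["chromosome"]))
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not present")
    med = df.set_index(["condition", "chromosome"])["median"]
    if med.index.duplicated().any():
        raise ValueError("duplicate (condition, chromosome) medians")

    out = pd.DataFrame(index=pd.Index(conditions, name="condition"))
    for chrom in chromosomes:
        col = med.xs(chrom, level="chromosome").reindex(conditions)
        out[f"median_{chrom}"] = col
        out[f"delta_{chrom}"] = col - med.get((reference, chrom), np.nan)
    if pair is not None:
        a, b = pair
        for chrom in (a, b):
            if chrom not in chromosomes:
                raise ValueError(f"pair chromosome {chrom!r} not present")
        out[f"delta_{a}_{b}"] = (
            med.xs(a, level="chromosome").reindex(conditions)
            - med.xs(b, level="chromosome").reindex(conditions)
        )
    return out
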