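"""Ground-truthed synthetic inputs for the radial-positioning pipeline.

Three generators stand in for the study's raw data so that every downstream
stage can be tested without a download:

* :func:`render_scene` — a 3-channel confocal-like z-stack of one nucleus
  (blue = DNA counterstain filling the nucleus, green/red = chromosome
  territory paint blobs) with anisotropic Gaussian blur, background, noise
  and quantization, together with the exact pre-blur geometry.
* :func:`simulate_expression` — a gene-level expression table (FPKM per
  condition plus log2 fold change against a reference condition) with
  planted per-chromosome deregulation fractions.
* :func:`simulate_envelope_sections` — 2D mid-optical sections of circular
  nuclei with a peripheral rim whose intensity is a controlled multiple of
  the interior, emulating envelope vs nucleoplasmic protein staining.

Conventions
-----------
All coordinate triples (``voxel_size``, semiaxes, physical points) are in
array axis order ``(z, y, x)`` and physical units of micrometres.  Voxel
centres sit at ``(i + 0.5) * voxel_size``.  The default voxel is
0.105 µm in-plane and 0.34 µm axial, the acquisition geometry the pipeline
targets, with 8-bit channels.

The territory ground truth is defined by the same ray construction the
measurement uses: a territory requested at fractional radial position ``f``
is centred at ``N + f * |NB| * d`` where ``B`` is the nuclear-boundary
intersection of the ray from the nucleus centre ``N`` along direction
``d``.  Recovery of ``100 f`` by the pipeline is therefore a closed loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneParams",
    "TerritorySpec",
    "Scene",
    "SceneTruth",
    "TerritoryTruth",
    "ExpressionSimParams",
    "EnvelopeSimParams",
    "PlacementError",
    "render_scene",
    "simulate_expression",
    "simulate_envelope_sections",
    "ellipsoid_mask",
    "ellipsoid_boundary_distance",
]

DEFAULT_VOXEL_SIZE = (0.34, 0.105, 0.105)  # µm, (z, y, x)


class PlacementError(ValueError):
    """A territory blob cannot be placed at the requested position."""


# ---------------------------------------------------------------------------
# geometry helpers (analytic ellipsoids; shared with tests as oracles)
# ---------------------------------------------------------------------------

def ellipsoid_mask(shape, voxel_size, center, semiaxes):
    """Boolean voxel grid of an axis-aligned ellipsoid in physical µm.

    A voxel belongs to the mask when its centre ``(i + 0.5) * voxel_size``
    satisfies the ellipsoid inequality.
    """
    grids = np.ogrid[tuple(slice(0, int(s)) for s in shape)]
    val = sum(
        ((g + 0.5) * vs - c) ** 2 / a**2
        for g, vs, c, a in zip(grids, voxel_size, center, semiaxes)
    )
    return val <= 1.0


def ellipsoid_boundary_distance(semiaxes, direction):
    """Distance from the centre of an axis-aligned ellipsoid to its surface
    along a unit ``direction``: ``1 / sqrt(sum((d_k / a_k)^2))``."""
    d = np.asarray(direction, dtype=float)
    return 1.0 / math.sqrt(float(np.sum((d / np.asarray(semiaxes, float)) ** 2)))


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("direction must be nonzero")
    return v / n


def _fibonacci_sphere(n=256):
    """Deterministic quasi-uniform unit directions (for fit checks)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)


_FIT_DIRECTIONS = _fibonacci_sphere(256)


# ---------------------------------------------------------------------------
# scene parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerritorySpec:
    """One chromosome-territory paint blob.

    ``fractional_radial_position`` is the requested %RD/100: 0 places the
    blob centre at the nucleus centre, 1 on the boundary along ``direction``.
    """

    channel: str = "green"
    fractional_radial_position: float = 0.5
    direction: Sequence[float] | str = "random"  # unit vector (z, y, x) or "random"
    blob_semiaxes: tuple[float, float, float] = (0.8, 1.0, 1.0)  # µm
    peak_intensity: float = 0.8  # fraction of dynamic range

    def validate(self):
        if self.channel not in ("green", "red"):
            raise ValueError(f"channel must be green or red, got {self.channel!r}")
        if not 0.0 <= self.fractional_radial_position <= 1.0:
            raise ValueError("fractional_radial_position must be in [0, 1]")
        if any(a <= 0 for a in self.blob_semiaxes):
            raise ValueError("blob_semiaxes must be positive")
        if not 0.0 < self.peak_intensity <= 1.0:
            raise ValueError("peak_intensity must be in (0, 1]")


@dataclass(frozen=True)
class SceneParams:
    """Full specification of one synthetic nucleus stack."""

    nucleus_semiaxes: tuple[float, float, float] = (3.2, 4.0, 4.0)  # µm (z, y, x)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    frame_shape: tuple[int, int, int] = (28, 96, 96)  # (z, y, x) voxels
    territories: tuple[TerritorySpec, ...] = ()
    psf_sigma: tuple[float, float, float] = (0.4, 0.2, 0.2)  # µm per axis
    noise_model: tuple = ("gaussian", 0.02)  # "none" | ("gaussian", σ) | ("poisson", scale)
    background_level: float = 0.05  # fraction of dynamic range
    bit_depth: int = 8
    nucleus_intensity: float = 0.8  # fraction of dynamic range
    shrink_to_fit: bool = True  # shrink blobs that would cross the boundary
    seed: int = 0

    def validate(self):
        if any(a <= 0 for a in self.nucleus_semiaxes):
            raise ValueError("nucleus_semiaxes must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if any(int(s) < 1 for s in self.frame_shape):
            raise ValueError("frame_shape must be >= 1 on every axis")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must be in [0, 1)")
        psf = self._psf_triple()
        if any(s < 0 for s in psf):
            raise ValueError("psf_sigma must be non-negative")
        model = self.noise_model
        if model != "none":
            kind, value = model
            if kind not in ("gaussian", "poisson") or value < 0:
                raise ValueError(f"unknown noise model {model!r}")
        extent = np.asarray(self.frame_shape) * np.asarray(self.voxel_size)
        center = extent / 2.0
        margin = np.asarray(self.nucleus_semiaxes) + 3.0 * np.asarray(psf)
        if np.any(center - margin < 0) or np.any(center + margin > extent):
            raise ValueError(
                "nucleus (plus 3 sigma blur margin) does not fit inside the frame"
            )
        for t in self.territories:
            t.validate()

    def _psf_triple(self):
        s = self.psf_sigma
        if np.isscalar(s):
            return (float(s),) * 3
        return tuple(float(v) for v in s)


@dataclass(frozen=True)
class TerritoryTruth:
    channel: str
    true_center: np.ndarray  # µm (z, y, x)
    true_fractional_rd: float
    direction: np.ndarray
    applied_semiaxes: tuple[float, float, float]  # after any shrink


@dataclass
class SceneTruth:
    """Pre-blur geometric ground truth of a rendered scene."""

    nucleus_mask: np.ndarray
    nucleus_center: np.ndarray
    nucleus_semiaxes: tuple[float, float, float]
    territories: list[TerritoryTruth]


@dataclass
class Scene:
    """A 3-channel voxel grid with its physical voxel dimensions."""

    voxels: np.ndarray  # (channel, z, y, x), integer dtype
    voxel_size: tuple[float, float, float]  # µm (z, y, x)
    channel_names: tuple[str, ...] = ("blue", "green", "red")
    scene_id: str = ""

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.voxels[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r} in {self.channel_names}") from None


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _fit_blob(nucleus_semiaxes, nucleus_center, blob_center, blob_semiaxes):
    """Largest scale s in (0, 1] at which the blob ellipsoid fits inside the
    nucleus, probing a fixed set of surface directions."""
    rel = np.asarray(blob_center) - np.asarray(nucleus_center)
    semi = np.asarray(nucleus_semiaxes, float)
    b = np.asarray(blob_semiaxes, float)

    def inside(s):
        pts = rel[None, :] + s * _FIT_DIRECTIONS * b[None, :]
        return bool(np.all(np.sum((pts / semi) ** 2, axis=1) <= 1.0))

    if inside(1.0):
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if inside(mid):
            lo = mid
        else:
            hi = mid
    return lo


def render_scene(params: SceneParams) -> tuple[Scene, SceneTruth]:
    """Render a 3-channel nucleus stack and its geometric ground truth.

    The blue channel is a filled ellipsoid at ``nucleus_intensity``; each
    territory is a filled ellipsoidal blob in its channel.  Blur, background,
    noise and quantization are applied in that order.  The truth records the
    pre-blur nucleus mask, nucleus centre, and each blob's exact centre and
    requested fractional radial position (exact by construction).

    Identical ``params`` (including seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(s) for s in params.frame_shape)
    vsize = tuple(float(v) for v in params.voxel_size)
    extent = np.asarray(shape) * np.asarray(vsize)
    center = extent / 2.0
    semi = params.nucleus_semiaxes

    nucleus = ellipsoid_mask(shape, vsize, center, semi)
    channels = {
        "blue": params.nucleus_intensity * nucleus.astype(np.float64),
        "green": np.zeros(shape, dtype=np.float64),
        "red": np.zeros(shape, dtype=np.float64),
    }

    truths: list[TerritoryTruth] = []
    for spec in params.territories:
        if isinstance(spec.direction, str):
            if spec.direction != "random":
                raise ValueError(f"unknown direction {spec.direction!r}")
            d = _unit(rng.normal(size=3))
        else:
            d = _unit(spec.direction)
        boundary = ellipsoid_boundary_distance(semi, d)
        c = center + spec.fractional_radial_position * boundary * d
        scale = _fit_blob(semi, center, c, spec.blob_semiaxes)
        if scale < 1.0:
            if not params.shrink_to_fit:
                raise PlacementError(
                    f"territory at fractional position "
                    f"{spec.fractional_radial_position} does not fit "
                    f"(would need shrink factor {scale:.3f})"
                )
            if scale < 0.05:
                raise PlacementError(
                    "territory blob cannot be shrunk enough to fit inside the nucleus"
                )
        applied = tuple(scale * a for a in spec.blob_semiaxes)
        blob = ellipsoid_mask(shape, vsize, c, applied)
        ch = channels[spec.channel]
        np.maximum(ch, spec.peak_intensity * blob, out=ch)
        truths.append(
            TerritoryTruth(
                channel=spec.channel,
                true_center=c,
                true_fractional_rd=float(spec.fractional_radial_position),
                direction=d,
                applied_semiaxes=applied,
            )
        )

    psf = params._psf_triple()
    sigma_vox = tuple(s / v for s, v in zip(psf, vsize))
    stack = []
    for name in ("blue", "green", "red"):
        img = channels[name]
        if any(s > 0 for s in sigma_vox):
            img = gaussian_filter(img, sigma=sigma_vox)
        img = img + params.background_level
        if params.noise_model != "none":
            kind, value = params.noise_model
            if kind == "gaussian" and value > 0:
                img = img + rng.normal(0.0, value, size=img.shape)
            elif kind == "poisson" and value > 0:
                img = rng.poisson(np.clip(img, 0.0, None) * value) / value
        stack.append(img)

    vmax = 2**params.bit_depth - 1
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    voxels = np.clip(np.rint(np.stack(stack) * vmax), 0, vmax).astype(dtype)

    scene = Scene(voxels=voxels, voxel_size=vsize)
    truth = SceneTruth(
        nucleus_mask=nucleus,
        nucleus_center=center,
        nucleus_semiaxes=tuple(semi),
        territories=truths,
    )
    return scene, truth


# ---------------------------------------------------------------------------
# expression table simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimParams:
    """Planted structure for a gene-level expression table.

    Deregulation fractions apply to the transcribing (non-silent) genes of a
    chromosome, so the realized per-chromosome percent deregulation converges
    to ``100 * (up + down)`` as the gene count grows.  Deregulated genes get
    ``|log2fc| = log2fc_threshold + |Normal(effect_loc, effect_scale)|`` so
    every planted call clears the threshold; background genes get
    ``Normal(0, null_log2fc_sd)`` fold changes.
    """

    n_genes_per_chromosome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500, "chr18": 500, "chr19": 500}
    )
    conditions: tuple[str, ...] = ("glass", "2kPa", "55kPa")
    reference: str = "glass"
    baseline_log_fpkm_mean: float = 2.0   # natural-log mean of transcribing FPKM
    baseline_log_fpkm_sigma: float = 1.2
    fraction_silent: float = 0.4          # FPKM <= 1 in all conditions
    # condition -> chromosome -> (up fraction, down fraction); "*" is the default
    deregulation: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "2kPa": {"chr1": (0.08, 0.08), "*": (0.045, 0.045)},
            "55kPa": {"*": (0.045, 0.045)},
        }
    )
    log2fc_threshold: float = 2.0
    effect_loc: float = 1.0
    effect_scale: float = 0.5
    null_log2fc_sd: float = 0.3
    seed: int = 0

    def validate(self):
        if not self.n_genes_per_chromosome:
            raise ValueError("n_genes_per_chromosome must not be empty")
        if any(n < 0 for n in self.n_genes_per_chromosome.values()):
            raise ValueError("gene counts must be non-negative")
        if not 0.0 <= self.fraction_silent <= 1.0:
            raise ValueError("fraction_silent must be in [0, 1]")
        if self.reference not in self.conditions:
            raise ValueError("reference must be one of the conditions")
        for cond, table in self.deregulation.items():
            if cond not in self.conditions or cond == self.reference:
                raise ValueError(f"deregulation given for invalid condition {cond!r}")
            for chrom, (up, down) in table.items():
                if not (0 <= up <= 1 and 0 <= down <= 1 and up + down <= 1):
                    raise ValueError(
                        f"invalid deregulation fractions for {cond}/{chrom}"
                    )

    def fractions(self, condition: str, chromosome: str) -> tuple[float, float]:
        table = self.deregulation.get(condition, {})
        return table.get(chromosome, table.get("*", (0.0, 0.0)))


def simulate_expression(params: ExpressionSimParams):
    """Simulate a gene-level expression table as a pandas DataFrame.

    Columns: ``gene_id``, ``chromosome``, ``fpkm_<condition>`` for every
    condition, and ``log2fc_<condition>`` for every non-reference condition.
    Silent genes have FPKM <= 1 in all conditions and are never deregulated.
    """
    import pandas as pd

    params.validate()
    rng = np.random.default_rng(params.seed)
    others = [c for c in params.conditions if c != params.reference]

    rows: dict[str, list] = {"gene_id": [], "chromosome": []}
    for cond in params.conditions:
        rows[f"fpkm_{cond}"] = []
    for cond in others:
        rows[f"log2fc_{cond}"] = []

    for chrom, n in params.n_genes_per_chromosome.items():
        silent = rng.random(n) < params.fraction_silent
        base = np.where(
            silent,
            rng.uniform(0.0, 1.0, size=n),  # FPKM <= 1 everywhere
            np.exp(
                rng.normal(
                    params.baseline_log_fpkm_mean,
                    params.baseline_log_fpkm_sigma,
                    size=n,
                )
            )
            + 1.0,  # transcribing genes clear the FPKM > 1 filter
        )
        rows["gene_id"].extend(f"{chrom}_g{i:05d}" for i in range(n))
        rows["chromosome"].extend([chrom] * n)
        rows[f"fpkm_{params.reference}"].extend(base)

        for cond in others:
            up_frac, down_frac = params.fractions(cond, chrom)
            u = rng.random(n)
            status = np.where(
                ~silent & (u < up_frac),
                1,
                np.where(~silent & (u < up_frac + down_frac), -1, 0),
            )
            effect = params.log2fc_threshold + np.abs(
                rng.normal(params.effect_loc, params.effect_scale, size=n)
            )
            null = rng.normal(0.0, params.null_log2fc_sd, size=n)
            log2fc = np.where(status == 0, null, status * effect)
            fpkm = np.where(silent, base, base * 2.0**log2fc)
            rows[f"fpkm_{cond}"].extend(fpkm)
            rows[f"log2fc_{cond}"].extend(log2fc)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2D envelope-stained sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvelopeSimParams:
    """Circular mid-sections with a peripheral rim of controlled contrast.

    ``rim_to_interior_ratio`` is the pre-noise intensity of the outer
    ``rim_width`` band relative to the interior; 1 emulates a fully
    nucleoplasmic distribution, >1 an envelope-enriched one.
    """

    section_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.105  # µm
    nucleus_radius: float = 5.0  # µm
    rim_width: float = 0.8  # µm
    rim_to_interior_ratio: float = 3.0
    interior_intensity: float = 0.25  # arbitrary units
    noise_sigma: float = 0.01
    n_nuclei: int = 10
    seed: int = 0

    def validate(self):
        if self.pixel_size <= 0 or self.nucleus_radius <= 0:
            raise ValueError("pixel_size and nucleus_radius must be positive")
        if not 0 < self.rim_width < self.nucleus_radius:
            raise ValueError("rim_width must be in (0, nucleus_radius)")
        if self.rim_to_interior_ratio < 0:
            raise ValueError("rim_to_interior_ratio must be >= 0")
        if self.noise_sigma < 0 or self.n_nuclei < 0:
            raise ValueError("noise_sigma and n_nuclei must be >= 0")
        extent = min(self.section_shape) * self.pixel_size
        if 2 * self.nucleus_radius >= extent:
            raise ValueError("nucleus does not fit inside the section")


def simulate_envelope_sections(params: EnvelopeSimParams):
    """Simulate 2D sections; returns a list of ``(image, mask)`` pairs.

    Images are float arrays; the mask is the exact circular nucleus.  Before
    noise, rim-band pixels have intensity ``ratio * interior_intensity`` and
    interior pixels ``interior_intensity``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ny, nx = params.section_shape
    yy, xx = np.ogrid[0:ny, 0:nx]
    cy, cx = ny / 2.0, nx / 2.0
    r = np.sqrt(((yy + 0.5) - cy) ** 2 + ((xx + 0.5) - cx) ** 2) * params.pixel_size
    mask = r <= params.nucleus_radius
    rim = mask & (r > params.nucleus_radius - params.rim_width)

    base = np.zeros((ny, nx), dtype=np.float64)
    base[mask] = params.interior_intensity
    base[rim] = params.rim_to_interior_ratio * params.interior_intensity

    out = []
    for _ in range(params.n_nuclei):
        img = base.copy()
        if params.noise_sigma > 0:
            img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
        out.append((img, mask.copy()))
    return out
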