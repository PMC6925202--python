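"""Synthetic scenes with known ground truth for every analysis stage.

Three generators emulate the statistical structure of the real data so the
whole pipeline is testable without microscope data:

* :func:`make_mps_localizations` — SMLM localization tables of a periodic
  ring scaffold (~185–190 nm period) along a straight axon, with labeling
  stochasticity (Poisson labels per ring), isotropic localization noise and
  uniform background.
* :func:`make_braid_image` — replica-EM-style images of regularly spaced
  braid ridges, each braid a pair of filaments with Gaussian cross-section
  whose FWHM equals the apparent width of a platinum-coated filament
  (core diameter + twice the coating thickness).
* :func:`make_correlative_pair` — the same ring geometry expressed both as
  an SMLM table and, through a known affine transform, as an EM braid image,
  plus matched control points.

Every generator is a pure function of its seed: identical parameters give
bit-identical output. Ground truth (ring positions, braid centerlines, true
transform, count bookkeeping) is returned alongside each scene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .correlate import Affine2D, ControlPoints
from .errors import ParameterError
from .geometry import Polyline
from .locio import empty_table
from .morphometry import LineSet
from .render import RenderedImage

__all__ = [
    "BraidSceneParams",
    "GroundTruth",
    "SceneParams",
    "braid_line_sets",
    "make_braid_image",
    "make_correlative_pair",
    "make_mps_localizations",
]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic periodic-scaffold localization scene.

    Defaults describe a proximal-axon scaffold as quantified in practice:
    185 nm ring period with a few nm of ring-to-ring jitter, a ~300 nm wide
    and 4 µm long straight axon, 10 nm localization precision, tens of
    localizations per ring and a light uniform background.
    """

    period: float = 185.0  # nm, ring center-to-center spacing
    period_jitter_sd: float = 5.0  # nm, independent per-ring positional jitter
    axon_length: float = 4000.0  # nm
    axon_width: float = 300.0  # nm
    axis_angle: float = 0.0  # degrees, axon axis vs x-axis
    localization_precision_sd: float = 10.0  # nm, isotropic
    labels_per_ring: float = 50.0  # expected localizations per ring (Poisson)
    background_density: float = 10.0  # localizations per um^2
    photon_mean: float = 5000.0  # photons per localization (log-normal)
    photon_sd: float = 2000.0
    n_frames: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ParameterError("period must be > 0")
        if self.axon_length < 2 * self.period:
            raise ParameterError("axon_length must cover at least two periods")
        if self.localization_precision_sd < 0 or self.period_jitter_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if (self.labels_per_ring < 0 or self.background_density < 0
                or self.photon_mean <= 0 or self.photon_sd < 0):
            raise ParameterError("densities and photon stats must be non-negative")
        if self.axon_width <= 0 or self.n_frames < 1:
            raise ParameterError("axon_width and n_frames must be positive")


@dataclass(frozen=True)
class BraidSceneParams:
    """Parameters of a synthetic replica-EM braid image.

    The apparent width of one platinum-coated filament is
    ``filament_diameter + 2 * coating_thickness`` (11 nm for a 7 nm actin
    filament with 2 nm of platinum); each filament is rendered as a ridge
    with Gaussian cross-section of that FWHM. ``braid_gap`` is the lateral
    center separation of the two intertwined filaments: the 9 nm default
    leaves them merged into one ~18 nm-wide braid ridge, larger values (>=
    ~3x the apparent width) model the split state where each filament is
    measured individually, and 0 superposes them exactly.
    """

    spacing: float = 184.0  # nm, braid center-to-center spacing
    spacing_jitter_sd: float = 0.0  # nm
    filament_diameter: float = 7.0  # nm, actin core
    coating_thickness: float = 2.0  # nm, platinum shell
    braid_gap: float = 9.0  # nm, separation of the two filaments
    pixel_size: float = 2.0  # nm
    image_size: int = 512  # pixels (square)
    noise_sd: float = 0.0  # additive Gaussian intensity noise (ridge peak = 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.pixel_size <= 0:
            raise ParameterError("spacing and pixel_size must be > 0")
        if self.filament_diameter <= 0 or self.coating_thickness < 0:
            raise ParameterError("filament geometry must be positive")
        if self.braid_gap < 0 or self.noise_sd < 0 or self.spacing_jitter_sd < 0:
            raise ParameterError("gap, jitter and noise must be >= 0")
        if self.image_size < 8:
            raise ParameterError("image_size too small")

    @property
    def apparent_filament_width(self) -> float:
        """FWHM of a single coated filament, nm."""
        return self.filament_diameter + 2.0 * self.coating_thickness


@dataclass
class GroundTruth:
    """Generator bookkeeping stored alongside every synthetic scene."""

    ring_positions: Optional[np.ndarray] = None  # nm along the axon axis
    braid_centerlines: Optional[list[Polyline]] = None  # braid centers
    filament_centerlines: Optional[list[Polyline]] = None  # individual filaments
    true_transform: Optional[Affine2D] = None  # correlative scenes only
    ring_label_counts: Optional[np.ndarray] = None  # per-ring Poisson draws
    n_background: Optional[int] = None

    def to_json(self, path: Union[str, Path]) -> Path:
        d: dict = {}
        if self.ring_positions is not None:
            d["ring_positions_nm"] = np.asarray(self.ring_positions).tolist()
        if self.braid_centerlines is not None:
            d["braid_centerlines"] = [p.to_dict() for p in self.braid_centerlines]
        if self.filament_centerlines is not None:
            d["filament_centerlines"] = [
                p.to_dict() for p in self.filament_centerlines
            ]
        if self.true_transform is not None:
            d["true_transform"] = self.true_transform.matrix.tolist()
        if self.ring_label_counts is not None:
            d["ring_label_counts"] = np.asarray(self.ring_label_counts).tolist()
        if self.n_background is not None:
            d["n_background"] = int(self.n_background)
        Path(path).write_text(json.dumps(d, indent=2))
        return Path(path)


def _axis_frame(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    th = np.deg2rad(angle_deg)
    u = np.array([np.cos(th), np.sin(th)])  # along the axon
    n = np.array([-np.sin(th), np.cos(th)])  # across the axon
    return u, n


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def make_mps_localizations(
    params: SceneParams,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a localization table of a periodic ring scaffold.

    Rings are placed at ``k * period`` plus independent Gaussian jitter along
    a straight axon axis at ``axis_angle``. Each ring contributes
    ``Poisson(labels_per_ring)`` localizations spread uniformly across the
    axon width (rings span the full width) and blurred isotropically by the
    localization precision; a uniform Poisson background covers the axon
    footprint. Photon counts are log-normal with the given mean/sd; frames
    are uniform over the acquisition.

    Returns the canonical localization table and a :class:`GroundTruth` with
    the jittered ring positions and count bookkeeping.
    """
    rng = np.random.default_rng(params.seed)
    n_rings = int(np.floor(params.axon_length / params.period)) + 1
    nominal = params.period * np.arange(n_rings)
    ring_positions = nominal + rng.normal(0.0, params.period_jitter_sd, n_rings)

    label_counts = rng.poisson(params.labels_per_ring, n_rings)
    axial = np.repeat(ring_positions, label_counts)
    n_ring_locs = len(axial)
    transverse = rng.uniform(-params.axon_width / 2, params.axon_width / 2,
                             n_ring_locs)

    area_um2 = params.axon_length * params.axon_width / 1e6
    n_bg = int(rng.poisson(params.background_density * area_um2))
    axial = np.concatenate([axial, rng.uniform(0, params.axon_length, n_bg)])
    transverse = np.concatenate([
        transverse,
        rng.uniform(-params.axon_width / 2, params.axon_width / 2, n_bg),
    ])

    n_total = n_ring_locs + n_bg
    if params.localization_precision_sd > 0:
        axial = axial + rng.normal(0, params.localization_precision_sd, n_total)
        transverse = transverse + rng.normal(
            0, params.localization_precision_sd, n_total)

    u, nvec = _axis_frame(params.axis_angle)
    xy = axial[:, None] * u[None, :] + transverse[:, None] * nvec[None, :]

    mu, sigma = _lognormal_params(params.photon_mean, params.photon_sd)
    photons = rng.lognormal(mu, sigma, n_total)
    frames = rng.integers(0, params.n_frames, n_total)

    table = pd.DataFrame({
        "frame": frames.astype(int),
        "x": xy[:, 0],
        "y": xy[:, 1],
        "photons": photons,
        "uncertainty": np.full(n_total, float(params.localization_precision_sd)),
        "channel": "A647",
    })
    if n_total == 0:
        table = empty_table()
    gt = GroundTruth(
        ring_positions=ring_positions,
        ring_label_counts=label_counts,
        n_background=n_bg,
    )
    return table, gt


def _render_ridges(
    centerlines: list[np.ndarray],
    sd: float,
    shape: tuple[int, int],
    pixel_size: float,
    origin: tuple[float, float],
) -> np.ndarray:
    """Sum of Gaussian-cross-section ridges along line segments.

    Each centerline is an ``(m, 2)`` polyline in nm; intensity at a pixel is
    ``exp(-d^2 / (2 sd^2))`` of its distance ``d`` to the nearest point of
    each segment, summed over centerlines (peak 1 per ridge).
    """
    h, w = shape
    xs = origin[0] + pixel_size * np.arange(w)
    ys = origin[1] + pixel_size * np.arange(h)
    gx, gy = np.meshgrid(xs, ys)
    img = np.zeros((h, w))
    for line in centerlines:
        best = np.full((h, w), np.inf)
        for p, q in zip(line[:-1], line[1:]):
            d = q - p
            len2 = float(d @ d)
            t = ((gx - p[0]) * d[0] + (gy - p[1]) * d[1]) / len2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (gx - (p[0] + t * d[0])) ** 2 + (gy - (p[1] + t * d[1])) ** 2
            best = np.minimum(best, dist2)
        img += np.exp(-best / (2.0 * sd**2))
    return img


def make_braid_image(
    params: BraidSceneParams,
) -> tuple[RenderedImage, GroundTruth]:
    """Render a synthetic replica-EM view of regularly spaced braids.

    Braids are vertical ridge pairs at ``k * spacing`` (plus optional
    jitter), centered in the image; each of the two filaments has a Gaussian
    cross-section whose FWHM equals the apparent coated-filament width, and
    the pair is separated laterally by ``braid_gap``. Additive Gaussian
    noise models the replica texture. Ground truth stores the braid and
    individual filament centerlines.

    Raises
    ------
    ParameterError
        If the image cannot contain at least three braids.
    """
    rng = np.random.default_rng(params.seed)
    size_nm = params.image_size * params.pixel_size
    margin = 4.0 * params.apparent_filament_width + params.braid_gap
    n_braids = int(np.floor((size_nm - 2 * margin) / params.spacing)) + 1
    if n_braids < 3:
        raise ParameterError(
            f"image ({size_nm:.0f} nm) too small for 3 braids at "
            f"{params.spacing:.0f} nm spacing"
        )
    span = (n_braids - 1) * params.spacing
    centers = (size_nm - span) / 2 + params.spacing * np.arange(n_braids)
    centers = centers + rng.normal(0, params.spacing_jitter_sd, n_braids)

    sd = params.apparent_filament_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    origin = (0.0, 0.0)
    shape = (params.image_size, params.image_size)

    braid_lines, filament_lines, filament_arrays = [], [], []
    for c in centers:
        braid_lines.append(Polyline(np.array([[c, 0.0], [c, size_nm]])))
        for off in (-params.braid_gap / 2, params.braid_gap / 2):
            arr = np.array([[c + off, 0.0], [c + off, size_nm]])
            filament_arrays.append(arr)
            filament_lines.append(Polyline(arr))

    img = _render_ridges(filament_arrays, sd, shape, params.pixel_size, origin)
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, shape)

    image = RenderedImage(pixels=img, pixel_size=params.pixel_size, origin=origin)
    gt = GroundTruth(
        ring_positions=centers,
        braid_centerlines=braid_lines,
        filament_centerlines=filament_lines,
    )
    return image, gt


def braid_line_sets(
    gt: GroundTruth,
    image: RenderedImage,
    kind: str = "between_braids",
) -> list[LineSet]:
    """Auto-place five-line measurement sets from braid-scene ground truth.

    For ``between_braids``, each consecutive braid pair yields one set of
    five horizontal lines at evenly spaced heights, giving spacing data
    points. Measurement-protocol plumbing for tests and simulations of the
    manual tracing step.
    """
    if gt.braid_centerlines is None:
        raise ParameterError("ground truth carries no braid centerlines")
    if kind != "between_braids":
        raise ParameterError("only between_braids sets are auto-placed")
    _, _, ymin, ymax = image.extent
    heights = np.linspace(ymin + (ymax - ymin) * 0.2,
                          ymin + (ymax - ymin) * 0.8, 5)
    xs = [p.vertices[0, 0] for p in gt.braid_centerlines]
    sets = []
    for x0, x1 in zip(xs[:-1], xs[1:]):
        seg = np.array([[[x0, h], [x1, h]] for h in heights])
        sets.append(LineSet(segments=seg, kind="between_braids"))
    return sets


def make_correlative_pair(
    loc_params: SceneParams,
    braid_params: BraidSceneParams,
    transform: Affine2D,
    n_fiducials: int = 6,
    fiducial_jitter_sd: float = 0.0,
) -> tuple[pd.DataFrame, RenderedImage, ControlPoints, GroundTruth]:
    """Simulate a correlative SMLM / replica-EM experiment.

    The same ring geometry drives both modalities: rings generate the
    localization table in the SMLM frame, and their centerlines — expressed
    through ``transform`` in the EM frame — are rendered as braid ridges.
    Control points are matched fiducial pairs with optional Gaussian jitter
    applied in the EM frame. Ground truth stores the true transform.
    """
    if n_fiducials < 3:
        raise ParameterError("need at least 3 fiducials")
    table, gt = make_mps_localizations(loc_params)

    u, nvec = _axis_frame(loc_params.axis_angle)
    half_w = loc_params.axon_width / 2
    sd = braid_params.apparent_filament_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    filament_arrays_em = []
    braid_lines_em = []
    for pos in gt.ring_positions:
        center = pos * u
        ends = np.array([center - half_w * nvec, center + half_w * nvec])
        braid_lines_em.append(Polyline(transform.apply(ends)))
        for off in (-braid_params.braid_gap / 2, braid_params.braid_gap / 2):
            seg = ends + off * u
            filament_arrays_em.append(transform.apply(seg))

    all_pts = np.concatenate(filament_arrays_em)
    pad = 10.0 * sd
    xmin, ymin = all_pts.min(axis=0) - pad
    xmax, ymax = all_pts.max(axis=0) + pad
    px = braid_params.pixel_size
    shape = (int(np.ceil((ymax - ymin) / px)) + 1,
             int(np.ceil((xmax - xmin) / px)) + 1)
    origin = (xmin, ymin)
    img = _render_ridges(filament_arrays_em, sd, shape, px, origin)
    rng = np.random.default_rng(braid_params.seed + 1)
    if braid_params.noise_sd > 0:
        img = img + rng.normal(0, braid_params.noise_sd, shape)
    em = RenderedImage(pixels=img, pixel_size=px, origin=origin)

    # non-collinear fiducials spread over the axon footprint (SMLM frame)
    for _ in range(100):
        axial = rng.uniform(0, loc_params.axon_length, n_fiducials)
        trans = rng.uniform(-half_w, half_w, n_fiducials)
        src = axial[:, None] * u[None, :] + trans[:, None] * nvec[None, :]
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-6) == 2:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise ParameterError("could not place non-collinear fiducials")
    dst = transform.apply(src)
    if fiducial_jitter_sd > 0:
        dst = dst + rng.normal(0, fiducial_jitter_sd, dst.shape)
    points = ControlPoints(src=src, dst=dst)

    gt.braid_centerlines = braid_lines_em
    gt.true_transform = transform
    return table, em, points, gt
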