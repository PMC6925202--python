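"""Correlative SMLM / platinum-replica EM registration.

The same unroofed axon can be imaged by single-molecule localization
microscopy and then by replica electron microscopy. To read both modalities
in one frame, matched landmark pairs (control points) are used to estimate a
planar affine transform from the SMLM coordinate frame to the EM view, the
localization data are mapped through it, and a two-channel overlay is
rendered on the EM pixel grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateControlPointsError, ParameterError
from .locio import LocalizationTable
from .render import RenderedImage, reconstruct

logger = logging.getLogger(__name__)

__all__ = [
    "Affine2D",
    "ControlPoints",
    "apply_affine",
    "fit_affine",
    "overlay",
]

_DET_TOL = 1e-12


@dataclass(frozen=True)
class Affine2D:
    """6-parameter planar affine map ``p -> A @ p + t`` (nm to nm).

    ``linear`` is the 2x2 linear part, ``translation`` the 2-vector offset.
    The linear part must be invertible; composition and inversion stay within
    the type.
    """

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.linear, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if a.shape != (2, 2) or t.shape != (2,):
            raise ParameterError("affine needs a 2x2 linear part and 2-vector")
        if abs(np.linalg.det(a)) <= _DET_TOL:
            raise ParameterError("affine linear part is singular")
        object.__setattr__(self, "linear", a)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_params(cls, *, rotation_deg: float = 0.0, scale: float = 1.0,
                    shear: float = 0.0, translation=(0.0, 0.0)) -> "Affine2D":
        """Convenience constructor from rotation/scale/shear/translation."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sh = np.array([[1.0, shear], [0.0, 1.0]])
        return cls(scale * rot @ sh, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(n, 2)`` (or ``(2,)``) point array through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.linear.T + self.translation

    def compose(self, other: "Affine2D") -> "Affine2D":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return Affine2D(self.linear @ other.linear,
                        self.linear @ other.translation + self.translation)

    def inverse(self) -> "Affine2D":
        inv = np.linalg.inv(self.linear)
        return Affine2D(inv, -inv @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        """Row-major 2x3 matrix ``[A | t]``."""
        return np.hstack([self.linear, self.translation[:, None]])

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"matrix": self.matrix.tolist()}, indent=2))
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "Affine2D":
        m = np.asarray(json.loads(Path(path).read_text())["matrix"], dtype=float)
        return cls(m[:, :2], m[:, 2])


@dataclass(frozen=True)
class ControlPoints:
    """Matched landmark pairs between the SMLM and EM frames, nm.

    At least three pairs, no duplicated source points, not all collinear.
    """

    src: np.ndarray  # (n, 2) SMLM frame
    dst: np.ndarray  # (n, 2) EM frame

    def __post_init__(self) -> None:
        s = np.asarray(self.src, dtype=float)
        d = np.asarray(self.dst, dtype=float)
        if s.ndim != 2 or s.shape[1] != 2 or s.shape != d.shape:
            raise ParameterError("control points need matching (n, 2) arrays")
        if len(s) < 3:
            raise DegenerateControlPointsError("need at least 3 control points")
        if len(np.unique(s, axis=0)) != len(s):
            raise DegenerateControlPointsError("duplicated source points")
        centered = s - s.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(s).max())) < 2:
            raise DegenerateControlPointsError("control points are collinear")
        object.__setattr__(self, "src", s)
        object.__setattr__(self, "dst", d)

    def __len__(self) -> int:
        return len(self.src)

    def to_csv(self, path: Union[str, Path]) -> Path:
        df = pd.DataFrame({
            "x_smlm": self.src[:, 0], "y_smlm": self.src[:, 1],
            "x_em": self.dst[:, 0], "y_em": self.dst[:, 1],
        })
        df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ControlPoints":
        df = pd.read_csv(path)
        return cls(src=df[["x_smlm", "y_smlm"]].to_numpy(float),
                   dst=df[["x_em", "y_em"]].to_numpy(float))


def fit_affine(
    points: ControlPoints, model: str = "affine"
) -> tuple[Affine2D, float]:
    """Least-squares transform from matched control points.

    ``model="affine"`` fits the full 6-parameter transform by linear least
    squares; ``model="similarity"`` constrains it to
    rotation + isotropic scale + translation (useful at low point counts).

    Returns
    -------
    (transform, rms_error)
        The fitted map and the root-mean-square residual in the target (EM)
        frame, nm.
    """
    src, dst = points.src, points.dst
    if model == "affine":
        design = np.hstack([src, np.ones((len(src), 1))])
        if np.linalg.matrix_rank(design) < 3:
            raise DegenerateControlPointsError("rank-deficient control points")
        sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
        transform = Affine2D(sol[:2].T, sol[2])
    elif model == "similarity":
        sc, dc = src.mean(axis=0), dst.mean(axis=0)
        s0, d0 = src - sc, dst - dc
        u, sv, vt = np.linalg.svd(d0.T @ s0)
        sgn = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, sgn]) @ vt
        scale = (sv[0] + sgn * sv[1]) / np.sum(s0**2)
        transform = Affine2D(scale * rot, dc - scale * rot @ sc)
    else:
        raise ParameterError(f"unknown model {model!r}")

    residuals = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    logger.info("fit_affine (%s, n=%d): rms residual %.2f nm",
                model, len(points), rms)
    return transform, rms


def apply_affine(t: Affine2D, table: LocalizationTable) -> LocalizationTable:
    """Map the x/y coordinates of a localization table; other fields kept."""
    out = table.copy()
    xy = t.apply(out[["x", "y"]].to_numpy(dtype=float))
    out["x"], out["y"] = xy[:, 0], xy[:, 1]
    return out


def overlay(
    em: RenderedImage,
    smlm: Union[RenderedImage, LocalizationTable],
    t: Affine2D,
) -> RenderedImage:
    """Render a two-channel EM-frame overlay of EM and registered SMLM data.

    Channel 0 is the EM view; channel 1 is the SMLM content resampled onto
    the EM pixel grid through ``t``. An SMLM *image* is pulled back with
    bilinear interpolation; a localization *table* is transformed exactly and
    re-rendered as a histogram on the EM grid (no double interpolation).
    EM pixels outside the transformed SMLM footprint carry channel-1 = 0.

    Raises
    ------
    ParameterError
        When the transformed SMLM footprint does not intersect the EM bounds.
    """
    if em.pixels.ndim != 2:
        raise ParameterError("EM image must be single-channel")
    exmin, exmax, eymin, eymax = em.extent

    if isinstance(smlm, RenderedImage):
        sxmin, sxmax, symin, symax = smlm.extent
        corners = np.array([[sxmin, symin], [sxmax, symin],
                            [sxmin, symax], [sxmax, symax]])
        tc = t.apply(corners)
        if (tc[:, 0].max() < exmin or tc[:, 0].min() > exmax
                or tc[:, 1].max() < eymin or tc[:, 1].min() > eymax):
            raise ParameterError("transformed SMLM footprint misses the EM view")
        h, w = em.shape
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        em_xy = em.pixel_to_phys(np.stack([rows, cols], axis=-1))
        src_xy = t.inverse().apply(em_xy.reshape(-1, 2))
        rc = smlm.phys_to_pixel(src_xy)
        ch2 = ndimage.map_coordinates(
            smlm.pixels.astype(float), [rc[:, 0], rc[:, 1]],
            order=1, mode="constant", cval=0.0,
        ).reshape(h, w)
    else:
        moved = apply_affine(t, smlm)
        x = moved["x"].to_numpy(float)
        y = moved["y"].to_numpy(float)
        inside = (x >= exmin) & (x <= exmax) & (y >= eymin) & (y <= eymax)
        if len(x) and not inside.any():
            raise ParameterError("transformed localizations miss the EM view")
        ch2 = reconstruct(
            moved, pixel_size=em.pixel_size, mode="histogram",
            bounds=((exmin, exmax - em.pixel_size), (eymin, eymax - em.pixel_size)),
        ).pixels
        ch2 = ch2[: em.shape[0], : em.shape[1]]
        padded = np.zeros(em.shape)
        padded[: ch2.shape[0], : ch2.shape[1]] = ch2
        ch2 = padded

    stack = np.stack([em.pixels.astype(float), ch2])
    return RenderedImage(pixels=stack, pixel_size=em.pixel_size, origin=em.origin)
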