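"""Planar geometry primitives shared across modules.

Coordinate convention (used everywhere in the package): physical nanometres,
origin at the top-left pixel *center* of an image, x increasing rightward and
y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["Polyline"]


@dataclass(frozen=True)
class Polyline:
    """Ordered vertex list in physical (nm) coordinates.

    Used both for manually traced axon paths and for measurement lines.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of ``(x, y)`` positions in nm, ``n >= 2``.
    band_width
        Averaging width perpendicular to the path, in nm, used when the
        polyline serves as a profile-extraction trace. 0 means a single
        sample line.
    """

    vertices: np.ndarray
    band_width: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ParameterError("polyline needs an (n>=2, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ParameterError("polyline vertices must be finite")
        seg = np.diff(v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ParameterError("consecutive polyline vertices must be distinct")
        if self.band_width < 0:
            raise ParameterError("band_width must be >= 0")
        object.__setattr__(self, "vertices", v)

    @property
    def segment_lengths(self) -> np.ndarray:
        seg = np.diff(self.vertices, axis=0)
        return np.hypot(seg[:, 0], seg[:, 1])

    @property
    def length(self) -> float:
        """Total arc length in nm."""
        return float(self.segment_lengths.sum())

    def resample(self, step: float) -> tuple[np.ndarray, np.ndarray]:
        """Resample at uniform arc-length ``step``.

        Returns
        -------
        points : (m, 2) array
            Positions along the path, starting at the first vertex.
        tangents : (m, 2) array
            Unit tangent of the segment each sample falls on.
        """
        if step <= 0:
            raise ParameterError("resampling step must be > 0")
        v = self.vertices
        seglen = self.segment_lengths
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = np.arange(0.0, cum[-1] + step / 2, step)
        s = s[s <= cum[-1] + 1e-9]
        x = np.interp(s, cum, v[:, 0])
        y = np.interp(s, cum, v[:, 1])
        # segment index of each sample (last sample belongs to last segment)
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
        tan = np.diff(v, axis=0) / seglen[:, None]
        return np.column_stack([x, y]), tan[idx]

    def to_dict(self) -> dict:
        return {
            "vertices_nm": self.vertices.tolist(),
            "band_width_nm": float(self.band_width),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Polyline":
        return cls(
            vertices=np.asarray(d["vertices_nm"], dtype=float),
            band_width=float(d.get("band_width_nm", 0.0)),
        )
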