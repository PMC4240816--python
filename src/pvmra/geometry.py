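"""Planar contour primitives shared by the phantom generator and the sharpness metric.

A vessel cross-section is delimited by a pair of closed polylines (inner and
outer contour) drawn in one slice plane of the volume. Coordinates are in
millimetres in the plane's two in-plane axes, ordered by ascending axis index.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = ["PlaneRef", "ContourPair", "contours_to_json", "contours_from_json"]


@dataclasses.dataclass(frozen=True)
class PlaneRef:
    """A single slice plane: ``axis`` is the axis held fixed at ``index``."""

    axis: int
    index: int

    @property
    def inplane_axes(self) -> tuple[int, int]:
        return tuple(a for a in range(3) if a != self.axis)  # type: ignore[return-value]


def _point_in_polygon(pt: np.ndarray, poly: np.ndarray) -> bool:
    """Even-odd crossing test; vertices (N, 2), closed implicitly."""
    x, y = pt
    inside = False
    px, py = poly[:, 0], poly[:, 1]
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    for ax, ay, bx, by in zip(px, py, qx, qy):
        if (ay > y) != (by > y):
            xcross = ax + (y - ay) / (by - ay) * (bx - ax)
            if x < xcross:
                inside = not inside
    return inside


@dataclasses.dataclass
class ContourPair:
    """Inner and outer closed polylines (mm) bracketing one vessel edge.

    The inner contour lies in the bright lumen, the outer contour in the dark
    background, so a segment joining them crosses the vessel border.
    """

    name: str
    inner: np.ndarray  # (Ni, 2) mm
    outer: np.ndarray  # (No, 2) mm
    plane: PlaneRef

    def __post_init__(self) -> None:
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        for which, poly in (("inner", self.inner), ("outer", self.outer)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(
                    f"contour '{self.name}': {which} polyline needs >= 3 vertices of 2 coords"
                )
        if not _point_in_polygon(self.inner.mean(axis=0), self.outer):
            raise ValueError(f"contour '{self.name}': inner contour not inside outer contour")


def contours_to_json(pairs: list[ContourPair], path: str | Path) -> None:
    payload = {
        "vessels": [
            {
                "name": p.name,
                "plane": {"axis": p.plane.axis, "index": p.plane.index},
                "inner_mm": p.inner.tolist(),
                "outer_mm": p.outer.tolist(),
            }
            for p in pairs
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def contours_from_json(path: str | Path) -> list[ContourPair]:
    payload = json.loads(Path(path).read_text())
    return [
        ContourPair(
            name=v["name"],
            inner=np.asarray(v["inner_mm"], dtype=float),
            outer=np.asarray(v["outer_mm"], dtype=float),
            plane=PlaneRef(axis=int(v["plane"]["axis"]), index=int(v["plane"]["index"])),
        )
        for v in payload["vessels"]
    ]
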