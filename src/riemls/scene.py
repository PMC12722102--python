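"""Drawable scene produced by turtle interpretation, plus text-format writers.

A :class:`Scene` is an ordered list of primitives (polylines, arrows, points,
filled uv polygons), each carrying parameter-space samples, 3-D samples when
the space is embedded, and pen state.  Writers emit OBJ (``l`` line
elements), ASCII PLY (edge lists), CSV trajectories and a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = ["SceneItem", "Scene"]


@dataclass
class SceneItem:
    kind: str  # polyline | arrow | point | polygon
    uv: Optional[np.ndarray] = None  # (n, 2)
    xyz: Optional[np.ndarray] = None  # (n, 3)
    width: float = 1.0
    color: int = 0
    depth: int = 0  # branch depth


class Scene:
    """Ordered collection of drawable primitives."""

    def __init__(self):
        self.items: List[SceneItem] = []

    def add(self, item: SceneItem):
        if item.kind in ("polyline", "polygon"):
            n = len(item.uv) if item.uv is not None else len(item.xyz)
            if n < 2:
                raise ValueError("polyline needs at least 2 points")
        if item.uv is not None and item.xyz is not None:
            if len(item.uv) != len(item.xyz):
                raise ValueError("uv and 3-D sample counts must match")
        self.items.append(item)
        return item

    def polylines(self):
        return [it for it in self.items if it.kind == "polyline"]

    def arrows(self):
        return [it for it in self.items if it.kind == "arrow"]

    def vertices3d(self) -> np.ndarray:
        """All 3-D polyline vertices in drawing order (for regression tests)."""
        chunks = [
            it.xyz for it in self.items if it.kind == "polyline" and it.xyz is not None
        ]
        return np.concatenate(chunks) if chunks else np.empty((0, 3))

    # -- writers -------------------------------------------------------------

    def _coords(self, item: SceneItem) -> np.ndarray:
        if item.xyz is not None:
            return np.asarray(item.xyz)
        uv = np.asarray(item.uv)
        return np.column_stack([uv, np.zeros(len(uv))])

    def to_obj(self, fh):
        """Wavefront OBJ: polylines/arrows as line elements, points as p."""
        close = False
        if isinstance(fh, str):
            fh, close = open(fh, "w"), True
        try:
            fh.write("# riemls scene\n")
            offset = 1
            for item in self.items:
                pts = self._coords(item)
                if item.kind == "arrow":
                    fh.write("# arrow\n")
                for p in pts:
                    fh.write(f"v {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
                n = len(pts)
                if item.kind in ("polyline", "arrow", "polygon") and n >= 2:
                    idx = " ".join(str(offset + i) for i in range(n))
                    fh.write(f"l {idx}\n")
                elif item.kind == "point":
                    fh.write(f"p {offset}\n")
                offset += n
        finally:
            if close:
                fh.close()

    def to_ply(self, fh):
        """ASCII PLY with vertex and edge elements."""
        close = False
        if isinstance(fh, str):
            fh, close = open(fh, "w"), True
        try:
            verts, edges = [], []
            for item in self.items:
                pts = self._coords(item)
                base = len(verts)
                verts.extend(pts)
                if item.kind in ("polyline", "arrow", "polygon"):
                    for i in range(len(pts) - 1):
                        edges.append((base + i, base + i + 1))
            fh.write(
                "ply\nformat ascii 1.0\ncomment riemls scene\n"
                f"element vertex {len(verts)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                f"element edge {len(edges)}\n"
                "property int vertex1\nproperty int vertex2\nend_header\n"
            )
            for p in verts:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            for a, b in edges:
                fh.write(f"{a} {b}\n")
        finally:
            if close:
                fh.close()

    def to_csv(self, fh):
        """Flat CSV: item, kind, vertex, p, q, x, y, z (blanks when absent)."""
        close = False
        if isinstance(fh, str):
            fh, close = open(fh, "w"), True
        try:
            fh.write("item,kind,vertex,p,q,x,y,z\n")
            for i, item in enumerate(self.items):
                n = len(item.uv) if item.uv is not None else len(item.xyz)
                for j in range(n):
                    pq = (
                        f"{item.uv[j][0]:.12g},{item.uv[j][1]:.12g}"
                        if item.uv is not None
                        else ","
                    )
                    xyz = (
                        f"{item.xyz[j][0]:.12g},{item.xyz[j][1]:.12g},{item.xyz[j][2]:.12g}"
                        if item.xyz is not None
                        else ",,"
                    )
                    fh.write(f"{i},{item.kind},{j},{pq},{xyz}\n")
        finally:
            if close:
                fh.close()

    def checksum(self) -> str:
        """SHA-256 of the rounded geometry (order-sensitive)."""
        h = hashlib.sha256()
        for item in self.items:
            h.update(item.kind.encode())
            for arr in (item.uv, item.xyz):
                if arr is not None:
                    h.update(np.round(np.asarray(arr), 9).tobytes())
        return h.hexdigest()

    def manifest(self, config: Optional[dict] = None) -> dict:
        return {
            "n_items": len(self.items),
            "kinds": sorted({it.kind for it in self.items}),
            "checksum": self.checksum(),
            "config": config or {},
        }

    def write_manifest(self, fh, config: Optional[dict] = None):
        close = False
        if isinstance(fh, str):
            fh, close = open(fh, "w"), True
        try:
            json.dump(self.manifest(config), fh, indent=2, sort_keys=True)
            fh.write("\n")
        finally:
            if close:
                fh.close()
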