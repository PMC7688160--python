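"""Leaflet region-of-interest polygons.

The valve-leaflet boundary is always a manually defined (or synthetic)
closed simple polygon in pixel coordinates; quantification restricts to
pixels whose centers fall inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as _draw_polygon

__all__ = ["LeafletROI"]


@dataclass(frozen=True)
class LeafletROI:
    """Closed simple polygon delimiting the valve leaflet.

    Vertices are (x, y) pixel coordinates, 0-based, with x the column and
    y the row of the image array.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=np.float64)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("ROI needs an (N, 2) array of at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_simple:
            raise ValueError("ROI polygon is self-intersecting")
        if poly.area <= 0:
            raise ValueError("ROI polygon has zero area")
        object.__setattr__(self, "vertices", verts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels inside the polygon for an image of `shape`."""
        if self.vertices[:, 0].max() >= shape[1] or self.vertices[:, 1].max() >= shape[0]:
            raise ValueError("ROI vertices fall outside the image bounds")
        rr, cc = _draw_polygon(self.vertices[:, 1], self.vertices[:, 0], shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float) -> "LeafletROI":
        return cls(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LeafletROI":
        """Load vertices from a two-column x,y CSV (header optional)."""
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        cols = [c.lower().strip() for c in df.columns]
        if "x" in cols and "y" in cols:
            verts = df[[df.columns[cols.index("x")], df.columns[cols.index("y")]]].to_numpy()
        else:  # headerless file: first row was data
            df = pd.read_csv(path, header=None, comment="#")
            verts = df.iloc[:, :2].to_numpy()
        return cls(verts)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.vertices, columns=["x", "y"]).to_csv(path, index=False)
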