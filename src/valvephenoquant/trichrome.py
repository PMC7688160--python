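"""Colorimetric segmentation of Masson's-trichrome sections and leaflet
morphometrics.

Pixels inside the leaflet ROI are classified into stain constituents by
closed rectangular windows in HSL space (hue may wrap through 0 deg);
pixels matching no window are background. Constituent area fractions are
positive pixels over non-background leaflet pixels. Mean leaflet
thickness is leaflet area divided by cusp length, the cusp length taken
as the longest geodesic path through the mask's skeleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label as _cc_label
from skimage.morphology import skeletonize
from scipy.ndimage import distance_transform_edt

from .color import rgb_to_hsl
from .roi import LeafletROI

__all__ = [
    "HslWindow",
    "CompositionResult",
    "DEFAULT_WINDOWS",
    "load_windows",
    "validate_windows",
    "classify_pixels",
    "area_fractions",
    "leaflet_thickness",
    "LABEL_OUTSIDE",
    "LABEL_BACKGROUND",
]

log = logging.getLogger(__name__)

LABEL_OUTSIDE = -1
LABEL_BACKGROUND = 0


@dataclass(frozen=True)
class HslWindow:
    """A stain class as a closed box in HSL space.

    `hue` is an inclusive interval in degrees; hue_lo > hue_hi means the
    interval wraps through 360->0 (e.g. the red window 250-25 deg).
    """

    name: str
    hue: tuple[float, float]
    saturation: tuple[float, float] = (0.0, 1.0)
    lightness: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for iv in (self.saturation, self.lightness):
            if not (0.0 <= iv[0] <= iv[1] <= 1.0):
                raise ValueError(f"{self.name}: S/L interval {iv} not within [0,1]")
        if not (0.0 <= self.hue[0] < 360.0 and 0.0 <= self.hue[1] < 360.0):
            raise ValueError(f"{self.name}: hue bounds must lie in [0,360)")

    @property
    def wraps(self) -> bool:
        return self.hue[0] > self.hue[1]

    def contains(self, h: np.ndarray, s: np.ndarray, l: np.ndarray) -> np.ndarray:
        """Vectorised membership test (closed intervals)."""
        h = np.mod(h, 360.0)
        if self.wraps:
            in_h = (h >= self.hue[0]) | (h <= self.hue[1])
        else:
            in_h = (h >= self.hue[0]) & (h <= self.hue[1])
        return (
            in_h
            & (s >= self.saturation[0]) & (s <= self.saturation[1])
            & (l >= self.lightness[0]) & (l <= self.lightness[1])
        )

    def shrunk(self, dh: float, ds: float, dl: float) -> "HslWindow":
        """Window shrunk inward by the given margins (used when painting
        synthetic pixels so quantisation cannot push them outside)."""
        lo, hi = self.hue
        span = (hi - lo) % 360.0 or 360.0
        if span <= 2 * dh:
            raise ValueError(f"{self.name}: hue margin {dh} empties the window")
        s = (self.saturation[0] + ds, self.saturation[1] - ds)
        l = (self.lightness[0] + dl, self.lightness[1] - dl)
        if s[0] >= s[1] or l[0] >= l[1]:
            raise ValueError(f"{self.name}: S/L margin empties the window")
        return HslWindow(self.name, ((lo + dh) % 360.0, (hi - dh) % 360.0), s, l)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform HSL samples inside the window, shape (n, 3)."""
        lo, hi = self.hue
        span = (hi - lo) % 360.0 or 360.0
        h = np.mod(lo + rng.uniform(0.0, span, n), 360.0)
        s = rng.uniform(*self.saturation, n)
        l = rng.uniform(*self.lightness, n)
        return np.stack([h, s, l], axis=-1)


#: The study's published stain windows: collagen stains blue, cytoplasm
#: and myocardium stain red (hue wrapping through 0 deg).
DEFAULT_WINDOWS = (
    HslWindow("collagen", hue=(150.0, 250.0), saturation=(0.1, 1.0), lightness=(0.1, 0.93)),
    HslWindow("cytoplasm", hue=(250.0, 25.0), saturation=(0.1, 1.0), lightness=(0.1, 0.93)),
)


def _hue_set(win: HslWindow) -> list[tuple[float, float]]:
    if win.wraps:
        return [(win.hue[0], 360.0), (0.0, win.hue[1])]
    return [win.hue]


def validate_windows(windows: list[HslWindow] | tuple[HslWindow, ...]) -> None:
    """Reject windows whose interiors overlap in HSL space.

    Shared boundaries (e.g. both study windows meeting at H=250) are
    allowed; boundary pixels go to the first matching window.
    """
    names = [w.name for w in windows]
    if len(set(names)) != len(names):
        raise ValueError("duplicate window names")
    for i, a in enumerate(windows):
        for b in windows[i + 1 :]:
            hue_overlap = any(
                min(ah, bh) - max(al, bl) > 0
                for al, ah in _hue_set(a)
                for bl, bh in _hue_set(b)
            )
            s_overlap = min(a.saturation[1], b.saturation[1]) > max(a.saturation[0], b.saturation[0])
            l_overlap = min(a.lightness[1], b.lightness[1]) > max(a.lightness[0], b.lightness[0])
            if hue_overlap and s_overlap and l_overlap:
                raise ValueError(f"windows {a.name!r} and {b.name!r} overlap in HSL space")


def load_windows(path: str | Path) -> list[HslWindow]:
    """Load stain windows from YAML: a list of {name, hue, saturation, lightness}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    windows = [
        HslWindow(
            entry["name"],
            tuple(entry["hue"]),
            tuple(entry.get("saturation", (0.0, 1.0))),
            tuple(entry.get("lightness", (0.0, 1.0))),
        )
        for entry in raw
    ]
    validate_windows(windows)
    return windows


def classify_pixels(
    hsl_image: np.ndarray,
    windows: list[HslWindow] | tuple[HslWindow, ...] = DEFAULT_WINDOWS,
    roi: LeafletROI | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Label every pixel: -1 outside the ROI, 0 background (no window
    matched), 1..k the stain classes in `windows` order.

    Returns (label image, class-name list aligned with labels 1..k).
    """
    validate_windows(windows)
    h, s, l = hsl_image[..., 0], hsl_image[..., 1], hsl_image[..., 2]
    labels = np.full(h.shape, LABEL_BACKGROUND, dtype=np.int16)
    unassigned = np.ones(h.shape, dtype=bool)
    for k, win in enumerate(windows, start=1):
        hit = win.contains(h, s, l) & unassigned
        labels[hit] = k
        unassigned &= ~hit
    if roi is not None:
        labels[~roi.mask(h.shape)] = LABEL_OUTSIDE
    return labels, [w.name for w in windows]


@dataclass(frozen=True)
class CompositionResult:
    """Per-class stain area fractions within the leaflet.

    Fractions are positive pixels over non-background leaflet pixels and
    sum to 1 across classes; `background_fraction` is relative to all
    leaflet pixels. `thickness` is filled by `leaflet_thickness`.
    """

    fractions: dict[str, float]
    background_fraction: float
    leaflet_area_px: int
    thickness_px: float | None = None

    def __post_init__(self) -> None:
        vals = list(self.fractions.values())
        if vals and abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1 over non-background pixels")
        if any(not 0 <= f <= 1 for f in vals + [self.background_fraction]):
            raise ValueError("fractions must lie in [0, 1]")


def area_fractions(labels: np.ndarray, class_names: list[str]) -> CompositionResult:
    """Constituent fractions: count(class c) / count(non-background ROI pixels)."""
    inside = labels != LABEL_OUTSIDE
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("ROI contains no pixels")
    n_bg = int((labels == LABEL_BACKGROUND).sum())
    n_fg = n_inside - n_bg
    if n_fg == 0:
        raise ValueError("leaflet is entirely background; fractions undefined")
    fractions = {
        name: int((labels == k).sum()) / n_fg
        for k, name in enumerate(class_names, start=1)
    }
    return CompositionResult(fractions, n_bg / n_inside, n_inside)


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Pixel chain ((N,2) row/col) of the longest geodesic through a skeleton."""
    rr, cc = np.nonzero(skel)
    n = len(rr)
    if n == 0:
        return np.empty((0, 2))
    if n == 1:
        return np.array([[rr[0], cc[0]]], dtype=float)
    index = {(r, c): i for i, (r, c) in enumerate(zip(rr, cc))}
    rows, cols, data = [], [], []
    for i, (r, c) in enumerate(zip(rr, cc)):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    data.append(np.hypot(dr, dc))
    from scipy.sparse import csr_matrix

    graph = csr_matrix((data, (rows, cols)), shape=(n, n))
    # double sweep: farthest node from an arbitrary start, then farthest from it
    d0 = dijkstra(graph, indices=0)
    far = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    d1, pred = dijkstra(graph, indices=far, return_predecessors=True)
    d1[np.isinf(d1)] = 0.0
    end = int(np.argmax(d1))
    chain = [end]
    while pred[chain[-1]] >= 0:
        chain.append(int(pred[chain[-1]]))
    chain = chain[::-1]
    return np.stack([rr[chain], cc[chain]], axis=-1).astype(float)


def cusp_length(mask: np.ndarray, path: np.ndarray | None = None) -> float:
    """Length along the cusp (px) of a leaflet mask.

    The longest geodesic path through the mask skeleton is measured as a
    coarse polyline (subsampled every 5 px, which removes rasterisation
    zigzag) and extended at both ends by the local half-width, since the
    skeleton stops about half a thickness short of the leaflet tips. A
    user-supplied centerline `path` ((N,2) row/col) overrides the skeleton.
    """
    mask = np.asarray(mask).astype(bool)
    if path is None:
        path = _longest_skeleton_path(skeletonize(mask))
    if len(path) == 0:
        raise ValueError("skeleton has zero length")
    step = 5
    nodes = np.vstack([path[::step], path[-1:]]) if len(path) > 1 else path
    length = float(np.sum(np.linalg.norm(np.diff(nodes, axis=0), axis=1)))
    dt = distance_transform_edt(mask)
    for end in (path[0], path[-1]):
        length += float(dt[int(end[0]), int(end[1])])
    return length


def leaflet_thickness(mask: np.ndarray, path: np.ndarray | None = None) -> float:
    """Mean leaflet thickness in pixels: mask area / length along the cusp.

    A disconnected mask is reduced to its largest component with a warning.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty leaflet mask")
    cc = _cc_label(mask, connectivity=2)
    if cc.max() > 1:
        log.warning("leaflet mask has %d components; using the largest", cc.max())
        sizes = np.bincount(cc.ravel())[1:]
        mask = cc == (int(np.argmax(sizes)) + 1)
    area = float(mask.sum())
    length = cusp_length(mask, path=path)
    if length <= 0:
        raise ValueError("skeleton has zero length")
    return area / length
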