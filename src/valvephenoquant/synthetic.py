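"""Synthetic inputs with known ground truth for every pipeline stage.

No imaging or qPCR data accompany the study, so each input kind —
Doppler velocity envelopes, trichrome-stained leaflet images,
two-channel fluorescence fields, and Cq tables — is emulated with an
explicit noise model and a ground-truth record, making every downstream
computation testable by parameter recovery. All randomness flows from
one integer seed per generator call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

from .color import hsl_to_rgb
from .doppler import VelocityTrace
from .roi import LeafletROI
from .trichrome import DEFAULT_WINDOWS, HslWindow, LABEL_BACKGROUND, LABEL_OUTSIDE

__all__ = [
    "DopplerGroundTruth",
    "TrichromeGroundTruth",
    "FluorescenceGroundTruth",
    "CtGroup",
    "CtGroundTruth",
    "TrichromeSample",
    "FluorescenceSample",
    "simulate_doppler",
    "simulate_trichrome",
    "simulate_fluorescence",
    "simulate_ct_table",
    "default_leaflet_polygon",
]


# ---------------------------------------------------------------------------
# Doppler


@dataclass(frozen=True)
class DopplerGroundTruth:
    """Parameters of a synthetic aortic-jet envelope.

    The ejection waveform within each cycle is v(t) = Vpeak sin^2(pi t/T_ej)
    over the ejection window and 0 in diastole; its analytic mean of
    4 v^2 (v in m/s) over the ejection window is 1.5 Vpeak^2 (the mean of
    sin^4 over a half period is 3/8). Defaults follow the study's imaging
    conditions: heart rate 465 beats/min under light anaesthesia.
    """

    peak_velocity: float = 1200.0  # mm/s
    heart_rate: float = 465.0  # beats/min
    ejection_fraction_of_cycle: float = 0.32
    n_cycles: int = 100
    noise_sd: float = 0.0  # mm/s, additive Gaussian truncated at 0
    sampling_rate: float = 8000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be positive")
        if not 0.0 < self.ejection_fraction_of_cycle < 1.0:
            raise ValueError("ejection_fraction_of_cycle must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def ejection_duration(self) -> float:
        return self.ejection_fraction_of_cycle * self.cycle_duration

    @property
    def mean_gradient_mmhg(self) -> float:
        """Closed-form mean gradient over the ejection window (mmHg)."""
        return 1.5 * (self.peak_velocity / 1000.0) ** 2


def simulate_doppler(gt: DopplerGroundTruth) -> VelocityTrace:
    """Uniformly sampled velocity envelope with one R-peak per cycle start."""
    rng = np.random.default_rng(gt.seed)
    dt = 1.0 / gt.sampling_rate
    total = gt.n_cycles * gt.cycle_duration
    n_samples = int(round(total / dt)) + 1
    t = np.arange(n_samples) * dt
    phase = np.mod(t, gt.cycle_duration)
    v = np.where(
        phase < gt.ejection_duration,
        gt.peak_velocity * np.sin(np.pi * phase / gt.ejection_duration) ** 2,
        0.0,
    )
    if gt.noise_sd > 0:
        v = np.maximum(v + rng.normal(0.0, gt.noise_sd, n_samples), 0.0)
    r_peaks = np.arange(gt.n_cycles) * gt.cycle_duration
    return VelocityTrace(t, v, r_peaks)


# ---------------------------------------------------------------------------
# trichrome histology


def default_leaflet_polygon(shape: tuple[int, int] = (192, 256)) -> LeafletROI:
    """An elongated leaflet-like hexagon filling most of the image."""
    h, w = shape
    return LeafletROI(
        np.array(
            [
                [0.10 * w, 0.45 * h],
                [0.35 * w, 0.20 * h],
                [0.75 * w, 0.25 * h],
                [0.90 * w, 0.55 * h],
                [0.60 * w, 0.80 * h],
                [0.25 * w, 0.75 * h],
            ]
        )
    )


@dataclass(frozen=True)
class TrichromeGroundTruth:
    """Painted composition of a synthetic trichrome-stained leaflet.

    Every painted pixel's HSL value is drawn uniformly inside its class
    window shrunk by `hsl_jitter` (degrees, sat, light margins), so 8-bit
    quantisation cannot push it across a window boundary.
    """

    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"collagen": 0.3, "cytoplasm": 0.7}
    )
    background_fraction: float = 0.1
    hsl_jitter: tuple[float, float, float] = (10.0, 0.08, 0.03)
    image_shape: tuple[int, int] = (192, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1 over non-background classes")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class TrichromeSample:
    image: np.ndarray  # uint8 RGB
    roi: LeafletROI
    truth_labels: np.ndarray  # -1 outside, 0 background, 1..k classes
    class_names: list[str]


def simulate_trichrome(
    gt: TrichromeGroundTruth,
    windows: tuple[HslWindow, ...] = DEFAULT_WINDOWS,
    roi: LeafletROI | None = None,
) -> TrichromeSample:
    """Paint a leaflet with exact per-class pixel counts.

    Non-background leaflet pixel counts match `class_fractions` to within
    one pixel (largest-remainder rounding); background pixels inside the
    leaflet are near-white (L > 0.96); pixels outside the leaflet are
    pure white.
    """
    rng = np.random.default_rng(gt.seed)
    by_name = {w.name: w for w in windows}
    missing = [n for n in gt.class_fractions if n not in by_name]
    if missing:
        raise ValueError(f"no HSL window for classes {missing}")
    shrunk = {n: by_name[n].shrunk(*gt.hsl_jitter) for n in gt.class_fractions}
    # truth labels follow window order so they compare directly with the
    # label image classify_pixels produces
    label_of = {w.name: k for k, w in enumerate(windows, start=1)}

    roi = roi or default_leaflet_polygon(gt.image_shape)
    mask = roi.mask(gt.image_shape)
    idx = np.flatnonzero(mask.ravel())
    rng.shuffle(idx)
    n_inside = len(idx)
    n_bg = int(round(gt.background_fraction * n_inside))
    n_fg = n_inside - n_bg

    names = list(gt.class_fractions)
    quotas = np.array([gt.class_fractions[n] * n_fg for n in names])
    counts = np.floor(quotas).astype(int)
    remainder = n_fg - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:remainder]] += 1

    hsl = np.zeros(gt.image_shape + (3,), dtype=np.float64)
    hsl[..., 2] = 1.0  # white outside leaflet
    labels = np.full(gt.image_shape, LABEL_OUTSIDE, dtype=np.int16)
    flat_labels = labels.ravel()

    pos = 0
    for i, name in enumerate(names):
        take = idx[pos : pos + counts[i]]
        pos += counts[i]
        hsl.reshape(-1, 3)[take] = shrunk[name].sample(rng, len(take))
        flat_labels[take] = label_of[name]
    bg_take = idx[pos:]
    hsl.reshape(-1, 3)[bg_take] = np.stack(
        [
            rng.uniform(0.0, 360.0, len(bg_take)),
            rng.uniform(0.0, 0.04, len(bg_take)),
            rng.uniform(0.965, 0.995, len(bg_take)),
        ],
        axis=-1,
    )
    flat_labels[bg_take] = LABEL_BACKGROUND

    image = np.round(hsl_to_rgb(hsl) * 255.0).astype(np.uint8)
    return TrichromeSample(image, roi, labels, [w.name for w in windows])


# ---------------------------------------------------------------------------
# fluorescence


@dataclass(frozen=True)
class FluorescenceGroundTruth:
    """A synthetic DAPI + marker field inside a leaflet ROI.

    `n_touching_pairs` of the nuclei are laid down as overlapping ellipse
    pairs whose union shows the two concave junction points the clump
    splitter targets; the rest are isolated. Marker coverage per nucleus
    is exact by construction (a half-plane cut through the nucleus pixel
    set at the requested area fraction).
    """

    n_nuclei: int = 100
    n_touching_pairs: int = 10
    nucleus_axes: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 8.0), (3.5, 5.5))
    marker_coverage_per_nucleus: tuple[float, ...] | float = 0.0
    diffuse_marker_fraction: float = 0.0
    psf_sigma: float = 1.0  # optical blur applied to the DAPI channel
    marker_psf_sigma: float = 0.0  # marker rendered sharp unless set
    noise_sd: float = 0.0  # 16-bit intensity units
    image_shape: tuple[int, int] = (384, 384)
    nucleus_intensity: float = 30000.0
    marker_intensity: float = 25000.0
    #: tissue autofluorescence inside the leaflet; sits between the dim
    #: marker-excluding nucleus interior and true stain so the median-
    #: within-leaflet threshold separates stain from everything else
    marker_background: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.n_touching_pairs * 2 > self.n_nuclei:
            raise ValueError("n_touching_pairs cannot exceed n_nuclei / 2")
        cov = self.coverages
        if any(not 0.0 <= c <= 1.0 for c in cov):
            raise ValueError("coverage fractions must lie in [0, 1]")
        if not 0.0 <= self.diffuse_marker_fraction <= 1.0:
            raise ValueError("diffuse_marker_fraction must lie in [0, 1]")

    @property
    def coverages(self) -> tuple[float, ...]:
        c = self.marker_coverage_per_nucleus
        if isinstance(c, (int, float)):
            return (float(c),) * self.n_nuclei
        if len(c) != self.n_nuclei:
            raise ValueError("marker_coverage_per_nucleus length must equal n_nuclei")
        return tuple(float(v) for v in c)


@dataclass(frozen=True)
class FluorescenceSample:
    dapi: np.ndarray  # uint16
    marker: np.ndarray  # uint16
    roi: LeafletROI
    truth: pd.DataFrame  # label, row, col, area, coverage, positive
    truth_labels: np.ndarray  # ground-truth nucleus label image


def _place_nuclei(gt: FluorescenceGroundTruth, roi: LeafletROI, rng: np.random.Generator):
    """Nucleus centers/axes/orientations: touching pairs first, then singles."""
    shape = gt.image_shape
    roi_mask = roi.mask(shape)
    (a_lo, a_hi), (b_lo, b_hi) = gt.nucleus_axes
    margin = a_hi + 2
    inner = np.argwhere(roi_mask)
    inner = inner[
        (inner[:, 0] > margin) & (inner[:, 0] < shape[0] - margin)
        & (inner[:, 1] > margin) & (inner[:, 1] < shape[1] - margin)
    ]
    if len(inner) == 0:
        raise ValueError("ROI too small for the requested nuclei")

    placed: list[tuple[float, float, float]] = []  # (row, col, radius) per ellipse
    specs = []  # (row, col, a, b, theta)

    def far_enough(r, c, rad, slack=3.0):
        return all(np.hypot(r - pr, c - pc) >= rad + prad + slack for pr, pc, prad in placed)

    max_tries = 8000
    for pair in range(gt.n_touching_pairs):
        for attempt in range(max_tries):
            r, c = inner[rng.integers(len(inner))] + rng.uniform(-0.5, 0.5, 2)
            theta = rng.uniform(0, np.pi)
            a1, a2 = rng.uniform(a_lo, a_hi, 2)
            b1, b2 = rng.uniform(b_lo, b_hi, 2)
            d = 0.8 * (a1 + a2)  # overlap ~20% of the combined major axes
            r2, c2 = r + d * np.sin(theta), c + d * np.cos(theta)
            if not (margin < r2 < shape[0] - margin and margin < c2 < shape[1] - margin):
                continue
            if not roi_mask[int(r2), int(c2)]:
                continue
            if far_enough(r, c, a1) and far_enough(r2, c2, a2):
                placed.append((r, c, a1))
                placed.append((r2, c2, a2))
                specs.append((r, c, a1, b1, theta))
                specs.append((r2, c2, a2, b2, theta))
                break
        else:
            raise ValueError("could not place touching pair: infeasible packing")

    n_single = gt.n_nuclei - 2 * gt.n_touching_pairs
    for _ in range(n_single):
        for attempt in range(max_tries):
            r, c = inner[rng.integers(len(inner))] + rng.uniform(-0.5, 0.5, 2)
            a = rng.uniform(a_lo, a_hi)
            b = rng.uniform(b_lo, b_hi)
            theta = rng.uniform(0, np.pi)
            if far_enough(r, c, a):
                placed.append((r, c, a))
                specs.append((r, c, a, b, theta))
                break
        else:
            raise ValueError("could not place nucleus: infeasible packing")
    return specs


def simulate_fluorescence(
    gt: FluorescenceGroundTruth, roi: LeafletROI | None = None
) -> FluorescenceSample:
    """Render the DAPI and marker channels plus the per-nucleus truth table."""
    rng = np.random.default_rng(gt.seed)
    roi = roi or default_leaflet_polygon(gt.image_shape)
    shape = gt.image_shape
    specs = _place_nuclei(gt, roi, rng)
    coverages = gt.coverages

    roi_mask = roi.mask(shape)
    truth_labels = np.zeros(shape, dtype=np.int32)
    dapi = np.zeros(shape, dtype=np.float64)
    # tissue autofluorescence inside the leaflet; nuclei exclude the marker
    # unless positive, so their interior sits below the leaflet background
    marker = np.where(roi_mask, gt.marker_background, 0.0)
    rows = []
    for label, ((r, c, a, b, theta), cov) in enumerate(zip(specs, coverages), start=1):
        rr, cc = _draw_ellipse(r, c, a, b, shape=shape, rotation=theta)
        dapi[rr, cc] = gt.nucleus_intensity
        # later nuclei of a touching pair overwrite the shared pixels
        truth_labels[rr, cc] = label
        marker[rr, cc] = 0.15 * gt.marker_background
        if cov > 0:
            # exact planted coverage: a half-plane cut through the pixel set
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            proj = rr * direction[0] + cc * direction[1]
            order = np.argsort(proj, kind="stable")
            n_cov = int(round(cov * len(rr)))
            marker[rr[order[:n_cov]], cc[order[:n_cov]]] = gt.marker_intensity
        rows.append({"label": label, "row": r, "col": c, "area": len(rr),
                     "coverage": cov, "positive": cov > 0.5})

    if gt.diffuse_marker_fraction > 0:
        # contiguous stain patches (thresholded smooth random field) so the
        # painted fraction survives the optical blur
        candidates = roi_mask & (truth_labels == 0)
        field_vals = gaussian_filter(rng.normal(size=shape), 6.0)
        n_diffuse = int(round(gt.diffuse_marker_fraction * roi_mask.sum()))
        flat = np.flatnonzero(candidates.ravel())
        order = np.argsort(-field_vals.ravel()[flat], kind="stable")
        take = flat[order[:n_diffuse]]
        marker.ravel()[take] = 0.7 * gt.marker_intensity

    if gt.psf_sigma > 0:
        dapi = gaussian_filter(dapi, gt.psf_sigma)
    if gt.marker_psf_sigma > 0:
        marker = gaussian_filter(marker, gt.marker_psf_sigma)
    if gt.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, gt.noise_sd, shape)
        marker = marker + rng.normal(0.0, gt.noise_sd, shape)
    dapi = np.clip(np.round(dapi), 0, 65535).astype(np.uint16)
    marker = np.clip(np.round(marker), 0, 65535).astype(np.uint16)

    return FluorescenceSample(dapi, marker, roi, pd.DataFrame(rows), truth_labels)


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class CtGroup:
    name: str
    n: int
    target_means: dict[str, float]  # mean Cq per target (incl. housekeepers)
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2 samples")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class CtGroundTruth:
    groups: tuple[CtGroup, ...]
    housekeeping_targets: tuple[str, str] = ("Gapdh", "Actb")
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.housekeeping_targets) != 2:
            raise ValueError("exactly two housekeeping targets are required")
        for grp in self.groups:
            for hk in self.housekeeping_targets:
                if hk not in grp.target_means:
                    raise ValueError(
                        f"group {grp.name!r} is missing housekeeping target {hk!r}"
                    )


def simulate_ct_table(gt: CtGroundTruth) -> pd.DataFrame:
    """Long-format Cq table: Cq ~ Normal(mean, sd) per sample and target."""
    rng = np.random.default_rng(gt.seed)
    rows = []
    for grp in gt.groups:
        for i in range(grp.n):
            sample = f"{grp.name}_{i + 1}"
            for target, mean in grp.target_means.items():
                rows.append(
                    {
                        "sample": sample,
                        "group": grp.name,
                        "target": target,
                        "cq": float(rng.normal(mean, grp.sd)) if grp.sd > 0 else float(mean),
                    }
                )
    return pd.DataFrame(rows)
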