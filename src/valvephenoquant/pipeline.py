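"""Whole-study orchestration over synthetic cohorts.

A study config names groups of mice with per-modality ground-truth
parameters; the pipeline simulates each mouse's raw inputs, runs every
enabled quantification stage, aggregates group summaries (mean +/- SEM),
classifies hemodynamic severity, and sends each endpoint through the
test-selection engine. One root seed deterministically derives all
per-mouse, per-modality seeds, so a study is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import doppler as dop
from . import ifquant as iq
from . import qpcr
from . import stats as st
from . import synthetic as syn
from . import trichrome as tri
from .color import rgb_to_hsl

__all__ = ["GroupConfig", "StudyConfig", "StudyResult", "run_cohort", "run_study"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupConfig:
    """One cohort group and its per-modality ground-truth parameters.

    Modality blocks are plain dicts so configs stay close to the YAML;
    omitted blocks disable that modality for the study (a modality must
    be configured for either every group or none).
    """

    name: str
    n: int
    doppler: dict | None = None
    trichrome: dict | None = None
    fluorescence: dict | None = None
    qpcr: dict | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.name!r}: n must be >= 1")


@dataclass(frozen=True)
class StudyConfig:
    groups: tuple[GroupConfig, ...]
    seed: int = 0
    severity_threshold: float = dop.SEVERITY_THRESHOLD_MM_S
    alpha: float = 0.05
    housekeeping: tuple[str, str] = qpcr.DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("study needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        for modality in ("doppler", "trichrome", "fluorescence", "qpcr"):
            present = [getattr(g, modality) is not None for g in self.groups]
            if any(present) and not all(present):
                raise ValueError(f"modality {modality!r} must be set for all groups or none")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groups = tuple(GroupConfig(**g) for g in raw.pop("groups"))
        if "housekeeping" in raw:
            raw["housekeeping"] = tuple(raw["housekeeping"])
        return cls(groups=groups, **raw)


@dataclass
class StudyResult:
    per_mouse: pd.DataFrame
    group_summary: pd.DataFrame
    severity: pd.DataFrame | None
    stats: pd.DataFrame
    results: list[st.TestResult] = dc_field(default_factory=list)


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _mouse_doppler(params: dict, mouse_rng: np.random.Generator, ss) -> dict:
    true_peak = float(
        mouse_rng.normal(params["peak_velocity"], params.get("between_mouse_sd", 0.0))
    )
    true_peak = max(true_peak, 1.0)
    n_images = int(params.get("n_images", 3))
    images = []
    for i in range(n_images):
        gt = syn.DopplerGroundTruth(
            peak_velocity=true_peak,
            heart_rate=params.get("heart_rate", 465.0),
            ejection_fraction_of_cycle=params.get("ejection_fraction_of_cycle", 0.32),
            n_cycles=int(params.get("n_cycles", 33)),
            noise_sd=params.get("noise_sd", 0.0) * true_peak
            if params.get("noise_relative", False)
            else params.get("noise_sd", 0.0),
            sampling_rate=params.get("sampling_rate", 4000.0),
            seed=_seed_of(ss.spawn(1)[0]),
        )
        image_summary, _ = dop.analyze_trace(syn.simulate_doppler(gt))
        images.append(image_summary)
    mouse = dop.summarize_mouse(images)
    return {
        "true_peak_velocity": true_peak,
        "peak_velocity": mouse.peak_velocity,
        "mean_gradient": mouse.mean_gradient,
        "n_cycles": mouse.n_cycles,
    }


def _mouse_trichrome(params: dict, mouse_rng: np.random.Generator, ss) -> dict:
    frac = float(
        np.clip(
            mouse_rng.normal(params.get("collagen_fraction", 0.3), params.get("between_mouse_sd", 0.0)),
            0.02,
            0.98,
        )
    )
    gt = syn.TrichromeGroundTruth(
        class_fractions={"collagen": frac, "cytoplasm": 1.0 - frac},
        background_fraction=params.get("background_fraction", 0.1),
        image_shape=tuple(params.get("image_shape", (128, 192))),
        seed=_seed_of(ss.spawn(1)[0]),
    )
    sample = syn.simulate_trichrome(gt)
    labels, names = tri.classify_pixels(rgb_to_hsl(sample.image), roi=sample.roi)
    comp = tri.area_fractions(labels, names)
    thickness = tri.leaflet_thickness(sample.roi.mask(gt.image_shape))
    return {
        "true_collagen_fraction": frac,
        "collagen_fraction": comp.fractions["collagen"],
        "leaflet_thickness": thickness,
    }


def _mouse_fluorescence(params: dict, mouse_rng: np.random.Generator, ss) -> dict:
    n_nuclei = int(params.get("n_nuclei", 60))
    pos_frac = float(params.get("runx2_positive_fraction", 0.5))
    n_pos = int(round(pos_frac * n_nuclei))
    coverages = np.full(n_nuclei, params.get("coverage_negative", 0.2))
    pos_idx = mouse_rng.permutation(n_nuclei)[:n_pos]
    coverages[pos_idx] = params.get("coverage_positive", 0.8)
    gt = syn.FluorescenceGroundTruth(
        n_nuclei=n_nuclei,
        n_touching_pairs=int(params.get("n_touching_pairs", 5)),
        marker_coverage_per_nucleus=tuple(coverages),
        diffuse_marker_fraction=params.get("diffuse_marker_fraction", 0.0),
        noise_sd=params.get("noise_sd", 100.0),
        image_shape=tuple(params.get("image_shape", (320, 320))),
        seed=_seed_of(ss.spawn(1)[0]),
    )
    sample = syn.simulate_fluorescence(gt)
    labels = iq.segment_nuclei(sample.dapi, sample.roi)
    threshold = iq.marker_threshold(sample.marker, sample.roi)
    quant = iq.runx2_positivity(labels, sample.marker, threshold)
    asma = iq.asma_area_fraction(sample.marker, sample.roi, threshold)
    return {
        "true_runx2_positivity": float(np.mean(coverages > 0.5)),
        "runx2_positivity": quant.runx2_positive_fraction,
        "n_nuclei_detected": quant.n_nuclei,
        "asma_area_fraction": asma,
    }


_ENDPOINTS = {
    "doppler": ("peak_velocity", "mean_gradient"),
    "trichrome": ("collagen_fraction", "leaflet_thickness"),
    "fluorescence": ("runx2_positivity", "n_nuclei_detected", "asma_area_fraction"),
}


def run_cohort(config: StudyConfig) -> StudyResult:
    """Simulate every mouse, quantify all enabled modalities, run statistics."""
    rows = []
    for g_idx, grp in enumerate(config.groups):
        for m_idx in range(grp.n):
            mouse_ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(g_idx, m_idx)
            )
            mouse_rng = np.random.default_rng(mouse_ss.spawn(1)[0])
            row: dict = {"group": grp.name, "mouse": f"{grp.name}_{m_idx + 1}"}
            if grp.doppler is not None:
                row.update(_mouse_doppler(grp.doppler, mouse_rng, mouse_ss))
            if grp.trichrome is not None:
                row.update(_mouse_trichrome(grp.trichrome, mouse_rng, mouse_ss))
            if grp.fluorescence is not None:
                row.update(_mouse_fluorescence(grp.fluorescence, mouse_rng, mouse_ss))
            rows.append(row)
    per_mouse = pd.DataFrame(rows)

    # qPCR runs cohort-wide from one simulated plate
    dct_endpoints: list[str] = []
    if config.groups[0].qpcr is not None:
        ct_gt = syn.CtGroundTruth(
            groups=tuple(
                syn.CtGroup(
                    name=g.name,
                    n=g.n,
                    target_means=dict(g.qpcr["target_means"]),
                    sd=g.qpcr.get("sd", 0.0),
                )
                for g in config.groups
            ),
            housekeeping_targets=config.housekeeping,
            seed=_seed_of(np.random.SeedSequence(entropy=config.seed, spawn_key=(999,))),
        )
        dct = qpcr.delta_ct(syn.simulate_ct_table(ct_gt), config.housekeeping)
        wide = dct.pivot_table(index=["sample", "group"], columns="target", values="delta_ct")
        wide.columns = [f"dct_{t}" for t in wide.columns]
        dct_endpoints = list(wide.columns)
        wide = wide.reset_index().rename(columns={"sample": "mouse"})
        per_mouse = per_mouse.merge(wide, on=["mouse", "group"], how="outer") \
            if not per_mouse.empty else wide

    # group summaries: mean +/- SEM per endpoint
    numeric = [c for c in per_mouse.columns if c not in ("group", "mouse")]
    summary_rows = []
    for name, sub in per_mouse.groupby("group", sort=False):
        for col in numeric:
            vals = sub[col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            summary_rows.append(
                {
                    "group": name,
                    "endpoint": col,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                }
            )
    group_summary = pd.DataFrame(summary_rows)

    severity = None
    if config.groups[0].doppler is not None:
        sev_rows = []
        for name, sub in per_mouse.groupby("group", sort=False):
            severe = sub["peak_velocity"] > config.severity_threshold
            sev_rows.append(
                {
                    "group": name,
                    "n": len(sub),
                    "n_severe": int(severe.sum()),
                    "fraction_severe": float(severe.mean()),
                }
            )
        severity = pd.DataFrame(sev_rows)

    # statistics: measured endpoints only (ground-truth columns excluded)
    endpoints = [
        ep
        for modality, eps in _ENDPOINTS.items()
        if getattr(config.groups[0], modality) is not None
        for ep in eps
    ] + dct_endpoints
    results = []
    if len(config.groups) >= 2:
        for ep in endpoints:
            groups = tuple(
                (name, sub[ep].dropna().to_numpy(dtype=float))
                for name, sub in per_mouse.groupby("group", sort=False)
            )
            try:
                spec = st.ComparisonSpec(ep, groups, alpha=config.alpha)
                results.append(st.compare(spec))
            except ValueError as exc:
                log.warning("skipping endpoint %s: %s", ep, exc)
    stats_table = st.report(results)

    return StudyResult(per_mouse, group_summary, severity, stats_table, results)


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyResult:
    """run_cohort + write all study artifacts under `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_cohort(config)
    result.per_mouse.to_csv(out / "per_mouse.csv", index=False)
    result.group_summary.to_csv(out / "group_summary.csv", index=False)
    if result.severity is not None:
        result.severity.to_csv(out / "severity.csv", index=False)
    result.stats.to_csv(out / "stats_results.csv", index=False)
    payload = {
        "seed": config.seed,
        "groups": {g.name: g.n for g in config.groups},
        "severity_threshold_mm_s": config.severity_threshold,
        "significant_endpoints": result.stats.loc[
            result.stats["significant"], "endpoint"
        ].tolist()
        if not result.stats.empty
        else [],
    }
    with open(out / "study.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    log.info("study artifacts written to %s", out)
    return result
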