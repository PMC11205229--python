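"""Synthetic eye and cohort generation.

Produces true-sensitivity fields on the 10-2 grid together with GCL
thickness maps that are consistent with the built-in structure-function
model, so the whole pipeline is exercisable without any clinical data.
Cohort defaults emulate a simulation dataset of 21 healthy eyes
(mean 10-2 sensitivity ~28.9 dB) and 32 glaucomatous eyes
(mean ~14.6 dB; 5 early / 8 moderate / 19 advanced).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import NearestNDInterpolator

from .grid import TestGrid, VFPoint, build_10_2_grid, displace_locations
from .observer import EyeProfile
from .structfunc import SFModelParams, ThicknessMap

__all__ = [
    "NormativeMap",
    "CohortSpec",
    "PAPER_SEVERITY_MIX",
    "DEFECT_DEPTH_DB",
    "make_normative_map",
    "gen_healthy_eye",
    "gen_glaucoma_eye",
    "gen_cohort",
    "write_cohort",
    "load_eye",
    "load_cohort",
]

#: severity mix of the emulated glaucoma sample: 5 early, 8 moderate, 19 advanced
PAPER_SEVERITY_MIX = (5 / 32, 8 / 32, 19 / 32)

#: mean defect depth (dB) in the primary hemifield, per severity, and the
#: fraction of that depth applied to the secondary hemifield.  Calibrated
#: once so the default 5/8/19 cohort mean lands near 14.6 dB.
DEFECT_DEPTH_DB = {"early": 5.0, "moderate": 12.0, "advanced": 24.0}
SECONDARY_FRACTION = {"early": 0.0, "moderate": 0.25, "advanced": 0.7}

_SEVERITIES = ("early", "moderate", "advanced")


@dataclass(frozen=True)
class NormativeMap:
    """Per-location normative sensitivity (dB) on the test grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("normative values must be a 1-D vector")
        if v.min() < 20.0 or v.max() > 40.0:
            raise ValueError("normative sensitivities must lie in [20, 40] dB")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CohortSpec:
    n_healthy: int = 21
    n_glaucoma: int = 32
    severity_mix: tuple[float, float, float] = PAPER_SEVERITY_MIX
    seed: int = 0
    sf_params: SFModelParams = field(default_factory=SFModelParams)
    normative: NormativeMap | None = None

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_glaucoma < 0:
            raise ValueError("cohort counts must be nonnegative")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")

    def severity_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of n_glaucoma over the mix."""
        raw = np.asarray(self.severity_mix) * self.n_glaucoma
        counts = np.floor(raw).astype(int)
        for i in np.argsort(raw - counts)[::-1][: self.n_glaucoma - counts.sum()]:
            counts[i] += 1
        return dict(zip(_SEVERITIES, (int(c) for c in counts)))


def make_normative_map(
    grid: TestGrid, foveal_db: float = 31.0, slope_db_per_deg: float = 0.35
) -> NormativeMap:
    """Hill-of-vision stand-in: sensitivity falls linearly with eccentricity.

    The defaults put the grid-average normative sensitivity near 28.9 dB.
    """
    if not 25.0 <= foveal_db <= 40.0:
        raise ValueError("foveal_db must lie in [25, 40]")
    ecc = grid.eccentricity("nominal")
    return NormativeMap(foveal_db - slope_db_per_deg * ecc)


def _thickness_from_field(
    grid: TestGrid,
    thresholds: np.ndarray,
    sf_params: SFModelParams,
    rng: np.random.Generator,
    *,
    pixel_size: float = 0.25,
    half_extent_deg: float = 15.0,
    noise_frac: float = 0.10,
) -> ThicknessMap:
    """Invert the SF model into a thickness raster consistent with the field.

    Each pixel takes the sensitivity of the nearest displaced grid location,
    is mapped through the inverse of the log10-linear model and perturbed by
    multiplicative lognormal noise (unit mean).
    """
    npix = int(round(2 * half_extent_deg / pixel_size)) + 1
    xs = (np.arange(npix) - (npix - 1) / 2.0) * pixel_size
    ys = ((npix - 1) / 2.0 - np.arange(npix)) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    interp = NearestNDInterpolator(np.asarray(grid.displaced, dtype=float), thresholds)
    sens = interp(np.column_stack([gx.ravel(), gy.ravel()])).reshape(npix, npix)
    thickness = 10.0 ** ((sens - sf_params.intercept) / sf_params.slope)
    if noise_frac > 0:
        sigma = np.sqrt(np.log(1.0 + noise_frac**2))
        thickness = thickness * rng.lognormal(-0.5 * sigma**2, sigma, thickness.shape)
    return ThicknessMap(np.clip(thickness, 0.1, 150.0), VFPoint(0.0, 0.0), pixel_size)


def gen_healthy_eye(
    normative: NormativeMap,
    between_eye_sd: float = 1.49,
    rng: np.random.Generator | None = None,
    *,
    location_sd: float = 1.0,
    sf_params: SFModelParams | None = None,
    grid: TestGrid | None = None,
    map_noise_frac: float = 0.10,
) -> EyeProfile:
    """A healthy eye: normative field plus an eye-level offset and small
    per-location noise, with a consistent GCL map."""
    rng = rng if rng is not None else np.random.default_rng()
    sf_params = sf_params or SFModelParams()
    grid = grid if grid is not None else displace_locations(build_10_2_grid())
    offset = rng.normal(0.0, between_eye_sd) if between_eye_sd > 0 else 0.0
    noise = rng.normal(0.0, location_sd, normative.values.shape) if location_sd > 0 else 0.0
    thresholds = np.clip(normative.values + offset + noise, 0.0, 40.0)
    gcl = _thickness_from_field(grid, thresholds, sf_params, rng, noise_frac=map_noise_frac)
    return EyeProfile(true_thresholds=thresholds, gcl_map=gcl, cohort="healthy",
                      severity="none")


def gen_glaucoma_eye(
    normative: NormativeMap,
    severity: str,
    rng: np.random.Generator | None = None,
    *,
    grid: TestGrid | None = None,
    sf_params: SFModelParams | None = None,
    depth_db: float | None = None,
    depth_sd: float = 2.0,
    gradient_max: float = 0.4,  # dB per degree, within-hemifield smoothness
    location_sd: float = 1.0,
    map_noise_frac: float = 0.10,
) -> EyeProfile:
    """A glaucomatous eye with a hemifield-respecting smooth defect.

    One hemifield (random sign) carries the full defect depth; the opposite
    hemifield carries a severity-dependent fraction of it (diffuse spread in
    advanced disease).  The defect varies smoothly within each hemifield and
    is discontinuous only across the horizontal midline.
    """
    if severity not in _SEVERITIES:
        raise ValueError(f"severity must be one of {_SEVERITIES}")
    rng = rng if rng is not None else np.random.default_rng()
    sf_params = sf_params or SFModelParams()
    grid = grid if grid is not None else displace_locations(build_10_2_grid())
    mean_depth = DEFECT_DEPTH_DB[severity] if depth_db is None else depth_db

    pts = grid.nominal
    upper = pts[:, 1] > 0
    primary_upper = bool(rng.random() < 0.5)
    depth_eye = max(0.0, rng.normal(mean_depth, depth_sd))
    angle = rng.uniform(0.0, 2 * np.pi)
    grad = rng.uniform(0.0, gradient_max) * np.array([np.cos(angle), np.sin(angle)])
    local = depth_eye + pts @ grad
    depth = np.where(upper == primary_upper, local,
                     SECONDARY_FRACTION[severity] * local)
    depth = np.maximum(depth, 0.0)
    if mean_depth == 0.0:
        depth = np.zeros_like(depth)

    noise = rng.normal(0.0, location_sd, pts.shape[0]) if location_sd > 0 else 0.0
    thresholds = np.clip(normative.values - depth + noise, 0.0, 40.0)
    gcl = _thickness_from_field(grid, thresholds, sf_params, rng, noise_frac=map_noise_frac)
    return EyeProfile(true_thresholds=thresholds, gcl_map=gcl, cohort="glaucoma",
                      severity=severity,
                      meta={"depth_db": float(depth_eye), "primary_upper": primary_upper})


def gen_cohort(spec: CohortSpec, out_dir=None) -> list[EyeProfile]:
    """A reproducible cohort of healthy and glaucomatous eyes.

    If ``out_dir`` is given, per-eye bundles and a manifest are written
    there as delimited text.
    """
    rng = np.random.default_rng(spec.seed)
    grid = displace_locations(build_10_2_grid())
    normative = spec.normative or make_normative_map(grid)
    eyes: list[EyeProfile] = []
    for i in range(spec.n_healthy):
        eye = gen_healthy_eye(normative, rng=rng, sf_params=spec.sf_params, grid=grid)
        eyes.append(_with_id(eye, f"healthy_{i:03d}"))
    counts = spec.severity_counts()
    k = 0
    for severity in _SEVERITIES:
        for _ in range(counts[severity]):
            eye = gen_glaucoma_eye(normative, severity, rng=rng,
                                   sf_params=spec.sf_params, grid=grid)
            eyes.append(_with_id(eye, f"glaucoma_{k:03d}"))
            k += 1
    if out_dir is not None:
        write_cohort(eyes, spec, out_dir)
    return eyes


def _with_id(eye: EyeProfile, eye_id: str) -> EyeProfile:
    return EyeProfile(
        true_thresholds=eye.true_thresholds, gcl_map=eye.gcl_map, cohort=eye.cohort,
        severity=eye.severity, fovea=eye.fovea, onh_center=eye.onh_center,
        eye_id=eye_id, meta=eye.meta,
    )


# ---------------------------------------------------------------------------
# per-eye text bundles

def write_cohort(eyes: list[EyeProfile], spec: CohortSpec, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": spec.seed,
        "n_healthy": spec.n_healthy,
        "n_glaucoma": spec.n_glaucoma,
        "severity_mix": list(spec.severity_mix),
        "eyes": [],
    }
    for eye in eyes:
        d = out / eye.eye_id
        d.mkdir(exist_ok=True)
        np.savetxt(d / "thresholds.tsv", eye.true_thresholds, fmt="%.4f",
                   header="true_threshold_db")
        if eye.gcl_map is not None:
            eye.gcl_map.to_text(d / "gcl_map.tsv")
        with open(d / "geometry.tsv", "w") as fh:
            fh.write("fovea_x\tfovea_y\tonh_x\tonh_y\n")
            fh.write(f"{eye.fovea.x}\t{eye.fovea.y}\t{eye.onh_center.x}\t{eye.onh_center.y}\n")
        manifest["eyes"].append(
            {"id": eye.eye_id, "cohort": eye.cohort, "severity": eye.severity}
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_eye(eye_dir) -> EyeProfile:
    d = Path(eye_dir)
    thresholds = np.loadtxt(d / "thresholds.tsv")
    gcl = ThicknessMap.from_text(d / "gcl_map.tsv") if (d / "gcl_map.tsv").exists() else None
    geom = np.loadtxt(d / "geometry.tsv", skiprows=1)
    eye_id = d.name
    cohort = "glaucoma" if eye_id.startswith("glaucoma") else "healthy"
    manifest = d.parent / "manifest.json"
    severity = "none" if cohort == "healthy" else "advanced"
    if manifest.exists():
        with open(manifest) as fh:
            for entry in json.load(fh)["eyes"]:
                if entry["id"] == eye_id:
                    cohort, severity = entry["cohort"], entry["severity"]
    return EyeProfile(
        true_thresholds=thresholds, gcl_map=gcl, cohort=cohort, severity=severity,
        fovea=VFPoint(float(geom[0]), float(geom[1])),
        onh_center=VFPoint(float(geom[2]), float(geom[3])), eye_id=eye_id,
    )


def load_cohort(cohort_dir) -> list[EyeProfile]:
    d = Path(cohort_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    return [load_eye(d / entry["id"]) for entry in manifest["eyes"]]
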