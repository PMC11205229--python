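"""Point-wise macular structure-function model.

Predicts expected sensitivity (dB) and an abnormality weight from local
ganglion-cell-layer (GCL) thickness, and samples per-location thickness
from a raster map.  The functional form — linear in log10(thickness) with a
logistic abnormality weight — is a documented stand-in behind a small,
pluggable parameter object; substitute fitted parameters via
:class:`SFModelParams` or a config file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grid import TestGrid, VFPoint

__all__ = [
    "ThicknessMap",
    "SFModelParams",
    "GclSample",
    "sample_gcl",
    "predict_sensitivity",
    "predict_abnormal_weight",
    "fit_sf_model",
]

DB_MIN, DB_MAX = 0.0, 40.0
THICKNESS_MAX_UM = 150.0


@dataclass(frozen=True)
class ThicknessMap:
    """A 2-D GCL thickness raster in micrometres.

    ``values[0, 0]`` is the top-left (superior-nasal for a right eye) pixel;
    rows run superior to inferior, columns nasal to temporal.  ``origin`` is
    the fundus-reference position (deg) of the raster centre and
    ``pixel_size`` the degree extent of one pixel.  Pixel centres sit at
    integer indices.
    """

    values: np.ndarray
    origin: VFPoint = VFPoint(0.0, 0.0)
    pixel_size: float = 0.25

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("thickness raster must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("thickness raster contains non-finite values")
        if v.min() < 0 or v.max() > THICKNESS_MAX_UM:
            raise ValueError(
                f"thickness values must lie in [0, {THICKNESS_MAX_UM}] um"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        """Fundus x (deg) of each column's pixel centre."""
        w = self.values.shape[1]
        return self.origin.x + (np.arange(w) - (w - 1) / 2.0) * self.pixel_size

    def y_coords(self) -> np.ndarray:
        """Fundus y (deg) of each row's pixel centre (row 0 is superior)."""
        h = self.values.shape[0]
        return self.origin.y + ((h - 1) / 2.0 - np.arange(h)) * self.pixel_size

    # -- I/O ---------------------------------------------------------------

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# origin_x_deg={self.origin.x}\n")
            fh.write(f"# origin_y_deg={self.origin.y}\n")
            fh.write(f"# pixel_size_deg={self.pixel_size}\n")
            np.savetxt(fh, self.values, fmt="%.4f", delimiter="\t")

    @classmethod
    def from_text(cls, path) -> "ThicknessMap":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = float(val)
                pos = fh.tell()
            values = np.loadtxt(fh, delimiter="\t")
        return cls(
            values=values,
            origin=VFPoint(header.get("origin_x_deg", 0.0), header.get("origin_y_deg", 0.0)),
            pixel_size=header.get("pixel_size_deg", 0.25),
        )

    @classmethod
    def from_image(cls, path, scale_um_per_unit: float, *,
                   origin: VFPoint = VFPoint(0.0, 0.0),
                   pixel_size: float = 0.25) -> "ThicknessMap":
        """Import a grayscale (e.g. 16-bit) image, value * scale -> um."""
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path), dtype=float)
        if raw.ndim == 3:
            raw = raw[..., 0]
        return cls(values=raw * scale_um_per_unit, origin=origin, pixel_size=pixel_size)


@dataclass(frozen=True)
class SFModelParams:
    """Parameters of the sensitivity-vs-log10(thickness) line and the
    abnormality-weight logistic.

    With the defaults the abnormality weight equals the standard 4:1
    mixture's abnormal fraction (0.2) at zero predicted deficit:
    ``mixing_midpoint = mixing_scale * ln(4)``.
    """

    intercept: float = 0.0  # dB
    slope: float = 20.0  # dB per log10(um)
    noise_sd: float = 2.0  # dB
    mixing_scale: float = 2.0  # dB
    mixing_midpoint: float = 2.0 * math.log(4.0)  # dB

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive (thicker GCL -> higher sensitivity)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.mixing_scale <= 0:
            raise ValueError("mixing_scale must be positive")

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for k in ("intercept", "slope", "noise_sd", "mixing_scale", "mixing_midpoint"):
                fh.write(f"{k}={getattr(self, k)}\n")

    @classmethod
    def from_text(cls, path) -> "SFModelParams":
        kv: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                kv[k.strip()] = float(v)
        return cls(**kv)


@dataclass(frozen=True)
class GclSample:
    location_index: int
    mean_thickness: float  # um
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("a GCL sample must cover at least one pixel")


def sample_gcl(
    thickness: ThicknessMap, grid: TestGrid, window_deg: float = 2.0
) -> list[GclSample]:
    """Mean GCL thickness in a square window around each displaced location.

    The window (side ``window_deg``) is centred on the displaced stimulus
    position; a pixel contributes when its centre falls inside the window.
    Raises if any window extends beyond the raster, naming the location.
    """
    if window_deg <= 0:
        raise ValueError("window_deg must be positive")
    half = window_deg / 2.0
    xs = thickness.x_coords()
    ys = thickness.y_coords()
    x_lo, x_hi = xs.min(), xs.max()
    y_lo, y_hi = ys.min(), ys.max()
    out: list[GclSample] = []
    for i, (px, py) in enumerate(np.asarray(grid.displaced, dtype=float)):
        if px - half < x_lo - 1e-9 or px + half > x_hi + 1e-9 or \
           py - half < y_lo - 1e-9 or py + half > y_hi + 1e-9:
            raise ValueError(
                f"sampling window for location {i} at ({px:.2f}, {py:.2f}) deg "
                "falls outside the thickness raster"
            )
        col = np.abs(xs - px) <= half + 1e-9
        row = np.abs(ys - py) <= half + 1e-9
        window = thickness.values[np.ix_(row, col)]
        out.append(
            GclSample(location_index=i, mean_thickness=float(window.mean()),
                      n_pixels=int(window.size))
        )
    return out


def predict_sensitivity(thickness, params: SFModelParams | None = None):
    """Expected sensitivity (dB) from GCL thickness (um), clamped to [0, 40].

    Accepts a scalar or array; thickness must be strictly positive.
    """
    if params is None:
        params = SFModelParams()
    t = np.asarray(thickness, dtype=float)
    if np.any(t <= 0):
        raise ValueError("thickness must be positive")
    pred = np.clip(params.intercept + params.slope * np.log10(t), DB_MIN, DB_MAX)
    return float(pred) if np.isscalar(thickness) else pred


def predict_abnormal_weight(predicted, normative, params: SFModelParams | None = None):
    """Abnormal-component mixing weight in [0, 1].

    Logistic in the predicted deficit ``d = normative - predicted``:
    ``1 / (1 + exp(-(d - midpoint) / scale))``.  Calibrated so that zero
    deficit reproduces the standard mixture's abnormal fraction.
    """
    if params is None:
        params = SFModelParams()
    if params.mixing_scale <= 0:
        raise ValueError("mixing_scale must be positive")
    d = np.asarray(normative, dtype=float) - np.asarray(predicted, dtype=float)
    w = 1.0 / (1.0 + np.exp(-(d - params.mixing_midpoint) / params.mixing_scale))
    return float(w) if w.ndim == 0 else w


def fit_sf_model(
    pairs: Iterable[tuple[float, float]] | Sequence[Sequence[float]],
    **mixing_kwargs,
) -> SFModelParams:
    """Ordinary least squares of sensitivity (dB) on log10(thickness).

    ``noise_sd`` is the residual standard deviation (ddof = 2).  Mixing
    parameters keep their defaults unless passed as keyword arguments.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (thickness, sensitivity) tuples")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs to fit")
    t, s = arr[:, 0], arr[:, 1]
    if np.any(t <= 0):
        raise ValueError("thickness must be positive")
    x = np.log10(t)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate design: all thicknesses equal")
    slope, intercept = np.polyfit(x, s, 1)
    resid = s - (intercept + slope * x)
    noise_sd = float(np.sqrt(np.sum(resid**2) / (len(s) - 2)))
    return SFModelParams(
        intercept=float(intercept), slope=float(slope), noise_sd=noise_sd, **mixing_kwargs
    )
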