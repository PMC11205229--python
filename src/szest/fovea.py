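"""Fovea localization on thickness maps and affine coordinate mapping.

The fovea is found as the point of maximum zero-normalized cross-correlation
(ZNCC) between the thickness map and a template of the foveal pit, with the
search constrained to a square region (default 12.5 x 12.5 deg).  Affine
registration itself is out of scope: a transform estimated elsewhere is
accepted and applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VFPoint
from .structfunc import ThicknessMap

__all__ = [
    "FoveaTemplate",
    "AffineTransform",
    "make_fovea_template",
    "locate_fovea",
    "apply_affine",
]


@dataclass(frozen=True)
class FoveaTemplate:
    """Mean foveal-pit thickness patch with odd dimensions (defined centre)."""

    raster: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        r = np.asarray(self.raster, dtype=float)
        if r.ndim != 2 or r.shape[0] % 2 == 0 or r.shape[1] % 2 == 0:
            raise ValueError("template must be 2-D with odd dimensions")
        if not np.all(np.isfinite(r)):
            raise ValueError("template contains non-finite values")
        object.__setattr__(self, "raster", r)


@dataclass(frozen=True)
class AffineTransform:
    """x' = A x + b in degree coordinates."""

    linear: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        a = np.asarray(self.linear, dtype=float).reshape(2, 2)
        b = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(a)) <= 1e-9:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "linear", a)
        object.__setattr__(self, "offset", b)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.offset)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    def to_text(self, path) -> None:
        vals = np.concatenate([self.linear.ravel(), self.offset])
        np.savetxt(path, vals[None, :], fmt="%.9f",
                   header="a11 a12 a21 a22 b1 b2")

    @classmethod
    def from_text(cls, path) -> "AffineTransform":
        vals = np.loadtxt(path).ravel()
        if vals.size != 6:
            raise ValueError("affine file must contain six numbers")
        return cls(vals[:4].reshape(2, 2), vals[4:])


def make_fovea_template(
    maps: list[ThicknessMap], half_width_deg: float = 3.0
) -> FoveaTemplate:
    """Pixelwise mean of fovea-centred crops (fovea assumed at each raster centre)."""
    if not maps:
        raise ValueError("need at least one map")
    ps = maps[0].pixel_size
    hw = int(round(half_width_deg / ps))
    crops = []
    for m in maps:
        if abs(m.pixel_size - ps) > 1e-9:
            raise ValueError("all maps must share one pixel size")
        h, w = m.shape
        ci, cj = (h - 1) // 2, (w - 1) // 2
        if ci - hw < 0 or cj - hw < 0 or ci + hw >= h or cj + hw >= w:
            raise ValueError("map does not cover the template window")
        crops.append(m.values[ci - hw: ci + hw + 1, cj - hw: cj + hw + 1])
    return FoveaTemplate(np.mean(crops, axis=0), ps)


def locate_fovea(
    thickness: ThicknessMap,
    template: FoveaTemplate,
    search_center: VFPoint = VFPoint(0.0, 0.0),
    search_half_width: float = 6.25,
) -> tuple[VFPoint, float]:
    """Best-matching template centre within the search region.

    Returns the peak position in fundus degrees and the ZNCC score in
    [-1, 1].  Ties are broken by distance to ``search_center``, then
    row-major order.  Raises on a zero-variance map or template.
    """
    if abs(template.pixel_size - thickness.pixel_size) > 1e-9:
        raise ValueError("template and map pixel sizes differ")
    tmpl = template.raster
    if tmpl.std() == 0:
        raise ValueError("flat template: ZNCC undefined")
    if thickness.values.std() == 0:
        raise ValueError("flat thickness map: ZNCC undefined")
    th, tw = tmpl.shape
    hh, hw = th // 2, tw // 2

    xs = thickness.x_coords()
    ys = thickness.y_coords()
    # candidate centres: inside the search box, window fully within raster
    in_x = np.abs(xs - search_center.x) <= search_half_width + 1e-9
    in_y = np.abs(ys - search_center.y) <= search_half_width + 1e-9
    rows = [i for i in np.nonzero(in_y)[0] if hh <= i < thickness.shape[0] - hh]
    cols = [j for j in np.nonzero(in_x)[0] if hw <= j < thickness.shape[1] - hw]
    if not rows or not cols:
        raise ValueError("search region does not fit within the raster")

    t0 = tmpl - tmpl.mean()
    t_norm = np.sqrt((t0**2).sum())
    best = (np.inf, np.inf, np.inf, -1, -1)  # (-score, dist, row-major, i, j)
    vals = thickness.values
    for i in rows:
        for j in cols:
            win = vals[i - hh: i + hh + 1, j - hw: j + hw + 1]
            w0 = win - win.mean()
            w_norm = np.sqrt((w0**2).sum())
            score = -1.0 if w_norm == 0 else float((w0 * t0).sum() / (w_norm * t_norm))
            dist = float(np.hypot(xs[j] - search_center.x, ys[i] - search_center.y))
            key = (-score, dist, i * vals.shape[1] + j)
            if key < (best[0], best[1], best[2]):
                best = (*key, i, j)
    i, j = best[3], best[4]
    return VFPoint(float(xs[j]), float(ys[i])), -best[0]


def apply_affine(points, transform: AffineTransform) -> list[VFPoint]:
    """Map points through x' = A x + b."""
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    out = pts @ transform.linear.T + transform.offset
    return [VFPoint(float(x), float(y)) for x, y in out]
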