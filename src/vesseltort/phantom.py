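"""Synthetic vascular phantoms with analytic ground truth.

A phantom emulates everything the pipeline consumes for one eye: a
fundus-like RGB intensity image (bright textured background, bright optic
disc, dark vessels), the binary vessel mask, a red/blue/green artery-vein
label map (crossing pixels green so the both-masks inclusion rule is
exercised), the optic disc circle, and a truth table of analytic arc
lengths, chord lengths and tortuosities per vessel.  Vessels are
parametric curves (line, circular arc, sinusoid, quadratic Bezier)
rasterized at a chosen width; arc lengths come from closed forms where
they exist and adaptive quadrature (tolerance 1e-8) otherwise, so the
truth error is negligible against the few-percent recovery bands used in
testing.  Every output is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter
from skimage import morphology

from .av_separation import AVLabelMap
from .optic_disc import OpticDisc
from .preprocess import VesselMask

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "PhantomTruth",
    "Phantom",
    "curve_samples",
    "curve_arc_length",
    "curve_endpoints",
    "rasterize_vessel",
    "generate_phantom",
    "make_radial_spec",
    "degrade",
]

QUAD_TOL = 1e-8


@dataclass(frozen=True)
class VesselSpec:
    """One parametric vessel: class, curve kind, geometry params, width.

    Param conventions (all coordinates are (x, y) in pixels, angles in
    degrees):

    - line:     p0, angle_deg, length
    - arc:      center, radius, theta0_deg, theta1_deg
    - sinusoid: p0, angle_deg, length, amplitude, wavelength
                (perpendicular displacement A*sin(2*pi*u/wavelength) along
                the axis u in [0, length]; zero displacement at u=0)
    - bezier:   p0, p1, p2 (quadratic Bezier control points)
    """

    vessel_class: str  # artery | vein
    curve_kind: str  # line | arc | sinusoid | bezier
    params: dict
    width_px: int = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; the seed fully determines the output."""

    image_size: tuple[int, int]  # (H, W)
    od_center_xy: tuple[float, float]
    od_radius_px: float
    vessels: tuple[VesselSpec, ...]
    gap_rate: float = 0.0
    spur_rate: float = 0.0
    seed: int = 0
    fov_deg: float = 45.0


@dataclass
class PhantomTruth:
    """Analytic per-vessel truth: arc, chord, tortuosity, endpoint pixels."""

    table: pd.DataFrame  # vessel, vessel_class, curve_kind, arc_px, chord_px,
    #                      tortuosity, start_x, start_y, end_x, end_y


@dataclass
class Phantom:
    image: np.ndarray  # H x W x 3 float in [0, 1]
    mask: VesselMask
    labels: AVLabelMap
    od: OpticDisc
    truth: PhantomTruth
    spec: PhantomSpec
    class_masks: dict = field(default_factory=dict)  # artery/vein raster masks


# ---------------------------------------------------------------------------
# Parametric curves


def _curve_fns(v: VesselSpec):
    """Return (point(t), speed(t)) with t in [0, 1]."""
    p = v.params
    kind = v.curve_kind
    if kind == "line":
        x0, y0 = p["p0"]
        a = math.radians(p["angle_deg"])
        L = p["length"]
        dx, dy = math.cos(a), math.sin(a)
        return (
            lambda t: (x0 + dx * L * t, y0 + dy * L * t),
            lambda t: L,
        )
    if kind == "arc":
        cx, cy = p["center"]
        r = p["radius"]
        t0 = math.radians(p["theta0_deg"])
        t1 = math.radians(p["theta1_deg"])
        span = t1 - t0
        return (
            lambda t: (cx + r * math.cos(t0 + span * t), cy + r * math.sin(t0 + span * t)),
            lambda t: r * abs(span),
        )
    if kind == "sinusoid":
        x0, y0 = p["p0"]
        a = math.radians(p["angle_deg"])
        L, A, lam = p["length"], p["amplitude"], p["wavelength"]
        k = 2 * math.pi / lam
        ux, uy = math.cos(a), math.sin(a)
        nx, ny = -uy, ux

        def point(t):
            u = L * t
            off = A * math.sin(k * u)
            return (x0 + ux * u + nx * off, y0 + uy * u + ny * off)

        def speed(t):
            u = L * t
            return L * math.sqrt(1.0 + (A * k * math.cos(k * u)) ** 2)

        return point, speed
    if kind == "bezier":
        (x0, y0), (x1, y1), (x2, y2) = p["p0"], p["p1"], p["p2"]

        def point(t):
            s = 1 - t
            return (
                s * s * x0 + 2 * s * t * x1 + t * t * x2,
                s * s * y0 + 2 * s * t * y1 + t * t * y2,
            )

        def speed(t):
            s = 1 - t
            dx = 2 * s * (x1 - x0) + 2 * t * (x2 - x1)
            dy = 2 * s * (y1 - y0) + 2 * t * (y2 - y1)
            return math.hypot(dx, dy)

        return point, speed
    raise ValueError(f"unknown curve kind: {kind!r}")


def curve_arc_length(v: VesselSpec) -> float:
    """Analytic arc length: closed form for lines and arcs, quadrature else."""
    p = v.params
    if v.curve_kind == "line":
        return float(p["length"])
    if v.curve_kind == "arc":
        return float(p["radius"] * abs(math.radians(p["theta1_deg"] - p["theta0_deg"])))
    _, speed = _curve_fns(v)
    val, _err = quad(speed, 0.0, 1.0, epsabs=QUAD_TOL, epsrel=QUAD_TOL, limit=200)
    return float(val)


def curve_endpoints(v: VesselSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    point, _ = _curve_fns(v)
    return point(0.0), point(1.0)


def curve_samples(v: VesselSpec, step: float = 0.25) -> np.ndarray:
    """Dense (x, y) samples along the curve, roughly ``step`` px apart."""
    point, _ = _curve_fns(v)
    n = max(2, int(math.ceil(curve_arc_length(v) / step)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    return np.asarray([point(t) for t in ts], dtype=np.float64)


def rasterize_vessel(v: VesselSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a vessel at its width; errors if the curve leaves bounds."""
    pts = curve_samples(v)
    margin = v.width_px // 2
    h, w = shape
    cols = np.round(pts[:, 0]).astype(int)
    rows = np.round(pts[:, 1]).astype(int)
    if (
        rows.min() < margin or rows.max() >= h - margin
        or cols.min() < margin or cols.max() >= w - margin
    ):
        raise ValueError("curve leaves image bounds")
    m = np.zeros(shape, dtype=bool)
    m[rows, cols] = True
    if margin > 0:
        m = morphology.dilation(m, morphology.disk(margin))
    return m


# ---------------------------------------------------------------------------
# Phantom assembly

_BG_RGB = (0.85, 0.55, 0.30)  # fundus-like orange background
_VESSEL_RGB = (0.35, 0.12, 0.08)  # dark red vessels
_OD_RGB = (0.95, 0.88, 0.55)  # bright yellowish disc


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom and its analytic truth table.

    Vessels of each class are rasterized into class masks; the label map
    colors artery-only pixels red, vein-only blue and crossings green.
    The intensity image carries dark vessels over a noisy bright background
    with a bright optic disc.  Optional mask degradation (gaps/spurs) runs
    at the spec's Poisson rates, reproducibly from the seed.
    """
    h, w = spec.image_size
    artery_m = np.zeros((h, w), dtype=bool)
    vein_m = np.zeros((h, w), dtype=bool)
    rows_t = []
    for i, v in enumerate(spec.vessels):
        vm = rasterize_vessel(v, (h, w))
        if v.vessel_class == "artery":
            artery_m |= vm
        elif v.vessel_class == "vein":
            vein_m |= vm
        else:
            raise ValueError(f"unknown vessel class: {v.vessel_class!r}")
        arc = curve_arc_length(v)
        (sx, sy), (ex, ey) = curve_endpoints(v)
        chord = math.hypot(ex - sx, ey - sy)
        rows_t.append(
            {
                "vessel": i,
                "vessel_class": v.vessel_class,
                "curve_kind": v.curve_kind,
                "arc_px": arc,
                "chord_px": chord,
                "tortuosity": arc / chord,
                "start_x": int(round(sx)), "start_y": int(round(sy)),
                "end_x": int(round(ex)), "end_y": int(round(ey)),
            }
        )

    mask = artery_m | vein_m
    if spec.gap_rate > 0 or spec.spur_rate > 0:
        mask = degrade(
            VesselMask(mask, "synthetic"), spec.gap_rate, spec.spur_rate, spec.seed
        ).mask

    # label map: red arteries, blue veins, green crossings
    label_rgb = np.zeros((h, w, 3), dtype=np.float64)
    only_a = artery_m & ~vein_m
    only_v = vein_m & ~artery_m
    both = artery_m & vein_m
    label_rgb[only_a] = (1.0, 0.0, 0.0)
    label_rgb[only_v] = (0.0, 0.0, 1.0)
    label_rgb[both] = (0.0, 1.0, 0.0)

    # intensity image
    rng = np.random.default_rng(spec.seed)
    noise = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    span = noise.max() - noise.min()
    if span > 0:
        noise = (noise - noise.min()) / span - 0.5
    image = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        image[..., c] = _BG_RGB[c] + 0.08 * noise
    rr, cc = np.ogrid[:h, :w]
    cx, cy = spec.od_center_xy
    od_disk = (cc - cx) ** 2 + (rr - cy) ** 2 <= spec.od_radius_px**2
    image[od_disk] = _OD_RGB
    image[artery_m | vein_m] = _VESSEL_RGB
    image = np.clip(image, 0.0, 1.0)

    od = OpticDisc(center_xy=spec.od_center_xy, radius_px=spec.od_radius_px)
    truth = PhantomTruth(table=pd.DataFrame(rows_t))
    return Phantom(
        image=image,
        mask=VesselMask(mask, "synthetic"),
        labels=AVLabelMap.from_rgb(label_rgb),
        od=od,
        truth=truth,
        spec=spec,
        class_masks={"artery": artery_m, "vein": vein_m},
    )


def make_radial_spec(
    seed: int,
    n_vessels: int = 20,
    image_size: tuple[int, int] = (420, 420),
    od_radius_px: float = 35.0,
    width_px: int = 3,
    gap_rate: float = 0.0,
    spur_rate: float = 0.0,
    fov_deg: float = 45.0,
    crossing: bool = True,
) -> PhantomSpec:
    """Radially arranged vessels leaving the optic disc, seeded layout.

    Vessels alternate artery/vein around evenly spaced directions with a
    small angular jitter, so same-class neighbors stay well separated and
    skeletons do not merge.  Curve kinds cycle line / sinusoid / bezier
    with gentle curvature (comparable to healthy retinal arcades); veins
    are drawn with larger sinusoid amplitudes and Bezier offsets than
    arteries, emulating the higher venous tortuosity seen in healthy
    retinas.  Every inner terminus sits 2 px outside the disc, inside the
    start annulus.

    With ``crossing`` (and at least 8 vessels) the last slot becomes a vein
    chord sweeping across the first artery's ray, so the label map carries
    a green artery-vein crossing and the overlap inclusion rule is
    exercised.
    """
    h, w = image_size
    cx, cy = w / 2.0, h / 2.0
    rng = np.random.default_rng(seed)
    kinds = ("line", "sinusoid", "bezier")
    vessels = []
    r0 = od_radius_px + 2.0
    n_radial = n_vessels - 1 if (crossing and n_vessels >= 8) else n_vessels
    artery0_angle = None
    for i in range(n_radial):
        angle = 360.0 * i / n_vessels + float(rng.uniform(-4.0, 4.0))
        if i == 0:
            artery0_angle = angle
        a = math.radians(angle)
        ux, uy = math.cos(a), math.sin(a)
        p0 = (cx + r0 * ux, cy + r0 * uy)
        # max extent along the ray before hitting the frame margin
        margin = width_px // 2 + 8
        lim = min(
            _ray_limit(p0[0], ux, margin, w - 1 - margin),
            _ray_limit(p0[1], uy, margin, h - 1 - margin),
        )
        length = float(min(lim - 2.0, rng.uniform(110.0, 150.0)))
        kind = kinds[i % len(kinds)]
        cls = "artery" if i % 2 == 0 else "vein"
        if kind == "line":
            params = {"p0": p0, "angle_deg": angle, "length": length}
        elif kind == "sinusoid":
            amp_lo, amp_hi = (3.0, 5.0) if cls == "vein" else (1.5, 3.0)
            params = {
                "p0": p0,
                "angle_deg": angle,
                "length": length,
                "amplitude": float(rng.uniform(amp_lo, amp_hi)),
                "wavelength": float(rng.uniform(60.0, 100.0)),
            }
        else:  # bezier
            p2 = (p0[0] + ux * length, p0[1] + uy * length)
            off_lo, off_hi = (10.0, 16.0) if cls == "vein" else (6.0, 10.0)
            off = float(rng.uniform(off_lo, off_hi)) * (1 if i % 4 < 2 else -1)
            pm = (
                (p0[0] + p2[0]) / 2 - uy * off,
                (p0[1] + p2[1]) / 2 + ux * off,
            )
            params = {"p0": p0, "p1": pm, "p2": p2}
        vessels.append(VesselSpec(cls, kind, params, width_px))
    if n_radial < n_vessels:
        # vein chord from 12 degrees below to 10 degrees above the first
        # artery's ray: guaranteed to cross it once at mid-radius
        a_lo = math.radians(artery0_angle - 12.0)
        a_hi = math.radians(artery0_angle + 10.0)
        p0 = (cx + r0 * math.cos(a_lo), cy + r0 * math.sin(a_lo))
        p2 = (cx + 140.0 * math.cos(a_hi), cy + 140.0 * math.sin(a_hi))
        pm = ((p0[0] + p2[0]) / 2, (p0[1] + p2[1]) / 2)
        vessels.append(
            VesselSpec("vein", "bezier", {"p0": p0, "p1": pm, "p2": p2}, width_px)
        )
    return PhantomSpec(
        image_size=image_size,
        od_center_xy=(cx, cy),
        od_radius_px=od_radius_px,
        vessels=tuple(vessels),
        gap_rate=gap_rate,
        spur_rate=spur_rate,
        seed=seed,
        fov_deg=fov_deg,
    )


def _ray_limit(x0: float, u: float, lo: float, hi: float) -> float:
    if u > 1e-9:
        return (hi - x0) / u
    if u < -1e-9:
        return (lo - x0) / u
    return math.inf


def degrade(mask: VesselMask, gap_rate: float, spur_rate: float, seed: int) -> VesselMask:
    """Stress a mask with gaps and spurs at Poisson rates per 100 fg pixels.

    Gaps delete a 1-2 px radius disk around randomly chosen foreground
    pixels (component count can only grow); spurs append 1-3 px runs in a
    random 8-direction from randomly chosen foreground pixels.  Output is
    reproducible from the seed; rates of zero are the identity.
    """
    if not 0 <= gap_rate <= 1 or not 0 <= spur_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    out = mask.mask.copy()
    if gap_rate == 0 and spur_rate == 0:
        return VesselMask(out, mask.provenance)
    rng = np.random.default_rng(seed)
    fg = np.argwhere(out)  # (row, col)
    n_fg = len(fg)
    h, w = out.shape
    n_gaps = rng.poisson(gap_rate * n_fg / 100.0)
    if n_gaps > 0 and n_fg > 0:
        idx = rng.integers(0, n_fg, size=n_gaps)
        for r, c in fg[idx]:
            rad = int(rng.integers(1, 3))
            out[max(0, r - rad): r + rad + 1, max(0, c - rad): c + rad + 1] = False
    n_spurs = rng.poisson(spur_rate * n_fg / 100.0)
    if n_spurs > 0 and n_fg > 0:
        dirs = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)])
        idx = rng.integers(0, n_fg, size=n_spurs)
        for r, c in fg[idx]:
            dr, dc = dirs[rng.integers(0, 8)]
            for step in range(1, int(rng.integers(1, 4)) + 1):
                rr_, cc_ = r + dr * step, c + dc * step
                if 0 <= rr_ < h and 0 <= cc_ < w:
                    out[rr_, cc_] = True
    return VesselMask(out, "synthetic")
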