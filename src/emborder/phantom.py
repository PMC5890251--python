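"""Synthetic two-phase tissue phantoms with analytically known border geometry.

The feather-follicle micrographs this package was designed around show an
epithelial sheet (bright) over mesenchyme (dark), separated by a border that
is either fringed with basal-cell filopodia (pre-branch: each basal cell
extends a handful of thin protrusions, a few microns long, into the
mesenchyme) or smooth and gently scalloped (post-branch).  This module
generates calibrated raster images of that situation together with the exact
polygonal geometry of the border, so the segmentation and tortuosity stages
can be validated against closed-form ground truth.

Coordinate convention: origin at the top-left corner of the domain, x
rightward, y downward, all in micrometres; pixel (row i, col j) has its
center at ((j + 0.5) * px, (i + 0.5) * px).  The epithelium occupies the
region above the border curve (smaller y).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from .errors import InfeasibleDensityError, ParameterError

_ARC_SEGMENTS = 64  # polyline segments per semicircular arc


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one phantom.

    Lengths are in micrometres, intensities on [0, 1].  ``group`` selects the
    border decoration: ``pre_branch`` grows filopodia on a straight base,
    ``post_branch`` grows semicircular scallops, ``custom`` uses the
    filopodia fields as given (zero density means a plain baseline).
    """

    group: str = "pre_branch"
    domain_size_um: tuple[float, float] = (51.2, 25.6)
    pixel_size_um: float = 0.1
    border_depth_um: float = 8.0
    baseline_amplitude_um: float = 0.0
    baseline_period_um: float = 12.8
    # filopodia (pre-branch) ------------------------------------------------
    filopodia_density_per_um: float = 0.4
    filopodia_length_um: tuple[float, float] = (2.0, 10.0)
    filopodia_length_fixed_um: float | None = None
    filopodia_base_width_um: float = 2.0
    filopodia_shape: str = "triangular"  # or "rounded_finger"
    filopodia_jitter: float = 1.0  # 0 = regular grid, 1 = full in-cell jitter
    # scallops (post-branch) ------------------------------------------------
    scallop_radius_um: float = 1.6
    scallop_spacing_um: float = 4.0
    # appearance ------------------------------------------------------------
    intensity_epithelium: float = 0.75
    intensity_mesenchyme: float = 0.35
    noise_sd: float = 0.05
    bias_field: str = "none"  # none | linear | quadratic
    bias_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.group not in ("pre_branch", "post_branch", "custom"):
            errs.append(f"unknown group {self.group!r}")
        w, h = self.domain_size_um
        if w <= 0 or h <= 0:
            errs.append("domain_size_um must be strictly positive")
        if self.pixel_size_um <= 0:
            errs.append("pixel_size_um must be strictly positive")
        if not 0 < self.border_depth_um < h:
            errs.append("border_depth_um must lie inside the domain height")
        lo, hi = self.filopodia_length_um
        if lo <= 0 or hi <= 0 or lo > hi:
            errs.append("filopodia_length_um must satisfy 0 < min <= max")
        if self.filopodia_base_width_um <= 0:
            errs.append("filopodia_base_width_um must be strictly positive")
        if self.filopodia_shape not in ("triangular", "rounded_finger"):
            errs.append(f"unknown filopodia_shape {self.filopodia_shape!r}")
        if self.filopodia_density_per_um < 0:
            errs.append("filopodia_density_per_um must be >= 0")
        if self.scallop_radius_um <= 0 or self.scallop_spacing_um <= 0:
            errs.append("scallop radius and spacing must be strictly positive")
        if self.intensity_epithelium == self.intensity_mesenchyme:
            errs.append("intensity_epithelium must differ from intensity_mesenchyme")
        if self.noise_sd < 0:
            errs.append("noise_sd must be >= 0")
        if self.bias_field not in ("none", "linear", "quadratic"):
            errs.append(f"unknown bias_field {self.bias_field!r}")
        # protrusions must stay inside the domain, or the analytic border
        # geometry would be truncated by the raster
        if self.group in ("pre_branch", "custom") and self.filopodia_density_per_um > 0:
            reach = (self.filopodia_length_fixed_um
                     if self.filopodia_length_fixed_um is not None
                     else self.filopodia_length_um[1])
            if self.border_depth_um + reach > h:
                errs.append("filopodia can extend beyond the domain height; "
                            "increase domain_size_um or border_depth margin")
        if self.group == "post_branch" and (
                self.border_depth_um + self.scallop_radius_um > h):
            errs.append("scallops extend beyond the domain height")
        if errs:
            raise ParameterError("; ".join(errs))


@dataclass
class GroundTruth:
    """Exact border geometry of one phantom.

    ``lambda_um`` is the exact polygonal arc length of ``border_polyline``,
    accumulated in closed form from the generating geometry (triangle sides,
    circular-arc chord sums), never re-measured off a raster.  ``mask`` is
    filled in by :func:`rasterize_phantom`.
    """

    border_polyline: np.ndarray  # (N, 2) vertices (x_um, y_um), open curve
    lambda_um: float
    d_um: float
    ratio: float
    mask: np.ndarray | None = None  # True where epithelium


def _chord_sum(radius: float, sweep: float, n_seg: int) -> float:
    """Exact polygonal length of a circular arc discretized into n_seg chords."""
    return n_seg * 2.0 * radius * math.sin(sweep / (2.0 * n_seg))


def _protrusion_count(density, width, base_width):
    """Requested protrusion count, clamped to the feasible maximum when only
    count rounding (not the density itself) would overflow it."""
    n = int(round(density * width))
    max_n = int(math.floor(width / base_width + 1e-9))
    if n > max_n and density <= 1.0 / base_width + 1e-9:
        n = max_n
    return n


def _protrusion_centers(rng, width, n, base_width, jitter):
    """Jittered-grid placement: one protrusion per cell, bases never overlap."""
    s = width / n
    if s < base_width - 1e-9:
        raise InfeasibleDensityError(
            f"cannot place {n} protrusions of base width {base_width} um on a "
            f"{width} um border without overlap; maximum feasible density is "
            f"{1.0 / base_width:.4g} per um ({math.floor(width / base_width)} protrusions)"
        )
    half_slack = max(0.0, (s - base_width) / 2.0)
    offsets = rng.uniform(-half_slack, half_slack, size=n) * jitter
    return (np.arange(n) + 0.5) * s + offsets


class _PolylineBuilder:
    """Accumulates vertices, silently dropping consecutive duplicates."""

    def __init__(self):
        self.pts: list[tuple[float, float]] = []

    def add(self, x, y):
        if self.pts:
            px, py = self.pts[-1]
            if abs(px - x) < 1e-12 and abs(py - y) < 1e-12:
                return
        self.pts.append((float(x), float(y)))

    def array(self):
        return np.asarray(self.pts, dtype=float)


def generate_border(spec: PhantomSpec) -> GroundTruth:
    """Build the border polyline and its exact length statistics.

    Returns an open polyline spanning the full domain width, with λ (arc
    length), d (endpoint distance) and their ratio computed in closed form.
    """
    spec.validate()
    width, _ = spec.domain_size_um
    y0 = spec.border_depth_um
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])

    # pre_branch/custom use the filopodia family (custom with zero density is
    # a plain baseline); post_branch uses scallops.
    use_filopodia = spec.group in ("pre_branch", "custom") and (
        spec.filopodia_density_per_um > 0
    )
    use_scallops = spec.group == "post_branch"

    b = _PolylineBuilder()
    lam = 0.0

    if spec.baseline_amplitude_um > 0:
        if use_filopodia or use_scallops:
            raise ParameterError(
                "a sinusoidal baseline cannot be combined with protrusions"
            )
        amp, per = spec.baseline_amplitude_um, spec.baseline_period_um
        n = max(2, int(math.ceil(width / per * 128)))
        xs = np.linspace(0.0, width, n + 1)
        ys = y0 + amp * np.sin(2.0 * math.pi * xs / per)
        for x, y in zip(xs, ys):
            b.add(x, y)
        for i in range(n):
            lam += math.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])
    elif use_filopodia and spec.filopodia_density_per_um > 0:
        w_base = spec.filopodia_base_width_um
        n = _protrusion_count(spec.filopodia_density_per_um, width, w_base)
        if n == 0:
            b.add(0.0, y0)
            b.add(width, y0)
            lam = width
        else:
            centers = np.sort(
                _protrusion_centers(rng, width, n, w_base, spec.filopodia_jitter)
            )
            if spec.filopodia_length_fixed_um is not None:
                lengths = np.full(n, spec.filopodia_length_fixed_um)
            else:
                lo, hi = spec.filopodia_length_um
                lengths = rng.uniform(lo, hi, size=n)
            b.add(0.0, y0)
            for c, length in zip(centers, lengths):
                r = w_base / 2.0
                b.add(c - r, y0)
                if spec.filopodia_shape == "triangular":
                    b.add(c, y0 + length)
                    lam += 2.0 * math.hypot(r, length)
                else:  # rounded_finger: straight sides + semicircular cap
                    if length <= r:
                        raise ParameterError(
                            "rounded_finger filopodia need length > base_width/2"
                        )
                    stem = length - r
                    b.add(c - r, y0 + stem)
                    cy = y0 + stem
                    for k in range(1, _ARC_SEGMENTS):
                        th = math.pi - k * math.pi / _ARC_SEGMENTS
                        b.add(c + r * math.cos(th), cy + r * math.sin(th))
                    b.add(c + r, cy)
                    lam += 2.0 * stem + _chord_sum(r, math.pi, _ARC_SEGMENTS)
                b.add(c + r, y0)
            b.add(width, y0)
            lam += width - n * w_base  # flat base between protrusions
    elif use_scallops:
        r, spacing = spec.scallop_radius_um, spec.scallop_spacing_um
        if spacing < 2.0 * r:
            raise ParameterError("scallop_spacing_um must be >= 2 * scallop_radius_um")
        n = int(math.floor(width / spacing + 1e-9))
        centers = (np.arange(n) + 0.5) * spacing
        b.add(0.0, y0)
        for c in centers:
            b.add(c - r, y0)
            for k in range(1, _ARC_SEGMENTS):
                th = k * math.pi / _ARC_SEGMENTS
                b.add(c - r * math.cos(th), y0 + r * math.sin(th))
            b.add(c + r, y0)
        b.add(width, y0)
        lam = (width - n * 2.0 * r) + n * _chord_sum(r, math.pi, _ARC_SEGMENTS)
    else:
        b.add(0.0, y0)
        b.add(width, y0)
        lam = width

    pts = b.array()
    d = math.hypot(pts[-1, 0] - pts[0, 0], pts[-1, 1] - pts[0, 1])
    truth = GroundTruth(
        border_polyline=pts, lambda_um=lam, d_um=d, ratio=lam / d
    )
    assert truth.ratio >= 1.0 - 1e-12
    return truth


def epithelium_polygon(truth: GroundTruth, spec: PhantomSpec) -> Polygon:
    """Closed polygon of the epithelial phase (above the border curve)."""
    width, _ = spec.domain_size_um
    ring = [(0.0, 0.0), (width, 0.0)] + [
        (x, y) for x, y in truth.border_polyline[::-1]
    ]
    return Polygon(ring)


def rasterize_phantom(
    truth: GroundTruth, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Render the phantom to a calibrated image and its noise-free phase mask.

    Each pixel takes the intensity of the phase containing its center, plus
    the optional bias field and seeded Gaussian noise, clipped to [0, 1].
    """
    spec.validate()
    px = spec.pixel_size_um
    width, height = spec.domain_size_um
    ncols = int(round(width / px))
    nrows = int(round(height / px))

    narrowest = (
        spec.filopodia_base_width_um
        if spec.group == "pre_branch" or (spec.group == "custom"
                                          and spec.filopodia_density_per_um > 0)
        else 2.0 * spec.scallop_radius_um
    )
    if narrowest < 3.0 * px:
        warnings.warn(
            f"narrowest protrusion ({narrowest} um) spans fewer than 3 pixels "
            f"at {px} um/px; geometry will be poorly resolved",
            stacklevel=2,
        )

    poly = epithelium_polygon(truth, spec)
    shapely.prepare(poly)
    xc = (np.arange(ncols) + 0.5) * px
    yc = (np.arange(nrows) + 0.5) * px
    xx, yy = np.meshgrid(xc, yc)
    mask = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(nrows, ncols)

    img = np.where(mask, spec.intensity_epithelium, spec.intensity_mesenchyme).astype(
        float
    )
    if spec.bias_field != "none" and spec.bias_amplitude != 0:
        u = xx / width - 0.5
        v = yy / height - 0.5
        if spec.bias_field == "linear":
            img += spec.bias_amplitude * u
        else:  # quadratic bowl, range [-A/2, A/2]
            img += spec.bias_amplitude * (2.0 * (u**2 + v**2) - 0.25)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth.mask = mask
    return img, mask


def spec_for_ratio(
    ratio: float,
    base_width_um: float = 5.0,
    width_um: float = 25.0,
    pixel_size_um: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """A contiguous-sawtooth phantom whose analytic λ/d equals ``ratio`` exactly.

    Teeth of base ``w`` and height ``(w/2)·sqrt(ratio² − 1)`` tile the border
    with no flat gaps, giving λ/d = sqrt(1 + (2h/w)²) = ratio in closed form.
    ``width_um`` must be an integer multiple of ``base_width_um``.  The default
    tooth base is wide enough that the sub-pixel slivers at tips and valleys
    (which a raster cannot carry) cost well under 10% of λ at 0.2 μm/px.
    """
    if ratio < 1.0:
        raise ParameterError("ratio must be >= 1")
    w = base_width_um
    n = width_um / w
    if abs(n - round(n)) > 1e-9:
        raise ParameterError("width_um must be a multiple of base_width_um")
    length = (w / 2.0) * math.sqrt(ratio**2 - 1.0)
    depth = 4.0
    height = depth + length + 4.0
    return PhantomSpec(
        group="custom",
        domain_size_um=(width_um, height),
        pixel_size_um=pixel_size_um,
        border_depth_um=depth,
        filopodia_density_per_um=0.0 if length == 0 else 1.0 / w,
        filopodia_length_fixed_um=None if length == 0 else length,
        filopodia_base_width_um=w,
        filopodia_shape="triangular",
        filopodia_jitter=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_dataset(
    n_pre: int,
    n_post: int,
    out_dir: str | Path,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    vary: bool = True,
):
    """Generate a two-group phantom collection with its ground-truth table.

    Emulates the published study design of ten follicles per group: pre-branch
    phantoms draw a per-phantom filopodia density in the 3–5 per 10 μm range
    and per-filopodium lengths from U(2, 10) μm; post-branch phantoms draw a
    scallop radius and spacing.  Writes 16-bit TIFF images, 8-bit PNG masks,
    a ground-truth CSV and a JSON spec index; returns the table and paths.
    """
    if n_pre < 1 or n_post < 1:
        raise ParameterError("n_pre and n_post must both be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_pre + n_post)
    rows, specs, items = [], {}, []
    for i in range(n_pre + n_post):
        group = "pre_branch" if i < n_pre else "post_branch"
        pid = f"pre_{i:02d}" if i < n_pre else f"post_{i - n_pre:02d}"
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(children[i])
        overrides = {"group": group, "seed": child_seed}
        if vary:
            if group == "pre_branch":
                overrides["filopodia_density_per_um"] = float(rng.uniform(0.3, 0.5))
            else:
                r = float(rng.uniform(1.2, 2.0))
                overrides["scallop_radius_um"] = r
                overrides["scallop_spacing_um"] = 2.0 * r + float(rng.uniform(0.8, 2.0))
        spec = replace(base, **overrides)
        truth = generate_border(spec)
        img, mask = rasterize_phantom(truth, spec)
        img_path = out_dir / "images" / f"{pid}.tif"
        mask_path = out_dir / "masks" / f"{pid}.png"
        tifffile.imwrite(img_path, np.round(img * 65535).astype(np.uint16))
        iio.imwrite(mask_path, (mask.astype(np.uint8) * 255))
        rows.append(
            {
                "id": pid,
                "group": "pre" if group == "pre_branch" else "post",
                "lambda_um": truth.lambda_um,
                "d_um": truth.d_um,
                "ratio": truth.ratio,
                "seed": child_seed,
            }
        )
        specs[pid] = asdict(spec)
        items.append((pid, spec, truth))

    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    with open(out_dir / "specs.json", "w") as fh:
        json.dump(specs, fh, indent=1)
    return table, {"dir": out_dir, "items": items}
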