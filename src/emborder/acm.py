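"""Hybrid local-global region-based active contour (level-set) segmentation.

The model segments a two-phase image I : Ω → R by evolving a level-set
function φ whose zero level set is the contour.  The energy combines the
two-phase piecewise-constant (Chan–Vese) data terms, weighted λ₁/λ₂,

    λ₁ ∫ |I − c₁|² H(φ) dx  +  λ₂ ∫ |I − c₂|² (1 − H(φ)) dx,

with kernel-weighted local binary fitting terms, weighted η₁/η₂,

    η₁ ∫∫ K_σ(x−y) |I(y) − f₁(x)|² H(φ(y)) dy dx
  + η₂ ∫∫ K_σ(x−y) |I(y) − f₂(x)|² (1 − H(φ(y))) dy dx,

plus the contour-length regularizer ν ∫ δ(φ) |∇φ| dx.  The local fitted
intensities f₁, f₂ absorb smooth intensity inhomogeneity (bias fields) that
defeats the global constants c₁, c₂.

Membership is smoothed with the arctan-regularized Heaviside
H_ε(x) = ½(1 + (2/π)·arctan(x/ε)) and its derivative
δ_ε(x) = (1/π)·ε/(ε² + x²); K_σ is an isotropic Gaussian.

Minimization alternates closed-form updates of (c₁, c₂, f₁, f₂) with
gradient-descent steps φ ← φ − α·∇_φF.  The descent field implemented here
is the exact gradient of the *discrete* energy (pixel sums, central
differences), which is what the finite-difference consistency tests check.

All quantities are in pixel units internally (σ and ε in px, integrals as
plain pixel sums); physical calibration enters only in the boundary module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d, gaussian_filter
from skimage.filters import threshold_otsu

from .errors import (
    DegeneratePhaseError,
    DivergenceError,
    ParameterError,
)

log = logging.getLogger(__name__)

_GRAD_EPS_DEFAULT = 0.05  # smoothing of |∇φ| in the length term (px units)
_FIT_FLOOR = 1e-8  # floor on local-fit denominators, as fraction of kernel mass
_PHASE_FLOOR = 1e-6  # minimum mean Heaviside mass per phase


@dataclass(frozen=True)
class ACMParams:
    """Energy and evolution coefficients.

    sigma and epsilon are in pixels.  ``smooth_phi`` applies a mild Gaussian
    smoothing of φ after each descent step (a standard stabilization for
    local-fitting level sets); switch it off to run the verbatim fixed-step
    iteration.
    """

    lambda1: float = 0.2
    lambda2: float = 0.2
    eta1: float = 1.0
    eta2: float = 1.0
    nu: float = 1.0
    sigma: float = 3.0
    epsilon: float = 1.0
    alpha: float = 0.1
    max_iter: int = 500
    tol: float = 1e-6
    tol_window: int = 5
    min_iter: int = 300
    stationary_window: int = 50
    grad_eps: float = _GRAD_EPS_DEFAULT
    kernel_truncation: float = 4.0
    smooth_phi: bool = False
    smooth_phi_sd: float = 0.5
    phi_clip: float | None = None

    def validate(self) -> None:
        errs = []
        for name in ("lambda1", "lambda2", "eta1", "eta2", "nu"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        for name in ("sigma", "epsilon", "alpha", "tol", "smooth_phi_sd"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be > 0")
        if self.max_iter < 1:
            errs.append("max_iter must be >= 1")
        if self.tol_window < 1:
            errs.append("tol_window must be >= 1")
        if self.stationary_window < 1:
            errs.append("stationary_window must be >= 1")
        if self.min_iter < 0:
            errs.append("min_iter must be >= 0")
        if self.grad_eps <= 0:
            errs.append("grad_eps must be > 0")
        if self.phi_clip is not None and self.phi_clip <= 0:
            errs.append("phi_clip must be > 0 when set")
        if self.kernel_truncation <= 0:
            errs.append("kernel_truncation must be > 0")
        if errs:
            raise ParameterError("; ".join(errs))


@dataclass
class FitState:
    """Optimal intensity fits for the current φ: global c₁/c₂, local f₁/f₂."""

    c1: float
    c2: float
    f1: np.ndarray
    f2: np.ndarray


@dataclass
class EnergyTrace:
    """Per-iteration total energy and its five components."""

    iteration: list[int] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    global1: list[float] = field(default_factory=list)
    global2: list[float] = field(default_factory=list)
    local1: list[float] = field(default_factory=list)
    local2: list[float] = field(default_factory=list)
    length: list[float] = field(default_factory=list)

    def append(self, k, comps):
        g1, g2, l1, l2, ln = comps
        self.iteration.append(k)
        self.global1.append(g1)
        self.global2.append(g2)
        self.local1.append(l1)
        self.local2.append(l2)
        self.length.append(ln)
        self.total.append(g1 + g2 + l1 + l2 + ln)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "total": self.total,
                "global1": self.global1,
                "global2": self.global2,
                "local1": self.local1,
                "local2": self.local2,
                "length": self.length,
            }
        )


# ---------------------------------------------------------------------------
# primitives


def heaviside_eps(x, epsilon: float):
    """Arctan-regularized Heaviside H_ε(x) = ½(1 + (2/π) arctan(x/ε))."""
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(x, dtype=float) / epsilon))


def dirac_eps(x, epsilon: float):
    """δ_ε(x) = (1/π) · ε / (ε² + x²), the derivative of H_ε."""
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    x = np.asarray(x, dtype=float)
    return (epsilon / np.pi) / (epsilon**2 + x**2)


def dirac_eps_prime(x, epsilon: float):
    """d/dx δ_ε(x) = −(2εx/π) / (ε² + x²)²."""
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    x = np.asarray(x, dtype=float)
    return -(2.0 * epsilon * x / np.pi) / (epsilon**2 + x**2) ** 2


def gaussian_kernel(sigma: float, truncation: float = 4.0) -> np.ndarray:
    """Discrete 2-D Gaussian on a (2⌈truncation·σ⌉+1)² support, sum exactly 1."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    k1 = _gaussian_taps(sigma, truncation)
    k2 = np.outer(k1, k1)
    return k2 / k2.sum()


def _gaussian_taps(sigma: float, truncation: float) -> np.ndarray:
    radius = int(np.ceil(truncation * sigma))
    t = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(t**2) / (2.0 * sigma**2))
    return k / k.sum()


def _kconv(field, taps):
    """Zero-padded separable convolution with the Gaussian taps.

    Zero padding makes the discrete double-sum local energy an exactly
    symmetric quadratic form over Ω×Ω, so its analytic gradient is the exact
    adjoint; the f-fields are ratios of two such convolutions and therefore
    renormalize themselves near the image edge (normalized convolution).
    """
    out = convolve1d(np.asarray(field, dtype=float), taps, axis=0, mode="constant")
    return convolve1d(out, taps, axis=1, mode="constant")


def _central_diff_pad(f, axis):
    """Central difference with replicate (edge-clamp) padding, h = 1 px."""
    g = np.empty_like(f, dtype=float)
    if axis == 0:
        g[1:-1, :] = 0.5 * (f[2:, :] - f[:-2, :])
        g[0, :] = 0.5 * (f[1, :] - f[0, :])
        g[-1, :] = 0.5 * (f[-1, :] - f[-2, :])
    else:
        g[:, 1:-1] = 0.5 * (f[:, 2:] - f[:, :-2])
        g[:, 0] = 0.5 * (f[:, 1] - f[:, 0])
        g[:, -1] = 0.5 * (f[:, -1] - f[:, -2])
    return g


def _central_diff_adjoint(a, axis):
    """Exact transpose of the replicate-padded central-difference operator."""
    g = -_central_diff_pad(a, axis)
    if axis == 0:
        g[0, :] = -0.5 * (a[0, :] + a[1, :])
        g[-1, :] = 0.5 * (a[-2, :] + a[-1, :])
    else:
        g[:, 0] = -0.5 * (a[:, 0] + a[:, 1])
        g[:, -1] = 0.5 * (a[:, -2] + a[:, -1])
    return g


# ---------------------------------------------------------------------------
# coefficient updates


def update_global_means(image, phi, epsilon: float) -> tuple[float, float]:
    """H_ε-weighted inside/outside means c₁, c₂ of the image."""
    image = np.asarray(image, dtype=float)
    h = heaviside_eps(phi, epsilon)
    m1 = float(h.mean())
    m2 = float((1.0 - h).mean())
    if m1 < _PHASE_FLOOR:
        raise DegeneratePhaseError(
            f"inside phase (phi > 0) has near-zero Heaviside mass ({m1:.3g})"
        )
    if m2 < _PHASE_FLOOR:
        raise DegeneratePhaseError(
            f"outside phase (phi < 0) has near-zero Heaviside mass ({m2:.3g})"
        )
    c1 = float((image * h).sum() / h.sum())
    c2 = float((image * (1.0 - h)).sum() / (1.0 - h).sum())
    return c1, c2


def update_local_fits(image, phi, epsilon: float, sigma: float,
                      truncation: float = 4.0,
                      fallback: tuple[float, float] | None = None):
    """Kernel-weighted local inside/outside intensity fits f₁, f₂.

    Pixels whose denominator convolution falls below the floor take the
    global mean as fallback (logged); this only happens when one phase is
    locally absent over the whole kernel support.
    """
    image = np.asarray(image, dtype=float)
    taps = _gaussian_taps(sigma, truncation)
    h = heaviside_eps(phi, epsilon)
    num1 = _kconv(h * image, taps)
    den1 = _kconv(h, taps)
    num2 = _kconv((1.0 - h) * image, taps)
    den2 = _kconv(1.0 - h, taps)
    if fallback is None:
        fallback = update_global_means(image, phi, epsilon)
    f1 = _safe_ratio(num1, den1, fallback[0], "f1")
    f2 = _safe_ratio(num2, den2, fallback[1], "f2")
    return f1, f2


def _safe_ratio(num, den, fallback_value, name):
    bad = den < _FIT_FLOOR
    if bad.any():
        log.debug("%s: %d pixels below denominator floor, using global mean",
                  name, int(bad.sum()))
    out = np.where(bad, fallback_value, num / np.where(bad, 1.0, den))
    return out


def update_fit(image, phi, params: ACMParams) -> FitState:
    """All four optimal coefficients for the current φ."""
    c1, c2 = update_global_means(image, phi, params.epsilon)
    f1, f2 = update_local_fits(
        image, phi, params.epsilon, params.sigma, params.kernel_truncation,
        fallback=(c1, c2),
    )
    return FitState(c1=c1, c2=c2, f1=f1, f2=f2)


# ---------------------------------------------------------------------------
# energy and gradient


def energy_components(image, phi, fit: FitState, params: ACMParams):
    """The five energy components (global₁, global₂, local₁, local₂, length).

    The double-integral local terms are evaluated with the convolution
    identity (expanding |I(y) − f(x)|² into three convolutions), which equals
    the literal double sum exactly.
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if image.shape != phi.shape:
        raise ParameterError("image and phi shapes differ")
    p = params
    h = heaviside_eps(phi, p.epsilon)
    g1 = p.lambda1 * float(((image - fit.c1) ** 2 * h).sum())
    g2 = p.lambda2 * float(((image - fit.c2) ** 2 * (1.0 - h)).sum())

    taps = _gaussian_taps(p.sigma, p.kernel_truncation)
    # Σ_x Σ_y K(x−y)(I(y) − f(x))² w(y)  with w = H or 1−H:
    #   Σ_x [ K*(I²w) − 2 f K*(Iw) + f² K*(w) ](x)
    a1 = _kconv(h, taps)
    b1 = _kconv(h * image, taps)
    c1c = _kconv(h * image**2, taps)
    l1 = p.eta1 * float((c1c - 2.0 * fit.f1 * b1 + fit.f1**2 * a1).sum())
    a2 = _kconv(1.0 - h, taps)
    b2 = _kconv((1.0 - h) * image, taps)
    c2c = _kconv((1.0 - h) * image**2, taps)
    l2 = p.eta2 * float((c2c - 2.0 * fit.f2 * b2 + fit.f2**2 * a2).sum())

    gx = _central_diff_pad(phi, 1)
    gy = _central_diff_pad(phi, 0)
    # |∇φ| is smoothed as sqrt(|∇φ|² + e²): the raw magnitude is kinked at
    # flat regions, which makes a fixed-step descent oscillate; the same
    # regularized density is used in the gradient, keeping them consistent.
    mag = np.sqrt(gx**2 + gy**2 + p.grad_eps**2)
    ln = p.nu * float((dirac_eps(phi, p.epsilon) * mag).sum())
    # squared terms can dip epsilon-negative through float cancellation
    return (max(g1, 0.0), max(g2, 0.0), max(l1, 0.0), max(l2, 0.0), ln)


def energy(image, phi, fit: FitState, params: ACMParams) -> float:
    """Total energy F(φ, c₁, c₂, f₁, f₂)."""
    return float(sum(energy_components(image, phi, fit, params)))


def gradient(image, phi, fit: FitState, params: ACMParams) -> np.ndarray:
    """∂F/∂φ with the coefficients (c₁, c₂, f₁, f₂) held fixed.

    Data terms: δ_ε(φ)·[λ₁(I−c₁)² − λ₂(I−c₂)² + η₁e₁ − η₂e₂] where
    e_i(x) = ∫ K_σ(x−y)|I(x) − f_i(y)|² dy, evaluated via three convolutions.
    Length term: the exact discrete gradient of Σ δ_ε(φ)|∇φ|, which is
    δ'_ε(φ)|∇φ| plus the adjoint central differences of δ_ε(φ)·∇φ/|∇φ| — the
    discrete counterpart of −δ_ε(φ)·div(∇φ/|∇φ|).
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    p = params
    d = dirac_eps(phi, p.epsilon)

    data = p.lambda1 * (image - fit.c1) ** 2 - p.lambda2 * (image - fit.c2) ** 2
    if p.eta1 > 0 or p.eta2 > 0:
        taps = _gaussian_taps(p.sigma, p.kernel_truncation)
        kones = _kconv(np.ones_like(image), taps)
        if p.eta1 > 0:
            e1 = image**2 * kones - 2.0 * image * _kconv(fit.f1, taps) + _kconv(
                fit.f1**2, taps
            )
            data = data + p.eta1 * e1
        if p.eta2 > 0:
            e2 = image**2 * kones - 2.0 * image * _kconv(fit.f2, taps) + _kconv(
                fit.f2**2, taps
            )
            data = data - p.eta2 * e2
    grad = d * data

    if p.nu > 0:
        gx = _central_diff_pad(phi, 1)
        gy = _central_diff_pad(phi, 0)
        mag = np.sqrt(gx**2 + gy**2 + p.grad_eps**2)
        grad = grad + p.nu * (
            dirac_eps_prime(phi, p.epsilon) * mag
            + _central_diff_adjoint(d * gx / mag, 1)
            + _central_diff_adjoint(d * gy / mag, 0)
        )
    return grad


# ---------------------------------------------------------------------------
# evolution


def evolve(image, phi0, params: ACMParams | None = None):
    """Alternate coefficient updates with fixed-step gradient descent on φ.

    Convergence is declared when either (a) the relative energy change stays
    below ``tol`` for ``tol_window`` consecutive iterations, or (b) the zero
    level set — the contour itself — has not moved for ``stationary_window``
    consecutive iterations.  The second signal matters in practice: with the
    heavy-tailed arctan Heaviside the energy keeps creeping downhill at a
    slow power-law rate long after the contour has frozen, so a pure
    energy-change rule either never fires or fires spuriously early.
    Returns (phi_final, EnergyTrace, converged).
    """
    params = params or ACMParams()
    params.validate()
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi0, dtype=float).copy()
    if image.shape != phi.shape:
        raise ParameterError("phi0 shape does not match image")
    if not np.all(np.isfinite(image)):
        raise ParameterError("image contains non-finite values")

    trace = EnergyTrace()
    converged = False
    quiet = 0
    still = 0
    prev = None
    prev_sign = phi > 0
    for k in range(params.max_iter):
        fit = update_fit(image, phi, params)
        comps = energy_components(image, phi, fit, params)
        total = sum(comps)
        if not np.isfinite(total):
            raise DivergenceError(
                f"non-finite energy at iteration {k}; try a smaller alpha"
            )
        trace.append(k, comps)
        if prev is not None:
            rel = abs(total - prev) / max(abs(prev), 1e-30)
            quiet = quiet + 1 if rel < params.tol else 0
            if quiet >= params.tol_window:
                converged = True
                break
        prev = total
        phi = phi - params.alpha * gradient(image, phi, fit, params)
        if params.smooth_phi:
            phi = gaussian_filter(phi, params.smooth_phi_sd, mode="nearest")
        if params.phi_clip is not None:
            # projected descent: clamping |φ| stops far-field saturation from
            # freezing the contour when large displacements must be covered
            phi = np.clip(phi, -params.phi_clip, params.phi_clip)
        sign = phi > 0
        still = still + 1 if np.array_equal(sign, prev_sign) else 0
        prev_sign = sign
        if still >= params.stationary_window and k + 1 >= params.min_iter:
            converged = True
            break
    return phi, trace, converged


def initial_phi(image, init="otsu", c0: float = 2.0, shape_spec=None) -> np.ndarray:
    """Build φ₀: a ±c₀ binary step from an Otsu threshold (default), the
    signed distance to a user rectangle/circle, or a ±c₀ step from a mask."""
    image = np.asarray(image, dtype=float)
    if isinstance(init, np.ndarray):
        if init.shape != image.shape:
            raise ParameterError("init mask shape does not match image")
        return np.where(init.astype(bool), c0, -c0)
    if init == "otsu":
        if np.ptp(image) == 0:
            raise DegeneratePhaseError("image is constant; cannot threshold")
        t = threshold_otsu(image)
        return np.where(image > t, c0, -c0).astype(float)
    nrows, ncols = image.shape
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    if init == "circle":
        cy, cx, r = shape_spec if shape_spec else (nrows / 2, ncols / 2,
                                                   min(nrows, ncols) / 4)
        return (r - np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)).astype(float)
    if init == "rectangle":
        r0, c0_, r1, c1 = shape_spec if shape_spec else (
            nrows // 4, ncols // 4, 3 * nrows // 4, 3 * ncols // 4)
        inside = (yy >= r0) & (yy < r1) & (xx >= c0_) & (xx < c1)
        d_in = np.minimum.reduce([yy - r0, r1 - 1 - yy, xx - c0_, c1 - 1 - xx])
        d_out = -np.maximum.reduce([r0 - yy, yy - (r1 - 1), c0_ - xx, xx - (c1 - 1)])
        return np.where(inside, d_in + 0.5, d_out - 0.5).astype(float)
    raise ParameterError(f"unknown initialization {init!r}")


@dataclass
class SegmentationResult:
    mask: np.ndarray  # True for the epithelial phase
    phi: np.ndarray
    trace: EnergyTrace
    converged: bool
    flipped: bool  # True if phases were swapped to honor the polarity


def segment(image, params: ACMParams | None = None, init="otsu",
            polarity: str = "bright", c0: float = 2.0,
            shape_spec=None) -> SegmentationResult:
    """Segment a two-phase image; the returned mask is the epithelial phase.

    ``polarity`` declares which phase is epithelium: "bright" (default) or
    "dark".  If the evolved inside phase (φ > 0) does not match, the mask is
    flipped (logged).
    """
    if polarity not in ("bright", "dark"):
        raise ParameterError("polarity must be 'bright' or 'dark'")
    image = np.asarray(image, dtype=float)
    phi0 = initial_phi(image, init=init, c0=c0, shape_spec=shape_spec)
    phi, trace, converged = evolve(image, phi0, params)
    mask = phi > 0
    if mask.all() or not mask.any():
        raise DegeneratePhaseError("segmentation collapsed to a single phase")
    mean_in = image[mask].mean()
    mean_out = image[~mask].mean()
    want_bright = polarity == "bright"
    flipped = (mean_in > mean_out) != want_bright
    if flipped:
        log.info("flipping phases so the %s phase is epithelium", polarity)
        mask = ~mask
        phi = -phi
    return SegmentationResult(mask=mask, phi=phi, trace=trace,
                              converged=converged, flipped=flipped)
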