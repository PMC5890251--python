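"""Independent brute-force oracles used by the test suite.

Everything here is written as literally as possible (explicit loops, direct
formulas) and never calls the implementation it is used to check.
"""

import math

import numpy as np


def polyline_length(vertices) -> float:
    """Arc length by direct per-segment accumulation."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(len(v) - 1):
        total += math.hypot(v[i + 1, 0] - v[i, 0], v[i + 1, 1] - v[i, 1])
    return total


def shoelace_area(vertices) -> float:
    """Polygon area by the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    s = 0.0
    for i in range(len(v)):
        x0, y0 = v[i]
        x1, y1 = v[(i + 1) % len(v)]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def heaviside(x, eps):
    return 0.5 * (1.0 + (2.0 / math.pi) * math.atan(x / eps))


def dirac(x, eps):
    return (1.0 / math.pi) * eps / (eps**2 + x**2)


def gauss_kernel_2d(sigma, truncation):
    r = int(np.ceil(truncation * sigma))
    k = np.zeros((2 * r + 1, 2 * r + 1))
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            k[i + r, j + r] = math.exp(-(i * i + j * j) / (2 * sigma**2))
    return k / k.sum()


def naive_energy(image, phi, c1, c2, f1, f2, lam1, lam2, eta1, eta2, nu,
                 sigma, truncation, eps, grad_eps):
    """Literal term-by-term re-summation of the five energy components.

    The local terms are evaluated as the explicit double sum over pixel
    pairs within the kernel support, pairs outside the image contributing
    nothing (the domain of integration is the image).
    """
    nr, nc = image.shape
    h = np.array([[heaviside(phi[i, j], eps) for j in range(nc)]
                  for i in range(nr)])
    g1 = lam1 * sum((image[i, j] - c1) ** 2 * h[i, j]
                    for i in range(nr) for j in range(nc))
    g2 = lam2 * sum((image[i, j] - c2) ** 2 * (1 - h[i, j])
                    for i in range(nr) for j in range(nc))

    kern = gauss_kernel_2d(sigma, truncation)
    r = kern.shape[0] // 2
    l1 = l2 = 0.0
    for i in range(nr):
        for j in range(nc):
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    yi, yj = i + di, j + dj
                    if not (0 <= yi < nr and 0 <= yj < nc):
                        continue
                    k = kern[di + r, dj + r]
                    l1 += eta1 * k * (image[yi, yj] - f1[i, j]) ** 2 * h[yi, yj]
                    l2 += eta2 * k * (image[yi, yj] - f2[i, j]) ** 2 * (
                        1 - h[yi, yj])

    ln = 0.0
    for i in range(nr):
        for j in range(nc):
            jm, jp = max(j - 1, 0), min(j + 1, nc - 1)
            im, ip = max(i - 1, 0), min(i + 1, nr - 1)
            gx = 0.5 * (phi[i, jp] - phi[i, jm])
            gy = 0.5 * (phi[ip, j] - phi[im, j])
            ln += nu * dirac(phi[i, j], eps) * math.sqrt(
                gx * gx + gy * gy + grad_eps**2)
    return g1, g2, l1, l2, ln


def naive_local_gradient_term(image, phi, f, sigma, truncation, eps):
    """δ_ε(φ(z)) · Σ_x K(x−z) (I(z) − f(x))² by direct double loop."""
    nr, nc = image.shape
    kern = gauss_kernel_2d(sigma, truncation)
    r = kern.shape[0] // 2
    out = np.zeros_like(image, dtype=float)
    for i in range(nr):
        for j in range(nc):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    xi, xj = i + di, j + dj
                    if not (0 <= xi < nr and 0 <= xj < nc):
                        continue
                    acc += kern[di + r, dj + r] * (
                        image[i, j] - f[xi, xj]) ** 2
            out[i, j] = dirac(phi[i, j], eps) * acc
    return out


# --- from-scratch two-phase piecewise-constant (Chan-Vese) oracle ----------


def cv_means(image, phi, eps):
    nr, nc = image.shape
    num1 = den1 = num2 = den2 = 0.0
    for i in range(nr):
        for j in range(nc):
            h = heaviside(phi[i, j], eps)
            num1 += image[i, j] * h
            den1 += h
            num2 += image[i, j] * (1 - h)
            den2 += 1 - h
    return num1 / den1, num2 / den2


def cv_energy(image, phi, c1, c2, lam1, lam2, nu, eps, grad_eps):
    g1, g2, _, _, ln = naive_energy(
        image, phi, c1, c2, np.zeros_like(image), np.zeros_like(image),
        lam1, lam2, 0.0, 0.0, nu, 1.0, 1.0, eps, grad_eps)
    return g1 + g2 + ln


def cv_gradient(image, phi, c1, c2, lam1, lam2, nu, eps, grad_eps):
    """Exact gradient of the discrete two-phase energy, coded from scratch.

    Data part: δ_ε(φ)(λ1(I−c1)² − λ2(I−c2)²).  Length part: differentiate
    Σ_p δ_ε(φ_p)·sqrt(gx_p²+gy_p²+e²) w.r.t. each pixel by explicit
    accumulation of every stencil dependency.
    """
    nr, nc = image.shape
    grad = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            d = dirac(phi[i, j], eps)
            grad[i, j] = d * (lam1 * (image[i, j] - c1) ** 2
                              - lam2 * (image[i, j] - c2) ** 2)
    if nu == 0:
        return grad
    # dependencies of gx_p, gy_p on neighbours (replicate padding)
    def mag_terms(i, j):
        jm, jp = max(j - 1, 0), min(j + 1, nc - 1)
        im, ip = max(i - 1, 0), min(i + 1, nr - 1)
        gx = 0.5 * (phi[i, jp] - phi[i, jm])
        gy = 0.5 * (phi[ip, j] - phi[im, j])
        return jm, jp, im, ip, gx, gy

    for i in range(nr):
        for j in range(nc):
            jm, jp, im, ip, gx, gy = mag_terms(i, j)
            mag = math.sqrt(gx * gx + gy * gy + _GRAD_EPS**2)
            w = dirac(phi[i, j], eps)
            # δ'_ε(φ_p)·mag contribution at p itself
            dd = -(2 * eps * phi[i, j] / math.pi) / (
                eps**2 + phi[i, j] ** 2) ** 2
            grad[i, j] += nu * dd * mag
            # chain through gx: ∂gx/∂φ[i,jp] = +0.5, ∂gx/∂φ[i,jm] = −0.5
            grad[i, jp] += nu * w * gx / mag * 0.5
            grad[i, jm] -= nu * w * gx / mag * 0.5
            grad[ip, j] += nu * w * gy / mag * 0.5
            grad[im, j] -= nu * w * gy / mag * 0.5
    return grad


_GRAD_EPS = 0.05  # matches the implementation's length-density smoothing


def pooled_t(a, b):
    """Two-sample pooled-variance t statistic, hand formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
        na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def permutation_ts(a, b):
    """t statistics of every label permutation (exhaustive)."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n = len(a)
    ts = []
    for idx in combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        ts.append(pooled_t(ga, gb))
    return np.array(ts)
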