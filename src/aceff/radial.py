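"""Radial basis machinery: transform, cutoff envelopes, orthogonal polynomials.

The distance-dependent part of the one-particle basis is

    R_n(r) = p_n(x(r)) * f_cut(r) / N_n ,        n = 1 .. n_max,

with a monotone radial transform r -> x(r) that amplifies the resolution close
to the central atom, a C^1 cutoff envelope f_cut with both an *inner* and an
*outer* cutoff, and polynomials p_n built so that the resulting R_n (not the
p_n themselves) are orthonormal in x-coordinates.  The seeds of the polynomial
family are pinned: p_0(x) = 1, p_1(x) = x.

The transform used here is

    x(r) = ((1 + r0) / (1 + r))**p        (default p = 2)

which is strictly decreasing, finite at r = 0 and steepest at small r.  The
multibody envelope is the two-sided quartic

    f_cut(r) = [ (r - r_in)(r_out - r) ]^2 * (2/(r_out - r_in))^4

on [r_in, r_out] and 0 outside; value and first derivative vanish at both
cutoffs.  The auxiliary *pair* basis (which carries short-range repulsion)
reuses the same construction with the one-sided envelope

    f_pair(r) = ((r_out - r)/r_out)^2     for r < r_out, else 0,

which is nonzero as r -> 0.

Orthogonalization is numerical: Gram-Schmidt of x * p_{n-1} against the
previously accepted members under the weighted inner product
<f, g> = ∫ f(x) g(x) f_cut(r(x))^2 dx evaluated with a fixed Gauss-Legendre
rule (default 2000 points), using the analytic inverse r(x).  The constant
p_0 is not itself a member of the radial basis; orthogonality is enforced
among n >= 1 only, which is what lets p_1 = x hold exactly alongside an
identity Gram matrix for {R_n}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as L

__all__ = [
    "RadialSpec",
    "OrthogonalPolynomialSet",
    "radial_transform",
    "radial_transform_derivative",
    "inverse_radial_transform",
    "cutoff_envelope",
    "cutoff_envelope_derivative",
    "pair_cutoff_envelope",
    "pair_cutoff_envelope_derivative",
    "build_orthogonal_polynomials",
    "evaluate_radial_basis",
]


@dataclass(frozen=True)
class RadialSpec:
    """Parameters of the radial channel.

    r_in / r_out are the inner and outer cutoffs in Angstrom; n_max the number
    of radial functions; transform_params = (p, r0) the exponent and length
    scale of the radial transform; envelope_params the (inner, outer) envelope
    exponents; quadrature_points the Gauss-Legendre count used for
    orthogonalization.
    """

    r_in: float = 0.8
    r_out: float = 5.0
    n_max: int = 6
    transform_params: tuple[float, float] = (2.0, 2.5)
    envelope_params: tuple[int, int] = (2, 2)
    quadrature_points: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 < self.r_in < self.r_out):
            raise ValueError("require 0 < r_in < r_out")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.quadrature_points < 4 * self.n_max:
            raise ValueError("quadrature_points must be >= 4 * n_max")

    def to_dict(self) -> dict:
        return {
            "r_in": self.r_in,
            "r_out": self.r_out,
            "n_max": self.n_max,
            "transform_params": list(self.transform_params),
            "envelope_params": list(self.envelope_params),
            "quadrature_points": self.quadrature_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadialSpec":
        return cls(
            r_in=d["r_in"],
            r_out=d["r_out"],
            n_max=d["n_max"],
            transform_params=tuple(d["transform_params"]),
            envelope_params=tuple(d["envelope_params"]),
            quadrature_points=d["quadrature_points"],
        )


def _check_r(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0):
        raise ValueError("distance r must be >= 0")
    return r


def radial_transform(r, spec: RadialSpec):
    """x(r) = ((1 + r0)/(1 + r))**p; strictly decreasing on r >= 0."""
    r = _check_r(r)
    p, r0 = spec.transform_params
    return ((1.0 + r0) / (1.0 + r)) ** p


def radial_transform_derivative(r, spec: RadialSpec):
    r = _check_r(r)
    p, r0 = spec.transform_params
    return -p * (1.0 + r0) ** p * (1.0 + r) ** (-p - 1.0)


def inverse_radial_transform(x, spec: RadialSpec):
    """Analytic inverse r(x) of the transform."""
    p, r0 = spec.transform_params
    x = np.asarray(x, dtype=float)
    return (1.0 + r0) * x ** (-1.0 / p) - 1.0


def cutoff_envelope(r, spec: RadialSpec):
    """Two-sided C^1 envelope: zero (with zero slope) at r_in and r_out,
    identically zero outside [r_in, r_out], peak value 1 at the midpoint."""
    r = np.asarray(r, dtype=float)
    a, b = spec.envelope_params
    h = 0.5 * (spec.r_out - spec.r_in)
    scale = h ** (-(a + b))
    inside = (r > spec.r_in) & (r < spec.r_out)
    out = np.zeros_like(r)
    ri = np.where(inside, r, 0.5 * (spec.r_in + spec.r_out))
    out = np.where(
        inside, scale * (ri - spec.r_in) ** a * (spec.r_out - ri) ** b, out
    )
    return out


def cutoff_envelope_derivative(r, spec: RadialSpec):
    r = np.asarray(r, dtype=float)
    a, b = spec.envelope_params
    h = 0.5 * (spec.r_out - spec.r_in)
    scale = h ** (-(a + b))
    inside = (r > spec.r_in) & (r < spec.r_out)
    ri = np.where(inside, r, 0.5 * (spec.r_in + spec.r_out))
    u = ri - spec.r_in
    v = spec.r_out - ri
    d = scale * (a * u ** (a - 1) * v ** b - b * u ** a * v ** (b - 1))
    return np.where(inside, d, 0.0)


def pair_cutoff_envelope(r, spec: RadialSpec):
    """One-sided envelope for the auxiliary two-body basis: no inner cutoff
    (nonzero as r -> 0, so the pair basis can carry short-range repulsion),
    zero with zero slope at r_out."""
    r = np.asarray(r, dtype=float)
    b = spec.envelope_params[1]
    inside = r < spec.r_out
    ri = np.where(inside, r, spec.r_out)
    return np.where(inside, ((spec.r_out - ri) / spec.r_out) ** b, 0.0)


def pair_cutoff_envelope_derivative(r, spec: RadialSpec):
    r = np.asarray(r, dtype=float)
    b = spec.envelope_params[1]
    inside = r < spec.r_out
    ri = np.where(inside, r, spec.r_out)
    return np.where(
        inside, -b / spec.r_out * ((spec.r_out - ri) / spec.r_out) ** (b - 1), 0.0
    )


@dataclass(frozen=True)
class OrthogonalPolynomialSet:
    """Polynomials p_0..p_degree_max stored as Legendre series on the
    transform interval [x_lo, x_hi], plus per-degree normalization constants
    N_n = ||p_n * f_cut||  (weighted L2 norm) so that R_n = p_n f_cut / N_n
    form an orthonormal set for n >= 1."""

    degree_max: int
    domain: tuple[float, float]
    coefficients: tuple[tuple[float, ...], ...]  # Legendre coefs per degree
    norms: tuple[float, ...]
    pair: bool = False

    def eval_p(self, n: int, x):
        c = np.asarray(self.coefficients[n])
        return L.legval(self._map(x), c)

    def eval_dp(self, n: int, x):
        c = np.asarray(self.coefficients[n])
        dc = L.legder(c) if len(c) > 1 else np.zeros(1)
        xm = self._map(x)
        return L.legval(xm, dc) * (2.0 / (self.domain[1] - self.domain[0]))

    def eval_all(self, x):
        """Values and x-derivatives of p_1..p_degree_max, stacked (n, ...)."""
        vals = [self.eval_p(n, x) for n in range(1, self.degree_max + 1)]
        ders = [self.eval_dp(n, x) for n in range(1, self.degree_max + 1)]
        return np.stack(vals), np.stack(ders)

    def _map(self, x):
        lo, hi = self.domain
        return (2.0 * np.asarray(x, dtype=float) - (lo + hi)) / (hi - lo)

    def to_dict(self) -> dict:
        return {
            "degree_max": self.degree_max,
            "domain": list(self.domain),
            "coefficients": [list(c) for c in self.coefficients],
            "norms": list(self.norms),
            "pair": self.pair,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrthogonalPolynomialSet":
        return cls(
            degree_max=d["degree_max"],
            domain=tuple(d["domain"]),
            coefficients=tuple(tuple(c) for c in d["coefficients"]),
            norms=tuple(d["norms"]),
            pair=d["pair"],
        )


def build_orthogonal_polynomials(
    spec: RadialSpec, pair: bool = False, degree_max: int | None = None
) -> OrthogonalPolynomialSet:
    """Construct p_0 = 1, p_1 = x and higher degrees by (twice-iterated)
    Gram-Schmidt of x * p_{n-1} against p_1..p_{n-1} under the measure
    f_cut(r(x))^2 dx, so that the composed radial functions are orthonormal.

    With ``pair=True`` the one-sided pair envelope defines both the weight and
    the x-interval (which then extends to x(0))."""
    degree_max = spec.n_max if degree_max is None else degree_max
    if pair:
        x_lo = float(radial_transform(spec.r_out, spec))
        x_hi = float(radial_transform(0.0, spec))
        weight_fn = lambda r: pair_cutoff_envelope(r, spec)  # noqa: E731
    else:
        x_lo = float(radial_transform(spec.r_out, spec))
        x_hi = float(radial_transform(spec.r_in, spec))
        weight_fn = lambda r: cutoff_envelope(r, spec)  # noqa: E731

    nodes, wts = np.polynomial.legendre.leggauss(spec.quadrature_points)
    xq = 0.5 * (x_hi - x_lo) * nodes + 0.5 * (x_hi + x_lo)
    wq = 0.5 * (x_hi - x_lo) * wts
    rq = inverse_radial_transform(xq, spec)
    W = weight_fn(rq) ** 2
    if not np.any(W > 0.0) or float(np.sum(W * wq)) <= 0.0:
        raise ValueError("degenerate measure: cutoff envelope vanishes on interval")

    # work on the mapped variable t in [-1, 1]; x = mid + half*t
    half = 0.5 * (x_hi - x_lo)
    mid = 0.5 * (x_hi + x_lo)
    tq = (xq - mid) / half

    def inner(ca, cb):
        return float(np.sum(L.legval(tq, ca) * L.legval(tq, cb) * W * wq))

    # p_0 = 1 and p_1 = x in the original variable, expressed on t
    coefs: list[np.ndarray] = [np.array([1.0]), np.array([mid, half])]
    for n in range(2, degree_max + 1):
        # x * p_{n-1} on the mapped variable: x = mid + half * t
        cand = L.legadd(L.legmulx(coefs[n - 1]) * half, coefs[n - 1] * mid)
        for _ in range(2):  # re-orthogonalize for stability
            for k in range(1, n):
                proj = inner(cand, coefs[k]) / inner(coefs[k], coefs[k])
                cand = L.legadd(cand, -proj * np.asarray(coefs[k]))
        nrm2 = inner(cand, cand)
        if not nrm2 > 0.0:
            raise ValueError("quadrature-rank failure during orthogonalization")
        coefs.append(np.asarray(cand))

    norms = [1.0]
    for n in range(1, degree_max + 1):
        norms.append(float(np.sqrt(inner(coefs[n], coefs[n]))))

    return OrthogonalPolynomialSet(
        degree_max=degree_max,
        domain=(x_lo, x_hi),
        coefficients=tuple(tuple(float(v) for v in c) for c in coefs),
        norms=tuple(norms),
        pair=pair,
    )


def evaluate_radial_basis(r, spec: RadialSpec, polys: OrthogonalPolynomialSet):
    """Values R_n(r) and analytic derivatives dR_n/dr, n = 1..degree_max.

    Returns arrays of shape (degree_max,) for scalar r, or
    (degree_max, len(r)) for array input.  Exactly zero beyond r_out.
    """
    r_arr = _check_r(np.atleast_1d(r))
    scalar = np.isscalar(r) or np.ndim(r) == 0

    if polys.pair:
        f = pair_cutoff_envelope(r_arr, spec)
        df = pair_cutoff_envelope_derivative(r_arr, spec)
    else:
        f = cutoff_envelope(r_arr, spec)
        df = cutoff_envelope_derivative(r_arr, spec)

    inside = r_arr < spec.r_out
    x = radial_transform(np.where(inside, r_arr, 0.0), spec)
    dxdr = radial_transform_derivative(np.where(inside, r_arr, 0.0), spec)
    pvals, pders = polys.eval_all(x)
    nrm = np.asarray(polys.norms[1:])[:, None]
    R = np.where(inside, pvals * f / nrm, 0.0)
    dR = np.where(inside, (pders * dxdr * f + pvals * df) / nrm, 0.0)
    if scalar:
        return R[:, 0], dR[:, 0]
    return R, dR
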